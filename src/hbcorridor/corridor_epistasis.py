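"""Neutral-corridor classification of genotypes and pathways; sign epistasis.

The *neutral corridor* for a trait is the interval spanned by the outer 95%
confidence limits of the ancestral and descendant genotypes.  Intermediate
genotypes whose trait value falls outside the corridor are putatively
selectively disfavored, and any forward pathway forced through such an
intermediate is classed inaccessible.  The default trait is P50 measured in
the simultaneous presence of KCl and IHP, the condition closest to the
in vivo red-cell environment.

Sign epistasis is diagnosed from the full landscape: for each site, the
effect of the substitution (difference of ln P50) is computed on every one
of the 2**(n−1) backgrounds; a site shows sign epistasis when the effect is
significantly positive on some background and significantly negative on
another.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .genotype_space import Pathway, SitePanel, build_space
from .oxygen_equilibrium import PhenotypeRecord

# genotype statuses relative to the corridor
WITHIN = "within"
MARGINALLY_BELOW = "marginally_below"
STRICTLY_BELOW = "strictly_below"
MARGINALLY_ABOVE = "marginally_above"
STRICTLY_ABOVE = "strictly_above"

# pathway statuses
ACCESSIBLE = "accessible"
MARGINAL = "marginal"
INACCESSIBLE = "inaccessible"

_STRICT = {STRICTLY_BELOW, STRICTLY_ABOVE}
_MARGINAL = {MARGINALLY_BELOW, MARGINALLY_ABOVE}


@dataclass(frozen=True)
class Corridor:
    """Trait interval between the outer confidence limits of the endpoints."""

    trait: str
    treatment: str
    floor: float
    ceiling: float
    ancestor_label: str
    descendant_label: str
    direction: str  # "increasing" | "decreasing" | "degenerate"

    def __post_init__(self) -> None:
        if not self.floor < self.ceiling:
            raise ValueError(f"corridor floor {self.floor} must be < ceiling {self.ceiling}")


@dataclass(frozen=True)
class GenotypeVerdict:
    genotype_label: str
    status: str
    distance_to_bound: float


@dataclass(frozen=True)
class PathwayVerdict:
    pathway: Pathway
    status: str
    limiting_genotypes: tuple[str, ...]


@dataclass(frozen=True)
class MutationEffect:
    """Effect of one substitution on one background, on the ln P50 scale."""

    site_index: int
    site_label: str
    background_label: str
    mutant_label: str
    delta: float
    se_delta: float
    sign: str  # "positive" | "negative" | "indistinguishable"


@dataclass(frozen=True)
class SignEpistasisReport:
    site_index: int
    site_label: str
    flagged: bool
    positive_backgrounds: tuple[str, ...]
    negative_backgrounds: tuple[str, ...]

    @property
    def witnesses(self) -> tuple[tuple[str, str], ...]:
        """(negative background, positive background) pairs proving sign flips."""
        return tuple(
            (n, p) for n in self.negative_backgrounds for p in self.positive_backgrounds
        )


def build_corridor(
    ancestor: PhenotypeRecord, descendant: PhenotypeRecord, trait: str = "P50"
) -> Corridor:
    """Corridor from the endpoint records' 95% confidence limits.

    floor = min of the two CI lower limits, ceiling = max of the upper
    limits; the direction of the evolved change is the sign of
    (descendant mean − ancestor mean), "degenerate" when the means tie.
    """
    if ancestor.treatment != descendant.treatment:
        raise ValueError(
            f"treatment mismatch: {ancestor.treatment!r} vs {descendant.treatment!r}"
        )
    floor = min(ancestor.ci95[0], descendant.ci95[0])
    ceiling = max(ancestor.ci95[1], descendant.ci95[1])
    diff = descendant.p50_mean - ancestor.p50_mean
    direction = "degenerate" if diff == 0 else ("increasing" if diff > 0 else "decreasing")
    return Corridor(
        trait=trait, treatment=ancestor.treatment, floor=floor, ceiling=ceiling,
        ancestor_label=ancestor.genotype_label,
        descendant_label=descendant.genotype_label, direction=direction,
    )


def classify_interval(
    mean: float,
    ci: tuple[float, float],
    corridor: Corridor,
    marginal_rule: str = "ci_overlap",
    epsilon: float = 0.05,
) -> tuple[str, float]:
    """Classify a (mean, 95% CI) trait estimate against the corridor.

    Under the default ``"ci_overlap"`` rule, strictly outside requires the
    estimate's own CI to exclude the bound; a mean beyond the bound whose CI
    still straddles it is marginal.  The alternative ``"epsilon"`` rule also
    calls marginal when the CI clears the bound by less than
    ``epsilon``·(corridor width).  Works on arbitrary real trait values (no
    positivity assumed), which makes the classification equivariant under
    trait negation.
    """
    if marginal_rule not in ("ci_overlap", "epsilon"):
        raise ValueError(f"unknown marginal rule {marginal_rule!r}")
    lo, hi = ci
    width = corridor.ceiling - corridor.floor
    slack = epsilon * width if marginal_rule == "epsilon" else 0.0
    if hi < corridor.floor - slack:
        return STRICTLY_BELOW, corridor.floor - mean
    if lo > corridor.ceiling + slack:
        return STRICTLY_ABOVE, mean - corridor.ceiling
    if mean < corridor.floor:
        return MARGINALLY_BELOW, corridor.floor - mean
    if mean > corridor.ceiling:
        return MARGINALLY_ABOVE, mean - corridor.ceiling
    return WITHIN, min(mean - corridor.floor, corridor.ceiling - mean)


def classify_genotype(
    record: PhenotypeRecord,
    corridor: Corridor,
    marginal_rule: str = "ci_overlap",
    epsilon: float = 0.05,
) -> GenotypeVerdict:
    """Corridor verdict for one genotype's summary record."""
    if record.treatment != corridor.treatment:
        raise ValueError(
            f"record treatment {record.treatment!r} differs from corridor "
            f"treatment {corridor.treatment!r}"
        )
    status, dist = classify_interval(
        record.p50_mean, record.ci95, corridor, marginal_rule, epsilon
    )
    return GenotypeVerdict(
        genotype_label=record.genotype_label, status=status, distance_to_bound=dist
    )


def classify_pathways(
    pathways: Sequence[Pathway],
    records: Mapping[str, PhenotypeRecord],
    corridor: Corridor,
) -> tuple[list[PathwayVerdict], Counter]:
    """Accessibility verdict for every forward pathway, plus summary counts.

    A pathway is inaccessible when ≥1 intermediate is strictly outside the
    corridor, marginal when none is strict but ≥1 is marginally outside,
    and accessible otherwise.  Endpoints are never judged.
    """
    verdict_cache: dict[str, GenotypeVerdict] = {}

    def verdict_for(label: str) -> GenotypeVerdict:
        if label not in verdict_cache:
            if label not in records:
                raise KeyError(f"no phenotype record for genotype {label!r}")
            verdict_cache[label] = classify_genotype(records[label], corridor)
        return verdict_cache[label]

    out: list[PathwayVerdict] = []
    counts: Counter = Counter()
    for path in pathways:
        strict, marginal = [], []
        for g in path.intermediates:
            v = verdict_for(g.label)
            if v.status in _STRICT:
                strict.append(g.label)
            elif v.status in _MARGINAL:
                marginal.append(g.label)
        if strict:
            status, limiting = INACCESSIBLE, strict
        elif marginal:
            status, limiting = MARGINAL, marginal
        else:
            status, limiting = ACCESSIBLE, []
        out.append(PathwayVerdict(pathway=path, status=status,
                                  limiting_genotypes=tuple(limiting)))
        counts[status] += 1
    for status in (ACCESSIBLE, MARGINAL, INACCESSIBLE):
        counts.setdefault(status, 0)
    return out, counts


def classify_landscape(
    records: Mapping[str, PhenotypeRecord], corridor: Corridor
) -> dict[str, GenotypeVerdict]:
    """Corridor verdicts for every genotype in the record table."""
    return {lbl: classify_genotype(rec, corridor) for lbl, rec in records.items()}


def mutation_effects(
    records: Mapping[str, PhenotypeRecord],
    panel: SitePanel,
    treatment: str | None = None,
    z_star: float = 1.96,
) -> list[MutationEffect]:
    """Per-background substitution effects on ln P50 for every site.

    For site *i* and each of the 2**(n−1) backgrounds *b* lacking the derived
    allele at *i*: delta = ln P50(b + i) − ln P50(b), with the delta-method
    SE sqrt((se/p50)² + (se/p50)²).  The sign is called positive/negative
    when |delta|/SE exceeds ``z_star`` (with SE = 0, any nonzero delta is
    called); otherwise indistinguishable.
    """
    space = build_space(panel)
    missing = [g.label for g in space.genotypes if g.label not in records]
    if missing:
        raise KeyError(f"incomplete landscape; missing records for {sorted(missing)}")
    if treatment is not None:
        bad = [lbl for lbl, r in records.items() if r.treatment != treatment]
        if bad:
            raise ValueError(f"records not in treatment {treatment!r}: {sorted(bad)}")
    effects: list[MutationEffect] = []
    n = panel.n_sites
    for pos in range(n):
        site = panel.sites[pos]
        for g in space.genotypes:
            if g.states[pos]:
                continue  # backgrounds lack the derived allele at this site
            mutant_states = list(g.states)
            mutant_states[pos] = True
            mutant = panel.genotype(mutant_states)
            rb, rm = records[g.label], records[mutant.label]
            delta = math.log(rm.p50_mean) - math.log(rb.p50_mean)
            se = math.sqrt(
                (rm.p50_se / rm.p50_mean) ** 2 + (rb.p50_se / rb.p50_mean) ** 2
            )
            if se > 0:
                significant = abs(delta) / se > z_star
            else:
                significant = abs(delta) > 1e-12
            if not significant:
                sign = "indistinguishable"
            else:
                sign = "positive" if delta > 0 else "negative"
            effects.append(MutationEffect(
                site_index=site.index, site_label=site.label,
                background_label=g.label, mutant_label=mutant.label,
                delta=delta, se_delta=se, sign=sign,
            ))
    return effects


def detect_sign_epistasis(effects: Iterable[MutationEffect]) -> list[SignEpistasisReport]:
    """Flag sites whose substitution effect flips sign across backgrounds."""
    by_site: dict[int, list[MutationEffect]] = {}
    for e in effects:
        by_site.setdefault(e.site_index, []).append(e)
    reports = []
    for site_index in sorted(by_site):
        es = by_site[site_index]
        pos = tuple(e.background_label for e in es if e.sign == "positive")
        neg = tuple(e.background_label for e in es if e.sign == "negative")
        reports.append(SignEpistasisReport(
            site_index=site_index, site_label=es[0].site_label,
            flagged=bool(pos) and bool(neg),
            positive_backgrounds=pos, negative_backgrounds=neg,
        ))
    return reports
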