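"""Seeded generators for every input the pipeline consumes.

Three generators are provided:

* :func:`generate_curve` — Hill-shaped O₂ saturation curves with Gaussian
  replicate noise on the saturation axis;
* :func:`generate_landscape_fixture` — a complete 2**n × 4-treatment table
  of phenotype records for the four-site nightjar hemoglobin panel.  The
  endpoint values are anchored to the measured native isoforms (ancestral
  GVAI ≡ the high-affinity highland HbA, derived SIVV ≡ the low-affinity
  lowland HbA); interior genotypes ramp between them.  Three genotypes
  (SIAI, SVAV, SIVI) are planted far below the neutral-corridor floor and
  one (GIAV) just below it, reproducing the qualitative accessibility
  structure of the measured landscape.  The interior values are *synthetic
  stand-ins*: the measured per-genotype values for the 14 intermediate
  recombinant hemoglobins are not public and are not reproduced here.
* :func:`generate_elution_fixture` — gel-filtration marker and sample
  elution volumes consistent with a known log-linear calibration.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .genotype_space import MutationSite, SitePanel, build_space, decode_label
from .oxygen_equilibrium import (
    EquilibriumCurve,
    PhenotypeRecord,
    TREATMENTS,
    ci95_of_mean,
    hill_saturation,
)
from .quaternary_structure import fit_elution_calibration

#: The four-substitution hemoglobin panel: three α-chain sites, one β-chain.
DEFAULT_PANEL = SitePanel((
    MutationSite(1, "G", "S", "Gα4S", "alphaA position 4"),
    MutationSite(2, "V", "I", "Vα13I", "alphaA position 13"),
    MutationSite(3, "A", "V", "Aα34V", "alphaA position 34"),
    MutationSite(4, "I", "V", "Iβ112V", "betaA position 112"),
))

#: Endpoint anchors per treatment: (ancestor P50, descendant P50,
#: ancestor SE, descendant SE, ancestor n50, descendant n50).  These are the
#: measured values for the native high-altitude (ancestral-identical) and
#: low-altitude (derived-identical) HbA isoforms.
DEFAULT_ANCHORS: dict[str, tuple[float, float, float, float, float, float]] = {
    "stripped": (2.48, 2.77, 0.03, 0.02, 1.77, 1.87),
    "KCl": (3.73, 4.24, 0.04, 0.04, 1.97, 2.12),
    "IHP": (43.55, 50.38, 1.06, 1.64, 2.35, 2.01),
    "KCl_IHP": (30.21, 36.12, 0.82, 1.30, 2.29, 2.13),
}

#: Treatments in which the dissociation-prone genotypes lose their effector
#: response (P50 collapses); stripped/KCl affinities are barely perturbed.
_EFFECTOR_TREATMENTS = ("IHP", "KCl_IHP")


@dataclass(frozen=True)
class LandscapeSpec:
    """Specification of the synthetic genotype × treatment landscape.

    ``strict_p50`` plants the flagged genotypes' effector-treatment P50 far
    below the corridor floor; the marginal genotype is planted one ancestral
    SE below the floor (computed from the spec's own CI method), so its mean
    is outside the corridor while its CI still straddles the floor.
    """

    panel: SitePanel = DEFAULT_PANEL
    anchors: Mapping[str, tuple[float, float, float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ANCHORS)
    )
    flagged_strict: tuple[str, ...] = ("SIAI", "SVAV", "SIVI")
    flagged_marginal: tuple[str, ...] = ("GIAV",)
    strict_p50: Mapping[str, float] = field(
        default_factory=lambda: {"IHP": 14.0, "KCl_IHP": 12.0}
    )
    strict_se: float = 0.5
    replicate_count: int = 3
    jitter_scale: float = 0.15  # fraction of |descendant − ancestor| per treatment
    seed: int = 0
    ci_method: str = "t"

    def __post_init__(self) -> None:
        endpoints = {self.panel.ancestral.label, self.panel.derived.label}
        for lbl in (*self.flagged_strict, *self.flagged_marginal):
            g = decode_label(lbl, self.panel)  # validates the label
            if g.label in endpoints:
                raise ValueError(f"flagged genotype {lbl!r} is a pathway endpoint")
        missing = [t for t in TREATMENTS if t not in self.anchors]
        if missing:
            raise ValueError(f"anchors missing treatments: {missing}")


@dataclass(frozen=True)
class LandscapeFixture:
    """Complete record table plus the spec that generated it."""

    spec: LandscapeSpec
    records: tuple[PhenotypeRecord, ...]

    def records_for(self, treatment: str) -> dict[str, PhenotypeRecord]:
        return {r.genotype_label: r for r in self.records if r.treatment == treatment}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "genotype_label": r.genotype_label,
                "treatment": r.treatment,
                "p50_mean": r.p50_mean,
                "p50_se": r.p50_se,
                "n50_mean": r.n50_mean,
                "n50_se": r.n50_se,
                "n_replicates": r.n_replicates,
                "ci_lo": r.ci95[0],
                "ci_hi": r.ci95[1],
            }
            for r in self.records
        )


def generate_landscape_fixture(spec: LandscapeSpec | None = None) -> LandscapeFixture:
    """Build the full 2**n × 4 phenotype-record table for the spec.

    Interior genotype means ramp linearly (in Hamming distance) between the
    endpoint anchors with small seeded jitter (clipped at ±2 jitter SD so the
    planted corridor pattern cannot be disturbed); flagged genotypes override
    the ramp in the effector treatments.
    """
    spec = spec or LandscapeSpec()
    panel = spec.panel
    n = panel.n_sites
    rng = np.random.default_rng(spec.seed)
    space = build_space(panel)
    anc_label = panel.ancestral.label
    desc_label = panel.derived.label
    k = spec.replicate_count

    records: list[PhenotypeRecord] = []
    for treatment in TREATMENTS:
        a_p50, d_p50, a_se, d_se, a_n50, d_n50 = spec.anchors[treatment]
        span = d_p50 - a_p50
        floor = min(
            ci95_of_mean(a_p50, a_se, k, spec.ci_method)[0],
            ci95_of_mean(d_p50, d_se, k, spec.ci_method)[0],
        )
        for g in space.genotypes:
            d = g.hamming_from_ancestral
            frac = d / n
            se = a_se + frac * (d_se - a_se)
            n50 = a_n50 + frac * (d_n50 - a_n50)
            if g.label == anc_label:
                p50 = a_p50
            elif g.label == desc_label:
                p50 = d_p50
            elif treatment in _EFFECTOR_TREATMENTS and g.label in spec.flagged_strict:
                p50 = spec.strict_p50[treatment]
                se = spec.strict_se
                n50 = 1.1  # dissociated dimers: cooperativity lost
            elif treatment in _EFFECTOR_TREATMENTS and g.label in spec.flagged_marginal:
                p50 = floor - a_se
                se = a_se
            else:
                jitter_sd = spec.jitter_scale * abs(span)
                jitter = float(np.clip(rng.normal(0.0, 1.0), -2.0, 2.0)) * jitter_sd
                p50 = a_p50 + frac * span + jitter
            n50_jit = n50 + float(np.clip(rng.normal(0.0, 1.0), -2.0, 2.0)) * 0.05
            records.append(PhenotypeRecord(
                genotype_label=g.label, treatment=treatment,
                p50_mean=p50, p50_se=se, n50_mean=n50_jit, n50_se=0.1,
                n_replicates=k,
                ci95=ci95_of_mean(p50, se, k, spec.ci_method),
            ))
    return LandscapeFixture(spec=spec, records=tuple(records))


def generate_curve(
    p50: float,
    n: float,
    po2_grid,
    sigma_y: float = 0.0,
    seed: int = 0,
    genotype_label: str = "synthetic",
    treatment: str = "stripped",
    replicate: int = 1,
) -> EquilibriumCurve:
    """Hill-shaped saturation curve with Gaussian noise on Y, truncated to [0, 1].

    ``sigma_y = 0`` returns exact Hill points; the same seed always returns
    the identical curve.
    """
    po2 = np.asarray(list(po2_grid), dtype=float)
    if po2.size == 0:
        raise ValueError("po2_grid is empty")
    if sigma_y < 0:
        raise ValueError("sigma_y must be ≥0")
    y = hill_saturation(po2, p50, n)
    if sigma_y > 0:
        rng = np.random.default_rng(seed)
        y = np.clip(y + rng.normal(0.0, sigma_y, size=po2.shape), 0.0, 1.0)
    return EquilibriumCurve(
        genotype_label=genotype_label, treatment=treatment, replicate=replicate,
        po2=tuple(po2), saturation=tuple(np.asarray(y, dtype=float)),
    )


@dataclass(frozen=True)
class ElutionFixture:
    """Synthetic gel-filtration markers and samples with known true MWs."""

    markers: tuple[tuple[str, float, float], ...]  # (name, mw_kda, elution_ml)
    samples: tuple[tuple[str, float, float], ...]  # (label, elution_ml, true_mw_kda)
    seed: int


def generate_elution_fixture(seed: int = 0, noise_sd_ml: float = 0.0) -> ElutionFixture:
    """Markers (Mb ≈17 kDa, human Hb ≈64.5 kDa) plus samples at tetramer,
    intermediate, and near-dimer positions on a log-linear column calibration.

    Sample volumes are generated by inverting the marker line at each true
    MW (optionally with Gaussian volume noise), so a noiseless fixture
    round-trips exactly through ``apparent_mw``.
    """
    # marker anchor volumes chosen for a small analytical SEC column
    markers = (("Mb", 17.0, 13.5), ("human_Hb", 64.5, 10.5))
    cal = fit_elution_calibration(markers)
    rng = np.random.default_rng(seed)

    def volume_for(mw: float) -> float:
        v = (np.log10(mw) - cal.intercept) / cal.slope
        if noise_sd_ml > 0:
            v += rng.normal(0.0, noise_sd_ml)
        return float(v)

    # SIVV assembles as an intact tetramer; the three dissociation-prone
    # genotypes sit between the tetramer (64.5) and dimer (32.25) masses
    true_mws = {"SIVV": 62.0, "SIAI": 42.0, "SVAV": 46.0, "SIVI": 40.0}
    samples = tuple(
        (label, volume_for(mw), mw) for label, mw in sorted(true_mws.items())
    )
    return ElutionFixture(markers=markers, samples=samples, seed=seed)
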