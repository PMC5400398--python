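"""End-to-end orchestration: inputs → corridor → verdicts → reports.

A :class:`RunConfig` names the input mode (synthetic fixture, summary table,
or raw curves), the treatment used for accessibility, and the statistical
conventions (CI method, significance threshold, marginal rule).  A run is
deterministic given the config and seed; the report records a hash of the
config, the seed, and the package version so results can be reproduced.
"""

from __future__ import annotations

import hashlib
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .corridor_epistasis import (
    Corridor, GenotypeVerdict, PathwayVerdict, SignEpistasisReport,
    build_corridor, classify_landscape, classify_pathways,
    detect_sign_epistasis, mutation_effects,
)
from .genotype_space import SitePanel, build_space, enumerate_pathways
from .io import (
    export_hypercube_dot, read_summary, write_epistasis_json,
    write_pathway_tsv, write_records_csv,
)
from .oxygen_equilibrium import (
    PhenotypeRecord, aggregate_replicates, fit_hill_nonlinear, normalize_treatment,
)
from .synthetic_data import DEFAULT_PANEL, LandscapeFixture, LandscapeSpec, \
    generate_landscape_fixture

#: The two dynamics assumptions under which pathway accessibility is judged.
ASSUMPTIONS = (
    "mutations are fixed sequentially on otherwise invariant genetic backgrounds",
    "once a mutation is fixed it does not later revert to the ancestral state",
)


@dataclass(frozen=True)
class RunConfig:
    mode: str = "fixture"  # "fixture" | "summary" | "curves"
    input_path: str | None = None
    panel: SitePanel = DEFAULT_PANEL
    treatment: str = "KCl_IHP"
    ci_method: str = "t"
    z_star: float = 1.96
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "treatment", normalize_treatment(self.treatment))
        if self.mode not in ("fixture", "summary", "curves"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode != "fixture":
            if self.input_path is None:
                raise ValueError(f"mode {self.mode!r} requires input_path")
            if not Path(self.input_path).exists():
                raise FileNotFoundError(self.input_path)

    def hash(self) -> str:
        payload = {
            "mode": self.mode, "input_path": self.input_path,
            "treatment": self.treatment, "ci_method": self.ci_method,
            "z_star": self.z_star, "seed": self.seed,
            "panel": [
                (s.index, s.ancestral_aa, s.derived_aa, s.label)
                for s in self.panel.sites
            ],
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass(frozen=True)
class RunReport:
    corridor: Corridor
    genotype_verdicts: dict[str, GenotypeVerdict]
    pathway_verdicts: tuple[PathwayVerdict, ...]
    summary_counts: Counter
    epistasis: tuple[SignEpistasisReport, ...]
    assumptions: tuple[str, ...]
    provenance: dict

    def __post_init__(self) -> None:
        n_paths = sum(self.summary_counts.values())
        if n_paths != len(self.pathway_verdicts):
            raise ValueError("summary counts do not sum to the number of pathways")


def _records_from_config(config: RunConfig) -> dict[str, PhenotypeRecord]:
    if config.mode == "fixture":
        fixture = generate_landscape_fixture(
            LandscapeSpec(panel=config.panel, seed=config.seed,
                          ci_method=config.ci_method)
        )
        return fixture.records_for(config.treatment)
    if config.mode == "summary":
        by_treatment = read_summary(config.input_path)
        if config.treatment not in by_treatment:
            raise ValueError(
                f"no records for treatment {config.treatment!r} in {config.input_path}"
            )
        return by_treatment[config.treatment]
    # raw curves: fit each replicate, aggregate per genotype
    from .io import read_curves

    curves = read_curves(config.input_path)
    grouped: dict[str, list] = {}
    for c in curves:
        if c.treatment == config.treatment:
            grouped.setdefault(c.genotype_label, []).append(c)
    return {
        label: aggregate_replicates(
            [fit_hill_nonlinear(c) for c in cs], ci_method=config.ci_method
        )
        for label, cs in grouped.items()
    }


def run_pipeline(config: RunConfig) -> RunReport:
    """Run the full accessibility analysis and (optionally) write artifacts."""
    panel = config.panel
    records = _records_from_config(config)
    space = build_space(panel)
    missing = [g.label for g in space.genotypes if g.label not in records]
    if missing:
        raise KeyError(
            f"landscape incomplete for treatment {config.treatment!r}; "
            f"missing genotypes: {sorted(missing)}"
        )
    anc, desc = panel.ancestral.label, panel.derived.label
    corridor = build_corridor(records[anc], records[desc])
    genotype_verdicts = classify_landscape(records, corridor)
    pathways = enumerate_pathways(panel)
    pathway_verdicts, counts = classify_pathways(pathways, records, corridor)
    effects = mutation_effects(records, panel, treatment=config.treatment,
                               z_star=config.z_star)
    epistasis = detect_sign_epistasis(effects)
    report = RunReport(
        corridor=corridor,
        genotype_verdicts=genotype_verdicts,
        pathway_verdicts=tuple(pathway_verdicts),
        summary_counts=counts,
        epistasis=tuple(epistasis),
        assumptions=ASSUMPTIONS,
        provenance={
            "config_hash": config.hash(),
            "seed": config.seed,
            "version": __version__,
            "mode": config.mode,
            "treatment": config.treatment,
            "ci_method": config.ci_method,
            "z_star": config.z_star,
        },
    )
    if config.out_dir is not None:
        _write_artifacts(report, records, space, config)
    return report


def report_to_json(report: RunReport) -> str:
    """Serialize the report body (no timestamps; byte-stable given config+seed)."""
    payload = {
        "provenance": report.provenance,
        "assumptions": list(report.assumptions),
        "corridor": {
            "trait": report.corridor.trait,
            "treatment": report.corridor.treatment,
            "floor": report.corridor.floor,
            "ceiling": report.corridor.ceiling,
            "ancestor": report.corridor.ancestor_label,
            "descendant": report.corridor.descendant_label,
            "direction": report.corridor.direction,
        },
        "genotype_verdicts": {
            lbl: {"status": v.status, "distance_to_bound": v.distance_to_bound}
            for lbl, v in sorted(report.genotype_verdicts.items())
        },
        "pathway_counts": dict(sorted(report.summary_counts.items())),
        "sign_epistasis": [
            {
                "site_index": r.site_index, "site_label": r.site_label,
                "flagged": r.flagged,
                "positive_backgrounds": list(r.positive_backgrounds),
                "negative_backgrounds": list(r.negative_backgrounds),
            }
            for r in report.epistasis
        ],
    }
    return json.dumps(payload, indent=2, ensure_ascii=False, sort_keys=False) + "\n"


def _write_artifacts(report, records, space, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report_to_json(report))
    write_records_csv(records.values(), out / "records.csv")
    write_pathway_tsv(report.pathway_verdicts, out / "pathways.tsv")
    write_epistasis_json(report.epistasis, out / "epistasis.json")
    (out / "hypercube.dot").write_text(
        export_hypercube_dot(space, report.genotype_verdicts)
    )
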