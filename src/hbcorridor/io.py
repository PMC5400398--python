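"""File I/O: measurement CSVs, pathway/epistasis reports, hypercube DOT.

Two CSV dialects are consumed.  Raw curves:

    genotype_label,treatment,replicate,po2_torr,saturation

with one row per equilibration step (PO₂ in torr).  Summaries (one row per
genotype × treatment, the shape of a published affinity table):

    genotype_label,treatment,p50_mean,p50_se,n50_mean,n50_se,n_replicates[,ci_lo,ci_hi]

When ``ci_lo``/``ci_hi`` are absent, a Student-t 95% CI is reconstructed
from the mean, SE, and replicate count.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .corridor_epistasis import (
    ACCESSIBLE, INACCESSIBLE, MARGINAL,
    GenotypeVerdict, PathwayVerdict, SignEpistasisReport,
    MARGINALLY_ABOVE, MARGINALLY_BELOW, STRICTLY_ABOVE, STRICTLY_BELOW,
)
from .genotype_space import HypercubeSpace
from .oxygen_equilibrium import (
    EquilibriumCurve, PhenotypeRecord, ci95_of_mean, normalize_treatment,
)

_CURVE_COLUMNS = ["genotype_label", "treatment", "replicate", "po2_torr", "saturation"]
_SUMMARY_COLUMNS = [
    "genotype_label", "treatment", "p50_mean", "p50_se",
    "n50_mean", "n50_se", "n_replicates",
]


class MeasurementFormatError(ValueError):
    """Malformed measurement file; message carries the offending row."""


def _load_frame(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise MeasurementFormatError(f"{path}: file is empty") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MeasurementFormatError(f"{path}: missing columns {missing}")
    return df


def read_curves(path: str | Path) -> list[EquilibriumCurve]:
    """Read raw saturation curves, one per genotype × treatment × replicate."""
    df = _load_frame(path, _CURVE_COLUMNS)
    curves = []
    for (label, treatment, rep), grp in df.groupby(
        ["genotype_label", "treatment", "replicate"], sort=True
    ):
        for idx, row in grp.iterrows():
            rowno = idx + 2  # header + 1-based
            if row["po2_torr"] <= 0:
                raise MeasurementFormatError(
                    f"{path}, row {rowno}: PO2 must be positive (got {row['po2_torr']})"
                )
            if not 0.0 <= row["saturation"] <= 1.0:
                raise MeasurementFormatError(
                    f"{path}, row {rowno}: saturation outside [0, 1] "
                    f"(got {row['saturation']})"
                )
        try:
            treatment_norm = normalize_treatment(str(treatment))
        except ValueError as exc:
            rowno = grp.index[0] + 2
            raise MeasurementFormatError(f"{path}, row {rowno}: {exc}") from exc
        curves.append(EquilibriumCurve(
            genotype_label=str(label), treatment=treatment_norm, replicate=int(rep),
            po2=tuple(grp["po2_torr"]), saturation=tuple(grp["saturation"]),
        ))
    return curves


def read_summary(path: str | Path) -> dict[str, dict[str, PhenotypeRecord]]:
    """Read a summary table; returns records keyed by treatment then genotype."""
    df = _load_frame(path, _SUMMARY_COLUMNS)
    has_ci = "ci_lo" in df.columns and "ci_hi" in df.columns
    out: dict[str, dict[str, PhenotypeRecord]] = {}
    for idx, row in df.iterrows():
        rowno = idx + 2
        try:
            treatment = normalize_treatment(str(row["treatment"]))
            k = int(row["n_replicates"])
            if has_ci and pd.notna(row["ci_lo"]) and pd.notna(row["ci_hi"]):
                ci = (float(row["ci_lo"]), float(row["ci_hi"]))
            else:
                ci = ci95_of_mean(float(row["p50_mean"]), float(row["p50_se"]), k)
            rec = PhenotypeRecord(
                genotype_label=str(row["genotype_label"]), treatment=treatment,
                p50_mean=float(row["p50_mean"]), p50_se=float(row["p50_se"]),
                n50_mean=float(row["n50_mean"]), n50_se=float(row["n50_se"]),
                n_replicates=k, ci95=ci,
            )
        except (ValueError, KeyError) as exc:
            raise MeasurementFormatError(f"{path}, row {rowno}: {exc}") from exc
        out.setdefault(treatment, {})[rec.genotype_label] = rec
    return out


def read_measurements(path: str | Path, mode: str):
    """Dispatch on ``mode``: ``"curves"`` or ``"summary"``."""
    if mode == "curves":
        return read_curves(path)
    if mode == "summary":
        return read_summary(path)
    raise ValueError(f"unknown measurement mode {mode!r}")


def write_records_csv(
    records: Iterable[PhenotypeRecord], path: str | Path
) -> None:
    rows = [
        {
            "genotype_label": r.genotype_label, "treatment": r.treatment,
            "p50_mean": r.p50_mean, "p50_se": r.p50_se,
            "n50_mean": r.n50_mean, "n50_se": r.n50_se,
            "n_replicates": r.n_replicates,
            "ci_lo": r.ci95[0], "ci_hi": r.ci95[1],
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_pathway_tsv(verdicts: Sequence[PathwayVerdict], path: str | Path) -> None:
    rows = [
        {
            "order": "->".join(str(i) for i in v.pathway.order),
            "genotypes": "->".join(g.label for g in v.pathway.genotype_sequence),
            "status": v.status,
            "limiting_genotypes": ",".join(v.limiting_genotypes),
        }
        for v in verdicts
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_epistasis_json(
    reports: Sequence[SignEpistasisReport], path: str | Path
) -> None:
    payload = [asdict(r) for r in reports]
    Path(path).write_text(json.dumps(payload, indent=2, ensure_ascii=False) + "\n")


_EDGE_CLASS_RANK = {ACCESSIBLE: 0, MARGINAL: 1, INACCESSIBLE: 2}
_STATUS_TO_CLASS = {
    STRICTLY_BELOW: INACCESSIBLE, STRICTLY_ABOVE: INACCESSIBLE,
    MARGINALLY_BELOW: MARGINAL, MARGINALLY_ABOVE: MARGINAL,
}


def export_hypercube_dot(
    space: HypercubeSpace,
    verdicts: Mapping[str, GenotypeVerdict] | None = None,
) -> str:
    """Render the genotype hypercube as DOT, edge class = worst endpoint verdict.

    Edges through a strictly-outside genotype are classed inaccessible,
    through a marginal genotype marginal, and accessible otherwise —
    mirroring the conventional three-color hypercube figure.
    """
    def node_class(label: str) -> str:
        if verdicts is None or label not in verdicts:
            return ACCESSIBLE
        return _STATUS_TO_CLASS.get(verdicts[label].status, ACCESSIBLE)

    colors = {ACCESSIBLE: "blue", MARGINAL: "slategray", INACCESSIBLE: "lightgray"}
    lines = ["graph hypercube {"]
    for g in space.genotypes:
        cls = node_class(g.label)
        lines.append(f'  "{g.label}" [class="{cls}"];')
    for a, b in space.edges:
        cls = max((node_class(a), node_class(b)), key=_EDGE_CLASS_RANK.get)
        lines.append(f'  "{a}" -- "{b}" [class="{cls}", color="{colors[cls]}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"
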