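"""Size-exclusion calibration and a tetramer–dimer dissociation index.

Gel filtration separates proteins by hydrodynamic size: log molecular weight
is linear in elution volume over a column's working range.  Calibrating that
line on markers of known MW (here monomeric myoglobin, ≈17 kDa, and
tetrameric human hemoglobin, ≈64.5 kDa) converts a sample's peak elution
volume into an apparent MW.  A hemoglobin eluting between the tetramer and
dimer positions indicates a tetramer–dimer equilibrium shifted toward
dissociation; the ``dimer_fraction`` index places the apparent MW linearly
between the two reference masses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class ElutionCalibration:
    """Least-squares line of log10(MW) on elution volume, with its markers."""

    slope: float
    intercept: float
    markers: tuple[tuple[str, float, float], ...]  # (name, mw_kda, elution_ml)
    r_squared: float


@dataclass(frozen=True)
class ElutionMeasurement:
    sample_label: str
    elution_ml: float
    apparent_mw_kda: float
    dimer_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.elution_ml <= 0:
            raise ValueError("elution volume must be positive")
        if self.dimer_fraction is not None and not 0.0 <= self.dimer_fraction <= 1.0:
            raise ValueError("dimer_fraction must lie in [0, 1]")


def fit_elution_calibration(
    markers: Sequence[tuple[str, float, float]]
) -> ElutionCalibration:
    """Fit log10(MW in kDa) = slope·(elution volume) + intercept on markers.

    With exactly two markers the line interpolates both points.  A positive
    slope (apparent MW increasing with elution volume) is physically
    surprising for size-exclusion media and triggers a warning, but is
    accepted: printed calibration coefficients are treated as data.
    """
    if len(markers) < 2:
        raise ValueError("need ≥2 markers for a calibration line")
    vols = np.array([m[2] for m in markers], dtype=float)
    mws = np.array([m[1] for m in markers], dtype=float)
    if np.any(mws <= 0):
        raise ValueError("marker molecular weights must be positive")
    if len(np.unique(vols)) != len(vols):
        raise ValueError("duplicate marker elution volumes")
    y = np.log10(mws)
    slope, intercept = (float(v) for v in np.polyfit(vols, y, 1))
    if slope > 0:
        warnings.warn(
            "calibration slope is positive: apparent MW increases with elution "
            "volume, the reverse of normal size-exclusion behavior",
            stacklevel=2,
        )
    pred = slope * vols + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return ElutionCalibration(
        slope=slope, intercept=intercept,
        markers=tuple((str(n), float(m), float(v)) for n, m, v in markers),
        r_squared=r2,
    )


def apparent_mw(cal: ElutionCalibration, elution_ml: float) -> float:
    """Apparent molecular weight 10**(slope·x + intercept) at elution volume x."""
    return float(10.0 ** (cal.slope * elution_ml + cal.intercept))


def dimer_fraction(
    apparent_mw_kda: float, mw_tetramer: float, mw_dimer: float
) -> float:
    """Linear tetramer–dimer index: 0 at the tetramer MW, 1 at the dimer MW.

    Values are clamped to [0, 1]; apparent MWs outside the reference bracket
    (common for partially dissociating hemoglobins) saturate the index.
    """
    if not mw_dimer < mw_tetramer:
        raise ValueError(
            f"mw_dimer ({mw_dimer}) must be below mw_tetramer ({mw_tetramer})"
        )
    frac = (mw_tetramer - apparent_mw_kda) / (mw_tetramer - mw_dimer)
    return float(min(1.0, max(0.0, frac)))
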