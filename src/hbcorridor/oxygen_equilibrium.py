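"""Hill-model O₂-equilibrium curves: forward model, fitting, and aggregation.

The Hill equation Y = PO₂ⁿ / (P50ⁿ + PO₂ⁿ) summarizes a hemoglobin
oxygen-equilibrium curve by two parameters: P50, the O₂ tension (torr) at
half-saturation (higher P50 = lower affinity), and the cooperativity
coefficient n50.  Two estimation routes are provided, mirroring standard
laboratory practice:

* nonlinear least squares on the raw (PO₂, Y) points restricted to a
  mid-saturation window (default 30–70% oxygenation);
* the linearized Hill plot, an ordinary regression of logit(Y) on ln(PO₂)
  restricted to 25–75% saturation, whose slope is n50 and whose zero
  crossing gives P50.

On exact Hill data the two routes coincide; on noisy data they differ
slightly because the logit transform reweights errors.  Replicate fits are
aggregated into mean ± SE summary records with Student-t 95% confidence
intervals, and allosteric-effector sensitivity is expressed as the P50
fold-change relative to the stripped (effector-free) condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

#: Canonical treatment tokens, in the conventional reporting order.
TREATMENTS = ("stripped", "KCl", "IHP", "KCl_IHP")

_TREATMENT_ALIASES = {
    "stripped": "stripped",
    "kcl": "KCl",
    "ihp": "IHP",
    "kcl_ihp": "KCl_IHP",
    "kcl+ihp": "KCl_IHP",
    "kclihp": "KCl_IHP",
    "ihp_kcl": "KCl_IHP",
}

DEFAULT_NONLINEAR_WINDOW = (0.30, 0.70)
DEFAULT_HILL_PLOT_WINDOW = (0.25, 0.75)


def normalize_treatment(token: str) -> str:
    """Map a treatment token (case-insensitive, '+'/'-'/' ' tolerated) to canon."""
    key = token.strip().lower().replace(" ", "").replace("-", "_")
    canon = _TREATMENT_ALIASES.get(key) or _TREATMENT_ALIASES.get(key.replace("+", "_"))
    if canon is None:
        raise ValueError(f"unknown treatment token {token!r}; expected one of {TREATMENTS}")
    return canon


def hill_saturation(po2, p50: float, n: float):
    """Fractional saturation Y at O₂ tension ``po2`` (torr); vectorized."""
    if p50 <= 0 or n <= 0:
        raise ValueError(f"p50 and n must be positive (got p50={p50}, n={n})")
    po2 = np.asarray(po2, dtype=float)
    if np.any(po2 < 0):
        raise ValueError("po2 must be nonnegative")
    x = po2 ** n
    out = x / (p50 ** n + x)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class EquilibriumCurve:
    """One replicate O₂ saturation curve for a genotype × treatment."""

    genotype_label: str
    treatment: str
    replicate: int
    po2: tuple[float, ...]
    saturation: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "treatment", normalize_treatment(self.treatment))
        po2 = tuple(float(x) for x in self.po2)
        sat = tuple(float(y) for y in self.saturation)
        if len(po2) != len(sat):
            raise ValueError("po2 and saturation lengths differ")
        if len(po2) < 3:
            raise ValueError(f"need ≥3 points, got {len(po2)}")
        if any(x <= 0 for x in po2):
            raise ValueError("PO2 values must be strictly positive (torr)")
        if any(not 0.0 <= y <= 1.0 for y in sat):
            raise ValueError("saturation values must lie in [0, 1]")
        object.__setattr__(self, "po2", po2)
        object.__setattr__(self, "saturation", sat)

    def sorted_points(self) -> tuple[np.ndarray, np.ndarray]:
        po2 = np.asarray(self.po2)
        sat = np.asarray(self.saturation)
        order = np.argsort(po2)
        return po2[order], sat[order]


@dataclass(frozen=True)
class HillFit:
    """Fitted (P50, n50) with uncertainty for one curve."""

    p50: float
    n50: float
    se_p50: float
    se_n50: float
    ci95_p50: tuple[float, float]
    method: str  # "nonlinear" | "hill_plot"
    points_used: int
    saturation_window: tuple[float, float]
    genotype_label: str = ""
    treatment: str = ""
    replicate: int | None = None

    def __post_init__(self) -> None:
        if self.p50 <= 0 or self.n50 <= 0:
            raise ValueError(f"fitted p50 and n50 must be positive "
                             f"(got {self.p50}, {self.n50})")
        lo, hi = self.ci95_p50
        if lo > hi:
            raise ValueError(f"ci95_p50 reversed: ({lo}, {hi})")


class FitError(RuntimeError):
    """Raised when a Hill fit cannot be computed; carries diagnostics."""


def _window_mask(y: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    return (y >= lo) & (y <= hi)


def fit_hill_nonlinear(
    curve: EquilibriumCurve,
    window: tuple[float, float] = DEFAULT_NONLINEAR_WINDOW,
) -> HillFit:
    """Nonlinear least-squares Hill fit on the mid-saturation window.

    Points with observed saturation outside ``window`` are dropped (not
    clamped).  Initialization: P50 from linear interpolation of PO₂ at
    Y = 0.5, n = 2.  Standard errors come from the regression covariance;
    CI95 = estimate ± t(m−2)·se.
    """
    po2, y = curve.sorted_points()
    mask = _window_mask(y, window)
    po2, y = po2[mask], y[mask]
    m = len(po2)
    if m < 3:
        raise FitError(
            f"{curve.genotype_label}/{curve.treatment}: only {m} points inside "
            f"saturation window {window}; need ≥3"
        )
    # interpolate PO2 at half-saturation for the starting value
    order = np.argsort(y)
    p50_0 = float(np.interp(0.5, y[order], po2[order]))
    if not np.isfinite(p50_0) or p50_0 <= 0:
        p50_0 = float(np.median(po2))
    try:
        popt, pcov = optimize.curve_fit(
            lambda x, p50, n: x ** n / (p50 ** n + x ** n),
            po2,
            y,
            p0=[p50_0, 2.0],
            maxfev=10_000,
        )
    except RuntimeError as exc:
        raise FitError(
            f"{curve.genotype_label}/{curve.treatment}: nonlinear Hill fit did "
            f"not converge (start p50={p50_0:.4g}, n=2): {exc}"
        ) from exc
    p50, n50 = (float(v) for v in popt)
    if p50 <= 0 or n50 <= 0:
        raise FitError(
            f"{curve.genotype_label}/{curve.treatment}: fit left the admissible "
            f"region (p50={p50:.4g}, n={n50:.4g})"
        )
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    se_p50, se_n50 = (float(v) if np.isfinite(v) else 0.0 for v in se)
    df = max(m - 2, 1)
    tcrit = float(stats.t.ppf(0.975, df))
    ci = (p50 - tcrit * se_p50, p50 + tcrit * se_p50)
    return HillFit(
        p50=p50, n50=n50, se_p50=se_p50, se_n50=se_n50, ci95_p50=ci,
        method="nonlinear", points_used=m, saturation_window=tuple(window),
        genotype_label=curve.genotype_label, treatment=curve.treatment,
        replicate=curve.replicate,
    )


def fit_hill_plot(
    curve: EquilibriumCurve,
    window: tuple[float, float] = DEFAULT_HILL_PLOT_WINDOW,
) -> HillFit:
    """Linearized Hill-plot fit: regress logit(Y) on ln(PO₂).

    Saturations of exactly 0 or 1 are excluded (the logit is undefined);
    ≥4 points must remain inside the window.  n50 is the slope; P50 the PO₂
    at which the line crosses zero.  The P50 CI is built on the log scale
    (delta method), keeping it positive.
    """
    po2, y = curve.sorted_points()
    mask = _window_mask(y, window) & (y > 0.0) & (y < 1.0)
    po2, y = po2[mask], y[mask]
    m = len(po2)
    if m < 4:
        raise FitError(
            f"{curve.genotype_label}/{curve.treatment}: only {m} usable points "
            f"inside saturation window {window}; need ≥4 for a Hill plot"
        )
    x = np.log(po2)
    z = np.log(y / (1.0 - y))
    xbar = x.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    if sxx == 0.0:
        raise FitError("all PO2 values identical; Hill plot slope undefined")
    slope = float(np.sum((x - xbar) * (z - z.mean())) / sxx)
    intercept = float(z.mean() - slope * xbar)
    if slope <= 0:
        raise FitError(f"nonpositive Hill-plot slope {slope:.4g}")
    resid = z - (intercept + slope * x)
    df = max(m - 2, 1)
    s2 = float(np.sum(resid ** 2) / df)
    var_slope = s2 / sxx
    var_intercept = s2 * (1.0 / m + xbar ** 2 / sxx)
    cov_ab = -s2 * xbar / sxx
    ln_p50 = -intercept / slope
    # delta method on ln P50 = -b/a: grad = (b/a², -1/a) wrt (a=slope, b=intercept)
    ga = intercept / slope ** 2
    gb = -1.0 / slope
    var_ln_p50 = ga * ga * var_slope + gb * gb * var_intercept + 2 * ga * gb * cov_ab
    se_ln_p50 = math.sqrt(max(var_ln_p50, 0.0))
    p50 = math.exp(ln_p50)
    se_p50 = p50 * se_ln_p50
    tcrit = float(stats.t.ppf(0.975, df))
    ci = (p50 * math.exp(-tcrit * se_ln_p50), p50 * math.exp(tcrit * se_ln_p50))
    return HillFit(
        p50=p50, n50=slope, se_p50=se_p50, se_n50=math.sqrt(var_slope),
        ci95_p50=ci, method="hill_plot", points_used=m,
        saturation_window=tuple(window), genotype_label=curve.genotype_label,
        treatment=curve.treatment, replicate=curve.replicate,
    )


@dataclass(frozen=True)
class PhenotypeRecord:
    """Per genotype × treatment summary: mean P50 ± SE, n50, and 95% CI."""

    genotype_label: str
    treatment: str
    p50_mean: float
    p50_se: float
    n50_mean: float
    n50_se: float
    n_replicates: int
    ci95: tuple[float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "treatment", normalize_treatment(self.treatment))
        if self.p50_mean <= 0:
            raise ValueError(f"{self.genotype_label}: p50_mean must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be ≥1")
        lo, hi = self.ci95
        if not lo <= self.p50_mean <= hi:
            raise ValueError(
                f"{self.genotype_label}: ci95 ({lo}, {hi}) does not contain "
                f"mean {self.p50_mean}"
            )


def ci95_of_mean(
    mean: float, se: float, n_replicates: int, method: str = "t"
) -> tuple[float, float]:
    """95% CI for a mean given its SE: Student t (default) or normal critical value."""
    if method == "t":
        crit = float(stats.t.ppf(0.975, max(n_replicates - 1, 1)))
    elif method == "normal":
        crit = float(stats.norm.ppf(0.975))
    else:
        raise ValueError(f"unknown CI method {method!r} (use 't' or 'normal')")
    return (mean - crit * se, mean + crit * se)


def aggregate_replicates(
    fits: Sequence[HillFit], ci_method: str = "t"
) -> PhenotypeRecord:
    """Combine replicate Hill fits into a mean ± SE summary record.

    With k ≥ 2 replicates, SE = sd/√k and CI95 = mean ± t(k−1)·SE (or a
    normal critical value when ``ci_method="normal"``).  A single fit is
    passed through with its own regression SE and CI.
    """
    if not fits:
        raise ValueError("no fits to aggregate")
    labels = {f.genotype_label for f in fits}
    treatments = {f.treatment for f in fits}
    if len(labels) > 1 or len(treatments) > 1:
        raise ValueError(
            f"mixed inputs: genotypes {sorted(labels)}, treatments {sorted(treatments)}"
        )
    k = len(fits)
    if k == 1:
        f = fits[0]
        return PhenotypeRecord(
            genotype_label=f.genotype_label, treatment=f.treatment,
            p50_mean=f.p50, p50_se=f.se_p50, n50_mean=f.n50, n50_se=f.se_n50,
            n_replicates=1, ci95=f.ci95_p50,
        )
    p50s = np.array([f.p50 for f in fits])
    n50s = np.array([f.n50 for f in fits])
    p50_mean = float(p50s.mean())
    p50_se = float(p50s.std(ddof=1) / math.sqrt(k))
    n50_mean = float(n50s.mean())
    n50_se = float(n50s.std(ddof=1) / math.sqrt(k))
    return PhenotypeRecord(
        genotype_label=fits[0].genotype_label, treatment=fits[0].treatment,
        p50_mean=p50_mean, p50_se=p50_se, n50_mean=n50_mean, n50_se=n50_se,
        n_replicates=k, ci95=ci95_of_mean(p50_mean, p50_se, k, ci_method),
    )


@dataclass(frozen=True)
class EffectorSensitivity:
    """P50 fold-change induced by an allosteric effector, with uncertainty."""

    genotype_label: str
    effector_treatment: str
    ratio: float
    se_ratio: float
    log_ratio: float
    se_log_ratio: float


def effector_sensitivity(
    stripped: PhenotypeRecord, with_effector: PhenotypeRecord
) -> EffectorSensitivity:
    """Effector sensitivity = P50(effector)/P50(stripped), SE by delta method.

    A ratio > 1 means the effector lowers O₂ affinity (raises P50), the
    normal allosteric response; ratios near 1 indicate a suppressed response.
    """
    if stripped.genotype_label != with_effector.genotype_label:
        raise ValueError(
            f"genotype mismatch: {stripped.genotype_label!r} vs "
            f"{with_effector.genotype_label!r}"
        )
    if stripped.treatment != "stripped" or with_effector.treatment == "stripped":
        raise ValueError(
            "expected a (stripped, effector) record pair, got "
            f"({stripped.treatment!r}, {with_effector.treatment!r})"
        )
    ratio = with_effector.p50_mean / stripped.p50_mean
    # delta method on ln ratio: var = (se_e/p_e)² + (se_s/p_s)²
    se_log = math.sqrt(
        (with_effector.p50_se / with_effector.p50_mean) ** 2
        + (stripped.p50_se / stripped.p50_mean) ** 2
    )
    return EffectorSensitivity(
        genotype_label=stripped.genotype_label,
        effector_treatment=with_effector.treatment,
        ratio=ratio, se_ratio=ratio * se_log,
        log_ratio=math.log(ratio), se_log_ratio=se_log,
    )
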