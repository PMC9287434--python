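"""Hill-equation concentration-inhibition fitting.

Two model variants are used:

* the MCI variant, fit to mean Min I_MCI/I_Control values across cells,

      Min([B]) = A + (1 - A) / (1 + ([B]/IC50)^nH)

  with a residual inhibition floor A (the brief wash before the readout
  lets some blocker leave the membrane, so saturation need not reach 0);
  when only two concentrations are available, A is constrained to 0 and
  nH to 1, leaving IC50 as the single free parameter;

* the traditional variant, fit per cell to fractional current during
  blocker/agonist co-application,

      I_drug/I_Control([B]) = 1 / (1 + ([B]/IC50)^nH)

  with cohort statistics (mean ± SEM of per-cell IC50s).

Fitting uses bounded least squares (IC50 > 0, 0 <= A < 1,
0.1 <= nH <= 5) with multi-start over log-spaced IC50 seeds.  Uncertainty
follows the weighting: for weighted fits to mean ± SEM values the
parameter SE comes from the absolute-sigma covariance (so doubling all
SEMs doubles the SE); unweighted fits scale the covariance by the
residual variance, and cohorts report the SEM across cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "DoseResponsePoint",
    "HillFit",
    "FitError",
    "eq1_evaluate",
    "eq2_evaluate",
    "fit_eq1",
    "fit_eq1_constrained",
    "fit_eq2",
    "fit_eq2_cohort",
    "ic50_uncertainty",
    "cohort_ic50_sem",
    "fold_ratio",
]

IDENTIFIABILITY_FLOOR = 0.98


class FitError(ValueError):
    """The requested fit is not defined on this input."""


@dataclass(frozen=True)
class DoseResponsePoint:
    conc_uM: float
    mean_value: float
    sem: float = 0.0
    n: int = 1

    def __post_init__(self) -> None:
        if not self.conc_uM > 0:
            raise FitError("concentration must be > 0")
        if not 0.0 < self.mean_value <= 1.2:
            raise FitError(f"mean value {self.mean_value} outside (0, 1.2]")
        if self.sem < 0:
            raise FitError("sem must be >= 0")


@dataclass(frozen=True)
class HillFit:
    A: float
    ic50_uM: float
    nH: float
    se_A: float = float("nan")
    se_ic50: float = float("nan")
    se_nH: float = float("nan")
    constraints_applied: frozenset = field(default_factory=frozenset)
    weighted: bool = False
    converged: bool = False
    identifiable: bool = True
    residual_sum: float = float("nan")


def eq1_evaluate(A: float, ic50_uM: float, nH: float, conc_uM):
    """MCI Hill curve: A + (1 - A) / (1 + (c/IC50)^nH)."""
    if not ic50_uM > 0:
        raise FitError("IC50 must be > 0")
    c = np.asarray(conc_uM, dtype=float)
    return A + (1.0 - A) / (1.0 + (c / ic50_uM) ** nH)


def eq2_evaluate(ic50_uM: float, nH: float, conc_uM):
    """Traditional-block Hill curve: 1 / (1 + (c/IC50)^nH); 1 at zero drug."""
    if not ic50_uM > 0:
        raise FitError("IC50 must be > 0")
    c = np.asarray(conc_uM, dtype=float)
    out = np.ones_like(c)
    np.divide(1.0, 1.0 + (c / ic50_uM) ** nH, out=out, where=c > 0)
    return out


def _as_points(points) -> list[DoseResponsePoint]:
    return [
        p if isinstance(p, DoseResponsePoint) else DoseResponsePoint(*p)
        for p in points
    ]


def _ic50_seeds(concs: np.ndarray) -> np.ndarray:
    lo, hi = np.min(concs), np.max(concs)
    return np.geomspace(lo / 3.0, hi * 3.0, 3)


def _covariance(res, weighted: bool, n: int, p: int) -> np.ndarray:
    J = res.jac
    try:
        cov = np.linalg.inv(J.T @ J)
    except np.linalg.LinAlgError:
        return np.full((p, p), np.nan)
    if not weighted:
        dof = max(n - p, 1)
        cov = cov * (2.0 * res.cost / dof)
    return cov


def fit_eq1(points, weights: str | None = None) -> HillFit:
    """Free three-parameter fit of the MCI Hill curve.

    ``weights='sem'`` weights residuals by 1/sem (absolute-sigma
    semantics); default is unweighted, matching fits to mean values.
    Needs at least 3 points; data showing no inhibition (all values at or
    above the identifiability floor) are flagged non-identifiable.
    """
    pts = _as_points(points)
    if len(pts) < 3:
        raise FitError(
            "free fit needs >= 3 points; use fit_eq1_constrained for sparser data"
        )
    c = np.array([p.conc_uM for p in pts])
    y = np.array([p.mean_value for p in pts])
    if np.all(y >= IDENTIFIABILITY_FLOOR):
        return HillFit(A=float("nan"), ic50_uM=float("nan"), nH=float("nan"),
                       converged=False, identifiable=False)
    weighted = weights == "sem"
    if weighted:
        sig = np.array([p.sem for p in pts])
        if np.any(sig <= 0):
            raise FitError("weighted fit requires positive SEM on every point")
    else:
        sig = np.ones_like(y)

    def resid(x):
        A, log_ic50, nH = x
        return (eq1_evaluate(A, np.exp(log_ic50), nH, c) - y) / sig

    best = None
    for seed in _ic50_seeds(c):
        res = optimize.least_squares(
            resid,
            x0=[max(0.0, float(np.min(y)) - 0.02), np.log(seed), 1.0],
            bounds=([0.0, -np.inf, 0.1], [0.999, np.inf, 5.0]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        if best is None or res.cost < best.cost:
            best = res
    A, log_ic50, nH = best.x
    # delta method for the log-parameterized IC50
    cov = _covariance(best, weighted, len(pts), 3)
    ic50 = float(np.exp(log_ic50))
    se = np.sqrt(np.abs(np.diag(cov)))
    return HillFit(
        A=float(A), ic50_uM=ic50, nH=float(nH),
        se_A=float(se[0]), se_ic50=float(se[1] * ic50), se_nH=float(se[2]),
        weighted=weighted, converged=bool(best.success),
        residual_sum=float(2.0 * best.cost),
    )


def fit_eq1_constrained(points, A: float = 0.0, nH: float = 1.0,
                        weights: str | None = None) -> HillFit:
    """Single-parameter MCI fit with A and nH fixed (sparse-data variant).

    For a single point the closed form IC50 = c * r / (1 - r) holds
    exactly (r the measured Min value); with several points the IC50 is
    the least-squares solution.  A point with r >= 1 carries no
    inhibition and cannot constrain IC50.
    """
    pts = _as_points(points)
    if not pts:
        raise FitError("at least one point required")
    c = np.array([p.conc_uM for p in pts])
    y = np.array([p.mean_value for p in pts])
    if np.any(y >= 1.0):
        raise FitError("a point with value >= 1 shows no inhibition; IC50 undefined")
    weighted = weights == "sem"
    sig = (np.array([p.sem for p in pts]) if weighted else np.ones_like(y))
    if weighted and np.any(sig <= 0):
        raise FitError("weighted fit requires positive SEM on every point")

    # per-point closed-form inversions seed (and, for n=1, solve) the fit
    inv = c * ((y - A) / (1.0 - y)) ** (1.0 / nH)
    if len(pts) == 1:
        return HillFit(A=A, ic50_uM=float(inv[0]), nH=nH, se_ic50=0.0,
                       constraints_applied=frozenset({"A", "nH"}),
                       converged=True, residual_sum=0.0)

    def resid(x):
        return (eq1_evaluate(A, np.exp(x[0]), nH, c) - y) / sig

    res = optimize.least_squares(resid, x0=[np.log(np.mean(inv))],
                                 xtol=1e-14, ftol=1e-14, gtol=1e-14)
    ic50 = float(np.exp(res.x[0]))
    cov = _covariance(res, weighted, len(pts), 1)
    return HillFit(
        A=A, ic50_uM=ic50, nH=nH, se_ic50=float(np.sqrt(abs(cov[0, 0])) * ic50),
        constraints_applied=frozenset({"A", "nH"}), weighted=weighted,
        converged=bool(res.success), residual_sum=float(2.0 * res.cost),
    )


def fit_eq2(points) -> HillFit:
    """Two-parameter traditional-block fit for one cell (IC50 and nH free)."""
    pts = _as_points(points)
    if len(pts) < 2:
        raise FitError("per-cell fit needs >= 2 points")
    c = np.array([p.conc_uM for p in pts])
    y = np.array([p.mean_value for p in pts])
    if np.all(y >= IDENTIFIABILITY_FLOOR):
        return HillFit(A=0.0, ic50_uM=float("nan"), nH=float("nan"),
                       converged=False, identifiable=False)

    def resid(x):
        return eq2_evaluate(np.exp(x[0]), x[1], c) - y

    best = None
    for seed in _ic50_seeds(c):
        res = optimize.least_squares(
            resid, x0=[np.log(seed), 1.0],
            bounds=([-np.inf, 0.1], [np.inf, 5.0]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        if best is None or res.cost < best.cost:
            best = res
    ic50 = float(np.exp(best.x[0]))
    cov = _covariance(best, False, len(pts), 2)
    se = np.sqrt(np.abs(np.diag(cov)))
    return HillFit(
        A=0.0, ic50_uM=ic50, nH=float(best.x[1]),
        se_ic50=float(se[0] * ic50), se_nH=float(se[1]),
        converged=bool(best.success), residual_sum=float(2.0 * best.cost),
    )


def fit_eq2_cohort(per_cell_points) -> tuple[list[HillFit], float, float]:
    """Per-cell traditional fits plus cohort mean ± SEM of the IC50."""
    fits = [fit_eq2(pts) for pts in per_cell_points]
    ic50s = np.array([f.ic50_uM for f in fits if f.converged])
    if ic50s.size == 0:
        raise FitError("no cell converged")
    sem = float(np.std(ic50s, ddof=1) / np.sqrt(ic50s.size)) if ic50s.size > 1 else 0.0
    return fits, float(np.mean(ic50s)), sem


def ic50_uncertainty(fit: HillFit) -> float:
    """Standard error of a fitted IC50 (from the fit covariance)."""
    return fit.se_ic50


def cohort_ic50_sem(fits) -> float:
    """SEM of IC50 across per-cell fits."""
    ic50s = np.array([f.ic50_uM for f in fits if f.converged])
    if ic50s.size < 2:
        return 0.0
    return float(np.std(ic50s, ddof=1) / np.sqrt(ic50s.size))


def _round_sigfigs(x: float, sigfigs: int) -> float:
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (sigfigs - 1))


def fold_ratio(fit_a, fit_b, round_to_sigfigs: int | None = None) -> float:
    """IC50 fold-difference between two fits (or bare IC50 values)."""
    a = fit_a.ic50_uM if isinstance(fit_a, HillFit) else float(fit_a)
    b = fit_b.ic50_uM if isinstance(fit_b, HillFit) else float(fit_b)
    if not b > 0:
        raise FitError("denominator IC50 must be > 0")
    r = a / b
    return _round_sigfigs(r, round_to_sigfigs) if round_to_sigfigs else r
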