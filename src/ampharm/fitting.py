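"""Concentration-response and competition-binding curve fitting.

The workhorse model is the four-parameter logistic (4PL) curve

    R(c) = basal + (top - basal) / (1 + 10**((log10 EC50 - log10 c) * hill))

with potency reported as pEC50 = -log10 EC50 (molar), so the half-maximal
response sits at log10 c = -pEC50

fitted by multistart least squares with an analytic Jacobian.  The analysis
convention mirrors standard agonist pharmacology practice:

* each independent experiment is fitted on its per-concentration means
  (technical replicates are averaged first);
* the Hill slope is tested against unity with an extra-sum-of-squares F test
  and, when not significantly different, the curve is refitted as a
  three-parameter logistic (3PL, hill = 1);
* mutant responses are normalized to the fitted minimum and maximum of the
  paired WT curve (0-100 % of the WT span);
* normalized experiments are combined by per-concentration means with
  between-experiment standard errors;
* curves whose span collapses below 10 % of the WT span, or whose potency
  falls below pEC50 = 6, are censored ("no curve") rather than reported.

Competition radioligand binding uses the same engine with a fixed Hill slope
of -1 (a decreasing 3PL in the competitor concentration).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import (
    AlignmentError,
    DegenerateDataError,
    DegenerateNormalizationError,
    InputError,
)

__all__ = [
    "LogisticFit",
    "BindingFit",
    "NormalizedCurve",
    "HillTest",
    "logistic4",
    "fit_logistic4",
    "fit_logistic3",
    "test_hill_unity",
    "normalize_to_wt",
    "combine_normalized",
    "detect_censoring",
    "fit_binding3",
]

LN10 = math.log(10.0)

#: minimum fraction of the WT span a fitted curve must retain to escape censoring
SPAN_FLOOR_FRAC = 0.10
#: potency floor; fits below this bound are reported as "pEC50 < 6"
PEC50_FLOOR = 6.0
#: log10 tolerance when aligning concentration grids across experiments
GRID_TOL_LOG10 = 0.01


@dataclass(frozen=True)
class LogisticFit:
    """A fitted logistic concentration-response curve.

    ``censored`` fits carry no parameter estimates (NaN), only the censoring
    bound (``pec50_bound``) as in a "no curve" table entry.
    """

    basal: float
    top: float
    pec50: float
    hill: float
    se_basal: float
    se_top: float
    se_pec50: float
    se_hill: float
    rss: float
    df: int
    n_points: int
    converged: bool
    hill_fixed: bool = False
    censored: bool = False
    pec50_bound: float | None = None

    @property
    def span(self) -> float:
        return self.top - self.basal


@dataclass(frozen=True)
class BindingFit:
    """A fitted competition radioligand-binding curve (decreasing 3PL)."""

    bottom: float
    top: float
    pic50: float
    se_bottom: float
    se_top: float
    se_pic50: float
    rss: float
    df: int
    converged: bool
    censored: bool = False

    @property
    def specific(self) -> float:
        """Maximum specific binding: fitted total minus nonspecific plateau."""
        return self.top - self.bottom


@dataclass(frozen=True)
class NormalizedCurve:
    """Combined normalized concentration-response data for one construct.

    ``points`` holds (log10 concentration, mean % of WT span, SE of mean)
    triples; the SE is NaN when only one experiment contributed.
    """

    construct: str
    receptor: str
    n_experiments: int
    points: tuple[tuple[float, float, float], ...] = field(default_factory=tuple)


class HillTest(NamedTuple):
    """Extra-sum-of-squares comparison of the free-Hill and unit-Hill fits."""

    F: float
    p: float
    chosen: LogisticFit
    hill_constrained: bool


def logistic4(
    logc: np.ndarray, basal: float, top: float, pec50: float, hill: float
) -> np.ndarray:
    """Evaluate the 4PL curve at log10 molar concentrations ``logc``.

    ``pec50`` is -log10 EC50, so the midpoint lies at ``logc == -pec50``.
    """
    u = np.clip((-pec50 - logc) * hill, -300.0, 300.0)
    return basal + (top - basal) / (1.0 + 10.0**u)


def _collapse_replicates(exp) -> tuple[np.ndarray, np.ndarray]:
    """Per-concentration means of the technical replicates of one experiment."""
    logc = np.array([math.log10(c) for c, _ in exp.points], dtype=float)
    y = np.array([float(np.mean(r)) for _, r in exp.points], dtype=float)
    order = np.argsort(logc)
    return logc[order], y[order]


def _validate_experiment(logc: np.ndarray, y: np.ndarray) -> None:
    if len(np.unique(np.round(logc, 9))) < 5:
        raise InputError(
            f"need >=5 distinct concentrations to fit a logistic curve, got {len(logc)}"
        )
    if not np.all(np.isfinite(y)):
        raise InputError("responses must be finite")
    if np.ptp(y) == 0.0:
        raise DegenerateDataError("all responses are equal; no curve to fit")


def _residuals_jac(logc: np.ndarray, y: np.ndarray, free_hill: bool):
    """Residual and Jacobian callables for least_squares.

    Parameter vector is (basal, top, pec50[, hill]); hill is frozen at 1 for
    the 3PL variant.
    """

    def resid(theta):
        basal, top, pec50 = theta[:3]
        hill = theta[3] if free_hill else 1.0
        return logistic4(logc, basal, top, pec50, hill) - y

    def jac(theta):
        basal, top, pec50 = theta[:3]
        hill = theta[3] if free_hill else 1.0
        u = np.clip((-pec50 - logc) * hill, -300.0, 300.0)
        f = 1.0 / (1.0 + 10.0**u)  # occupancy-like factor in (0, 1)
        g = f * (1.0 - f)
        cols = [
            1.0 - f,
            f,
            LN10 * hill * (top - basal) * g,
        ]
        if free_hill:
            cols.append(-LN10 * (-pec50 - logc) * (top - basal) * g)
        return np.stack(cols, axis=1)

    return resid, jac


def _fit_ls(logc, y, free_hill: bool, hill_starts: Sequence[float]) -> LogisticFit:
    """Multistart least squares over (basal, top, pEC50 [, hill])."""
    resid, jac = _residuals_jac(logc, y, free_hill)
    lo, hi = float(np.min(y)), float(np.max(y))
    pec50_starts = np.linspace(-logc.max(), -logc.min(), 4)
    best = None
    for p0 in pec50_starts:
        for h0 in hill_starts if free_hill else (1.0,):
            theta0 = [lo, hi, p0] + ([h0] if free_hill else [])
            try:
                sol = optimize.least_squares(resid, theta0, jac=jac, method="lm")
            except Exception:  # pragma: no cover - LM rarely raises
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    n = len(y)
    p = 4 if free_hill else 3
    if best is None or not best.success:
        nan = float("nan")
        return LogisticFit(
            nan, nan, nan, nan, nan, nan, nan, nan,
            rss=float("inf"), df=n - p, n_points=n,
            converged=False, hill_fixed=not free_hill,
        )
    theta = best.x
    rss = float(2.0 * best.cost)
    df = n - p
    J = jac(theta)
    se = np.full(p, np.nan)
    if df > 0:
        jtj = J.T @ J
        try:
            cov = np.linalg.pinv(jtj) * (rss / df)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        except np.linalg.LinAlgError:  # pragma: no cover
            pass
    basal, top, pec50 = theta[:3]
    hill = theta[3] if free_hill else 1.0
    se_hill = se[3] if free_hill else 0.0
    # canonical orientation: report top >= basal, flipping the sign of hill
    if top < basal:
        basal, top = top, basal
        se0, se1 = se[1], se[0]
        se = se.copy()
        se[0], se[1] = se0, se1
        hill = -hill
    return LogisticFit(
        basal=float(basal),
        top=float(top),
        pec50=float(pec50),
        hill=float(hill),
        se_basal=float(se[0]),
        se_top=float(se[1]),
        se_pec50=float(se[2]),
        se_hill=float(se_hill),
        rss=rss,
        df=df,
        n_points=n,
        converged=True,
        hill_fixed=not free_hill,
    )


def fit_logistic4(exp) -> LogisticFit:
    """Fit the four-parameter logistic to one experiment.

    Technical replicates are averaged per concentration before fitting.
    Inverted (monotone decreasing) data converge to a fit with ``hill < 0``
    rather than a silently mis-oriented positive-Hill fit.
    """
    logc, y = _collapse_replicates(exp)
    _validate_experiment(logc, y)
    return _fit_ls(logc, y, free_hill=True, hill_starts=(1.0, 2.0, -1.0))


def fit_logistic3(exp) -> LogisticFit:
    """Fit the three-parameter logistic (Hill slope frozen at 1)."""
    logc, y = _collapse_replicates(exp)
    _validate_experiment(logc, y)
    return _fit_ls(logc, y, free_hill=False, hill_starts=(1.0,))


def test_hill_unity(exp, alpha: float = 0.05) -> HillTest:
    """Test whether the Hill slope differs from unity and pick the fit.

    Extra-sum-of-squares F test between the 4PL fit and the nested 3PL
    (hill = 1) fit.  When p >= ``alpha`` the Hill slope is constrained to 1
    and the 3PL fit is returned as ``chosen``; otherwise the 4PL fit is kept
    and ``hill_constrained`` is False, flagging the unusual curve.
    """
    fit4 = fit_logistic4(exp)
    if not fit4.converged:
        raise DegenerateDataError("4PL fit did not converge; cannot test Hill slope")
    fit3 = fit_logistic3(exp)
    extra = fit3.rss - fit4.rss
    scale = max(fit3.rss, fit4.rss, 1.0)
    if fit4.df <= 0 or extra <= 1e-12 * scale:
        # perfect nested agreement (noiseless hill=1 data): no evidence at all
        return HillTest(0.0, 1.0, fit3, True)
    F = extra / (fit4.rss / fit4.df)
    p = float(stats.f.sf(F, 1, fit4.df))
    if p >= alpha:
        return HillTest(float(F), p, fit3, True)
    return HillTest(float(F), p, fit4, False)


def normalize_to_wt(mut_exp, wt_fit: LogisticFit):
    """Express responses as percent of the WT curve's fitted span.

    Each response r maps to ``100 * (r - wt_basal) / (wt_top - wt_basal)``;
    concentrations are untouched.  The WT fit must be converged, uncensored
    and from the paired experiment at the same receptor.
    """
    if wt_fit.censored or not wt_fit.converged:
        raise DegenerateNormalizationError("WT fit censored or not converged")
    span = wt_fit.span
    if span <= 0:
        raise DegenerateNormalizationError(f"WT span must be positive, got {span}")
    points = tuple(
        (c, tuple(100.0 * (float(r) - wt_fit.basal) / span for r in rs))
        for c, rs in mut_exp.points
    )
    return replace(mut_exp, points=points)


def combine_normalized(exps: Sequence) -> NormalizedCurve:
    """Combine normalized experiments into one mean curve.

    Technical replicates are averaged within experiment first; the combined
    curve is the per-concentration mean across experiments with its SE
    (NaN for a single experiment).  All experiments must share the same
    concentration grid to within 0.01 log10 units.
    """
    if not exps:
        raise InputError("no experiments to combine")
    grids, means = [], []
    for e in exps:
        logc, y = _collapse_replicates(e)
        grids.append(logc)
        means.append(y)
    ref = grids[0]
    for e, g in zip(exps, grids):
        if len(g) != len(ref) or np.any(np.abs(g - ref) > GRID_TOL_LOG10):
            bad = g if len(g) != len(ref) else g[np.abs(g - ref) > GRID_TOL_LOG10]
            raise AlignmentError(
                f"experiment {e.experiment!r} grid mismatch at log10 conc {bad}"
            )
    arr = np.stack(means)
    mean = arr.mean(axis=0)
    if arr.shape[0] > 1:
        se = arr.std(axis=0, ddof=1) / math.sqrt(arr.shape[0])
    else:
        se = np.full(arr.shape[1], np.nan)
    first = exps[0]
    return NormalizedCurve(
        construct=first.construct,
        receptor=first.receptor,
        n_experiments=len(exps),
        points=tuple(zip(ref.tolist(), mean.tolist(), se.tolist())),
    )


def detect_censoring(
    fit: LogisticFit,
    wt_fit: LogisticFit,
    span_floor_frac: float = SPAN_FLOOR_FRAC,
    pec50_floor: float = PEC50_FLOOR,
    pec50_range: tuple[float, float] | None = None,
) -> LogisticFit:
    """Apply the "no curve" censoring rules to an attempted fit.

    A fit is censored when it failed to converge, its span is below
    ``span_floor_frac`` of the WT span, or its potency falls below the
    reporting floor.  When ``pec50_range`` (the tested concentration window,
    as admissible pEC50 bounds) is given, fits whose midpoint lies outside
    it are also censored: their plateau and basal are extrapolations not
    defined by any tested concentration.  Censored fits carry only the bound
    ``pEC50 < 6``.
    """
    wt_span = wt_fit.span
    low_span = fit.converged and wt_span > 0 and fit.span < span_floor_frac * wt_span
    low_potency = fit.converged and fit.pec50 < pec50_floor
    out_of_range = (
        fit.converged
        and pec50_range is not None
        and not (pec50_range[0] <= fit.pec50 <= pec50_range[1])
    )
    if not fit.converged or low_span or low_potency or out_of_range:
        nan = float("nan")
        return replace(
            fit,
            basal=nan, top=nan, pec50=nan, hill=nan,
            se_basal=nan, se_top=nan, se_pec50=nan, se_hill=nan,
            censored=True,
            pec50_bound=pec50_floor,
        )
    return fit


def fit_binding3(exp, nonspecific_conc: float = 3e-6) -> BindingFit:
    """Fit a decreasing three-parameter logistic to competition-binding counts.

    Bound counts fall from ``top`` (total binding) to ``bottom`` (nonspecific,
    defined by the reserved competitor concentration, 3 uM unlabeled agonist)
    with midpoint pIC50.  Maximum specific binding is ``top - bottom``.
    A curve with no specific window (all counts at nonspecific) is returned
    censored rather than raising.
    """
    logc, y = _collapse_replicates(exp)
    if len(logc) < 5:
        raise InputError(
            f"need >=5 competitor concentrations plus nonspecific, got {len(logc)}"
        )
    has_nonspecific = np.any(np.abs(logc - math.log10(nonspecific_conc)) <= GRID_TOL_LOG10)
    if not has_nonspecific:
        raise InputError(
            "no nonspecific-binding measurement (reserved competitor conc 3e-6 M)"
        )
    nan = float("nan")
    if np.ptp(y) == 0.0:
        return BindingFit(
            bottom=float(y[0]), top=float(y[0]), pic50=nan,
            se_bottom=nan, se_top=nan, se_pic50=nan,
            rss=0.0, df=len(y) - 3, converged=False, censored=True,
        )
    # hill = -1 is the sign flip of our parametrization: fit with responses
    # reversed so the shared increasing-logistic engine applies.
    fit = _fit_ls(logc, -y, free_hill=False, hill_starts=(1.0,))
    if not fit.converged:
        return BindingFit(
            bottom=nan, top=nan, pic50=nan, se_bottom=nan, se_top=nan,
            se_pic50=nan, rss=float("inf"), df=len(y) - 3,
            converged=False, censored=True,
        )
    bottom, top = -fit.top, -fit.basal
    specific = top - bottom
    total = max(abs(top), abs(bottom), 1e-12)
    censored = specific <= 0.02 * total
    return BindingFit(
        bottom=float(bottom),
        top=float(top),
        pic50=float(fit.pec50),
        se_bottom=fit.se_top,
        se_top=fit.se_basal,
        se_pic50=fit.se_pec50,
        rss=fit.rss,
        df=fit.df,
        converged=True,
        censored=bool(censored),
    )
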