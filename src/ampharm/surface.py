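"""ELISA cell-surface expression and competition-binding summaries.

Expression is an antibody read-out (A490 - A650/595 absorbance) of
epitope-tagged receptor at the plasma membrane.  Within every experiment the
absorbances are anchored to WT (100 %) and empty-vector transfected cells
(0 %); normalized percentages are then averaged across experiments with a
t-based 95 % confidence interval, and a mutant differs significantly from WT
when that interval excludes 100 %.  Per-experiment normalization makes the
percentages invariant to day-to-day gain or offset drift of the plate
reader.

Competition binding summaries average per-experiment pIC50 fits and express
the maximum specific binding window (total minus nonspecific) as a
percentage of the same-day WT window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, InputError, PairingError
from .fitting import BindingFit

__all__ = [
    "ExpressionMeasurement",
    "BindingSummary",
    "normalize_expression",
    "ci_excludes_100",
    "summarize_binding",
]


@dataclass(frozen=True)
class ExpressionMeasurement:
    """Normalized cell-surface expression of one construct at one receptor."""

    construct: str
    receptor: str
    per_experiment_pct: tuple[float, ...]
    pct: float
    se: float
    ci95: tuple[float, float]
    n: int


@dataclass(frozen=True)
class BindingSummary:
    """Competition-binding summary for one construct at one receptor."""

    construct: str
    receptor: str
    pic50: float
    pic50_se: float
    max_specific_pct_wt: float
    max_specific_se: float
    n: int
    censored: bool = False


def normalize_expression(
    wt: Sequence[float],
    vector: Sequence[float],
    mutant: Sequence[float],
    construct: str = "",
    receptor: str = "",
) -> ExpressionMeasurement:
    """Anchor per-experiment absorbances to WT = 100 %, empty vector = 0 %.

    ``wt``, ``vector`` and ``mutant`` are same-length per-experiment
    absorbance vectors; experiment i of each belongs to the same plate.  The
    summary is the mean +/- SE of the per-experiment percentages with a
    t-based 95 % CI (n - 1 degrees of freedom).
    """
    wt = np.asarray(wt, dtype=float)
    vector = np.asarray(vector, dtype=float)
    mutant = np.asarray(mutant, dtype=float)
    if not (len(wt) == len(vector) == len(mutant)):
        raise PairingError("WT, vector and mutant absorbances must align per experiment")
    if len(wt) < 2:
        raise InputError("need >= 2 experiments to normalize expression")
    if np.any(wt <= vector):
        bad = np.nonzero(wt <= vector)[0]
        raise DegenerateDataError(
            f"WT absorbance must exceed empty vector in every experiment; "
            f"violated in experiment(s) {bad.tolist()}"
        )
    pct = 100.0 * (mutant - vector) / (wt - vector)
    mean = float(pct.mean())
    se = float(pct.std(ddof=1) / math.sqrt(len(pct)))
    tcrit = float(stats.t.ppf(0.975, len(pct) - 1))
    ci = (mean - tcrit * se, mean + tcrit * se)
    return ExpressionMeasurement(
        construct=construct,
        receptor=receptor,
        per_experiment_pct=tuple(float(p) for p in pct),
        pct=mean,
        se=se,
        ci95=ci,
        n=len(pct),
    )


def ci_excludes_100(m: ExpressionMeasurement) -> bool:
    """Significance call for a mutant's expression: 95 % CI excludes 100 %."""
    if m.n < 3:
        raise InputError(f"{m.construct}: need n >= 3 for the CI test, got {m.n}")
    lo, hi = m.ci95
    return not (lo <= 100.0 <= hi)


def summarize_binding(
    fits: Sequence[BindingFit],
    wt_fits: Sequence[BindingFit],
    construct: str = "",
    receptor: str = "",
) -> BindingSummary:
    """Average per-experiment binding fits; specific window as % of WT.

    ``fits[i]`` and ``wt_fits[i]`` come from the same experiment (same-day
    WT).  A summary is censored when no experiment produced a specific
    binding window.
    """
    if len(fits) != len(wt_fits):
        raise PairingError("mutant and WT binding fits must pair per experiment")
    live = [(f, w) for f, w in zip(fits, wt_fits) if not (f.censored or w.censored)]
    if not live:
        nan = float("nan")
        return BindingSummary(
            construct, receptor, nan, nan, nan, nan, n=len(fits), censored=True
        )
    pic50s = np.array([f.pic50 for f, _ in live])
    ratios = np.array([100.0 * f.specific / w.specific for f, w in live])
    n = len(live)
    se = float(pic50s.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
    ratio_se = float(ratios.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
    return BindingSummary(
        construct=construct,
        receptor=receptor,
        pic50=float(pic50s.mean()),
        pic50_se=se,
        max_specific_pct_wt=float(ratios.mean()),
        max_specific_se=ratio_se,
        n=n,
        censored=False,
    )
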