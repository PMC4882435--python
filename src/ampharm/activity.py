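"""Relative activity: log(RA), dlog(RA) and the per-mutant summary row.

The relative activity RA = Emax / EC50 condenses potency and efficacy into a
single number.  On the log scale, with EC50 in molar and Emax as percent of
the WT span,

    log(RA) = log10(Emax%) + pEC50

and the WT-minus-mutant difference

    dlog(RA) = delta_pEC50 + 2 - log10(Emax%)          (log10(100) = 2)

is the central perturbation statistic: 0 for a WT-like mutant, positive for
loss of function, and sensitive to potency and efficacy changes alike.

Uncertainty on dlog(RA) is propagated in quadrature from the WT pEC50 SE,
the mutant pEC50 SE and the Emax SE (on the log scale), treating the WT Emax
as the normalization constant:

    se = sqrt(se_wt^2 + se_mut^2 + (se_emax / (Emax% * ln 10))^2)
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InputError, PairingError
from .fitting import LogisticFit

__all__ = [
    "PharmSummaryRow",
    "log_ra",
    "delta_log_ra",
    "propagate_se_dlogra",
    "summarize_mutant",
]

LN10 = math.log(10.0)

#: minimum number of uncensored experiments for an uncensored summary row
MIN_EXPERIMENTS = 3


@dataclass(frozen=True)
class PharmSummaryRow:
    """Per-mutant, per-receptor pharmacology summary (one table row).

    Censored rows (``censored=True``) carry the potency bound in
    ``pec50_bound`` and NaN in the mutant parameter fields.  When available,
    the per-experiment values behind the summary are kept so the exact
    (raw-value) paths of the inferential layer can be used.
    """

    construct: str
    receptor: str
    wt_pec50: float
    wt_se: float
    mut_pec50: float
    mut_se: float
    delta_pec50: float
    emax_pct: float
    emax_se: float
    dlogra: float
    dlogra_se: float
    n: int
    censored: bool = False
    pec50_bound: float | None = None
    wt_pec50_values: tuple[float, ...] | None = None
    mut_pec50_values: tuple[float, ...] | None = None
    emax_values: tuple[float, ...] | None = None
    dlogra_values: tuple[float, ...] | None = None

    def check_identity(self, tol: float = 1e-9) -> bool:
        """dlog(RA) must equal delta_pEC50 + 2 - log10(Emax%) within tol."""
        if self.censored:
            return True
        lhs = self.dlogra
        rhs = self.delta_pec50 + 2.0 - math.log10(self.emax_pct)
        return abs(lhs - rhs) <= tol


def log_ra(emax_pct: float, pec50: float) -> float:
    """log10 relative activity, log10(Emax%) + pEC50.

    ``emax_pct`` is on the percent-of-WT scale (WT = 100, so WT's log(RA) is
    pEC50 + 2); ``pec50`` is -log10 EC50 with EC50 in molar.
    """
    if not emax_pct > 0:
        raise InputError(f"Emax must be positive to take its log, got {emax_pct}")
    if not math.isfinite(pec50):
        raise InputError(f"pEC50 must be finite, got {pec50}")
    return math.log10(emax_pct) + pec50


def propagate_se_dlogra(
    se_wt_pec50: float, se_mut_pec50: float, emax_pct: float, se_emax: float
) -> float:
    """Quadrature propagation of the dlog(RA) standard error."""
    return math.sqrt(
        se_wt_pec50**2 + se_mut_pec50**2 + (se_emax / (emax_pct * LN10)) ** 2
    )


def delta_log_ra(
    wt: tuple[float, float],
    mut: tuple[float, float],
    se_wt_pec50: float | None = None,
    se_mut_pec50: float | None = None,
    se_emax: float | None = None,
) -> tuple[float, float]:
    """WT-minus-mutant difference in log relative activity, with SE.

    ``wt`` and ``mut`` are (Emax%, pEC50) pairs; by convention the WT Emax is
    100.  Returns (dlogRA, se); the SE is NaN unless all three component SEs
    are supplied.
    """
    wt_emax, wt_pec50 = wt
    mut_emax, mut_pec50 = mut
    value = log_ra(wt_emax, wt_pec50) - log_ra(mut_emax, mut_pec50)
    if None in (se_wt_pec50, se_mut_pec50, se_emax):
        return value, float("nan")
    return value, propagate_se_dlogra(se_wt_pec50, se_mut_pec50, mut_emax, se_emax)


def _mean_se(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    se = arr.std(ddof=1) / math.sqrt(len(arr)) if len(arr) > 1 else float("nan")
    return float(arr.mean()), float(se)


def summarize_mutant(
    wt_fits: Sequence[LogisticFit],
    mut_fits: Sequence[LogisticFit],
    construct: str,
    receptor: str,
    span_floor_pct: float = 10.0,
    pec50_floor: float = 6.0,
) -> PharmSummaryRow:
    """Condense paired per-experiment fits into one summary row.

    ``wt_fits[i]`` and ``mut_fits[i]`` come from the same experiment.  pEC50
    columns are means +/- SE across experiments; the mutant Emax (%WT) is the
    normalized fitted plateau 100*(mut_top - wt_basal)/wt_span averaged
    across experiments; delta_pEC50 and dlog(RA) are computed from the
    unrounded means, the dlog(RA) SE by propagation.  The row is censored
    ("no curve") when fewer than MIN_EXPERIMENTS experiments yield an
    uncensored mutant fit, or when the summary itself falls below the
    reporting floors (mean normalized plateau under ``span_floor_pct``
    percent of the WT span, or mean potency under ``pec50_floor``); the
    reported bound is the potency floor.
    """
    if len(wt_fits) != len(mut_fits):
        raise PairingError(
            f"{construct}/{receptor}: {len(wt_fits)} WT vs {len(mut_fits)} mutant fits"
        )
    if len(wt_fits) < MIN_EXPERIMENTS:
        raise InputError(
            f"{construct}/{receptor}: need >= {MIN_EXPERIMENTS} experiments, got {len(wt_fits)}"
        )
    wt_pec50s = [f.pec50 for f in wt_fits if not f.censored]
    wt_mean, wt_se = _mean_se(wt_pec50s)
    n = len(mut_fits)
    live = [(w, m) for w, m in zip(wt_fits, mut_fits) if not m.censored]
    nan = float("nan")

    def censored_row() -> PharmSummaryRow:
        bound = next(
            (m.pec50_bound for m in mut_fits if m.censored and m.pec50_bound),
            pec50_floor,
        )
        return PharmSummaryRow(
            construct=construct, receptor=receptor,
            wt_pec50=wt_mean, wt_se=wt_se,
            mut_pec50=nan, mut_se=nan, delta_pec50=nan,
            emax_pct=nan, emax_se=nan, dlogra=nan, dlogra_se=nan,
            n=n, censored=True, pec50_bound=bound,
            wt_pec50_values=tuple(wt_pec50s),
        )

    if len(live) < MIN_EXPERIMENTS:
        return censored_row()
    mut_mean, mut_se_ = _mean_se([m.pec50 for _, m in live])
    emax_values = [100.0 * (m.top - w.basal) / w.span for w, m in live]
    emax_mean, emax_se = _mean_se(emax_values)
    if emax_mean < span_floor_pct or mut_mean < pec50_floor:
        return censored_row()
    delta = wt_mean - mut_mean
    dlogra = delta + 2.0 - math.log10(emax_mean)
    dlogra_se = propagate_se_dlogra(wt_se, mut_se_, emax_mean, emax_se)
    dlogra_values = tuple(
        (w.pec50 - m.pec50) + 2.0 - math.log10(max(e, 1e-12))
        for (w, m), e in zip(live, emax_values)
        if e > 0
    )
    return PharmSummaryRow(
        construct=construct, receptor=receptor,
        wt_pec50=wt_mean, wt_se=wt_se,
        mut_pec50=mut_mean, mut_se=mut_se_,
        delta_pec50=delta,
        emax_pct=emax_mean, emax_se=emax_se,
        dlogra=dlogra, dlogra_se=dlogra_se,
        n=n, censored=False,
        wt_pec50_values=tuple(wt_pec50s),
        mut_pec50_values=tuple(m.pec50 for _, m in live),
        emax_values=tuple(emax_values),
        dlogra_values=dlogra_values,
    )
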