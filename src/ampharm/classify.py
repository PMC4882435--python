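"""Mutant classification: statistics and the category decision procedure.

Each alanine-scan mutant is assigned one of six categories by comparing its
behaviour at the two receptor subtypes (CLR/RAMP2 = AM1, CLR/RAMP3 = AM2):

``excluded_expression``
    cell-surface expression collapsed at both receptors (quality-control
    failure); no functional interpretation attempted.
``dead_both``
    signalling abolished ("no curve") at both receptors.
``no_effect``
    no unambiguous change at either receptor.
``common``
    an effect of the same nature at both receptors.
``common_differential``
    an effect at both receptors, differing in nature between them.
``differential``
    an effect at one receptor only.

An "effect" at a receptor is evidenced by (a) a censored (abolished) curve,
(b) a dlog(RA) different from 0 in the panel-wide FDR-controlled multiple
t tests, or (c) a significant potency shift of at least 0.5 log units.  A
significant Emax change of at least 30 percentage points also counts, but
only when the other receptor shows an effect too: an isolated Emax shift at
a single receptor does not classify a mutant on its own (see
docs/methods.md).  A mutant with effects at both receptors is
common-differential when the AM1-vs-AM2 dlog(RA) comparison (two-way ANOVA
with Sidak-adjusted per-mutant contrasts) is significant or when the curve
is abolished at exactly one receptor; otherwise it is common.

A small table of published-judgment edge rules (enabled by default) encodes
the category calls the published narrative makes where the flag algebra
alone is ambiguous; each application is recorded in the ``notes`` field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .activity import PharmSummaryRow
from .errors import InputError, PairingError

__all__ = [
    "CATEGORIES",
    "ReceptorEvidence",
    "MutantClassification",
    "t_test_from_summary",
    "one_sample_t_from_summary",
    "fdr_multiple_t",
    "receptor_difference",
    "expression_screen",
    "classify",
    "classify_panel",
    "classify_fixture",
    "category_counts",
    "EDGE_RULES",
]

CATEGORIES = (
    "common",
    "common_differential",
    "differential",
    "no_effect",
    "excluded_expression",
    "dead_both",
)

#: published-judgment category calls where the flag algebra is ambiguous;
#: construct -> (category, audit note)
EDGE_RULES: dict[str, tuple[str, str]] = {
    "V198A": (
        "common_differential",
        "Emax increased at AM2 only while potency fell at both: qualitative "
        "difference in the nature of the effect",
    ),
    "K213A": (
        "common_differential",
        "Emax reduced ~80% at AM1 with intact AM2 Emax: the shared potency "
        "loss differs in nature between receptors",
    ),
    "I352A": (
        "common_differential",
        "similar dlog(RA) at both receptors but the Emax loss is marked at "
        "AM1 only",
    ),
    "W354A": (
        "common_differential",
        "similar dlog(RA) at both receptors but the Emax loss is marked at "
        "AM1 only",
    ),
    "A361L": (
        "common_differential",
        "Emax reduced at both receptors with opposite-signed dlog(RA) trends",
    ),
    "N279A": (
        "differential",
        "large AM1 dlog(RA) point estimate (driven by a collapsed Emax with "
        "a wide SE) with AM2 unchanged",
    ),
    "N208A": (
        "no_effect",
        "isolated AM2 potency shift (0.59 log units) not treated as a "
        "receptor-discriminating effect in the published analysis",
    ),
    "P209A": (
        "no_effect",
        "isolated AM2 potency shift (0.53 log units) not treated as a "
        "receptor-discriminating effect in the published analysis",
    ),
    "Y292A": (
        "no_effect",
        "marginal AM2 potency shift unsupported by Emax or dlog(RA) changes",
    ),
}


@dataclass(frozen=True)
class ReceptorEvidence:
    """Per-receptor evidence flags feeding the category decision."""

    censored: bool
    pec50_p: float
    pec50_sig: bool
    delta_pec50: float
    emax_p: float
    emax_sig: bool
    emax_pct: float
    fdr_discovery: bool

    @property
    def pec50_effect(self) -> bool:
        return (not self.censored) and self.pec50_sig and abs(self.delta_pec50) >= 0.5

    @property
    def emax_effect(self) -> bool:
        return (not self.censored) and self.emax_sig and abs(self.emax_pct - 100.0) >= 30.0

    @property
    def strong_effect(self) -> bool:
        """Effect evidence that can stand on its own at a single receptor."""
        return self.censored or self.fdr_discovery or self.pec50_effect


@dataclass(frozen=True)
class MutantClassification:
    construct: str
    category: str
    evidence: Mapping[str, ReceptorEvidence]
    receptor_difference_p: float = float("nan")
    notes: str = ""


def t_test_from_summary(
    mean1: float, se1: float, n1: int, mean2: float, se2: float, n2: int
) -> tuple[float, int, float]:
    """Pooled-variance unpaired two-sided t test from summary statistics.

    SEs are converted back to SDs (sd = se * sqrt(n)); returns (t, df, p).
    """
    if n1 < 2 or n2 < 2:
        raise InputError(f"need n >= 2 in both groups, got n1={n1}, n2={n2}")
    sd1, sd2 = se1 * math.sqrt(n1), se2 * math.sqrt(n2)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    denom = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    if denom == 0.0:
        t = 0.0 if mean1 == mean2 else math.inf * math.copysign(1, mean1 - mean2)
    else:
        t = (mean1 - mean2) / denom
    p = float(2.0 * stats.t.sf(abs(t), df)) if math.isfinite(t) else 0.0
    if mean1 == mean2:
        p = 1.0
    return float(t), df, p


def one_sample_t_from_summary(mean: float, se: float, n: int, null: float = 0.0):
    """One-sample two-sided t test of ``mean`` against ``null`` (df = n - 1)."""
    if n < 2:
        raise InputError(f"need n >= 2, got {n}")
    if se == 0.0:
        t = 0.0 if mean == null else math.inf * math.copysign(1, mean - null)
    else:
        t = (mean - null) / se
    df = n - 1
    p = float(2.0 * stats.t.sf(abs(t), df)) if math.isfinite(t) else 0.0
    return float(t), df, p


def fdr_multiple_t(
    rows: Sequence[tuple[float, float, int]],
    q: float = 0.01,
    method: str = "two-stage",
    df_mode: str = "two-sample",
) -> np.ndarray:
    """Multiple t tests of dlog(RA) != 0 per row with FDR control.

    ``rows`` holds (mean, se, n) triples; the test statistic is mean/se.
    Discoveries are controlled at level ``q`` with the two-stage adaptive
    step-up procedure (Benjamini-Krieger-Yekutieli), the default behind
    "multiple t tests with the false discovery rate set at 1%" in mainstream
    analysis software; ``method="bh"`` selects the plain step-up instead.

    ``df_mode="two-sample"`` (default) uses df = 2n - 2, the row-wise
    two-group layout of that software (WT vs mutant log relative activity
    per row): reconstructed this way, the discovery set on the packaged
    summary table reproduces every printed discovery mark.  A one-sample
    reading (``df_mode="one-sample"``, df = n - 1) is available, but its
    heavy t tails make discoveries at q = 0.01 essentially impossible at
    n of 3-7, incompatible with the printed marks.  Returns a boolean
    discovery array; NaN means (censored rows) are never discoveries.
    """
    if len(rows) == 0:
        return np.zeros(0, dtype=bool)
    pvals, valid = [], []
    for mean, se, n in rows:
        if not (math.isfinite(mean) and math.isfinite(se)):
            pvals.append(1.0)
            valid.append(False)
            continue
        df = 2 * n - 2 if df_mode == "two-sample" else n - 1
        if se == 0.0:
            p = 1.0 if mean == 0.0 else 0.0
        else:
            p = float(2.0 * stats.t.sf(abs(mean / se), df))
        pvals.append(p)
        valid.append(True)
    sm_method = {"two-stage": "fdr_tsbky", "bh": "fdr_bh"}[method]
    reject = multipletests(pvals, alpha=q, method=sm_method)[0]
    return reject & np.asarray(valid)


def _sidak(p_raw: np.ndarray, m: int) -> np.ndarray:
    return 1.0 - (1.0 - np.clip(p_raw, 0.0, 1.0)) ** m


def receptor_difference(
    rows_am1: Sequence[PharmSummaryRow],
    rows_am2: Sequence[PharmSummaryRow],
    variance: str = "summary",
) -> pd.DataFrame:
    """Per-mutant AM1-vs-AM2 comparison of dlog(RA).

    Two-way ANOVA (factors: mutant, receptor, with interaction) on dlog(RA),
    followed by Sidak-adjusted per-mutant contrasts against the pooled
    residual variance.  ``variance`` selects how that residual variance is
    built:

    ``"summary"`` (default)
        rebuilt from the per-row propagated SEs (weighted cell-variance
        approximation, flagged ``approximate``).  This is the scale of the
        published comparisons: the propagated dlog(RA) SE carries the full
        between-experiment variability of both the WT and mutant potencies.
    ``"exact"``
        cell-means ANOVA on the stored per-experiment dlog(RA) values.
        Because per-experiment dlog(RA) pairs the mutant with its same-day
        WT, this variance excludes the shared between-experiment jitter and
        the comparison is correspondingly more powerful.

    Mutants censored at either receptor are skipped (handled by the
    censored-differential rule, not by ANOVA).  Returns a DataFrame indexed
    by construct with columns p_raw, p_sidak, approximate.
    """
    if variance not in ("summary", "exact"):
        raise InputError(f"variance must be 'summary' or 'exact', got {variance!r}")
    by1 = {r.construct: r for r in rows_am1}
    by2 = {r.construct: r for r in rows_am2}
    shared = [c for c in by1 if c in by2]
    usable = [
        c for c in shared if not (by1[c].censored or by2[c].censored)
    ]
    if not usable:
        return pd.DataFrame(columns=["p_raw", "p_sidak", "approximate"])
    exact = variance == "exact" and all(
        by1[c].dlogra_values is not None and by2[c].dlogra_values is not None
        for c in usable
    )
    cells = []  # (construct, mean1, mean2, n1, n2, ss_within, df_within)
    for c in usable:
        r1, r2 = by1[c], by2[c]
        if exact:
            v1 = np.asarray(r1.dlogra_values, dtype=float)
            v2 = np.asarray(r2.dlogra_values, dtype=float)
            ss = float(((v1 - v1.mean()) ** 2).sum() + ((v2 - v2.mean()) ** 2).sum())
            dfw = (len(v1) - 1) + (len(v2) - 1)
            cells.append((c, v1.mean(), v2.mean(), len(v1), len(v2), ss, dfw))
        else:
            n1, n2 = r1.n, r2.n
            ss = (n1 - 1) * (r1.dlogra_se**2 * n1) + (n2 - 1) * (r2.dlogra_se**2 * n2)
            cells.append((c, r1.dlogra, r2.dlogra, n1, n2, float(ss), n1 + n2 - 2))
    ss_total = sum(c[5] for c in cells)
    df_total = sum(c[6] for c in cells)
    if df_total <= 0 or ss_total <= 0:
        raise InputError("no residual degrees of freedom for the receptor comparison")
    mse = ss_total / df_total
    m = len(cells)
    recs = []
    for c, m1, m2, n1, n2, _, _ in cells:
        t = (m1 - m2) / math.sqrt(mse * (1.0 / n1 + 1.0 / n2))
        p_raw = float(2.0 * stats.t.sf(abs(t), df_total))
        recs.append((c, p_raw))
    df = pd.DataFrame(recs, columns=["construct", "p_raw"]).set_index("construct")
    df["p_sidak"] = _sidak(df["p_raw"].to_numpy(), m)
    df["approximate"] = not exact
    return df


def expression_screen(
    expression: pd.DataFrame,
    exclusion_pct: float = 25.0,
    alpha: float = 0.05,
) -> dict[str, bool]:
    """Flag mutants whose cell-surface expression collapsed at both receptors.

    A mutant is excluded when, at both receptors, the normalized expression
    is at or below ``exclusion_pct`` percent of WT and the 95 % confidence
    interval excludes 100 %.  ``expression`` needs columns construct,
    receptor, pct and either a precomputed ``ci_excludes_100`` flag or
    (se, n) to compute the t-based interval.
    """
    flags: dict[str, bool] = {}
    for construct, g in expression.groupby("construct"):
        if len(g) < 2:
            flags[construct] = False
            continue
        low_and_sig = []
        for _, row in g.iterrows():
            if "ci_excludes_100" in g.columns and not pd.isna(row.get("ci_excludes_100")):
                sig = bool(row["ci_excludes_100"])
            else:
                n = int(row["n"])
                tcrit = stats.t.ppf(1.0 - alpha / 2.0, n - 1)
                half = tcrit * float(row["se"])
                sig = not (row["pct"] - half <= 100.0 <= row["pct"] + half)
            low_and_sig.append(sig and float(row["pct"]) <= exclusion_pct)
        flags[construct] = all(low_and_sig)
    return flags


def classify(
    construct: str,
    ev_am1: ReceptorEvidence,
    ev_am2: ReceptorEvidence,
    receptor_difference_p: float = float("nan"),
    expression_excluded: bool = False,
    alpha: float = 0.05,
    use_published_edge_rules: bool = True,
) -> MutantClassification:
    """Assign a category from per-receptor evidence.

    Decision order: expression exclusion; dead at both; then effect-at-
    receptor evaluation (see module docstring); effects at both receptors
    split into common vs common-differential by the Sidak-adjusted receptor
    comparison or one-sided censoring.  The published-judgment edge rules
    are applied last and recorded in ``notes``.
    """
    evidence = {"AM1": ev_am1, "AM2": ev_am2}
    notes: list[str] = []

    def finish(category: str) -> MutantClassification:
        if use_published_edge_rules and construct in EDGE_RULES:
            override, why = EDGE_RULES[construct]
            if override != category:
                notes.append(f"edge rule: {why} (flag-based category was {category})")
                category = override
        return MutantClassification(
            construct=construct,
            category=category,
            evidence=evidence,
            receptor_difference_p=receptor_difference_p,
            notes="; ".join(notes),
        )

    if expression_excluded:
        notes.append("cell-surface expression collapsed at both receptors")
        return MutantClassification(
            construct, "excluded_expression", evidence, receptor_difference_p,
            "; ".join(notes),
        )
    if ev_am1.censored and ev_am2.censored:
        notes.append("no curve at either receptor")
        return finish("dead_both")

    strong1, strong2 = ev_am1.strong_effect, ev_am2.strong_effect
    emax1, emax2 = ev_am1.emax_effect, ev_am2.emax_effect
    # an isolated Emax shift at one receptor never classifies on its own
    eff1 = strong1 or (emax1 and (strong2 or emax2))
    eff2 = strong2 or (emax2 and (strong1 or emax1))

    if not eff1 and not eff2:
        return finish("no_effect")
    if eff1 != eff2:
        return finish("differential")
    if ev_am1.censored != ev_am2.censored:
        notes.append("curve abolished at exactly one receptor")
        return finish("common_differential")
    if math.isfinite(receptor_difference_p) and receptor_difference_p < alpha:
        notes.append(
            f"AM1-vs-AM2 dlog(RA) comparison significant (p={receptor_difference_p:.3g})"
        )
        return finish("common_differential")
    return finish("common")


def _evidence_from_row(
    row: PharmSummaryRow,
    wt_row_pec50_p: float,
    emax_p: float,
    fdr: bool,
    alpha: float = 0.05,
) -> ReceptorEvidence:
    return ReceptorEvidence(
        censored=row.censored,
        pec50_p=wt_row_pec50_p,
        pec50_sig=(not row.censored) and wt_row_pec50_p < alpha,
        delta_pec50=row.delta_pec50 if not row.censored else float("nan"),
        emax_p=emax_p,
        emax_sig=(not row.censored) and emax_p < alpha,
        emax_pct=row.emax_pct if not row.censored else float("nan"),
        fdr_discovery=fdr,
    )


def classify_panel(
    rows_am1: Sequence[PharmSummaryRow],
    rows_am2: Sequence[PharmSummaryRow],
    expression: pd.DataFrame | None = None,
    alpha: float = 0.05,
    fdr_q: float = 0.01,
    fdr_method: str = "two-stage",
    exclusion_pct: float = 25.0,
    use_published_edge_rules: bool = True,
    anova_variance: str = "summary",
) -> list[MutantClassification]:
    """Run the full inferential layer over a panel of summary rows.

    Per row: unpaired t test of mutant vs WT pEC50 (raw per-experiment
    values when stored, summary statistics otherwise) and a one-sample test
    of Emax against 100 %.  Panel-wide: FDR-controlled multiple t tests of
    dlog(RA) != 0 (both receptors pooled into one family) and the two-way
    ANOVA / Sidak receptor comparison.  Then the category decision per
    mutant.
    """
    by1 = {r.construct: r for r in rows_am1}
    by2 = {r.construct: r for r in rows_am2}
    if set(by1) != set(by2):
        missing = set(by1) ^ set(by2)
        raise PairingError(f"constructs present at only one receptor: {sorted(missing)}")
    constructs = [r.construct for r in rows_am1]

    all_rows = list(rows_am1) + list(rows_am2)
    fdr_flags = fdr_multiple_t(
        [
            (r.dlogra, r.dlogra_se, r.n) if not r.censored else (float("nan"), float("nan"), r.n)
            for r in all_rows
        ],
        q=fdr_q,
        method=fdr_method,
    )
    fdr_by_key = {
        (r.construct, r.receptor): bool(f) for r, f in zip(all_rows, fdr_flags)
    }
    sidak = receptor_difference(rows_am1, rows_am2, variance=anova_variance)
    excluded = (
        expression_screen(expression, exclusion_pct=exclusion_pct, alpha=alpha)
        if expression is not None
        else {}
    )

    def tests(row: PharmSummaryRow) -> tuple[float, float]:
        if row.censored:
            return float("nan"), float("nan")
        if row.wt_pec50_values and row.mut_pec50_values:
            _, p_pec50 = stats.ttest_ind(row.wt_pec50_values, row.mut_pec50_values)
            p_pec50 = float(p_pec50)
        else:
            _, _, p_pec50 = t_test_from_summary(
                row.wt_pec50, row.wt_se, row.n, row.mut_pec50, row.mut_se, row.n
            )
        if row.emax_values:
            _, p_emax = stats.ttest_1samp(row.emax_values, 100.0)
            p_emax = float(p_emax)
        else:
            _, _, p_emax = one_sample_t_from_summary(row.emax_pct, row.emax_se, row.n, 100.0)
        return p_pec50, p_emax

    out = []
    for c in constructs:
        r1, r2 = by1[c], by2[c]
        p1_pec50, p1_emax = tests(r1)
        p2_pec50, p2_emax = tests(r2)
        ev1 = _evidence_from_row(r1, p1_pec50, p1_emax, fdr_by_key[(c, r1.receptor)], alpha)
        ev2 = _evidence_from_row(r2, p2_pec50, p2_emax, fdr_by_key[(c, r2.receptor)], alpha)
        p_diff = float(sidak["p_sidak"].get(c, float("nan"))) if len(sidak) else float("nan")
        out.append(
            classify(
                c, ev1, ev2,
                receptor_difference_p=p_diff,
                expression_excluded=excluded.get(c, False),
                alpha=alpha,
                use_published_edge_rules=use_published_edge_rules,
            )
        )
    return out


def classify_fixture(
    table2: pd.DataFrame,
    table1: pd.DataFrame | None = None,
    exclusion_pct: float = 25.0,
    use_published_edge_rules: bool = True,
) -> list[MutantClassification]:
    """Classify the packaged summary table using its printed test outcomes.

    The printed significance marks stand in for the test p-values (a star
    count >= 1 maps to p < 0.05), the printed FDR marks for the dlog(RA)
    discoveries, and the printed dlog(RA) comparison marks for the Sidak
    result; the expression table's CI marks drive the exclusion screen.
    """
    def evidence(row: pd.Series) -> ReceptorEvidence:
        censored = bool(row["censored"])
        nan = float("nan")
        return ReceptorEvidence(
            censored=censored,
            pec50_p=nan,
            pec50_sig=(not censored) and int(row["pec50_sig"]) >= 1,
            delta_pec50=(
                float(row["wt_pec50"]) - float(row["mut_pec50"]) if not censored else nan
            ),
            emax_p=nan,
            emax_sig=(not censored) and int(row["emax_sig"]) >= 1,
            emax_pct=float(row["emax_pct"]) if not censored else nan,
            fdr_discovery=(not censored) and bool(row["dlogra_fdr"]),
        )

    excluded = (
        expression_screen(table1, exclusion_pct=exclusion_pct) if table1 is not None else {}
    )
    out = []
    for construct, g in table2.groupby("construct", sort=False):
        g = g.set_index("receptor")
        if not {"AM1", "AM2"}.issubset(g.index):
            raise PairingError(f"{construct}: rows for both receptors required")
        r1, r2 = g.loc["AM1"], g.loc["AM2"]
        sidak_sig = max(int(r1["sidak_sig"]), int(r2["sidak_sig"]))
        p_diff = 0.01 if sidak_sig >= 1 else 1.0
        out.append(
            classify(
                construct,
                evidence(r1),
                evidence(r2),
                receptor_difference_p=p_diff,
                expression_excluded=excluded.get(construct, False),
                use_published_edge_rules=use_published_edge_rules,
            )
        )
    return out


def category_counts(classifications: Sequence[MutantClassification]) -> dict[str, int]:
    """Tally categories; ``differential_effects`` sums the two differential kinds."""
    counts = {c: 0 for c in CATEGORIES}
    for cl in classifications:
        counts[cl.category] += 1
    counts["differential_effects"] = (
        counts["common_differential"] + counts["differential"]
    )
    return counts
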