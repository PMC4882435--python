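"""Display rendering and the summary-table consistency audit.

Rounding is confined to this module: internal files carry full precision and
only the rendered table applies the display conventions (pEC50 and the
delta columns to 2 decimal places, percentages to 1, censored cells printed
"<6", ">2"/" >3", "No curve" and "-" exactly as the summary-table footnotes
define them).
"""

from __future__ import annotations

import math
from typing import Sequence

import pandas as pd

from .activity import PharmSummaryRow, delta_log_ra

__all__ = ["render_table2", "summary_rows_to_frame", "audit_table2"]

SUMMARY_CSV_COLUMNS = [
    "construct", "receptor", "wt_pec50", "wt_se", "mut_pec50", "mut_se",
    "delta_pec50", "emax_pct", "emax_se", "dlogRA", "dlogRA_se", "n", "censored",
]


def _pm(value: float, se: float, nd: int) -> str:
    if not math.isfinite(value):
        return "-"
    if not math.isfinite(se):
        return f"{value:.{nd}f}"
    return f"{value:.{nd}f} ± {se:.{nd}f}"


def render_table2(rows: Sequence[PharmSummaryRow]) -> str:
    """Render summary rows in the printed-table layout (one receptor block)."""
    header = ["Construct", "Receptor", "WT pEC50", "Mutant pEC50",
              "dLog pEC50", "Emax (%WT)", "dLog(RA)", "n"]
    lines = ["\t".join(header)]
    for r in rows:
        if r.censored:
            bound = r.pec50_bound if r.pec50_bound is not None else 6.0
            cells = [
                r.construct, r.receptor, _pm(r.wt_pec50, r.wt_se, 2),
                f"<{bound:g}", ">2", "No curve", "-", str(r.n),
            ]
        else:
            cells = [
                r.construct, r.receptor,
                _pm(r.wt_pec50, r.wt_se, 2),
                _pm(r.mut_pec50, r.mut_se, 2),
                f"{r.delta_pec50:.2f}",
                _pm(r.emax_pct, r.emax_se, 1),
                _pm(r.dlogra, r.dlogra_se, 2),
                str(r.n),
            ]
        lines.append("\t".join(cells))
    return "\n".join(lines)


def summary_rows_to_frame(rows: Sequence[PharmSummaryRow]) -> pd.DataFrame:
    """Full-precision summary-table CSV frame (the machine dialect)."""
    recs = []
    for r in rows:
        recs.append(
            (r.construct, r.receptor, r.wt_pec50, r.wt_se, r.mut_pec50, r.mut_se,
             r.delta_pec50, r.emax_pct, r.emax_se, r.dlogra, r.dlogra_se, r.n,
             int(r.censored))
        )
    return pd.DataFrame(recs, columns=SUMMARY_CSV_COLUMNS)


def audit_table2(table2: pd.DataFrame, tol: float = 0.03) -> pd.DataFrame:
    """Consistency audit of the packaged cAMP summary table.

    For every non-censored row, recompute dlog(RA) from the pEC50 and Emax
    columns via the identity dlogRA = (WT pEC50 - mutant pEC50) + 2 -
    log10(Emax%), compare with the printed value at ``tol``, and also report
    the printed delta-pEC50 column against the recomputed difference (the
    printed column contains several typos; the recomputed identity is the
    authoritative check).
    """
    recs = []
    for _, row in table2.iterrows():
        if bool(row["censored"]):
            continue
        value, _ = delta_log_ra(
            (100.0, float(row["wt_pec50"])),
            (float(row["emax_pct"]), float(row["mut_pec50"])),
        )
        delta = float(row["wt_pec50"]) - float(row["mut_pec50"])
        printed = float(row["dlogra"])
        printed_delta = float(row["delta_pec50_printed"])
        recs.append(
            {
                "construct": row["construct"],
                "receptor": row["receptor"],
                "dlogra_printed": printed,
                "dlogra_recomputed": value,
                "dlogra_abs_diff": abs(value - printed),
                "dlogra_consistent": abs(value - printed) <= tol,
                "delta_pec50_printed": printed_delta,
                "delta_pec50_recomputed": delta,
                "delta_pec50_consistent": abs(delta - printed_delta) <= 0.011,
            }
        )
    return pd.DataFrame(recs)
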