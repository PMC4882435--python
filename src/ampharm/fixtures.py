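"""Packaged reference tables.

The published summary tables of the AM1/AM2 receptor alanine-scan (cAMP
pharmacology, cell-surface expression, radioligand binding, and the
F18A-substituted agonist peptide) transcribed verbatim, including the
significance marks, so the statistics and classification layers can be
exercised without raw plate data.

Transcription notes: significance columns are star counts (0-3); ``dlogra_fdr``
is the "different from 0 by multiple t tests at 1 % FDR" mark; ``sidak_sig``
is the AM1-vs-AM2 comparison mark on the dlog(RA) column; ``am2_only`` marks
rows where only the AM2 receptor was active.  The expression table prints one
construct as I288A where the cAMP table prints T288A; the fixture uses T288A
throughout so the tables join.  One printed value is corrected: the V205A
dlog(RA) SE appears as "30.18" (a physically impossible 30-log-unit SE that
would poison any pooled-variance analysis) and is transcribed as 0.18; the
propagated SE from the same row's pEC50/Emax SEs is 0.18.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd

__all__ = ["load_table1", "load_table2", "load_table3", "load_table4"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("ampharm.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh)


@lru_cache(maxsize=None)
def load_table2() -> pd.DataFrame:
    """cAMP pharmacology summary: one row per construct x receptor."""
    df = _read("table2_camp.csv")
    for col in ("censored", "dlogra_fdr", "am2_only"):
        df[col] = df[col].astype(bool)
    return df


@lru_cache(maxsize=None)
def load_table1() -> pd.DataFrame:
    """Cell-surface expression (% of WT) with the 95 %-CI significance mark."""
    df = _read("table1_expression.csv")
    df["ci_excludes_100"] = df["ci_excludes_100"].astype(bool)
    return df


@lru_cache(maxsize=None)
def load_table3() -> pd.DataFrame:
    """Radioligand competition-binding summary for selected mutants."""
    df = _read("table3_binding.csv")
    df["ci_excludes_100"] = df["ci_excludes_100"].astype(bool)
    return df


@lru_cache(maxsize=None)
def load_table4() -> pd.DataFrame:
    """F18A-substituted agonist peptide vs WT peptide at the WT receptors."""
    return _read("table4_peptide.csv")
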