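"""End-to-end orchestration: fit -> summarize -> classify -> report.

Two input modes:

raw
    plate-level concentration-response CSV (the dialect written by
    :mod:`ampharm.simulate`).  Every experiment is fitted (free-Hill fit,
    Hill-unity test, constrained refit), censoring rules are applied against
    the paired WT fit, per-mutant summary rows are built, and the full
    inferential layer (t tests, FDR, ANOVA/Sidak, expression screen) runs.

summary
    an already-summarized table (the printed-table CSV dialect).  Fitting is
    skipped; the statistics and classification layers run either from the
    printed significance marks (fixture dialect) or from the summary
    statistics.

The pipeline is deterministic: same config + same inputs give byte-identical
outputs, recorded in a machine-readable run log.
"""

from __future__ import annotations

import json
import math
from collections import defaultdict
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .activity import PharmSummaryRow, summarize_mutant
from .classify import (
    MutantClassification,
    category_counts,
    classify_fixture,
    classify_panel,
)
from .config import PipelineConfig
from .errors import AmpharmError, DegenerateDataError, InputError, PairingError
from .fitting import LogisticFit, detect_censoring, test_hill_unity
from .report import audit_table2, summary_rows_to_frame
from .simulate import DoseResponseExperiment, read_panel_csv

__all__ = ["run_pipeline", "fit_panel", "summarize_panel"]


def fit_panel(
    exps: Sequence[DoseResponseExperiment],
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Fit every experiment; one result row per construct x receptor x experiment."""
    config = config or PipelineConfig()
    fits = {}
    for e in exps:
        try:
            test = test_hill_unity(e, alpha=config.alpha)
        except DegenerateDataError:
            continue  # unfittable curves are reported via the summary path
        fits[(e.construct, e.receptor, e.experiment)] = (e, test)
    rows = []
    for (construct, receptor, experiment), (e, test) in fits.items():
        f = test.chosen
        rows.append(
            (construct, receptor, experiment, e.wt_construct,
             f.basal, f.top, f.pec50, f.hill,
             f.se_basal, f.se_top, f.se_pec50, f.se_hill,
             f.rss, f.df, test.F, test.p, test.hill_constrained, f.converged)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "construct", "receptor", "experiment", "wt_construct",
            "basal", "top", "pec50", "hill",
            "se_basal", "se_top", "se_pec50", "se_hill",
            "rss", "df", "hill_F", "hill_p", "hill_constrained", "converged",
        ],
    )


def summarize_panel(
    exps: Sequence[DoseResponseExperiment],
    config: PipelineConfig | None = None,
) -> list[PharmSummaryRow]:
    """Per-experiment fits, censoring against the paired WT, summary rows."""
    config = config or PipelineConfig()
    chosen = {}
    for e in exps:
        try:
            fit = test_hill_unity(e, alpha=config.alpha).chosen
        except DegenerateDataError:
            # flat or unfittable responses: carry an unconverged fit so the
            # censoring rules (not a crash) decide the row's fate
            nan = float("nan")
            fit = LogisticFit(
                nan, nan, nan, nan, nan, nan, nan, nan,
                rss=float("inf"), df=0, n_points=len(e.points), converged=False,
            )
        chosen[(e.construct, e.receptor, e.experiment)] = fit
    groups = defaultdict(list)
    for e in exps:
        if e.wt_construct is None:
            continue
        groups[(e.construct, e.receptor)].append(e)
    rows = []
    for (construct, receptor), mut_exps in sorted(groups.items()):
        wt_fits, mut_fits = [], []
        for e in sorted(mut_exps, key=lambda x: x.experiment):
            wt_key = (e.wt_construct, receptor, e.experiment)
            if wt_key not in chosen:
                raise PairingError(
                    f"{construct}/{receptor}: no WT curve for experiment {e.experiment!r}"
                )
            wt_fit = chosen[wt_key]
            # per-experiment censoring on convergence, the potency floor and
            # the tested concentration window; the span floor is judged on
            # the summary mean (a single noisy experiment of a weak but real
            # responder should not void it)
            logc = [math.log10(c) for c, _ in e.points]
            pec50_range = (-max(logc) - 1.0, -min(logc) + 1.0)
            mut_fit = detect_censoring(
                chosen[(construct, receptor, e.experiment)],
                wt_fit,
                span_floor_frac=0.0,
                pec50_floor=config.pec50_floor,
                pec50_range=pec50_range,
            )
            wt_fits.append(wt_fit)
            mut_fits.append(mut_fit)
        rows.append(
            summarize_mutant(
                wt_fits, mut_fits, construct, receptor,
                span_floor_pct=100.0 * config.span_floor_frac,
                pec50_floor=config.pec50_floor,
            )
        )
    return rows


def _classify_rows(
    rows: Sequence[PharmSummaryRow],
    expression: pd.DataFrame | None,
    config: PipelineConfig,
) -> list[MutantClassification]:
    r1 = [r for r in rows if r.receptor == config.receptors[0]]
    r2 = [r for r in rows if r.receptor == config.receptors[1]]
    if not r1 or not r2:
        # a single-receptor panel cannot be classified into the
        # common/differential taxonomy; report summaries only
        return []
    return classify_panel(
        r1, r2,
        expression=expression,
        alpha=config.alpha,
        fdr_q=config.fdr_q,
        fdr_method=config.fdr_method,
        exclusion_pct=config.expression_exclusion_pct,
        use_published_edge_rules=config.use_published_edge_rules,
        anova_variance=config.anova_variance,
    )


def _summary_frame_to_rows(df: pd.DataFrame) -> list[PharmSummaryRow]:
    rows = []
    dlog_col = "dlogRA" if "dlogRA" in df.columns else "dlogra"
    se_col = dlog_col + ("_se" if dlog_col == "dlogRA" else "_se")
    nan = float("nan")
    for _, r in df.iterrows():
        censored = bool(r["censored"])
        delta = r.get("delta_pec50")
        if delta is None or (isinstance(delta, float) and math.isnan(delta)):
            delta = (
                float(r["wt_pec50"]) - float(r["mut_pec50"]) if not censored else nan
            )
        rows.append(
            PharmSummaryRow(
                construct=str(r["construct"]),
                receptor=str(r["receptor"]),
                wt_pec50=float(r["wt_pec50"]),
                wt_se=float(r["wt_se"]),
                mut_pec50=float(r["mut_pec50"]) if not censored else nan,
                mut_se=float(r["mut_se"]) if not censored else nan,
                delta_pec50=float(delta) if not censored else nan,
                emax_pct=float(r["emax_pct"]) if not censored else nan,
                emax_se=float(r["emax_se"]) if not censored else nan,
                dlogra=float(r[dlog_col]) if not censored else nan,
                dlogra_se=float(r[se_col]) if not censored else nan,
                n=int(r["n"]),
                censored=censored,
                pec50_bound=6.0 if censored else None,
            )
        )
    return rows


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured pipeline and write the report bundle.

    Returns a dict with the summary rows, classifications, category tallies
    and output paths.  Any stage failure aborts with the stage name; no
    partial outputs are left in ``outdir``.
    """
    config.validate()
    if not config.raw_csv and not config.summary_csv:
        raise InputError("no input: set raw_csv or summary_csv")
    outdir = Path(config.outdir)
    expression = None
    if config.expression_csv:
        expression = pd.read_csv(config.expression_csv)

    artefacts: dict[str, object] = {}
    stage = "read"
    try:
        if config.raw_csv:
            exps = read_panel_csv(config.raw_csv)
            if not exps:
                raise InputError(f"no experiments found in {config.raw_csv}")
            stage = "fit"
            fit_frame = fit_panel(exps, config)
            stage = "summarize"
            rows = summarize_panel(exps, config)
            stage = "classify"
            classifications = _classify_rows(rows, expression, config)
            artefacts["fits"] = fit_frame
        else:
            stage = "summarize"
            df = pd.read_csv(config.summary_csv)
            if df.empty:
                raise InputError(f"no rows found in {config.summary_csv}")
            if "pec50_sig" in df.columns:
                # fixture dialect: printed significance marks drive the tests
                stage = "classify"
                classifications = classify_fixture(
                    df,
                    expression,
                    exclusion_pct=config.expression_exclusion_pct,
                    use_published_edge_rules=config.use_published_edge_rules,
                )
                rows = _summary_frame_to_rows(
                    df.rename(columns={"dlogra": "dlogRA", "dlogra_se": "dlogRA_se"})
                )
                artefacts["audit"] = audit_table2(df)
            else:
                rows = _summary_frame_to_rows(df)
                stage = "classify"
                classifications = _classify_rows(rows, expression, config)
    except AmpharmError as err:
        raise type(err)(f"[stage: {stage}] {err}") from err

    counts = category_counts(classifications)
    outdir.mkdir(parents=True, exist_ok=True)
    summary_path = outdir / "summary.csv"
    summary_rows_to_frame(rows).to_csv(summary_path, index=False, float_format="%.17g")
    cls_path = outdir / "classification.csv"
    pd.DataFrame(
        [
            {
                "construct": c.construct,
                "category": c.category,
                "receptor_difference_p": c.receptor_difference_p,
                "notes": c.notes,
            }
            for c in classifications
        ]
    ).to_csv(cls_path, index=False)
    if "fits" in artefacts:
        artefacts["fits"].to_csv(outdir / "fits.csv", index=False, float_format="%.17g")
    if "audit" in artefacts:
        artefacts["audit"].to_csv(outdir / "table2_audit.csv", index=False)
    log = {
        "package": "ampharm",
        "version": __version__,
        "config": config.to_dict(),
        "n_summary_rows": len(rows),
        "n_censored_rows": sum(r.censored for r in rows),
        "category_counts": counts,
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2), encoding="utf-8")
    return {
        "rows": rows,
        "classifications": classifications,
        "counts": counts,
        "outdir": str(outdir),
    }
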