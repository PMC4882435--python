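"""Curve fitting: exact recovery, oracles, censoring rules, binding fits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ampharm.errors import AlignmentError, DegenerateDataError, InputError
from ampharm.fitting import (
    combine_normalized,
    detect_censoring,
    fit_binding3,
    fit_logistic3,
    fit_logistic4,
    logistic4,
    normalize_to_wt,
)
from ampharm.fitting import test_hill_unity as hill_unity  # avoid pytest collection
from ampharm.simulate import DoseResponseExperiment, default_concentrations

from conftest import make_experiment


def _grid_search_oracle(exp, hills=(1.0,), refine=3, fix_hill=None):
    """Independent fit: exhaustive (pEC50, hill) grid with the analytic
    least-squares solve of (basal, top) at each node, then local refinement.
    ``fix_hill`` freezes the slope (the 3PL oracle).
    """
    logc = np.array([math.log10(c) for c, _ in exp.points])
    y = np.array([np.mean(r) for _, r in exp.points])

    def rss_at(pec50, hill):
        f = 1.0 / (1.0 + 10.0 ** np.clip((-pec50 - logc) * hill, -300, 300))
        X = np.stack([1.0 - f, f], axis=1)  # columns: basal, top
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = X @ coef - y
        return float(resid @ resid), coef

    p_lo, p_hi = -logc.max() - 1, -logc.min() + 1
    h_lo, h_hi = min(hills) - 0.5, max(hills) + 0.5
    best = None
    for _ in range(refine + 1):
        h_grid = [fix_hill] if fix_hill is not None else np.linspace(h_lo, h_hi, 41)
        for p in np.linspace(p_lo, p_hi, 61):
            for h in h_grid:
                rss, coef = rss_at(p, h)
                if best is None or rss < best[0]:
                    best = (rss, p, h, coef)
        _, p0, h0, _ = best
        dp, dh = (p_hi - p_lo) / 60, (h_hi - h_lo) / 40
        p_lo, p_hi = p0 - 2 * dp, p0 + 2 * dp
        h_lo, h_hi = h0 - 2 * dh, h0 + 2 * dh
    return best  # (rss, pec50, hill, (basal, top))


@pytest.mark.parametrize(
    "basal, top, pec50, hill",
    [(0.0, 100.0, 9.0, 1.0), (20.0, 120.0, 8.3, 1.0), (0.0, 50.0, 9.7, 2.0)],
)
def test_noiseless_recovery_exact(basal, top, pec50, hill):
    exp = make_experiment(basal=basal, top=top, pec50=pec50, hill=hill)
    fit = fit_logistic4(exp)
    assert fit.converged
    assert fit.pec50 == pytest.approx(pec50, abs=1e-6)
    assert fit.basal == pytest.approx(basal, abs=1e-6)
    assert fit.top == pytest.approx(top, abs=1e-6)
    assert fit.hill == pytest.approx(hill, abs=1e-6)
    assert fit.top >= fit.basal
    assert fit.df == len(exp.points) - 4


def test_noisy_fit_matches_grid_search_oracle():
    exp = make_experiment(noise_sd=5.0, n_replicates=3, seed=11)
    fit = fit_logistic4(exp)
    rss_o, pec50_o, hill_o, _ = _grid_search_oracle(exp, hills=(0.5, 1.0, 2.0))
    assert fit.pec50 == pytest.approx(pec50_o, abs=1e-4)
    assert fit.hill == pytest.approx(hill_o, abs=1e-3)
    assert fit.rss <= rss_o + 1e-9


def test_inverted_curve_reports_negative_hill():
    exp = make_experiment(basal=100.0, top=0.0, pec50=9.0, hill=1.0)
    # basal > top with hill 1 is a decreasing curve; the canonical fit keeps
    # top >= basal and flips the Hill sign instead of mis-orienting silently
    fit = fit_logistic4(exp)
    assert fit.converged
    assert fit.top >= fit.basal
    assert fit.hill < 0


def test_too_few_concentrations_raises():
    exp = make_experiment(concentrations=(1e-10, 1e-9, 1e-8, 1e-7))
    with pytest.raises(InputError, match="5"):
        fit_logistic4(exp)


def test_constant_responses_raise_degenerate():
    exp = DoseResponseExperiment(
        "X", "AM1", "e1", tuple((c, (5.0,)) for c in default_concentrations())
    )
    with pytest.raises(DegenerateDataError):
        fit_logistic4(exp)


def test_hill_unity_noiseless_identity():
    """Data generated with hill = 1 and no noise: F = 0, p = 1, 3PL chosen."""
    exp = make_experiment(hill=1.0)
    res = hill_unity(exp)
    assert res.F == 0.0
    assert res.p == 1.0
    assert res.hill_constrained
    assert res.chosen.hill_fixed
    assert res.chosen.pec50 == pytest.approx(9.0, abs=1e-6)


def test_hill_unity_detects_steep_slope():
    """A genuinely steep curve (hill = 3) at low noise rejects unity."""
    rejected = 0
    for seed in range(10):
        exp = make_experiment(hill=3.0, noise_sd=1.0, n_replicates=3, seed=seed)
        res = hill_unity(exp)
        rejected += not res.hill_constrained
    assert rejected >= 8


def test_3pl_rss_never_beats_4pl():
    for seed in range(5):
        exp = make_experiment(noise_sd=6.0, n_replicates=2, seed=seed)
        assert fit_logistic3(exp).rss >= fit_logistic4(exp).rss - 1e-9


@given(scale=st.floats(min_value=0.05, max_value=50.0))
@settings(max_examples=10, deadline=None)
def test_fit_invariant_to_response_scaling(scale):
    """Multiplying all responses by a positive constant leaves pEC50 fixed
    and scales the span."""
    base = make_experiment(noise_sd=4.0, n_replicates=2, seed=3)
    scaled = DoseResponseExperiment(
        base.construct, base.receptor, base.experiment,
        tuple((c, tuple(scale * r for r in rs)) for c, rs in base.points),
    )
    f0, f1 = fit_logistic3(base), fit_logistic3(scaled)
    assert f1.pec50 == pytest.approx(f0.pec50, abs=1e-6)
    assert f1.span == pytest.approx(scale * f0.span, rel=1e-6)


def test_normalize_anchors_and_published_plateau():
    wt_exp = make_experiment(basal=10.0, top=110.0, pec50=9.51, construct="WT")
    wt_fit = fit_logistic4(wt_exp)
    # anchor points: a response at the WT basal maps to 0, at the WT top to 100
    anchors = DoseResponseExperiment(
        "A", "AM1", "e1",
        ((1e-12, (wt_fit.basal,)), (1e-6, (wt_fit.top,))),
    )
    normed = normalize_to_wt(anchors, wt_fit)
    assert normed.points[0][1][0] == pytest.approx(0.0, abs=1e-9)
    assert normed.points[1][1][0] == pytest.approx(100.0, abs=1e-9)
    # WT's own noiseless data through its own fit spans 0..100 (the fitted
    # plateau of the normalized curve is exactly 100, the basal exactly 0)
    wt_norm_fit = fit_logistic4(normalize_to_wt(wt_exp, wt_fit))
    assert wt_norm_fit.basal == pytest.approx(0.0, abs=1e-4)
    assert wt_norm_fit.top == pytest.approx(100.0, abs=1e-4)
    # a mutant at 17.7 % of the WT span plateaus at 17.7 when normalized
    mut = make_experiment(basal=10.0, top=10.0 + 17.7, pec50=7.32, construct="R274A")
    mut_fit = fit_logistic4(normalize_to_wt(mut, wt_fit))
    assert mut_fit.top == pytest.approx(17.7, abs=1e-6)


def test_normalize_rejects_degenerate_wt_span():
    from ampharm.errors import DegenerateNormalizationError
    from dataclasses import replace

    exp = make_experiment()
    bad = replace(fit_logistic4(exp), top=0.0, basal=0.0)
    with pytest.raises(DegenerateNormalizationError):
        normalize_to_wt(exp, bad)


def test_combine_single_and_degenerate():
    e = make_experiment(noise_sd=2.0, n_replicates=3, seed=1)
    single = combine_normalized([e])
    per_conc = [np.mean(rs) for _, rs in e.points]
    np.testing.assert_allclose([m for _, m, _ in single.points], per_conc)
    assert all(math.isnan(se) for _, _, se in single.points)
    twin = combine_normalized([e, e])
    assert all(se == 0.0 for _, _, se in twin.points)


def test_combine_matches_two_stage_averaging_oracle():
    exps = [make_experiment(noise_sd=3.0, n_replicates=3, seed=s) for s in range(4)]
    combined = combine_normalized(exps)
    # oracle: replicate means within experiment, then mean/SE across
    stage1 = np.array([[np.mean(rs) for _, rs in e.points] for e in exps])
    np.testing.assert_allclose([m for _, m, _ in combined.points], stage1.mean(axis=0))
    np.testing.assert_allclose(
        [se for _, _, se in combined.points],
        stage1.std(axis=0, ddof=1) / math.sqrt(4),
    )


def test_combine_rejects_mismatched_grids():
    a = make_experiment()
    b = make_experiment(concentrations=tuple(c * 1.2 for c in default_concentrations()))
    with pytest.raises(AlignmentError):
        combine_normalized([a, b])


def test_normalization_commutes_with_combination():
    wt_fit = fit_logistic4(make_experiment(basal=5.0, top=105.0))
    exps = [make_experiment(noise_sd=3.0, n_replicates=2, seed=s) for s in range(3)]
    first = combine_normalized([normalize_to_wt(e, wt_fit) for e in exps])
    raw = combine_normalized(exps)
    span = wt_fit.span
    second = [(100.0 * (m - wt_fit.basal) / span) for _, m, _ in raw.points]
    np.testing.assert_allclose([m for _, m, _ in first.points], second, atol=1e-9)


def test_detect_censoring_rules():
    wt_fit = fit_logistic4(make_experiment())
    healthy = fit_logistic4(make_experiment(top=80.0, pec50=8.5))
    assert not detect_censoring(healthy, wt_fit).censored

    flat = fit_logistic4(make_experiment(top=9.9, pec50=8.5))  # 9.9 % of WT span
    censored = detect_censoring(flat, wt_fit)
    assert censored.censored
    assert censored.pec50_bound == 6.0
    assert math.isnan(censored.pec50)

    weak = fit_logistic4(
        make_experiment(pec50=5.5, concentrations=tuple(10.0 ** (-9 + 0.5 * k) for k in range(13)))
    )
    assert detect_censoring(weak, wt_fit).censored  # below the pEC50 floor

    out = fit_logistic4(make_experiment(pec50=9.0))
    assert detect_censoring(out, wt_fit, pec50_range=(10.0, 14.0)).censored


BINDING_CONCS = tuple(10.0 ** (-11 + 0.6 * k) for k in range(9)) + (3e-6,)


def _binding_exp(top=5000.0, bottom=800.0, pic50=8.56, noise_sd=0.0, seed=0):
    logc = np.log10(np.array(BINDING_CONCS))
    y = bottom + (top - bottom) / (1.0 + 10.0 ** (logc + pic50))
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        y = y + noise_sd * rng.standard_normal(len(y))
    return DoseResponseExperiment(
        "WT", "AM1", "b1", tuple((c, (float(v),)) for c, v in zip(BINDING_CONCS, y))
    )


def test_binding_noiseless_recovery():
    fit = fit_binding3(_binding_exp())
    assert fit.converged and not fit.censored
    assert fit.pic50 == pytest.approx(8.56, abs=1e-6)
    assert fit.specific == pytest.approx(4200.0, abs=1e-3)


def test_binding_all_nonspecific_is_censored():
    exp = DoseResponseExperiment(
        "X", "AM1", "b2", tuple((c, (800.0,)) for c in BINDING_CONCS)
    )
    assert fit_binding3(exp).censored


def test_binding_requires_nonspecific_point():
    exp = DoseResponseExperiment(
        "X", "AM1", "b3",
        tuple((c, (800.0,)) for c in BINDING_CONCS[:-1]),
    )
    with pytest.raises(InputError, match="nonspecific"):
        fit_binding3(exp)


def test_binding_noisy_matches_grid_oracle():
    exp = _binding_exp(noise_sd=60.0, seed=4)
    fit = fit_binding3(exp)
    # oracle on the reversed (increasing) problem, hill fixed at 1
    flipped = DoseResponseExperiment(
        "X", "AM1", "b4", tuple((c, tuple(-r for r in rs)) for c, rs in exp.points)
    )
    _, pec50_o, _, _ = _grid_search_oracle(flipped, fix_hill=1.0)
    assert fit.pic50 == pytest.approx(pec50_o, abs=1e-4)
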