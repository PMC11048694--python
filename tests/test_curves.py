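"""Exponential learning-curve model: formula, sampler, comparison."""

import warnings

import numpy as np
import pandas as pd
import pytest

from skillcurve import curves, synth
from skillcurve.curves import CurveParams, MCMCConfig, curve_value


# ---------------------------------------------------------------------------
# curve formula


def test_curve_anchors_baseline_at_trial_one():
    for gamma in (-5.0, 0.0, 2.0):
        assert curve_value(CurveParams(10.0, 40.0, gamma), 1) == pytest.approx(10.0)


def test_curve_rate_zero_limit_is_flat():
    p = CurveParams(10.0, 40.0, -30.0)  # exp(gamma) ~ 0: no learning
    for t in (1, 5, 20, 200):
        assert curve_value(p, t) == pytest.approx(10.0, abs=1e-6)


def test_curve_value_against_scalar_formula():
    # eta(3) = 40 + (10-40) * exp(-exp(0)*2)
    import math

    expected = 40.0 + (10.0 - 40.0) * math.exp(-2.0)
    assert curve_value(CurveParams(10.0, 40.0, 0.0), 3) == pytest.approx(expected, abs=1e-12)
    assert expected == pytest.approx(35.9399, abs=5e-4)


def test_curve_monotone_between_baseline_and_asymptote():
    t = np.arange(1, 41)
    rng = np.random.default_rng(1)
    for _ in range(50):
        a, b, g = rng.uniform(5, 30), rng.uniform(20, 70), rng.uniform(-3, 1)
        eta = curve_value(CurveParams(a, b, g), t)
        d = np.diff(eta)
        assert np.all(d >= -1e-12) if b >= a else np.all(d <= 1e-12)
        assert np.all(eta >= min(a, b) - 1e-9) and np.all(eta <= max(a, b) + 1e-9)


# ---------------------------------------------------------------------------
# hierarchical sampler


def _shared_params_data(n=20, T=20, sigma=0.2, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(1, T + 1, dtype=float)
    eta = curve_value(CurveParams(15.0, 45.0, -1.0), t)
    return eta[None, :] + rng.normal(scale=sigma, size=(n, T))


def test_degenerate_recovery_shared_parameters(reduced_mcmc):
    """All participants share one curve at near-zero noise: population
    means land within 2% of the generating values."""
    y = _shared_params_data()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        post = curves.fit_hierarchical(y, reduced_mcmc)
    ps = post.population_summary()
    assert ps["mu_alpha"]["mean"] == pytest.approx(15.0, rel=0.02)
    assert ps["mu_beta"]["mean"] == pytest.approx(45.0, rel=0.02)
    assert ps["mu_gamma"]["mean"] == pytest.approx(-1.0, rel=0.05, abs=0.05)


def test_posterior_predictive_within_data_hull(default_study, tiny_mcmc):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        post = curves.fit_hierarchical(default_study.trial_scores, tiny_mcmc, task="pad")
    fitted = post.fitted_curves().to_numpy()
    sig = float(post.chains.stacked("sigma").mean())
    lo, hi = np.nanmin(post.y), np.nanmax(post.y)
    assert fitted.min() >= lo - 3 * sig
    assert fitted.max() <= hi + 3 * sig


def test_seeded_runs_are_bit_reproducible(tiny_mcmc):
    y = _shared_params_data(n=8, sigma=1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p1 = curves.fit_hierarchical(y, tiny_mcmc)
        p2 = curves.fit_hierarchical(y, tiny_mcmc)
    for k in p1.chains.draws:
        np.testing.assert_array_equal(p1.chains.draws[k], p2.chains.draws[k])


def test_rejects_nonfinite_and_warns_on_constant():
    y = _shared_params_data(n=5)
    y[0, 0] = np.inf
    with pytest.raises(ValueError, match="non-finite"):
        curves.fit_hierarchical(y, MCMCConfig(chains=1, iterations=10, warmup=5))
    with pytest.warns(UserWarning, match="identical"):
        with warnings.catch_warnings():
            warnings.simplefilter("always")
            try:
                curves.fit_hierarchical(np.full((4, 6), 7.0),
                                        MCMCConfig(chains=1, iterations=20, warmup=10))
            except Exception:
                pass


def test_individual_estimates_and_cross_task_correlation(default_study, tiny_mcmc):
    """Cross-task correlations of individual estimates reflect the
    generator's shared components (attenuation-aware bands), and
    permuting one task's labels destroys them."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        post_a = curves.fit_hierarchical(default_study.trial_scores, tiny_mcmc, task="piano")
        post_b = curves.fit_hierarchical(default_study.trial_scores, tiny_mcmc, task="pad")
    ia, ib = curves.individual_estimates(post_a), curves.individual_estimates(post_b)
    assert list(ia.columns) == ["alpha", "beta", "gamma"]
    r_beta = np.corrcoef(ia["beta"], ib["beta"])[0, 1]
    r_gamma = np.corrcoef(ia["gamma"], ib["gamma"])[0, 1]
    assert 0.55 <= r_beta <= 0.95          # generator cross-task corr 0.8
    assert 0.2 <= r_gamma <= 0.8           # generator cross-task corr 0.5, attenuated
    # permuted labels -> near-zero association
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(ib))
    r_perm = np.corrcoef(ia["gamma"], ib["gamma"].to_numpy()[perm])[0, 1]
    assert abs(r_perm) < 0.3


def test_truth_recovery_single_participant(tiny_mcmc):
    y = _shared_params_data(n=1, sigma=0.05, seed=3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        post = curves.fit_hierarchical(y, tiny_mcmc)
    est = curves.individual_estimates(post).iloc[0]
    assert est["alpha"] == pytest.approx(15.0, abs=0.5)
    assert est["beta"] == pytest.approx(45.0, abs=0.5)
    assert est["gamma"] == pytest.approx(-1.0, abs=0.1)


# ---------------------------------------------------------------------------
# model comparison


def test_elpd_self_difference_is_zero(tiny_mcmc):
    y = _shared_params_data(n=10, sigma=2.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        comp = curves.compare_models(y, families=("exponential",), config=tiny_mcmc)
    assert float(comp.diff.loc["exponential", "exponential"]) == 0.0


def test_exponential_beats_linear_on_exponential_data(tiny_mcmc):
    cfg = synth.SynthConfig(n_participants=30, seed=41)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fac, _ = synth.gen_factors(cfg)
        scores, _ = synth.gen_performance(cfg, fac)
        comp = curves.compare_models(scores, families=("linear", "exponential"),
                                     config=tiny_mcmc, task="pad")
    assert comp.elpd["exponential"] > comp.elpd["linear"]
    assert comp.best() == "exponential"


def test_linear_data_nesting_check(tiny_mcmc):
    """On straight-line data with per-participant intercept and slope
    heterogeneity, the exponential's elpd is within 2 SE of linear."""
    rng = np.random.default_rng(5)
    n, T = 30, 20
    t = np.arange(1, T + 1, dtype=float)
    icpt = 20 + rng.normal(scale=3, size=(n, 1))
    slope = 0.5 + rng.normal(scale=0.15, size=(n, 1))
    y = icpt + slope * t[None, :] + rng.normal(scale=3.0, size=(n, T))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        comp = curves.compare_models(y, families=("linear", "exponential"),
                                     config=tiny_mcmc)
    d = float(comp.diff.loc["linear", "exponential"])
    se = float(comp.diff_se.loc["linear", "exponential"])
    assert abs(d) <= 2 * se
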