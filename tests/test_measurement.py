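"""CFA estimation, fit indices (vs a closed-form oracle), factor scores."""

import numpy as np
import pandas as pd
import pytest

from skillcurve import measurement as M
from skillcurve import synth


def fit_index_oracle(chi2_m, df_m, chi2_b, df_b, n):
    """Independently coded incremental/absolute fit-index formulas."""
    d_m = chi2_m - df_m
    d_b = chi2_b - df_b
    cfi = 1.0 - max(d_m, 0.0) / max(d_b, d_m, 0.0) if max(d_b, d_m, 0.0) > 0 else 1.0
    tli = ((chi2_b / df_b) - (chi2_m / df_m)) / ((chi2_b / df_b) - 1.0)
    ifi = (chi2_b - chi2_m) / (chi2_b - df_m)
    rmsea = np.sqrt(max(d_m, 0.0) / (df_m * (n - 1)))
    return cfi, tli, ifi, rmsea


# ---------------------------------------------------------------------------
# prepare_indicators


def test_standardization_two_point_and_orientation():
    df = pd.DataFrame({"C": [10.0, 20.0], "SS": [1.0, 2.0], "ZVT": [30.0, 60.0]})
    out = M.prepare_indicators(df, columns=["C", "SS", "ZVT"])
    # sample-SD (n-1) convention: two points map to +/- 1/sqrt(2)
    assert np.allclose(sorted(out["C"]), [-np.sqrt(0.5), np.sqrt(0.5)])
    # ZVT is a completion time: the slower participant gets the lower score
    assert out["ZVT"].iloc[1] < out["ZVT"].iloc[0]
    assert np.allclose(out.mean(), 0, atol=1e-12)
    assert np.allclose(out.std(ddof=1), 1, atol=1e-12)


def test_zero_variance_column_rejected():
    df = pd.DataFrame({"ZVT": [30.0, 30.0, 30.0], "C": [1.0, 2.0, 3.0]})
    with pytest.raises(ValueError, match="ZVT"):
        M.prepare_indicators(df, columns=["ZVT", "C"])


# ---------------------------------------------------------------------------
# fit_cfa


def test_noiseless_two_factor_identifiability():
    """Data generated exactly from a 2-factor model with zero residual
    noise are recovered up to sign at tight tolerance."""
    rng = np.random.default_rng(3)
    lam = np.array([[0.9, 0.0], [0.8, 0.0], [0.7, 0.0],
                    [0.0, 0.9], [0.0, 0.8], [0.0, 0.7]])
    phi = np.array([[1.0, 0.3], [0.3, 1.0]])
    f = rng.multivariate_normal(np.zeros(2), phi, size=4000)
    X = f @ lam.T + rng.normal(scale=1e-6, size=(4000, 6))
    cols = [f"v{i}" for i in range(6)]
    spec = M.CFASpec(structure={"F1": cols[:3], "F2": cols[3:]})
    ind = pd.DataFrame(X, columns=cols)
    model = M.fit_cfa(ind, spec, compute_se=False)
    # implied covariance reproduces S up to the residual-variance floor
    S = model.sample_cov.to_numpy()
    assert np.abs(model.implied_cov() - S).max() < 5e-4
    est = np.abs(model.loadings.to_numpy()[lam != 0])
    assert np.abs(est - np.abs(lam[lam != 0])).max() < 0.01  # finite-sample factor scale
    assert abs(model.factor_cov.iloc[0, 1] - 0.3) < 0.05


def test_battery_structure_recovery_n500():
    """Loadings of the four-factor battery model recovered within 0.1 at
    n=500 (unit-variance indicators, primary loadings 0.7)."""
    cfg = synth.SynthConfig(n_participants=500, bsr_missing_fraction=0.0, seed=17)
    _, battery = synth.gen_factors(cfg)
    ind = M.prepare_indicators(battery)
    model = M.fit_cfa(ind, compute_se=False)
    assert model.converged
    pat = model.spec.loading_pattern()
    est = model.loadings.to_numpy()
    true = cfg.loadings.reindex(model.loadings.index)[model.loadings.columns].to_numpy()
    assert np.abs(est[pat] - true[pat]).max() < 0.1
    # factor correlations near truth too
    assert np.abs(model.factor_cov.to_numpy() - cfg.factor_corr.to_numpy()).max() < 0.12


def test_fiml_handles_missing_bsr():
    cfg = synth.SynthConfig(n_participants=400, seed=23)
    _, battery = synth.gen_factors(cfg)
    ind = M.prepare_indicators(battery)
    assert ind["BS_R"].isna().any()
    model = M.fit_cfa(ind, compute_se=False)
    assert model.estimator == "fiml"
    pat = model.spec.loading_pattern()
    true = cfg.loadings.reindex(model.loadings.index)[model.loadings.columns].to_numpy()
    assert np.abs(model.loadings.to_numpy()[pat] - true[pat]).max() < 0.12


def test_orthogonal_spec_gives_identity_phi():
    rng = np.random.default_rng(5)
    cols = [f"v{i}" for i in range(6)]
    spec = M.CFASpec(structure={"F1": cols[:3], "F2": cols[3:]},
                     fixed_zero_corr=[("F1", "F2")])
    X = rng.standard_normal((300, 6))
    model = M.fit_cfa(pd.DataFrame(X, columns=cols), spec, compute_se=False)
    assert np.allclose(model.factor_cov.to_numpy(), np.eye(2))


# ---------------------------------------------------------------------------
# fit indices


def test_fit_indices_match_formula_oracle():
    """Indices computed by the package match the independently coded
    closed-form oracle to 1e-8 on random small models."""
    rng = np.random.default_rng(11)
    cols = [f"v{i}" for i in range(6)]
    spec = M.CFASpec(structure={"F1": cols[:3], "F2": cols[3:]})
    for rep in range(5):
        lam = np.zeros((6, 2))
        lam[:3, 0] = rng.uniform(0.5, 0.9, 3)
        lam[3:, 1] = rng.uniform(0.5, 0.9, 3)
        phi = np.array([[1.0, 0.4], [0.4, 1.0]])
        f = rng.multivariate_normal(np.zeros(2), phi, size=150)
        X = f @ lam.T + rng.normal(scale=0.7, size=(150, 6))
        model = M.fit_cfa(pd.DataFrame(X, columns=cols), spec, compute_se=False)
        idx = M.fit_indices(model)
        cfi, tli, ifi, rmsea = fit_index_oracle(
            model.chi2_model, model.df_model,
            model.chi2_baseline, model.df_baseline, model.n)
        assert abs(idx.CFI - min(max(cfi, 0), 1)) < 1e-8
        assert abs(idx.TLI - min(max(tli, 0), 1)) < 1e-8
        assert abs(idx.IFI - min(max(ifi, 0), 1)) < 1e-8
        assert abs(idx.RMSEA - rmsea) < 1e-8
        # SRMR oracle: RMS of standardised residual moments
        S = model.sample_cov.to_numpy()
        R = model.implied_cov()
        d = np.sqrt(np.diag(S))
        res = (S - R) / np.outer(d, d)
        iu = np.triu_indices(6)
        assert abs(idx.SRMR - np.sqrt(np.mean(res[iu] ** 2))) < 1e-8


def test_saturated_fit_yields_perfect_indices():
    """A model whose implied covariance reproduces S exactly (chi2 = 0)
    yields CFI = TLI = 1, RMSEA = 0 and SRMR = 0."""
    lam = pd.DataFrame({"F1": [0.8, 0.7]}, index=["v0", "v1"])
    phi = pd.DataFrame(np.eye(1), index=["F1"], columns=["F1"])
    resid = pd.Series([0.36, 0.51], index=["v0", "v1"])
    spec = M.CFASpec(structure={"F1": ["v0", "v1"]})
    S = pd.DataFrame(lam.to_numpy() @ lam.to_numpy().T + np.diag(resid),
                     index=["v0", "v1"], columns=["v0", "v1"])
    model = M.MeasurementModel(
        spec=spec, loadings=lam, factor_cov=phi, residual_var=resid,
        n=100, estimator="ml", converged=True, grad_norm=0.0, fmin=0.0,
        chi2_model=0.0, df_model=1, chi2_baseline=50.0, df_baseline=1,
        sample_cov=S,
    )
    idx = M.fit_indices(model)
    assert idx.CFI == 1.0
    assert idx.TLI == 1.0
    assert idx.RMSEA == 0.0
    assert idx.SRMR < 1e-12


# ---------------------------------------------------------------------------
# factor scores


def test_single_perfect_indicator_score_equals_indicator():
    rng = np.random.default_rng(9)
    x = rng.standard_normal(200)
    noise = rng.normal(scale=1e-4, size=(200, 2))
    df = pd.DataFrame({"v0": x + noise[:, 0], "v1": x + noise[:, 1]})
    spec = M.CFASpec(structure={"F1": ["v0", "v1"]})
    model = M.fit_cfa(df, spec, compute_se=False)
    fs = M.factor_scores(model, df)
    assert np.corrcoef(fs["F1"], df["v0"])[0, 1] > 0.999


def test_factor_scores_track_truth_and_handle_missing():
    cfg = synth.SynthConfig(n_participants=500, seed=29)
    factors, battery = synth.gen_factors(cfg)
    ind = M.prepare_indicators(battery)
    model = M.fit_cfa(ind, compute_se=False)
    fs = M.factor_scores(model, ind)
    for fac in fs.columns:
        assert np.corrcoef(fs[fac], factors[fac])[0, 1] >= 0.8
    # participants missing BS_R still get a WM score (other WM indicators remain)
    miss = ind["BS_R"].isna()
    assert miss.any()
    assert fs.loc[miss, "WM"].notna().all()


def test_factor_correlation_recovery_and_symmetry():
    cfg = synth.SynthConfig(n_participants=500, bsr_missing_fraction=0.0, seed=31)
    _, battery = synth.gen_factors(cfg)
    model = M.fit_cfa(M.prepare_indicators(battery), compute_se=False)
    phi = M.factor_correlations(model)
    assert np.allclose(phi, phi.T)
    assert np.allclose(np.diag(phi), 1.0)
    assert abs(phi.loc["WM", "PS"] - 0.44) < 0.1
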