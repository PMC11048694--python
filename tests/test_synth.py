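"""Generator structure, moment checks, reproducibility, round trips."""

import time

import numpy as np
import pandas as pd
import pytest

from skillcurve import scoring, synth
from skillcurve.measurement import BATTERY_COLUMNS, prepare_indicators


def test_gen_factors_moment_check():
    """Empirical indicator correlations match Lambda Phi Lambda' + Theta
    within 0.05 (large-n moment check over all 105 pairs)."""
    cfg = synth.SynthConfig(n_participants=4000, bsr_missing_fraction=0.0, seed=5)
    _, battery = synth.gen_factors(cfg)
    ind = prepare_indicators(battery)
    emp = ind.corr().to_numpy()
    lam = cfg.loadings.to_numpy()
    implied = lam @ cfg.factor_corr.to_numpy() @ lam.T + np.diag(cfg.theta_resid())
    # reorder implied to the indicator order of the prepared table
    order = [list(cfg.loadings.index).index(c) for c in ind.columns]
    implied = implied[np.ix_(order, order)]
    assert np.abs(emp - implied).max() < 0.05


def test_gen_factors_identity_when_noiseless():
    lam = pd.DataFrame(np.eye(4), index=BATTERY_COLUMNS[:4],
                       columns=["WM", "PS", "PM", "DX"])
    cfg = synth.SynthConfig(
        n_participants=50, loadings=lam,
        residual_var=pd.Series(1e-12, index=BATTERY_COLUMNS[:4]),
        bsr_missing_fraction=0.0, seed=3,
    )
    factors, battery = synth.gen_factors(cfg)
    # undo the raw-scale affine map: indicators are exact affine images of factors
    for i, col in enumerate(BATTERY_COLUMNS[:4]):
        r = np.corrcoef(battery[col], factors.iloc[:, i])[0, 1]
        assert abs(r) > 0.999999


def test_bsr_missing_fraction():
    cfg = synth.SynthConfig(seed=2)
    _, battery = synth.gen_factors(cfg)
    assert battery["BS_R"].isna().sum() == round(22 / 86 * 86)
    assert battery.drop(columns="BS_R").notna().all().all()


def test_gen_performance_zero_noise_zero_coupling():
    cfg = synth.SynthConfig(n_participants=5, coupling=(0.0, 0.0, 0.0), seed=9)
    cfg.curve_truth = {
        t: synth.TaskCurveTruth(mu=tr.mu, sd=(0.0, 0.0, 0.0), corr=tr.corr, sigma=0.0,
                                error_rate_first=0.0, error_rate_last=0.0)
        for t, tr in cfg.curve_truth.items()
    }
    fac, _ = synth.gen_factors(cfg)
    scores, truth = synth.gen_performance(cfg, fac)
    for task, tr in cfg.curve_truth.items():
        df = scores[scores["task"] == task]
        t = df["trial"].to_numpy(dtype=float)
        eta = tr.mu[1] + (tr.mu[0] - tr.mu[1]) * np.exp(-np.exp(tr.mu[2]) * (t - 1))
        assert np.array_equal(df["correct"].to_numpy(), np.rint(np.maximum(0, eta)))
        assert (df["wrong_key"] == 0).all() and (df["wrong_order"] == 0).all()


def test_coupling_moment_check():
    """Coupling of 0.5 SD on the asymptote yields the attenuated
    ability-beta correlation 0.5/sqrt(1.25) ~ 0.45 at large n."""
    cfg = synth.SynthConfig(n_participants=1000, coupling=(0.0, 0.5, 0.0), seed=4)
    fac, _ = synth.gen_factors(cfg)
    _, truth = synth.gen_performance(cfg, fac)
    ability = fac[cfg.coupling_factor]
    ability = (ability - ability.mean()) / ability.std(ddof=1)
    r = np.corrcoef(ability, truth["piano"]["beta"])[0, 1]
    assert r == pytest.approx(0.5 / np.sqrt(1.25), abs=0.1)


def test_gen_performance_seeded_reproducibility():
    cfg = synth.SynthConfig(n_participants=10, seed=6)
    fac, _ = synth.gen_factors(cfg)
    s1, _ = synth.gen_performance(cfg, fac, seed=77)
    s2, _ = synth.gen_performance(cfg, fac, seed=77)
    pd.testing.assert_frame_equal(s1, s2)


def test_keylog_roundtrip_500_random_targets():
    """Scoring generated key logs reproduces 500 random target count
    triples exactly."""
    rng = np.random.default_rng(10)
    rows = []
    for i in range(500):
        rows.append({
            "participant": f"p{i}", "task": rng.choice(["piano", "pad"]),
            "trial": 1, "correct": int(rng.integers(0, 60)),
            "wrong_key": int(rng.integers(0, 6)), "wrong_order": int(rng.integers(0, 6)),
        })
    target = pd.DataFrame(rows)
    events = synth.gen_keylog(target, seed=11)
    scored = scoring.score_dataset(events, synth.default_sequences())
    merged = target.merge(scored, on=["participant", "task", "trial"],
                          suffixes=("_want", ""))
    assert len(merged) == (target[["correct", "wrong_key", "wrong_order"]].sum(axis=1) > 0).sum()
    for col in ("correct", "wrong_key", "wrong_order"):
        assert (merged[col] == merged[f"{col}_want"]).all()


def test_keylog_impossible_target_rejected():
    seq = {"solo": scoring.SequenceSpec(keys=("a", "b", "c", "d"))}
    target = pd.DataFrame([{"participant": "p", "task": "solo", "trial": 1,
                            "correct": 1, "wrong_key": 0, "wrong_order": 1}])
    # 4 unique keys: wrong-order is always possible; missing columns are not
    with pytest.raises(ValueError, match="lacks columns"):
        synth.gen_keylog(target.drop(columns="wrong_order"), seq, seed=0)


def test_gen_gaze_noiseless_hinge():
    cfg = synth.SynthConfig(n_participants=6, gaze_missing=0, seed=8)
    cfg.gaze_truth = {t: {**g, "sigma_g": 0.0, "a_cv": 0.0, "tau_sd": 0.0}
                      for t, g in cfg.gaze_truth.items()}
    gz, true_tau = synth.gen_gaze(cfg)
    piano = gz[gz["task"] == "piano"].pivot_table(index="participant",
                                                  columns="trial",
                                                  values="gaze_changes")
    tau = cfg.gaze_truth["piano"]["tau_mean"]
    t = piano.columns.to_numpy(dtype=float)
    from skillcurve.gaze import hinge_mean

    expected = np.rint(hinge_mean(cfg.gaze_truth["piano"]["a_mean"], tau, t))
    assert np.array_equal(piano.iloc[0].to_numpy(), expected)
    assert (piano.loc[:, piano.columns >= int(np.ceil(tau))] == 0).all().all()


def test_gaze_tau_bounds_enforced():
    cfg = synth.SynthConfig(seed=1)
    cfg.gaze_truth["piano"]["tau_mean"] = 25.0
    with pytest.raises(ValueError, match="tau_mean"):
        synth.gen_gaze(cfg)


def test_full_study_bit_identical_and_fast():
    t0 = time.time()
    s1 = synth.simulate_study(seed=42)
    assert time.time() - t0 < 10.0
    s2 = synth.simulate_study(seed=42)
    pd.testing.assert_frame_equal(s1.trial_scores, s2.trial_scores)
    pd.testing.assert_frame_equal(s1.battery, s2.battery)
    pd.testing.assert_frame_equal(s1.events, s2.events)
    pd.testing.assert_frame_equal(s1.gaze, s2.gaze)
    pd.testing.assert_frame_equal(s1.musicality, s2.musicality)
    # every downstream schema present
    assert set(s1.events.columns) == set(scoring.EVENT_COLUMNS)
    assert set(scoring.SCORE_COLUMNS) <= set(s1.trial_scores.columns)
    assert s1.battery.shape == (86, 15)
    assert {"gaze_changes", "key_presses"} <= set(s1.gaze.columns)


def test_dip_scenario_truth_has_dip_at_trial_two():
    cfg = synth.dip_scenario_config()
    prof = synth.true_association_profile(cfg, "pad", n=60000, seed=0)
    b = prof["b_true"].to_numpy()
    assert int(np.argmin(b)) + 1 == 2
    assert b[-3:].mean() > b[1] + 0.05
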