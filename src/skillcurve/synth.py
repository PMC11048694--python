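"""Seeded synthetic-study generator.

Produces a complete synthetic cognito-motor learning study with the
statistical structure the analysis pipeline assumes, so every stage can
be exercised end to end without any external download:

* battery scores from a four-factor measurement model (working memory,
  processing speed, psychomotor speed, dexterity) with a DSP_S
  cross-loading and a configurable missing fraction for the Corsi task;
* per-trial performance counts following hierarchical exponential
  learning curves with correlated individual (alpha, beta, gamma),
  cross-task parameter correlations, and a configurable ability ->
  curve-parameter coupling;
* key-press event logs that the scorer maps back exactly to the target
  correct / wrong-key / wrong-order counts (round-trip property);
* gaze-change counts declining linearly to zero at an individual change
  point;
* musicality covariates (Gold-MSI total, cumulative piano practice
  hours) drawn independent of performance.

Defaults mirror the study conditions: 86 participants, two tasks
(piano, pad) x 20 trials of 20 s, population log learning rates -1.98
(piano) and -1.10 (pad), change points near trials 7 and 5, trial-1
error rates ~15% and ~10.5% declining over practice.  All outputs are
bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import measurement
from .curves import curve_value, CurveParams
from .gaze import hinge_mean
from .scoring import SequenceSpec

__all__ = [
    "SynthConfig",
    "TaskCurveTruth",
    "SyntheticStudy",
    "default_sequences",
    "gen_factors",
    "gen_performance",
    "gen_keylog",
    "gen_gaze",
    "gen_musicality",
    "simulate_study",
    "dip_scenario_config",
    "true_association_profile",
]


def default_sequences() -> dict[str, SequenceSpec]:
    return {
        "piano": SequenceSpec(
            keys=("C4", "A3", "E4", "G3"),
            hands=("right_ring", "left_middle", "right_thumb", "left_thumb"),
        ),
        "pad": SequenceSpec(
            keys=("b1", "b5", "b2", "b6"),
            hands=("right_index", "left_index", "right_index", "left_index"),
        ),
    }


@dataclass(frozen=True)
class TaskCurveTruth:
    """Population curve truth for one task."""

    mu: tuple[float, float, float]          # (alpha, beta, gamma)
    sd: tuple[float, float, float]
    corr: tuple[tuple[float, ...], ...] = (
        (1.0, 0.4, 0.1),
        (0.4, 1.0, 0.3),
        (0.1, 0.3, 1.0),
    )
    sigma: float = 2.5                      # residual SD of counts
    error_rate_first: float = 0.15          # trial-1 error rate
    error_rate_last: float = 0.06           # trial-20 error rate
    wrong_key_share: float = 0.5            # split of errors into wrong-key


def _default_loadings() -> pd.DataFrame:
    lam = pd.DataFrame(
        0.0,
        index=measurement.BATTERY_COLUMNS,
        columns=list(measurement.FACTOR_STRUCTURE),
    )
    for fac, inds in measurement.FACTOR_STRUCTURE.items():
        for ind in inds:
            lam.loc[ind, fac] = 0.7
    lam.loc["DSP_S", "WM"] = 0.55
    lam.loc["DSP_S", "PS"] = 0.30
    return lam


def _default_phi() -> pd.DataFrame:
    facs = list(measurement.FACTOR_STRUCTURE)
    phi = pd.DataFrame(np.eye(4), index=facs, columns=facs)
    vals = {("WM", "PS"): 0.44, ("WM", "PM"): 0.10, ("WM", "DX"): 0.10,
            ("PS", "PM"): 0.55, ("PS", "DX"): 0.55, ("PM", "DX"): 0.60}
    for (a, b), v in vals.items():
        phi.loc[a, b] = phi.loc[b, a] = v
    return phi


@dataclass
class SynthConfig:
    """Full truth configuration of the synthetic study."""

    n_participants: int = 86
    trials: int = 20
    tasks: tuple[str, ...] = ("piano", "pad")
    loadings: pd.DataFrame = field(default_factory=_default_loadings)
    factor_corr: pd.DataFrame = field(default_factory=_default_phi)
    residual_var: pd.Series | None = None       # default: 1 - communality
    bsr_missing_fraction: float = 22 / 86
    curve_truth: dict[str, TaskCurveTruth] = field(default_factory=lambda: {
        "piano": TaskCurveTruth(mu=(22.0, 45.0, -1.98), sd=(5.0, 8.0, 0.6),
                                error_rate_first=0.15, error_rate_last=0.065),
        "pad": TaskCurveTruth(mu=(30.0, 55.0, -1.10), sd=(6.0, 9.0, 0.6),
                              error_rate_first=0.105, error_rate_last=0.025),
    })
    cross_task_corr: tuple[float, float, float] = (0.6, 0.8, 0.5)
    coupling_factor: str = "PM"
    #: ability -> (alpha, beta, gamma) shifts, in parameter-SD units per
    #: ability SD; sized so the implied trial-wise association shows the
    #: strong-start / early-dip / rebound-to-plateau shape
    coupling: tuple[float, float, float] = (0.50, 0.55, 0.10)
    gaze_truth: dict[str, dict] = field(default_factory=lambda: {
        "piano": {"tau_mean": 7.06, "tau_sd": 1.5, "a_mean": 14.0, "a_cv": 0.35, "sigma_g": 1.2},
        "pad": {"tau_mean": 4.92, "tau_sd": 1.0, "a_mean": 11.0, "a_cv": 0.35, "sigma_g": 1.2},
    })
    gaze_missing: int = 12
    seed: int = 1

    def theta_resid(self) -> pd.Series:
        if self.residual_var is not None:
            return self.residual_var
        lam = self.loadings.to_numpy()
        phi = self.factor_corr.to_numpy()
        comm = np.einsum("ij,jk,ik->i", lam, phi, lam)
        resid = 1.0 - comm
        if (resid <= 0).any():
            raise ValueError("communality >= 1; lower the loadings")
        return pd.Series(resid, index=self.loadings.index)

    def validate(self) -> None:
        phi = self.factor_corr.to_numpy()
        if np.min(np.linalg.eigvalsh(phi)) < 0:
            raise ValueError("factor correlation matrix is not positive semi-definite")
        for task, tr in self.curve_truth.items():
            if np.min(np.linalg.eigvalsh(np.asarray(tr.corr))) < 0:
                raise ValueError(f"curve correlation for {task!r} not PSD")
            if not (0 <= tr.error_rate_first <= 1 and 0 <= tr.error_rate_last <= 1):
                raise ValueError("error rates must be in [0, 1]")
        for task, gz in self.gaze_truth.items():
            if not (1 <= gz["tau_mean"] <= self.trials):
                raise ValueError(f"gaze tau_mean for {task!r} outside [1, trials]")


@dataclass
class SyntheticStudy:
    """One generated study plus its ground truth."""

    events: pd.DataFrame
    trial_scores: pd.DataFrame
    battery: pd.DataFrame
    gaze: pd.DataFrame
    musicality: pd.DataFrame
    true_factors: pd.DataFrame
    true_curves: dict[str, pd.DataFrame]
    true_tau: dict[str, pd.Series]
    config: SynthConfig

    def write_dir(self, out_dir) -> None:
        import json
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.events.to_csv(out / "events.csv", index=False)
        self.trial_scores.to_csv(out / "trial_scores.csv", index=False)
        self.battery.to_csv(out / "battery.csv")
        self.gaze.to_csv(out / "gaze.csv", index=False)
        self.musicality.to_csv(out / "musicality.csv", index=False)
        truth = {
            "factors": self.true_factors.reset_index().to_dict(orient="list"),
            "curves": {k: v.reset_index().to_dict(orient="list")
                       for k, v in self.true_curves.items()},
            "tau": {k: v.tolist() for k, v in self.true_tau.items()},
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=1))


def _participant_ids(n: int) -> list[str]:
    return [f"P{i:03d}" for i in range(1, n + 1)]


def gen_factors(cfg: SynthConfig, seed: int | None = None):
    """True factor scores and the battery table they generate.

    factors ~ MVN(0, Phi); indicators = Lambda f + e with diagonal
    residual covariance; the Corsi reversed span (BS_R) is set missing
    for the configured fraction of participants.  Timed indicators are
    emitted on their raw orientation (seconds; larger = worse) so that
    :func:`measurement.prepare_indicators` has something to flip.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_participants
    ids = _participant_ids(n)
    phi = cfg.factor_corr.to_numpy()
    lam = cfg.loadings.to_numpy()
    theta = cfg.theta_resid().to_numpy()
    f = rng.multivariate_normal(np.zeros(4), phi, size=n)
    e = rng.normal(scale=np.sqrt(theta), size=(n, len(theta)))
    x = f @ lam.T + e
    battery = pd.DataFrame(x, index=pd.Index(ids, name="participant"),
                           columns=cfg.loadings.index)
    # raw-ish scales: shift/scale, flip timed indicators to seconds
    for col in battery.columns:
        if col in measurement.TIMED_INDICATORS:
            battery[col] = 60.0 - 10.0 * battery[col]
        else:
            battery[col] = 30.0 + 8.0 * battery[col]
    if "BS_R" in battery.columns and cfg.bsr_missing_fraction > 0:
        n_missing = int(round(cfg.bsr_missing_fraction * n))
        miss = rng.choice(n, size=n_missing, replace=False)
        battery.iloc[miss, battery.columns.get_loc("BS_R")] = np.nan
    factors = pd.DataFrame(f, index=battery.index, columns=cfg.factor_corr.columns)
    return factors, battery


def _draw_curve_params(cfg: SynthConfig, ability: np.ndarray, rng) -> dict[str, np.ndarray]:
    """Correlated (alpha, beta, gamma) per task with shared cross-task
    components: theta_task = sqrt(rho) u + sqrt(1-rho) v_task on the
    standardised scale, then scaled, shifted, and coupled to ability."""
    n = len(ability)
    rho = np.asarray(cfg.cross_task_corr)
    coup = np.asarray(cfg.coupling)
    out = {}
    # shared standardised component uses the first task's corr structure
    first = cfg.curve_truth[cfg.tasks[0]]
    u = rng.multivariate_normal(np.zeros(3), np.asarray(first.corr), size=n)
    for task in cfg.tasks:
        tr = cfg.curve_truth[task]
        v = rng.multivariate_normal(np.zeros(3), np.asarray(tr.corr), size=n)
        z = np.sqrt(rho) * u + np.sqrt(1 - rho) * v
        theta = np.asarray(tr.mu) + np.asarray(tr.sd) * (z + coup * ability[:, None])
        out[task] = theta
    return out


def gen_performance(cfg: SynthConfig, true_factors: pd.DataFrame, seed: int | None = None):
    """Trial-score table plus the generating per-participant curves.

    Correct counts are ``round(max(0, eta_it + Normal(0, sigma)))``;
    error counts follow a per-trial error-rate schedule interpolating
    exponentially between the trial-1 and trial-20 rates, split into
    wrong-key and wrong-order by the configured share.
    """
    cfg.validate()
    rng = np.random.default_rng((cfg.seed + 1) if seed is None else seed)
    ids = list(true_factors.index)
    ability = true_factors[cfg.coupling_factor].to_numpy()
    ability = (ability - ability.mean()) / ability.std(ddof=1)
    params = _draw_curve_params(cfg, ability, rng)
    t = np.arange(1, cfg.trials + 1, dtype=float)

    rows = []
    true_curves = {}
    for task in cfg.tasks:
        tr = cfg.curve_truth[task]
        theta = params[task]
        true_curves[task] = pd.DataFrame(
            theta, index=pd.Index(ids, name="participant"),
            columns=["alpha", "beta", "gamma"],
        )
        a, b, g = theta[:, 0:1], theta[:, 1:2], theta[:, 2:3]
        eta = b + (a - b) * np.exp(-np.exp(g) * (t - 1.0))
        y = np.rint(np.maximum(0.0, eta + rng.normal(scale=tr.sigma, size=eta.shape)))
        # error-rate schedule: exponential interpolation trial 1 -> 20
        decay = np.log(max(tr.error_rate_first, 1e-9) / max(tr.error_rate_last, 1e-9)) / (cfg.trials - 1)
        er = tr.error_rate_first * np.exp(-decay * (t - 1.0))
        for i, pid in enumerate(ids):
            for j, trial in enumerate(t):
                correct = int(y[i, j])
                rate = float(np.clip(er[j] * np.exp(rng.normal(scale=0.3)), 0.0, 0.6))
                # errors per correct press on the odds scale so the
                # realised error rate errors/total matches the schedule
                odds = min(rate / (1.0 - rate), 1.0)
                errors = int(rng.binomial(max(correct, 1), odds)) if correct > 0 else 0
                wk = int(rng.binomial(errors, tr.wrong_key_share)) if errors else 0
                wo = errors - wk
                total = correct + errors
                rows.append({
                    "participant": pid, "task": task, "trial": int(trial),
                    "correct": correct, "wrong_key": wk, "wrong_order": wo,
                    "total": total,
                    "error_rate": (errors / total) if total else np.nan,
                })
    scores = pd.DataFrame(rows)
    return scores, true_curves


def gen_keylog(
    trial_score_target: pd.DataFrame,
    seqs: dict[str, SequenceSpec] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Key-press event log consistent with target per-trial counts.

    Emits, per trial, a seeded random interleaving of ``correct``
    correct presses, ``wrong_key`` presses of an out-of-sequence key and
    ``wrong_order`` presses of an in-sequence key out of turn, walking
    the same looped pointer the scorer uses, so scoring the log
    reproduces the target counts exactly.
    """
    seqs = seqs or default_sequences()
    rng = np.random.default_rng(seed)
    req = {"participant", "task", "trial", "correct", "wrong_key", "wrong_order"}
    missing = req - set(trial_score_target.columns)
    if missing:
        raise ValueError(f"target table lacks columns {sorted(missing)}")

    rows = []
    for rec in trial_score_target.itertuples(index=False):
        seq = seqs[rec.task]
        if rec.wrong_order > 0 and len(set(seq.keys)) < 2:
            raise ValueError("wrong-order events impossible with a 1-key sequence")
        labels = (["c"] * int(rec.correct) + ["k"] * int(rec.wrong_key)
                  + ["o"] * int(rec.wrong_order))
        order = rng.permutation(len(labels))
        p = 0
        time_ms = 0.0
        off_keys = [f"x{j}" for j in range(1, 5)]
        for idx, pos in enumerate(order, start=1):
            lab = labels[pos]
            if lab == "c":
                key = seq.keys[p]
                p = (p + 1) % 4
            elif lab == "k":
                key = off_keys[rng.integers(len(off_keys))]
            else:
                choices = [k for k in seq.keys if k != seq.keys[p]]
                key = choices[rng.integers(len(choices))]
                p = (seq.index(key) + 1) % 4
            time_ms += float(rng.gamma(4.0, 75.0))  # ~300 ms inter-press
            rows.append({
                "participant": rec.participant, "task": rec.task,
                "trial": int(rec.trial), "press_index": idx,
                "key": key, "time_ms": round(time_ms, 1),
            })
    return pd.DataFrame(rows, columns=["participant", "task", "trial",
                                       "press_index", "key", "time_ms"])


def gen_gaze(cfg: SynthConfig, seed: int | None = None,
             trial_scores: pd.DataFrame | None = None):
    """Gaze-change counts from the hinge model, plus the true tau_i.

    Counts are the hinge mean plus Gaussian noise, floored at zero and
    rounded; ``key_presses`` comes from the trial-score table when
    given.  The configured number of participants is dropped entirely
    (gaze could not be analysed for them), mirroring missing video data.
    """
    cfg.validate()
    rng = np.random.default_rng((cfg.seed + 2) if seed is None else seed)
    n = cfg.n_participants
    ids = _participant_ids(n)
    t = np.arange(1, cfg.trials + 1, dtype=float)
    drop = set(rng.choice(n, size=min(cfg.gaze_missing, n), replace=False).tolist())

    presses = None
    if trial_scores is not None:
        presses = trial_scores.set_index(["participant", "task", "trial"])["total"]

    rows, true_tau = [], {}
    for task in cfg.tasks:
        gz = cfg.gaze_truth[task]
        a = gz["a_mean"] * np.exp(rng.normal(scale=gz["a_cv"], size=n))
        tau = np.clip(rng.normal(gz["tau_mean"], gz["tau_sd"], size=n),
                      1.3, cfg.trials - 0.5)
        true_tau[task] = pd.Series(tau, index=pd.Index(ids, name="participant"))
        mu = hinge_mean(a[:, None], tau[:, None], t[None, :])
        counts = np.rint(np.maximum(0.0, mu + rng.normal(scale=gz["sigma_g"], size=mu.shape)))
        for i, pid in enumerate(ids):
            if i in drop:
                continue
            for j, trial in enumerate(t):
                kp = 0
                if presses is not None:
                    kp = int(presses.get((pid, task, int(trial)), 0))
                rows.append({"participant": pid, "task": task, "trial": int(trial),
                             "gaze_changes": int(counts[i, j]), "key_presses": kp})
    gaze = pd.DataFrame(rows, columns=["participant", "task", "trial",
                                       "gaze_changes", "key_presses"])
    return gaze, true_tau


def gen_musicality(cfg: SynthConfig, seed: int | None = None) -> pd.DataFrame:
    """Gold-MSI totals and cumulative piano hours, independent of
    performance (the study found no musicality-performance link)."""
    rng = np.random.default_rng((cfg.seed + 3) if seed is None else seed)
    n = cfg.n_participants
    ids = _participant_ids(n)
    msi = np.clip(rng.normal(56.8, 17.1, size=n), 18, 126)
    has_exp = rng.random(n) < (37 / 86)
    hours = np.where(
        has_exp,
        np.clip(np.exp(rng.normal(np.log(900.0), 0.6, size=n)), 120, 2944),
        0.0,
    )
    return pd.DataFrame(
        {"participant": ids, "gold_msi_total": np.round(msi, 1),
         "piano_hours": np.round(hours, 1)}
    )


def simulate_study(cfg: SynthConfig | None = None, seed: int | None = None,
                   with_events: bool = True) -> SyntheticStudy:
    """Generate a full synthetic study from one root seed.

    The root seed is split per stage, so each component is individually
    reproducible and the full bundle is bit-identical under a fixed
    seed.
    """
    cfg = cfg or SynthConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    root = np.random.SeedSequence(cfg.seed)
    subs = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in root.spawn(5)]
    factors, battery = gen_factors(cfg, seed=subs[0])
    scores, true_curves = gen_performance(cfg, factors, seed=subs[1])
    gaze, true_tau = gen_gaze(cfg, seed=subs[2], trial_scores=scores)
    musicality = gen_musicality(cfg, seed=subs[3])
    events = gen_keylog(scores, seed=subs[4]) if with_events else pd.DataFrame(
        columns=["participant", "task", "trial", "press_index", "key", "time_ms"])
    return SyntheticStudy(
        events=events, trial_scores=scores, battery=battery, gaze=gaze,
        musicality=musicality, true_factors=factors, true_curves=true_curves,
        true_tau=true_tau, config=cfg,
    )


def dip_scenario_config(n_participants: int = 200, seed: int = 1) -> SynthConfig:
    """Association-shape study configuration.

    Coupling and curve heterogeneity chosen so the generator-implied
    trial-wise association dips at exactly trial 2 and then climbs to a
    plateau: strong direct coupling on baseline (trial 1 is pure alpha,
    so its association is clean), a fast mean learning rate with large
    uncoupled rate heterogeneity (rate variance dilutes the association
    most strongly immediately after trial 1), and asymptote coupling
    that restores the association toward the plateau.  The default
    sample size is larger than the study's so that the Monte-Carlo
    error of a single-replication shape estimate is small against the
    configured trial-1-to-trial-2 drop; the shape itself does not
    depend on n.
    """
    truth = TaskCurveTruth(
        mu=(30.0, 55.0, 0.0), sd=(6.0, 9.0, 1.2),
        corr=((1.0, 0.4, 0.0), (0.4, 1.0, 0.0), (0.0, 0.0, 1.0)),
    )
    return SynthConfig(
        n_participants=n_participants,
        coupling=(0.70, 0.55, 0.0),
        curve_truth={"piano": truth, "pad": truth},
        seed=seed,
    )


def true_association_profile(
    cfg: SynthConfig | None = None,
    task: str = "piano",
    n: int = 200_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Monte-Carlo oracle for the generator-implied trial-wise
    association between the coupled ability and standardised noise-free
    performance: corr(ability, eta_t) per trial at large n."""
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(seed)
    ability = rng.standard_normal(n)
    params = _draw_curve_params(cfg, ability, rng)[task]
    t = np.arange(1, cfg.trials + 1, dtype=float)
    a, b, g = params[:, 0:1], params[:, 1:2], params[:, 2:3]
    eta = b + (a - b) * np.exp(-np.exp(g) * (t - 1.0))
    z = (eta - eta.mean(axis=0)) / eta.std(axis=0, ddof=1)
    r = (z * ability[:, None]).mean(axis=0) * n / (n - 1)
    return pd.DataFrame({"trial": t.astype(int), "b_true": r})
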