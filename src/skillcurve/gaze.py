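"""Gaze change-point modelling.

Gaze changes between the display and the keys are counted per trial;
they decline across practice and reach (essentially) zero once a
participant no longer needs visual control.  The trial at which that
happens is modelled as an individual change point ``tau_i`` in a
piecewise hinge model on the count scale:

    g_it ~ Normal+(mu_it, sigma_g),
    mu_it = a_i * max(0, (tau_i - t) / (tau_i - 1)),

i.e. a linear decline from ``a_i`` at trial 1 to zero at ``tau_i``,
exactly flat at zero afterwards, with truncated-Gaussian observation
noise (counts are nonnegative).  ``tau_i`` is continuous in [1, T]
through a logit-scaled hierarchical prior, and ``a_i`` is positive
through a log-scale hierarchical prior; hyperparameters get conjugate
normal / inverse-gamma updates while the individual pairs
``(log a_i, logit-scaled tau_i)`` take adaptive Metropolis steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .curves import MCMCConfig, REDUCED_CONFIG
from .mcmc import Chains, run_chains, summarize, AdaptiveScale

__all__ = ["ChangePointFit", "fit_changepoint", "gaze_rate", "hinge_mean"]

GAZE_COLUMNS = ["participant", "task", "trial", "gaze_changes", "key_presses"]


def hinge_mean(a, tau, t):
    """Expected gaze count: linear decline to zero at tau, flat after."""
    a = np.asarray(a, dtype=float)
    tau = np.asarray(tau, dtype=float)
    t = np.asarray(t, dtype=float)
    denom = np.maximum(tau - 1.0, 1e-9)
    return a * np.maximum(0.0, (tau - t) / denom)


def gaze_rate(records: pd.DataFrame) -> pd.DataFrame:
    """Gaze changes per key press per trial; missing where no presses."""
    out = records.copy()
    presses = out["key_presses"].to_numpy(dtype=float)
    changes = out["gaze_changes"].to_numpy(dtype=float)
    rate = np.divide(changes, presses, out=np.full_like(changes, np.nan),
                     where=presses > 0)
    out["gaze_rate"] = rate
    return out


@dataclass
class ChangePointFit:
    """Population and individual change-point estimates."""

    chains: Chains
    participants: list
    config: MCMCConfig
    n_trials: int
    flagged_all_zero: list

    def population_tau(self) -> dict[str, float]:
        """Posterior summary of the population-typical change point
        (inverse-transformed population location of the tau scale)."""
        return summarize(self.chains.stacked("tau_pop"))

    def individual_tau(self) -> pd.DataFrame:
        tau = self.chains.stacked("tau")          # (S, n)
        lo, hi = np.quantile(tau, [0.025, 0.975], axis=0)
        return pd.DataFrame(
            {"tau_mean": tau.mean(axis=0), "tau_low": lo, "tau_high": hi},
            index=pd.Index(self.participants, name="participant"),
        )

    def rhat(self) -> dict[str, np.ndarray]:
        keys = ("tau_pop", "mu_loga", "sigma_g")
        return {k: v for k, v in self.chains.rhat().items() if k in keys}

    def max_rhat(self) -> float:
        from .mcmc import _nanmax_all

        return _nanmax_all(self.rhat().values())


def _to_matrix(records: pd.DataFrame, task: str | None):
    df = records
    if task is not None and "task" in df.columns:
        df = df[df["task"] == task]
    wide = df.pivot_table(index="participant", columns="trial",
                          values="gaze_changes", aggfunc="first").sort_index(axis=1)
    return wide.to_numpy(dtype=float), list(wide.index), wide.columns.to_numpy(dtype=float)


def fit_changepoint(
    records: pd.DataFrame | np.ndarray,
    config: MCMCConfig = REDUCED_CONFIG,
    *,
    task: str | None = None,
) -> ChangePointFit:
    """Fit the hierarchical hinge change-point model for one task.

    Participants whose counts are all zero are kept (their ``tau_i``
    concentrates at the lower boundary) and flagged.  Negative counts
    are rejected.  Warns when population-level split-Rhat exceeds 1.01.
    """
    if isinstance(records, pd.DataFrame):
        y, participants, t = _to_matrix(records, task)
    else:
        y = np.asarray(records, dtype=float)
        participants = list(range(y.shape[0]))
        t = np.arange(1, y.shape[1] + 1, dtype=float)
    if np.nanmin(y) < 0:
        raise ValueError("negative gaze counts")
    n, T = y.shape
    if T < 5:
        raise ValueError("need at least 5 trials per participant")
    mask = ~np.isnan(y)
    y0 = np.where(mask, y, 0.0)
    all_zero = [participants[i] for i in range(n) if np.nansum(y[i]) == 0]
    if all_zero:
        warnings.warn(f"all-zero gaze counts for {all_zero}; tau at lower boundary",
                      stacklevel=2)

    span = T - 1.0

    def tau_of(w):  # logit scale -> (1, T)
        return 1.0 + span * special.expit(w)

    iters, warm = config.iterations, config.warmup
    keep = iters - warm

    def chain_fn(rng: np.random.Generator) -> dict[str, np.ndarray]:
        # crude starts: a from trial-1 counts, tau from last trial above 10% of a
        a0 = np.maximum(y0[:, 0], 0.5)
        tau0 = np.empty(n)
        for i in range(n):
            above = np.flatnonzero(mask[i] & (y0[i] > 0.1 * a0[i]))
            tau0[i] = min(T - 0.5, (t[above[-1]] + 1.0)) if above.size else 1.5
        loga = np.log(a0) + rng.normal(scale=0.2, size=n)
        w = special.logit(np.clip((tau0 - 1.0) / span, 0.02, 0.98)) + rng.normal(scale=0.2, size=n)
        mu_a, s2_a = float(loga.mean()), max(float(loga.var()), 0.1)
        mu_w, s2_w = float(w.mean()), max(float(w.var()), 0.1)
        sigma_g = max(float(np.nanstd(y)) * 0.3, 0.5)
        adapt = AdaptiveScale.start(n, init=-1.5)
        adapt_sig = AdaptiveScale.start(1, init=-2.0, target=0.4)

        def loglik(loga_, w_, sig) -> np.ndarray:
            mu = hinge_mean(np.exp(loga_)[:, None], tau_of(w_)[:, None], t[None, :])
            # Normal truncated to [0, inf): log phi((y-mu)/sig) - log(1 - Phi(-mu/sig))
            z = (y0 - mu) / sig
            logZ = special.log_ndtr(mu / sig)
            ll = -0.5 * z**2 - np.log(sig) - logZ
            return np.where(mask, ll, 0.0).sum(axis=1)

        out = {"tau": np.empty((keep, n)), "a": np.empty((keep, n)),
               "tau_pop": np.empty(keep), "mu_loga": np.empty(keep),
               "sigma_g": np.empty(keep)}
        ll_cur = loglik(loga, w, sigma_g)
        for it in range(iters):
            # individual (log a_i, w_i) MH
            for _ in range(config.mh_substeps):
                pl = loga + adapt.scale * rng.standard_normal(n)
                pw = w + adapt.scale * rng.standard_normal(n)
                pw = np.clip(pw, -12.0, 12.0)
                ll_prop = loglik(pl, pw, sigma_g)
                lp_cur = -0.5 * ((loga - mu_a) ** 2 / s2_a + (w - mu_w) ** 2 / s2_w)
                lp_prop = -0.5 * ((pl - mu_a) ** 2 / s2_a + (pw - mu_w) ** 2 / s2_w)
                acc = np.log(rng.uniform(size=n)) < (ll_prop + lp_prop - ll_cur - lp_cur)
                loga = np.where(acc, pl, loga)
                w = np.where(acc, pw, w)
                ll_cur = np.where(acc, ll_prop, ll_cur)
                if it < warm:
                    adapt.update(acc, it)
            # conjugate hyper updates (Normal means, inverse-gamma variances)
            for vec, which in ((loga, "a"), (w, "w")):
                prec = n / (s2_a if which == "a" else s2_w) + 1.0 / 25.0
                mean = vec.sum() / (s2_a if which == "a" else s2_w) / prec
                draw = rng.normal(mean, 1.0 / np.sqrt(prec))
                ss = float(((vec - draw) ** 2).sum())
                var = 1.0 / rng.gamma(2.0 + n / 2.0, 1.0 / (0.5 + ss / 2.0))
                if which == "a":
                    mu_a, s2_a = draw, var
                else:
                    mu_w, s2_w = draw, var
            # observation noise scale: scalar MH on log sigma_g
            prop_sig = float(np.exp(np.log(sigma_g) + adapt_sig.scale[0] * rng.standard_normal()))
            ll_prop_tot = loglik(loga, w, prop_sig).sum()
            # Half-Normal(0, 2*sd_y) prior on sigma_g, Jacobian of the log step
            sd_y = max(float(np.nanstd(y)), 1.0)
            lp = lambda s: -0.5 * (s / (2 * sd_y)) ** 2 + np.log(s)
            if np.log(rng.uniform()) < (ll_prop_tot + lp(prop_sig)) - (ll_cur.sum() + lp(sigma_g)):
                sigma_g = prop_sig
                ll_cur = loglik(loga, w, sigma_g)
                acc_s = np.array([True])
            else:
                acc_s = np.array([False])
            if it < warm:
                adapt_sig.update(acc_s, it)
            if it >= warm:
                j = it - warm
                out["tau"][j] = tau_of(w)
                out["a"][j] = np.exp(loga)
                out["tau_pop"][j] = tau_of(np.array(mu_w))
                out["mu_loga"][j] = mu_a
                out["sigma_g"][j] = sigma_g
        return out

    chains = run_chains(config.chains, config.seed, chain_fn, warm)
    fit = ChangePointFit(chains=chains, participants=participants, config=config,
                         n_trials=T, flagged_all_zero=all_zero)
    mx = fit.max_rhat()
    if mx > 1.01:
        warnings.warn(f"change-point model: max split-Rhat {mx:.3f} > 1.01", stacklevel=2)
    return fit
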