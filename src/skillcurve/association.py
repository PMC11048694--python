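"""Trial-wise performance-ability association analysis.

Model-fitted performance is standardised within each task x trial
(1 unit = 1 SD) so that regression coefficients are comparable across
the learning phase, then standardised performance is regressed on one
predictor at a time (a latent cognito-motor factor, musical
sophistication, or piano experience), controlling for individual
learning rates, with trials treated as factors:

    z_it = delta_t + b_t * x_i + c_t * g_i + u_i + eps_it

where ``x_i`` is the standardised predictor, ``g_i`` the standardised
posterior-mean learning rate, ``u_i`` a participant random intercept and
every coefficient is trial-indexed.  The model is linear-Gaussian, so it
is sampled by exact blocked Gibbs; ``b_t`` is reported in SD-per-SD
units with a 95% credible interval per trial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .curves import MCMCConfig, REDUCED_CONFIG
from .mcmc import run_chains, rhat_dataset

__all__ = [
    "AssociationCurve",
    "standardize_by_trial",
    "trialwise_model",
    "association_profile",
    "rate_ability_correlations",
]


def standardize_by_trial(fitted: pd.DataFrame) -> pd.DataFrame:
    """Standardise fitted performance within each task x trial.

    ``fitted`` is either a wide participant x trial table (one task) or
    a long table with columns participant, task, trial and one value
    column (``eta`` or ``correct``).  Uses the sample (n-1) SD; each
    task x trial then has mean 0 and SD 1 exactly.  Idempotent.
    """
    if {"participant", "trial"}.issubset(fitted.columns):
        value = next(c for c in ("eta", "z", "correct") if c in fitted.columns)
        df = fitted.copy()
        group_cols = ["task", "trial"] if "task" in df.columns else ["trial"]

        def _z(x: pd.Series) -> pd.Series:
            sd = x.std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                raise ValueError(f"zero per-trial SD at {x.name}")
            return (x - x.mean()) / sd

        df["z"] = df.groupby(group_cols, group_keys=False)[value].apply(_z)
        return df
    # wide: columns are trials
    out = fitted.copy().astype(float)
    for col in out.columns:
        sd = out[col].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"zero per-trial SD at trial {col}")
        out[col] = (out[col] - out[col].mean()) / sd
    return out


@dataclass
class AssociationCurve:
    """Per-trial standardised coefficient b_t with 95% credible interval."""

    predictor: str
    trials: np.ndarray
    b_mean: np.ndarray
    b_lower: np.ndarray
    b_upper: np.ndarray
    rhat_b: np.ndarray
    config: MCMCConfig
    c_mean: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"trial": self.trials.astype(int), "b_mean": self.b_mean,
             "b_low": self.b_lower, "b_high": self.b_upper}
        )

    def covers_zero(self) -> np.ndarray:
        return (self.b_lower <= 0) & (self.b_upper >= 0)


def _standardize_vec(x: np.ndarray, name: str) -> np.ndarray:
    sd = np.nanstd(x, ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError(f"{name} has zero variance")
    return (x - np.nanmean(x)) / sd


def trialwise_model(
    z: pd.DataFrame,
    x: np.ndarray | pd.Series,
    g: np.ndarray | pd.Series,
    config: MCMCConfig = REDUCED_CONFIG,
    *,
    predictor: str = "predictor",
    global_rate_control: bool = False,
) -> AssociationCurve:
    """Estimate trial-specific standardised coefficients b_t.

    Parameters
    ----------
    z
        Wide participant x trial table of standardised fitted
        performance (from :func:`standardize_by_trial`).
    x, g
        Predictor and individual learning-rate estimate per participant
        (aligned with the rows of ``z``); both are re-standardised to
        mean 0, SD 1 on the non-missing participants.
    global_rate_control
        When True the learning-rate control enters with a single global
        coefficient instead of one per trial.

    Exact blocked Gibbs: per-trial coefficient blocks, participant
    random intercepts and the two variance components all have
    conjugate full conditionals.  Participants missing the predictor
    are dropped; more than 50% missing is refused.
    """
    Z = z.to_numpy(dtype=float)
    x = np.asarray(x, dtype=float)
    g = np.asarray(g, dtype=float)
    if len(x) != Z.shape[0] or len(g) != Z.shape[0]:
        raise ValueError("x and g must align with the rows of z")
    ok = ~np.isnan(x) & ~np.isnan(g) & ~np.isnan(Z).all(axis=1)
    if ok.mean() < 0.5:
        raise ValueError(f"predictor {predictor!r} missing for more than 50% of participants")
    Z = Z[ok]
    xs = _standardize_vec(x[ok], "predictor")
    gs = _standardize_vec(g[ok], "learning rate")
    n, T = Z.shape
    trials = np.asarray(z.columns, dtype=float)
    mask = ~np.isnan(Z)
    Z0 = np.where(mask, Z, 0.0)

    prior_prec = 1.0 / 4.0       # N(0, 2^2) on every coefficient
    a0, b0 = 2.0, 0.5            # inverse-gamma on both variances
    iters, warm = config.iterations, config.warmup
    keep = iters - warm
    complete = bool(mask.all())

    if complete and not global_rate_control:
        return _trialwise_collapsed(Z, xs, gs, trials, config, predictor,
                                    prior_prec, a0, b0)

    def chain_fn(rng: np.random.Generator) -> dict[str, np.ndarray]:
        delta = np.zeros(T)
        b = rng.normal(scale=0.1, size=T)
        c = rng.normal(scale=0.1, size=T)
        c_glob = 0.0
        u = np.zeros(n)
        sig2, sig2_u = 1.0, 0.1
        out = {"b": np.empty((keep, T)), "c": np.empty((keep, T)),
               "sigma": np.empty(keep), "sigma_u": np.empty(keep)}
        X3 = np.column_stack([np.ones(n), xs, gs])   # per-trial design
        for it in range(iters):
            # per-trial coefficient blocks
            R = Z0 - u[:, None]
            if global_rate_control:
                Rg = R - c_glob * gs[:, None]
                X2 = X3[:, :2]
                for t_ in range(T):
                    m = mask[:, t_]
                    A = X2[m].T @ X2[m] / sig2 + prior_prec * np.eye(2)
                    Ainv = np.linalg.inv(A)
                    mean = Ainv @ (X2[m].T @ Rg[m, t_]) / sig2
                    dr = rng.multivariate_normal(mean, Ainv)
                    delta[t_], b[t_] = dr
                    c[t_] = c_glob
                # global c given everything else
                resid = Z0 - delta[None, :] - b[None, :] * xs[:, None] - u[:, None]
                gg = np.where(mask, gs[:, None], 0.0)
                A = (gg**2).sum() / sig2 + prior_prec
                mean = (gg * np.where(mask, resid, 0.0)).sum() / sig2 / A
                c_glob = rng.normal(mean, 1.0 / np.sqrt(A))
                c[:] = c_glob
            else:
                for t_ in range(T):
                    m = mask[:, t_]
                    A = X3[m].T @ X3[m] / sig2 + prior_prec * np.eye(3)
                    Ainv = np.linalg.inv(A)
                    mean = Ainv @ (X3[m].T @ R[m, t_]) / sig2
                    dr = rng.multivariate_normal(mean, Ainv)
                    delta[t_], b[t_], c[t_] = dr
            # random intercepts
            fitted = delta[None, :] + b[None, :] * xs[:, None] + c[None, :] * gs[:, None]
            resid = np.where(mask, Z0 - fitted, 0.0)
            cnt = mask.sum(axis=1)
            prec_u = cnt / sig2 + 1.0 / sig2_u
            mean_u = (resid.sum(axis=1) / sig2) / prec_u
            u = rng.normal(mean_u, 1.0 / np.sqrt(prec_u))
            # variances
            r2 = np.where(mask, Z0 - fitted - u[:, None], 0.0)
            sig2 = 1.0 / rng.gamma(a0 + mask.sum() / 2.0, 1.0 / (b0 + (r2**2).sum() / 2.0))
            sig2_u = 1.0 / rng.gamma(a0 + n / 2.0, 1.0 / (b0 + (u**2).sum() / 2.0))
            if it >= warm:
                j = it - warm
                out["b"][j] = b
                out["c"][j] = c
                out["sigma"][j] = np.sqrt(sig2)
                out["sigma_u"][j] = np.sqrt(sig2_u)
        return out

    chains = run_chains(config.chains, config.seed, chain_fn, warm)
    bdraws = chains.draws["b"]                        # (chain, draw, T)
    pooled = bdraws.reshape(-1, T)
    lo, hi = np.quantile(pooled, [0.025, 0.975], axis=0)
    rh = rhat_dataset({"b": bdraws})["b"]
    if np.nanmax(rh) > 1.01:
        warnings.warn(f"trial-wise model: max Rhat on b_t = {np.nanmax(rh):.3f} > 1.01",
                      stacklevel=2)
    return AssociationCurve(
        predictor=predictor, trials=trials, b_mean=pooled.mean(axis=0),
        b_lower=lo, b_upper=hi, rhat_b=np.asarray(rh), config=config,
        c_mean=chains.stacked("c").mean(axis=0),
    )


def _trialwise_collapsed(Z, xs, gs, trials, config, predictor, prior_prec, a0, b0):
    """Collapsed Gibbs for complete data: the participant intercept is
    integrated out of the coefficient update (the per-participant
    marginal covariance is sigma^2 I + sigma_u^2 11', inverted by
    Woodbury), which breaks the intercept-coefficient ridge that makes
    the uncollapsed sampler mix slowly on smooth fitted performance."""
    n, T = Z.shape
    R3 = np.column_stack([np.ones(n), xs, gs])      # (n, 3)
    RR = np.einsum("ni,nj->nij", R3, R3)            # (n, 3, 3)
    sumRR = RR.sum(axis=0)
    iters, warm = config.iterations, config.warmup
    keep = iters - warm
    eyeT = np.eye(T)
    ones = np.ones((T, T))

    def chain_fn(rng: np.random.Generator) -> dict[str, np.ndarray]:
        sig2, sig2_u = 1.0, 0.1
        u = np.zeros(n)
        out = {"b": np.empty((keep, T)), "c": np.empty((keep, T)),
               "sigma": np.empty(keep), "sigma_u": np.empty(keep)}
        rowsum = Z.sum(axis=1)                      # (n,)
        for it in range(iters):
            # joint draw of all (delta_t, b_t, c_t) with u marginalised
            ci = (sig2_u / sig2) / (sig2 + T * sig2_u)   # Woodbury factor
            A = (np.kron(eyeT, sumRR) / sig2
                 - np.kron(ones, (ci * RR.sum(axis=0))))
            rhs = (np.einsum("nt,nk->tk", Z, R3) / sig2
                   - ci * rowsum @ R3 * np.ones((T, 1))).reshape(T * 3)
            A[np.diag_indices_from(A)] += prior_prec
            L = np.linalg.cholesky(A)
            mean = np.linalg.solve(A, rhs)
            beta = mean + np.linalg.solve(L.T, rng.standard_normal(T * 3))
            B = beta.reshape(T, 3)                  # rows: (delta_t, b_t, c_t)
            # intercepts given coefficients
            fitted = R3 @ B.T                       # (n, T)
            resid = Z - fitted
            prec_u = T / sig2 + 1.0 / sig2_u
            u = rng.normal(resid.sum(axis=1) / sig2 / prec_u, 1.0 / np.sqrt(prec_u))
            r2 = resid - u[:, None]
            sig2 = 1.0 / rng.gamma(a0 + n * T / 2.0, 1.0 / (b0 + (r2**2).sum() / 2.0))
            sig2_u = 1.0 / rng.gamma(a0 + n / 2.0, 1.0 / (b0 + (u**2).sum() / 2.0))
            if it >= warm:
                j = it - warm
                out["b"][j] = B[:, 1]
                out["c"][j] = B[:, 2]
                out["sigma"][j] = np.sqrt(sig2)
                out["sigma_u"][j] = np.sqrt(sig2_u)
        return out

    chains = run_chains(config.chains, config.seed, chain_fn, warm)
    bdraws = chains.draws["b"]
    pooled = bdraws.reshape(-1, T)
    lo, hi = np.quantile(pooled, [0.025, 0.975], axis=0)
    rh = rhat_dataset({"b": bdraws})["b"]
    if np.nanmax(rh) > 1.01:
        warnings.warn(f"trial-wise model: max Rhat on b_t = {np.nanmax(rh):.3f} > 1.01",
                      stacklevel=3)
    return AssociationCurve(
        predictor=predictor, trials=trials, b_mean=pooled.mean(axis=0),
        b_lower=lo, b_upper=hi, rhat_b=np.asarray(rh), config=config,
        c_mean=chains.stacked("c").mean(axis=0),
    )


def association_profile(curve: AssociationCurve, plateau_trials: int = 3) -> dict:
    """Shape summary of an association trajectory.

    Reports the trial-1 coefficient, the argmin trial, the plateau
    (mean of the last ``plateau_trials`` coefficients) and whether the
    dip-then-rebound pattern holds (an interior minimum after trial 1
    followed by recovery toward a higher plateau).
    """
    b = np.asarray(curve.b_mean)
    trials = np.asarray(curve.trials, dtype=int)
    i_min = int(np.argmin(b))
    plateau = float(b[-plateau_trials:].mean())
    dip = bool(i_min > 0 and i_min < len(b) - 1 and plateau > b[i_min] and b[0] > b[i_min])
    return {
        "predictor": curve.predictor,
        "initial": float(b[0]),
        "min_trial": int(trials[i_min]),
        "min_value": float(b[i_min]),
        "plateau": plateau,
        "plateau_trials": [int(t) for t in trials[-plateau_trials:]],
        "dip_rebound": dip,
    }


def rate_ability_correlations(
    g: pd.DataFrame | pd.Series,
    scores: pd.DataFrame,
) -> pd.DataFrame:
    """Pearson correlations between individual estimates and abilities.

    ``g`` holds one or more per-participant columns (e.g. the learning
    rate gamma, or an error-decline rate), ``scores`` the factor scores
    and musicality covariates; rows are aligned on the participant
    index.  Returns one row per (g column, score column) with Pearson r
    and the two-sided p value over pairwise-complete observations.
    """
    gdf = g.to_frame() if isinstance(g, pd.Series) else g
    joined = gdf.join(scores, how="inner", lsuffix="_g")
    rows = []
    for gc in gdf.columns:
        for sc in scores.columns:
            pair = joined[[gc, sc]].dropna()
            if len(pair) < 3:
                raise ValueError(f"fewer than 3 paired observations for {gc} vs {sc}")
            r, p = stats.pearsonr(pair[gc], pair[sc])
            rows.append({"variable": gc, "ability": sc, "r": float(r),
                         "p": float(p), "n": len(pair)})
    return pd.DataFrame(rows)
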