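"""Hierarchical Bayesian exponential learning curves.

Per-trial performance (correct key presses) of participant ``i`` at
trial ``t`` is modelled as

    y_it ~ Normal(eta_it, sigma),
    eta_it = beta_i + (alpha_i - beta_i) * exp(-exp(gamma_i) * (t - 1)),

so ``alpha_i`` is baseline performance (the trial-1 mean), ``beta_i`` the
asymptote approached with practice, and ``gamma_i`` the log learning
rate (the rate constant is ``exp(gamma)``, keeping ``gamma``
unconstrained; more negative means slower learning).  The individual
triples are exchangeable draws from a multivariate normal population,
``(alpha_i, beta_i, gamma_i) ~ MVN(mu, Sigma)``, so all three parameters
vary across participants and may correlate.

Sampling is blocked Gibbs: an exact Normal-Inverse-Wishart draw for
``(mu, Sigma)``, an exact inverse-gamma draw for ``sigma^2``, and
adaptive random-walk Metropolis for the individual triples (vectorised
over participants).  Candidate curve families for model comparison
(linear/quadratic/cubic with per-participant coefficient vectors) are
fully conjugate and sampled exactly; families are compared by
Pareto-smoothed importance-sampling leave-one-out elpd.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .mcmc import Chains, run_chains, sample_niw, summarize, AdaptiveScale

__all__ = [
    "CurveParams",
    "MCMCConfig",
    "REDUCED_CONFIG",
    "FULL_CONFIG",
    "Posterior",
    "ModelComparison",
    "curve_value",
    "pivot_scores",
    "fit_hierarchical",
    "fit_polynomial",
    "compare_models",
    "individual_estimates",
]

PARAM_NAMES = ("alpha", "beta", "gamma")
GAMMA_CLIP = (-12.0, 4.0)


@dataclass(frozen=True)
class CurveParams:
    """One participant's curve: baseline, asymptote, log learning rate."""

    alpha: float
    beta: float
    gamma: float


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler configuration; the study profile is 4 chains x 5000
    iterations with 2000 warm-up."""

    chains: int = 4
    iterations: int = 5000
    warmup: int = 2000
    seed: int = 1
    mh_substeps: int = 6

    def with_seed(self, seed: int) -> "MCMCConfig":
        return replace(self, seed=seed)


FULL_CONFIG = MCMCConfig()
REDUCED_CONFIG = MCMCConfig(chains=2, iterations=1500, warmup=500)


def curve_value(p: CurveParams | tuple, t) -> np.ndarray | float:
    """Expected performance eta(t) of the exponential curve, t >= 1."""
    if isinstance(p, tuple) and not isinstance(p, CurveParams):
        p = CurveParams(*p)
    t = np.asarray(t, dtype=float)
    out = p.beta + (p.alpha - p.beta) * np.exp(-np.exp(p.gamma) * (t - 1.0))
    return float(out) if out.ndim == 0 else out


def pivot_scores(
    scores: pd.DataFrame, task: str | None = None, value: str = "correct"
) -> tuple[np.ndarray, list, np.ndarray]:
    """Wide participant x trial matrix from a long trial-score table."""
    df = scores
    if task is not None:
        df = df[df["task"] == task]
        if df.empty:
            raise ValueError(f"no rows for task {task!r}")
    wide = df.pivot_table(index="participant", columns="trial", values=value, aggfunc="first")
    wide = wide.sort_index(axis=1)
    return wide.to_numpy(dtype=float), list(wide.index), wide.columns.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# posterior container


@dataclass
class Posterior:
    """Post-warm-up draws with convergence diagnostics.

    ``chains.draws`` holds ``mu`` (chain, draw, k), ``sigma_pop`` (chain,
    draw, k) population SDs, ``corr`` (chain, draw, k, k), ``theta``
    (chain, draw, n, k) individual parameters, and ``sigma`` residual SD.
    """

    chains: Chains
    participants: list
    config: MCMCConfig
    family: str
    y: np.ndarray
    t: np.ndarray
    param_names: tuple[str, ...] = PARAM_NAMES
    divergences: int = 0

    def rhat(self) -> dict[str, np.ndarray]:
        keys = ["mu", "sigma_pop", "sigma"]
        return {k: v for k, v in self.chains.rhat().items() if k in keys}

    def max_rhat(self) -> float:
        from .mcmc import _nanmax_all

        return _nanmax_all(self.rhat().values())

    def population_summary(self) -> dict[str, dict[str, float]]:
        mu = self.chains.stacked("mu")
        out = {}
        for j, name in enumerate(self.param_names):
            out[f"mu_{name}"] = summarize(mu[:, j])
        out["sigma"] = summarize(self.chains.stacked("sigma"))
        return out

    def individual_means(self) -> pd.DataFrame:
        theta = self.chains.stacked("theta").mean(axis=0)
        return pd.DataFrame(theta, index=pd.Index(self.participants, name="participant"),
                            columns=list(self.param_names))

    def fitted_curves(self) -> pd.DataFrame:
        """Posterior-mean fitted performance eta_it, participant x trial."""
        theta = self.chains.stacked("theta")  # (S, n, k)
        eta = _family_eta(self.family, theta, self.t).mean(axis=0)
        return pd.DataFrame(eta, index=pd.Index(self.participants, name="participant"),
                            columns=pd.Index(self.t.astype(int), name="trial"))

    def log_likelihood(self, thin: int = 1) -> np.ndarray:
        """Pointwise log-likelihood (chain, draw, observation) for LOO."""
        theta = self.chains.draws["theta"][:, ::thin]         # (c, s, n, k)
        sig = self.chains.draws["sigma"][:, ::thin]           # (c, s)
        c, s, n, k = theta.shape
        eta = _family_eta(self.family, theta.reshape(c * s, n, k), self.t)
        eta = eta.reshape(c, s, n, len(self.t))
        mask = ~np.isnan(self.y)
        resid = np.where(mask, self.y - eta, 0.0)
        ll = (
            -0.5 * (resid / sig[..., None, None]) ** 2
            - np.log(sig)[..., None, None]
            - 0.5 * np.log(2 * np.pi)
        )
        return ll[:, :, mask]

    def to_inferencedata(self, thin: int = 1):
        import arviz as az

        return az.from_dict(
            posterior={"mu": self.chains.draws["mu"], "sigma": self.chains.draws["sigma"]},
            log_likelihood={"y": self.log_likelihood(thin=thin)},
        )


def _family_eta(family: str, theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    """eta for stacked draws; theta (..., n, k), t (T,) -> (..., n, T)."""
    if family == "exponential":
        a, b, g = theta[..., 0:1], theta[..., 1:2], theta[..., 2:3]
        rate = np.exp(np.clip(g, *GAMMA_CLIP))
        return b + (a - b) * np.exp(-rate * (t - 1.0))
    X = _poly_design(family, t)  # (T, k)
    return theta @ X.T


def _poly_design(family: str, t: np.ndarray) -> np.ndarray:
    degree = {"linear": 1, "quadratic": 2, "cubic": 3}[family]
    ts = (t - t.mean()) / (t.max() - t.min())  # centred, scaled for stability
    return np.vander(ts, degree + 1, increasing=True)


# ---------------------------------------------------------------------------
# exponential sampler


def _check_scores(y: np.ndarray) -> None:
    if np.isinf(y).any():
        raise ValueError("non-finite performance values in input")
    obs = y[~np.isnan(y)]
    if obs.size == 0:
        raise ValueError("no observed performance values")
    if np.allclose(obs, obs.flat[0]):
        warnings.warn("all performance values identical; learning rate is unidentified",
                      stacklevel=3)


def _crude_curve_inits(y: np.ndarray, t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = y.shape[0]
    first = np.array([row[~np.isnan(row)][0] if (~np.isnan(row)).any() else 0.0 for row in y])
    late = np.array([np.nanmean(row[-3:]) if (~np.isnan(row[-3:])).any() else first[i]
                     for i, row in enumerate(y)])
    theta = np.column_stack([first, late, np.full(n, -1.0)])
    theta += rng.normal(scale=[1.0, 1.0, 0.3], size=(n, 3))
    return theta


def fit_hierarchical(
    scores: pd.DataFrame | np.ndarray,
    config: MCMCConfig = REDUCED_CONFIG,
    priors: dict | None = None,
    *,
    task: str | None = None,
    value: str = "correct",
) -> Posterior:
    """Sample the hierarchical exponential model for one task.

    Parameters
    ----------
    scores
        Long trial-score table (``participant, task, trial`` + value
        column) or a ready participant x trial matrix.
    config
        Chains / iterations / warm-up / seed.
    priors
        Optional overrides of the weakly informative defaults, keys
        ``m0, kappa0, nu0, psi0, sigma_a0, sigma_b0`` (the location
        defaults are scale-adapted: trial-1 and last-trial means).

    Returns
    -------
    Posterior with population and individual draws; warns when any
    split-Rhat among population parameters exceeds 1.01.
    """
    if isinstance(scores, pd.DataFrame):
        y, participants, t = pivot_scores(scores, task=task, value=value)
    else:
        y = np.asarray(scores, dtype=float)
        participants = list(range(y.shape[0]))
        t = np.arange(1, y.shape[1] + 1, dtype=float)
    _check_scores(y)
    n, T = y.shape
    if T < 2:
        raise ValueError("need at least 2 trials per participant")
    mask = ~np.isnan(y)
    n_obs = int(mask.sum())
    y0 = np.where(mask, y, 0.0)

    first_mean = float(np.nanmean(y[:, 0]))
    last_mean = float(np.nanmean(y[:, -1]))
    first_sd = max(float(np.nanstd(y[:, 0])), 1.0)
    last_sd = max(float(np.nanstd(y[:, -1])), 1.0)
    pr = {
        "m0": np.array([first_mean, last_mean, -1.0]),
        "kappa0": 0.01,
        "nu0": 7.0,
        # prior mean of Sigma is psi0 / (nu0 - d - 1) = psi0 / 3
        "psi0": 3.0 * np.diag([(2 * first_sd) ** 2, (2 * last_sd) ** 2, 1.5**2]),
        "sigma_a0": 2.0,
        "sigma_b0": max(0.25 * np.nanvar(y - np.nanmean(y, axis=0)), 1.0),
    }
    if priors:
        pr.update(priors)

    iters, warm = config.iterations, config.warmup
    keep = iters - warm

    def chain_fn(rng: np.random.Generator) -> dict[str, np.ndarray]:
        theta = _crude_curve_inits(y, t, rng)
        mu = theta.mean(axis=0)
        sigma_mat = np.cov(theta, rowvar=False) + np.eye(3)
        sigma = max(np.nanstd(y) * 0.3, 0.5)
        adapt = AdaptiveScale.start(n, init=-1.5)

        # per-participant empirical proposal covariance (adaptive
        # Metropolis): learned during warm-up, frozen afterwards
        warm_floor = 150
        mom_n = 0
        mom_mean = np.zeros((n, 3))
        mom_m2 = np.zeros((n, 3, 3))
        prop_chol = None

        def loglik(th: np.ndarray) -> np.ndarray:
            eta = _family_eta("exponential", th[None], t)[0]
            r = np.where(mask, y0 - eta, 0.0)
            return -0.5 * (r**2).sum(axis=1) / sigma**2 - mask.sum(axis=1) * np.log(sigma)

        out = {
            "mu": np.empty((keep, 3)),
            "sigma_pop": np.empty((keep, 3)),
            "corr": np.empty((keep, 3, 3)),
            "theta": np.empty((keep, n, 3)),
            "sigma": np.empty(keep),
        }
        ll_cur = loglik(theta)
        for it in range(iters):
            L = np.linalg.cholesky(sigma_mat + 1e-9 * np.eye(3))
            prec = np.linalg.inv(sigma_mat + 1e-9 * np.eye(3))
            for _ in range(config.mh_substeps):
                z = rng.standard_normal((n, 3))
                if prop_chol is None:
                    step = z @ L.T
                else:
                    step = np.einsum("nij,nj->ni", prop_chol, z)
                prop = theta + adapt.scale[:, None] * step
                prop[:, 2] = np.clip(prop[:, 2], *GAMMA_CLIP)
                ll_prop = loglik(prop)
                d_cur = theta - mu
                d_prop = prop - mu
                lp_cur = -0.5 * np.einsum("ij,jk,ik->i", d_cur, prec, d_cur)
                lp_prop = -0.5 * np.einsum("ij,jk,ik->i", d_prop, prec, d_prop)
                log_acc = (ll_prop + lp_prop) - (ll_cur + lp_cur)
                acc = np.log(rng.uniform(size=n)) < log_acc
                theta = np.where(acc[:, None], prop, theta)
                ll_cur = np.where(acc, ll_prop, ll_cur)
                if it < warm:
                    adapt.update(acc, it)
            if it < warm:
                mom_n += 1
                d = theta - mom_mean
                mom_mean += d / mom_n
                mom_m2 += np.einsum("ni,nj->nij", d, theta - mom_mean)
                if it == warm - 1 or (it >= warm_floor and prop_chol is None):
                    cov = mom_m2 / max(mom_n - 1, 1) + 1e-6 * np.eye(3)
                    prop_chol = np.linalg.cholesky((2.38**2 / 3.0) * cov)
                    adapt.log_scale[:] = 0.0
            mu, sigma_mat = sample_niw(rng, theta, pr["m0"], pr["kappa0"], pr["nu0"], pr["psi0"])
            eta = _family_eta("exponential", theta[None], t)[0]
            ssr = float((np.where(mask, y0 - eta, 0.0) ** 2).sum())
            sigma2 = 1.0 / rng.gamma(pr["sigma_a0"] + n_obs / 2.0,
                                     1.0 / (pr["sigma_b0"] + ssr / 2.0))
            sigma = float(np.sqrt(sigma2))
            ll_cur = loglik(theta)  # sigma changed
            if it >= warm:
                j = it - warm
                sd = np.sqrt(np.diag(sigma_mat))
                out["mu"][j] = mu
                out["sigma_pop"][j] = sd
                out["corr"][j] = sigma_mat / np.outer(sd, sd)
                out["theta"][j] = theta
                out["sigma"][j] = sigma
        return out

    chains = run_chains(config.chains, config.seed, chain_fn, warm)
    post = Posterior(chains=chains, participants=participants, config=config,
                     family="exponential", y=y, t=t)
    _warn_rhat(post)
    return post


def _warn_rhat(post: Posterior) -> None:
    mx = post.max_rhat()
    if mx > 1.01:
        warnings.warn(
            f"convergence warning: max split-Rhat {mx:.3f} > 1.01 "
            f"({post.family} model); consider more iterations",
            stacklevel=3,
        )


# ---------------------------------------------------------------------------
# conjugate polynomial families


def fit_polynomial(
    scores: pd.DataFrame | np.ndarray,
    family: str,
    config: MCMCConfig = REDUCED_CONFIG,
    *,
    task: str | None = None,
    value: str = "correct",
) -> Posterior:
    """Exact-Gibbs hierarchical polynomial curve (linear/quadratic/cubic).

    Per-participant coefficient vectors share the exponential model's
    random-effects structure: ``c_i ~ MVN(mu, Sigma)`` with a conjugate
    Normal-Inverse-Wishart hyperprior, so every update is exact.
    """
    if family not in ("linear", "quadratic", "cubic"):
        raise ValueError(f"unknown family {family!r}")
    if isinstance(scores, pd.DataFrame):
        y, participants, t = pivot_scores(scores, task=task, value=value)
    else:
        y = np.asarray(scores, dtype=float)
        participants = list(range(y.shape[0]))
        t = np.arange(1, y.shape[1] + 1, dtype=float)
    _check_scores(y)
    n, T = y.shape
    X = _poly_design(family, t)
    k = X.shape[1]
    mask = ~np.isnan(y)
    n_obs = int(mask.sum())
    y0 = np.where(mask, y, 0.0)

    ybar = float(np.nanmean(y))
    ysd = max(float(np.nanstd(y)), 1.0)
    m0 = np.zeros(k)
    m0[0] = ybar
    pr = {
        "m0": m0, "kappa0": 0.01, "nu0": float(k + 4),
        "psi0": (4.0) * np.eye(k) * (2 * ysd) ** 2 / 4.0,
        "sigma_a0": 2.0, "sigma_b0": 1.0,
    }
    iters, warm = config.iterations, config.warmup
    keep = iters - warm
    names = tuple(f"c{j}" for j in range(k))

    def chain_fn(rng: np.random.Generator) -> dict[str, np.ndarray]:
        # least-squares starts (complete rows); fall back to mean level
        theta = np.zeros((n, k))
        for i in range(n):
            m = mask[i]
            if m.sum() >= k:
                theta[i], *_ = np.linalg.lstsq(X[m], y[i, m], rcond=None)
            else:
                theta[i, 0] = np.nanmean(y[i]) if m.any() else ybar
        theta += rng.normal(scale=0.5, size=(n, k))
        mu = theta.mean(axis=0)
        sigma_mat = np.cov(theta, rowvar=False) + np.eye(k)
        sigma = ysd * 0.3

        out = {
            "mu": np.empty((keep, k)),
            "sigma_pop": np.empty((keep, k)),
            "corr": np.empty((keep, k, k)),
            "theta": np.empty((keep, n, k)),
            "sigma": np.empty(keep),
        }
        for it in range(iters):
            prec_pop = np.linalg.inv(sigma_mat + 1e-9 * np.eye(k))
            # exact draw of each c_i (same X for complete rows; per-row masks)
            for pattern in np.unique(mask, axis=0):
                rows = np.flatnonzero((mask == pattern).all(axis=1))
                Xo = X[pattern]
                A = Xo.T @ Xo / sigma**2 + prec_pop
                Ainv = np.linalg.inv(A)
                La = np.linalg.cholesky(Ainv)
                rhs = (y0[np.ix_(rows, np.flatnonzero(pattern))] @ Xo) / sigma**2 + mu @ prec_pop
                mean = rhs @ Ainv.T
                theta[rows] = mean + rng.standard_normal((rows.size, k)) @ La.T
            mu, sigma_mat = sample_niw(rng, theta, pr["m0"], pr["kappa0"], pr["nu0"], pr["psi0"])
            eta = theta @ X.T
            ssr = float((np.where(mask, y0 - eta, 0.0) ** 2).sum())
            sigma = float(np.sqrt(1.0 / rng.gamma(pr["sigma_a0"] + n_obs / 2.0,
                                                  1.0 / (pr["sigma_b0"] + ssr / 2.0))))
            if it >= warm:
                j = it - warm
                sd = np.sqrt(np.diag(sigma_mat))
                out["mu"][j] = mu
                out["sigma_pop"][j] = sd
                out["corr"][j] = sigma_mat / np.outer(sd, sd)
                out["theta"][j] = theta
                out["sigma"][j] = sigma
        return out

    chains = run_chains(config.chains, config.seed, chain_fn, warm)
    post = Posterior(chains=chains, participants=participants, config=config,
                     family=family, y=y, t=t, param_names=names)
    _warn_rhat(post)
    return post


# ---------------------------------------------------------------------------
# model comparison


@dataclass
class ModelComparison:
    """PSIS-LOO elpd per curve family with pairwise differences."""

    elpd: dict[str, float]
    se: dict[str, float]
    diff: pd.DataFrame          # diff[a][b] = elpd(a) - elpd(b)
    diff_se: pd.DataFrame
    pareto_k_frac: dict[str, float]
    unreliable: bool = False

    def best(self) -> str:
        return max(self.elpd, key=self.elpd.get)


def compare_models(
    scores: pd.DataFrame | np.ndarray,
    families: tuple[str, ...] = ("linear", "quadratic", "cubic", "exponential"),
    config: MCMCConfig = REDUCED_CONFIG,
    *,
    task: str | None = None,
    value: str = "correct",
    thin: int = 2,
) -> ModelComparison:
    """Compare curve families on the same data by PSIS-LOO elpd.

    Pairwise elpd differences are computed from the pointwise elpd
    contributions (difference SE = sqrt(N * var(pointwise diffs))).  The
    comparison is flagged unreliable when more than 10% of points have
    Pareto k > 0.7 for any family.
    """
    import arviz as az

    posts: dict[str, Posterior] = {}
    for fam in families:
        fit = fit_hierarchical if fam == "exponential" else fit_polynomial
        kwargs = {"task": task, "value": value}
        if fam == "exponential":
            posts[fam] = fit(scores, config, **kwargs)
        else:
            posts[fam] = fit(scores, fam, config, **kwargs)

    elpd, se, kfrac, pointwise = {}, {}, {}, {}
    for fam, post in posts.items():
        idata = post.to_inferencedata(thin=thin)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = az.loo(idata, pointwise=True)
        elpd[fam] = float(res.elpd_loo)
        se[fam] = float(res.se)
        pointwise[fam] = np.asarray(res.loo_i)
        kfrac[fam] = float(np.mean(np.asarray(res.pareto_k) > 0.7))

    fams = list(posts)
    dm = pd.DataFrame(0.0, index=fams, columns=fams)
    dse = pd.DataFrame(0.0, index=fams, columns=fams)
    for a in fams:
        for b in fams:
            if a == b:
                continue
            d = pointwise[a] - pointwise[b]
            dm.loc[a, b] = float(d.sum())
            dse.loc[a, b] = float(np.sqrt(len(d) * np.var(d)))
    unreliable = any(v > 0.10 for v in kfrac.values())
    if unreliable:
        warnings.warn("PSIS-LOO unreliable: >10% of points with Pareto k > 0.7", stacklevel=2)
    return ModelComparison(elpd=elpd, se=se, diff=dm, diff_se=dse,
                           pareto_k_frac=kfrac, unreliable=unreliable)


def individual_estimates(post: Posterior) -> pd.DataFrame:
    """Per-participant posterior means of (alpha, beta, gamma)."""
    return post.individual_means()
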