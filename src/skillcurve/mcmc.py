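"""Shared MCMC machinery for the hierarchical models.

All models in this package (learning curves, gaze change points,
trial-wise association models) are sampled with blocked Gibbs sweeps:
hyperparameters with conjugate priors are drawn exactly, participant-level
parameters that enter the likelihood nonlinearly are updated with
adaptive random-walk Metropolis steps, vectorised across participants
(their full conditionals are independent).  Proposal scales adapt toward
a target acceptance rate during warm-up only, so post-warm-up draws form
a fixed Markov chain.

Convergence is summarised with the rank-normalised split-Rhat from
arviz; random-walk samplers have no divergent transitions, so the
divergence count reported for API parity is always zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["Chains", "rhat", "summarize", "sample_niw", "AdaptiveScale"]


def rhat(draws: np.ndarray) -> float:
    """Rank-normalised split-Rhat for one parameter, draws (nchain, ndraw)."""
    import arviz as az

    return float(az.rhat(np.asarray(draws)[None, ...][0]))


def rhat_dataset(groups: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Split-Rhat per parameter for arrays shaped (nchain, ndraw, ...)."""
    import arviz as az

    ds = az.convert_to_dataset(groups)
    rh = az.rhat(ds)
    return {k: np.asarray(rh[k]) for k in groups}


@dataclass
class Chains:
    """Post-warm-up draws: name -> array (nchain, ndraw, *shape)."""

    draws: dict[str, np.ndarray]
    warmup: int
    attrs: dict = field(default_factory=dict)

    @property
    def nchain(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def ndraw(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Draws pooled over chains, shape (nchain*ndraw, *shape)."""
        a = self.draws[name]
        return a.reshape(-1, *a.shape[2:])

    def rhat(self) -> dict[str, np.ndarray]:
        return rhat_dataset(self.draws)

    def max_rhat(self) -> float:
        return _nanmax_all(self.rhat().values())


def _nanmax_all(arrays) -> float:
    """Max over parameter Rhats; NaN when undefined (single chain)."""
    vals = np.concatenate([np.atleast_1d(np.asarray(v, dtype=float)).ravel()
                           for v in arrays])
    if np.isnan(vals).all():
        return float("nan")
    return float(np.nanmax(vals))


def summarize(samples: np.ndarray, prob: float = 0.95) -> dict[str, float]:
    """Posterior mean and central credible interval for a 1-d sample."""
    lo, hi = np.quantile(samples, [(1 - prob) / 2, 1 - (1 - prob) / 2])
    return {"mean": float(np.mean(samples)), "lower": float(lo), "upper": float(hi)}


def sample_niw(
    rng: np.random.Generator,
    theta: np.ndarray,
    m0: np.ndarray,
    kappa0: float,
    nu0: float,
    psi0: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (mu, Sigma) from the Normal-Inverse-Wishart full conditional.

    ``theta`` is the (n, d) matrix of individual-level parameters; the
    conjugate update and an inverse-Wishart draw (via the Bartlett
    decomposition of the Wishart on the inverse scale) give an exact
    Gibbs step for the population mean and covariance.
    """
    n, d = theta.shape
    tbar = theta.mean(axis=0)
    S = (theta - tbar).T @ (theta - tbar)
    kappa_n = kappa0 + n
    nu_n = nu0 + n
    m_n = (kappa0 * m0 + n * tbar) / kappa_n
    psi_n = psi0 + S + (kappa0 * n / kappa_n) * np.outer(tbar - m0, tbar - m0)

    # Sigma ~ IW(nu_n, psi_n): draw W ~ Wishart(nu_n, psi_n^-1), Sigma = W^-1
    L = np.linalg.cholesky(np.linalg.inv(psi_n))
    A = np.zeros((d, d))
    for i in range(d):
        A[i, i] = np.sqrt(rng.chisquare(nu_n - i))
        for j in range(i):
            A[i, j] = rng.standard_normal()
    W = L @ A @ A.T @ L.T
    sigma = np.linalg.inv(W)
    sigma = 0.5 * (sigma + sigma.T)
    mu = rng.multivariate_normal(m_n, sigma / kappa_n)
    return mu, sigma


@dataclass
class AdaptiveScale:
    """Robbins-Monro adaptation of per-block log proposal scales."""

    log_scale: np.ndarray
    target: float = 0.3
    rate: float = 0.66

    @classmethod
    def start(cls, n: int, init: float = -1.0, target: float = 0.3) -> "AdaptiveScale":
        return cls(log_scale=np.full(n, init, dtype=float), target=target)

    @property
    def scale(self) -> np.ndarray:
        return np.exp(self.log_scale)

    def update(self, accepted: np.ndarray, iteration: int) -> None:
        step = 1.0 / (iteration + 1) ** self.rate
        self.log_scale += step * (accepted.astype(float) - self.target)
        np.clip(self.log_scale, -10.0, 3.0, out=self.log_scale)


def run_chains(
    n_chains: int,
    seed: int,
    chain_fn: Callable[[np.random.Generator], dict[str, np.ndarray]],
    warmup: int,
) -> Chains:
    """Run independent chains from spawned RNG streams and stack draws."""
    streams = np.random.SeedSequence(seed).spawn(n_chains)
    per_chain = [chain_fn(np.random.default_rng(s)) for s in streams]
    stacked = {
        k: np.stack([c[k] for c in per_chain], axis=0) for k in per_chain[0]
    }
    return Chains(draws=stacked, warmup=warmup)
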