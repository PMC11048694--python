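"""Confirmatory factor analysis of the cognito-motor test battery.

Fifteen indicators measure four correlated latent abilities:

* working memory (WM): digit spans forward/reversed/sequential, Corsi
  block span reversed (``DSP_F, DSP_R, DSP_S, BS_R``);
* processing speed (PS): coding, symbol search, number-connection test,
  trail-making A (``C, SS, ZVT, TMT_A``) plus a cross-loading of
  ``DSP_S``;
* psychomotor speed (PM): clicking speed right/left/both
  (``Click_R, Click_L, Click_B``);
* dexterity (DX): Purdue Pegboard right/left/both/assembly
  (``PP_R, PP_L, PP_B, PP_A``).

The model ``Sigma = Lambda Phi Lambda' + Theta`` (standardised factors,
unit-diagonal ``Phi``) is fitted by maximum likelihood: the discrepancy
``F = log|Sigma| + tr(S Sigma^-1) - log|S| - p`` is minimised on the
sample covariance when data are complete, and the casewise (full
information) likelihood is maximised when indicators are missing (the
Corsi task could not be administered to part of the sample).  Fit is
summarised with CFI, TLI, IFI, RMSEA and SRMR; per-participant factor
scores use the regression method ``F_hat = Phi Lambda' Sigma^-1 x`` on
the available indicators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "FACTOR_STRUCTURE",
    "TIMED_INDICATORS",
    "BATTERY_COLUMNS",
    "CFASpec",
    "MeasurementModel",
    "FitIndices",
    "prepare_indicators",
    "fit_cfa",
    "fit_indices",
    "factor_scores",
    "factor_correlations",
]

#: Default loading pattern of the four-factor battery model.
FACTOR_STRUCTURE: dict[str, list[str]] = {
    "WM": ["DSP_F", "DSP_R", "DSP_S", "BS_R"],
    "PS": ["C", "SS", "ZVT", "TMT_A", "DSP_S"],
    "PM": ["Click_R", "Click_L", "Click_B"],
    "DX": ["PP_R", "PP_L", "PP_B", "PP_A"],
}

#: Indicators scored as completion times: lower raw value = better.
TIMED_INDICATORS = ("ZVT", "TMT_A")

BATTERY_COLUMNS = [
    "Click_R", "Click_L", "Click_B",
    "PP_R", "PP_L", "PP_B", "PP_A",
    "C", "SS", "ZVT", "TMT_A",
    "DSP_F", "DSP_R", "DSP_S", "BS_R",
]

HEYWOOD_FLOOR = 1e-4


@dataclass
class CFASpec:
    """Loading sparsity and factor-correlation pattern.

    ``structure`` maps factor name -> indicator list (cross-loadings are
    simply repeated indicators).  ``fixed_zero_corr`` lists factor pairs
    whose covariance is constrained to zero; by default every factor
    covariance is estimated freely.
    """

    structure: dict[str, list[str]] = field(default_factory=lambda: dict(FACTOR_STRUCTURE))
    fixed_zero_corr: list[tuple[str, str]] = field(default_factory=list)

    @property
    def factors(self) -> list[str]:
        return list(self.structure)

    @property
    def indicators(self) -> list[str]:
        seen: list[str] = []
        for inds in self.structure.values():
            for ind in inds:
                if ind not in seen:
                    seen.append(ind)
        return seen

    def loading_pattern(self) -> np.ndarray:
        """Boolean indicator x factor matrix of free loadings."""
        inds, facs = self.indicators, self.factors
        pat = np.zeros((len(inds), len(facs)), dtype=bool)
        for j, f in enumerate(facs):
            for ind in self.structure[f]:
                pat[inds.index(ind), j] = True
        return pat

    def free_corr_pairs(self) -> list[tuple[int, int]]:
        facs = self.factors
        fixed = {frozenset(p) for p in self.fixed_zero_corr}
        pairs = []
        for j in range(len(facs)):
            for k in range(j + 1, len(facs)):
                if frozenset((facs[j], facs[k])) not in fixed:
                    pairs.append((j, k))
        return pairs


@dataclass
class MeasurementModel:
    """Fitted CFA: estimates, objective value and chi-square statistics."""

    spec: CFASpec
    loadings: pd.DataFrame           # indicator x factor
    factor_cov: pd.DataFrame         # Phi, unit diagonal
    residual_var: pd.Series          # Theta diagonal
    n: int
    estimator: str                   # "ml" or "fiml"
    converged: bool
    grad_norm: float
    fmin: float
    chi2_model: float
    df_model: int
    chi2_baseline: float
    df_baseline: int
    sample_cov: pd.DataFrame         # S (EM estimate under FIML)
    heywood: list[str] = field(default_factory=list)
    param_se: dict[str, float] = field(default_factory=dict)

    def implied_cov(self) -> np.ndarray:
        L = self.loadings.to_numpy()
        P = self.factor_cov.to_numpy()
        return L @ P @ L.T + np.diag(self.residual_var.to_numpy())


@dataclass
class FitIndices:
    chi2_model: float
    df_model: int
    chi2_baseline: float
    df_baseline: int
    CFI: float
    TLI: float
    IFI: float
    RMSEA: float
    SRMR: float

    def as_dict(self) -> dict[str, float]:
        return {
            "chi2_model": self.chi2_model, "df_model": self.df_model,
            "chi2_baseline": self.chi2_baseline, "df_baseline": self.df_baseline,
            "CFI": self.CFI, "TLI": self.TLI, "IFI": self.IFI,
            "RMSEA": self.RMSEA, "SRMR": self.SRMR,
        }


def prepare_indicators(table: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Orient and z-standardise battery scores.

    Timed scores (ZVT, TMT_A) are sign-flipped before standardisation so
    higher = better throughout; every retained column then has sample
    mean 0 and SD 1 (n-1 convention).  Missing cells stay missing.
    """
    columns = columns or [c for c in BATTERY_COLUMNS if c in table.columns]
    out = table[columns].astype(float).copy()
    for col in columns:
        x = out[col]
        if x.notna().sum() < 2 or np.isclose(x.std(ddof=1), 0.0) or x.std(ddof=1) != x.std(ddof=1):
            raise ValueError(f"indicator {col!r} has zero variance (or <2 observations)")
        if col in TIMED_INDICATORS:
            x = -x
        out[col] = (x - x.mean()) / x.std(ddof=1)
    return out


# ---------------------------------------------------------------------------
# parameterisation


def _unpack(theta, pat, free_pairs, n_fac):
    n_load = int(pat.sum())
    lam = np.zeros(pat.shape)
    lam[pat] = theta[:n_load]
    phi = np.eye(n_fac)
    for m, (j, k) in enumerate(free_pairs):
        phi[j, k] = phi[k, j] = theta[n_load + m]
    res = HEYWOOD_FLOOR + np.exp(theta[n_load + len(free_pairs):])
    return lam, phi, res


def _pack_start(S, pat, free_pairs):
    d = np.sqrt(np.diag(S))
    lam0 = np.repeat((0.6 * d)[:, None], pat.shape[1], axis=1)[pat]
    phi0 = np.full(len(free_pairs), 0.3)
    res0 = np.log(np.maximum(0.4 * np.diag(S), 1e-3))
    return np.concatenate([lam0, phi0, res0])


def _ml_discrepancy(S, sigma):
    p = S.shape[0]
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return np.inf
    _, logdet_s = np.linalg.slogdet(S)
    return logdet + float(np.trace(np.linalg.solve(sigma, S))) - logdet_s - p


def _fiml_nll(X_patterns, sigma):
    """-2 log L (up to the 2*pi constant) under mean-zero MVN by pattern."""
    total = 0.0
    for obs_idx, Xo in X_patterns:
        sub = sigma[np.ix_(obs_idx, obs_idx)]
        sign, logdet = np.linalg.slogdet(sub)
        if sign <= 0:
            return np.inf
        total += Xo.shape[0] * logdet + float(np.einsum("ij,ij->", Xo @ np.linalg.inv(sub), Xo))
    return total


def _group_patterns(X: np.ndarray):
    mask = ~np.isnan(X)
    patterns = {}
    for i in range(X.shape[0]):
        key = tuple(mask[i])
        patterns.setdefault(key, []).append(i)
    out = []
    for key, rows in patterns.items():
        obs = np.flatnonzero(np.array(key))
        if obs.size:
            out.append((obs, X[np.ix_(rows, obs)]))
    return out


def _em_saturated(X: np.ndarray, max_iter: int = 200, tol: float = 1e-8) -> np.ndarray:
    """EM estimate of an unstructured mean-zero covariance with missing cells."""
    p = X.shape[1]
    df = pd.DataFrame(X)
    sigma = df.cov(ddof=0).to_numpy()
    sigma = np.where(np.isnan(sigma), 0.0, sigma)
    sigma[np.diag_indices(p)] = np.nanvar(X, axis=0)
    patterns = _group_patterns(X)
    n = sum(Xo.shape[0] for _, Xo in patterns)
    for _ in range(max_iter):
        acc = np.zeros((p, p))
        for obs, Xo in patterns:
            mis = np.setdiff1d(np.arange(p), obs)
            Soo = sigma[np.ix_(obs, obs)]
            Soo_inv = np.linalg.inv(Soo)
            Exx = np.zeros((p, p))
            Exx[np.ix_(obs, obs)] = Xo.T @ Xo
            if mis.size:
                B = sigma[np.ix_(mis, obs)] @ Soo_inv          # regression of missing on observed
                Xm = Xo @ B.T                                   # conditional means
                cond = sigma[np.ix_(mis, mis)] - B @ sigma[np.ix_(obs, mis)]
                Exx[np.ix_(mis, obs)] = Xm.T @ Xo
                Exx[np.ix_(obs, mis)] = Exx[np.ix_(mis, obs)].T
                Exx[np.ix_(mis, mis)] = Xm.T @ Xm + Xo.shape[0] * cond
            acc += Exx
        new = acc / n
        if np.max(np.abs(new - sigma)) < tol:
            sigma = new
            break
        sigma = new
    return sigma


def fit_cfa(
    indicators: pd.DataFrame,
    spec: CFASpec | None = None,
    n: int | None = None,
    *,
    gtol: float = 1e-6,
    compute_se: bool = True,
) -> MeasurementModel:
    """Fit the CFA by maximum likelihood.

    Complete data: minimises the ML discrepancy on the sample covariance
    ``S`` and takes ``chi2 = (n-1) * F`` at the optimum.  Incomplete
    data: maximises the casewise full-information likelihood (mean
    structure saturated by prior standardisation) and takes
    ``chi2 = 2(logL_saturated - logL_model)`` with the saturated
    covariance estimated by EM.  Residual variances are bounded below at
    ``1e-4``; hitting the bound (Heywood case) raises a warning.
    """
    spec = spec or CFASpec()
    cols = spec.indicators
    missing_cols = [c for c in cols if c not in indicators.columns]
    if missing_cols:
        raise ValueError(f"indicator table lacks columns {missing_cols}")
    X = indicators[cols].to_numpy(dtype=float)
    n = n or X.shape[0]
    p = len(cols)
    pat = spec.loading_pattern()
    pairs = spec.free_corr_pairs()
    n_fac = len(spec.factors)
    has_missing = bool(np.isnan(X).any())

    if has_missing:
        estimator = "fiml"
        patterns = _group_patterns(X)
        S = _em_saturated(X)

        def objective(theta):
            lam, phi, res = _unpack(theta, pat, pairs, n_fac)
            if np.min(np.linalg.eigvalsh(phi)) < 1e-8:
                return np.inf
            sigma = lam @ phi @ lam.T + np.diag(res)
            return _fiml_nll(patterns, sigma)
    else:
        estimator = "ml"
        S = np.cov(X, rowvar=False, ddof=1)

        def objective(theta):
            lam, phi, res = _unpack(theta, pat, pairs, n_fac)
            if np.min(np.linalg.eigvalsh(phi)) < 1e-8:
                return np.inf
            sigma = lam @ phi @ lam.T + np.diag(res)
            return _ml_discrepancy(S, sigma)

    x0 = _pack_start(S, pat, pairs)
    bounds = (
        [(None, None)] * int(pat.sum())
        + [(-0.999, 0.999)] * len(pairs)
        + [(None, None)] * p
    )
    res_opt = optimize.minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": 2000, "ftol": 1e-12, "gtol": gtol})
    grad_norm = float(np.max(np.abs(res_opt.jac))) if res_opt.jac is not None else np.nan
    if not res_opt.success:
        warnings.warn(
            f"CFA optimisation did not converge ({res_opt.message}); "
            f"best objective {res_opt.fun:.6g}, max |grad| {grad_norm:.3g}",
            stacklevel=2,
        )

    lam, phi, resid = _unpack(res_opt.x, pat, pairs, n_fac)
    heywood = [cols[i] for i in np.flatnonzero(resid < HEYWOOD_FLOOR + 1e-6)]
    if heywood:
        warnings.warn(f"Heywood case: residual variance at floor for {heywood}", stacklevel=2)

    # sign convention: majority-positive loadings per factor
    for j in range(n_fac):
        col = lam[:, j]
        if col[pat[:, j]].sum() < 0:
            lam[:, j] = -col
            for k in range(n_fac):
                if k != j:
                    phi[j, k] = phi[k, j] = -phi[j, k]

    if estimator == "ml":
        chi2_model = max((n - 1) * res_opt.fun, 0.0)
        # independence baseline: diagonal Sigma -> F_B = -log|R|
        d = np.sqrt(np.diag(S))
        R = S / np.outer(d, d)
        chi2_baseline = max(-(n - 1) * np.linalg.slogdet(R)[1], 0.0)
    else:
        patterns = _group_patterns(X)
        ll_sat = _fiml_nll(patterns, S)
        sigma_diag = np.diag(np.diag(S))
        chi2_model = max(res_opt.fun - ll_sat, 0.0)
        chi2_baseline = max(_fiml_nll(patterns, sigma_diag) - ll_sat, 0.0)

    n_free = int(pat.sum()) + len(pairs) + p
    df_model = p * (p + 1) // 2 - n_free
    df_baseline = p * (p - 1) // 2

    param_se: dict[str, float] = {}
    if compute_se:
        param_se = _corr_standard_errors(objective, res_opt.x, estimator, n, pat, pairs, spec)

    return MeasurementModel(
        spec=spec,
        loadings=pd.DataFrame(np.where(pat, lam, 0.0), index=cols, columns=spec.factors),
        factor_cov=pd.DataFrame(phi, index=spec.factors, columns=spec.factors),
        residual_var=pd.Series(resid, index=cols),
        n=n,
        estimator=estimator,
        converged=bool(res_opt.success),
        grad_norm=grad_norm,
        fmin=float(res_opt.fun),
        chi2_model=float(chi2_model),
        df_model=df_model,
        chi2_baseline=float(chi2_baseline),
        df_baseline=df_baseline,
        sample_cov=pd.DataFrame(S, index=cols, columns=cols),
        heywood=heywood,
        param_se=param_se,
    )


def _corr_standard_errors(objective, xhat, estimator, n, pat, pairs, spec):
    """Delta-method SEs for the free factor correlations via numerical Hessian."""
    scale = (n - 1) / 2.0 if estimator == "ml" else 0.5  # -> -logL curvature
    n_load = int(pat.sum())
    idx = list(range(n_load, n_load + len(pairs)))
    if not idx:
        return {}
    eps = 1e-4
    k = len(xhat)
    H = np.zeros((k, k))
    f0 = objective(xhat)
    for a in range(k):
        for b in range(a, k):
            da = np.zeros(k); da[a] = eps
            db = np.zeros(k); db[b] = eps
            H[a, b] = H[b, a] = (
                objective(xhat + da + db) - objective(xhat + da)
                - objective(xhat + db) + f0
            ) / eps**2
    H *= scale
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    ses = {}
    facs = spec.factors
    for m, (j, kk) in enumerate(pairs):
        v = cov[idx[m], idx[m]]
        ses[f"{facs[j]}~~{facs[kk]}"] = float(np.sqrt(v)) if v > 0 else float("nan")
    return ses


def fit_indices(model: MeasurementModel, S: np.ndarray | None = None, n: int | None = None) -> FitIndices:
    """CFI, TLI, IFI, RMSEA and SRMR from the model and baseline chi-squares.

    ``CFI = 1 - max(chi2_M - df_M, 0) / max(chi2_B - df_B, chi2_M - df_M, 0)``;
    ``TLI = ((chi2_B/df_B) - (chi2_M/df_M)) / ((chi2_B/df_B) - 1)``;
    ``IFI = (chi2_B - chi2_M) / (chi2_B - df_M)``;
    ``RMSEA = sqrt(max(chi2_M - df_M, 0) / (df_M (n-1)))``;
    SRMR is the RMS of the standardised residual covariances over the
    ``p(p+1)/2`` unique elements.
    """
    n = n or model.n
    S = model.sample_cov.to_numpy() if S is None else np.asarray(S)
    cm, dm = model.chi2_model, model.df_model
    cb, db = model.chi2_baseline, model.df_baseline
    if db <= 0:
        raise ValueError("baseline degrees of freedom must be positive")

    num = max(cm - dm, 0.0)
    den = max(cb - db, cm - dm, 0.0)
    cfi = 1.0 if den == 0 else 1.0 - num / den
    tli = ((cb / db) - (cm / dm)) / ((cb / db) - 1.0) if dm > 0 else float("nan")
    ifi = (cb - cm) / (cb - dm) if (cb - dm) != 0 else float("nan")
    rmsea = float(np.sqrt(num / (dm * (n - 1)))) if dm > 0 else 0.0

    sigma = model.implied_cov()
    d = np.sqrt(np.diag(S))
    std_resid = (S - sigma) / np.outer(d, d)
    iu = np.triu_indices_from(std_resid)
    srmr = float(np.sqrt(np.mean(std_resid[iu] ** 2)))

    clip = lambda v: float(min(max(v, 0.0), 1.0))
    return FitIndices(
        chi2_model=float(cm), df_model=int(dm),
        chi2_baseline=float(cb), df_baseline=int(db),
        CFI=clip(cfi), TLI=clip(tli), IFI=clip(ifi),
        RMSEA=rmsea, SRMR=srmr,
    )


def factor_scores(model: MeasurementModel, indicators: pd.DataFrame) -> pd.DataFrame:
    """Regression-method factor scores, ``F_hat = Phi Lambda' Sigma^-1 x``.

    For participants with missing indicators the observed-indicator
    submatrix of the implied covariance is used.  A factor with no
    observed indicator (counting cross-loadings) gets a missing score.
    """
    cols = model.spec.indicators
    X = indicators[cols].to_numpy(dtype=float)
    L = model.loadings.to_numpy()
    P = model.factor_cov.to_numpy()
    sigma = model.implied_cov()
    facs = model.spec.factors
    pat = model.spec.loading_pattern()

    out = np.full((X.shape[0], len(facs)), np.nan)
    cache: dict[tuple, np.ndarray] = {}
    for i in range(X.shape[0]):
        obs = np.flatnonzero(~np.isnan(X[i]))
        if obs.size == 0:
            continue
        key = tuple(obs)
        if key not in cache:
            cache[key] = P @ L[obs].T @ np.linalg.inv(sigma[np.ix_(obs, obs)])
        scores = cache[key] @ X[i, obs]
        for j in range(len(facs)):
            if pat[obs, j].any():
                out[i, j] = scores[j]
    return pd.DataFrame(out, index=indicators.index, columns=facs)


def factor_correlations(model: MeasurementModel) -> pd.DataFrame:
    """Factor correlation table; SEs (where computed) in ``model.param_se``."""
    return model.factor_cov.copy()
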