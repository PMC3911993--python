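"""Maximum-likelihood covariance-structure estimation.

The model-implied covariance in the all-y parameterization is

    Sigma(theta) = Lambda (I - B)^-1 Psi (I - B)^-T Lambda^T + Theta_eps

and the ML discrepancy between the sample covariance S (divisor N-1) and
Sigma is

    F(theta) = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p  >= 0,

zero exactly at Sigma = S.  T = (N-1) F(theta_hat) is the model chi-square.
Minimization uses L-BFGS-B with the analytic gradient

    dF/dtheta_k = tr[(Sigma^-1 - Sigma^-1 S Sigma^-1) dSigma/dtheta_k],

which reduces to closed-form matrix entries for each slot type.  Standard
errors come from the inverse numerical Hessian of ((N-1)/2) F at the
optimum (observed information).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import (
    IdentificationError,
    NotPositiveDefiniteError,
    PathsemError,
    SingularStructureError,
)
from .model import SemModel

__all__ = [
    "SampleMoments",
    "FitIndices",
    "FitResult",
    "sample_covariance",
    "implied_covariance",
    "ml_discrepancy",
    "fit_ml",
    "fit_indices",
    "standardize",
    "wald_tests",
]

_PENALTY = 1e10


@dataclass
class SampleMoments:
    """Sample covariance matrix (divisor N-1) with its variable names."""

    S: np.ndarray
    n: int
    names: list[str]

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        if self.S.shape != (len(self.names), len(self.names)):
            raise ValueError("S does not match the variable list")
        if not np.allclose(self.S, self.S.T, atol=1e-10):
            raise ValueError("S must be symmetric")

    def reorder(self, names: list[str]) -> "SampleMoments":
        missing = [v for v in names if v not in self.names]
        if missing:
            raise PathsemError(f"data lacks model variables: {missing}")
        idx = [self.names.index(v) for v in names]
        return SampleMoments(self.S[np.ix_(idx, idx)], self.n, list(names))


@dataclass
class FitIndices:
    chi_square: float
    df: int
    p_chi: float
    rmsea: float
    rmsea_ci_low: float
    rmsea_ci_high: float
    rmsea_pclose: float
    srmr: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class FitResult:
    """ML estimates with Wald statistics and goodness-of-fit indices."""

    model: SemModel
    theta_hat: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    standardized: dict[str, float]
    indices: FitIndices | None
    converged: bool
    n_iter: int
    warnings: list[str]
    fmin: float
    n: int

    @property
    def param_names(self) -> list[str]:
        return self.model.param_names

    def estimates(self) -> dict[str, float]:
        return dict(zip(self.param_names, self.theta_hat))

    def to_dict(self) -> dict:
        return {
            "parameters": [
                {
                    "name": nm,
                    "estimate": float(est),
                    "se": float(se) if np.isfinite(se) else None,
                    "z": float(z) if np.isfinite(z) else None,
                    "p": float(pv) if np.isfinite(pv) else None,
                    "standardized": self.standardized.get(nm),
                }
                for nm, est, se, z, pv in zip(
                    self.param_names, self.theta_hat, self.se, self.z, self.p
                )
            ],
            "indices": self.indices.to_dict() if self.indices is not None else None,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "warnings": self.warnings,
            "fmin": self.fmin,
            "n": self.n,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)

    def summary(self) -> str:
        lines = [
            f"{'parameter':<22}{'est':>10}{'se':>10}{'z':>9}{'p':>9}{'std':>9}",
        ]
        for nm, est, se, z, pv in zip(
            self.param_names, self.theta_hat, self.se, self.z, self.p
        ):
            std = self.standardized.get(nm)
            lines.append(
                f"{nm:<22}{est:>10.4f}{se:>10.4f}{z:>9.3f}{pv:>9.4f}"
                + (f"{std:>9.4f}" if std is not None else f"{'':>9}")
            )
        if self.indices is not None:
            ix = self.indices
            lines.append(
                f"chi2={ix.chi_square:.4f} df={ix.df} p={ix.p_chi:.4f} "
                f"RMSEA={ix.rmsea:.4f} [{ix.rmsea_ci_low:.4f}, {ix.rmsea_ci_high:.4f}] "
                f"pclose={ix.rmsea_pclose:.4f} SRMR={ix.srmr:.4f}"
            )
        lines.append(
            f"converged={self.converged} iterations={self.n_iter} "
            f"warnings={self.warnings or 'none'}"
        )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# moments
# ---------------------------------------------------------------------------


def sample_covariance(data: pd.DataFrame) -> SampleMoments:
    """Unbiased sample covariance (divisor N-1) of a sample x variable table.

    Rows containing missing values are dropped (listwise deletion).  A
    zero-variance column is an error: it carries no covariance information
    and makes S singular.
    """
    df = pd.DataFrame(data)
    df = df.dropna(axis=0)
    n = len(df)
    if n < 3:
        raise PathsemError(f"need at least 3 complete samples, have {n}")
    values = df.to_numpy(dtype=float)
    variances = values.var(axis=0, ddof=1)
    dead = [c for c, v in zip(df.columns, variances) if v <= 0.0]
    if dead:
        raise PathsemError(f"zero-variance column(s): {dead}")
    S = np.cov(values, rowvar=False, ddof=1)
    S = np.atleast_2d(S)
    return SampleMoments(S=S, n=n, names=[str(c) for c in df.columns])


# ---------------------------------------------------------------------------
# implied covariance and discrepancy
# ---------------------------------------------------------------------------


def _structural_inverse(model: SemModel, beta: np.ndarray) -> np.ndarray:
    m = beta.shape[0]
    imb = np.eye(m) - beta
    det = np.linalg.det(imb)
    if abs(det) < 1e-12:
        loops = _feedback_description(model, beta)
        raise SingularStructureError(
            f"I - B is singular; feedback with unit gain in: {loops}"
        )
    return np.linalg.inv(imb)


def _feedback_description(model: SemModel, beta: np.ndarray) -> str:
    import networkx as nx

    g = nx.DiGraph()
    m = beta.shape[0]
    g.add_nodes_from(range(m))
    for i in range(m):
        for j in range(m):
            if beta[i, j] != 0.0 or model.beta_free[i, j] >= 0:
                g.add_edge(j, i)
    cycles = []
    for comp in nx.strongly_connected_components(g):
        if len(comp) > 1 or any(g.has_edge(v, v) for v in comp):
            cycles.append("{" + ", ".join(model.latent_names[v] for v in sorted(comp)) + "}")
    return "; ".join(cycles) if cycles else "unknown loop"


def implied_covariance(model: SemModel, theta: np.ndarray) -> np.ndarray:
    """Sigma(theta) = Lambda (I-B)^-1 Psi (I-B)^-T Lambda^T + Theta_eps."""
    lam, beta, psi, th = model.matrices(theta)
    a = _structural_inverse(model, beta)
    lat_cov = a @ psi @ a.T
    sigma = lam @ lat_cov @ lam.T + np.diag(th)
    return (sigma + sigma.T) / 2.0


def _chol_logdet(mat: np.ndarray) -> tuple[np.ndarray, float]:
    chol = np.linalg.cholesky(mat)
    return chol, 2.0 * float(np.sum(np.log(np.diag(chol))))


def ml_discrepancy(S: np.ndarray, Sigma: np.ndarray) -> float:
    """F = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p (Wishart ML fit function)."""
    S = np.asarray(S, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    if S.shape != Sigma.shape or S.shape[0] != S.shape[1]:
        raise ValueError("S and Sigma must be square of equal order")
    p = S.shape[0]
    try:
        _, logdet_s = _chol_logdet(S)
        chol_sig, logdet_sig = _chol_logdet(Sigma)
    except np.linalg.LinAlgError as exc:
        raise NotPositiveDefiniteError("S and Sigma must be positive definite") from exc
    x = np.linalg.solve(Sigma, S)
    f = logdet_sig + float(np.trace(x)) - logdet_s - p
    return max(f, 0.0)


def _f_and_grad(
    theta: np.ndarray, model: SemModel, S: np.ndarray, logdet_s: float
) -> tuple[float, np.ndarray]:
    """ML discrepancy and its analytic gradient; large penalty off the
    admissible region (Sigma not PD or I-B singular)."""
    p = model.n_observed
    q = model.q
    lam, beta, psi, th = model.matrices(theta)
    m = beta.shape[0]
    imb = np.eye(m) - beta
    try:
        a = np.linalg.inv(imb)
    except np.linalg.LinAlgError:
        return _PENALTY, np.zeros(q)
    lat_cov = a @ psi @ a.T
    sigma = lam @ lat_cov @ lam.T + np.diag(th)
    sigma = (sigma + sigma.T) / 2.0
    try:
        chol, logdet_sig = _chol_logdet(sigma)
    except np.linalg.LinAlgError:
        return _PENALTY, np.zeros(q)
    sig_inv = np.linalg.inv(sigma)
    f = logdet_sig + float(np.sum(sig_inv * S)) - logdet_s - p
    # M = Sigma^-1 - Sigma^-1 S Sigma^-1 ; dF = tr(M dSigma)
    mmat = sig_inv - sig_inv @ S @ sig_inv
    grad = np.zeros(q)
    mlg = mmat @ lam @ lat_cov              # p x m  (loading slots)
    pmat = lam.T @ mmat @ lam               # m x m
    xb = lat_cov @ pmat @ a                 # m x m  (path slots, entry [b, a])
    qmat = a.T @ pmat @ a                   # m x m  (psi slots)
    for k, slot in enumerate(model.theta_map):
        if slot.matrix == "lambda":
            grad[k] = 2.0 * mlg[slot.row, slot.col]
        elif slot.matrix == "beta":
            grad[k] = 2.0 * xb[slot.col, slot.row]
        elif slot.matrix == "psi":
            i, j = slot.row, slot.col
            grad[k] = qmat[j, i] if i == j else 2.0 * qmat[j, i]
        else:
            grad[k] = mmat[slot.row, slot.row]
    return f, grad


def default_start(model: SemModel, moments: SampleMoments) -> np.ndarray:
    """Starting values: 0.5 for free loadings and paths, observed variances
    for variance slots (halved where variance is split between a latent and
    its measurement error)."""
    S = moments.reorder(model.observed_names).S
    var = np.diag(S)
    obs_of_latent: dict[int, float] = {}
    # anchor indicator's variance stands in for the latent's scale
    for j in range(model.n_latent):
        col = model.lam[:, j]
        rows = np.nonzero((model.lam_free[:, j] >= 0) | (col != 0.0))[0]
        obs_of_latent[j] = float(var[rows[0]]) if len(rows) else 1.0
    is_indicator = model.th_free >= 0
    theta0 = np.empty(model.q)
    for k, slot in enumerate(model.theta_map):
        if slot.matrix in ("lambda", "beta"):
            theta0[k] = 0.5
        elif slot.matrix == "psi":
            if slot.row == slot.col:
                v = obs_of_latent[slot.row]
                lat_name = model.latent_names[slot.row]
                split = lat_name not in model.observed_names  # real latent
                theta0[k] = 0.5 * v if split else v
            else:
                theta0[k] = 0.0
        else:
            theta0[k] = 0.5 * var[slot.row]
    return theta0


def fit_ml(
    model: SemModel,
    moments: SampleMoments,
    start: np.ndarray | None = None,
    max_iter: int = 1000,
    compute_se: bool = True,
    alpha: float = 0.05,
) -> FitResult:
    """Fit the model by minimizing the ML discrepancy.

    Raises :class:`IdentificationError` before optimization when the free
    parameter count exceeds the number of distinct covariance moments.
    Non-convergence is reported through ``converged=False`` plus a warning,
    never silently.
    """
    p = model.n_observed
    if p == 0:
        raise PathsemError("model has no observed variables")
    n_moments = p * (p + 1) // 2
    if model.q > n_moments:
        raise IdentificationError(
            f"model has {model.q} free parameters but only {n_moments} "
            "distinct covariance moments"
        )
    moments = moments.reorder(model.observed_names)
    S = moments.S
    try:
        _, logdet_s = _chol_logdet(S)
    except np.linalg.LinAlgError as exc:
        raise NotPositiveDefiniteError("sample covariance is not positive definite") from exc

    theta0 = default_start(model, moments) if start is None else np.asarray(start, float)
    # L-BFGS-B line searches can fail at the admissibility boundary (the
    # discrepancy jumps to a penalty where Sigma loses definiteness); restart
    # from the terminal point before giving up, and accept a stationary point
    # by its gradient norm.
    n_iter_total = 0
    res = None
    x0 = theta0
    for _ in range(3):
        res = optimize.minimize(
            _f_and_grad,
            x0,
            args=(model, S, logdet_s),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-9},
        )
        n_iter_total += int(res.nit)
        if res.success or res.nit == 0:
            break
        x0 = res.x
    theta_hat = res.x
    fmin = float(max(res.fun, 0.0))
    warnings: list[str] = []
    _, grad = _f_and_grad(theta_hat, model, S, logdet_s)
    stationary = float(np.max(np.abs(grad))) < 1e-5 * max(1.0, fmin)
    converged = (bool(res.success) or stationary) and fmin < _PENALTY / 2
    if not converged:
        warnings.append(f"nonconvergence: {res.message}")

    # Heywood check: negative variance estimates
    for k, slot in enumerate(model.theta_map):
        if slot.matrix == "theta" or (slot.matrix == "psi" and slot.row == slot.col):
            if theta_hat[k] < 0:
                warnings.append(f"heywood: {slot.name} = {theta_hat[k]:.4g}")

    n = moments.n
    t_stat = max((n - 1) * fmin, 0.0)
    df = model.degrees_of_freedom()
    sigma_hat = implied_covariance(model, theta_hat)
    indices = fit_indices(t_stat, df, n, S, sigma_hat) if df >= 1 else None

    if compute_se and model.q > 0:
        se, hess_warn = _wald_se(model, theta_hat, S, logdet_s, n)
        warnings.extend(hess_warn)
    else:
        se = np.full(model.q, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = theta_hat / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))

    std = standardize(model, theta_hat)
    return FitResult(
        model=model,
        theta_hat=theta_hat,
        se=se,
        z=z,
        p=pvals,
        standardized=std,
        indices=indices,
        converged=converged,
        n_iter=n_iter_total,
        warnings=warnings,
        fmin=fmin,
        n=n,
    )


def _wald_se(
    model: SemModel, theta_hat: np.ndarray, S: np.ndarray, logdet_s: float, n: int
) -> tuple[np.ndarray, list[str]]:
    """SEs from the inverse Hessian of ((N-1)/2) F, Hessian by central
    differences of the analytic gradient."""
    q = model.q
    hess = np.empty((q, q))
    for k in range(q):
        h = 1e-5 * max(1.0, abs(theta_hat[k]))
        up = theta_hat.copy()
        up[k] += h
        dn = theta_hat.copy()
        dn[k] -= h
        _, gu = _f_and_grad(up, model, S, logdet_s)
        _, gd = _f_and_grad(dn, model, S, logdet_s)
        hess[k] = (gu - gd) / (2.0 * h)
    hess = 0.5 * (n - 1) * (hess + hess.T) / 2.0
    warn: list[str] = []
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hess)
        warn.append("singular information matrix; SEs from pseudo-inverse")
    diag = np.diag(cov).copy()
    if np.any(diag <= 0):
        bad = [model.param_names[i] for i in np.nonzero(diag <= 0)[0]]
        warn.append(f"non-positive Hessian diagonal for {bad}; SEs set to inf")
        diag[diag <= 0] = np.inf
    return np.sqrt(diag), warn


# ---------------------------------------------------------------------------
# fit indices
# ---------------------------------------------------------------------------


def _ncp_bound(t: float, df: int, prob: float) -> float:
    """Noncentrality lambda with P(chi2_df(lambda) >= t) = prob, or 0 when
    no admissible lambda exists (sf is increasing in lambda)."""
    if stats.chi2.sf(t, df) >= prob:
        return 0.0
    lo, hi = 0.0, max(t, 1.0)
    while stats.ncx2.sf(t, df, hi) < prob:
        hi *= 2.0
        if hi > 1e8:
            return hi
    return float(optimize.brentq(lambda lam: stats.ncx2.sf(t, df, lam) - prob, lo, hi, xtol=1e-10))


def fit_indices(T: float, df: int, N: int, S: np.ndarray, Sigma_hat: np.ndarray) -> FitIndices:
    """RMSEA (with 90% noncentral-chi-square CI and close-fit p-value) and SRMR.

    RMSEA = sqrt(max(T - df, 0) / (df (N-1))).  The CI inverts the
    noncentral chi-square in its noncentrality; p-close tests H0:
    RMSEA <= 0.05.  SRMR is the root mean square of correlation-scale
    residuals over the lower triangle including the diagonal.
    """
    if df < 1:
        raise PathsemError("fit indices are undefined at df = 0 (saturated model)")
    if N < 2:
        raise PathsemError("need N >= 2")
    scale = df * (N - 1)
    rmsea = math.sqrt(max(T - df, 0.0) / scale)
    # 90% CI: noncentrality for which T sits at the 95th / 5th percentile of
    # the noncentral chi-square (sf = 0.05 gives the lower bound, 0.95 the
    # upper; 0 when no admissible noncentrality exists)
    lam_lo = _ncp_bound(T, df, 0.05)
    lam_hi = _ncp_bound(T, df, 0.95)
    ci_low = math.sqrt(lam_lo / scale)
    ci_high = math.sqrt(lam_hi / scale)
    lam0 = 0.05**2 * scale
    pclose = float(stats.ncx2.sf(T, df, lam0)) if lam0 > 0 else float(stats.chi2.sf(T, df))
    p_chi = float(stats.chi2.sf(T, df))

    S = np.asarray(S, float)
    Sigma_hat = np.asarray(Sigma_hat, float)
    p = S.shape[0]
    d = np.sqrt(np.diag(S))
    resid_sq = []
    for i in range(p):
        for j in range(i + 1):
            resid_sq.append(((S[i, j] - Sigma_hat[i, j]) / (d[i] * d[j])) ** 2)
    srmr = math.sqrt(float(np.mean(resid_sq)))
    return FitIndices(
        chi_square=float(T),
        df=int(df),
        p_chi=p_chi,
        rmsea=rmsea,
        rmsea_ci_low=ci_low,
        rmsea_ci_high=ci_high,
        rmsea_pclose=pclose,
        srmr=srmr,
    )


# ---------------------------------------------------------------------------
# standardization and Wald tests
# ---------------------------------------------------------------------------


def standardize(model: SemModel, theta: np.ndarray) -> dict[str, float]:
    """Standardized structural coefficients and loadings.

    A path j -> i is rescaled by sqrt(implied var of source / implied var
    of target); a loading by sqrt(latent var / indicator var).
    """
    lam, beta, psi, th = model.matrices(theta)
    a = _structural_inverse(model, beta)
    lat_cov = a @ psi @ a.T
    sigma = lam @ lat_cov @ lam.T + np.diag(th)
    lat_var = np.diag(lat_cov)
    obs_var = np.diag(sigma)
    if np.any(lat_var <= 0) or np.any(obs_var <= 0):
        raise PathsemError("zero or negative implied variance; cannot standardize")
    out: dict[str, float] = {}
    for k, slot in enumerate(model.theta_map):
        if slot.matrix == "beta":
            i, j = slot.row, slot.col
            out[slot.name] = float(theta[k] * math.sqrt(lat_var[j] / lat_var[i]))
        elif slot.matrix == "lambda":
            i, j = slot.row, slot.col
            out[slot.name] = float(theta[k] * math.sqrt(lat_var[j] / obs_var[i]))
    return out


def wald_tests(fit: FitResult, alpha: float = 0.05) -> pd.DataFrame:
    """Per-parameter z = theta_hat / se with two-sided normal p-values."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if np.any(fit.se == 0):
        bad = [n for n, s in zip(fit.param_names, fit.se) if s == 0]
        raise PathsemError(f"zero standard error for {bad}")
    with np.errstate(invalid="ignore"):
        z = fit.theta_hat / fit.se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "parameter": fit.param_names,
            "estimate": fit.theta_hat,
            "se": fit.se,
            "z": z,
            "p": p,
            "significant": p < alpha,
        }
    ).set_index("parameter")
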