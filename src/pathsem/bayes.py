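"""Bayesian SEM estimation via data-augmentation Gibbs sampling, with
Gelman-Rubin convergence diagnostics.

The sampler alternates three closed-form conditional blocks per iteration:

1. latent scores given parameters — a multivariate-normal conditional of
   the stochastic latents given the observed vector (pass-through latents
   are identical to their observed variable and never resampled);
2. loadings and structural paths given latents and variances — per-equation
   conjugate normal updates under N(0, prior_coef_sd^2) priors;
3. residual and measurement variances given everything else — conjugate
   inverse-gamma updates under IG(prior_var_shape, prior_var_rate) priors.

This requires a recursive structural matrix (B strictly lower-triangular in
some latent ordering) and diagonal Psi; models violating either are
rejected with guidance rather than silently mis-sampled.

Convergence is summarized by the potential scale reduction factor per
parameter, psrf = sqrt(V_hat / W) with V_hat = ((n-1)/n) W + B/n, and by
the multivariate Brooks-Gelman statistic
sqrt((n-1)/n + ((m+1)/m) lambda_1), lambda_1 the largest eigenvalue of
W_pooled^-1 (B_matrix / n).  The basic (no degrees-of-freedom correction)
form is used.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import PathsemError
from .fit import SampleMoments, fit_ml, sample_covariance, standardize
from .model import SemModel

__all__ = [
    "BayesConfig",
    "ChainSet",
    "ConvergenceReport",
    "gibbs_sample",
    "gelman_rubin",
    "posterior_summary",
]


@dataclass
class BayesConfig:
    n_chains: int = 4
    n_iter: int = 20000
    burn_in: int | None = None  # defaults to n_iter // 2
    seed: int = 0
    prior_coef_sd: float = 10.0
    prior_var_shape: float = 0.001
    prior_var_rate: float = 0.001
    overdispersed_starts: bool = True

    def __post_init__(self):
        if self.n_chains < 2:
            raise PathsemError("Gelman-Rubin needs at least 2 chains")
        if self.burn_in is None:
            self.burn_in = self.n_iter // 2
        if not 0 <= self.burn_in < self.n_iter:
            raise PathsemError("burn_in must be < n_iter")
        if self.prior_coef_sd <= 0 or self.prior_var_shape <= 0 or self.prior_var_rate <= 0:
            raise PathsemError("prior hyperparameters must be positive")


@dataclass
class ChainSet:
    """Posterior draws: (n_chains, n_iter, n_free_parameters)."""

    draws: np.ndarray
    param_names: list[str]
    config: BayesConfig
    model: SemModel | None = None

    def __post_init__(self):
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 3:
            raise PathsemError("draws must be (chains, iterations, parameters)")
        if self.draws.shape[2] != len(self.param_names):
            raise PathsemError("parameter names do not match draw array")

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_iter(self) -> int:
        return self.draws.shape[1]

    def post_burn_in(self, burn_in: int | None = None) -> np.ndarray:
        b = self.config.burn_in if burn_in is None else burn_in
        if b >= self.n_iter:
            raise PathsemError(f"burn_in {b} >= chain length {self.n_iter}")
        return self.draws[:, b:, :]

    def write_csv(self, directory, prefix: str = "chain") -> list[str]:
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for c in range(self.n_chains):
            df = pd.DataFrame(self.draws[c], columns=self.param_names)
            df.insert(0, "iteration", np.arange(1, self.n_iter + 1))
            path = directory / f"{prefix}{c + 1}.csv"
            df.to_csv(path, index=False)
            paths.append(str(path))
        return paths


@dataclass
class ConvergenceReport:
    psrf: dict[str, float]
    mpsrf: float
    n_used: int

    def to_dict(self) -> dict:
        return {"psrf": self.psrf, "mpsrf": self.mpsrf, "n_used": self.n_used}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


# ---------------------------------------------------------------------------
# model preprocessing
# ---------------------------------------------------------------------------


def _check_recursive(model: SemModel) -> None:
    m = model.n_latent
    g = nx.DiGraph()
    g.add_nodes_from(range(m))
    for i in range(m):
        for j in range(m):
            if model.beta_free[i, j] >= 0 or model.beta[i, j] != 0.0:
                g.add_edge(j, i)
    if not nx.is_directed_acyclic_graph(g):
        cyc = nx.find_cycle(g)
        names = " -> ".join(model.latent_names[u] for u, _ in cyc)
        raise PathsemError(
            f"Gibbs sampling requires a recursive structural model; remove the "
            f"feedback loop {names} (e.g. prune self-regulation paths) and retry"
        )


def _check_diagonal_psi(model: SemModel) -> None:
    m = model.n_latent
    for i in range(m):
        for j in range(i):
            if model.psi_free[i, j] >= 0 or model.psi[i, j] != 0.0:
                raise PathsemError(
                    "Gibbs sampling supports diagonal Psi only; free residual "
                    f"covariance {model.latent_names[i]}~~{model.latent_names[j]} "
                    "is not sampled — collapse the pair into a latent instead"
                )


@dataclass
class _Plan:
    """Precomputed index lists for one Gibbs sweep."""

    sto: np.ndarray  # indices of stochastic latents
    meas: list[tuple[int, np.ndarray, np.ndarray, int]]  # (obs row, lam cols, slots, th slot)
    struct: list[tuple[int, np.ndarray, np.ndarray, int]]  # (lat row, beta cols, slots, psi slot)


def _make_plan(model: SemModel) -> _Plan:
    observed = set(model.observed_names)
    sto = np.array(
        [j for j, name in enumerate(model.latent_names) if name not in observed],
        dtype=int,
    )
    meas = []
    for i in range(model.n_observed):
        cols = np.nonzero(model.lam_free[i] >= 0)[0]
        th_slot = int(model.th_free[i])
        if len(cols) or th_slot >= 0:
            slots = model.lam_free[i, cols]
            meas.append((i, cols, slots, th_slot))
    struct = []
    for i in range(model.n_latent):
        cols = np.nonzero(model.beta_free[i] >= 0)[0]
        psi_slot = int(model.psi_free[i, i])
        if len(cols) or psi_slot >= 0:
            slots = model.beta_free[i, cols]
            struct.append((i, cols, slots, psi_slot))
    return _Plan(sto=sto, meas=meas, struct=struct)


def _start_values(model: SemModel, moments: SampleMoments, config: BayesConfig) -> list[np.ndarray]:
    """Chain starting points; overdispersed around the ML solution when
    requested, otherwise the default deterministic start."""
    from .fit import default_start

    base = default_start(model, moments)
    if not config.overdispersed_starts:
        return [base.copy() for _ in range(config.n_chains)]
    ml = fit_ml(model, moments)
    theta, se = ml.theta_hat, ml.se
    se = np.where(np.isfinite(se), se, np.abs(theta) * 0.5 + 0.5)
    starts = []
    mults = [0.0, 2.0, -2.0, 1.0, -1.0, 3.0, -3.0, 0.5]
    is_var = np.array(
        [s.matrix == "theta" or (s.matrix == "psi" and s.row == s.col) for s in model.theta_map]
    )
    for c in range(config.n_chains):
        mult = mults[c % len(mults)]
        t = theta + mult * se
        # keep variance starts strictly positive
        floor = np.maximum(0.05 * np.abs(theta), 1e-3)
        t[is_var] = np.maximum(np.abs(t[is_var]), floor[is_var])
        starts.append(t)
    return starts


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------


def gibbs_sample(model: SemModel, data: pd.DataFrame, config: BayesConfig) -> ChainSet:
    """Run the data-augmentation Gibbs sampler; bit-identical for a fixed
    seed and config."""
    _check_recursive(model)
    _check_diagonal_psi(model)
    frame = pd.DataFrame(data)
    missing = [v for v in model.observed_names if v not in frame.columns]
    if missing:
        raise PathsemError(f"data lacks model variables: {missing}")
    frame = frame[model.observed_names].dropna(axis=0)
    y = frame.to_numpy(dtype=float)
    # no mean structure: profile the means out by centering, matching the
    # covariance-only ML fit
    y = y - y.mean(axis=0)
    n = y.shape[0]
    if n < 3:
        raise PathsemError("need at least 3 complete samples")
    q = model.q
    draws = np.empty((config.n_chains, config.n_iter, q))
    if q == 0:
        draws = np.zeros((config.n_chains, config.n_iter, 0))
        return ChainSet(draws=draws, param_names=[], config=config, model=model)

    moments = sample_covariance(frame)
    starts = _start_values(model, moments, config)
    plan = _make_plan(model)
    obs_index = {v: i for i, v in enumerate(model.observed_names)}
    det = [j for j in range(model.n_latent) if j not in set(plan.sto.tolist())]

    c0 = config.prior_coef_sd**2
    a0 = config.prior_var_shape
    b0 = config.prior_var_rate

    for chain in range(config.n_chains):
        rng = np.random.default_rng([int(config.seed) & 0x7FFFFFFF, chain])
        theta = starts[chain].copy()
        eta = np.zeros((n, model.n_latent))
        for j in det:
            eta[:, j] = y[:, obs_index[model.latent_names[j]]]
        if len(plan.sto):
            eta[:, plan.sto] = 0.0
        eye_m = np.eye(model.n_latent)
        for it in range(config.n_iter):
            lam, beta, psi, th = model.matrices(theta)
            # (a) latent scores
            if len(plan.sto):
                a = np.linalg.inv(eye_m - beta)
                cmat = a @ psi @ a.T
                sigma = lam @ cmat @ lam.T + np.diag(th)
                kt = cmat[plan.sto] @ lam.T  # k x p
                solved = np.linalg.solve(sigma, kt.T)  # p x k
                mean = y @ solved
                cov = cmat[np.ix_(plan.sto, plan.sto)] - kt @ solved
                cov = (cov + cov.T) / 2.0
                try:
                    chol = np.linalg.cholesky(cov)
                except np.linalg.LinAlgError:
                    chol = np.linalg.cholesky(cov + 1e-10 * np.eye(len(plan.sto)))
                eta[:, plan.sto] = mean + rng.standard_normal((n, len(plan.sto))) @ chol.T
            # (b) + (c) measurement equations
            for i, cols, slots, th_slot in plan.meas:
                fixed_cols = np.nonzero((model.lam_free[i] < 0) & (model.lam[i] != 0.0))[0]
                offset = eta[:, fixed_cols] @ model.lam[i, fixed_cols] if len(fixed_cols) else 0.0
                resid_var = theta[th_slot] if th_slot >= 0 else model.th[i]
                r = y[:, i] - offset
                if len(cols):
                    x = eta[:, cols]
                    coefs = _draw_coefs(rng, x, r, resid_var, c0)
                    theta[slots] = coefs
                    r = r - x @ coefs
                if th_slot >= 0:
                    theta[th_slot] = _draw_variance(rng, r, a0, b0)
            # structural equations
            for i, cols, slots, psi_slot in plan.struct:
                fixed_cols = np.nonzero((model.beta_free[i] < 0) & (model.beta[i] != 0.0))[0]
                offset = eta[:, fixed_cols] @ model.beta[i, fixed_cols] if len(fixed_cols) else 0.0
                resid_var = theta[psi_slot] if psi_slot >= 0 else model.psi[i, i]
                r = eta[:, i] - offset
                if len(cols):
                    x = eta[:, cols]
                    coefs = _draw_coefs(rng, x, r, resid_var, c0)
                    theta[slots] = coefs
                    r = r - x @ coefs
                if psi_slot >= 0:
                    theta[psi_slot] = _draw_variance(rng, r, a0, b0)
            draws[chain, it] = theta
    return ChainSet(draws=draws, param_names=model.param_names, config=config, model=model)


def _draw_coefs(rng, x: np.ndarray, r: np.ndarray, resid_var: float, c0: float) -> np.ndarray:
    d = x.shape[1]
    prec = x.T @ x / resid_var + np.eye(d) / c0
    cov = np.linalg.inv(prec)
    mean = cov @ (x.T @ r) / resid_var
    chol = np.linalg.cholesky((cov + cov.T) / 2.0)
    return mean + chol @ rng.standard_normal(d)


def _draw_variance(rng, r: np.ndarray, a0: float, b0: float) -> float:
    shape = a0 + r.shape[0] / 2.0
    rate = b0 + 0.5 * float(r @ r)
    return rate / rng.gamma(shape)


# ---------------------------------------------------------------------------
# diagnostics and summaries
# ---------------------------------------------------------------------------


def gelman_rubin(chains: ChainSet, burn_in: int | None = None) -> ConvergenceReport:
    """Univariate psrf per parameter and multivariate Brooks-Gelman psrf."""
    if chains.n_chains < 2:
        raise PathsemError("need at least 2 chains")
    x = chains.post_burn_in(burn_in)
    m, n, q = x.shape
    if n < 4:
        raise PathsemError("need at least 4 post-burn-in draws per chain")
    if q == 0:
        return ConvergenceReport(psrf={}, mpsrf=float("nan"), n_used=n)
    chain_means = x.mean(axis=1)  # m x q
    within = x.var(axis=1, ddof=1)  # m x q
    w = within.mean(axis=0)
    dead = np.nonzero(w <= 0)[0]
    if len(dead):
        names = [chains.param_names[i] for i in dead]
        raise PathsemError(f"zero within-chain variance for {names}")
    b = n * chain_means.var(axis=0, ddof=1)
    v_hat = (n - 1) / n * w + b / n
    psrf = np.sqrt(v_hat / w)

    # multivariate: largest eigenvalue of W^-1 (B/n)
    centered = x - chain_means[:, None, :]
    w_mat = np.einsum("cij,cik->jk", centered, centered) / (m * (n - 1))
    dm = chain_means - chain_means.mean(axis=0)
    b_mat_over_n = dm.T @ dm / (m - 1)
    try:
        lam1 = float(np.max(np.real(np.linalg.eigvals(np.linalg.solve(w_mat, b_mat_over_n)))))
    except np.linalg.LinAlgError:
        lam1 = float(
            np.max(np.real(np.linalg.eigvals(np.linalg.pinv(w_mat) @ b_mat_over_n)))
        )
    mpsrf = float(np.sqrt((n - 1) / n + (m + 1) / m * lam1))
    return ConvergenceReport(
        psrf={name: float(v) for name, v in zip(chains.param_names, psrf)},
        mpsrf=mpsrf,
        n_used=n,
    )


def posterior_summary(
    chains: ChainSet,
    burn_in: int | None = None,
    standardized: bool = False,
) -> pd.DataFrame:
    """Pooled post-burn-in posterior mean, sd and 95% equal-tail credible
    interval per free parameter; optionally also for the standardized
    coefficients, computed per draw then summarized."""
    x = chains.post_burn_in(burn_in)
    pooled = x.reshape(-1, x.shape[2])
    rows = {}
    for j, name in enumerate(chains.param_names):
        col = pooled[:, j]
        rows[name] = _summary_row(col)
    if standardized:
        if chains.model is None:
            raise PathsemError("standardized summaries need the model attached")
        std_names = None
        std_draws = []
        step = max(1, pooled.shape[0] // 4000)  # thin for the per-draw transform
        for draw in pooled[::step]:
            std = standardize(chains.model, draw)
            if std_names is None:
                std_names = list(std)
            std_draws.append([std[k] for k in std_names])
        arr = np.asarray(std_draws)
        for j, name in enumerate(std_names or []):
            rows[f"std:{name}"] = _summary_row(arr[:, j])
    return pd.DataFrame.from_dict(rows, orient="index")


def _summary_row(col: np.ndarray) -> dict:
    return {
        "mean": float(col.mean()),
        "sd": float(col.std(ddof=1)) if len(col) > 1 else 0.0,
        "ci_2.5%": float(np.percentile(col, 2.5)),
        "ci_97.5%": float(np.percentile(col, 97.5)),
    }
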