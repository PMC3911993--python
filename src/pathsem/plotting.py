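"""Diagnostic plots: MCMC traces and running psrf evolution."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .bayes import ChainSet, ConvergenceReport, gelman_rubin

__all__ = ["psrf_evolution", "plot_psrf", "plot_traces"]


def psrf_evolution(chains: ChainSet, n_points: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Running psrf per parameter over growing chain prefixes (the first
    half of each prefix discarded as burn-in).  Returns (iteration cut
    points, points x parameters psrf array)."""
    n = chains.n_iter
    cuts = np.unique(np.linspace(max(8, n // n_points), n, n_points).astype(int))
    out = np.full((len(cuts), len(chains.param_names)), np.nan)
    for k, cut in enumerate(cuts):
        sub = ChainSet(
            draws=chains.draws[:, :cut, :],
            param_names=chains.param_names,
            config=chains.config,
            model=chains.model,
        )
        try:
            rep = gelman_rubin(sub, burn_in=cut // 2)
        except Exception:
            continue
        out[k] = [rep.psrf[p] for p in chains.param_names]
    return cuts, out


def plot_psrf(chains: ChainSet, path: str | Path, n_points: int = 20) -> None:
    """psrf vs iteration, one line per parameter, with the 1.1 guide line."""
    cuts, curves = psrf_evolution(chains, n_points)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for j, name in enumerate(chains.param_names):
        ax.plot(cuts, curves[:, j], lw=0.8, label=name)
    ax.axhline(1.1, color="grey", ls="--", lw=0.8)
    ax.set_xlabel("iteration")
    ax.set_ylabel("psrf")
    ax.set_title("Gelman-Rubin shrink factor evolution")
    if len(chains.param_names) <= 12:
        ax.legend(fontsize=6, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_traces(chains: ChainSet, path: str | Path, max_params: int = 12) -> None:
    names = chains.param_names[:max_params]
    if not names:
        return
    fig, axes = plt.subplots(len(names), 1, figsize=(7, 1.3 * len(names)), sharex=True)
    axes = np.atleast_1d(axes)
    for ax, name in zip(axes, names):
        j = chains.param_names.index(name)
        for c in range(chains.n_chains):
            ax.plot(chains.draws[c, :, j], lw=0.3)
        ax.set_ylabel(name, fontsize=6)
    axes[-1].set_xlabel("iteration")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
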