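"""Iterative model refinement: collinearity collapse, then backward pruning.

The refinement loop mirrors the two-stage workflow the package implements:

1. Groups of observed variables with near-identical expression
   (|Pearson r| above a threshold, connected-component closure) are
   collapsed into latent variables, once, before any pruning.
2. The model is refit and the single structural path with the largest
   non-significant Wald p-value is removed; this repeats until every
   remaining path is significant or a round cap is hit.

Self-feedback paths are removed deterministically before the first fit: a
self-loop on a variable measured by a single error-free indicator only
enters the implied covariance through the ratios coef/(1 - loop) and
var/(1 - loop)^2, so it is never identified in this model class and would
otherwise stall the Wald-based loop on a singular information matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import PathsemError
from .fit import FitIndices, FitResult, SampleMoments, fit_ml, sample_covariance, wald_tests
from .model import SemModel, build_sem_model

__all__ = [
    "SearchConfig",
    "SearchStep",
    "SearchResult",
    "detect_collinear_groups",
    "collapse_to_latent",
    "prune_step",
    "search",
]


@dataclass
class SearchConfig:
    alpha: float = 0.05
    collinearity_threshold: float = 0.9
    rmsea_max: float = 0.1
    srmr_max: float = 0.1
    max_rounds: int = 100
    refit_each_removal: bool = True  # False: drop all non-significant paths at once

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise PathsemError("alpha must be in (0, 1)")
        if not 0 < self.collinearity_threshold < 1:
            raise PathsemError("collinearity_threshold must be in (0, 1)")


@dataclass
class SearchStep:
    action: str  # "collapse" | "prune" | "drop-self-loop" | "stop"
    detail: str
    indices: FitIndices | None = None

    def to_dict(self) -> dict:
        return {
            "action": self.action,
            "detail": self.detail,
            "indices": self.indices.to_dict() if self.indices else None,
        }


@dataclass
class SearchResult:
    model: SemModel
    fit: FitResult
    trace: list[SearchStep] = field(default_factory=list)

    def trace_json(self) -> str:
        return json.dumps([s.to_dict() for s in self.trace], indent=2)

    def retained_paths(self) -> set[tuple[str, str]]:
        return {
            (src, tgt)
            for tgt, preds in self.model.structure.regressions.items()
            for src in preds
        }

    def latent_groups(self) -> list[frozenset[str]]:
        return [frozenset(v) for v in self.model.structure.measurement.values()]


def detect_collinear_groups(data: pd.DataFrame, threshold: float = 0.9) -> list[list[str]]:
    """Connected components of the |Pearson r| > threshold graph; singletons
    omitted.  Groups and members are returned in column order."""
    df = pd.DataFrame(data)
    if df.shape[1] < 2:
        raise PathsemError("need at least 2 variables")
    corr = df.corr().to_numpy()
    cols = list(df.columns)
    g = nx.Graph()
    g.add_nodes_from(cols)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if abs(corr[i, j]) > threshold:
                g.add_edge(cols[i], cols[j])
    order = {c: i for i, c in enumerate(cols)}
    groups = [
        sorted(comp, key=order.get)
        for comp in nx.connected_components(g)
        if len(comp) > 1
    ]
    groups.sort(key=lambda grp: order[grp[0]])
    return groups


def collapse_to_latent(model: SemModel, group: list[str], name: str) -> SemModel:
    """Replace a group of observed variables by a latent they all indicate.

    The first group member anchors the latent scale (loading fixed to 1),
    the rest load freely; each member gains a free measurement error.  All
    structural paths touching a member re-attach to the latent, duplicates
    merged.
    """
    if len(group) < 2:
        raise PathsemError("a latent needs at least 2 indicators")
    structure = model.structure.copy()
    for v in group:
        if v not in structure.observed:
            raise PathsemError(f"{v!r} is not an observed variable of the model")
        if v in structure.indicators:
            raise PathsemError(f"{v!r} already indicates a latent")
    if name in structure.observed or name in structure.measurement:
        raise PathsemError(f"latent name {name!r} already in use")
    members = set(group)
    structure.measurement[name] = list(group)
    new_reg: dict[str, list[str]] = {}
    for tgt, preds in structure.regressions.items():
        tgt2 = name if tgt in members else tgt
        merged = new_reg.setdefault(tgt2, [])
        for src in preds:
            src2 = name if src in members else src
            if src2 not in merged:
                merged.append(src2)
    structure.regressions = new_reg
    structure.covariances = [
        (name if a in members else a, name if b in members else b)
        for a, b in structure.covariances
        if not ({a, b} <= members)
    ]
    structure.covariances = [(a, b) for a, b in structure.covariances if a != b]
    return build_sem_model(structure)


def _structural_pvalues(fit: FitResult, alpha: float) -> pd.DataFrame:
    tab = wald_tests(fit, alpha)
    mask = [s.matrix == "beta" for s in fit.model.theta_map]
    return tab.loc[np.array(mask)]


def prune_step(model: SemModel, fit: FitResult, alpha: float = 0.05) -> tuple[SemModel, str] | None:
    """Remove the single structural path with the largest Wald p >= alpha;
    return None (stop signal) when every path is significant."""
    paths = _structural_pvalues(fit, alpha)
    weak = paths[~paths["significant"]]
    if weak.empty:
        return None
    worst = weak["p"].idxmax()
    tgt, src = worst.split("~", 1)
    structure = model.structure.copy()
    structure.regressions[tgt].remove(src)
    if not structure.regressions[tgt]:
        del structure.regressions[tgt]
    return build_sem_model(structure), worst


def _drop_self_loops(model: SemModel) -> tuple[SemModel, list[str]]:
    structure = model.structure.copy()
    dropped = []
    for tgt in list(structure.regressions):
        if tgt in structure.regressions[tgt]:
            structure.regressions[tgt].remove(tgt)
            dropped.append(f"{tgt}~{tgt}")
            if not structure.regressions[tgt]:
                del structure.regressions[tgt]
    if dropped:
        return build_sem_model(structure), dropped
    return model, dropped


def search(
    skeleton: SemModel,
    data: pd.DataFrame,
    config: SearchConfig | None = None,
) -> SearchResult:
    """Run the full refinement loop from a prior skeleton.

    Deterministic given the data: collinearity detection and collapse run
    once, then fit/prune alternate until the stop signal or ``max_rounds``.
    """
    config = config or SearchConfig()
    cols = [c for c in data.columns if c in skeleton.observed_names]
    missing = [v for v in skeleton.observed_names if v not in cols]
    if missing:
        raise PathsemError(f"data lacks model variables: {missing}")
    frame = pd.DataFrame(data)[skeleton.observed_names]
    moments = sample_covariance(frame)

    trace: list[SearchStep] = []
    model, dropped = _drop_self_loops(skeleton)
    for name in dropped:
        trace.append(SearchStep("drop-self-loop", name))

    groups = detect_collinear_groups(frame, config.collinearity_threshold)
    for k, group in enumerate(groups, start=1):
        name = f"lv_{group[0]}"
        model = collapse_to_latent(model, group, name)
        trace.append(SearchStep("collapse", f"{name} := {' + '.join(group)}"))

    fit = None
    for _ in range(config.max_rounds):
        fit = fit_ml(model, moments, alpha=config.alpha)
        if not fit.converged:
            trace.append(SearchStep("stop", "optimizer failed to converge", fit.indices))
            break
        if config.refit_each_removal:
            step = prune_step(model, fit, config.alpha)
            if step is None:
                trace.append(SearchStep("stop", "all paths significant", fit.indices))
                break
            model, removed = step
            trace.append(SearchStep("prune", removed, fit.indices))
        else:
            paths = _structural_pvalues(fit, config.alpha)
            weak = paths[~paths["significant"]]
            if weak.empty:
                trace.append(SearchStep("stop", "all paths significant", fit.indices))
                break
            structure = model.structure.copy()
            for name in weak.index:
                tgt, src = name.split("~", 1)
                structure.regressions[tgt].remove(src)
                if not structure.regressions[tgt]:
                    del structure.regressions[tgt]
                trace.append(SearchStep("prune", name, fit.indices))
            model = build_sem_model(structure)
    else:
        trace.append(SearchStep("stop", "max_rounds reached", fit.indices if fit else None))

    if fit is None or fit.model is not model:
        fit = fit_ml(model, moments, alpha=config.alpha)
    return SearchResult(model=model, fit=fit, trace=trace)
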