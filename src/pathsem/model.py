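"""Structural equation model representation.

The model is held in the all-y LISREL form

    y = Lambda * eta + epsilon        (measurement)
    eta = B * eta + zeta              (structural)

with ``epsilon ~ N(0, Theta)`` (diagonal) and ``zeta ~ N(0, Psi)``.  Every
observed variable that is not an indicator of a declared latent receives a
pass-through latent of the same name (loading fixed to 1, measurement error
fixed to 0), so purely observed path models and latent-variable models share
one parameterization and one estimation code path.

Two layers are exposed:

* :class:`ModelStructure` — the symbolic description (which variables exist,
  which latents measure which indicators, which paths are free).  Model
  search manipulates this layer.
* :class:`SemModel` — compiled pattern matrices plus a ``theta_map`` listing
  the free-parameter slots in a fixed order.  Estimation consumes this layer.

Parameter names follow the common SEM text convention: ``"y~x"`` for the
structural path x -> y, ``"f=~ind"`` for a loading, ``"a~~b"`` for a
(residual) variance or covariance.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .errors import ModelSpecError

__all__ = [
    "ParamSlot",
    "ModelStructure",
    "SemModel",
    "build_sem_model",
    "parse_model",
    "model_to_text",
]


@dataclass(frozen=True)
class ParamSlot:
    """One free parameter: its name and position in a pattern matrix."""

    name: str
    matrix: str  # "lambda" | "beta" | "psi" | "theta"
    row: int
    col: int


@dataclass
class ModelStructure:
    """Symbolic SEM description.

    Parameters
    ----------
    observed
        Ordered observed-variable names (the columns of the data table the
        model refers to).
    measurement
        Mapping latent name -> ordered indicator list.  The first indicator
        anchors the latent scale (loading fixed to 1).
    regressions
        Mapping target -> ordered predictor list.  Targets and predictors are
        latent names or non-indicator observed names.
    covariances
        Extra free (co)variances between latent-level variables, e.g. a
        saturated block of exogenous predictors.
    fixed
        Overrides mapping parameter name -> fixed value.  A slot named here
        is removed from the free-parameter vector.
    """

    observed: list[str]
    measurement: dict[str, list[str]] = field(default_factory=dict)
    regressions: dict[str, list[str]] = field(default_factory=dict)
    covariances: list[tuple[str, str]] = field(default_factory=list)
    fixed: dict[str, float] = field(default_factory=dict)

    # -- helpers ----------------------------------------------------------

    def copy(self) -> "ModelStructure":
        return ModelStructure(
            observed=list(self.observed),
            measurement={k: list(v) for k, v in self.measurement.items()},
            regressions={k: list(v) for k, v in self.regressions.items()},
            covariances=list(self.covariances),
            fixed=dict(self.fixed),
        )

    @property
    def indicators(self) -> set[str]:
        out: set[str] = set()
        for inds in self.measurement.values():
            out.update(inds)
        return out

    def latent_order(self) -> list[str]:
        """Declared latents first, then pass-through latents in observed order."""
        ind = self.indicators
        return list(self.measurement) + [o for o in self.observed if o not in ind]

    def validate(self) -> None:
        if len(set(self.observed)) != len(self.observed):
            raise ModelSpecError("duplicate observed variable names")
        ind_seen: set[str] = set()
        for lat, inds in self.measurement.items():
            if lat in self.observed:
                raise ModelSpecError(f"latent name {lat!r} clashes with an observed variable")
            if not inds:
                raise ModelSpecError(f"latent {lat!r} has no indicators")
            for i in inds:
                if i not in self.observed:
                    raise ModelSpecError(f"indicator {i!r} of {lat!r} is not an observed variable")
                if i in ind_seen:
                    raise ModelSpecError(f"indicator {i!r} assigned to two latents")
                ind_seen.add(i)
        valid = set(self.latent_order())
        for tgt, preds in self.regressions.items():
            for v in [tgt, *preds]:
                if v in ind_seen:
                    raise ModelSpecError(
                        f"{v!r} is an indicator; regress on its latent instead"
                    )
                if v not in valid:
                    raise ModelSpecError(f"unknown variable {v!r} in regression")
            if len(set(preds)) != len(preds):
                raise ModelSpecError(f"duplicate predictor in equation for {tgt!r}")
        for a, b in self.covariances:
            for v in (a, b):
                if v not in valid:
                    raise ModelSpecError(f"unknown variable {v!r} in covariance")
            if a == b:
                raise ModelSpecError("use variances, not a self-covariance")


@dataclass
class SemModel:
    """Compiled pattern matrices with a free-parameter map.

    ``*_free`` arrays hold the index into theta for free slots and -1 for
    fixed entries; the companion value array holds the fixed values (and is
    overwritten at free slots when :meth:`matrices` fills in a theta vector).
    """

    observed_names: list[str]
    latent_names: list[str]
    lam: np.ndarray
    lam_free: np.ndarray
    beta: np.ndarray
    beta_free: np.ndarray
    psi: np.ndarray
    psi_free: np.ndarray
    th: np.ndarray  # diagonal of Theta_epsilon, length p
    th_free: np.ndarray
    theta_map: list[ParamSlot]
    structure: ModelStructure

    @property
    def n_observed(self) -> int:
        return len(self.observed_names)

    @property
    def n_latent(self) -> int:
        return len(self.latent_names)

    @property
    def q(self) -> int:
        """Number of free parameters."""
        return len(self.theta_map)

    @property
    def param_names(self) -> list[str]:
        return [s.name for s in self.theta_map]

    def degrees_of_freedom(self) -> int:
        p = self.n_observed
        return p * (p + 1) // 2 - self.q

    def matrices(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Return (Lambda, B, Psi, theta_eps_diag) at the parameter vector."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.q,):
            raise ValueError(f"theta must have length {self.q}, got {theta.shape}")
        lam = self.lam.copy()
        beta = self.beta.copy()
        psi = self.psi.copy()
        th = self.th.copy()
        for k, slot in enumerate(self.theta_map):
            if slot.matrix == "lambda":
                lam[slot.row, slot.col] = theta[k]
            elif slot.matrix == "beta":
                beta[slot.row, slot.col] = theta[k]
            elif slot.matrix == "psi":
                psi[slot.row, slot.col] = theta[k]
                psi[slot.col, slot.row] = theta[k]
            else:
                th[slot.row] = theta[k]
        return lam, beta, psi, th

    def theta_from_dict(self, values: dict[str, float]) -> np.ndarray:
        """Build a full theta vector from a name -> value mapping."""
        missing = [s.name for s in self.theta_map if s.name not in values]
        if missing:
            raise ModelSpecError(f"no value supplied for parameters: {missing}")
        extra = set(values) - {s.name for s in self.theta_map}
        if extra:
            raise ModelSpecError(f"unknown parameter names: {sorted(extra)}")
        return np.array([values[s.name] for s in self.theta_map], dtype=float)

    def slot_index(self, name: str) -> int:
        for k, s in enumerate(self.theta_map):
            if s.name == name:
                return k
        raise KeyError(name)


def build_sem_model(structure: ModelStructure) -> SemModel:
    """Compile a :class:`ModelStructure` into pattern matrices."""
    structure.validate()
    obs = structure.observed
    lats = structure.latent_order()
    p, m = len(obs), len(lats)
    oi = {v: i for i, v in enumerate(obs)}
    li = {v: i for i, v in enumerate(lats)}

    lam = np.zeros((p, m))
    lam_free = np.full((p, m), -1, dtype=int)
    beta = np.zeros((m, m))
    beta_free = np.full((m, m), -1, dtype=int)
    psi = np.zeros((m, m))
    psi_free = np.full((m, m), -1, dtype=int)
    th = np.zeros(p)
    th_free = np.full(p, -1, dtype=int)

    theta_map: list[ParamSlot] = []
    fixed = dict(structure.fixed)

    def add(name: str, matrix: str, row: int, col: int, default_fixed: float | None = None):
        """Register a slot: fixed if overridden (or default), else free."""
        if name in fixed:
            val = fixed.pop(name)
            _set(matrix, row, col, val)
        elif default_fixed is not None:
            _set(matrix, row, col, default_fixed)
        else:
            k = len(theta_map)
            theta_map.append(ParamSlot(name, matrix, row, col))
            if matrix == "lambda":
                lam_free[row, col] = k
            elif matrix == "beta":
                beta_free[row, col] = k
            elif matrix == "psi":
                psi_free[row, col] = k
                psi_free[col, row] = k
            else:
                th_free[row] = k

    def _set(matrix: str, row: int, col: int, val: float):
        if matrix == "lambda":
            lam[row, col] = val
        elif matrix == "beta":
            beta[row, col] = val
        elif matrix == "psi":
            psi[row, col] = val
            psi[col, row] = val
        else:
            th[row] = val

    # measurement: declared latents
    for lat, inds in structure.measurement.items():
        for j, ind in enumerate(inds):
            name = f"{lat}=~{ind}"
            add(name, "lambda", oi[ind], li[lat], default_fixed=1.0 if j == 0 else None)
    # pass-through latents
    ind_set = structure.indicators
    for o in obs:
        if o not in ind_set:
            lam[oi[o], li[o]] = 1.0

    # structural paths
    for tgt, preds in structure.regressions.items():
        for src in preds:
            add(f"{tgt}~{src}", "beta", li[tgt], li[src])

    # latent (residual) variances
    for lat in lats:
        add(f"{lat}~~{lat}", "psi", li[lat], li[lat])
    # free covariances
    for a, b in structure.covariances:
        i, j = li[a], li[b]
        add(f"{a}~~{b}", "psi", max(i, j), min(i, j))

    # measurement errors: free for indicators, fixed 0 for pass-through
    for o in obs:
        if o in ind_set:
            add(f"{o}~~{o}", "theta", oi[o], oi[o])
        else:
            add(f"{o}~~{o}.eps", "theta", oi[o], oi[o], default_fixed=0.0)

    if fixed:
        raise ModelSpecError(f"fix() names no parameter of this model: {sorted(fixed)}")

    model = SemModel(
        observed_names=list(obs),
        latent_names=lats,
        lam=lam,
        lam_free=lam_free,
        beta=beta,
        beta_free=beta_free,
        psi=psi,
        psi_free=psi_free,
        th=th,
        th_free=th_free,
        theta_map=theta_map,
        structure=structure.copy(),
    )
    _check_anchors(model)
    return model


def _check_anchors(model: SemModel) -> None:
    """Every latent needs a scale anchor: a loading fixed to 1 or a fixed variance."""
    for j, lat in enumerate(model.latent_names):
        fixed_load = np.any((model.lam_free[:, j] < 0) & (model.lam[:, j] != 0.0))
        fixed_var = model.psi_free[j, j] < 0
        if not (fixed_load or fixed_var):
            raise ModelSpecError(f"latent {lat!r} has no scale anchor")


# ---------------------------------------------------------------------------
# plain-text model grammar
# ---------------------------------------------------------------------------

_FIX_RE = re.compile(r"^fix\(\s*(?P<name>[^,]+?)\s*,\s*(?P<value>[-+0-9.eE]+)\s*\)$")


def parse_model(text: str) -> ModelStructure:
    """Parse the plain-text model grammar.

    Lines (``#`` comments allowed)::

        target <- source1 + source2     structural paths
        latent := ind1 + ind2           measurement (first indicator anchors)
        a ~~ b                          free covariance
        fix(name, value)                constrain a parameter

    The observed-variable set is inferred: every symbol that is not a
    declared latent, in order of first appearance.
    """
    measurement: dict[str, list[str]] = {}
    regressions: dict[str, list[str]] = {}
    covariances: list[tuple[str, str]] = []
    fixed: dict[str, float] = {}
    seen: list[str] = []

    def note(v: str):
        if v not in seen:
            seen.append(v)

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        m = _FIX_RE.match(line)
        if m:
            fixed[m.group("name").strip()] = float(m.group("value"))
            continue
        if ":=" in line:
            lhs, rhs = line.split(":=", 1)
            lat = lhs.strip()
            inds = [t.strip() for t in rhs.split("+")]
            if lat in measurement:
                raise ModelSpecError(f"line {lineno}: latent {lat!r} declared twice")
            measurement[lat] = inds
            for i in inds:
                note(i)
            continue
        if "<-" in line:
            lhs, rhs = line.split("<-", 1)
            tgt = lhs.strip()
            preds = [t.strip() for t in rhs.split("+")]
            regressions.setdefault(tgt, [])
            for s in preds:
                if s not in regressions[tgt]:
                    regressions[tgt].append(s)
            note(tgt)
            for s in preds:
                note(s)
            continue
        if "~~" in line:
            a, b = (t.strip() for t in line.split("~~", 1))
            covariances.append((a, b))
            note(a)
            note(b)
            continue
        raise ModelSpecError(f"line {lineno}: cannot parse {raw!r}")

    observed = [v for v in seen if v not in measurement]
    struct = ModelStructure(
        observed=observed,
        measurement=measurement,
        regressions=regressions,
        covariances=covariances,
        fixed=fixed,
    )
    struct.validate()
    return struct


def model_to_text(structure: ModelStructure) -> str:
    """Serialize a structure back to the model grammar (round-trips with
    :func:`parse_model` up to comment and whitespace)."""
    lines = []
    for lat, inds in structure.measurement.items():
        lines.append(f"{lat} := " + " + ".join(inds))
    for tgt, preds in structure.regressions.items():
        if preds:
            lines.append(f"{tgt} <- " + " + ".join(preds))
    for a, b in structure.covariances:
        lines.append(f"{a} ~~ {b}")
    for name, value in structure.fixed.items():
        lines.append(f"fix({name}, {value:g})")
    return "\n".join(lines) + "\n"
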