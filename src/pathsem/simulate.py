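"""Synthetic expression data with known pathway structure.

The generator draws log-scale abundances from a linear-Gaussian structural
equation system: per sample, structural disturbances zeta ~ N(0, Psi) are
propagated through eta = (I - B)^-1 zeta and observed as
y = Lambda eta + eps with eps ~ N(0, Theta).  Defaults emulate the study
scale this package targets: 48 biological samples of a wheat-leaf proteome
with one intact Rubisco large subunit spot (RLS2), two small subunit spots
(RSS174, RSS175) and seven degradation-product spots (dp#), including two
pairs with near-identical expression (implied |r| > 0.9) that the model
search should absorb into latent variables.

True coefficients are implementation-documented constants on a unit-variance
scale (each structural coefficient equals its standardized value); they are
stand-ins for the undeposited original data, not published estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import PathsemError
from .model import ModelStructure, SemModel, build_sem_model
from .prior import PriorEdge, ProteinRecord

__all__ = ["TrueModel", "simulate", "rubisco_fixture", "fragment_fixture", "rodermel_regulation"]

DEFAULT_N = 48  # samples in the study this generator stands in for

RUBISCO_SPOTS = ["RLS2", "RSS174", "RSS175", "dp39", "dp12", "dp37", "dp44", "dp7", "dp15", "dp17"]


@dataclass
class TrueModel:
    """A fully valued SEM used as a data-generating truth."""

    model: SemModel
    theta_true: np.ndarray
    description: str = ""

    def __post_init__(self):
        self.theta_true = np.asarray(self.theta_true, dtype=float)
        if self.theta_true.shape != (self.model.q,):
            raise PathsemError("theta_true length does not match the model")

    def true_values(self) -> dict[str, float]:
        return dict(zip(self.model.param_names, self.theta_true))


def simulate(
    true_model: TrueModel,
    n: int = DEFAULT_N,
    seed: int | np.random.Generator = 0,
    time_blocks: int | None = None,
) -> pd.DataFrame:
    """Draw ``n`` exchangeable samples from the structural system.

    ``time_blocks`` optionally appends a balanced categorical ``time``
    column (samples remain exchangeable; the column is a covariate label
    only, mirroring a pooled multi-timepoint design).
    """
    if n < 1:
        raise PathsemError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    model = true_model.model
    lam, beta, psi, th = model.matrices(true_model.theta_true)
    m = beta.shape[0]
    imb = np.eye(m) - beta
    if abs(np.linalg.det(imb)) < 1e-12:
        raise PathsemError("I - B is singular; cannot simulate")
    # Psi may be only PSD (zero residuals); use eigen square root
    evals, evecs = np.linalg.eigh((psi + psi.T) / 2.0)
    if np.any(evals < -1e-10):
        raise PathsemError("Psi is not positive semidefinite")
    root = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None)))
    zeta = rng.standard_normal((n, m)) @ root.T
    eta = np.linalg.solve(imb, zeta.T).T
    eps = rng.standard_normal((n, model.n_observed)) * np.sqrt(np.clip(th, 0.0, None))
    y = eta @ lam.T + eps
    out = pd.DataFrame(y, columns=model.observed_names)
    if time_blocks:
        out["time"] = np.arange(n) % time_blocks + 1
    return out


# ---------------------------------------------------------------------------
# Rubisco fixtures
# ---------------------------------------------------------------------------


def rubisco_fixture(stage: str = "final") -> TrueModel:
    """The Rubisco degradation fixtures.

    ``stage="prior"`` is the hypothesis-stage skeleton: every spot observed,
    degradation paths intact -> primary -> secondary, literature regulation
    paths (small subunits up-regulate RLS2; RLS2 self-feedback), and a
    planted correlation between the two small-subunit spots.

    ``stage="final"`` is the post-search structure: a latent RSS measured by
    RSS174/RSS175 and a latent dplat measured by dp15/dp17 (both indicator
    pairs implied at |r| > 0.9), paths RSS -> RLS2/dp39/dp12/dp37,
    RLS2 -> dp44, dp39 -> dp7 and dp39 -> dplat.  All latent-level variables
    have unit implied variance, so each path coefficient equals its
    standardized value; values lie in [0.5, 0.8].
    """
    if stage == "prior":
        structure = ModelStructure(
            observed=list(RUBISCO_SPOTS),
            regressions={
                "RLS2": ["RSS174", "RSS175", "RLS2"],
                "dp39": ["RLS2"],
                "dp12": ["RLS2"],
                "dp37": ["RLS2"],
                "dp44": ["RSS174", "RSS175"],
                "dp7": ["dp39"],
                "dp15": ["dp39"],
                "dp17": ["dp39"],
            },
            covariances=[("RSS174", "RSS175")],
        )
        model = build_sem_model(structure)
        values = {
            "RLS2~RSS174": 0.35,
            "RLS2~RSS175": 0.35,
            "RLS2~RLS2": 0.15,  # weak self-feedback, |b| < 1
            "dp39~RLS2": 0.70,
            "dp12~RLS2": 0.60,
            "dp37~RLS2": 0.55,
            "dp44~RSS174": 0.30,
            "dp44~RSS175": 0.30,
            "dp7~dp39": 0.70,
            "dp15~dp39": 0.65,
            "dp17~dp39": 0.65,
            "RSS174~~RSS174": 1.0,
            "RSS175~~RSS175": 1.0,
            "RSS174~~RSS175": 0.95,
            "RLS2~~RLS2": 0.40,
            "dp39~~dp39": 0.51,
            "dp12~~dp12": 0.64,
            "dp37~~dp37": 0.70,
            "dp44~~dp44": 0.72,
            "dp7~~dp7": 0.51,
            "dp15~~dp15": 0.58,
            "dp17~~dp17": 0.58,
        }
        theta = model.theta_from_dict(values)
        return TrueModel(model, theta, description="hypothesis-stage Rubisco skeleton")

    if stage == "final":
        structure = ModelStructure(
            observed=list(RUBISCO_SPOTS),
            measurement={
                "RSS": ["RSS174", "RSS175"],
                "dplat": ["dp15", "dp17"],
            },
            regressions={
                "RLS2": ["RSS"],
                "dp39": ["RSS"],
                "dp12": ["RSS"],
                "dp37": ["RSS"],
                "dp44": ["RLS2"],
                "dp7": ["dp39"],
                "dplat": ["dp39"],
            },
        )
        model = build_sem_model(structure)
        values = {
            "RSS=~RSS175": 1.0,
            "dplat=~dp17": 1.0,
            "RLS2~RSS": 0.70,
            "dp39~RSS": 0.65,
            "dp12~RSS": 0.55,
            "dp37~RSS": 0.50,
            "dp44~RLS2": 0.60,
            "dp7~dp39": 0.70,
            "dplat~dp39": 0.75,
            # unit latent variances: residual = 1 - coef^2
            "RSS~~RSS": 1.0,
            "dplat~~dplat": 1.0 - 0.75**2,
            "RLS2~~RLS2": 1.0 - 0.70**2,
            "dp39~~dp39": 1.0 - 0.65**2,
            "dp12~~dp12": 1.0 - 0.55**2,
            "dp37~~dp37": 1.0 - 0.50**2,
            "dp44~~dp44": 1.0 - 0.60**2,
            "dp7~~dp7": 1.0 - 0.70**2,
            # measurement errors small enough that indicator pairs exceed |r| = 0.9
            "RSS174~~RSS174": 0.05,
            "RSS175~~RSS175": 0.05,
            "dp15~~dp15": 0.08,
            "dp17~~dp17": 0.08,
        }
        theta = model.theta_from_dict(values)
        return TrueModel(model, theta, description="post-search Rubisco structure")

    raise PathsemError(f"unknown fixture stage {stage!r} (use 'prior' or 'final')")


def rodermel_regulation() -> list[PriorEdge]:
    """Literature regulation annotations: small-subunit up-regulation of the
    large subunit and large-subunit self-feedback."""
    return [
        PriorEdge("RSS174", "RLS2", "regulation", "RSS up-regulation of RLS synthesis"),
        PriorEdge("RSS175", "RLS2", "regulation", "RSS up-regulation of RLS synthesis"),
        PriorEdge("RLS2", "RLS2", "regulation", "RLS self-feedback when in excess"),
    ]


# Base residue intervals on the RLS2 reference (length 475).  Secondary
# products sit in coverage gaps of dp37 so that each fragment's immediate
# precursor, not every ancestor, is its parent after reduction.
_RLS_BASE = {
    "RLS2": [(0, 475)],
    "dp39": [(50, 400)],
    "dp37": [(10, 45), (100, 140), (220, 360)],
    "dp12": [(420, 470)],
    "dp7": [(60, 95)],
    "dp15": [(365, 395)],
    "dp17": [(150, 210)],
}
_MASSES = {
    "RLS2": 52.7,
    "dp39": 38.9,
    "dp37": 36.8,
    "dp12": 12.4,
    "dp7": 7.1,
    "dp15": 15.3,
    "dp17": 17.2,
    "RSS174": 15.2,
    "RSS175": 15.1,
    "dp44": 12.0,
}
# jitter-safe margin for the secondary-product intervals
_JITTER = 2


def fragment_fixture(seed: int = 0) -> list[ProteinRecord]:
    """Ten protein records whose evidence reproduces the hypothesis-stage
    degradation edge set under :func:`pathsem.prior.build_prior_graph`.

    The RLS2 family carries interval evidence on the RLS2 reference; the
    small-subunit family carries peptide evidence, with the dp44 peptides
    shared by both intact small-subunit spots ("and/or" parentage).  The
    seed jitters masses and secondary-product interval bounds without
    altering the containment structure.
    """
    rng = np.random.default_rng(seed)

    def jit_mass(m: float) -> float:
        return round(m + rng.uniform(-0.2, 0.2), 2)

    records: list[ProteinRecord] = []
    for pid in ["RLS2", "dp39", "dp37", "dp12"]:
        records.append(
            ProteinRecord(
                id=pid,
                tier="intact" if pid == "RLS2" else "fragment",
                mass_kda=jit_mass(_MASSES[pid]),
                reference_subunit="RLS2",
                evidence=frozenset(_RLS_BASE[pid]),
            )
        )
    for pid in ["dp7", "dp15", "dp17"]:
        ivals = []
        for start, end in _RLS_BASE[pid]:
            d = int(rng.integers(-_JITTER, _JITTER + 1))
            ivals.append((start + d, end + d))
        records.append(
            ProteinRecord(
                id=pid,
                tier="fragment",
                mass_kda=jit_mass(_MASSES[pid]),
                reference_subunit="RLS2",
                evidence=frozenset(ivals),
            )
        )
    shared = frozenset({"GFKAGVK", "DTDILAAFR", "VALEACVK"})
    records.append(
        ProteinRecord(
            id="RSS174",
            tier="intact",
            mass_kda=jit_mass(_MASSES["RSS174"]),
            reference_subunit="RSS174",
            evidence=shared | {"EHGNSPGYY"},
        )
    )
    records.append(
        ProteinRecord(
            id="RSS175",
            tier="intact",
            mass_kda=jit_mass(_MASSES["RSS175"]),
            reference_subunit="RSS175",
            evidence=shared | {"QVQCISFIA"},
        )
    )
    records.append(
        ProteinRecord(
            id="dp44",
            tier="fragment",
            mass_kda=jit_mass(_MASSES["dp44"]),
            reference_subunit=None,
            evidence=frozenset({"GFKAGVK", "DTDILAAFR"}),
        )
    )
    return records
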