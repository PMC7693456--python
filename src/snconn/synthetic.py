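"""Synthetic two-group cohort generator with known ground truth.

The generator emulates the data structure of a 43-vs-43 patient/control
resting-state study on a 19-node salience-network atlas:

* per-subject ROI time series drawn from a stationary zero-mean Gaussian
  process with a specified node-node correlation matrix (downstream stages
  consume only second-order structure, so no hemodynamic model is needed);
* planted connectivity deficits: for each planted edge the patient-group
  population Fisher-z connectivity is lowered by ``delta_z``, with the
  resulting target matrix repaired to a valid correlation matrix by
  eigenvalue clipping;
* a planted mediation structure linking a clinical variable X (standardized
  internally), one edge's Fisher-z connectivity M, and a behavioral score Y:

      M = i_M + a * X + (covariates) + e_M
      Y = i_Y + c' * X + b * M + (covariates) + e_Y

* demographic, clinical and behavioral variables drawn from the marginal
  means/SDs of the reference patient cohort (mutually independent unless a
  mediation structure ties them together);
* six-parameter random-walk head-motion traces for framewise-displacement
  analyses.

Everything is driven by one integer seed: the same configuration always
yields a byte-identical cohort.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from statsmodels.stats.correlation_tools import corr_clipped

from . import datasets
from .atlas import ANTERIOR, POSTERIOR, ROIAtlas, ROINode, default_sn_atlas
from .timeseries import (
    ConnectivityMatrix,
    MotionParams,
    TimeSeriesMatrix,
    fc_matrix,
)

PATIENT = "patient"
CONTROL = "control"

#: Eigenvalue floor used when repairing indefinite target correlation matrices.
EIG_FLOOR = 1e-6

#: Latent edge-z values are clipped to this magnitude before tanh so the
#: implied correlation stays strictly inside (-1, 1) with PD headroom.
Z_LATENT_CLIP = 1.8

#: Background correlation of the two mediator-edge nodes to the rest of the
#: network.  Kept weak so the mediator edge can vary over a wide range per
#: subject without breaking positive-definiteness.
MEDIATOR_BACKGROUND_R = 0.10


@dataclass
class MediationGroundTruth:
    """Structural coefficients of the planted X -> M -> Y mediation.

    ``a``, ``b`` and ``c_prime`` are on the standardized-X scale: X enters
    the equations as a zero-mean unit-variance variable, and the stored
    clinical value is ``mean + sd * X``.  ``edge`` indexes the mediator
    edge (its Fisher-z connectivity is M).  ``covariate_effects`` maps a
    covariate name to its (effect on M, effect on Y) pair, applied to the
    standardized covariate.
    """

    a: float = 0.5
    b: float = 0.4
    c_prime: float = 0.1
    noise_sd_M: float = 0.3
    noise_sd_Y: float = 1.2
    x_var: str = "hemoglobin"
    y_var: str = "FDST"
    edge: Tuple[int, int] = (4, 6)  # dACC -- right anterior insula
    i_Y: float = 5.3
    covariate_effects: Dict[str, Tuple[float, float]] = field(default_factory=dict)


@dataclass
class SyntheticConfig:
    """Full specification of a synthetic cohort.

    Defaults reproduce the reference study design: 43 subjects per group,
    19 nodes, 230 retained volumes at TR = 2 s, clinical marginals from the
    patient arm of the reference table, and a 24:19 male:female split.
    """

    n_per_group: int = 43
    n_nodes: int = 19
    n_timepoints: int = 230
    tr_seconds: float = 2.0
    planted_edges: List[Tuple[int, int, float]] = field(default_factory=list)
    mediation: Optional[MediationGroundTruth] = field(
        default_factory=MediationGroundTruth
    )
    clinical_means_sds: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(datasets.CLINICAL_REFERENCE)
    )
    base_within_r: float = 0.30
    base_between_r: float = 0.15
    repair_tolerance: float = 0.05
    include_timeseries: bool = True
    include_motion: bool = False
    translation_step_mm: float = 0.04
    rotation_step_rad: float = 6e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 3:
            raise ValueError("n_per_group must be >= 3")
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be >= 2")
        for i, j, dz in self.planted_edges:
            if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes and i != j):
                raise ValueError(f"invalid planted edge ({i}, {j})")
            if not math.isfinite(dz):
                raise ValueError(f"non-finite delta_z on edge ({i}, {j})")
        if self.mediation is not None:
            i, j = self.mediation.edge
            if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes and i != j):
                raise ValueError(f"invalid mediation edge ({i}, {j})")
            if self.mediation.x_var not in self.clinical_means_sds:
                raise ValueError(
                    f"mediation x_var {self.mediation.x_var!r} not among "
                    f"clinical variables"
                )

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        # only keys present in the mapping override dataclass defaults
        d = dict(d)
        if d.get("mediation") is not None:
            med = dict(d["mediation"])
            med["edge"] = tuple(med["edge"])
            med["covariate_effects"] = {
                k: tuple(v) for k, v in med.get("covariate_effects", {}).items()
            }
            d["mediation"] = MediationGroundTruth(**med)
        if "planted_edges" in d:
            d["planted_edges"] = [tuple(e) for e in d["planted_edges"]]
        if "clinical_means_sds" in d:
            d["clinical_means_sds"] = {
                k: tuple(v) for k, v in d["clinical_means_sds"].items()
            }
        return cls(**d)


@dataclass
class SubjectRecord:
    """One synthetic subject: labels, covariates, scores, and imaging data."""

    subject_id: str
    group: str
    age: float
    gender: str  # "M" | "F"
    education: float
    clinical: Dict[str, float] = field(default_factory=dict)
    behavior: Dict[str, float] = field(default_factory=dict)
    timeseries: Optional[TimeSeriesMatrix] = None
    connectivity: Optional[ConnectivityMatrix] = None
    motion: Optional[MotionParams] = None

    @property
    def gender_code(self) -> int:
        """0/1 coding used in regressions (M = 0, F = 1)."""
        return 0 if self.gender == "M" else 1


@dataclass
class CohortDataset:
    """A generated cohort plus the configuration that produced it."""

    subjects: List[SubjectRecord]
    atlas: ROIAtlas
    ground_truth: SyntheticConfig

    def group(self, label: str) -> List[SubjectRecord]:
        return [s for s in self.subjects if s.group == label]

    def connectivity(self, label: Optional[str] = None) -> List[ConnectivityMatrix]:
        subs = self.subjects if label is None else self.group(label)
        out = []
        for s in subs:
            if s.connectivity is None:
                raise ValueError(f"subject {s.subject_id} has no connectivity")
            out.append(s.connectivity)
        return out

    def to_frame(self) -> pd.DataFrame:
        """Subject metadata table (one row per subject)."""
        rows = []
        for s in self.subjects:
            row = {
                "subject_id": s.subject_id,
                "group": s.group,
                "age": s.age,
                "gender": s.gender,
                "gender_code": s.gender_code,
                "education": s.education,
            }
            row.update(s.clinical)
            row.update(s.behavior)
            rows.append(row)
        return pd.DataFrame(rows)


def _generic_atlas(n_nodes: int) -> ROIAtlas:
    n_ant = max(1, round(n_nodes * 7 / 19))
    nodes = [
        ROINode(k, f"node_{k:02d}", ANTERIOR if k < n_ant else POSTERIOR)
        for k in range(n_nodes)
    ]
    return ROIAtlas(nodes)


def _base_correlation(cfg: SyntheticConfig, atlas: ROIAtlas) -> np.ndarray:
    """Block-structured base correlation: stronger within a subnetwork.

    When a mediation structure is configured, the two mediator-edge nodes
    are coupled to the rest of the network at only
    :data:`MEDIATOR_BACKGROUND_R`, which leaves the mediator edge a wide
    positive-definite admissible range for its per-subject variation.
    """
    sub = np.array([n.subnetwork == ANTERIOR for n in atlas.nodes])
    same = sub[:, None] == sub[None, :]
    c = np.where(same, cfg.base_within_r, cfg.base_between_r).astype(float)
    if cfg.mediation is not None:
        i, j = cfg.mediation.edge
        r_bg = min(cfg.base_between_r, MEDIATOR_BACKGROUND_R)
        edge_base = c[i, j]
        c[[i, j], :] = r_bg
        c[:, [i, j]] = r_bg
        c[i, j] = c[j, i] = edge_base
    np.fill_diagonal(c, 1.0)
    return c


def _make_pd(target: np.ndarray) -> np.ndarray:
    """Return a choleskyable correlation matrix near ``target``.

    Eigenvalue clipping via ``corr_clipped`` with an escalating floor; the
    loop terminates because a large enough floor shrinks the matrix toward
    the identity.
    """
    floor = EIG_FLOOR
    for _ in range(8):
        try:
            np.linalg.cholesky(target)
            return target
        except np.linalg.LinAlgError:
            target = corr_clipped(target, threshold=floor)
            floor *= 100.0
    raise ValueError("could not repair correlation matrix to positive definite")


def _repair_correlation(target: np.ndarray, tol: float, context: str) -> np.ndarray:
    """Project to the nearest valid correlation matrix by eigenvalue clipping.

    Refuses when the repair moves any off-diagonal entry by more than
    ``tol``, which signals an unachievable planted configuration.
    """
    eigvals = np.linalg.eigvalsh(target)
    if eigvals.min() >= EIG_FLOOR:
        return target
    repaired = corr_clipped(target, threshold=EIG_FLOOR)
    shift = np.max(np.abs(repaired - target))
    if shift > tol:
        raise ValueError(
            f"{context}: target correlation matrix not repairable to "
            f"positive definite within tolerance (max shift {shift:.4f} > {tol})"
        )
    return repaired


def generate_motion(
    n_volumes: int,
    seed: Optional[int] = None,
    translation_step_mm: float = 0.04,
    rotation_step_rad: float = 6e-4,
    rng: Optional[np.random.Generator] = None,
) -> MotionParams:
    """Random-walk six-parameter motion trace (translations mm, rotations rad).

    Each parameter is a cumulative sum of i.i.d. Gaussian steps; a step
    scale of zero yields perfectly still traces (all FD = 0).
    """
    if n_volumes < 2:
        raise ValueError("n_volumes must be >= 2")
    if rng is None:
        rng = np.random.default_rng(seed)
    steps = rng.standard_normal((n_volumes, 6))
    steps[:, :3] *= translation_step_mm
    steps[:, 3:] *= rotation_step_rad
    steps[0] = 0.0
    return MotionParams(np.cumsum(steps, axis=0))


def _gender_sequence(n: int, rng: np.random.Generator) -> List[str]:
    m, f = datasets.GENDER_SPLIT
    n_male = round(n * m / (m + f))
    seq = ["M"] * n_male + ["F"] * (n - n_male)
    rng.shuffle(seq)
    return seq


def generate_cohort(config: SyntheticConfig) -> CohortDataset:
    """Generate a complete cohort from a :class:`SyntheticConfig`.

    Control subjects' time series are drawn from the base correlation
    matrix; patient subjects from the base matrix with each planted edge's
    Fisher-z connectivity lowered by its ``delta_z`` (repaired to positive
    definite).  When a mediation structure is configured, the mediator
    edge's latent z varies per subject according to the structural
    equations, in both groups alike, and the target behavioral score is
    produced by the Y equation instead of its marginal distribution.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    atlas = default_sn_atlas() if cfg.n_nodes == 19 else _generic_atlas(cfg.n_nodes)

    base = _base_correlation(cfg, atlas)
    z_base = np.arctanh(np.clip(base, -0.999999, 0.999999))

    # patient-group target: planted Fisher-z deficits, then PD repair
    z_pat = z_base.copy()
    for i, j, dz in cfg.planted_edges:
        z_pat[i, j] -= dz
        z_pat[j, i] -= dz
    pat = np.tanh(z_pat)
    np.fill_diagonal(pat, 1.0)
    pat = _repair_correlation(pat, cfg.repair_tolerance, "patient group")

    group_target = {CONTROL: base, PATIENT: pat}

    med = cfg.mediation
    subjects: List[SubjectRecord] = []
    for group in (PATIENT, CONTROL):
        genders = _gender_sequence(cfg.n_per_group, rng)
        demo = datasets.DEMOGRAPHIC_REFERENCE
        for k in range(cfg.n_per_group):
            sid = f"sub-{'PAT' if group == PATIENT else 'CON'}{k + 1:03d}"
            age = max(18.0, rng.normal(*demo["age"][group]))
            edu = max(0.0, rng.normal(*demo["education"][group]))

            clinical: Dict[str, float] = {}
            x_std = 0.0
            for var, (mu, sd) in cfg.clinical_means_sds.items():
                u = rng.standard_normal()
                if med is not None and var == med.x_var:
                    x_std = u
                clinical[var] = mu + sd * u

            behavior: Dict[str, float] = {}
            for test, per_group in datasets.BEHAVIOR_REFERENCE.items():
                mu, sd = per_group[group]
                behavior[test] = rng.normal(mu, sd)

            # subject-level target correlation matrix
            target = group_target[group]
            m_latent = None
            if med is not None:
                i, j = med.edge
                cov_m = cov_y = 0.0
                for cname, (bm, by) in med.covariate_effects.items():
                    if cname == "age":
                        cval = (age - demo["age"][group][0]) / demo["age"][group][1]
                    elif cname == "education":
                        cval = (edu - demo["education"][group][0]) / max(
                            demo["education"][group][1], 1e-12
                        )
                    elif cname == "gender":
                        cval = 0.0 if genders[k] == "M" else 1.0
                    else:
                        raise ValueError(f"unknown covariate {cname!r}")
                    cov_m += bm * cval
                    cov_y += by * cval
                i_m = np.arctanh(target[i, j])  # group base z at mediator edge
                m_latent = (
                    i_m + med.a * x_std + cov_m + rng.normal(0.0, med.noise_sd_M)
                )
                m_clipped = float(np.clip(m_latent, -Z_LATENT_CLIP, Z_LATENT_CLIP))
                target = target.copy()
                target[i, j] = target[j, i] = np.tanh(m_clipped)
                target = _make_pd(target)
                # ground truth M is the achieved edge z after clip/repair,
                # keeping the structural equations self-consistent
                m_used = float(np.arctanh(target[i, j]))
                behavior[med.y_var] = (
                    med.i_Y
                    + med.c_prime * x_std
                    + med.b * m_used
                    + cov_y
                    + rng.normal(0.0, med.noise_sd_Y)
                )

            chol = np.linalg.cholesky(target)
            raw = rng.standard_normal((cfg.n_timepoints, cfg.n_nodes))
            series = TimeSeriesMatrix(
                raw @ chol.T, tr_seconds=cfg.tr_seconds, node_labels=atlas.labels
            )
            conn = fc_matrix(series, to_fisher_z=True)
            conn.subject_id = sid

            motion = None
            if cfg.include_motion:
                motion = generate_motion(
                    cfg.n_timepoints,
                    translation_step_mm=cfg.translation_step_mm,
                    rotation_step_rad=cfg.rotation_step_rad,
                    rng=rng,
                )

            subjects.append(
                SubjectRecord(
                    subject_id=sid,
                    group=group,
                    age=float(age),
                    gender=genders[k],
                    education=float(edu),
                    clinical=clinical,
                    behavior=behavior,
                    timeseries=series if cfg.include_timeseries else None,
                    connectivity=conn,
                    motion=motion,
                )
            )

    return CohortDataset(subjects=subjects, atlas=atlas, ground_truth=cfg)


def mediation_table(
    dataset: CohortDataset, standardize_x: bool = False
) -> pd.DataFrame:
    """Per-subject table for mediation fitting on a generated cohort.

    Columns: X (the configured clinical variable), M (the mediator edge's
    measured Fisher-z connectivity), Y (the configured behavioral score),
    plus age, gender (0/1) and education.  With ``standardize_x`` the X
    column is centered/scaled by its configured mean and SD, putting fitted
    coefficients on the same scale as the generator's ground truth.
    """
    med = dataset.ground_truth.mediation
    if med is None:
        raise ValueError("cohort was generated without a mediation structure")
    i, j = med.edge
    rows = []
    for s in dataset.subjects:
        if s.connectivity is None:
            raise ValueError(f"subject {s.subject_id} has no connectivity")
        x = s.clinical[med.x_var]
        if standardize_x:
            mu, sd = dataset.ground_truth.clinical_means_sds[med.x_var]
            x = (x - mu) / sd
        rows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "X": x,
                "M": s.connectivity.values[i, j],
                "Y": s.behavior[med.y_var],
                "age": s.age,
                "gender": s.gender_code,
                "education": s.education,
            }
        )
    return pd.DataFrame(rows)
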