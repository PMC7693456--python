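"""End-to-end orchestration: cohort -> FC -> group stats -> NBS -> classifier
-> association -> mediation, with deterministic per-stage seeding and a JSON
run report.

Stage seeds are derived by hashing the global seed with the stage name, so
adding or reordering downstream stages never perturbs the randomness of
earlier ones.  When the NBS stage finds no significant component, the
feature-dependent stages (classification, association, mediation) are
skipped with an explicit report entry rather than an error.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as snio
from .association import association_table
from .group_stats import demographics_table
from .mediation import MediationSpec, run_mediation
from .nbs import NBSConfig, extract_significant_z, nbs_permutation_test
from .svm import (
    aggregate_weights,
    loocv_svm,
    permutation_significance,
    top_fraction_edges,
    CONTROL_LABEL,
    PATIENT_LABEL,
)
from .synthetic import CONTROL, PATIENT, CohortDataset, SyntheticConfig, generate_cohort

log = logging.getLogger("snconn")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return zlib.crc32(f"{global_seed}:{stage}".encode()) & 0x7FFFFFFF


@dataclass
class RunConfig:
    out_dir: str
    data_dir: Optional[str] = None
    simulate: Optional[dict] = None
    seed: int = 0
    nbs: dict = field(default_factory=dict)
    classifier: dict = field(default_factory=dict)
    association_variables: List[str] = field(default_factory=list)
    mediation: List[dict] = field(default_factory=list)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.data_dir is None and self.simulate is None:
            raise ValueError("config needs either data_dir or a simulate block")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _load_or_simulate(cfg: RunConfig) -> CohortDataset:
    if cfg.simulate is not None:
        sim = dict(cfg.simulate)
        sim.setdefault("seed", stage_seed(cfg.seed, "simulate"))
        return generate_cohort(SyntheticConfig.from_dict(sim))
    data = Path(cfg.data_dir)
    from .atlas import ROIAtlas

    atlas = ROIAtlas.from_tsv(data / "atlas.tsv")
    subjects = snio.read_subjects(data / "subjects.tsv")
    mats = snio.read_cohort_matrices(data / "matrices", subjects, atlas=atlas)
    from .synthetic import SubjectRecord

    recs = []
    for (_, row), m in zip(subjects.iterrows(), mats):
        known = {"subject_id", "group", "age", "gender", "gender_code", "education"}
        extra = {k: row[k] for k in subjects.columns if k not in known}
        recs.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                age=float(row.get("age", np.nan)),
                gender=str(row.get("gender", "M")),
                education=float(row.get("education", np.nan)),
                clinical=extra,
                connectivity=m,
            )
        )
    gt_path = data / "ground_truth.json"
    gt = snio.read_ground_truth(gt_path) if gt_path.exists() else SyntheticConfig()
    return CohortDataset(subjects=recs, atlas=atlas, ground_truth=gt)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run report dict."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "stages": {}}

    log.info("stage: cohort")
    dataset = _load_or_simulate(cfg)
    subjects = dataset.to_frame()
    snio.write_subjects(out / "subjects.tsv", subjects)
    dataset.atlas.to_tsv(out / "atlas.tsv")
    report["stages"]["cohort"] = {
        "n_subjects": len(dataset.subjects),
        "n_patients": len(dataset.group(PATIENT)),
        "n_controls": len(dataset.group(CONTROL)),
    }

    log.info("stage: group statistics")
    numeric = [
        c
        for c in subjects.columns
        if c not in ("subject_id", "group", "gender", "gender_code")
        and pd.api.types.is_numeric_dtype(subjects[c])
    ]
    demo = demographics_table(subjects, variables=numeric)
    demo.to_csv(out / "group_stats.tsv", sep="\t", index=False)
    report["stages"]["group_stats"] = {"n_variables": len(demo)}

    log.info("stage: NBS")
    nbs_kwargs = dict(cfg.nbs)
    nbs_kwargs.setdefault("seed", stage_seed(cfg.seed, "nbs"))
    nbs_cfg = NBSConfig(**nbs_kwargs)
    patients = dataset.connectivity(PATIENT)
    controls = dataset.connectivity(CONTROL)
    nbs_res = nbs_permutation_test(patients, controls, nbs_cfg)
    edge_table = nbs_res.edge_table()
    edge_table.to_csv(out / "nbs_edges.tsv", sep="\t", index=False)
    np.savetxt(out / "nbs_mask.tsv", nbs_res.significant_mask, fmt="%d", delimiter="\t")
    report["stages"]["nbs"] = {
        "n_components": len(nbs_res.components),
        "n_significant_components": len(nbs_res.significant_components),
        "n_significant_edges": int(nbs_res.significant_mask.sum() // 2),
        "fwer_p": [c.fwer_p for c in nbs_res.components],
    }

    if not nbs_res.significant_components:
        msg = "no significant NBS component; downstream stages skipped"
        log.info(msg)
        for stage in ("classifier", "association", "mediation"):
            report["stages"][stage] = {"skipped": True, "reason": msg}
        _write_report(out, report)
        return report

    z_table = extract_significant_z(
        nbs_res.significant_mask,
        dataset.connectivity(),
        node_labels=dataset.atlas.labels,
    )
    z_table.to_csv(out / "significant_z.tsv", sep="\t")
    top = top_fraction_edges(
        [(row["edge"], row["t_value"]) for _, row in edge_table.iterrows()]
    )
    report["stages"]["nbs"]["top_20pct_edges"] = [e for e, _ in top]

    log.info("stage: classifier")
    labels = np.array(
        [
            PATIENT_LABEL if s.group == PATIENT else CONTROL_LABEL
            for s in dataset.subjects
        ]
    )
    clf_kwargs = dict(cfg.classifier)
    n_perm = int(clf_kwargs.pop("n_permutations", 1000))
    cost = float(clf_kwargs.pop("cost", 1.0))
    clf = permutation_significance(
        z_table.to_numpy(),
        labels,
        n_permutations=n_perm,
        seed=stage_seed(cfg.seed, "classifier"),
        cost=cost,
    )
    _, fold_weights = loocv_svm(z_table.to_numpy(), labels, cost=cost)
    weight_table, thr = aggregate_weights(fold_weights, list(z_table.columns))
    weight_table.to_csv(out / "svm_weights.tsv", sep="\t", index=False)
    report["stages"]["classifier"] = {
        "confusion": dict(zip(("tp", "fn", "tn", "fp"), clf.confusion)),
        "metrics": clf.metrics,
        "permutation_p": clf.permutation_p,
        "weight_selection_threshold": thr,
        "selected_edges": weight_table.loc[weight_table["selected"], "edge"].tolist(),
    }

    log.info("stage: association")
    pat_ids = [s.subject_id for s in dataset.group(PATIENT)]
    assoc_vars = cfg.association_variables or [
        c for c in numeric if c not in ("age", "education")
    ]
    pat_meta = subjects.set_index("subject_id").loc[pat_ids, assoc_vars]
    assoc = association_table(z_table.loc[pat_ids], pat_meta)
    assoc.to_csv(out / "association.tsv", sep="\t", index=False)
    report["stages"]["association"] = {
        "n_tests": len(assoc),
        "n_flagged": int(assoc["flagged"].sum()) if len(assoc) else 0,
    }

    log.info("stage: mediation")
    med_reports = []
    for k, spec_dict in enumerate(cfg.mediation):
        d = dict(spec_dict)
        d.setdefault("seed", stage_seed(cfg.seed, f"mediation_{k}"))
        spec = MediationSpec(**d)
        frame = subjects.set_index("subject_id").loc[pat_ids].copy()
        frame["gender"] = frame["gender_code"]
        if spec.m in z_table.columns:
            frame[spec.m] = z_table.loc[pat_ids, spec.m]
        fit = run_mediation(frame.reset_index(), spec)
        med_reports.append({"x": spec.x, "m": spec.m, "y": spec.y, **fit.to_dict()})
    report["stages"]["mediation"] = {"fits": med_reports}
    with open(out / "mediation.json", "w") as fh:
        json.dump(med_reports, fh, indent=2)

    _write_report(out, report)
    return report


def _write_report(out: Path, report: dict) -> None:
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
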