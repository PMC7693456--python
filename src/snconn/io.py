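"""Plain-text (TSV/JSON) readers and writers for all pipeline artifacts.

Square connectivity matrices are stored full-square with a header row and a
leading label column so they are human-inspectable; the reader validates
symmetry (1e-9), finiteness (naming the offending cell), and label
agreement with the atlas.  Round-trips are lossless to double precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .atlas import ROIAtlas
from .synthetic import CohortDataset, SyntheticConfig
from .timeseries import ConnectivityMatrix, TimeSeriesMatrix


def write_matrix(path: str | Path, matrix: ConnectivityMatrix) -> None:
    labels = matrix.node_labels or [f"node_{k:02d}" for k in range(matrix.n_nodes)]
    with open(path, "w") as fh:
        fh.write("label\t" + "\t".join(labels) + "\n")
        for lab, row in zip(labels, matrix.values):
            fh.write(lab + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


def read_matrix(
    path: str | Path,
    atlas: Optional[ROIAtlas] = None,
    scale: str = "fisher_z",
    subject_id: str = "",
) -> ConnectivityMatrix:
    """Read a square labelled TSV matrix, validating shape and content."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "label":
            raise ValueError(f"{path}: first header cell must be 'label'")
        labels = header[1:]
        n = len(labels)
        values = np.empty((n, n))
        row_labels = []
        for r, line in enumerate(fh):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != n + 1:
                raise ValueError(f"{path}: row {r + 2} has {len(cells)} cells")
            row_labels.append(cells[0])
            for c, cell in enumerate(cells[1:]):
                try:
                    v = float(cell)
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric cell at row {cells[0]!r}, "
                        f"column {labels[c]!r}: {cell!r}"
                    ) from None
                if not np.isfinite(v):
                    raise ValueError(
                        f"{path}: non-finite value at row {cells[0]!r}, "
                        f"column {labels[c]!r}"
                    )
                values[r, c] = v
    if row_labels != labels:
        raise ValueError(f"{path}: row labels disagree with column labels")
    if atlas is not None and labels != atlas.labels:
        raise ValueError(
            f"{path}: matrix labels do not match atlas node order"
        )
    asym = np.max(np.abs(values - values.T))
    if asym > 1e-9:
        raise ValueError(f"{path}: asymmetry {asym:.3g} exceeds 1e-9")
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 0.0)
    return ConnectivityMatrix(
        values, scale=scale, subject_id=subject_id, node_labels=labels
    )


def write_timeseries(path: str | Path, ts: TimeSeriesMatrix) -> None:
    labels = ts.node_labels or [f"node_{k:02d}" for k in range(ts.n_nodes)]
    with open(path, "w") as fh:
        fh.write("\t".join(labels) + "\n")
        for row in ts.values:
            fh.write("\t".join(f"{v:.17g}" for v in row) + "\n")


def read_timeseries(
    path: str | Path, tr_seconds: float = 2.0, atlas: Optional[ROIAtlas] = None
) -> TimeSeriesMatrix:
    df = pd.read_csv(path, sep="\t")
    labels = list(df.columns)
    if atlas is not None and labels != atlas.labels:
        raise ValueError(f"{path}: column labels do not match atlas node order")
    return TimeSeriesMatrix(
        df.to_numpy(dtype=float), tr_seconds=tr_seconds, node_labels=labels
    )


def write_subjects(path: str | Path, subjects: pd.DataFrame) -> None:
    subjects.to_csv(path, sep="\t", index=False)


def read_subjects(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_cohort(dataset: CohortDataset, out_dir: str | Path) -> None:
    """Write a cohort as the on-disk layout all CLI stages consume.

    ``<out>/timeseries/<subject>.tsv`` (if generated),
    ``<out>/matrices/<subject>.tsv`` (Fisher-z), ``subjects.tsv``,
    ``atlas.tsv`` and ``ground_truth.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.atlas.to_tsv(out / "atlas.tsv")
    write_subjects(out / "subjects.tsv", dataset.to_frame())
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(dataset.ground_truth.to_dict(), fh, indent=2)
    ts_dir = out / "timeseries"
    mat_dir = out / "matrices"
    mat_dir.mkdir(exist_ok=True)
    for s in dataset.subjects:
        if s.timeseries is not None:
            ts_dir.mkdir(exist_ok=True)
            write_timeseries(ts_dir / f"{s.subject_id}.tsv", s.timeseries)
        if s.connectivity is not None:
            write_matrix(mat_dir / f"{s.subject_id}.tsv", s.connectivity)


def read_cohort_matrices(
    matrices_dir: str | Path,
    subjects: pd.DataFrame,
    atlas: Optional[ROIAtlas] = None,
    scale: str = "fisher_z",
) -> List[ConnectivityMatrix]:
    """Load per-subject matrices in subjects-table order."""
    matrices_dir = Path(matrices_dir)
    out = []
    for sid in subjects["subject_id"]:
        p = matrices_dir / f"{sid}.tsv"
        if not p.exists():
            raise FileNotFoundError(f"no matrix for subject {sid}: {p}")
        out.append(read_matrix(p, atlas=atlas, scale=scale, subject_id=str(sid)))
    return out


def read_ground_truth(path: str | Path) -> SyntheticConfig:
    with open(path) as fh:
        return SyntheticConfig.from_dict(json.load(fh))
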