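"""ROI time-series cleaning, head-motion summaries, and connectivity matrices.

The cleaning pipeline mirrors the last stages of a standard resting-state
preprocessing stream, applied to already-extracted ROI time series: linear
detrending, regression of nuisance time courses, and zero-phase low-pass
filtering below 0.1 Hz.  Connectivity is the Pearson correlation between
node time courses, Fisher-z transformed (z = atanh r) to stabilize variance
for group statistics.

Head motion is summarized by framewise displacement (FD) in the Power
formulation: the sum of absolute frame-to-frame changes of the three
translations plus the three rotations converted to arc length on a 50 mm
sphere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import signal

#: Correlations are clipped to +/-(1 - R_CLIP) before atanh so z stays finite.
R_CLIP = 1e-7


@dataclass
class TimeSeriesMatrix:
    """Timepoints x nodes ROI time-series matrix for one subject."""

    values: np.ndarray
    tr_seconds: float = 2.0
    node_labels: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 2:
            raise ValueError("time series must be 2-D with >= 2 timepoints")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.node_labels is not None and len(self.node_labels) != self.values.shape[1]:
            raise ValueError("node_labels length != number of columns")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_seconds)


@dataclass
class MotionParams:
    """Volumes x 6 rigid-body motion: translations (mm), rotations (rad)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 6:
            raise ValueError("motion must be a volumes x 6 matrix")
        if self.values.shape[0] < 2:
            raise ValueError("motion requires >= 2 volumes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("motion contains non-finite values")


@dataclass
class ConnectivityMatrix:
    """Symmetric node x node connectivity, raw Pearson r or Fisher z.

    The diagonal is stored as 0 on both scales so that elementwise mask
    algebra (significant-edge extraction) is well defined.
    """

    values: np.ndarray
    scale: str  # "pearson_r" | "fisher_z"
    subject_id: str = ""
    node_labels: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if self.scale not in ("pearson_r", "fisher_z"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.all(np.isfinite(v)):
            raise ValueError("connectivity matrix contains non-finite values")
        if np.max(np.abs(v - v.T)) > 1e-12:
            raise ValueError("connectivity matrix asymmetric beyond 1e-12")
        if np.any(np.diag(v) != 0.0):
            raise ValueError("diagonal must be stored as 0")
        if self.scale == "pearson_r":
            off = v[~np.eye(v.shape[0], dtype=bool)]
            if off.size and np.max(np.abs(off)) >= 1.0:
                raise ValueError("off-diagonal r must lie in (-1, 1)")
        if self.node_labels is not None and len(self.node_labels) != v.shape[0]:
            raise ValueError("node_labels length != matrix size")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


def _drop_collinear(design: np.ndarray) -> np.ndarray:
    """Drop columns that are linearly redundant, keeping the earliest ones."""
    if design.shape[1] == 0:
        return design
    keep: list[int] = []
    for j in range(design.shape[1]):
        trial = design[:, keep + [j]]
        if np.linalg.matrix_rank(trial) > len(keep):
            keep.append(j)
    if len(keep) < design.shape[1]:
        warnings.warn(
            f"nuisance matrix rank-deficient: dropped "
            f"{design.shape[1] - len(keep)} redundant column(s)",
            stacklevel=3,
        )
    return design[:, keep]


def clean_timeseries(
    ts: TimeSeriesMatrix,
    nuisance: Optional[np.ndarray] = None,
    cutoff_hz: float = 0.1,
    filter_order: int = 4,
) -> TimeSeriesMatrix:
    """Detrend, regress out nuisance time courses, and low-pass filter.

    Steps, in order: (1) remove per-column mean and linear trend; (2) OLS
    regression of the (demeaned) nuisance regressors, keeping residuals;
    (3) zero-phase Butterworth low-pass below ``cutoff_hz`` (applied
    forward-backward, so the effective attenuation is twice the design
    order).  Pass ``cutoff_hz=None`` to skip filtering.

    Parameters
    ----------
    ts : TimeSeriesMatrix
    nuisance : array of shape (timepoints, k), optional
        Nuisance regressors (e.g. tissue signals, motion expansions).
        Rank-deficient matrices are reduced with a warning.
    cutoff_hz : float or None
        Low-pass cutoff; must be below the Nyquist frequency.
    """
    x = ts.values.copy()
    t = x.shape[0]

    if cutoff_hz is not None and cutoff_hz >= ts.nyquist_hz:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz >= Nyquist {ts.nyquist_hz} Hz "
            f"(TR = {ts.tr_seconds} s)"
        )

    # (1)+(2) joint projection onto intercept, linear trend, and nuisance:
    # a single OLS residualization, so detrending never re-introduces
    # nuisance leakage (and vice versa) and the step is idempotent
    trend = np.arange(t, dtype=float)
    trend -= trend.mean()
    design = [np.ones(t), trend]
    if nuisance is not None:
        nuis = np.asarray(nuisance, dtype=float)
        if nuis.ndim == 1:
            nuis = nuis[:, None]
        if nuis.shape[0] != t:
            raise ValueError(
                f"nuisance has {nuis.shape[0]} rows, time series has {t}"
            )
        nuis = _drop_collinear(
            np.column_stack(design + [nuis - nuis.mean(axis=0)])
        )[:, 2:]
        design.append(nuis)
    d = np.column_stack(design)
    beta, *_ = np.linalg.lstsq(d, x, rcond=None)
    x = x - d @ beta

    # (3) zero-phase low-pass
    if cutoff_hz is not None:
        sos = signal.butter(
            filter_order, cutoff_hz, btype="low", fs=1.0 / ts.tr_seconds,
            output="sos",
        )
        x = signal.sosfiltfilt(sos, x, axis=0)

    return TimeSeriesMatrix(x, tr_seconds=ts.tr_seconds, node_labels=ts.node_labels)


def framewise_displacement(
    m: MotionParams, head_radius_mm: float = 50.0
) -> Tuple[np.ndarray, float]:
    """Power framewise displacement per frame transition, plus its mean.

    FD_t = sum_i |d translation_i| + r * sum_i |d rotation_i| for t = 2..T,
    with rotations converted to displacement on a sphere of radius ``r``
    (default 50 mm).

    Returns
    -------
    (fd, mean_fd) : FD series of length T-1 and its mean.
    """
    if head_radius_mm <= 0:
        raise ValueError("head_radius_mm must be positive")
    diffs = np.abs(np.diff(m.values, axis=0))
    fd = diffs[:, :3].sum(axis=1) + head_radius_mm * diffs[:, 3:].sum(axis=1)
    return fd, float(fd.mean())


def fc_matrix(ts: TimeSeriesMatrix, to_fisher_z: bool = True) -> ConnectivityMatrix:
    """Pearson ROI-to-ROI correlation matrix, optionally Fisher-z transformed.

    Off-diagonal entries are the Pearson correlation of the two node time
    courses; with ``to_fisher_z`` they are z = atanh(r) after clipping r to
    +/-(1 - 1e-7) so perfectly correlated pairs stay finite.  The diagonal
    is set to 0.
    """
    x = ts.values
    sd = x.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = (
            [ts.node_labels[k] for k in dead]
            if ts.node_labels is not None
            else list(map(int, dead))
        )
        raise ValueError(f"zero-variance node column(s): {names}")

    r = np.corrcoef(x, rowvar=False)
    r = (r + r.T) / 2.0  # enforce exact symmetry
    r = np.clip(r, -(1.0 - R_CLIP), 1.0 - R_CLIP)
    if to_fisher_z:
        out = np.arctanh(r)
        scale = "fisher_z"
    else:
        out = r
        scale = "pearson_r"
    np.fill_diagonal(out, 0.0)
    return ConnectivityMatrix(
        out, scale=scale, subject_id="", node_labels=ts.node_labels
    )
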