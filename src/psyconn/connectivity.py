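"""ROI time-series preprocessing and subject-level connectivity matrices.

The stage contract mirrors standard resting-state practice: nuisance
(confound) regression first, then bandpass temporal filtering, then Pearson
correlation between ROI time courses.  :func:`compute_connectivity` enforces
that ordering; the individual steps are exposed for testing and reuse.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import linalg as sla
from scipy.signal import butter, filtfilt

from .errors import AlignmentError, CollinearityError, DegenerateSeriesError

__all__ = [
    "TimeSeriesMatrix",
    "ConnectivityStack",
    "regress_confounds",
    "bandpass",
    "correlation_matrix",
    "compute_connectivity",
]


@dataclass
class TimeSeriesMatrix:
    """One subject's ROI time courses.

    Parameters
    ----------
    subject_id : str
        Subject identifier.
    data : ndarray, shape (T, R)
        One column per ROI, one row per time sample.  No missing samples.
    tr : float
        Repetition time in seconds (sampling interval).
    roi_ids : sequence of int
        ROI identifiers matching a :class:`~psyconn.morphometry.RoiSet`.
    """

    subject_id: str
    data: np.ndarray
    tr: float
    roi_ids: Sequence[int] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time series must be a T x R matrix")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contains missing or non-finite samples")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if not self.roi_ids:
            self.roi_ids = list(range(1, self.data.shape[1] + 1))
        if len(self.roi_ids) != self.data.shape[1]:
            raise AlignmentError("roi_ids length does not match number of columns")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass
class ConnectivityStack:
    """Per-subject R x R Pearson correlation matrices.

    Each matrix is symmetric with unit diagonal; off-diagonal entries lie in
    [-1, 1].
    """

    subject_ids: list[str]
    matrices: np.ndarray  # (n_subjects, R, R)
    roi_ids: Sequence[int]

    def __post_init__(self):
        self.matrices = np.asarray(self.matrices, dtype=float)
        if self.matrices.ndim != 3 or self.matrices.shape[1] != self.matrices.shape[2]:
            raise ValueError("matrices must have shape (n_subjects, R, R)")
        if len(self.subject_ids) != self.matrices.shape[0]:
            raise AlignmentError("subject_ids length does not match matrices")
        if len(self.roi_ids) != self.matrices.shape[1]:
            raise AlignmentError("roi_ids length does not match matrix size")
        if not np.allclose(self.matrices, np.swapaxes(self.matrices, 1, 2), atol=1e-8):
            raise ValueError("correlation matrices must be symmetric")
        diags = np.diagonal(self.matrices, axis1=1, axis2=2)
        if not np.allclose(diags, 1.0, atol=1e-8):
            raise ValueError("correlation matrices must have unit diagonal")

    @property
    def n_subjects(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_rois(self) -> int:
        return self.matrices.shape[1]


def regress_confounds(ts: TimeSeriesMatrix, confounds: np.ndarray) -> TimeSeriesMatrix:
    """Residualize every ROI series on an intercept plus the confound columns.

    Residuals are orthogonal to every confound column.  A Friston-24 motion
    model (6 series, their one-step lags, and the squares of both) is the
    expected shape, but any full-column-rank matrix is accepted.

    Raises
    ------
    CollinearityError
        If ``[intercept | confounds]`` is rank deficient; the error names the
        offending confound columns.
    """
    C = np.asarray(confounds, dtype=float)
    if C.ndim != 2 or C.shape[0] != ts.n_samples:
        raise AlignmentError(
            f"confounds must have {ts.n_samples} rows, got shape {C.shape}"
        )
    X = np.column_stack([np.ones(ts.n_samples), C])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns from a pivoted QR of the design
        _, R, piv = sla.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = sorted(piv[np.flatnonzero(diag < tol)])
        # report in confound-column indexing (intercept is column -1)
        offending = [int(j) - 1 for j in bad]
        raise CollinearityError(offending)
    beta, *_ = np.linalg.lstsq(X, ts.data, rcond=None)
    resid = ts.data - X @ beta
    return replace(ts, data=resid)


def bandpass(ts: TimeSeriesMatrix, low_hz: float, high_hz: float, order: int = 4) -> TimeSeriesMatrix:
    """Zero-phase Butterworth bandpass filter applied column-wise.

    A 4th-order Butterworth filter run forward and backward (``filtfilt``)
    keeps the pass band (default 0.01-0.1 Hz) with no phase distortion, so
    downstream correlations are unaffected by filter delay.
    """
    nyquist = 0.5 / ts.tr
    if not (0.0 < low_hz < high_hz < nyquist):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < Nyquist ({nyquist})"
        )
    b, a = butter(order, [low_hz, high_hz], btype="bandpass", fs=1.0 / ts.tr)
    filtered = filtfilt(b, a, ts.data, axis=0)
    return replace(ts, data=filtered)


def correlation_matrix(ts: TimeSeriesMatrix) -> np.ndarray:
    """Pearson correlation between all ROI pairs; symmetric with unit diagonal.

    Raises
    ------
    DegenerateSeriesError
        If any ROI column is constant (zero variance), naming the ROI.
    """
    bad = np.flatnonzero(np.ptp(ts.data, axis=0) == 0)
    if bad.size:
        ids = [ts.roi_ids[i] for i in bad]
        raise DegenerateSeriesError(f"constant time series for ROI(s) {ids}")
    r = np.corrcoef(ts.data, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def compute_connectivity(
    series: Sequence[TimeSeriesMatrix],
    confounds: Sequence[np.ndarray] | None = None,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
) -> ConnectivityStack:
    """Run the full per-subject preprocessing chain and stack the matrices.

    Stage order is fixed: confound regression, then bandpass, then Pearson
    correlation.
    """
    if confounds is not None and len(confounds) != len(series):
        raise AlignmentError("one confound matrix per subject is required")
    roi_ids = list(series[0].roi_ids)
    mats = []
    ids = []
    for k, ts in enumerate(series):
        if list(ts.roi_ids) != roi_ids:
            raise AlignmentError(f"subject {ts.subject_id} has mismatched ROI ids")
        if confounds is not None:
            ts = regress_confounds(ts, confounds[k])
        ts = bandpass(ts, low_hz, high_hz)
        mats.append(correlation_matrix(ts))
        ids.append(ts.subject_id)
    return ConnectivityStack(subject_ids=ids, matrices=np.stack(mats), roi_ids=roi_ids)
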