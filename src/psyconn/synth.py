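"""Synthetic cohort generator with known planted structure.

Every input the pipeline consumes is generated here so that each downstream
stage has a recoverable ground truth:

* a subjects x parameters psychometric score table (truncated-Gaussian
  scores on a bounded 0-130 scale, block-structured missingness per test
  battery);
* per-subject gray-matter density volumes with score-linked foci planted at
  known parcel locations, plus total-brain-volume scalars;
* per-subject ROI time series (default 480 samples at TR = 1 s) whose
  population correlation on planted edges varies linearly with the
  subject's standardized score, plus Friston-24-shaped confound matrices.

A single integer seed on :class:`GroundTruth` fully determines all emitted
data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter

from .connectivity import TimeSeriesMatrix
from .errors import InvalidMomentError, PlacementError
from .morphometry import GmStack

__all__ = [
    "GroundTruth",
    "PsychometricTable",
    "generate_scores",
    "generate_gm_maps",
    "generate_parcellation",
    "generate_timeseries",
    "edge_effect_for_target_correlation",
    "effective_samples",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class PlantedFocus:
    """A gray-matter focus whose density tracks one parameter's score."""

    parameter: str
    parcel: int
    center: tuple[int, int, int]  # voxel indices
    beta_vbm: float  # density units per score unit


@dataclass(frozen=True)
class PlantedEdge:
    """A connectivity edge whose correlation tracks one parameter's score."""

    parameter: str
    i: int  # 0-based ROI index
    j: int
    beta_edge: float  # correlation units per score z-score

    def __post_init__(self):
        if self.i == self.j:
            raise ValueError("planted edge must join two distinct ROIs")
        if self.i > self.j:  # store unordered pairs canonically
            lo, hi = self.j, self.i
            object.__setattr__(self, "i", lo)
            object.__setattr__(self, "j", hi)


@dataclass
class GroundTruth:
    """Planted effects and score model behind one synthetic cohort."""

    planted_foci: list[PlantedFocus] = field(default_factory=list)
    planted_edges: list[PlantedEdge] = field(default_factory=list)
    score_model: dict[str, tuple[float, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        pairs = [(e.i, e.j) for e in self.planted_edges]
        if len(set(pairs)) != len(pairs):
            raise ValueError("planted edge pairs must be unique")
        for e in self.planted_edges:
            if not np.isfinite(e.beta_edge):
                raise ValueError("edge effect sizes must be finite")
        for f in self.planted_foci:
            if not np.isfinite(f.beta_vbm):
                raise ValueError("focus effect sizes must be finite")

    def child_seed(self, stage: int) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        ss = np.random.SeedSequence(self.seed, spawn_key=(stage,))
        return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PsychometricTable:
    """Subjects x parameters score matrix with block-structured missingness.

    Missing entries are NaN and cover whole batteries: a subject either has
    all of a battery's parameters or none of them, matching cohorts where
    some test batteries were administered on separate days.
    """

    scores: pd.DataFrame  # index: subject ids, columns: parameter names

    def __post_init__(self):
        for col in self.scores.columns:
            observed = self.scores[col].dropna()
            if observed.nunique() < 2:
                raise ValueError(f"parameter {col!r} has fewer than 2 distinct observed values")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def parameters(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def n_subjects(self) -> int:
        return len(self.scores)


def generate_scores(
    n_subjects: int,
    parameters: Sequence[str],
    moments: Mapping[str, tuple[float, float]],
    missing_blocks: Mapping[str, tuple[Sequence[str], float]] | None = None,
    seed: int = 0,
    scale_range: tuple[float, float] = (0.0, 130.0),
) -> PsychometricTable:
    """Draw a psychometric score table from per-parameter (mean, SD) moments.

    Scores are Gaussian truncated to ``scale_range`` (the questionnaire
    scale), so column sample moments converge to the requested moments as n
    grows whenever the moments sit well inside the scale.

    Parameters
    ----------
    missing_blocks : mapping, optional
        ``battery name -> (parameter names, fraction of subjects missing)``.
        Each missing subject lacks the battery's entire parameter block.
    """
    if n_subjects < 10:
        raise ValueError("n_subjects must be >= 10")
    rng = np.random.default_rng(seed)
    lo, hi = scale_range
    cols = {}
    for param in parameters:
        mean, sd = moments[param]
        if sd <= 0:
            raise InvalidMomentError(f"SD for {param!r} must be positive, got {sd}")
        a, b = (lo - mean) / sd, (hi - mean) / sd
        cols[param] = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n_subjects, random_state=rng)
    ids = [f"sub-{k + 1:03d}" for k in range(n_subjects)]
    df = pd.DataFrame(cols, index=ids, columns=list(parameters))
    if missing_blocks:
        for battery, (block_params, fraction) in missing_blocks.items():
            if not 0.0 <= fraction < 1.0:
                raise ValueError(f"missing fraction for battery {battery!r} must be in [0, 1)")
            n_missing = int(round(fraction * n_subjects))
            drop = rng.choice(n_subjects, size=n_missing, replace=False)
            df.iloc[drop, [df.columns.get_loc(p) for p in block_params]] = np.nan
    return PsychometricTable(df)


def generate_parcellation(
    shape: tuple[int, int, int], n_parcels: int
) -> np.ndarray:
    """Toy integer-labeled atlas: contiguous equal-size blocks labeled 1..P."""
    n_vox = int(np.prod(shape))
    if n_parcels < 1 or n_parcels > n_vox:
        raise ValueError("n_parcels must be between 1 and the voxel count")
    labels = 1 + (np.arange(n_vox) * n_parcels) // n_vox
    return labels.reshape(shape).astype(np.int32)


def _centered_scores(table: PsychometricTable, truth: GroundTruth, parameter: str, standardize: bool):
    s = table.scores[parameter]
    mean, sd = truth.score_model.get(parameter, (float(s.mean()), float(s.std(ddof=1))))
    z = (s.to_numpy(dtype=float) - mean) / (sd if standardize else 1.0)
    return np.nan_to_num(z, nan=0.0)  # missing score -> population-mean subject


def generate_gm_maps(
    table: PsychometricTable,
    truth: GroundTruth,
    grid: tuple[int, int, int] = (12, 12, 12),
    voxel_size_mm: float = 4.0,
    baseline: float = 0.5,
    noise_sd: float = 0.05,
    smooth_fwhm_mm: float = 8.0,
) -> GmStack:
    """Per-subject gray-matter density maps with planted score-linked foci.

    At a planted focus the density is ``baseline + beta_vbm * (score -
    model mean)`` exactly; the effect falls off as a Gaussian bump of the
    smoothing width around the focus, emulating already-smoothed (8-mm FWHM)
    modulated maps.  Noise is a smoothed Gaussian field rescaled to
    ``noise_sd``.  TBV is the map sum times the voxel volume.
    """
    shape = tuple(grid)
    for f in truth.planted_foci:
        if any(not (0 <= c < s) for c, s in zip(f.center, shape)):
            raise PlacementError(f"focus at {f.center} lies outside grid {shape}")
    rng = np.random.default_rng(truth.child_seed(1))
    sigma_vox = smooth_fwhm_mm * _FWHM_TO_SIGMA / voxel_size_mm

    bumps = []
    for f in truth.planted_foci:
        delta = np.zeros(shape)
        delta[f.center] = 1.0
        bump = gaussian_filter(delta, sigma_vox)
        bump /= bump[f.center]  # unit peak so the focus voxel carries beta exactly
        bumps.append(bump)

    centered = {
        f.parameter: _centered_scores(table, truth, f.parameter, standardize=False)
        for f in truth.planted_foci
    }
    n = table.n_subjects
    data = np.empty((n, *shape))
    for s_idx in range(n):
        vol = np.full(shape, baseline)
        for f, bump in zip(truth.planted_foci, bumps):
            vol = vol + f.beta_vbm * centered[f.parameter][s_idx] * bump
        noise = gaussian_filter(rng.standard_normal(shape), sigma_vox)
        noise *= noise_sd / noise.std()
        data[s_idx] = np.clip(vol + noise, 0.0, None)

    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = -voxel_size_mm * (np.asarray(shape) - 1) / 2.0  # center the grid
    return GmStack(subject_ids=table.subject_ids, data=data, affine=affine)


def effective_samples(
    T: int,
    tr_seconds: float,
    low_hz: float,
    high_hz: float,
    n_confounds: int = 24,
    n_sim: int = 200,
    seed: int = 987654321,
) -> float:
    """Effective sample count of a preprocessed series, by Monte Carlo.

    Bandpass filtering and nuisance regression leave a sample correlation
    with far fewer independent samples than T.  This measures the noise of
    the correlation estimate empirically: pairs of independent series are
    pushed through the actual preprocessing chain (Friston-24-shaped
    confound regression, then the Butterworth bandpass) and the variance of
    their sample correlation is inverted, ``N_eff = 1/var + 3``.  The
    result is cached per argument tuple.
    """
    key = (T, tr_seconds, low_hz, high_hz, n_confounds, n_sim, seed)
    if key in _NEFF_CACHE:
        return _NEFF_CACHE[key]
    from .connectivity import bandpass as _bp
    from .connectivity import correlation_matrix as _cm
    from .connectivity import regress_confounds as _rc

    rng = np.random.default_rng(seed)
    rs = np.empty(n_sim)
    for k in range(n_sim):
        ts = TimeSeriesMatrix("eff", rng.standard_normal((T, 2)), tr_seconds)
        if n_confounds:
            ts = _rc(ts, _friston24(rng, T)[:, :n_confounds])
        ts = _bp(ts, low_hz, high_hz)
        rs[k] = _cm(ts)[0, 1]
    neff = float(1.0 / np.var(rs) + 3.0)
    _NEFF_CACHE[key] = neff
    return neff


_NEFF_CACHE: dict = {}


def edge_effect_for_target_correlation(target_r: float, t_effective: float) -> float:
    """Edge effect size (per score z-score) giving a target edge-score correlation.

    The observed per-subject edge weight is the planted population value
    ``r0 + beta * z`` plus sampling noise of variance ~ 1/(N_eff - 3); the
    correlation between scores and observed weights is then
    ``beta / sqrt(beta^2 + 1/(N_eff - 3))``.  Inverting for beta gives the
    effect size that produces ``target_r`` at the stated effective sample
    count.
    """
    if not 0.0 < abs(target_r) < 1.0:
        raise ValueError("target correlation must lie in (0, 1) in magnitude")
    sigma = 1.0 / np.sqrt(t_effective - 3.0)
    return float(np.sign(target_r) * abs(target_r) * sigma / np.sqrt(1.0 - target_r**2))


def _nearest_correlation(C: np.ndarray, eig_floor: float = 1e-6) -> np.ndarray:
    """Project a symmetric matrix to a positive-definite correlation matrix."""
    w, V = np.linalg.eigh(C)
    if w.min() >= eig_floor:
        return C
    w = np.clip(w, eig_floor, None)
    C = (V * w) @ V.T
    d = np.sqrt(np.diag(C))
    C = C / np.outer(d, d)
    np.fill_diagonal(C, 1.0)
    return C


def _friston24(rng: np.random.Generator, T: int, phi: float = 0.95, sd: float = 0.5) -> np.ndarray:
    """Six AR(1) 'motion' series, their one-sample lags, and both sets squared."""
    from scipy.signal import lfilter

    innov = rng.standard_normal((T, 6)) * sd * np.sqrt(1 - phi**2)
    innov[0] /= np.sqrt(1 - phi**2)  # start at the stationary distribution
    motion = lfilter([1.0], [1.0, -phi], innov, axis=0)
    lag = np.vstack([np.zeros(6), motion[:-1]])
    return np.hstack([motion, lag, motion**2, lag**2])


def generate_timeseries(
    table: PsychometricTable,
    truth: GroundTruth,
    n_rois: int,
    T: int = 480,
    tr_seconds: float = 1.0,
    r0: float = 0.1,
) -> tuple[list[TimeSeriesMatrix], list[np.ndarray]]:
    """Per-subject ROI time series plus 24-column confound matrices.

    Each subject's samples are drawn i.i.d. from a multivariate normal whose
    correlation is ``r0`` everywhere off-diagonal except on planted edges,
    where it equals ``clip(r0 + beta_edge * z_score, -0.95, 0.95)``.
    Matrices made indefinite by planted edges are projected to the nearest
    positive-definite correlation (eigenvalue floor 1e-6).
    """
    if n_rois < 2:
        raise ValueError("n_rois must be >= 2")
    if T < 64:
        raise ValueError("T must be >= 64")
    for e in truth.planted_edges:
        if e.j >= n_rois:
            raise ValueError(f"planted edge ({e.i}, {e.j}) outside 0..{n_rois - 1}")
    rng = np.random.default_rng(truth.child_seed(2))
    z_by_param = {
        e.parameter: _centered_scores(table, truth, e.parameter, standardize=True)
        for e in truth.planted_edges
    }
    base = np.full((n_rois, n_rois), r0)
    np.fill_diagonal(base, 1.0)

    series, confounds = [], []
    for s_idx, sid in enumerate(table.subject_ids):
        C = base.copy()
        for e in truth.planted_edges:
            val = r0 + e.beta_edge * z_by_param[e.parameter][s_idx]
            if not -1.0 < val < 1.0:
                warnings.warn(
                    f"requested correlation {val:.3f} on edge ({e.i}, {e.j}) outside (-1, 1); clipped",
                    stacklevel=2,
                )
            C[e.i, e.j] = C[e.j, e.i] = np.clip(val, -0.95, 0.95)
        C = _nearest_correlation(C)
        L = np.linalg.cholesky(C)
        X = rng.standard_normal((T, n_rois)) @ L.T
        series.append(TimeSeriesMatrix(subject_id=sid, data=X, tr=tr_seconds))
        confounds.append(_friston24(rng, T))
    return series, confounds
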