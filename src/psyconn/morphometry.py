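"""Voxel-based morphometry regression, small-volume FWE correction and ROI definition.

Each psychometric parameter is regressed voxelwise against gray-matter
density with total brain volume (TBV) as a covariate.  Familywise error is
controlled within each atlas parcel ("gyrus") by a permutation max-|t| test:
scores are shuffled across subjects and the within-parcel maximum |t| forms
the null.  Surviving voxels seed spherical ROIs (default 5-mm diameter)
centered on the peak-|t| voxel; ROIs pooled across parameters are
deduplicated by a single forward pass that drops any sphere intersecting an
earlier-retained sphere.

The permutation small-volume correction replaces the random-field-theory
voxel-level FWE of SPM-style pipelines; it is distribution free and controls
the same familywise error within each parcel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, DegenerateDesignError, InsufficientDataError

__all__ = [
    "GmStack",
    "Roi",
    "RoiSet",
    "voxelwise_regression",
    "small_volume_fwe",
    "define_rois",
    "dedup_rois",
    "discover_rois",
]


@dataclass
class GmStack:
    """Subjects x volume stack of modulated gray-matter density maps.

    Parameters
    ----------
    subject_ids : list of str
    data : ndarray, shape (n_subjects, X, Y, Z)
        Non-negative density values.
    affine : ndarray, shape (4, 4)
        Invertible voxel-to-world (RAS/MNI millimeter) mapping.
    tbv : ndarray, shape (n_subjects,)
        Total brain value per subject: the sum of the subject's map times
        the voxel volume.
    """

    subject_ids: list[str]
    data: np.ndarray
    affine: np.ndarray
    tbv: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must have shape (n_subjects, X, Y, Z)")
        if len(self.subject_ids) != self.data.shape[0]:
            raise AlignmentError("subject_ids length does not match data")
        if not np.all(np.isfinite(self.data)) or np.any(self.data < 0):
            raise ValueError("densities must be finite and non-negative")
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")
        if self.tbv is None:
            self.tbv = self.data.reshape(self.data.shape[0], -1).sum(axis=1) * self.voxel_volume
        self.tbv = np.asarray(self.tbv, dtype=float)
        if self.tbv.shape != (self.data.shape[0],):
            raise AlignmentError("tbv must be one scalar per subject")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def volume_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))


@dataclass
class Roi:
    """A spherical region of interest around a regression peak."""

    id: int
    center: tuple[float, float, float]  # world coordinates, mm
    radius_mm: float
    parameter: str
    peak_t: float
    parcel: int

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise ValueError("radius must be positive")


@dataclass
class RoiSet:
    """Ordered ROI collection (parameter-list order, then discovery order)."""

    rois: list[Roi] = field(default_factory=list)

    def __len__(self):
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)

    def __getitem__(self, i):
        return self.rois[i]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "id": r.id,
                    "x": r.center[0],
                    "y": r.center[1],
                    "z": r.center[2],
                    "radius_mm": r.radius_mm,
                    "peak_t": r.peak_t,
                    "parameter": r.parameter,
                    "parcel": r.parcel,
                }
                for r in self.rois
            ]
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "RoiSet":
        return cls(
            [
                Roi(
                    id=int(row["id"]),
                    center=(float(row["x"]), float(row["y"]), float(row["z"])),
                    radius_mm=float(row["radius_mm"]),
                    parameter=str(row["parameter"]),
                    peak_t=float(row["peak_t"]),
                    parcel=int(row["parcel"]),
                )
                for _, row in df.iterrows()
            ]
        )


def _design(stack: GmStack, scores: pd.Series | np.ndarray):
    """Observed-subject mask, score vector and TBV covariate for a fit."""
    if isinstance(scores, pd.Series):
        s = scores.reindex(stack.subject_ids).to_numpy(dtype=float)
    else:
        s = np.asarray(scores, dtype=float)
        if s.shape != (stack.n_subjects,):
            raise AlignmentError("scores length does not match subjects")
    keep = np.isfinite(s)
    return keep, s[keep], stack.tbv[keep]


def _fit_t(Y: np.ndarray, score: np.ndarray, tbv: np.ndarray):
    """Slope t-statistics for density ~ 1 + score + tbv at every voxel.

    Y is (n, V).  Returns (t, df).  A zero-residual voxel (perfect fit)
    yields t = +/-inf.
    """
    n = score.shape[0]
    X = np.column_stack([np.ones(n), score, tbv])
    XtX_inv = np.linalg.pinv(X.T @ X)
    beta = XtX_inv @ (X.T @ Y)  # (3, V)
    resid = Y - X @ beta
    df = n - 3
    ss_res = np.einsum("ij,ij->j", resid, resid)
    ss_tot = np.einsum("ij,ij->j", Y - Y.mean(axis=0), Y - Y.mean(axis=0))
    # zero-residual voxels (perfect linear fit) up to float rounding
    perfect = ss_res <= 1e-12 * np.maximum(ss_tot, np.finfo(float).tiny)
    sigma2 = ss_res / df
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sigma2 * XtX_inv[1, 1])
        t = np.where(se > 0, beta[1] / np.where(se > 0, se, 1.0), np.sign(beta[1]) * np.inf)
    t = np.where(perfect, np.sign(beta[1]) * np.inf, t)
    t = np.where(np.isnan(t), 0.0, t)
    return t, df


def voxelwise_regression(
    stack: GmStack, scores: pd.Series | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise t and two-sided p volumes for one psychometric parameter.

    At each voxel the t-statistic is the score-slope t from the linear model
    ``density ~ intercept + score + tbv`` with n - 3 degrees of freedom.
    Subjects with a missing score are dropped.

    Returns
    -------
    t_volume, p_volume : ndarray
        Same spatial shape as the stack's volumes.
    """
    keep, s, tbv = _design(stack, scores)
    n = int(keep.sum())
    if n <= 3:
        raise InsufficientDataError(f"need more than 3 subjects with scores, got {n}")
    if np.ptp(s) == 0:
        raise DegenerateDesignError("score column is constant")
    shape = stack.volume_shape
    Y = stack.data[keep].reshape(n, -1)
    t, df = _fit_t(Y, s, tbv)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isinf(t), 0.0, p)
    return t.reshape(shape), p.reshape(shape)


def small_volume_fwe(
    t_volume: np.ndarray,
    p_volume: np.ndarray,
    parcellation: np.ndarray,
    stack: GmStack,
    scores: pd.Series | np.ndarray,
    n_perm: int = 1000,
    alpha_fwe: float = 0.05,
    alpha_unc: float = 0.001,
    seed: int | np.random.Generator = 0,
) -> dict[int, np.ndarray]:
    """Per-parcel small-volume FWE correction by permutation max-|t|.

    For each of ``n_perm`` permutations the score vector is shuffled across
    subjects and the voxelwise regression re-fit; the within-parcel maximum
    |t| forms the parcel's null distribution.  A voxel survives iff its
    uncorrected p <= ``alpha_unc`` AND its |t| exceeds the (1 - alpha_fwe)
    quantile of that null.

    Returns
    -------
    dict mapping parcel id -> boolean significance mask (volume shape).
    Parcels with fewer than 2 voxels are skipped with a warning.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    parcellation = np.asarray(parcellation)
    if parcellation.shape != stack.volume_shape:
        raise AlignmentError("parcellation grid does not match the density grid")
    rng = np.random.default_rng(seed)
    keep, s, tbv = _design(stack, scores)
    n = int(keep.sum())
    if n <= 3:
        raise InsufficientDataError(f"need more than 3 subjects with scores, got {n}")
    Y = stack.data[keep].reshape(n, -1)

    flat_parcel = parcellation.reshape(-1)
    parcel_ids = [int(pid) for pid in np.unique(flat_parcel) if pid > 0]
    voxels_by_parcel = {}
    for pid in parcel_ids:
        idx = np.flatnonzero(flat_parcel == pid)
        if idx.size < 2:
            warnings.warn(f"parcel {pid} has fewer than 2 voxels; skipped", stacklevel=2)
            continue
        voxels_by_parcel[pid] = idx

    max_t = np.zeros((n_perm, len(voxels_by_parcel)))
    cols = list(voxels_by_parcel)
    for b in range(n_perm):
        sp = rng.permutation(s)
        t_perm, _ = _fit_t(Y, sp, tbv)
        abs_t = np.abs(t_perm)
        for j, pid in enumerate(cols):
            max_t[b, j] = abs_t[voxels_by_parcel[pid]].max()

    abs_obs = np.abs(t_volume.reshape(-1))
    p_flat = p_volume.reshape(-1)
    masks = {}
    for j, pid in enumerate(cols):
        # alpha_fwe >= 1 disables the permutation criterion entirely
        thresh = -np.inf if alpha_fwe >= 1.0 else np.quantile(max_t[:, j], 1.0 - alpha_fwe, method="higher")
        mask = np.zeros(flat_parcel.shape, dtype=bool)
        idx = voxels_by_parcel[pid]
        mask[idx] = (p_flat[idx] <= alpha_unc) & (abs_obs[idx] > thresh)
        masks[pid] = mask.reshape(stack.volume_shape)
    return masks


def _peak_voxel(abs_t: np.ndarray, mask: np.ndarray) -> tuple[int, int, int]:
    """Max-|t| voxel in a mask; ties broken by smallest x-fastest linear index."""
    vals = np.where(mask, abs_t, -np.inf)
    flat = vals.flatten(order="F")  # x varies fastest
    k = int(np.argmax(flat))
    return tuple(int(c) for c in np.unravel_index(k, abs_t.shape, order="F"))


def define_rois(
    masks: Mapping[tuple[str, int], np.ndarray],
    t_volumes: Mapping[str, np.ndarray],
    affine: np.ndarray,
    diameter_mm: float = 5.0,
) -> RoiSet:
    """One spherical ROI per (parameter, parcel) significance mask.

    Each ROI is centered on the world coordinate of the mask's max-|t| voxel
    with radius ``diameter_mm / 2``.  Input order (parameter, then parcel
    discovery order) is preserved, which the deduplication pass relies on.
    """
    rois = []
    for k, ((param, parcel), mask) in enumerate(masks.items(), start=1):
        if not mask.any():
            raise ValueError(f"empty mask for ({param}, parcel {parcel})")
        t_vol = t_volumes[param]
        ijk = _peak_voxel(np.abs(t_vol), mask)
        world = (np.asarray(affine) @ np.array([*ijk, 1.0]))[:3]
        rois.append(
            Roi(
                id=k,
                center=tuple(float(c) for c in world),
                radius_mm=diameter_mm / 2.0,
                parameter=param,
                peak_t=float(t_vol[ijk]),
                parcel=int(parcel),
            )
        )
    return RoiSet(rois)


def dedup_rois(rois: RoiSet) -> RoiSet:
    """Drop ROIs whose sphere intersects an earlier-retained ROI's sphere.

    A single forward pass in parameter-list order: an ROI is retained iff
    its center is at distance >= (sum of radii) from every already-retained
    center.  Retained ROIs are renumbered 1..R preserving order, so the
    operation is idempotent and never reorders survivors.
    """
    kept: list[Roi] = []
    for roi in rois:
        c = np.asarray(roi.center)
        overlaps = any(
            np.linalg.norm(c - np.asarray(k.center)) < roi.radius_mm + k.radius_mm
            for k in kept
        )
        if not overlaps:
            kept.append(roi)
    return RoiSet(
        [
            Roi(
                id=i,
                center=r.center,
                radius_mm=r.radius_mm,
                parameter=r.parameter,
                peak_t=r.peak_t,
                parcel=r.parcel,
            )
            for i, r in enumerate(kept, start=1)
        ]
    )


def discover_rois(
    stack: GmStack,
    scores: pd.DataFrame,
    parcellation: np.ndarray,
    parameters: Sequence[str] | None = None,
    n_perm: int = 1000,
    alpha_fwe: float = 0.05,
    alpha_unc: float = 0.001,
    diameter_mm: float = 5.0,
    seed: int = 0,
) -> tuple[RoiSet, RoiSet]:
    """Full morphometry stage: regression, small-volume FWE, ROIs, dedup.

    Iterates the parameter columns in list order, pools one ROI per
    significant (parameter, parcel) pair, and deduplicates overlapping
    spheres.

    Returns
    -------
    (deduplicated RoiSet, pre-dedup RoiSet)
    """
    parameters = list(parameters) if parameters is not None else list(scores.columns)
    masks: dict[tuple[str, int], np.ndarray] = {}
    t_volumes: dict[str, np.ndarray] = {}
    rng = np.random.default_rng(seed)
    for param in parameters:
        col = scores[param]
        t_vol, p_vol = voxelwise_regression(stack, col)
        t_volumes[param] = t_vol
        parcel_masks = small_volume_fwe(
            t_vol,
            p_vol,
            parcellation,
            stack,
            col,
            n_perm=n_perm,
            alpha_fwe=alpha_fwe,
            alpha_unc=alpha_unc,
            seed=rng,
        )
        for pid in sorted(parcel_masks):
            if parcel_masks[pid].any():
                masks[(param, pid)] = parcel_masks[pid]
    if not masks:
        return RoiSet([]), RoiSet([])
    pooled = define_rois(masks, t_volumes, stack.affine, diameter_mm=diameter_mm)
    return dedup_rois(pooled), pooled
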