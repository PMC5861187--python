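"""Edge-wise regression and network-based statistic (NBS) permutation inference.

For one psychometric parameter, every unordered ROI pair's correlation is
regressed on the score (simple regression; the slope t is equivalent to the
score-edge Pearson correlation t with n - 2 degrees of freedom).  Edges
surviving a primary threshold (default p < 0.005, two-sided on |t|) form a
supra-threshold graph whose connected components are the candidate
networks.  Familywise error over components is controlled by permuting the
score vector across subjects and recording the maximum component edge count
under the null; the component-level FWE p-value uses the add-one
permutation convention.

:func:`target_edge_count` additionally tunes the primary threshold by
bisection so that the largest significant component carries as close to a
target number of edges (default 15) as possible, never splitting a network
that is already at or below the target at the loosest threshold.

Edge indexing convention: the R(R-1)/2 unordered edges are enumerated in
upper-triangle row-major order, i.e. (0,1), (0,2), ..., (0,R-1), (1,2), ...
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .connectivity import ConnectivityStack
from .errors import DegenerateDesignError, InsufficientDataError

__all__ = [
    "EdgeStatMap",
    "NetworkComponent",
    "edge_regression",
    "extract_components",
    "nbs_fwe",
    "target_edge_count",
    "edge_index_pairs",
]

_TINY_P = np.nextafter(0.0, 1.0)


def edge_index_pairs(n_rois: int) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle row-major edge enumeration (the package-wide convention)."""
    return np.triu_indices(n_rois, k=1)


@dataclass
class EdgeStatMap:
    """Per-edge t and two-sided p for one parameter's edge-wise regression."""

    roi_ids: Sequence[int]
    t: np.ndarray  # (E,) upper-triangle row-major
    p: np.ndarray  # (E,) in (0, 1]
    n_effective: int

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        n_edges = len(self.roi_ids) * (len(self.roi_ids) - 1) // 2
        if self.t.shape != (n_edges,) or self.p.shape != (n_edges,):
            raise ValueError("t and p must cover all R(R-1)/2 edges")


@dataclass
class NetworkComponent:
    """A connected set of supra-threshold edges tied to one parameter."""

    parameter: str
    edges: list[tuple[int, int]]  # ROI id pairs
    edge_t: np.ndarray
    fwe_p: float | None = None
    primary_p: float | None = None
    n_perm: int | None = None
    edge_indices: list[int] = field(default_factory=list)  # upper-tri positions

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def nodes(self) -> list[int]:
        return sorted({n for e in self.edges for n in e})


def _edge_vectors(stack: ConnectivityStack) -> np.ndarray:
    iu, ju = edge_index_pairs(stack.n_rois)
    return stack.matrices[:, iu, ju]


def _align_scores(stack: ConnectivityStack, scores) -> np.ndarray:
    if isinstance(scores, pd.Series):
        return scores.reindex(stack.subject_ids).to_numpy(dtype=float)
    s = np.asarray(scores, dtype=float)
    if s.shape != (stack.n_subjects,):
        raise ValueError("scores length does not match subjects")
    return s


def _edge_t_from_r(r: np.ndarray, df: int) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / np.clip(1.0 - r**2, 0.0, None))
    # |r| at 1 up to float rounding marks a perfect (zero-residual) fit
    t = np.where(1.0 - r**2 <= 1e-12, np.sign(r) * np.inf, t)
    return np.where(np.isnan(t), 0.0, t)


def edge_regression(stack: ConnectivityStack, scores) -> EdgeStatMap:
    """Simple regression of every edge weight on the score.

    Subjects with a missing score are dropped (recorded in
    ``n_effective``).  The slope t-statistic with n - 2 degrees of freedom
    is computed through the equivalent correlation form
    ``t = r * sqrt(df / (1 - r^2))``; p is two-sided.
    """
    s = _align_scores(stack, scores)
    keep = np.isfinite(s)
    n = int(keep.sum())
    if n < 4:
        raise InsufficientDataError(f"need >= 4 subjects with scores, got {n}")
    s = s[keep]
    if np.ptp(s) == 0:
        raise DegenerateDesignError("score column is constant")
    E = _edge_vectors(stack)[keep]
    sc = s - s.mean()
    Ec = E - E.mean(axis=0)
    denom = np.linalg.norm(sc) * np.linalg.norm(Ec, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (sc @ Ec) / np.where(denom > 0, denom, 1.0), 0.0)
    df = n - 2
    t = _edge_t_from_r(r, df)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, _TINY_P, 1.0)
    return EdgeStatMap(roi_ids=list(stack.roi_ids), t=t, p=p, n_effective=n)


def _component_labels(n_rois: int, supra: np.ndarray):
    """Connected-component labels of the supra-threshold graph and edge partition."""
    iu, ju = edge_index_pairs(n_rois)
    ei, ej = iu[supra], ju[supra]
    adj = coo_matrix((np.ones(ei.size), (ei, ej)), shape=(n_rois, n_rois))
    _, labels = connected_components(adj, directed=False)
    return labels, ei, ej


def _max_component_size(n_rois: int, supra: np.ndarray) -> int:
    if not supra.any():
        return 0
    labels, ei, _ = _component_labels(n_rois, supra)
    return int(np.bincount(labels[ei]).max())


def extract_components(
    stats_map: EdgeStatMap, primary_p: float, parameter: str = ""
) -> list[NetworkComponent]:
    """Partition supra-threshold edges (p < primary_p) into connected components.

    Positive- and negative-t edges are thresholded jointly on |t| (two-sided
    p) and may share a component.  Components are returned largest first;
    every supra-threshold edge appears in exactly one component.
    """
    if not 0.0 < primary_p < 1.0:
        raise ValueError("primary_p must be in (0, 1)")
    n_rois = len(stats_map.roi_ids)
    supra = stats_map.p < primary_p
    if not supra.any():
        return []
    labels, ei, ej = _component_labels(n_rois, supra)
    edge_pos = np.flatnonzero(supra)
    comp_of_edge = labels[ei]
    comps = []
    roi_ids = list(stats_map.roi_ids)
    for lab in np.unique(comp_of_edge):
        sel = comp_of_edge == lab
        idx = edge_pos[sel]
        comps.append(
            NetworkComponent(
                parameter=parameter,
                edges=[(roi_ids[a], roi_ids[b]) for a, b in zip(ei[sel], ej[sel])],
                edge_t=stats_map.t[idx],
                primary_p=primary_p,
                edge_indices=[int(k) for k in idx],
            )
        )
    comps.sort(key=lambda c: -c.n_edges)
    return comps


def _null_max_sizes(
    E: np.ndarray, s: np.ndarray, n_rois: int, r_crit: float, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Permutation distribution of the maximum component edge count.

    Permutes the score vector across subjects (breaking the subject link,
    the same null as shuffling the correlation matrices) and re-runs the
    edge regression + component extraction.
    """
    sc = s - s.mean()
    Ec = E - E.mean(axis=0)
    e_norm = np.linalg.norm(Ec, axis=0)
    s_norm = np.linalg.norm(sc)
    denom = s_norm * e_norm
    safe = denom > 0
    out = np.zeros(n_perm, dtype=int)
    for b in range(n_perm):
        sp = rng.permutation(sc)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(safe, (sp @ Ec) / np.where(safe, denom, 1.0), 0.0)
        out[b] = _max_component_size(n_rois, np.abs(r) > r_crit)
    return out


def nbs_fwe(
    stack: ConnectivityStack,
    scores,
    primary_p: float = 0.005,
    n_perm: int = 5000,
    seed: int = 0,
    parameter: str = "",
    alpha: float = 0.05,
) -> list[NetworkComponent]:
    """NBS familywise-error correction over supra-threshold components.

    Each observed component's FWE p-value is
    ``(1 + #{permutation max size >= observed size}) / (n_perm + 1)``;
    components with FWE p <= ``alpha`` are significant.  All observed
    components are returned with their p-values so callers can filter.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    stats_map = edge_regression(stack, scores)
    comps = extract_components(stats_map, primary_p, parameter=parameter)
    for c in comps:
        c.n_perm = n_perm
    if not comps:
        return []
    s = _align_scores(stack, scores)
    keep = np.isfinite(s)
    E = _edge_vectors(stack)[keep]
    s = s[keep]
    df = stats_map.n_effective - 2
    t_crit = stats.t.isf(primary_p / 2.0, df)
    r_crit = t_crit / np.sqrt(df + t_crit**2)
    rng = np.random.default_rng(seed)
    null_max = _null_max_sizes(E, s, stack.n_rois, r_crit, n_perm, rng)
    for c in comps:
        c.fwe_p = float((1 + np.sum(null_max >= c.n_edges)) / (n_perm + 1))
    return comps


def target_edge_count(
    stack: ConnectivityStack,
    scores,
    target: int = 15,
    p_floor: float = 1e-6,
    p_ceiling: float = 0.005,
    n_perm: int = 5000,
    seed: int = 0,
    parameter: str = "",
    alpha: float = 0.05,
    max_iter: int = 30,
) -> NetworkComponent | None:
    """Tighten the primary threshold until the network is near the target size.

    The loosest threshold ``p_ceiling`` is evaluated first: if nothing is
    significant there the result is ``None``; if the largest significant
    component already has at most ``target`` edges it is returned unchanged
    (a network smaller than the target is never inflated).  Otherwise a
    log-scale bisection over primary thresholds in ``[p_floor, p_ceiling]``
    minimizes the absolute distance between the largest significant
    component's edge count and the target, breaking ties toward the smaller
    (stricter) threshold.  The same permutation stream (fixed seed) is used
    at every threshold so sizes shrink monotonically as the threshold
    tightens.
    """
    if not p_floor < p_ceiling:
        raise ValueError("p_floor must be below p_ceiling")

    def largest_significant(primary: float) -> NetworkComponent | None:
        comps = nbs_fwe(
            stack, scores, primary_p=primary, n_perm=n_perm, seed=seed,
            parameter=parameter, alpha=alpha,
        )
        sig = [c for c in comps if c.fwe_p is not None and c.fwe_p <= alpha]
        return max(sig, key=lambda c: c.n_edges) if sig else None

    at_ceiling = largest_significant(p_ceiling)
    if at_ceiling is None:
        return None
    if at_ceiling.n_edges <= target:
        return at_ceiling

    best = (abs(at_ceiling.n_edges - target), p_ceiling, at_ceiling)
    lo, hi = np.log(p_floor), np.log(p_ceiling)
    for _ in range(max_iter):
        mid = (lo + hi) / 2.0
        primary = float(np.exp(mid))
        comp = largest_significant(primary)
        size = comp.n_edges if comp is not None else 0
        if comp is not None:
            cand = (abs(size - target), primary, comp)
            # ties toward the smaller threshold
            if cand[0] < best[0] or (cand[0] == best[0] and primary < best[1]):
                best = cand
        if size > target:
            hi = mid
        elif size < target:
            lo = mid
        else:
            break
    return best[2]
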