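"""Edge-wise regression and NBS permutation inference on controlled fixtures."""

import numpy as np
import pytest

from psyconn.errors import DegenerateDesignError, InsufficientDataError
from psyconn.nbs import (
    EdgeStatMap,
    edge_index_pairs,
    edge_regression,
    extract_components,
    nbs_fwe,
    target_edge_count,
)

from conftest import make_stack_from_edges


# six subjects, three ROIs: edge weights chosen by hand so the simple
# regression t can be recomputed from the closed-form slope/SE formula
FIX_SCORES = np.array([42.0, 55.0, 48.0, 61.0, 50.0, 58.0])
FIX_EDGES = np.array(
    [
        [0.10, 0.30, -0.05],
        [0.22, 0.28, 0.01],
        [0.15, 0.33, -0.02],
        [0.35, 0.25, 0.04],
        [0.18, 0.31, 0.00],
        [0.30, 0.27, 0.03],
    ]
)


def _closed_form_t(x, y):
    n = len(x)
    b = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
    a = y.mean() - b * x.mean()
    resid = y - a - b * x
    se = np.sqrt(resid @ resid / (n - 2) / ((n - 1) * np.var(x, ddof=1)))
    return b / se


def test_edge_t_matches_hand_computed_simple_regression(scores_series):
    stack = make_stack_from_edges(FIX_EDGES, n_rois=3)
    out = edge_regression(stack, scores_series(FIX_SCORES))
    for e in range(3):
        expected = _closed_form_t(FIX_SCORES, FIX_EDGES[:, e])
        assert out.t[e] == pytest.approx(expected, abs=1e-10)
    assert out.n_effective == 6


def test_edge_t_matches_statsmodels_on_random_fixtures(rng):
    import statsmodels.api as sm

    for _ in range(20):
        n = int(rng.integers(8, 30))
        E = rng.uniform(-0.8, 0.8, (n, 6))
        s = rng.normal(60, 10, n)
        stack = make_stack_from_edges(E, n_rois=4)
        out = edge_regression(stack, s)
        for e in range(6):
            fit = sm.OLS(E[:, e], sm.add_constant(s)).fit()
            assert out.t[e] == pytest.approx(fit.tvalues[1], abs=1e-8)
            assert out.p[e] == pytest.approx(fit.pvalues[1], abs=1e-8)


def test_missing_scores_dropped_and_counted(scores_series):
    s = scores_series(np.r_[FIX_SCORES, np.nan, np.nan], ids=[f"sub-{k:03d}" for k in range(8)])
    E = np.vstack([FIX_EDGES, [[0.5, 0.5, 0.5]] * 2])
    stack = make_stack_from_edges(E, n_rois=3, subject_ids=list(s.index))
    out = edge_regression(stack, s)
    assert out.n_effective == 6
    assert out.t[0] == pytest.approx(_closed_form_t(FIX_SCORES, FIX_EDGES[:, 0]), abs=1e-10)


def test_edge_exactly_linear_in_score_flagged(rng):
    s = rng.normal(60, 10, 10)
    E = rng.uniform(-0.5, 0.5, (10, 3))
    E[:, 1] = 0.002 * (s - 60)  # deterministic edge
    out = edge_regression(make_stack_from_edges(E, 3), s)
    assert np.isinf(out.t[1])
    assert 0 < out.p[1] <= 1e-300  # add-one floor keeps p in (0, 1]


def test_degenerate_inputs_rejected(rng):
    with pytest.raises(DegenerateDesignError):
        edge_regression(make_stack_from_edges(rng.uniform(-0.5, 0.5, (8, 3)), 3), np.full(8, 5.0))
    with pytest.raises(InsufficientDataError):
        edge_regression(make_stack_from_edges(rng.uniform(-0.5, 0.5, (3, 3)), 3), np.arange(3.0))


# ---------------------------------------------------------------------------
# component extraction


def _stat_map(n_rois, sig_pairs):
    iu, ju = edge_index_pairs(n_rois)
    p = np.ones(iu.size)
    t = np.zeros(iu.size)
    for a, b in sig_pairs:
        k = int(np.flatnonzero((iu == a) & (ju == b))[0])
        p[k] = 1e-6
        t[k] = 5.0
    return EdgeStatMap(roi_ids=list(range(1, n_rois + 1)), t=t, p=p, n_effective=50)


def test_components_match_networkx_oracle():
    import networkx as nx

    path = [(i, i + 1) for i in range(10)]  # 10-edge path over ROIs 0..10
    isolated = [(12, 13)]
    sm = _stat_map(15, path + isolated)
    comps = extract_components(sm, 0.005)
    assert sorted(c.n_edges for c in comps) == [1, 10]
    g = nx.Graph([(i + 1, j + 1) for i, j in path + isolated])
    oracle = sorted(len(c) for c in nx.connected_components(g))
    assert sorted(len(c.nodes) for c in comps) == oracle


def test_fully_suprathreshold_graph_is_one_complete_component():
    n = 6
    iu, ju = edge_index_pairs(n)
    sm = _stat_map(n, list(zip(iu, ju)))
    comps = extract_components(sm, 0.005)
    assert len(comps) == 1
    assert comps[0].n_edges == n * (n - 1) // 2


def test_no_suprathreshold_edges_empty_list():
    assert extract_components(_stat_map(5, []), 0.005) == []


def test_every_supra_edge_in_exactly_one_component(rng):
    iu, ju = edge_index_pairs(12)
    t = rng.standard_normal(iu.size) * 3
    from scipy import stats as st

    p = 2 * st.t.sf(np.abs(t), 40)
    sm = EdgeStatMap(roi_ids=list(range(1, 13)), t=t, p=p, n_effective=42)
    comps = extract_components(sm, 0.1)
    all_idx = sorted(i for c in comps for i in c.edge_indices)
    assert all_idx == sorted(np.flatnonzero(p < 0.1))


# ---------------------------------------------------------------------------
# permutation FWE


def _planted_stack(rng, n=60, n_rois=12, n_edges=10, beta=0.05, noise=0.03):
    s = rng.normal(60, 10, n)
    z = (s - s.mean()) / s.std()
    iu, ju = edge_index_pairs(n_rois)
    E = rng.normal(0.1, noise, (n, iu.size))
    planted = []
    for k in range(n_edges):
        a, b = 0, k + 1
        idx = int(np.flatnonzero((iu == a) & (ju == b))[0])
        E[:, idx] += beta * z
        planted.append((a + 1, b + 1))  # ROI ids are 1-based
    return make_stack_from_edges(E, n_rois), s, planted


def test_observed_size_above_all_permutations_hits_floor(rng):
    # independent per-edge noise keeps any single lucky permutation from
    # reassembling the whole 10-edge component, so the observed size
    # exceeds every permuted maximum and the p-value sits at the add-one floor
    stack, s, _ = _planted_stack(rng, n=100, beta=0.15, noise=0.05)
    comps = nbs_fwe(stack, s, n_perm=100, seed=0)
    assert comps[0].fwe_p == pytest.approx(1 / 101)


def test_fwe_p_monotone_in_component_size(rng):
    stack, s, _ = _planted_stack(rng, beta=0.06, noise=0.05)
    comps = nbs_fwe(stack, s, primary_p=0.05, n_perm=200, seed=1)
    sizes = [c.n_edges for c in comps]
    ps = [c.fwe_p for c in comps]
    for (s1, p1), (s2, p2) in zip(zip(sizes, ps), zip(sizes[1:], ps[1:])):
        assert s1 >= s2 and p1 <= p2


def test_fixed_seed_reproduces_fwe_pvalues(rng):
    stack, s, _ = _planted_stack(rng)
    a = nbs_fwe(stack, s, n_perm=200, seed=7)
    b = nbs_fwe(stack, s, n_perm=200, seed=7)
    assert [c.fwe_p for c in a] == [c.fwe_p for c in b]


def test_planted_component_recovered(rng):
    stack, s, planted = _planted_stack(rng, beta=0.1, noise=0.03)
    comps = nbs_fwe(stack, s, n_perm=200, seed=3)
    sig = [c for c in comps if c.fwe_p <= 0.05]
    assert sig
    got = {tuple(sorted(e)) for e in sig[0].edges}
    want = {tuple(sorted(e)) for e in planted}
    jac = len(got & want) / len(got | want)
    assert jac >= 0.5


# ---------------------------------------------------------------------------
# edge-count targeting


def _graded_stack(rng, n=80, n_rois=12, sizes=(40,), beta_hi=0.12, beta_lo=0.02):
    """A connected planted network of 40 edges with graded effect sizes, so
    tightening the primary threshold shrinks the surviving component."""
    s = rng.normal(60, 10, n)
    z = (s - s.mean()) / s.std()
    iu, ju = edge_index_pairs(n_rois)
    E = rng.normal(0.1, 0.03, (n, iu.size))
    # star-plus-ring so any edge subset including the hub stays connected
    edges = [(0, k) for k in range(1, n_rois)] + [
        (a, b) for a in range(1, n_rois) for b in range(a + 1, n_rois)
    ]
    edges = edges[:40]
    betas = np.linspace(beta_hi, beta_lo, len(edges))
    for (a, b), beta in zip(edges, betas):
        idx = int(np.flatnonzero((iu == min(a, b)) & (ju == max(a, b)))[0])
        E[:, idx] += beta * z
    return make_stack_from_edges(E, n_rois), s


def test_target_matches_grid_scan_oracle(rng):
    stack, s = _graded_stack(rng)
    comp = target_edge_count(stack, s, target=15, n_perm=200, seed=5)
    assert comp is not None

    # oracle: scan 50 thresholds, keep the size closest to 15 among
    # significant largest components (ties toward the stricter threshold)
    best = None
    for primary in np.geomspace(1e-6, 0.005, 50)[::-1]:
        comps = nbs_fwe(stack, s, primary_p=float(primary), n_perm=200, seed=5)
        sig = [c for c in comps if c.fwe_p <= 0.05]
        if not sig:
            continue
        size = max(c.n_edges for c in sig)
        if best is None or abs(size - 15) <= abs(best - 15):
            best = size
    assert abs(comp.n_edges - 15) <= abs(best - 15)


def test_small_network_returned_unchanged_at_loosest_threshold(rng):
    stack, s, _ = _planted_stack(rng, n_edges=8, beta=0.12, noise=0.03)
    comp = target_edge_count(stack, s, target=15, n_perm=200, seed=2)
    assert comp is not None
    assert comp.n_edges <= 15
    assert comp.primary_p == pytest.approx(0.005)


def test_null_data_yields_none(rng):
    E = rng.normal(0.1, 0.03, (60, 66))
    s = rng.normal(60, 10, 60)
    assert target_edge_count(make_stack_from_edges(E, 12), s, n_perm=200, seed=0) is None
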