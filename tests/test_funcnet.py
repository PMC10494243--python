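import itertools

import networkx as nx
import numpy as np
import pytest

from isletnet import (
    CleanTraceSet,
    CorrelationMatrix,
    IsletConfig,
    apply_threshold,
    correlation_matrix,
    generate_islet,
    glucose_control_protocol,
    network_metrics,
    preprocess_traces,
    threshold_for_degree,
)
from isletnet.funcnet import community_labels


def _clean_from_matrix(X, fs=10.0):
    n = X.shape[1]
    from isletnet import Protocol, Segment

    prot = Protocol([Segment("x", 0.0, X.shape[0] / fs + 1)])
    return CleanTraceSet(
        f_norm=X, f_filt=X, fs=fs, t0=0.0, positions=np.zeros((n, 2)),
        cell_ids=[f"c{i}" for i in range(n)], islet_id="test", protocol=prot,
        band=(0.02, 1.5),
    )


def _corr_from_offdiag(vals, n):
    R = np.eye(n)
    iu = np.triu_indices(n, 1)
    R[iu] = vals
    R[(iu[1], iu[0])] = vals
    return CorrelationMatrix(R=R, interval=(0.0, 60.0), cell_ids=[str(i) for i in range(n)])


# ------------------------------------------------------------ correlation

def test_identical_traces_have_unit_correlation():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(1000)
    clean = _clean_from_matrix(np.column_stack([x, x, x]))
    corr = correlation_matrix(clean, (0.0, 100.0))
    off = corr.offdiag_values()
    np.testing.assert_allclose(off, 1.0, rtol=1e-12)


def test_independent_noise_has_small_correlation():
    rng = np.random.default_rng(1)
    n_samp = 4000
    clean = _clean_from_matrix(rng.standard_normal((n_samp, 10)))
    corr = correlation_matrix(clean, (0.0, 400.0))
    assert np.abs(corr.offdiag_values()).max() <= 3.0 / np.sqrt(n_samp) * 2


def test_zero_variance_cell_is_flagged_not_correlated():
    rng = np.random.default_rng(2)
    X = rng.standard_normal((1000, 4))
    X[:, 2] = 5.0
    corr = correlation_matrix(_clean_from_matrix(X), (0.0, 100.0))
    assert np.isnan(corr.R[2, 0]) and np.isnan(corr.R[0, 2])
    assert corr.offdiag_values().size == 3  # pairs among the 3 live cells


def test_interval_too_short_rejected():
    clean = _clean_from_matrix(np.random.default_rng(0).standard_normal((1000, 3)))
    with pytest.raises(ValueError):
        correlation_matrix(clean, (0.0, 10.0))


# ------------------------------------------------------------ thresholding

def test_four_cell_worked_example():
    corr = _corr_from_offdiag([0.9, 0.8, 0.7, 0.6, 0.5, 0.4], 4)
    r_th, k = threshold_for_degree(corr, 2.0)
    assert r_th == pytest.approx(0.6)
    assert k == pytest.approx(2.0)
    net = apply_threshold(corr, r_th)
    assert net.graph.number_of_edges() == 4


def test_saturated_matrix_gives_complete_graph():
    n = 6
    corr = _corr_from_offdiag(np.ones(n * (n - 1) // 2), n)
    r_th, k = threshold_for_degree(corr, n - 1.0)
    net = apply_threshold(corr, r_th)
    assert net.graph.number_of_edges() == n * (n - 1) // 2
    assert k == pytest.approx(n - 1.0)


def _exhaustive_threshold(R, k_target):
    """Independent oracle: try every off-diagonal value as the threshold."""
    n = R.shape[0]
    iu = np.triu_indices(n, 1)
    vals = R[iu]
    vals = vals[np.isfinite(vals)]
    best = None
    for t in np.unique(vals):
        k = 2.0 * np.sum(vals >= t) / n
        dist = abs(k - k_target)
        if best is None or dist < best[0] - 1e-12 or (
            abs(dist - best[0]) <= 1e-12 and t > best[1]
        ):
            best = (dist, t, k)
    return best[1], best[2]


def test_threshold_search_matches_exhaustive_oracle():
    rng = np.random.default_rng(0)
    for _ in range(500):
        n = int(rng.integers(4, 25))
        M = rng.standard_normal((n, 40))
        R = np.corrcoef(M)
        corr = CorrelationMatrix(R=R, interval=(0.0, 60.0),
                                 cell_ids=[str(i) for i in range(n)])
        k_target = float(rng.uniform(0.5, n - 1.5))
        got = threshold_for_degree(corr, k_target)
        want = _exhaustive_threshold(R, k_target)
        assert got[0] == pytest.approx(want[0], abs=1e-12)
        assert got[1] == pytest.approx(want[1], abs=1e-12)


def test_realized_degree_is_monotone_in_threshold():
    rng = np.random.default_rng(5)
    R = np.corrcoef(rng.standard_normal((30, 60)))
    corr = CorrelationMatrix(R=R, interval=(0.0, 60.0),
                             cell_ids=[str(i) for i in range(30)])
    ks = []
    for t in np.linspace(-1, 1, 41):
        net = apply_threshold(corr, t)
        ks.append(net.avg_degree)
    assert all(a >= b for a, b in zip(ks, ks[1:]))


def test_unreachable_degree_target_rejected():
    corr = _corr_from_offdiag([0.9, 0.8, 0.7, 0.6, 0.5, 0.4], 4)
    with pytest.raises(ValueError):
        threshold_for_degree(corr, 3.5)
    with pytest.raises(ValueError):
        threshold_for_degree(corr, 0.0)


def test_threshold_above_range_gives_empty_graph():
    corr = _corr_from_offdiag([0.9, 0.8, 0.7, 0.6, 0.5, 0.4], 4)
    net = apply_threshold(corr, 1.0 + 1e-9)
    assert net.graph.number_of_edges() == 0
    net2 = apply_threshold(corr, 0.0)
    assert net2.graph.number_of_edges() == 6


# ---------------------------------------------------------------- metrics

def test_two_disjoint_cliques_modularity_and_component():
    R = np.full((8, 8), -0.5)
    for block in (slice(0, 4), slice(4, 8)):
        R[block, block] = 0.9
    np.fill_diagonal(R, 1.0)
    corr = CorrelationMatrix(R=R, interval=(0.0, 60.0),
                             cell_ids=[str(i) for i in range(8)])
    net = apply_threshold(corr, 0.5)
    m = network_metrics(net, corr)
    # closed form: Q = sum_c (e_c/m - (d_c/2m)^2) = 2 * (0.5 - 0.25)
    assert m.modularity == pytest.approx(0.5)
    assert m.relative_largest_component == pytest.approx(0.5)
    assert m.n_communities == 2


def test_complete_graph_has_zero_modularity_and_full_component():
    n = 6
    corr = _corr_from_offdiag(np.ones(n * (n - 1) // 2), n)
    net = apply_threshold(corr, 0.5)
    m = network_metrics(net, corr)
    assert m.modularity == pytest.approx(0.0, abs=1e-12)
    assert m.relative_largest_component == 1.0


def test_empty_graph_metrics():
    n = 5
    corr = _corr_from_offdiag(np.full(n * (n - 1) // 2, 0.1), n)
    net = apply_threshold(corr, 0.99)
    m = network_metrics(net, corr)
    assert m.avg_degree == 0.0
    assert m.modularity == 0.0  # singleton partition by convention
    assert m.relative_largest_component == pytest.approx(1.0 / n)


def test_optimized_modularity_bounded_on_graph_suite():
    rng = np.random.default_rng(7)
    graphs = []
    for i in range(40):  # random graphs of varying density
        n = int(rng.integers(5, 30))
        p = float(rng.uniform(0.05, 0.9))
        graphs.append(nx.gnp_random_graph(n, p, seed=int(rng.integers(1 << 30))))
    for k in range(2, 7):  # structured: cliques, stars, cycles, grids
        graphs.append(nx.complete_graph(k * 3))
        graphs.append(nx.star_graph(k * 4))
        graphs.append(nx.cycle_graph(k * 5))
    assert len(graphs) >= 50
    for g in graphs:
        n = g.number_of_nodes()
        R = np.zeros((n, n))
        for i, j in g.edges:
            R[i, j] = R[j, i] = 1.0
        np.fill_diagonal(R, 1.0)
        corr = CorrelationMatrix(R=R, interval=(0.0, 60.0),
                                 cell_ids=[str(i) for i in range(n)])
        m = network_metrics(apply_threshold(corr, 0.5), corr)
        assert 0.0 <= m.modularity <= 1.0
        if g.number_of_edges():
            # singleton partition has modularity exactly 0
            singletons = [{v} for v in g.nodes]
            assert nx.community.modularity(g, singletons) == pytest.approx(
                0.0, abs=1e-12
            ) or nx.community.modularity(g, singletons) < 0


# ------------------------------------------------- generator integration

@pytest.fixture(scope="module")
def sync_pair():
    prot = glucose_control_protocol(pre_s=120.0, stim_s=600.0, post_s=120.0)
    out = {}
    for sync in (0.0, 1.0):
        cfg = IsletConfig(n_cells=15, seed=5, noise_sd=0.0, sync=sync,
                          deact_delay_median_s=60.0)
        traces, _ = generate_islet(cfg, prot)
        clean = preprocess_traces(traces, band=(0.02, 1.5),
                                  correct_bleach=False)
        out[sync] = correlation_matrix(clean, (300.0, 700.0))
    return out


def test_synchronized_islet_more_correlated_than_fragmented(sync_pair):
    lo = np.nanmean(sync_pair[0.0].offdiag_values())
    hi = np.nanmean(sync_pair[1.0].offdiag_values())
    assert hi > lo


def test_planted_synchrony_communities_are_recovered():
    from sklearn.metrics import adjusted_rand_score

    prot = glucose_control_protocol(pre_s=120.0, stim_s=900.0, post_s=120.0)
    cfg = IsletConfig(n_cells=40, seed=11, noise_sd=0.01, sync=0.95,
                      n_communities=2, deact_delay_median_s=60.0)
    traces, truth = generate_islet(cfg, prot)
    clean = preprocess_traces(traces, band=(0.02, 1.5), correct_bleach=False)
    corr = correlation_matrix(clean, (300.0, 900.0))
    # anti-phase communities: within-community R is high, across is
    # negative, so any mid-gap threshold separates the planted blocks
    net = apply_threshold(corr, 0.3)
    labels = community_labels(net)
    assert adjusted_rand_score(truth.communities, labels) > 0.9
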