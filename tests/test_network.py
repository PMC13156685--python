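"""Network construction, cross-site similarity, topology vs brute force."""

from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import breathshift as bs
from breathshift.network import (
    CorrelationNetwork,
    _graph_at_cutoff,
    correlation_of_correlations,
)
from breathshift.tables import FeatureTable


def _table_from_log(log_x, prefix="discovery"):
    log_x = np.asarray(log_x, dtype=float)
    n = log_x.shape[0]
    samples = pd.DataFrame(
        {
            "cohort": prefix,
            "subject_id": [f"S{i // 4}" for i in range(n)],
            "timepoint_index": [(i % 4) + 1 for i in range(n)],
            "time_min": [(-15.0, -5.0, 0.0, 25.0)[i % 4] for i in range(n)],
            "polarity": "positive",
        },
        index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
    )
    cols = [bs.feature_id_for_mz(100.0 + j) for j in range(log_x.shape[1])]
    return FeatureTable(samples, pd.DataFrame(10.0 ** log_x, index=samples.index,
                                              columns=cols))


def _net_from_matrix(r: np.ndarray, cutoff=0.7) -> CorrelationNetwork:
    cols = [f"f{i}" for i in range(r.shape[0])]
    rdf = pd.DataFrame(r, index=cols, columns=cols)
    g = nx.Graph()
    g.add_nodes_from(cols)
    for i, j in combinations(range(len(cols)), 2):
        if r[i, j] > cutoff:
            g.add_edge(cols[i], cols[j], rho=float(r[i, j]))
    return CorrelationNetwork(graph=g, correlation_matrix=rdf, cutoff=cutoff)


# -- construction -----------------------------------------------------------

def test_affine_copies_form_complete_unit_graph():
    base = np.random.default_rng(1).normal(size=8)
    log_x = np.column_stack([base, 2 * base + 1, -0.0 + 3 * base])
    net = bs.build_correlation_network(_table_from_log(log_x), cutoff=0.7)
    assert net.graph.number_of_edges() == 3
    assert all(d["rho"] == pytest.approx(1.0) for _, _, d in net.graph.edges(data=True))


def test_cutoff_one_gives_empty_edge_set():
    base = np.random.default_rng(1).normal(size=8)
    log_x = np.column_stack([base, 2 * base])
    net = bs.build_correlation_network(_table_from_log(log_x), cutoff=1.0)
    assert net.graph.number_of_edges() == 0


def test_independent_noise_rarely_exceeds_high_cutoff():
    rng = np.random.default_rng(7)
    log_x = rng.normal(size=(100, 40))
    net = bs.build_correlation_network(_table_from_log(log_x), cutoff=0.7)
    n_pairs = 40 * 39 / 2
    assert net.graph.number_of_edges() < 0.01 * n_pairs


def test_constant_feature_warned_and_isolated():
    rng = np.random.default_rng(8)
    log_x = rng.normal(size=(10, 3))
    log_x[:, 2] = 1.5
    with pytest.warns(UserWarning, match="constant"):
        net = bs.build_correlation_network(_table_from_log(log_x), cutoff=0.0)
    assert net.graph.degree(net.features[2]) == 0


# -- cross-site similarity --------------------------------------------------

def test_identical_networks_have_identity_metrics():
    rng = np.random.default_rng(5)
    log_x = rng.normal(size=(30, 12))
    net = bs.build_correlation_network(_table_from_log(log_x), cutoff=0.5)
    sim = bs.cross_site_similarity(net, net)
    assert sim.trace_similarity == pytest.approx(1.0)
    assert sim.trace_distance == pytest.approx(0.0, abs=1e-12)
    assert sim.eigenvalue_corr == pytest.approx(1.0)
    assert sim.corr_of_corrs == pytest.approx(1.0)
    per = sim.per_cutoff.dropna(subset=["jaccard"])
    assert np.allclose(per["jaccard"], 1.0)
    assert np.allclose(per["edge_difference"], 0.0)


def test_edge_disjoint_networks_have_zero_jaccard():
    r_a = np.eye(3)
    r_a[0, 1] = r_a[1, 0] = 0.9
    r_b = np.eye(3)
    r_b[1, 2] = r_b[2, 1] = 0.9
    sim = bs.cross_site_similarity(_net_from_matrix(r_a), _net_from_matrix(r_b),
                                   cutoffs=[0.7])
    assert sim.per_cutoff.loc[0.7, "jaccard"] == 0.0


def test_node_set_mismatch_instructs_to_intersect():
    rng = np.random.default_rng(5)
    net_a = bs.build_correlation_network(_table_from_log(rng.normal(size=(12, 4))))
    net_b = bs.build_correlation_network(
        _table_from_log(rng.normal(size=(12, 3))), cutoff=0.7
    )
    with pytest.raises(ValueError, match="intersect"):
        bs.cross_site_similarity(net_a, net_b)


def test_trace_similarity_symmetric_and_selfunit():
    rng = np.random.default_rng(9)
    x = rng.normal(size=(40, 6))
    y = rng.normal(size=(40, 6))
    ra, rb = np.corrcoef(x, rowvar=False), np.corrcoef(y, rowvar=False)
    assert bs.trace_similarity(ra, ra) == pytest.approx(1.0)
    assert bs.trace_similarity(ra, rb) == pytest.approx(bs.trace_similarity(rb, ra))


def test_eigenvalue_correlation_invariant_to_joint_relabeling():
    rng = np.random.default_rng(10)
    x = rng.normal(size=(30, 5))
    y = x + rng.normal(scale=0.5, size=x.shape)
    ra, rb = np.corrcoef(x, rowvar=False), np.corrcoef(y, rowvar=False)
    perm = rng.permutation(5)
    assert bs.eigenvalue_correlation(ra, rb) == pytest.approx(
        bs.eigenvalue_correlation(ra[np.ix_(perm, perm)], rb[np.ix_(perm, perm)])
    )


# -- permutation p-values ---------------------------------------------------

def test_shared_structure_attains_permutation_floor():
    rng = np.random.default_rng(11)
    latent = rng.normal(size=(60, 4))
    mix = rng.normal(size=(4, 10))
    xa = latent @ mix + 0.3 * rng.normal(size=(60, 10))
    xb = latent @ mix + 0.3 * rng.normal(size=(60, 10))
    p, observed = bs.permutation_pvalue("corr_of_corrs", xa, xb, n_perm=99, seed=1)
    assert p == pytest.approx(1 / 100)
    assert observed > 0.5


def test_pure_noise_permutation_p_is_calibrated():
    """On independent-noise cohorts the permutation p should rarely be
    small; at least 90% of seeds exceed 0.05."""
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        xa = rng.normal(size=(40, 8))
        xb = rng.normal(size=(40, 8))
        p, _ = bs.permutation_pvalue("trace_similarity", xa, xb, n_perm=79, seed=seed)
        hits += p > 0.05
    assert hits >= 18


def test_zero_permutations_rejected():
    with pytest.raises(ValueError):
        bs.permutation_pvalue("trace_similarity", np.eye(4), np.eye(4), n_perm=0)


# -- topology vs brute force ------------------------------------------------

def _bf_components(g):
    nodes = list(g.nodes)
    seen, n_comp = set(), 0
    for start in nodes:
        if start in seen:
            continue
        n_comp += 1
        stack = [start]
        while stack:
            u = stack.pop()
            if u in seen:
                continue
            seen.add(u)
            stack.extend(v for v in g.neighbors(u) if v not in seen)
    return n_comp


def _bf_clustering(g):
    vals = []
    for u in g.nodes:
        nbrs = list(g.neighbors(u))
        k = len(nbrs)
        if k < 2:
            vals.append(0.0)
            continue
        links = sum(1 for a, b in combinations(nbrs, 2) if g.has_edge(a, b))
        vals.append(2.0 * links / (k * (k - 1)))
    return float(np.mean(vals)) if vals else np.nan


def _bf_shortest_paths(g, nodes):
    """Floyd-Warshall distances over the given node subset."""
    idx = {u: i for i, u in enumerate(nodes)}
    n = len(nodes)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for u, v in g.edges:
        if u in idx and v in idx:
            dist[idx[u], idx[v]] = dist[idx[v], idx[u]] = 1.0
    for k in range(n):
        dist = np.minimum(dist, dist[:, [k]] + dist[[k], :])
    return dist


def _bf_betweenness(g):
    """Exact unnormalized betweenness by shortest-path enumeration."""
    nodes = list(g.nodes)
    bt = dict.fromkeys(nodes, 0.0)
    for s, t in combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        for w in nodes:
            if w in (s, t):
                continue
            frac = sum(1 for p in paths if w in p) / len(paths)
            bt[w] += frac
    return bt


@pytest.mark.parametrize("seed", range(10))
def test_topology_metrics_match_bruteforce_on_random_graphs(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 13))
    # random correlation-like symmetric matrix
    x = rng.normal(size=(n + 4, n))
    r = np.corrcoef(x, rowvar=False)
    net = _net_from_matrix(r, cutoff=0.0)
    cutoff = float(rng.uniform(-0.2, 0.5))
    profile = bs.topology_profile(net, [cutoff]).iloc[0]
    g = _graph_at_cutoff(net, cutoff)

    assert profile["n_connected_components"] == _bf_components(g)
    assert profile["clustering_coefficient"] == pytest.approx(_bf_clustering(g))

    largest = list(
        max(nx.connected_components(g), key=lambda c: (len(c), tuple(sorted(c))))
    )
    if len(largest) >= 2:
        dist = _bf_shortest_paths(g, largest)
        iu = np.triu_indices(len(largest), k=1)
        assert profile["avg_path_length"] == pytest.approx(dist[iu].mean())
        assert profile["diameter"] == pytest.approx(dist[iu].max())
    bt = _bf_betweenness(g)
    assert profile["mean_betweenness"] == pytest.approx(np.mean(list(bt.values())))


def test_triangle_path_and_star_closed_forms():
    tri = _net_from_matrix(np.ones((3, 3)))
    row = bs.topology_profile(tri, [0.5]).iloc[0]
    assert row["clustering_coefficient"] == pytest.approx(1.0)
    assert row["avg_path_length"] == pytest.approx(1.0)
    assert row["diameter"] == 1

    # path graph on 4 nodes: betweenness (0, 2, 2, 0)
    r = np.eye(4)
    for i in range(3):
        r[i, i + 1] = r[i + 1, i] = 0.9
    row = bs.topology_profile(_net_from_matrix(r), [0.5]).iloc[0]
    assert row["diameter"] == 3
    assert row["mean_betweenness"] == pytest.approx(1.0)

    # 10-node star: center betweenness = 9*8/2 = 36
    r = np.eye(10)
    r[0, 1:] = r[1:, 0] = 0.9
    net = _net_from_matrix(r)
    g = _graph_at_cutoff(net, 0.5)
    bt = nx.betweenness_centrality(g, normalized=False)
    assert bt["f0"] == pytest.approx(36.0)


def test_empty_graph_reports_markers_not_errors():
    net = _net_from_matrix(np.eye(4))
    row = bs.topology_profile(net, [0.99]).iloc[0]
    assert row["n_connected_components"] == 4
    assert np.isnan(row["avg_path_length"]) and np.isnan(row["diameter"])


# -- degree-FC correlation --------------------------------------------------

def test_perfectly_inverse_degree_fc_gives_minus_one():
    r = np.eye(4)
    for i, j in [(0, 1), (0, 2), (0, 3), (1, 2)]:  # degrees 3, 2, 2, 1
        r[i, j] = r[j, i] = 0.9
    net = _net_from_matrix(r)
    degs = np.array([net.graph.degree(f) for f in net.features], dtype=float)
    stats = pd.DataFrame({"mean_log2fc": -degs}, index=net.features)
    rho, p, defined = bs.degree_fc_correlation(net, stats)
    assert defined
    assert rho == pytest.approx(-1.0)
    assert p < 0.05


def test_constant_fold_change_flagged_undefined():
    r = np.eye(3)
    r[0, 1] = r[1, 0] = 0.9
    net = _net_from_matrix(r)
    stats = pd.DataFrame({"mean_log2fc": [1.0, 1.0, 1.0]}, index=net.features)
    with pytest.warns(UserWarning, match="undefined"):
        rho, p, defined = bs.degree_fc_correlation(net, stats)
    assert (rho, defined) == (0.0, False)


def test_hub_blocks_with_small_hub_fc_give_negative_correlation():
    """Blocks of correlated features whose fold change shrinks with block
    size produce the hubs-change-least signature at rho = 0.7."""
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        sizes = [12, 6, 3, 1, 1, 1]
        fcs = [0.2, 0.8, 1.5, 2.5, 2.5, 2.5]
        cols, fc_map = [], {}
        n_samples = 48
        for b, (size, fc) in enumerate(zip(sizes, fcs)):
            latent = rng.normal(size=n_samples)
            for m in range(size):
                col = 0.95 * latent + 0.3 * rng.normal(size=n_samples)
                cols.append(col)
                fc_map[len(cols) - 1] = fc
        log_x = np.column_stack(cols)
        table = _table_from_log(log_x)
        net = bs.build_correlation_network(table, cutoff=0.7)
        stats = pd.DataFrame(
            {"mean_log2fc": [fc_map[i] for i in range(len(cols))]},
            index=net.features,
        )
        rho, _, defined = bs.degree_fc_correlation(net, stats)
        hits += defined and rho < 0
    assert hits >= 9


# -- writers ----------------------------------------------------------------

def test_graphml_and_edge_list_roundtrip(tmp_path):
    rng = np.random.default_rng(13)
    x = rng.normal(size=(30, 6))
    table = _table_from_log(np.column_stack([x[:, :3], x[:, :3] + 0.1 * x[:, 3:]]))
    stats = pd.DataFrame({"mean_log2fc": np.linspace(0, 1, 6)},
                         index=table.feature_ids)
    net = bs.build_correlation_network(table, cutoff=0.5, stats=stats)
    from breathshift.network import write_edge_list_tsv, write_graphml

    write_graphml(net, tmp_path / "net.graphml")
    back = nx.read_graphml(tmp_path / "net.graphml")
    assert back.number_of_edges() == net.graph.number_of_edges()
    write_edge_list_tsv(net, tmp_path / "edges.tsv")
    edges = pd.read_csv(tmp_path / "edges.tsv", sep="\t")
    assert len(edges) == net.graph.number_of_edges()
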