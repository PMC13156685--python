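"""Correlation-network construction and cross-cohort concordance metrics.

Per cohort, Pearson correlations of log10 intensities across all samples
define a weighted feature graph (edge iff rho strictly above the cutoff).
Cross-site similarity is quantified per cutoff by the Jaccard index of edge
sets, the Pearson correlation and mean absolute difference of edge weights
over the union of edges, and — cutoff-independently — the correlation of
correlations over the full upper triangle, the trace-based matrix
similarity tr(Ra' Rb)/(|Ra|_F |Rb|_F), and the Pearson correlation of the
descending eigenvalue spectra.  Topology profiles track fragmentation and
efficiency across cutoffs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sstats

from .tables import FeatureTable


@dataclass
class CorrelationNetwork:
    """Thresholded weighted feature graph plus its full correlation matrix."""

    graph: nx.Graph
    correlation_matrix: pd.DataFrame
    cutoff: float
    log_data: pd.DataFrame = field(default=None, repr=False)  # samples x features

    @property
    def features(self) -> list[str]:
        return list(self.correlation_matrix.columns)


def _log10_matrix(table: FeatureTable, feature_subset=None) -> pd.DataFrame:
    inten = table.intensities
    if feature_subset is not None:
        inten = inten[list(feature_subset)]
    x = inten.to_numpy(dtype=float)
    if np.any(x <= 0):
        raise ValueError("correlation networks expect positive intensities (impute first)")
    return pd.DataFrame(np.log10(x), index=inten.index, columns=inten.columns)


def _corr_from_log(log_data: pd.DataFrame) -> pd.DataFrame:
    x = log_data.to_numpy(dtype=float)
    sd = x.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature(s): correlations undefined, "
            "excluded from edges"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r = np.asarray(r, dtype=float)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=log_data.columns, columns=log_data.columns)


def _edges_from_matrix(r: pd.DataFrame, cutoff: float):
    """(i, j, rho) for upper-triangle entries with rho strictly > cutoff."""
    vals = r.to_numpy()
    n = vals.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    rho = vals[iu, ju]
    keep = np.isfinite(rho) & (rho > cutoff)
    cols = list(r.columns)
    return [(cols[i], cols[j], float(v)) for i, j, v in zip(iu[keep], ju[keep], rho[keep])]


def build_correlation_network(
    table: FeatureTable,
    feature_subset=None,
    cutoff: float = 0.7,
    stats: pd.DataFrame | None = None,
) -> CorrelationNetwork:
    """Build the cohort's correlation network over all samples.

    Pearson rho is computed on log10 intensities of every sample of the
    cohort (subject x timepoint); an edge is retained iff rho > ``cutoff``
    (strict).  If ``stats`` is given, each node receives its
    ``mean_log2fc`` as attribute.  Constant features keep their node but get
    no edges (their correlations are undefined).
    """
    log_data = _log10_matrix(table, feature_subset)
    if log_data.shape[0] < 3:
        raise ValueError("need at least 3 samples to estimate correlations")
    r = _corr_from_log(log_data)
    g = nx.Graph()
    g.add_nodes_from(r.columns)
    g.add_weighted_edges_from(_edges_from_matrix(r, cutoff), weight="rho")
    if stats is not None:
        nx.set_node_attributes(
            g,
            {f: float(stats.loc[f, "mean_log2fc"]) for f in r.columns if f in stats.index},
            "mean_log2fc",
        )
    return CorrelationNetwork(graph=g, correlation_matrix=r, cutoff=cutoff, log_data=log_data)


# ---------------------------------------------------------------------------
# Cross-site similarity
# ---------------------------------------------------------------------------

def trace_similarity(ra: np.ndarray, rb: np.ndarray) -> float:
    """tr(Ra' Rb) / (|Ra|_F |Rb|_F); equals 1 iff the matrices are
    proportional, and lies in [0, 1] for correlation matrices."""
    ra = np.asarray(ra, dtype=float)
    rb = np.asarray(rb, dtype=float)
    return float(np.sum(ra * rb) / (np.linalg.norm(ra) * np.linalg.norm(rb)))


def eigenvalue_correlation(ra: np.ndarray, rb: np.ndarray) -> float:
    """Pearson correlation between descending-sorted eigenvalue spectra."""
    ea = np.sort(np.linalg.eigvalsh(ra))[::-1]
    eb = np.sort(np.linalg.eigvalsh(rb))[::-1]
    return float(sstats.pearsonr(ea, eb).statistic)


def correlation_of_correlations(
    ra: pd.DataFrame, rb: pd.DataFrame, edges_only: float | None = None
) -> float:
    """Pearson correlation between the upper-triangle entries of two
    correlation matrices (all pairs by default; with ``edges_only`` = a
    cutoff, restricted to pairs above the cutoff in either matrix)."""
    va = ra.to_numpy()
    vb = rb.to_numpy()
    iu, ju = np.triu_indices(va.shape[0], k=1)
    a, b = va[iu, ju], vb[iu, ju]
    finite = np.isfinite(a) & np.isfinite(b)
    a, b = a[finite], b[finite]
    if edges_only is not None:
        sel = (a > edges_only) | (b > edges_only)
        a, b = a[sel], b[sel]
    return float(sstats.pearsonr(a, b).statistic)


@dataclass
class CrossSiteSimilarity:
    per_cutoff: pd.DataFrame  # index cutoff; jaccard, weighted_edge_corr, edge_difference
    corr_of_corrs: float
    trace_similarity: float
    trace_distance: float
    eigenvalue_corr: float
    permutation_p: dict = field(default_factory=dict)


def cross_site_similarity(
    net_a: CorrelationNetwork, net_b: CorrelationNetwork, cutoffs=None
) -> CrossSiteSimilarity:
    """Structural similarity between two cohorts' networks.

    Per cutoff: Jaccard index of unweighted edge sets; Pearson correlation
    of the two rho vectors over the union of edges (an edge absent from one
    site contributes that site's sub-threshold rho); and the mean absolute
    rho difference over the union.  Cutoff-independent: correlation of
    correlations over the full upper triangle, trace-based similarity (and
    1 - similarity as distance), and eigenvalue-spectrum correlation.
    """
    if list(net_a.features) != list(net_b.features):
        raise ValueError(
            "networks have different node sets; intersect features and rebuild first"
        )
    if cutoffs is None:
        cutoffs = np.round(np.arange(0.1, 0.91, 0.1), 10)
    ra, rb = net_a.correlation_matrix, net_b.correlation_matrix

    va_full = ra.to_numpy()
    vb_full = rb.to_numpy()
    iu, ju = np.triu_indices(va_full.shape[0], k=1)
    ua, ub = va_full[iu, ju], vb_full[iu, ju]
    finite = np.isfinite(ua) & np.isfinite(ub)

    rows = []
    for cut in cutoffs:
        in_a = finite & (ua > cut)
        in_b = finite & (ub > cut)
        union = in_a | in_b
        n_union = int(union.sum())
        jaccard = float((in_a & in_b).sum() / n_union) if n_union else np.nan
        if n_union >= 2:
            va, vb = ua[union], ub[union]
            wec = (
                float(sstats.pearsonr(va, vb).statistic)
                if va.std() > 0 and vb.std() > 0
                else np.nan
            )
            ed = float(np.mean(np.abs(va - vb)))
        elif n_union == 1:
            wec = np.nan
            ed = float(np.abs(ua[union] - ub[union])[0])
        else:
            wec, ed = np.nan, np.nan
        rows.append(
            {"cutoff": float(cut), "jaccard": jaccard,
             "weighted_edge_corr": wec, "edge_difference": ed}
        )

    ts = trace_similarity(ra.to_numpy(), rb.to_numpy())
    return CrossSiteSimilarity(
        per_cutoff=pd.DataFrame(rows).set_index("cutoff"),
        corr_of_corrs=correlation_of_correlations(ra, rb),
        trace_similarity=ts,
        trace_distance=1.0 - ts,
        eigenvalue_corr=eigenvalue_correlation(ra.to_numpy(), rb.to_numpy()),
    )


# ---------------------------------------------------------------------------
# Permutation p-values
# ---------------------------------------------------------------------------

_METRICS = {
    "trace_similarity": lambda ra, rb: trace_similarity(ra, rb),
    "eigenvalue_corr": lambda ra, rb: eigenvalue_correlation(ra, rb),
    "corr_of_corrs": lambda ra, rb: correlation_of_correlations(
        pd.DataFrame(ra), pd.DataFrame(rb)
    ),
}


def permutation_pvalue(
    metric,
    net_a_samples: pd.DataFrame,
    net_b_samples: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation p-value for a cross-site similarity metric.

    The null is built by permuting the sample rows of cohort B independently
    per feature column (destroying B's correlation structure while keeping
    its marginals), recomputing R_B and the metric; the p-value is
    ``(1 + #{null >= observed}) / (1 + n_perm)``.

    ``metric`` is a name in {trace_similarity, eigenvalue_corr,
    corr_of_corrs} or a callable on two correlation matrices; the sample
    inputs are log10 intensity matrices (samples x features).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    fn = _METRICS[metric] if isinstance(metric, str) else metric
    xa = np.asarray(net_a_samples, dtype=float)
    xb = np.asarray(net_b_samples, dtype=float)
    ra = np.corrcoef(xa, rowvar=False)
    rb = np.corrcoef(xb, rowvar=False)
    observed = fn(ra, rb)
    rng = np.random.default_rng(seed)
    count = 0
    xb_perm = xb.copy()
    for _ in range(n_perm):
        for j in range(xb_perm.shape[1]):
            xb_perm[:, j] = rng.permutation(xb[:, j])
        rb_null = np.corrcoef(xb_perm, rowvar=False)
        if fn(ra, rb_null) >= observed:
            count += 1
    return (1 + count) / (1 + n_perm), float(observed)


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------

def _graph_at_cutoff(net: CorrelationNetwork, cutoff: float) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(net.features)
    g.add_weighted_edges_from(_edges_from_matrix(net.correlation_matrix, cutoff), weight="rho")
    return g


def topology_profile(net: CorrelationNetwork, cutoffs=None) -> pd.DataFrame:
    """Topology metrics of the thresholded graph across cutoffs.

    Per cutoff: number of connected components; mean local clustering
    coefficient; average shortest-path length and diameter of the largest
    connected component (NaN when it has < 2 nodes); mean unnormalized
    shortest-path betweenness over all nodes.  Empty graphs yield NaN
    markers, not exceptions.
    """
    if cutoffs is None:
        cutoffs = np.round(np.arange(0.1, 0.91, 0.1), 10)
    rows = []
    for cut in cutoffs:
        g = _graph_at_cutoff(net, cut)
        n_comp = nx.number_connected_components(g) if g.number_of_nodes() else 0
        clustering = nx.average_clustering(g) if g.number_of_nodes() else np.nan
        if g.number_of_nodes():
            # largest component; ties broken by node labels for determinism
            largest = max(nx.connected_components(g),
                          key=lambda c: (len(c), tuple(sorted(c))))
            sub = g.subgraph(largest)
            if sub.number_of_nodes() >= 2:
                apl = nx.average_shortest_path_length(sub)
                diam = nx.diameter(sub)
            else:
                apl, diam = np.nan, np.nan
            btw = float(np.mean(list(nx.betweenness_centrality(g, normalized=False).values())))
        else:
            apl, diam, btw = np.nan, np.nan, np.nan
        rows.append(
            {
                "cutoff": float(cut),
                "n_connected_components": n_comp,
                "clustering_coefficient": clustering,
                "avg_path_length": apl,
                "diameter": diam,
                "mean_betweenness": btw,
            }
        )
    return pd.DataFrame(rows).set_index("cutoff")


def degree_fc_correlation(
    net: CorrelationNetwork, stats: pd.DataFrame
) -> tuple[float, float, bool]:
    """Spearman rank correlation (midrank ties, two-sided p) between node
    degree and mean Log2FC.  Negative values mean hub features change least.
    Returns ``(rho, p, defined)``; when every degree (or every fold change)
    is identical the correlation is undefined and reported as (0, nan,
    False)."""
    degrees = np.array([net.graph.degree(f) for f in net.features], dtype=float)
    fc = np.array([stats.loc[f, "mean_log2fc"] for f in net.features], dtype=float)
    if np.all(degrees == degrees[0]) or np.all(fc == fc[0]):
        warnings.warn("degree-FC correlation undefined (constant input); reported as 0")
        return 0.0, float("nan"), False
    res = sstats.spearmanr(degrees, fc)
    return float(res.statistic), float(res.pvalue), True


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_graphml(net: CorrelationNetwork, path) -> None:
    g = nx.Graph()
    for node, data in net.graph.nodes(data=True):
        g.add_node(node, **{k: float(v) for k, v in data.items()})
    for i, j, data in net.graph.edges(data=True):
        g.add_edge(i, j, rho=float(data.get("rho", np.nan)))
    nx.write_graphml(g, path)


def write_edge_list_tsv(net: CorrelationNetwork, path) -> None:
    rows = [(i, j, d["rho"]) for i, j, d in net.graph.edges(data=True)]
    pd.DataFrame(rows, columns=["feature_i", "feature_j", "rho"]).to_csv(
        path, sep="\t", index=False
    )
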