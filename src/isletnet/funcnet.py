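"""Functional connectivity networks of beta cells.

Nodes are cells (placed at their physical positions); an undirected edge
joins two cells whose band-passed Ca2+ traces correlate at or above a
threshold over an analysis interval.  Instead of a fixed threshold, the
threshold is chosen per islet so that the realized average node degree
matches a setpoint (<k> = 8 for the first plateau interval); that same
threshold is then reused on the second interval of the same islet, so the
change in network structure between intervals is directly comparable.

Four metrics summarize each network: the average node degree and average
correlation coefficient (synchronicity), the modularity of an optimized
community partition (functional segregation, in [0, 1] for similarity
graphs), and the relative size of the largest connected component
(functional integration).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .preprocess import CleanTraceSet


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson correlations over one analysis interval.

    Zero-variance cells yield NaN rows/columns; those pairs never form edges
    and are skipped when searching for a degree-matching threshold.
    """

    R: np.ndarray
    interval: tuple[float, float]
    cell_ids: list[str]

    @property
    def n_cells(self) -> int:
        return self.R.shape[0]

    def offdiag_values(self) -> np.ndarray:
        """Finite upper-triangle correlation values."""
        iu = np.triu_indices(self.n_cells, k=1)
        vals = self.R[iu]
        return vals[np.isfinite(vals)]


def correlation_matrix(
    clean: CleanTraceSet,
    interval: tuple[float, float],
    method: str = "pearson",
    min_length_s: float = 30.0,
) -> CorrelationMatrix:
    """Correlation of the filtered traces restricted to ``interval``.

    ``method`` is ``"pearson"`` (default, the similarity measure used for
    islet functional networks) or ``"spearman"``.
    """
    a, b = interval
    if b - a < min_length_s:
        raise ValueError(f"interval must be at least {min_length_s} s long")
    if clean.n_cells < 2:
        raise ValueError("need at least two cells")
    X = clean.slice_interval(interval, which="filt")
    if method == "spearman":
        from scipy.stats import rankdata

        X = rankdata(X, axis=0)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X.T)
    R[sd == 0, :] = np.nan
    R[:, sd == 0] = np.nan
    np.fill_diagonal(R, 1.0)
    return CorrelationMatrix(R=R, interval=(a, b), cell_ids=list(clean.cell_ids))


def threshold_for_degree(
    corr: CorrelationMatrix, k_target: float = 8.0
) -> tuple[float, float]:
    """Correlation threshold whose realized average degree is closest to
    ``k_target``.

    Candidate thresholds are the off-diagonal correlation values themselves
    (edge rule is ``R >= R_th``, so each candidate yields a distinct edge
    count); ties in |<k> - k_target| break toward the higher threshold, i.e.
    the sparser network.  Returns ``(R_th, realized_k)``.
    """
    n = corr.n_cells
    if not 0 < k_target <= n - 1:
        raise ValueError("k_target must lie in (0, n_cells - 1]")
    vals = np.sort(corr.offdiag_values())[::-1]
    if vals.size == 0:
        raise ValueError("no finite off-diagonal correlations")
    if 2.0 * vals.size / n < k_target:
        raise ValueError("k_target unreachable: too few valid pairs")
    uniq, first_idx = np.unique(-vals, return_index=True)
    uniq = -uniq  # descending unique thresholds
    counts = np.searchsorted(-vals, -uniq, side="right")  # edges at >= t
    k_real = 2.0 * counts / n
    best = None
    for t, k in zip(uniq, k_real):
        dist = abs(k - k_target)
        if best is None or dist < best[0] - 1e-12:
            best = (dist, float(t), float(k))
    assert best is not None
    return best[1], best[2]


@dataclass
class FunctionalNetwork:
    """Thresholded similarity graph on the islet's cells."""

    graph: nx.Graph
    threshold: float
    cell_ids: list[str]
    positions: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def avg_degree(self) -> float:
        g = self.graph
        return 2.0 * g.number_of_edges() / g.number_of_nodes()


def apply_threshold(
    corr: CorrelationMatrix,
    r_th: float,
    positions: np.ndarray | None = None,
) -> FunctionalNetwork:
    """Graph with an edge wherever ``R_ij >= r_th`` (i != j, finite R).

    Reusing a first-interval threshold on a second-interval correlation
    matrix is exactly this call with the stored ``r_th``.
    """
    if not -1.0 <= r_th <= 1.0 + 1e-12:
        # thresholds above 1 are allowed only as an explicit "no edges"
        if r_th < -1.0:
            raise ValueError("threshold below -1 is meaningless")
    n = corr.n_cells
    g = nx.Graph()
    g.add_nodes_from(range(n))
    iu, ju = np.triu_indices(n, k=1)
    mask = np.isfinite(corr.R[iu, ju]) & (corr.R[iu, ju] >= r_th)
    g.add_edges_from(zip(iu[mask].tolist(), ju[mask].tolist()))
    if positions is not None:
        for i in range(n):
            g.nodes[i]["x"] = float(positions[i, 0])
            g.nodes[i]["y"] = float(positions[i, 1])
    for cid, i in zip(corr.cell_ids, range(n)):
        g.nodes[i]["cell_id"] = cid
    return FunctionalNetwork(
        graph=g, threshold=float(r_th), cell_ids=list(corr.cell_ids),
        positions=positions,
    )


@dataclass(frozen=True)
class NetworkMetrics:
    avg_degree: float
    avg_correlation: float
    modularity: float
    relative_largest_component: float
    n_communities: int = 1


def detect_communities(graph: nx.Graph, method: str = "greedy") -> list[set]:
    """Community partition by modularity maximization.

    ``"greedy"`` (Clauset-Newman-Moore, deterministic) is the default;
    ``"louvain"`` uses a fixed seed.  A graph without edges partitions into
    singletons (modularity 0 by convention).
    """
    if graph.number_of_edges() == 0:
        return [{v} for v in graph.nodes]
    if method == "greedy":
        return [set(c) for c in nx.community.greedy_modularity_communities(graph)]
    if method == "louvain":
        return [set(c) for c in nx.community.louvain_communities(graph, seed=0)]
    raise ValueError(f"unknown community method {method!r}")


def network_metrics(
    net: FunctionalNetwork,
    corr: CorrelationMatrix,
    community_method: str = "greedy",
) -> NetworkMetrics:
    """The four summary metrics of one functional network.

    avg_degree = 2|E|/n; avg_correlation = mean off-diagonal R; modularity
    of the optimized partition (0 for an edgeless or unpartitionable
    network); relative largest component = |largest CC| / n.
    """
    g = net.graph
    n = g.number_of_nodes()
    comms = detect_communities(g, community_method)
    q = (
        float(nx.community.modularity(g, comms))
        if g.number_of_edges() > 0
        else 0.0
    )
    lcc = max((len(c) for c in nx.connected_components(g)), default=0)
    vals = corr.offdiag_values()
    return NetworkMetrics(
        avg_degree=net.avg_degree,
        avg_correlation=float(np.mean(vals)) if vals.size else np.nan,
        modularity=q,
        relative_largest_component=lcc / n,
        n_communities=len(comms),
    )


def community_labels(net: FunctionalNetwork, method: str = "greedy") -> np.ndarray:
    """Integer community label per cell, in node order."""
    comms = detect_communities(net.graph, method)
    labels = np.empty(net.n_cells, dtype=int)
    for k, c in enumerate(comms):
        for v in c:
            labels[v] = k
    return labels


def build_network(
    clean: CleanTraceSet,
    interval: tuple[float, float],
    k_target: float = 8.0,
    r_th: float | None = None,
    method: str = "pearson",
) -> tuple[FunctionalNetwork, CorrelationMatrix, NetworkMetrics]:
    """Correlate, threshold (adaptively unless ``r_th`` is given), and
    measure one interval's functional network."""
    corr = correlation_matrix(clean, interval, method=method)
    if r_th is None:
        r_th, _ = threshold_for_degree(corr, k_target)
    net = apply_threshold(corr, r_th, positions=clean.positions)
    return net, corr, network_metrics(net, corr)
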