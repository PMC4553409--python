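"""Binary brain graphs and their nodal/global topology metrics.

Connectivity matrices are binarized at correlation thresholds (default
0.05..0.30 in steps of 0.05); an edge exists where the back-transformed
correlation r = tanh(z) exceeds the threshold (signed — negative
correlations never form edges). Six nodal metrics and eleven global metrics
are computed per threshold; small-worldness uses degree-preserving
double-edge-swap random references (Humphries & Gurney convention,
sigma = gamma / lambda with gamma = C/<C_null>, lambda = L/<L_null>).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .connectivity import ConnectivityMatrix

__all__ = [
    "BinaryGraph",
    "binarize",
    "nodal_metrics",
    "global_metrics",
    "random_reference",
    "network_feature_block",
    "DEFAULT_THRESHOLDS",
    "NODAL_METRICS",
    "GLOBAL_METRICS",
]

DEFAULT_THRESHOLDS = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30)

NODAL_METRICS = (
    "degree",
    "shortest_path_length",
    "global_efficiency",
    "local_efficiency",
    "clustering_coefficient",
    "betweenness",
)

# Network means of the six nodal metrics plus five whole-network-only metrics.
GLOBAL_METRICS = NODAL_METRICS + (
    "assortativity",
    "transitivity",
    "gamma",
    "lambda",
    "small_worldness",
)


@dataclass
class BinaryGraph:
    """Symmetric 0/1 adjacency with no self-loops, at a stated threshold."""

    adjacency: np.ndarray
    threshold: float = 0.0

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency)
        A = (A != 0).astype(np.int8)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        np.fill_diagonal(A, 0)
        self.adjacency = A

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def density(self) -> float:
        n = self.n_nodes
        return 0.0 if n < 2 else self.n_edges / (n * (n - 1) / 2)

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def to_networkx(self) -> nx.Graph:
        return nx.from_numpy_array(self.adjacency)


def binarize(z: ConnectivityMatrix | np.ndarray, threshold: float,
             use_absolute: bool = False) -> BinaryGraph:
    """Edge wherever tanh(z) > threshold; NaN entries never form edges.

    The threshold applies to the signed correlation by default (negative
    correlations never form edges); ``use_absolute`` thresholds |r| instead.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    zmat = z.z if isinstance(z, ConnectivityMatrix) else np.asarray(z, dtype=float)
    with np.errstate(invalid="ignore"):
        r = np.tanh(zmat)
        if use_absolute:
            r = np.abs(r)
        A = np.where(np.isnan(r), 0, (r > threshold).astype(np.int8))
    A = (A & A.T).astype(np.int8)
    np.fill_diagonal(A, 0)
    return BinaryGraph(adjacency=A, threshold=threshold)


def _hop_distances(A: np.ndarray) -> np.ndarray:
    """All-pairs BFS hop distances; inf where unreachable."""
    if A.shape[0] == 0:
        return np.zeros((0, 0))
    return shortest_path(csr_matrix(A), method="D", unweighted=True, directed=False)


def _pairwise_efficiency_rows(D: np.ndarray) -> np.ndarray:
    """Row means of 1/d over j != i, with 1/inf = 0."""
    n = D.shape[0]
    if n < 2:
        return np.zeros(n)
    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (n - 1)


def _nodal_path_length(D: np.ndarray) -> np.ndarray:
    """Mean hop distance to reachable nodes (0 for isolated nodes)."""
    n = D.shape[0]
    out = np.zeros(n)
    for i in range(n):
        d = np.delete(D[i], i)
        reach = np.isfinite(d) & (d > 0)
        out[i] = d[reach].mean() if reach.any() else 0.0
    return out


def _triangles(A: np.ndarray) -> np.ndarray:
    """Number of edges among each node's neighbours (= triangles through it)."""
    return np.einsum("ij,jk,ki->i", A, A, A) / 2.0


def nodal_metrics(g: BinaryGraph) -> pd.DataFrame:
    """The six per-node metrics as a nodes x metrics DataFrame.

    degree; shortest_path_length (mean BFS hops to reachable nodes);
    global_efficiency (mean of 1/d over all other nodes, 1/inf = 0);
    local_efficiency (global efficiency of the neighbour-induced subgraph,
    0 when degree < 2); clustering_coefficient (2t/(k(k-1)), 0 when k < 2);
    betweenness (normalized fraction of shortest paths through the node).
    """
    A = g.adjacency.astype(float)
    n = g.n_nodes
    k = g.degrees().astype(float)
    D = _hop_distances(A)

    tri = _triangles(A)
    with np.errstate(invalid="ignore", divide="ignore"):
        clustering = np.where(k >= 2, 2.0 * tri / (k * (k - 1)), 0.0)

    local_eff = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(A[i])
        if nbrs.size < 2:
            continue
        sub = A[np.ix_(nbrs, nbrs)]
        local_eff[i] = _pairwise_efficiency_rows(_hop_distances(sub)).mean()

    betweenness = np.array(
        [v for _, v in sorted(nx.betweenness_centrality(g.to_networkx(),
                                                        normalized=True).items())]
    ) if n > 2 else np.zeros(n)

    return pd.DataFrame(
        {
            "degree": k,
            "shortest_path_length": _nodal_path_length(D),
            "global_efficiency": _pairwise_efficiency_rows(D),
            "local_efficiency": local_eff,
            "clustering_coefficient": clustering,
            "betweenness": betweenness,
        }
    )


def characteristic_path_length(g: BinaryGraph) -> float:
    """Mean hop distance over reachable ordered pairs (0 if no edges)."""
    D = _hop_distances(g.adjacency.astype(float))
    off = ~np.eye(g.n_nodes, dtype=bool)
    reach = np.isfinite(D) & off & (D > 0)
    return float(D[reach].mean()) if reach.any() else 0.0


def mean_clustering(g: BinaryGraph) -> float:
    A = g.adjacency.astype(float)
    k = g.degrees().astype(float)
    tri = _triangles(A)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(k >= 2, 2.0 * tri / (k * (k - 1)), 0.0)
    return float(c.mean()) if c.size else 0.0


def assortativity(g: BinaryGraph) -> float:
    """Newman's degree assortativity: Pearson correlation of end-node degrees
    over edges (each undirected edge counted in both orientations)."""
    A = g.adjacency
    k = g.degrees().astype(float)
    ii, jj = np.nonzero(np.triu(A, 1))
    if ii.size < 2:
        return np.nan
    x = np.concatenate([k[ii], k[jj]])
    y = np.concatenate([k[jj], k[ii]])
    sx = x.std()
    if sx == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def transitivity(g: BinaryGraph) -> float:
    """3 x triangles / connected triples."""
    A = g.adjacency.astype(float)
    k = g.degrees().astype(float)
    triples = (k * (k - 1)).sum()  # 2 x number of unordered connected triples
    if triples == 0:
        return np.nan
    closed = np.trace(A @ A @ A)  # 6 x number of triangles
    return float(closed / triples)


def random_reference(g: BinaryGraph, n_rewires_per_edge: int = 10,
                     seed: int = 0) -> BinaryGraph:
    """Degree-preserving randomization by double-edge swaps.

    The degree sequence is preserved exactly and the graph stays simple.
    If no valid swap can be found within the attempt budget (e.g. a
    triangle), the best effort so far is returned with a warning.
    """
    G = g.to_networkx()
    m = G.number_of_edges()
    if m < 2:
        return BinaryGraph(adjacency=g.adjacency.copy(), threshold=g.threshold)
    nswap = n_rewires_per_edge * m
    try:
        nx.double_edge_swap(G, nswap=nswap, max_tries=100 * nswap, seed=seed)
    except nx.NetworkXAlgorithmError:
        warnings.warn("double-edge swap budget exhausted; returning best effort",
                      stacklevel=2)
    except nx.NetworkXError:
        # Fewer than 2 independent edges to swap.
        pass
    A = nx.to_numpy_array(G, nodelist=range(g.n_nodes), dtype=np.int8)
    return BinaryGraph(adjacency=A, threshold=g.threshold)


def global_metrics(g: BinaryGraph, n_null: int = 100, seed: int = 0) -> dict[str, float]:
    """The eleven whole-network metrics.

    Network means of the six nodal metrics, plus assortativity, transitivity,
    gamma = C/<C_null>, lambda = L/<L_null> and small_worldness = gamma/lambda
    against ``n_null`` degree-preserving random references. Graphs with no
    edges get NaN for the whole-network-only metrics.
    """
    nm = nodal_metrics(g)
    out = {name: float(nm[name].mean()) for name in NODAL_METRICS}
    if g.n_edges < 1:
        out.update({k: np.nan for k in
                    ("assortativity", "transitivity", "gamma", "lambda",
                     "small_worldness")})
        return out
    out["assortativity"] = assortativity(g)
    out["transitivity"] = transitivity(g)

    C = mean_clustering(g)
    L = characteristic_path_length(g)
    null_C = np.empty(n_null)
    null_L = np.empty(n_null)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_null):
            null = random_reference(g, seed=seed + i)
            null_C[i] = mean_clustering(null)
            null_L[i] = characteristic_path_length(null)
    mC, mL = null_C.mean(), null_L.mean()
    gamma = C / mC if mC > 0 else np.nan
    lam = L / mL if mL > 0 else np.nan
    out["gamma"] = gamma
    out["lambda"] = lam
    out["small_worldness"] = gamma / lam if np.isfinite(gamma) and np.isfinite(lam) and lam != 0 else np.nan
    return out


def network_feature_block(z: ConnectivityMatrix,
                          thresholds=DEFAULT_THRESHOLDS,
                          roi_names: dict[int, str] | None = None,
                          n_null: int = 100,
                          seed: int = 0) -> pd.DataFrame:
    """All graph-theory features of one connectivity matrix.

    Emits 11 global metrics and R x 6 nodal metrics at each threshold, with
    canonical names ``metric@threshold`` (NMglobal) and
    ``metric@threshold@roi`` (NMnodal). For 116 nodes at 6 thresholds this
    is 66 NMglobal and 4176 NMnodal features.

    Returns a DataFrame indexed by feature name with columns
    ``value`` and ``subcategory``.
    """
    roi_ids = z.roi_ids
    labels = [roi_names.get(i, f"R{i}") if roi_names else f"R{i}" for i in roi_ids]
    names, values, subcats = [], [], []
    for t_i, thr in enumerate(thresholds):
        g = binarize(z, thr)
        gm = global_metrics(g, n_null=n_null, seed=seed + 1000 * t_i)
        for metric in GLOBAL_METRICS:
            names.append(f"{metric}@{thr:.2f}")
            values.append(gm[metric])
            subcats.append("NMglobal")
        nm = nodal_metrics(g)
        for metric in NODAL_METRICS:
            col = nm[metric].to_numpy()
            for node, label in enumerate(labels):
                names.append(f"{metric}@{thr:.2f}@{label}")
                values.append(float(col[node]))
                subcats.append("NMnodal")
    return pd.DataFrame({"value": values, "subcategory": subcats}, index=names)
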