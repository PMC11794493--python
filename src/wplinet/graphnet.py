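"""Weighted graph metrics on functional connectivity matrices.

The full weighted complete graph is analyzed (no thresholding or
binarization). Conventions, all recorded in the output metadata:

* distance between adjacent nodes = 1 / weight (``-log(w)`` available);
* shortest paths by Dijkstra on those lengths; unreachable pairs are
  excluded from the characteristic path length (their count is reported)
  and contribute 0 to efficiencies;
* weighted clustering per Onnela (triangle weights normalized by the
  network-wide maximum weight; Barrat variant available).

For a complete uniform graph with weight w these give E_glob = w, L = 1/w,
C = 1 — and for WPLI graphs whose direct edges are shortest paths, global
efficiency equals the mean off-diagonal weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import dijkstra


@dataclass
class WeightedGraph:
    """Symmetric non-negative weight matrix with zero diagonal."""

    W: np.ndarray
    node_labels: list[str] | None = None

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("W must be square")
        if not np.allclose(W, W.T, atol=1e-10):
            raise ValueError("W must be symmetric")
        if W.min() < 0:
            raise ValueError("weights must be non-negative")
        W = W.copy()
        np.fill_diagonal(W, 0.0)
        self.W = W
        if self.node_labels is None:
            self.node_labels = [f"n{i}" for i in range(W.shape[0])]

    @property
    def n(self) -> int:
        return self.W.shape[0]


@dataclass
class NetworkMetrics:
    """Bundle of local and global weighted-network properties."""

    strength: np.ndarray            # per node
    clustering: np.ndarray          # per node
    char_path_length: float
    global_efficiency: float
    local_efficiency: float
    n_unreachable_pairs: int        # ordered pairs excluded from L
    meta: dict = field(default_factory=dict)

    @property
    def mean_strength(self) -> float:
        """Network-level 'connection strength' (mean node strength)."""
        return float(np.mean(self.strength))

    @property
    def mean_clustering(self) -> float:
        return float(np.mean(self.clustering))

    def as_dict(self) -> dict:
        return {
            "strength": self.mean_strength,
            "clustering": self.mean_clustering,
            "char_path_length": self.char_path_length,
            "global_efficiency": self.global_efficiency,
            "local_efficiency": self.local_efficiency,
            "n_unreachable_pairs": self.n_unreachable_pairs,
            **self.meta,
        }


def node_strength(g: WeightedGraph) -> np.ndarray:
    """s_i = sum_j w_ij."""
    return g.W.sum(axis=1)


def clustering_coefficient(g: WeightedGraph, variant: str = "onnela") -> np.ndarray:
    """Weighted clustering coefficient per node.

    Onnela: C_i = [1 / (k_i (k_i - 1))] * sum_{j,h} (w'_ij w'_ih w'_jh)^{1/3}
    with w' = w / max(W) and k_i the number of nonzero-weight neighbors;
    C_i = 0 for nodes with fewer than two neighbors.

    Barrat: C_i = [1 / (s_i (k_i - 1))] * sum_{j,h} ((w_ij + w_ih) / 2) a_ij a_ih a_jh.
    """
    W = g.W
    k = (W > 0).sum(axis=1)
    out = np.zeros(g.n)
    if variant == "onnela":
        wmax = W.max()
        if wmax == 0:
            return out
        A = np.cbrt(W / wmax)
        tri = np.diagonal(A @ A @ A)  # 2 x sum over unordered triangles
        valid = k >= 2
        out[valid] = tri[valid] / (k[valid] * (k[valid] - 1))
    elif variant == "barrat":
        a = (W > 0).astype(float)
        s = W.sum(axis=1)
        for i in range(g.n):
            if k[i] < 2 or s[i] == 0:
                continue
            acc = 0.0
            nbrs = np.where(a[i] > 0)[0]
            for j in nbrs:
                for h in nbrs:
                    if j != h and a[j, h] > 0:
                        acc += (W[i, j] + W[i, h]) / 2
            out[i] = acc / (s[i] * (k[i] - 1))
    else:
        raise ValueError(f"unknown clustering variant {variant!r}")
    return out


def shortest_paths(g: WeightedGraph, distance: str = "inverse") -> np.ndarray:
    """All-pairs shortest-path distances.

    Edge length is 1/w (``distance="inverse"``, default) or -log(w)
    (``distance="neglog"``, only valid for weights <= 1); missing edges
    (w = 0) are non-adjacent. Unreachable pairs get inf, the diagonal 0.
    """
    W = g.W
    with np.errstate(divide="ignore"):
        if distance == "inverse":
            L = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), np.inf)
        elif distance == "neglog":
            if W.max() > 1:
                raise ValueError("-log distance requires weights <= 1")
            L = np.where(W > 0, -np.log(np.where(W > 0, W, 1.0)), np.inf)
        else:
            raise ValueError(f"unknown distance rule {distance!r}")
    np.fill_diagonal(L, 0.0)
    finite = np.where(np.isfinite(L), L, 0.0)
    mask = np.isfinite(L) & (~np.eye(g.n, dtype=bool))
    d = dijkstra(np.where(mask, finite, 0.0), directed=False)
    return d


def characteristic_path_length(d: np.ndarray) -> tuple[float, int]:
    """Mean shortest-path distance over reachable ordered pairs.

    Returns ``(L, n_unreachable)`` where ``n_unreachable`` counts ordered
    off-diagonal pairs with infinite distance (excluded from the mean).
    Raises if no pair is reachable.
    """
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    n_unreachable = int(off.sum() - finite.sum())
    if finite.sum() == 0:
        raise ValueError("no reachable pair: characteristic path length undefined")
    return float(d[finite].mean()), n_unreachable


def global_efficiency(d: np.ndarray) -> float:
    """E = mean over ordered pairs of 1/d, with 1/inf = 0."""
    n = d.shape[0]
    if n < 2:
        raise ValueError("global efficiency undefined for fewer than 2 nodes")
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(d[off] > 0, 1.0 / d[off], np.inf)
    inv = np.where(np.isfinite(inv), inv, 0.0)
    # d can be 0 only on the diagonal, which is excluded
    return float(inv.sum() / (n * (n - 1)))


def local_efficiency(g: WeightedGraph, distance: str = "inverse",
                     neighbor_threshold: float = 0.0) -> float:
    """Mean over nodes of the global efficiency of the neighborhood subgraph.

    A node's neighborhood is the set of nodes with w_ij > threshold
    (default 0). Nodes with fewer than two neighbors contribute 0.
    """
    acc = 0.0
    for i in range(g.n):
        nbrs = np.where(g.W[i] > neighbor_threshold)[0]
        nbrs = nbrs[nbrs != i]
        if len(nbrs) < 2:
            continue
        sub = WeightedGraph(g.W[np.ix_(nbrs, nbrs)])
        acc += global_efficiency(shortest_paths(sub, distance=distance))
    return acc / g.n


def network_summary(W, band: str | None = None,
                    condition: dict | None = None,
                    subject: int | None = None,
                    distance: str = "inverse",
                    clustering_variant: str = "onnela") -> NetworkMetrics:
    """All metrics for one connectivity matrix, with metadata for statistics.

    ``W`` may be a :class:`~wplinet.connectivity.ConnectivityMatrix` or a
    plain symmetric array.
    """
    if hasattr(W, "W"):
        band = band or getattr(W.band, "name", None)
        condition = condition if condition is not None else getattr(W, "condition", None)
        subject = subject if subject is not None else getattr(W, "subject", None)
        g = WeightedGraph(W.W, node_labels=list(W.channel_labels))
    else:
        g = WeightedGraph(np.asarray(W))
    d = shortest_paths(g, distance=distance)
    L, n_unreach = characteristic_path_length(d)
    return NetworkMetrics(
        strength=node_strength(g),
        clustering=clustering_coefficient(g, variant=clustering_variant),
        char_path_length=L,
        global_efficiency=global_efficiency(d),
        local_efficiency=local_efficiency(g, distance=distance),
        n_unreachable_pairs=n_unreach,
        meta={"band": band, "subject": subject,
              **({} if not condition else condition),
              "distance_rule": distance,
              "clustering_variant": clustering_variant,
              "unreachable_convention": "excluded from L, 0 in efficiency"},
    )
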