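"""Weighted graph measures for streamline-probability connectomes.

Edge lengths are the inverse of the connection weights; since streamline
probabilities lie in (0, 1], every finite length is >= 1 and all
efficiency measures land in [0, 1].

Nodal efficiency of region j is the mean inverse weighted shortest-path
length to every other region:

    E_nodal(j) = 1/(N-1) * sum_{i != j} 1 / l_ij

Local efficiency of region i is the same quantity computed inside the
subgraph induced by i's neighbors after removing i itself:

    E_local(i) = 1/(N_Gi (N_Gi - 1)) * sum_{j != h in G_i} 1 / l_jh

with path lengths restricted to that subgraph.  Disconnected pairs
contribute 0 (1/inf).  Small-worldness compares mean clustering and
characteristic path length against degree-preserving rewired nulls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from .io import ConnectomeSet


@dataclass
class WeightedGraph:
    """Symmetric nonnegative weight matrix with derived inverse lengths."""

    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if np.any(w < 0):
            raise ValueError("negative weights are not allowed")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        w = w.copy()
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    @property
    def lengths(self) -> np.ndarray:
        """1/weight where connected, +inf otherwise."""
        w = self.weights
        with np.errstate(divide="ignore"):
            ln = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
        np.fill_diagonal(ln, 0.0)
        return ln

    @property
    def degree(self) -> np.ndarray:
        return (self.weights > 0).sum(axis=0)


def _as_graph(g) -> WeightedGraph:
    return g if isinstance(g, WeightedGraph) else WeightedGraph(np.asarray(g))


def shortest_path_lengths(g) -> np.ndarray:
    """All-pairs weighted shortest paths (Dijkstra over inverse weights)."""
    g = _as_graph(g)
    w = g.weights
    with np.errstate(divide="ignore"):
        inv = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    sp = shortest_path(csr_matrix(inv), method="D", directed=False)
    return sp


def nodal_efficiency(g) -> np.ndarray:
    g = _as_graph(g)
    if g.n < 2:
        raise ValueError("need at least 2 regions")
    sp = shortest_path_lengths(g)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(sp) & (sp > 0), 1.0 / sp, 0.0)
    return inv.sum(axis=0) / (g.n - 1)


def local_efficiency(g) -> np.ndarray:
    g = _as_graph(g)
    if g.n < 3:
        raise ValueError("need at least 3 regions")
    w = g.weights
    out = np.zeros(g.n)
    for i in range(g.n):
        nbrs = np.flatnonzero(w[i] > 0)
        k = len(nbrs)
        if k < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        sp = shortest_path_lengths(WeightedGraph(sub))
        with np.errstate(divide="ignore"):
            inv = np.where(np.isfinite(sp) & (sp > 0), 1.0 / sp, 0.0)
        out[i] = inv.sum() / (k * (k - 1))
    return out


def weighted_clustering(g) -> np.ndarray:
    """Onnela weighted clustering on weights rescaled by the max weight."""
    g = _as_graph(g)
    if g.n < 3:
        raise ValueError("need at least 3 regions")
    w = g.weights
    mx = w.max()
    if mx == 0:
        return np.zeros(g.n)
    what = np.cbrt(w / mx)
    tri = np.diag(what @ what @ what)
    k = g.degree.astype(float)
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, tri / denom, 0.0)
    return c


def characteristic_path_length(g) -> float:
    """Mean of finite off-diagonal shortest-path lengths."""
    g = _as_graph(g)
    sp = shortest_path_lengths(g)
    off = ~np.eye(g.n, dtype=bool)
    vals = sp[off]
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        return float("nan")
    return float(vals.mean())


def _largest_component(w: np.ndarray) -> np.ndarray:
    ncomp, labels = connected_components(csr_matrix(w > 0), directed=False)
    if ncomp == 1:
        return w
    sizes = np.bincount(labels)
    keep = np.flatnonzero(labels == sizes.argmax())
    return w[np.ix_(keep, keep)]


def _rewired_null(w: np.ndarray, rng: np.random.Generator,
                  n_swap_factor: int, max_tries: int = 5) -> np.ndarray:
    """Degree-preserving Maslov-Sneppen rewiring, weights shuffled onto
    the new topology.  Falls back to the largest component if the rewired
    graph keeps coming out disconnected."""
    n = w.shape[0]
    iu = np.triu_indices(n, k=1)
    weights = w[iu][w[iu] > 0]
    G0 = nx.from_numpy_array(w > 0)
    n_swap = n_swap_factor * G0.number_of_edges()
    if n_swap == 0:
        return w.copy()
    H = None
    for _ in range(max_tries):
        Gt = G0.copy()
        try:
            nx.double_edge_swap(Gt, nswap=n_swap, max_tries=100 * n_swap,
                                seed=int(rng.integers(2**31)))
        except nx.NetworkXError:
            pass
        if nx.is_connected(Gt):
            H = Gt
            break
    if H is None:
        warnings.warn("rewired null disconnected after retries; "
                      "using largest component")
        H = Gt.subgraph(max(nx.connected_components(Gt), key=len)).copy()
        H = nx.convert_node_labels_to_integers(H)
    perm = rng.permutation(len(weights))
    out = np.zeros((H.number_of_nodes(), H.number_of_nodes()))
    for k, (a, b) in enumerate(H.edges()):
        out[a, b] = out[b, a] = weights[perm[k % len(weights)]]
    return out


def small_worldness(g, n_null: int = 10, seed=None,
                    n_swap_factor: int = 10) -> float:
    """sigma = (C/C_null) / (L/L_null) against rewired null networks.

    ``n_swap_factor == 0`` keeps the original graph as its own null
    (sigma exactly 1), a useful degenerate check.
    """
    g = _as_graph(g)
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    w = g.weights
    ncomp, _ = connected_components(csr_matrix(w > 0), directed=False)
    if ncomp > 1:
        warnings.warn("graph disconnected; using largest component")
        w = _largest_component(w)
        g = WeightedGraph(w)
    rng = np.random.default_rng(seed)
    C = float(weighted_clustering(g).mean())
    L = characteristic_path_length(g)
    c_null, l_null = [], []
    for _ in range(n_null):
        h = WeightedGraph(_rewired_null(w, rng, n_swap_factor))
        c_null.append(float(weighted_clustering(h).mean()))
        l_null.append(characteristic_path_length(h))
    Cn, Ln = float(np.mean(c_null)), float(np.mean(l_null))
    return (C / Cn) / (L / Ln)


def whole_brain_summaries(cset: ConnectomeSet) -> pd.DataFrame:
    """SC total (sum of streamline probabilities over undirected pairs)
    and mean SC distance (over pairs with a retained connection)."""
    n = cset.n_regions
    iu = np.triu_indices(n, k=1)
    rows = []
    for k, sid in enumerate(cset.ids):
        scv = cset.sc[k][iu]
        dv = cset.dist[k][iu]
        present = scv > 0
        rows.append(
            {
                "id": sid,
                "sc_total": float(scv.sum()),
                "mean_sc_distance": float(dv[present].mean()) if present.any()
                else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def compute_metrics(
    cset: ConnectomeSet,
    n_null: int = 10,
    seed=None,
    n_swap_factor: int = 10,
) -> pd.DataFrame:
    """Per-subject metric table.

    One row per subject: whole-brain scalars (characteristic path length,
    small-worldness, SC total, mean SC distance, mean clustering) plus
    wide region-wise columns ``ne_<label>``, ``le_<label>``.
    Shortest paths use inverse-weight edge lengths (recorded in
    ``DataFrame.attrs`` for auditability).
    """
    labels = cset.regions["label"].tolist()
    summaries = whole_brain_summaries(cset).set_index("id")
    ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    child_seeds = ss.generate_state(cset.n_subjects)
    rows = []
    for k, sid in enumerate(cset.ids):
        g = WeightedGraph(cset.sc[k])
        ne = nodal_efficiency(g)
        le = local_efficiency(g)
        row = {
            "id": sid,
            "char_path_length": characteristic_path_length(g),
            "small_worldness": small_worldness(
                g, n_null=n_null, seed=int(child_seeds[k]),
                n_swap_factor=n_swap_factor,
            ),
            "mean_clustering": float(weighted_clustering(g).mean()),
            "sc_total": summaries.loc[sid, "sc_total"],
            "mean_sc_distance": summaries.loc[sid, "mean_sc_distance"],
        }
        row.update({f"ne_{lab}": v for lab, v in zip(labels, ne)})
        row.update({f"le_{lab}": v for lab, v in zip(labels, le)})
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["edge_length"] = "inverse_weight"
    return df
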