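"""Commute-time kernels and consensus-network construction.

The commute-time (CT) kernel of a weighted undirected graph is the
Moore-Penrose pseudoinverse of its Laplacian L = D - W.  It encodes
random-walk closeness: the expected commute time between i and j is
vol(G) * (K_ii + K_jj - 2 K_ij), with vol(G) the sum of weighted degrees.
Kernels from heterogeneous data sources (a protein-interaction network and
a co-expression network) are cosine-normalized onto a common scale and
fused by a weighted mean; the consensus kernel is then materialized back
into a network by reweighting the base interactome's edges and adding the
globally strongest non-interactome pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "KernelMatrix",
    "ct_kernel",
    "cosine_normalize",
    "consensus_kernel",
    "materialize_network",
    "adjacency_to_graph",
]

_PSD_TOL = -1e-8


@dataclass
class KernelMatrix:
    """Symmetric positive semi-definite gene x gene similarity."""

    nodes: list[str]
    K: np.ndarray

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        if self.K.shape != (len(self.nodes), len(self.nodes)):
            raise ValueError("kernel shape does not match node list")
        if not np.allclose(self.K, self.K.T, atol=1e-8):
            raise ValueError("kernel must be symmetric")

    @property
    def index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.nodes)}

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh((self.K + self.K.T) / 2.0).min())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.K, index=self.nodes, columns=self.nodes)


def _largest_component(net: nx.Graph) -> nx.Graph:
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    if nx.is_connected(net):
        return net
    comps = sorted(nx.connected_components(net), key=lambda c: (-len(c), min(c)))
    dropped = net.number_of_nodes() - len(comps[0])
    warnings.warn(
        f"network is disconnected; using largest component and dropping {dropped} nodes",
        stacklevel=3,
    )
    return net.subgraph(comps[0]).copy()


def ct_kernel(net: nx.Graph, eig_cutoff: float = 1e-10) -> KernelMatrix:
    """Commute-time kernel: pseudoinverse of the weighted Laplacian.

    Disconnected inputs are reduced to their largest connected component
    (with a warning).  The pseudoinverse is built by eigendecomposition,
    discarding eigenvalues below ``eig_cutoff`` times the largest.
    """
    net = _largest_component(net)
    nodes = sorted(net.nodes())
    L = nx.laplacian_matrix(net, nodelist=nodes, weight="weight").toarray().astype(float)
    vals, vecs = np.linalg.eigh(L)
    keep = vals > eig_cutoff * vals.max()
    K = (vecs[:, keep] / vals[keep]) @ vecs[:, keep].T
    K = (K + K.T) / 2.0
    return KernelMatrix(nodes=nodes, K=K)


def commute_time(kernel: KernelMatrix, net: nx.Graph, u: str, v: str) -> float:
    """Expected commute time vol(G) * (K_uu + K_vv - 2 K_uv)."""
    vol = 2.0 * sum(d.get("weight", 1.0) for _, _, d in net.edges(data=True))
    ix = kernel.index
    i, j = ix[u], ix[v]
    return vol * (kernel.K[i, i] + kernel.K[j, j] - 2.0 * kernel.K[i, j])


def cosine_normalize(kernel: KernelMatrix) -> KernelMatrix:
    """K'_ij = K_ij / sqrt(K_ii * K_jj); unit diagonal."""
    d = np.diag(kernel.K).copy()
    bad = np.flatnonzero(d <= 0)
    if bad.size:
        raise ValueError(
            f"non-positive kernel diagonal at nodes: {[kernel.nodes[i] for i in bad[:5]]}"
        )
    s = np.sqrt(d)
    K = kernel.K / np.outer(s, s)
    np.fill_diagonal(K, 1.0)
    return KernelMatrix(nodes=list(kernel.nodes), K=K)


def consensus_kernel(
    k_ppi: KernelMatrix, k_coexp: KernelMatrix | None, weight_ppi: float = 0.5
) -> KernelMatrix:
    """Fuse two cosine-normalized kernels by a weighted mean on the union of
    their node sets.

    Nodes absent from one kernel are embedded with an identity row (unit
    diagonal, zero off-diagonal) in that kernel, so the mean of PSD inputs
    stays PSD.
    """
    if k_coexp is None or len(k_coexp.nodes) == 0:
        return KernelMatrix(nodes=list(k_ppi.nodes), K=k_ppi.K.copy())
    if not 0.0 <= weight_ppi <= 1.0:
        raise ValueError("weight_ppi must be in [0,1]")
    union = sorted(set(k_ppi.nodes) | set(k_coexp.nodes))
    if not set(k_ppi.nodes) & set(k_coexp.nodes):
        warnings.warn(
            "kernels share no nodes; consensus degenerates to a block diagonal",
            stacklevel=2,
        )
    where = {n: i for i, n in enumerate(union)}
    K = np.zeros((len(union), len(union)))
    for kern, w in ((k_ppi, weight_ppi), (k_coexp, 1.0 - weight_ppi)):
        emb = np.eye(len(union))
        pos = [where[n] for n in kern.nodes]
        emb[np.ix_(pos, pos)] = kern.K
        K += w * emb
    return KernelMatrix(nodes=union, K=(K + K.T) / 2.0)


def materialize_network(
    kernel: KernelMatrix, base: nx.Graph, extra_edge_quantile: float = 0.999
) -> nx.Graph:
    """Discrete consensus network from the consensus kernel.

    Keeps every base (interactome) edge, reweighted by the kernel
    similarity, and adds the non-base pairs whose similarity strictly
    exceeds the given global quantile of all non-base similarities
    (quantile 1.0 therefore adds nothing).  Deterministic.
    """
    if not 0.0 <= extra_edge_quantile <= 1.0:
        raise ValueError("extra_edge_quantile must be in [0,1]")
    ix = kernel.index
    n = len(kernel.nodes)
    out = nx.Graph()
    out.add_nodes_from(kernel.nodes)

    in_base = np.zeros((n, n), dtype=bool)
    for u, v in base.edges():
        if u in ix and v in ix:
            i, j = ix[u], ix[v]
            in_base[i, j] = in_base[j, i] = True
    # base edges between nodes missing from the kernel keep their weight
    for u, v, d in base.edges(data=True):
        if u in ix and v in ix:
            w = kernel.K[ix[u], ix[v]]
        else:
            w = d.get("weight", 1.0)
        if u != v:
            out.add_edge(u, v, weight=float(w))

    iu, ju = np.triu_indices(n, k=1)
    nonbase = ~in_base[iu, ju]
    sims = kernel.K[iu, ju][nonbase]
    if sims.size:
        cut = np.quantile(sims, extra_edge_quantile)
        take = np.flatnonzero(sims > cut)
        for t in take:
            i, j = iu[nonbase][t], ju[nonbase][t]
            out.add_edge(kernel.nodes[i], kernel.nodes[j], weight=float(kernel.K[i, j]))
    return out


def adjacency_to_graph(adj: pd.DataFrame, min_weight: float = 0.0) -> nx.Graph:
    """Weighted graph from a symmetric adjacency DataFrame (e.g. |S|^beta),
    keeping edges with weight > min_weight."""
    a = adj.to_numpy(dtype=float)
    nodes = list(adj.index)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    iu, ju = np.triu_indices(len(nodes), k=1)
    keep = a[iu, ju] > min_weight
    for i, j in zip(iu[keep], ju[keep]):
        g.add_edge(nodes[i], nodes[j], weight=float(a[i, j]))
    return g
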