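"""MCODE dense-complex mining and hypergeometric gene-set enrichment.

MCODE proceeds in three stages: (1) vertex weighting — each vertex is
scored by the highest k-core of its closed neighborhood times that core's
density; (2) complex prediction — greedy outward expansion from the
highest-weight unvisited seed, including neighbors whose weight is within
``node_score_cutoff`` of the seed's; (3) post-processing — complexes
without a sufficiently dense core are discarded and singly-connected
fringe nodes are trimmed (haircut).  Complexes are node-disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from disconet.stats import bh_adjust, hypergeom_tail

__all__ = [
    "Complex",
    "mcode",
    "vertex_weights",
    "hypergeom_enrichment",
    "count_driver_rich_modules",
]


@dataclass
class Complex:
    members: set[str]
    score: float
    seed_node: str

    def __len__(self) -> int:
        return len(self.members)


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def _highest_kcore(g: nx.Graph) -> tuple[int, nx.Graph]:
    """The maximum-k k-core of a graph (k, subgraph); (0, empty) if edgeless."""
    if g.number_of_edges() == 0:
        return 0, nx.Graph()
    core_nums = nx.core_number(g)
    k = max(core_nums.values())
    sub = g.subgraph([v for v, c in core_nums.items() if c >= k])
    return k, sub


def vertex_weights(net: nx.Graph, degree_cutoff: int = 2) -> dict[str, float]:
    """MCODE stage-1 weights: highest-k-core index of the closed
    neighborhood times that core's density; vertices below the degree
    cutoff weigh 0."""
    weights: dict[str, float] = {}
    for v in net.nodes():
        if net.degree(v) < degree_cutoff:
            weights[v] = 0.0
            continue
        closed = net.subgraph(set(net.neighbors(v)) | {v})
        k, core = _highest_kcore(closed)
        weights[v] = k * _density(core)
    return weights


def mcode(
    net: nx.Graph,
    degree_cutoff: int = 2,
    node_score_cutoff: float = 0.2,
    k_core: int = 2,
    max_depth: int = 100,
    haircut: bool = True,
    fluff: bool = False,
    fluff_density: float = 0.1,
) -> list[Complex]:
    """Run MCODE with the published defaults and return scored complexes.

    Score = density x size; complexes sorted by score desc, then size desc,
    then seed id.
    """
    if net.number_of_nodes() == 0:
        return []
    weights = vertex_weights(net, degree_cutoff=degree_cutoff)
    visited: set[str] = set()
    complexes: list[Complex] = []

    for seed in sorted(net.nodes(), key=lambda v: (-weights[v], v)):
        if seed in visited or weights[seed] <= 0:
            continue
        threshold = weights[seed] * (1.0 - node_score_cutoff)
        members = {seed}
        frontier = [(seed, 0)]
        visited.add(seed)
        while frontier:
            v, depth = frontier.pop()
            if depth >= max_depth:
                continue
            for nb in net.neighbors(v):
                if nb in visited or nb in members:
                    continue
                if weights[nb] >= threshold:
                    members.add(nb)
                    visited.add(nb)
                    frontier.append((nb, depth + 1))

        sub = net.subgraph(members).copy()
        core_nums = nx.core_number(sub) if sub.number_of_edges() else {}
        if not core_nums or max(core_nums.values()) < k_core:
            continue
        if haircut:
            sub = nx.k_core(sub, 2)
            if sub.number_of_nodes() == 0:
                continue
        if fluff:
            extra = set()
            for v in list(sub.nodes()):
                for nb in net.neighbors(v):
                    if nb in sub or nb in extra:
                        continue
                    hood = net.subgraph(set(net.neighbors(nb)) | {nb})
                    if _density(hood) > fluff_density:
                        extra.add(nb)
            sub = net.subgraph(set(sub.nodes()) | extra).copy()
        final = set(sub.nodes())
        complexes.append(
            Complex(members=final, score=_density(sub) * len(final), seed_node=seed)
        )

    complexes.sort(key=lambda c: (-c.score, -len(c), c.seed_node))
    return complexes


def hypergeom_enrichment(
    query: set[str],
    collection: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of the query in each gene set of a
    collection, BH-adjusted across the collection."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query) & universe
    rows = []
    for name in sorted(collection):
        members = collection[name] & universe
        x = len(query & members)
        p = hypergeom_tail(x, len(universe), len(members), len(query))
        rows.append({"set": name, "set_size": len(members), "overlap": x, "p": p})
    out = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p"])
    out["p_adjusted"] = bh_adjust(out["p"]) if len(out) else out["p"]
    return out


def count_driver_rich_modules(
    complexes: list[Complex],
    candidate_set: set[str],
    known_drivers: set[str],
    min_k: int = 3,
    max_k: int = 11,
) -> pd.DataFrame:
    """Per-complex counts of candidate genes and known drivers, filtered to
    complexes holding between min_k and max_k known drivers."""
    rows = []
    for i, c in enumerate(complexes, start=1):
        n_drv = len(c.members & set(known_drivers))
        rows.append(
            {
                "complex": i,
                "seed_node": c.seed_node,
                "size": len(c),
                "score": c.score,
                "n_candidates": len(c.members & set(candidate_set)),
                "n_known_drivers": n_drv,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["complex", "seed_node", "size", "score", "n_candidates", "n_known_drivers"],
    )
    return df[(df["n_known_drivers"] >= min_k) & (df["n_known_drivers"] <= max_k)].reset_index(
        drop=True
    )
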