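"""DIAMOnD seed expansion and hub/bottleneck topology statistics.

DIAMOnD grows a disease module from a seed set by repeatedly adding the
node whose links into the current set are most statistically surprising
under a hypergeometric null: for a network of N nodes and a current set of
size s, a candidate of degree k with ks links into the set scores
p(k, ks) = sum_{i=ks..k} C(s,i) C(N-s,k-i) / C(N,k); the smallest p wins.
Hubs and bottlenecks are the top fraction of the network by degree and
betweenness centrality; their overrepresentation in a candidate set is
judged against uniformly drawn node sets of equal size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from disconet.stats import hypergeom_tail, mann_whitney

__all__ = [
    "RankedNeighbors",
    "diamond_expand",
    "degree_betweenness",
    "flag_hubs_bottlenecks",
    "randomization_test",
]


@dataclass
class RankedNeighbors:
    """Ordered DIAMOnD additions with their connectivity significance."""

    table: pd.DataFrame  # gene, iteration, p_connectivity, k, ks
    truncated: bool = False
    dropped_not_expressed: list[str] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene"])


def diamond_expand(
    net: nx.Graph,
    seeds: set[str],
    n_add: int,
    allowlist: set[str] | None = None,
    alpha: int = 1,
) -> RankedNeighbors:
    """Iterative DIAMOnD expansion of a seed set.

    Edges are binarized (any positive weight counts as a link); seed links
    may be up-weighted by the integer ``alpha`` (the original algorithm's
    seed weight; 1 leaves the null model unchanged).  Ties in p are broken
    by larger ks, then lexicographic gene id.  The tissue-expression
    ``allowlist`` is applied to the ranked list after expansion so ranks do
    not depend on it.
    """
    if n_add < 1:
        raise ValueError("n_add must be >= 1")
    nodes = set(net.nodes())
    missing = set(seeds) - nodes
    if missing:
        warnings.warn(
            f"{len(missing)} seed genes absent from the network were dropped",
            stacklevel=2,
        )
    cluster = set(seeds) & nodes
    if not cluster:
        raise ValueError("no seed genes present in the network")

    N = net.number_of_nodes() + (alpha - 1) * len(cluster)
    s_extra = (alpha - 1) * len(cluster)

    # candidate bookkeeping: ks = links into the current set (seed links
    # counted alpha times), k = alpha-adjusted degree
    degree = dict(net.degree())
    ks: dict[str, int] = {}
    for node in nodes - cluster:
        ks[node] = sum(
            alpha if nb in seeds else 1
            for nb in net.neighbors(node)
            if nb in cluster
        )

    rows = []
    truncated = False
    for it in range(1, n_add + 1):
        s = len(cluster) + s_extra
        best = None
        for node, links in ks.items():
            if links <= 0:
                continue
            k = degree[node]
            if alpha != 1:
                k += (alpha - 1) * sum(1 for nb in net.neighbors(node) if nb in seeds)
            p = hypergeom_tail(links, N, s, k)
            key = (p, -links, node)
            if best is None or key < best[0]:
                best = (key, node, p, k, links)
        if best is None:
            truncated = True
            break
        _, node, p, k, links = best
        rows.append(
            {"gene": node, "iteration": it, "p_connectivity": p, "k": k, "ks": links}
        )
        cluster.add(node)
        del ks[node]
        for nb in net.neighbors(node):
            if nb not in cluster:
                ks[nb] = ks.get(nb, 0) + 1

    table = pd.DataFrame(
        rows, columns=["gene", "iteration", "p_connectivity", "k", "ks"]
    )
    dropped: list[str] = []
    if allowlist is not None:
        keep = table["gene"].isin(set(allowlist))
        dropped = list(table.loc[~keep, "gene"])
        table = table[keep].reset_index(drop=True)
    return RankedNeighbors(table=table, truncated=truncated, dropped_not_expressed=dropped)


def degree_betweenness(net: nx.Graph, weighted_paths: bool = False) -> pd.DataFrame:
    """Per-node degree (neighbor count) and exact unnormalized betweenness
    centrality (unweighted shortest paths by default)."""
    deg = dict(net.degree())
    btw = nx.betweenness_centrality(
        net, normalized=False, weight="distance" if weighted_paths else None
    )
    nodes = sorted(net.nodes())
    return pd.DataFrame(
        {
            "degree": [deg[n] for n in nodes],
            "betweenness": [btw[n] for n in nodes],
        },
        index=pd.Index(nodes, name="gene"),
    )


def flag_hubs_bottlenecks(stats: pd.DataFrame, top_fraction: float = 0.2) -> pd.DataFrame:
    """Flag the top fraction of nodes by degree (hubs) and betweenness
    (bottlenecks); ties at the quantile threshold are included."""
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0,1)")
    out = stats.copy()
    for col, flag in (("degree", "is_hub"), ("betweenness", "is_bottleneck")):
        cut = np.quantile(stats[col].to_numpy(dtype=float), 1.0 - top_fraction)
        out[flag] = stats[col] >= cut
    return out


def randomization_test(
    flags: pd.DataFrame,
    candidate_set: set[str],
    n_rand: int = 10_000,
    rng_seed: int = 0,
) -> dict:
    """Empirical significance of hub/bottleneck overrepresentation.

    Draws ``n_rand`` uniform node sets of the candidate set's size and
    reports, for hubs and bottlenecks, the add-one empirical p-value
    P(random fraction >= observed), plus a secondary Mann-Whitney p
    comparing the candidate degree distribution against the pooled random
    draws.
    """
    if n_rand < 100:
        raise ValueError("n_rand must be >= 100")
    nodes = np.array(flags.index)
    candidate = sorted(set(candidate_set) & set(flags.index))
    m = len(candidate)
    if m == 0 or m > len(nodes):
        raise ValueError("candidate set empty or larger than the network")
    rng = np.random.default_rng(rng_seed)

    hub = flags["is_hub"].to_numpy(dtype=bool)
    bot = flags["is_bottleneck"].to_numpy(dtype=bool)
    deg = flags["degree"].to_numpy(dtype=float)
    pos = {n: i for i, n in enumerate(flags.index)}
    cand_idx = np.array([pos[g] for g in candidate])

    obs_hub = hub[cand_idx].mean()
    obs_bot = bot[cand_idx].mean()

    draws = np.empty((n_rand, m), dtype=np.int64)
    for r in range(n_rand):
        draws[r] = rng.choice(len(nodes), size=m, replace=False)
    rand_hub = hub[draws].mean(axis=1)
    rand_bot = bot[draws].mean(axis=1)

    p_hub = (1 + int((rand_hub >= obs_hub - 1e-12).sum())) / (n_rand + 1)
    p_bot = (1 + int((rand_bot >= obs_bot - 1e-12).sum())) / (n_rand + 1)
    mw_p = mann_whitney(deg[cand_idx], deg[draws].ravel())

    return {
        "hub_fraction": float(obs_hub),
        "bottleneck_fraction": float(obs_bot),
        "empirical_p_hub": float(p_hub),
        "empirical_p_bottleneck": float(p_bot),
        "mannwhitney_p_degree": float(mw_p),
        "n_rand": n_rand,
        "set_size": m,
    }
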