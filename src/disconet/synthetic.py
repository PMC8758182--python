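"""Synthetic inputs with the statistical structure the pipeline assumes.

The generators emulate, at desk scale, the data regimes of a tumour
target-discovery study: a scale-free protein interactome with a dense
planted disease neighbourhood around seed genes; negative-binomial RNA-seq
counts with latent-factor co-expression blocks, a subset of block genes
strongly up-regulated in tumours; driver labels concentrated in specific
blocks (split across CGC / COSMIC / MutFam-style sources so that seed
assembly recovers them exactly); bioactivities straddling the pChEMBL 6
threshold; and protein families whose relatives are either compact or
dispersed in the interactome.

Every generator is a pure function of :class:`SyntheticConfig`: equal
configs give bitwise-identical outputs.  Role assignments (blocks, Hi-DEGs,
drivers, planted module, seeds) are computed once from the config and
shared by all generators, so the emitted files are mutually consistent.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from disconet import io

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "make_interactome",
    "make_counts",
    "make_mutation_table",
    "make_drug_tables",
    "write_all",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Stated world of the synthetic study, scaled to desk size.

    Defaults keep the real study's strong tumour:normal imbalance and the
    planted structure sizes used throughout the test suite: 1,000 genes,
    60 tumour / 20 normal samples, four 40-gene co-expression blocks, a
    40-gene planted interactome module around 10 seeds, Hi-DEG fold change
    2^4, and NB dispersion 0.2 (typical bulk RNA-seq biological CV ~0.45).
    """

    n_genes: int = 1000
    n_samples_tumour: int = 60
    n_samples_normal: int = 20
    n_blocks: int = 4
    block_size: int = 40
    n_seeds: int = 10
    planted_module_size: int = 40
    ba_attachment: int = 3
    nb_dispersion: float = 0.2
    lfc_up: float = 4.0
    driver_fraction_in_block: float = 0.25
    rng_seed: int = 0

    # fixed aspects of the stated world (not dials): background driver rate
    # among non-block genes, latent block-factor scale, baseline mean scale
    background_driver_rate: float = 0.02
    block_factor_sigma: float = 0.4
    mean_log_expression: float = math.log(100.0)

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_samples_tumour": self.n_samples_tumour,
            "n_samples_normal": self.n_samples_normal,
            "n_blocks": self.n_blocks,
            "block_size": self.block_size,
            "n_seeds": self.n_seeds,
            "planted_module_size": self.planted_module_size,
            "ba_attachment": self.ba_attachment,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.block_size < 3:
            raise ValueError("block_size must be >= 3")
        if self.planted_module_size > self.n_genes:
            raise ValueError("planted_module_size cannot exceed n_genes")
        if self.n_blocks * self.block_size > self.n_genes:
            raise ValueError("blocks do not fit into the gene universe")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if not 0.0 <= self.driver_fraction_in_block <= 1.0:
            raise ValueError("driver_fraction_in_block must be in [0,1]")
        if self.n_seeds > self.planted_module_size:
            raise ValueError("n_seeds cannot exceed planted_module_size")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic stream per generator purpose."""
        return np.random.default_rng([self.rng_seed, stream])


@dataclass
class SyntheticTruth:
    """Ground truth sufficient to score recovery for every pipeline stage."""

    planted_module_genes: set[str]
    planted_block_assignment: dict[str, int]
    planted_hidegs: set[str]
    planted_drivers: set[str]
    seed_genes: set[str] = field(default_factory=set)
    driver_blocks: set[int] = field(default_factory=set)

    def to_json(self) -> dict:
        return {
            "planted_module_genes": sorted(self.planted_module_genes),
            "planted_block_assignment": dict(sorted(self.planted_block_assignment.items())),
            "planted_hidegs": sorted(self.planted_hidegs),
            "planted_drivers": sorted(self.planted_drivers),
            "seed_genes": sorted(self.seed_genes),
            "driver_blocks": sorted(self.driver_blocks),
        }

    @classmethod
    def from_json(cls, obj: dict) -> "SyntheticTruth":
        return cls(
            planted_module_genes=set(obj["planted_module_genes"]),
            planted_block_assignment={k: int(v) for k, v in obj["planted_block_assignment"].items()},
            planted_hidegs=set(obj["planted_hidegs"]),
            planted_drivers=set(obj["planted_drivers"]),
            seed_genes=set(obj.get("seed_genes", [])),
            driver_blocks=set(obj.get("driver_blocks", [])),
        )


def gene_ids(config: SyntheticConfig) -> list[str]:
    return [f"G{i + 1:06d}" for i in range(config.n_genes)]


def _roles(config: SyntheticConfig) -> SyntheticTruth:
    """Deterministic role assignment shared by all generators."""
    genes = gene_ids(config)
    block_assignment: dict[str, int] = {}
    blocks: list[list[str]] = []
    for b in range(config.n_blocks):
        members = genes[b * config.block_size : (b + 1) * config.block_size]
        blocks.append(members)
        for g in members:
            block_assignment[g] = b

    # Hi-DEGs: the first quarter of each block is strongly up-regulated
    n_hideg_per_block = max(1, math.ceil(config.block_size / 4))
    hidegs = {g for members in blocks for g in members[:n_hideg_per_block]}

    # drivers concentrated in the first two blocks, plus a thin background
    # among genes outside any block
    rng = config.rng(11)
    driver_blocks = set(range(min(2, config.n_blocks)))
    drivers: set[str] = set()
    for b in driver_blocks:
        k = int(round(config.driver_fraction_in_block * len(blocks[b])))
        if k:
            drivers |= set(rng.choice(blocks[b], size=k, replace=False))
    non_block = [g for g in genes if g not in block_assignment]
    k_bg = int(round(config.background_driver_rate * len(non_block)))
    if k_bg:
        drivers |= set(rng.choice(non_block, size=k_bg, replace=False))

    # planted interactome module: drivers first, then Hi-DEGs, then filler
    pool = sorted(drivers) + sorted(hidegs - drivers)
    pool += [g for g in genes if g not in set(pool)]
    module = set(pool[: config.planted_module_size])
    seeds = set(sorted(module, key=pool.index)[: config.n_seeds])

    return SyntheticTruth(
        planted_module_genes=module,
        planted_block_assignment=block_assignment,
        planted_hidegs=hidegs,
        planted_drivers=drivers,
        seed_genes=seeds,
        driver_blocks=driver_blocks,
    )


# ---------------------------------------------------------------------------
# interactome
# ---------------------------------------------------------------------------

def make_interactome(config: SyntheticConfig) -> tuple[nx.Graph, SyntheticTruth]:
    """Scale-free interactome with a dense planted module around the seeds.

    A preferential-attachment graph (|E| = m * (n - m)) is rewired so the
    planted module is a genuine dense neighbourhood: its internal edge
    density is at least 5x the density of the rest of the graph, its
    induced subgraph is connected, and its members carry on average
    ``2 * ba_attachment`` internal links — majority-internal connectivity,
    without which a member is usually invisible to seed-connectivity
    methods.  Rewiring preserves the total edge count and keeps the graph
    connected.
    """
    truth = _roles(config)
    rng = config.rng(21)
    n, m = config.n_genes, config.ba_attachment
    g_int = nx.barabasi_albert_graph(n, m, seed=int(rng.integers(2**31 - 1)))
    genes = gene_ids(config)
    # decouple roles from attachment order: without this permutation the
    # planted module would sit on the earliest (hub) nodes and its density
    # signal would vanish into their background degree
    perm = rng.permutation(n)
    g = nx.relabel_nodes(g_int, {i: genes[perm[i]] for i in range(n)})

    module = sorted(truth.planted_module_genes)
    mod_set = set(module)
    n_mod_pairs = len(module) * (len(module) - 1) // 2
    n_out_pairs = n * (n - 1) // 2 - n_mod_pairs

    # members' links are majority-internal (mean internal degree 2m against
    # ~m external), the defining feature of a dense disease neighbourhood;
    # the 5x-density floor alone leaves most members without seed links
    min_internal = config.ba_attachment * len(module)

    def state() -> tuple[float, float, int, bool]:
        e_in = sum(1 for u, v in g.edges() if u in mod_set and v in mod_set)
        e_out = g.number_of_edges() - e_in
        connected = nx.is_connected(g.subgraph(module))
        return e_in / n_mod_pairs, e_out / n_out_pairs, e_in, connected

    target = 5.0
    guard = 0
    while True:
        d_in, d_out, e_in, mod_connected = state()
        dense_enough = (
            (d_out == 0 or d_in / max(d_out, 1e-12) >= target)
            and e_in >= min_internal
        )
        if dense_enough and mod_connected:
            break
        guard += 1
        if guard > 20 * n_mod_pairs:
            raise RuntimeError("module densification failed to converge")
        if not mod_connected and dense_enough:
            # bridge two components of the induced module subgraph
            comps = sorted(
                nx.connected_components(g.subgraph(module)), key=lambda c: (len(c), min(c))
            )
            u = sorted(comps[0])[int(rng.integers(len(comps[0])))]
            rest = sorted(mod_set - set(comps[0]))
            v = rest[int(rng.integers(len(rest)))]
        else:
            absent = [
                (module[i], module[j])
                for i in range(len(module))
                for j in range(i + 1, len(module))
                if not g.has_edge(module[i], module[j])
            ]
            if not absent:
                break
            u, v = absent[int(rng.integers(len(absent)))]
        g.add_edge(u, v)
        # remove a random outside edge that keeps the graph connected
        outside = [
            e for e in g.edges() if not (e[0] in mod_set and e[1] in mod_set)
        ]
        order = rng.permutation(len(outside))
        for a, b in (outside[i] for i in order):
            g.remove_edge(a, b)
            if nx.is_connected(g):
                break
            g.add_edge(a, b)

    nx.set_edge_attributes(g, 1.0, "weight")
    return g, truth


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def make_counts(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.Series, SyntheticTruth]:
    """NB counts with latent-factor co-expression blocks and planted Hi-DEGs.

    Per-gene baseline means are log-normal around exp(mean_log_expression);
    each (block, sample) pair draws a shared log-normal factor which
    induces within-block correlation; planted Hi-DEGs have their tumour
    mean multiplied by 2**lfc_up.  Counts are NB(mean, dispersion).
    """
    truth = _roles(config)
    rng = config.rng(31)
    genes = gene_ids(config)
    n_t, n_n = config.n_samples_tumour, config.n_samples_normal
    samples = [f"T{i + 1:03d}" for i in range(n_t)] + [
        f"N{i + 1:03d}" for i in range(n_n)
    ]
    groups = pd.Series(
        ["tumour"] * n_t + ["normal"] * n_n, index=pd.Index(samples, name="sample_id"),
        name="group",
    )

    base = np.exp(rng.normal(config.mean_log_expression, 1.0, size=config.n_genes))
    sigma = config.block_factor_sigma
    factors = np.exp(
        rng.normal(0.0, sigma, size=(config.n_blocks, n_t + n_n)) - sigma**2 / 2.0
    )

    mu = np.tile(base[:, None], (1, n_t + n_n))
    for i, g in enumerate(genes):
        b = truth.planted_block_assignment.get(g)
        if b is not None:
            mu[i] *= factors[b]
        if g in truth.planted_hidegs:
            mu[i, :n_t] *= 2.0**config.lfc_up

    r = 1.0 / config.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=samples)
    return df, groups, truth


# ---------------------------------------------------------------------------
# mutation table
# ---------------------------------------------------------------------------

def make_mutation_table(config: SyntheticConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Gene-level mutation table whose driver-assembly output is exactly the
    planted drivers.

    Drivers are split round-robin across sources: CGC rows (curated, any
    count), COSMIC rows with mutation ratio strictly above 3%, and MutFam
    rows placed in the top quartile of a 4-gene family of decoys.  Decoy
    COSMIC rows sit at or below the 3% ratio.
    """
    truth = _roles(config)
    rng = config.rng(41)
    drivers = sorted(truth.planted_drivers)
    non_drivers = [g for g in gene_ids(config) if g not in truth.planted_drivers]
    rows: list[dict] = []

    for i, g in enumerate(drivers):
        source = ("CGC", "COSMIC", "MUTFAM")[i % 3]
        if source == "CGC":
            rows.append(
                {
                    "gene": g,
                    "n_mutations": int(rng.integers(2, 30)),
                    "n_samples_tested": 100,
                    "source": "CGC",
                    "mutfam_id": "",
                }
            )
        elif source == "COSMIC":
            rows.append(
                {
                    "gene": g,
                    "n_mutations": int(rng.integers(4, 25)),  # ratio > 3% at 100 tested
                    "n_samples_tested": 100,
                    "source": "COSMIC",
                    "mutfam_id": "",
                }
            )
        else:
            fam = f"MF{i:04d}"
            rows.append(
                {
                    "gene": g,
                    "n_mutations": 10,
                    "n_samples_tested": 100,
                    "source": "MUTFAM",
                    "mutfam_id": fam,
                }
            )
            decoys = rng.choice(non_drivers, size=3, replace=False)
            for d, c in zip(decoys, (5, 3, 1)):
                rows.append(
                    {
                        "gene": str(d),
                        "n_mutations": c,
                        "n_samples_tested": 100,
                        "source": "MUTFAM",
                        "mutfam_id": fam,
                    }
                )

    # COSMIC decoys at or below the ratio threshold
    n_decoy = min(50, len(non_drivers))
    for d in rng.choice(non_drivers, size=n_decoy, replace=False):
        rows.append(
            {
                "gene": str(d),
                "n_mutations": int(rng.integers(0, 4)),  # ratio <= 3%
                "n_samples_tested": 100,
                "source": "COSMIC",
                "mutfam_id": "",
            }
        )
    df = pd.DataFrame(rows, columns=io.MUTATION_COLUMNS)
    return df, truth


# ---------------------------------------------------------------------------
# drugs and protein families
# ---------------------------------------------------------------------------

def make_drug_tables(
    config: SyntheticConfig, network: nx.Graph
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bioactivities straddling pChEMBL 6, plus compact and dispersed
    protein families.

    The compact family's relatives are neighbors of the network's top hub
    (so their open neighborhoods overlap); the dispersed family's relatives
    are pairwise non-adjacent genes with no shared neighbors.  Both are
    druggable with annotated drugs; a third family is not druggable.
    """
    truth = _roles(config)
    rng = config.rng(51)
    drivers = sorted(truth.planted_drivers)
    module = sorted(truth.planted_module_genes)

    # bioactivities: half the targeted genes above threshold, half below
    targets = sorted(set(drivers[:10]) | set(module[:10]))
    bio_rows = []
    for i, g in enumerate(targets):
        for j in range(int(rng.integers(1, 4))):
            above = (i + j) % 2 == 0
            pchembl = float(rng.uniform(6.0, 9.5)) if above else float(rng.uniform(3.5, 5.9))
            drug = f"D{(i * 7 + j) % 40 + 1:03d}"
            atc = "L01XE" if (i + j) % 3 == 0 else ("C07AB" if (i + j) % 3 == 1 else "")
            bio_rows.append(
                {
                    "gene": g,
                    "drug": drug,
                    "pchembl": round(pchembl, 2),
                    "atc_code": atc,
                    "direct_binding": bool((i + j) % 5 != 4),
                }
            )
    bioactivity = pd.DataFrame(bio_rows, columns=io.BIOACTIVITY_COLUMNS)

    # compact family: low-degree neighbors of the top hub share that hub
    hub = max(sorted(network.nodes()), key=lambda v: (network.degree(v), v))
    neighbors = sorted(network.neighbors(hub), key=lambda v: (network.degree(v), v))
    compact = neighbors[:5] if len(neighbors) >= 5 else neighbors

    # dispersed family: greedily pick genes with pairwise-disjoint closed
    # neighborhoods
    dispersed: list[str] = []
    blocked: set[str] = set(compact) | {hub}
    for g in sorted(network.nodes(), key=lambda v: (network.degree(v), v)):
        if g in blocked:
            continue
        hood = set(network.neighbors(g)) | {g}
        if hood & blocked:
            continue
        dispersed.append(g)
        blocked |= hood
        if len(dispersed) == 5:
            break

    fam_rows = []
    for fam, members, druggable, drugs_ann in (
        ("FF_COMPACT", compact, True, "D901,D902"),
        ("FF_DISPERSED", dispersed, True, "D903"),
        ("FF_INERT", module[:4], False, ""),
    ):
        for g in members:
            fam_rows.append(
                {
                    "gene": g,
                    "funfam": fam,
                    "is_druggable": druggable,
                    "annotated_drugs": drugs_ann,
                }
            )
    funfams = pd.DataFrame(fam_rows, columns=["gene", "funfam", "is_druggable", "annotated_drugs"])
    return bioactivity, funfams


# ---------------------------------------------------------------------------
# one-call writer
# ---------------------------------------------------------------------------

def write_all(config: SyntheticConfig, outdir) -> SyntheticTruth:
    """Generate every pipeline input under ``outdir``.

    Files: counts.tsv, samples.tsv, interactome.sif, mutations.tsv,
    bioactivity.tsv, funfams.tsv, allowlist.txt, genesets.gmt, truth.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    net, truth = make_interactome(config)
    counts, groups, _ = make_counts(config)
    mutations, _ = make_mutation_table(config)
    bioactivity, funfams = make_drug_tables(config, net)

    io.write_counts(counts, outdir / "counts.tsv")
    io.write_sample_sheet(groups, outdir / "samples.tsv")
    io.write_sif(net, outdir / "interactome.sif")
    io.write_mutation_table(mutations, outdir / "mutations.tsv")
    io.write_bioactivity(bioactivity, outdir / "bioactivity.tsv")
    io.write_funfams(funfams, outdir / "funfams.tsv")
    io.write_gene_list(gene_ids(config), outdir / "allowlist.txt")

    blocks: dict[str, set[str]] = {}
    for g, b in truth.planted_block_assignment.items():
        blocks.setdefault(f"BLOCK{b + 1}", set()).add(g)
    blocks["PLANTED_MODULE"] = set(truth.planted_module_genes)
    blocks["PLANTED_HIDEG"] = set(truth.planted_hidegs)
    io.write_gmt(blocks, outdir / "genesets.gmt")

    (outdir / "truth.json").write_text(
        json.dumps(truth.to_json(), indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return truth
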