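"""Stage orchestration: run each pipeline step against a working directory.

Every stage reads and writes plain-text files under one working directory
and appends a manifest entry (config hash, input/output hashes, package
version), so a rerun with identical inputs is verifiably byte-identical.
One RNG seed in the config governs every stochastic stage.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from disconet import __version__, io
from disconet import complexes as cx
from disconet import diffusion, drugs, expression, kernels, seeds, synthetic

__all__ = ["PipelineConfig", "run_stage", "STAGES"]


@dataclass
class PipelineConfig:
    """All thresholds of every stage plus the working directory and seed."""

    workdir: str = "run"
    rng_seed: int = 0

    # synthetic world
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

    # seed assembly
    ratio_threshold: float = 0.03
    cosmic_strict: bool = True

    # expression
    lfc_min: float = 4.0
    alpha: float = 0.01
    n_top_genes: int = 5000
    beta_grid: list[int] = field(default_factory=lambda: list(range(1, 13)))
    r2_min: float = 0.8
    min_module_size: int = 30
    cut_height_quantile: float = 0.99
    enrich_alpha: float = 0.05

    # fusion
    weight_ppi: float = 0.5
    extra_edge_quantile: float = 0.999

    # diffusion + topology
    n_add: int = 200
    diamond_alpha: int = 1
    top_fraction: float = 0.2
    n_rand: int = 10_000

    # complexes
    mcode_input: str = "consensus"  # or "interactome"
    mcode_degree_cutoff: int = 2
    mcode_node_score_cutoff: float = 0.2
    mcode_k_core: int = 2
    mcode_max_depth: int = 100
    driver_rich_min: int = 3
    driver_rich_max: int = 11

    # drugs
    pchembl_min: float = 6.0

    @property
    def path(self) -> Path:
        return Path(self.workdir)

    def synthetic_config(self) -> synthetic.SyntheticConfig:
        return synthetic.SyntheticConfig(
            n_genes=self.n_genes,
            n_samples_tumour=self.n_samples_tumour,
            n_samples_normal=self.n_samples_normal,
            n_blocks=self.n_blocks,
            block_size=self.block_size,
            n_seeds=self.n_seeds,
            planted_module_size=self.planted_module_size,
            ba_attachment=self.ba_attachment,
            nb_dispersion=self.nb_dispersion,
            lfc_up=self.lfc_up,
            driver_fraction_in_block=self.driver_fraction_in_block,
            rng_seed=self.rng_seed,
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


class DependencyError(RuntimeError):
    """A stage's upstream outputs are missing."""


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _require(cfg: PipelineConfig, names: list[str], produced_by: str) -> None:
    missing = [n for n in names if not (cfg.path / n).exists()]
    if missing:
        raise DependencyError(
            f"missing {missing}; run the '{produced_by}' stage first"
        )


def _manifest_update(cfg: PipelineConfig, stage: str, inputs: list[str], outputs: list[str]) -> dict:
    cfg_hash = hashlib.sha256(
        json.dumps(asdict(cfg), sort_keys=True).encode()
    ).hexdigest()[:16]
    entry = {
        "stage": stage,
        "version": __version__,
        "config_hash": cfg_hash,
        "inputs": {n: _sha(cfg.path / n) for n in inputs},
        "outputs": {n: _sha(cfg.path / n) for n in outputs},
    }
    mpath = cfg.path / "manifest.json"
    manifest = json.loads(mpath.read_text()) if mpath.exists() else {}
    manifest[stage] = entry
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return entry


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, log=print) -> None:
    cfg.path.mkdir(parents=True, exist_ok=True)
    truth = synthetic.write_all(cfg.synthetic_config(), cfg.path)
    log(
        f"simulate: {cfg.n_genes} genes, {cfg.n_samples_tumour}+{cfg.n_samples_normal} samples, "
        f"{len(truth.planted_drivers)} planted drivers, module {len(truth.planted_module_genes)}"
    )
    _manifest_update(
        cfg,
        "simulate",
        [],
        [
            "counts.tsv",
            "samples.tsv",
            "interactome.sif",
            "mutations.tsv",
            "bioactivity.tsv",
            "funfams.tsv",
            "allowlist.txt",
            "genesets.gmt",
            "truth.json",
        ],
    )


def stage_seeds(cfg: PipelineConfig, log=print) -> None:
    _require(cfg, ["mutations.tsv", "allowlist.txt"], "simulate")
    table = io.read_mutation_table(cfg.path / "mutations.tsv")
    allow = io.read_gene_list(cfg.path / "allowlist.txt")
    cgc = set(table.loc[table["source"] == "CGC", "gene"])
    cosmic = seeds.filter_cosmic(table, cfg.ratio_threshold, strict=cfg.cosmic_strict)
    mutfam = seeds.select_mutfam_top_quartile(table, allow)
    drv = seeds.assemble_drivers(cgc, cosmic, mutfam)
    drv.to_frame().to_csv(cfg.path / "drivers.tsv", sep="\t", index=False)
    mw_p = seeds.compare_mutation_distributions(
        table.loc[table["source"] == "CGC", "n_mutations"],
        table.loc[table["source"] == "MUTFAM", "n_mutations"],
    ) if (table["source"] == "CGC").any() and (table["source"] == "MUTFAM").any() else None
    log(
        f"seeds: CGC {len(cgc)} + COSMIC {len(cosmic)} + MutFam {len(mutfam)} "
        f"-> {len(drv)} non-redundant drivers (CGC-vs-MutFam MW p={mw_p})"
    )
    _manifest_update(cfg, "seeds", ["mutations.tsv", "allowlist.txt"], ["drivers.tsv"])


def stage_express(cfg: PipelineConfig, log=print) -> None:
    _require(cfg, ["counts.tsv", "samples.tsv"], "simulate")
    _require(cfg, ["drivers.tsv"], "seeds")
    counts = io.read_counts(cfg.path / "counts.tsv")
    groups = io.read_sample_sheet(cfg.path / "samples.tsv")
    drv = seeds.DriverSet.from_frame(pd.read_csv(cfg.path / "drivers.tsv", sep="\t"))

    de = expression.de_test(counts, groups)
    de.to_csv(cfg.path / "de_table.tsv", sep="\t")
    hidegs = expression.select_hidegs(de, cfg.lfc_min, cfg.alpha)

    top = expression.select_top_genes(de, cfg.n_top_genes)
    S = expression.bicor_matrix(counts.loc[top])
    beta = expression.choose_beta(S, cfg.beta_grid, cfg.r2_min)
    adj = expression.soft_threshold(S, beta)
    adj.to_csv(cfg.path / "adjacency.tsv", sep="\t")
    t = expression.tom(adj)
    partition = expression.detect_modules(t, cfg.min_module_size, cfg.cut_height_quantile)

    enr = expression.module_driver_enrichment(partition, drv, alpha=cfg.enrich_alpha)
    enr.to_csv(cfg.path / "enrichment.tsv", sep="\t", index=False)
    enriched = set(enr.loc[enr["enriched"], "module"]) - {expression.UNASSIGNED}

    seed_set, provenance = expression.build_seed_set(drv, hidegs, partition, enriched)
    modules_table = pd.DataFrame(
        {
            "gene": partition.index,
            "module": partition.values,
            "is_hideg": [g in set(hidegs.index) for g in partition.index],
            "is_driver": [g in drv.genes for g in partition.index],
        }
    )
    modules_table.to_csv(cfg.path / "modules.tsv", sep="\t", index=False)
    io.write_gene_list(seed_set, cfg.path / "seeds.txt")
    provenance.to_csv(cfg.path / "seed_provenance.tsv", sep="\t", index=False)
    log(
        f"express: {len(hidegs)} Hi-DEGs, beta={beta}, "
        f"{partition.nunique() - (1 if (partition == expression.UNASSIGNED).any() else 0)} modules, "
        f"{len(enriched)} driver-enriched, {len(drv)} drivers -> {len(seed_set)} seeds"
    )
    _manifest_update(
        cfg,
        "express",
        ["counts.tsv", "samples.tsv", "drivers.tsv"],
        ["de_table.tsv", "adjacency.tsv", "modules.tsv", "enrichment.tsv", "seeds.txt"],
    )


def stage_fuse(cfg: PipelineConfig, log=print) -> None:
    _require(cfg, ["interactome.sif"], "simulate")
    _require(cfg, ["adjacency.tsv"], "express")
    ppi = io.read_network(cfg.path / "interactome.sif")
    adj = pd.read_csv(cfg.path / "adjacency.tsv", sep="\t", index_col=0)
    coexp_net = kernels.adjacency_to_graph(adj, min_weight=1e-6)

    k_ppi = kernels.cosine_normalize(kernels.ct_kernel(ppi))
    k_co = kernels.cosine_normalize(kernels.ct_kernel(coexp_net))
    consensus = kernels.consensus_kernel(k_ppi, k_co, cfg.weight_ppi)
    net = kernels.materialize_network(consensus, ppi, cfg.extra_edge_quantile)
    io.write_network(net, cfg.path / "consensus_network.tsv")
    log(
        f"fuse: PPI {ppi.number_of_nodes()}n/{ppi.number_of_edges()}e + "
        f"coexpression {coexp_net.number_of_nodes()}n -> consensus "
        f"{net.number_of_nodes()}n/{net.number_of_edges()}e"
    )
    _manifest_update(
        cfg, "fuse", ["interactome.sif", "adjacency.tsv"], ["consensus_network.tsv"]
    )


def stage_diffuse(cfg: PipelineConfig, log=print) -> None:
    _require(cfg, ["consensus_network.tsv"], "fuse")
    _require(cfg, ["seeds.txt"], "express")
    net = io.read_network(cfg.path / "consensus_network.tsv")
    seed_set = io.read_gene_list(cfg.path / "seeds.txt")
    allow = io.read_gene_list(cfg.path / "allowlist.txt")
    ranked = diffusion.diamond_expand(
        net, seed_set, cfg.n_add, allowlist=allow, alpha=cfg.diamond_alpha
    )
    ranked.table.to_csv(cfg.path / "neighbors.tsv", sep="\t", index=False)
    log(
        f"diffuse: {len(seed_set)} seeds + {len(ranked.table)} ranked neighbours "
        f"({len(ranked.dropped_not_expressed)} dropped by expression filter)"
    )
    _manifest_update(
        cfg,
        "diffuse",
        ["consensus_network.tsv", "seeds.txt", "allowlist.txt"],
        ["neighbors.tsv"],
    )


def stage_topology(cfg: PipelineConfig, log=print) -> None:
    _require(cfg, ["consensus_network.tsv"], "fuse")
    _require(cfg, ["neighbors.tsv"], "diffuse")
    net = io.read_network(cfg.path / "consensus_network.tsv")
    seed_set = io.read_gene_list(cfg.path / "seeds.txt")
    nb = pd.read_csv(cfg.path / "neighbors.tsv", sep="\t")
    candidate = (seed_set | set(nb["gene"])) & set(net.nodes())

    stats = diffusion.degree_betweenness(net)
    flags = diffusion.flag_hubs_bottlenecks(stats, cfg.top_fraction)
    flags.to_csv(cfg.path / "topology.tsv", sep="\t")
    summary = diffusion.randomization_test(
        flags, candidate, n_rand=cfg.n_rand, rng_seed=cfg.rng_seed
    )
    io.write_json(summary, cfg.path / "topology_summary.json")
    log(
        f"topology: candidate subnetwork {len(candidate)} genes, "
        f"{summary['hub_fraction']:.1%} hubs (p={summary['empirical_p_hub']:.3g}), "
        f"{summary['bottleneck_fraction']:.1%} bottlenecks (p={summary['empirical_p_bottleneck']:.3g})"
    )
    _manifest_update(
        cfg,
        "topology",
        ["consensus_network.tsv", "neighbors.tsv", "seeds.txt"],
        ["topology.tsv", "topology_summary.json"],
    )


def stage_modules(cfg: PipelineConfig, log=print) -> None:
    source = "consensus_network.tsv" if cfg.mcode_input == "consensus" else "interactome.sif"
    _require(cfg, [source], "fuse" if cfg.mcode_input == "consensus" else "simulate")
    _require(cfg, ["neighbors.tsv"], "diffuse")
    net = io.read_network(cfg.path / source)
    found = cx.mcode(
        net,
        degree_cutoff=cfg.mcode_degree_cutoff,
        node_score_cutoff=cfg.mcode_node_score_cutoff,
        k_core=cfg.mcode_k_core,
        max_depth=cfg.mcode_max_depth,
    )
    rows = [
        {
            "complex": i + 1,
            "seed_node": c.seed_node,
            "size": len(c),
            "score": c.score,
            "members": ",".join(sorted(c.members)),
        }
        for i, c in enumerate(found)
    ]
    pd.DataFrame(rows, columns=["complex", "seed_node", "size", "score", "members"]).to_csv(
        cfg.path / "complexes.tsv", sep="\t", index=False
    )

    seed_set = io.read_gene_list(cfg.path / "seeds.txt")
    nb = pd.read_csv(cfg.path / "neighbors.tsv", sep="\t")
    candidate = seed_set | set(nb["gene"])
    gmt_path = cfg.path / "genesets.gmt"
    if gmt_path.exists():
        collection = io.read_gmt(gmt_path)
        enr = cx.hypergeom_enrichment(candidate, collection, set(net.nodes()))
        enr.to_csv(cfg.path / "enrichment_by_set.tsv", sep="\t", index=False)
    drv = seeds.DriverSet.from_frame(pd.read_csv(cfg.path / "drivers.tsv", sep="\t"))
    rich = cx.count_driver_rich_modules(
        found, candidate, drv.genes, cfg.driver_rich_min, cfg.driver_rich_max
    )
    rich.to_csv(cfg.path / "driver_rich_complexes.tsv", sep="\t", index=False)
    log(f"modules: {len(found)} complexes, {len(rich)} rich in known drivers")
    _manifest_update(
        cfg,
        "modules",
        [source, "neighbors.tsv", "seeds.txt"],
        ["complexes.tsv", "driver_rich_complexes.tsv"],
    )


def stage_drugs(cfg: PipelineConfig, log=print) -> None:
    _require(cfg, ["neighbors.tsv"], "diffuse")
    _require(cfg, ["bioactivity.tsv", "funfams.tsv"], "simulate")
    seed_set = io.read_gene_list(cfg.path / "seeds.txt")
    nb = pd.read_csv(cfg.path / "neighbors.tsv", sep="\t")
    candidate = seed_set | set(nb["gene"])
    bio = io.read_bioactivity(cfg.path / "bioactivity.tsv")
    fams = io.read_funfams(cfg.path / "funfams.tsv")

    direct = drugs.map_drugs(candidate, bio, cfg.pchembl_min)
    inherited = drugs.inherit_funfam_drugs(candidate, fams, direct)
    direct.to_csv(cfg.path / "drug_pairs_direct.tsv", sep="\t", index=False)
    inherited.to_csv(cfg.path / "drug_pairs_inherited.tsv", sep="\t", index=False)

    net = io.read_network(cfg.path / "consensus_network.tsv")
    scores = {}
    for fam, members in fams.groupby("funfam")["gene"].agg(set).items():
        scores[fam] = drugs.side_effect_propensity(members, net)
    io.write_json(scores, cfg.path / "funfam_scores.json")
    anti = drugs.count_antineoplastic(direct, bio)
    io.write_json(anti, cfg.path / "antineoplastic.json")
    log(
        f"drugs: {direct['gene'].nunique() if len(direct) else 0} targets / "
        f"{direct['drug'].nunique() if len(direct) else 0} direct drugs, "
        f"{len(inherited)} inherited pairs, {anti['n_antineoplastic']} antineoplastic"
    )
    _manifest_update(
        cfg,
        "drugs",
        ["neighbors.tsv", "seeds.txt", "bioactivity.tsv", "funfams.tsv"],
        ["drug_pairs_direct.tsv", "drug_pairs_inherited.tsv", "funfam_scores.json"],
    )


def stage_report(cfg: PipelineConfig, log=print) -> None:
    _require(cfg, ["drug_pairs_direct.tsv", "funfam_scores.json"], "drugs")
    _require(cfg, ["topology.tsv"], "topology")
    _require(cfg, ["modules.tsv"], "express")
    seed_set = io.read_gene_list(cfg.path / "seeds.txt")
    nb = pd.read_csv(cfg.path / "neighbors.tsv", sep="\t")
    direct = pd.read_csv(cfg.path / "drug_pairs_direct.tsv", sep="\t").fillna({"atc_code": ""})
    inherited = pd.read_csv(cfg.path / "drug_pairs_inherited.tsv", sep="\t")
    if "gene" not in direct.columns or direct.empty:
        direct = pd.DataFrame(columns=["gene", "drug", "pchembl", "atc_code", "source"])
    if inherited.empty:
        inherited = pd.DataFrame(columns=["gene", "drug", "funfam", "source"])
    fams = io.read_funfams(cfg.path / "funfams.tsv")
    scores = json.loads((cfg.path / "funfam_scores.json").read_text())
    flags = pd.read_csv(cfg.path / "topology.tsv", sep="\t", index_col=0)
    modules_table = pd.read_csv(cfg.path / "modules.tsv", sep="\t")
    partition = modules_table.set_index("gene")["module"]

    report = drugs.build_report(
        seed_set,
        list(nb["gene"]),
        direct,
        inherited,
        fams,
        scores,
        topology_flags=flags,
        partition=partition,
    )
    report.to_csv(cfg.path / "report.tsv", sep="\t", index=False)
    io.write_json(report.to_dict(orient="records"), cfg.path / "report.json")
    log(f"report: {len(report)} candidate genes written to report.tsv")
    _manifest_update(
        cfg,
        "report",
        ["seeds.txt", "neighbors.tsv", "drug_pairs_direct.tsv", "topology.tsv"],
        ["report.tsv", "report.json"],
    )


STAGES = {
    "simulate": stage_simulate,
    "seeds": stage_seeds,
    "express": stage_express,
    "fuse": stage_fuse,
    "diffuse": stage_diffuse,
    "topology": stage_topology,
    "modules": stage_modules,
    "drugs": stage_drugs,
    "report": stage_report,
}

PIPELINE_ORDER = list(STAGES)


def run_stage(stage_name: str, cfg: PipelineConfig, log=print) -> None:
    """Run one named stage (or 'all' for the full pipeline in order)."""
    if stage_name == "all":
        for name in PIPELINE_ORDER:
            t0 = time.perf_counter()
            STAGES[name](cfg, log=log)
            log(f"  [{name} done in {time.perf_counter() - t0:.1f}s]")
        return
    if stage_name not in STAGES:
        raise KeyError(f"unknown stage: {stage_name}")
    STAGES[stage_name](cfg, log=log)
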