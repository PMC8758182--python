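"""Drug-target mapping, protein-family drug inheritance, and side-effect
propensity scoring.

Candidate genes are mapped to drugs three ways: (i) direct high-affinity
bioactivities (pChEMBL >= 6, i.e. potency at or below 1 uM, direct binding
only); (ii) inheritance of drugs annotated to a druggable protein
functional family (FunFam) by any of its relatives; (iii) a side-effect
propensity proxy per FunFam — the median pairwise network similarity
(Jaccard overlap of open neighborhoods) of the family's relatives; compact
families (high median similarity) are associated with fewer off-target
side effects than dispersed ones.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

__all__ = [
    "map_drugs",
    "inherit_funfam_drugs",
    "side_effect_propensity",
    "count_antineoplastic",
    "build_report",
    "ANTINEOPLASTIC_ATC_PREFIX",
]

ANTINEOPLASTIC_ATC_PREFIX = "L01"


def map_drugs(
    candidates: set[str], table: pd.DataFrame, pchembl_min: float = 6.0
) -> pd.DataFrame:
    """Direct drug-target pairs: candidate gene, direct binding, and
    pChEMBL >= pchembl_min (inclusive)."""
    if pchembl_min <= 0:
        raise ValueError("pchembl_min must be > 0")
    keep = (
        table["gene"].isin(set(candidates))
        & table["direct_binding"]
        & (table["pchembl"] >= pchembl_min)
    )
    out = table.loc[keep, ["gene", "drug", "pchembl", "atc_code"]].copy()
    out["source"] = "direct"
    return out.sort_values(["gene", "drug"], kind="mergesort").reset_index(drop=True)


def inherit_funfam_drugs(
    candidates: set[str],
    funfams: pd.DataFrame,
    direct_pairs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Drugs inherited by candidates from their druggable FunFams.

    For every candidate mapped to a druggable family with annotated drugs,
    emit one (gene, drug) pair per annotated drug, skipping pairs already
    found as direct mappings.
    """
    existing: set[tuple[str, str]] = set()
    if direct_pairs is not None and len(direct_pairs):
        existing = set(zip(direct_pairs["gene"], direct_pairs["drug"]))
    rows = []
    for r in funfams.itertuples():
        if r.gene not in candidates or not r.is_druggable:
            continue
        drugs = [d for d in str(r.annotated_drugs).split(",") if d]
        for d in drugs:
            if (r.gene, d) in existing:
                continue
            rows.append({"gene": r.gene, "drug": d, "funfam": r.funfam, "source": "inherited"})
    out = pd.DataFrame(rows, columns=["gene", "drug", "funfam", "source"])
    return out.drop_duplicates(["gene", "drug"]).sort_values(
        ["gene", "drug"], kind="mergesort"
    ).reset_index(drop=True)


def side_effect_propensity(funfam_members: set[str], net: nx.Graph) -> float | None:
    """Median pairwise Jaccard similarity of open neighborhoods of the
    family's relatives present in the network, in [0,1].

    Higher = more compact family = drugs hitting its relatives are less
    likely to cause off-target side effects.  None when fewer than two
    relatives are in the network (distinct from a true 0).
    """
    members = sorted(set(funfam_members) & set(net.nodes()))
    if len(members) < 2:
        return None
    hoods = {m: set(net.neighbors(m)) for m in members}
    sims = []
    for i, a in enumerate(members):
        for b in members[i + 1 :]:
            union = hoods[a] | hoods[b]
            sims.append(len(hoods[a] & hoods[b]) / len(union) if union else 0.0)
    sims.sort()
    n = len(sims)
    mid = n // 2
    return float(sims[mid]) if n % 2 else float((sims[mid - 1] + sims[mid]) / 2.0)


def count_antineoplastic(pairs: pd.DataFrame, table: pd.DataFrame) -> dict:
    """Count distinct mapped drugs whose ATC code marks them antineoplastic
    (prefix L01); drugs without an ATC code are reported separately."""
    atc = (
        table.dropna(subset=["atc_code"])
        .drop_duplicates("drug")
        .set_index("drug")["atc_code"]
        .to_dict()
    )
    drugs = sorted(set(pairs["drug"])) if len(pairs) else []
    anti = [d for d in drugs if str(atc.get(d, "")).startswith(ANTINEOPLASTIC_ATC_PREFIX)]
    unclassified = [d for d in drugs if d not in atc or pd.isna(atc[d]) or atc[d] == ""]
    return {
        "n_antineoplastic": len(anti),
        "antineoplastic_drugs": anti,
        "unclassified_drugs": unclassified,
    }


def build_report(
    seeds: set[str],
    neighbors: list[str],
    direct_pairs: pd.DataFrame,
    inherited_pairs: pd.DataFrame,
    funfams: pd.DataFrame,
    funfam_scores: dict[str, float | None],
    topology_flags: pd.DataFrame | None = None,
    partition: pd.Series | None = None,
) -> pd.DataFrame:
    """Assemble the per-gene candidate target report.

    One row per candidate gene (seed or retained neighbor) with drug
    mappings, FunFam memberships, the family side-effect score, and
    hub/bottleneck flags.  Raises on gene identifiers appearing in stage
    outputs but not among the candidates.
    """
    candidates = sorted(set(seeds) | set(neighbors))
    cand_set = set(candidates)
    offenders = sorted(
        (set(direct_pairs["gene"]) | set(inherited_pairs["gene"])) - cand_set
    )
    if offenders:
        raise ValueError(f"drug pairs reference non-candidate genes: {offenders[:10]}")

    direct_by_gene = direct_pairs.groupby("gene")["drug"].agg(sorted).to_dict()
    inherited_by_gene = inherited_pairs.groupby("gene")["drug"].agg(sorted).to_dict()
    fams_by_gene: dict[str, list[str]] = {}
    for r in funfams.itertuples():
        fams_by_gene.setdefault(r.gene, []).append(r.funfam)

    rows = []
    for g in candidates:
        fams = sorted(fams_by_gene.get(g, []))
        scores = [funfam_scores[f] for f in fams if funfam_scores.get(f) is not None]
        row = {
            "gene": g,
            "origin": "seed" if g in seeds else "neighbor",
            "drugs_direct": ",".join(direct_by_gene.get(g, [])),
            "drugs_inherited": ",".join(inherited_by_gene.get(g, [])),
            "funfams": ",".join(fams),
            "side_effect_score": max(scores) if scores else "",
            "is_hub": "",
            "is_bottleneck": "",
            "module": "",
        }
        if topology_flags is not None and g in topology_flags.index:
            row["is_hub"] = bool(topology_flags.loc[g, "is_hub"])
            row["is_bottleneck"] = bool(topology_flags.loc[g, "is_bottleneck"])
        if partition is not None and g in partition.index:
            row["module"] = partition[g]
        rows.append(row)
    return pd.DataFrame(rows)
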