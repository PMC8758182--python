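"""Readers and writers for the pipeline's plain-text interchange formats.

All tables are UTF-8 TSV without quoting; graphs travel as SIF or 2/3-column
edge lists; gene-set collections as GMT.  Every writer here round-trips
through the matching reader with no loss.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

MUTATION_COLUMNS = ["gene", "n_mutations", "n_samples_tested", "source", "mutfam_id"]
BIOACTIVITY_COLUMNS = ["gene", "drug", "pchembl", "atc_code", "direct_binding"]


def read_mutation_table(path) -> pd.DataFrame:
    """Read a gene-level mutation table (gene, n_mutations, n_samples_tested,
    source in {CGC, COSMIC, MUTFAM}, mutfam_id)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "mutfam_id": str})
    missing = set(MUTATION_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"mutation table missing columns: {sorted(missing)}")
    if "mutfam_id" not in df.columns:
        df["mutfam_id"] = pd.NA
    bad = df[(df["source"] == "MUTFAM") & df["mutfam_id"].isna()]
    if len(bad):
        raise ValueError("MUTFAM rows must carry a mutfam_id")
    if (df["n_samples_tested"] < 1).any():
        raise ValueError("n_samples_tested must be >= 1")
    return df


def write_mutation_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_counts(path) -> pd.DataFrame:
    """Read a genes x samples integer count matrix (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise ValueError("duplicate gene or sample identifiers")
    return df.astype(int)


def write_counts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def read_sample_sheet(path) -> pd.Series:
    """Read sample_id -> group mapping; groups are arbitrary labels
    (the pipeline expects exactly two, e.g. tumour/normal)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return df.set_index("sample_id")["group"]


def write_sample_sheet(groups: pd.Series, path) -> None:
    groups.rename_axis("sample_id").rename("group").reset_index().to_csv(
        path, sep="\t", index=False
    )


def read_network(path) -> nx.Graph:
    """Read a SIF (node, interaction, node) or 2/3-column edge list into an
    undirected weighted graph.  A numeric third column is a weight
    (default 1.0); a non-numeric one is a SIF interaction type."""
    g = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or parts == [""]:
                continue
            if len(parts) == 2:
                u, v, w = parts[0], parts[1], 1.0
            elif len(parts) >= 3:
                try:
                    w = float(parts[2])
                    u, v = parts[0], parts[1]
                except ValueError:  # SIF: node <tab> interaction <tab> node
                    u, v, w = parts[0], parts[2], 1.0
            if u == v:
                continue
            g.add_edge(u, v, weight=w)
    return g


def write_network(g: nx.Graph, path) -> None:
    """Write sorted (node_a, node_b, weight) rows; pairs stored once."""
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in g.edges()):
            w = g[u][v].get("weight", 1.0)
            fh.write(f"{u}\t{v}\t{w:.10g}\n")


def write_sif(g: nx.Graph, path, interaction: str = "pp") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in g.edges()):
            fh.write(f"{u}\t{interaction}\t{v}\n")


def read_gene_list(path) -> set[str]:
    """One gene per line (e.g. the tissue-expression allowlist)."""
    with open(path, encoding="utf-8") as fh:
        return {line.strip() for line in fh if line.strip()}


def write_gene_list(genes, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def read_gmt(path) -> dict[str, set[str]]:
    """GMT: set_name <tab> description <tab> gene..."""
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, genes = parts[0], {g for g in parts[2:] if g}
            if name in sets:
                raise ValueError(f"duplicate gene-set name: {name}")
            if genes:
                sets[name] = genes
    return sets


def write_gmt(sets: dict[str, set[str]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(sets):
            genes = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\tna\t{genes}\n")


def read_bioactivity(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "drug": str, "atc_code": str})
    if "direct_binding" not in df.columns:
        df["direct_binding"] = True
    else:
        df["direct_binding"] = df["direct_binding"].astype(bool)
    if ((df["pchembl"] < 0) | (df["pchembl"] > 14)).any():
        raise ValueError("pchembl outside [0, 14]")
    return df


def write_bioactivity(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_funfams(path) -> pd.DataFrame:
    """gene -> FunFam map with per-family druggability and annotated drugs.

    Columns: gene, funfam, is_druggable, annotated_drugs (comma-joined,
    may be empty).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df["is_druggable"] = df["is_druggable"].map(
        {"True": True, "False": False, "1": True, "0": False}
    )
    return df


def write_funfams(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_truth(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")
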