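"""Assembly of the known/putative driver gene set from mutation tables.

Three sources feed the driver set: a curated cancer-gene list (CGC), a
somatic-mutation catalogue filtered by per-gene mutation ratio (COSMIC), and
mutationally enriched protein domain families (MutFams) from which the most
mutated member genes are taken.  A Mann-Whitney comparison of mutation-count
distributions between sources supports pooling them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from disconet.stats import mann_whitney

__all__ = [
    "DriverSet",
    "filter_cosmic",
    "select_mutfam_top_quartile",
    "assemble_drivers",
    "compare_mutation_distributions",
]


@dataclass
class DriverSet:
    """Non-redundant driver gene set with per-gene source provenance."""

    genes: set[str] = field(default_factory=set)
    provenance: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.provenance) != self.genes:
            raise ValueError("provenance must cover exactly the member genes")

    def __len__(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene": g, "sources": ",".join(sorted(self.provenance[g]))}
            for g in sorted(self.genes)
        ]
        return pd.DataFrame(rows, columns=["gene", "sources"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DriverSet":
        prov = {r.gene: set(r.sources.split(",")) for r in df.itertuples()}
        return cls(genes=set(prov), provenance=prov)


def filter_cosmic(
    table: pd.DataFrame,
    ratio_threshold: float = 0.03,
    strict: bool = True,
    min_mutations: int | None = None,
) -> set[str]:
    """Select COSMIC genes whose mutation ratio exceeds a threshold.

    The mutation ratio is n_mutations / n_samples_tested.  The default is the
    strict inequality ratio > 0.03; ``strict=False`` switches to >=, and
    ``min_mutations`` optionally adds an absolute-count filter (off by
    default).
    """
    if not 0 < ratio_threshold < 1:
        raise ValueError("ratio_threshold must be in (0, 1)")
    sub = table[table["source"] == "COSMIC"]
    if sub.empty:
        return set()
    ratio = sub["n_mutations"] / sub["n_samples_tested"]
    keep = ratio > ratio_threshold if strict else ratio >= ratio_threshold
    if min_mutations is not None:
        keep &= sub["n_mutations"] >= min_mutations
    return set(sub.loc[keep, "gene"])


def select_mutfam_top_quartile(table: pd.DataFrame, allowlist: set[str]) -> set[str]:
    """Per MutFam, keep genes in the top quartile by mutation count, then
    intersect with the tissue-expression allowlist.

    The 75th percentile uses linear interpolation; genes with count >= that
    percentile are kept.  A family with fewer than 4 genes degenerates to its
    maximum-count gene(s).
    """
    sub = table[table["source"] == "MUTFAM"]
    selected: set[str] = set()
    for _, fam in sub.groupby("mutfam_id"):
        counts = fam["n_mutations"].to_numpy(dtype=float)
        if len(fam) < 4:
            cut = counts.max()
        else:
            cut = np.percentile(counts, 75)
        selected |= set(fam.loc[fam["n_mutations"] >= cut, "gene"])
    return selected & set(allowlist)


def assemble_drivers(cgc: set[str], cosmic: set[str], mutfam: set[str]) -> DriverSet:
    """Union the three source sets, recording every source each gene came from."""
    prov: dict[str, set[str]] = {}
    for name, genes in (("CGC", cgc), ("COSMIC", cosmic), ("MUTFAM", mutfam)):
        for g in genes:
            prov.setdefault(g, set()).add(name)
    return DriverSet(genes=set(prov), provenance=prov)


def compare_mutation_distributions(a, b) -> float:
    """Two-sided Mann-Whitney U p-value comparing two mutation-count lists.

    Exact for small groups (<= 10 in the smaller group), normal approximation
    with tie correction otherwise.
    """
    return mann_whitney(a, b)
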