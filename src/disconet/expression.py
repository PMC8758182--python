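"""Differential expression and weighted co-expression module detection.

The stage mirrors a classical two-group RNA-seq workflow: an exact
negative-binomial test on normalized counts (common dispersion estimated by
conditional maximum likelihood on library-size-equalized pseudo-counts),
selection of highly differentially expressed genes (Hi-DEGs), a biweight
midcorrelation network over the most fold-changed genes, soft-thresholding
to an approximately scale-free weighted adjacency, topological-overlap
clustering into modules, and a binomial test for driver overrepresentation
per module.  The stage is deterministic: no randomness anywhere.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import squareform
from scipy.special import gammaln
from scipy.stats import linregress

from disconet.seeds import DriverSet
from disconet.stats import bh_adjust, binom_tail

__all__ = [
    "size_factors",
    "de_test",
    "select_hidegs",
    "select_top_genes",
    "bicor_matrix",
    "scale_free_fit",
    "choose_beta",
    "tom",
    "detect_modules",
    "module_driver_enrichment",
    "build_seed_set",
    "UNASSIGNED",
]

UNASSIGNED = "unassigned"


# ---------------------------------------------------------------------------
# normalization and the exact NB test
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> np.ndarray:
    """Median-of-ratios size factors (geometric mean 1.0 across samples).

    Genes with a zero count in any sample are excluded from the reference;
    if none remain, library-size ratios are used instead.
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if positive.any():
        logs = np.log(mat[positive])
        ref = logs.mean(axis=1)  # log geometric mean per gene
        sf = np.exp(np.median(logs - ref[:, None], axis=0))
    else:
        lib = mat.sum(axis=0)
        sf = lib / np.exp(np.mean(np.log(np.maximum(lib, 1.0))))
    return sf / np.exp(np.mean(np.log(sf)))


def _conditional_loglik(pseudo: np.ndarray, groups: list[np.ndarray], r: float) -> float:
    """Log-likelihood of counts conditional on their per-group sums, for iid
    NB(r, p) samples; the nuisance p cancels, leaving r identifiable."""
    total = 0.0
    for idx in groups:
        y = pseudo[:, idx]
        n = y.shape[1]
        s = y.sum(axis=1)
        total += (gammaln(y + r) - gammaln(r) - gammaln(y + 1)).sum()
        total -= (gammaln(s + n * r) - gammaln(n * r) - gammaln(s + 1)).sum()
    return total


def estimate_common_dispersion(
    pseudo: np.ndarray, groups: list[np.ndarray]
) -> float:
    """Common NB dispersion phi (variance = mu + phi*mu^2) maximizing the
    conditional likelihood across all genes and both groups."""

    def neg(log_phi: float) -> float:
        return -_conditional_loglik(pseudo, groups, 1.0 / np.exp(log_phi))

    res = minimize_scalar(neg, bounds=(np.log(1e-6), np.log(5.0)), method="bounded")
    return float(np.exp(res.x))


def _exact_nb_p(y1: int, s: int, n1: int, n2: int, phi: float) -> float:
    """Exact two-sided p for the group-1 sum given the overall sum, both
    group sums NB with per-sample dispersion phi.

    Convention: p = sum of conditional probabilities of all outcomes no more
    likely than the observed one (the usual exact-test doubling-free rule).
    """
    if s == 0:
        return 1.0
    r = 1.0 / phi
    r1, r2 = n1 * r, n2 * r
    # support window: beyond ~40 conditional sds the pmf underflows
    if s > 50_000:
        f1 = n1 / (n1 + n2)
        sd = np.sqrt(s * f1 * (1 - f1) * (1.0 + phi * s / (n1 + n2)))
        lo = max(0, int(s * f1 - 40 * sd))
        hi = min(s, int(s * f1 + 40 * sd) + 1)
        if not (lo <= y1 <= hi):
            lo, hi = 0, s
    else:
        lo, hi = 0, s
    k = np.arange(lo, hi + 1)
    logw = (
        gammaln(k + r1)
        - gammaln(k + 1)
        + gammaln(s - k + r2)
        - gammaln(s - k + 1)
    )
    logw -= logw.max()
    w = np.exp(logw)
    w_obs = w[y1 - lo]
    # relative tie tolerance: mirrored outcomes under symmetric designs must
    # count as "no more likely" despite float error in gammaln at huge r
    # (~1e-6 relative); genuine adjacent-outcome ratios are far larger
    return float(w[w <= w_obs * (1.0 + 1e-4)].sum() / w.sum())


def de_test(
    counts: pd.DataFrame,
    groups: pd.Series,
    reference: str | None = None,
    dispersion: float | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Two-group exact negative-binomial differential expression test.

    Parameters
    ----------
    counts
        genes x samples integer counts.
    groups
        sample -> group label; exactly two groups, each with >= 2 samples.
    reference
        baseline group for the fold change ("normal" if present); log2fc is
        target over reference.
    dispersion
        fixed per-sample NB dispersion; estimated by conditional maximum
        likelihood when None.

    Returns a table indexed by gene with log2fc, p_value, p_adjusted.
    """
    groups = groups.loc[counts.columns]
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"expected exactly two groups, got {labels}")
    if reference is None:
        reference = "normal" if "normal" in labels else labels[0]
    target = next(l for l in labels if l != reference)
    idx_t = np.flatnonzero((groups == target).to_numpy())
    idx_r = np.flatnonzero((groups == reference).to_numpy())
    if len(idx_t) < 2 or len(idx_r) < 2:
        raise ValueError("each group needs at least 2 samples")

    mat = counts.to_numpy(dtype=float)
    sf = size_factors(counts)
    norm = mat / sf
    # pseudo-counts: normalized counts rounded back to integers so the
    # conditional NB arithmetic stays exact
    pseudo = np.rint(norm).astype(np.int64)

    if dispersion is None:
        dispersion = estimate_common_dispersion(pseudo, [idx_t, idx_r])

    m_t = norm[:, idx_t].mean(axis=1)
    m_r = norm[:, idx_r].mean(axis=1)
    log2fc = np.log2((m_t + pseudocount) / (m_r + pseudocount))

    n1, n2 = len(idx_t), len(idx_r)
    y1 = pseudo[:, idx_t].sum(axis=1)
    s = y1 + pseudo[:, idx_r].sum(axis=1)
    pvals = np.ones(len(counts))
    for i in range(len(counts)):
        if s[i] == 0:
            log2fc[i] = 0.0
            continue
        pvals[i] = _exact_nb_p(int(y1[i]), int(s[i]), n1, n2, dispersion)

    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_value": pvals,
            "p_adjusted": bh_adjust(pvals),
            "dispersion": dispersion,
        },
        index=counts.index.rename("gene"),
    )


def select_hidegs(
    de: pd.DataFrame, lfc_min: float = 4.0, alpha: float = 0.01
) -> pd.Series:
    """Highly differentially expressed genes: |log2fc| >= lfc_min and
    adjusted p < alpha.  Returns gene -> 'up'/'down'."""
    if lfc_min <= 0 or alpha <= 0:
        raise ValueError("thresholds must be positive")
    keep = (de["log2fc"].abs() >= lfc_min) & (de["p_adjusted"] < alpha)
    sel = de.loc[keep, "log2fc"]
    return pd.Series(np.where(sel > 0, "up", "down"), index=sel.index, name="direction")


def select_top_genes(de: pd.DataFrame, n_top: int = 5000) -> list[str]:
    """Top genes ranked by absolute fold change (ties broken by gene id)."""
    absfc = de["log2fc"].abs()
    order = sorted(de.index, key=lambda g: (-absfc[g], g))
    return order[:n_top]


# ---------------------------------------------------------------------------
# biweight midcorrelation
# ---------------------------------------------------------------------------

def bicor_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Pairwise biweight midcorrelation between gene expression profiles.

    Rows are genes, columns samples.  Weights follow the standard 9-MAD
    tuning: u = (x - med) / (9 * mad), w = (1 - u^2)^2 on |u| < 1.  Genes
    with zero MAD (or fully down-weighted profiles) fall back to Pearson.
    """
    X = expr.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    if n_samples < 3:
        raise ValueError("need at least 3 samples")

    med = np.median(X, axis=1, keepdims=True)
    mad = np.median(np.abs(X - med), axis=1, keepdims=True)
    ok = mad[:, 0] > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        u = (X - med) / (9.0 * mad)
        w = np.square(1.0 - np.square(u)) * (np.abs(u) < 1.0)
    w = np.nan_to_num(w)
    v = (X - med) * w
    norms = np.linalg.norm(v, axis=1)
    ok &= norms > 0

    rows = np.empty_like(X)
    rows[ok] = v[ok] / np.where(norms[ok, None] == 0, 1.0, norms[ok, None])
    S = np.empty((n_genes, n_genes))
    if (~ok).any():
        # zero-MAD (or fully down-weighted) genes: every pair involving such
        # a gene is computed as plain Pearson on both sides
        c = X - X.mean(axis=1, keepdims=True)
        cn = np.linalg.norm(c, axis=1, keepdims=True)
        cn[cn == 0] = 1.0
        pearson_rows = c / cn
        rows[~ok] = pearson_rows[~ok]
        S = rows @ rows.T
        SP = pearson_rows @ pearson_rows.T
        S[~ok, :] = SP[~ok, :]
        S[:, ~ok] = SP[:, ~ok]
    else:
        S = rows @ rows.T
    S = np.clip(S, -1.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return pd.DataFrame(S, index=expr.index, columns=expr.index)


# ---------------------------------------------------------------------------
# scale-free fit, soft threshold, TOM
# ---------------------------------------------------------------------------

def scale_free_fit(connectivity, n_bins: int = 10) -> float:
    """R^2 of log10(frequency) on log10(mean connectivity) over equal-width
    connectivity bins; empty bins dropped.  Degenerate inputs give 0."""
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if k.size < 2 or np.unique(k).size < 2:
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    freq = np.bincount(idx, minlength=n_bins).astype(float)
    sums = np.bincount(idx, weights=k, minlength=n_bins)
    keep = freq > 0
    if keep.sum() < 2:
        return 0.0
    mean_k = sums[keep] / freq[keep]
    res = linregress(np.log10(mean_k), np.log10(freq[keep]))
    return float(res.rvalue**2)


def soft_threshold(S: pd.DataFrame, beta: int) -> pd.DataFrame:
    """Unsigned weighted adjacency a_ij = |S_ij|^beta with zero diagonal."""
    a = np.abs(S.to_numpy(dtype=float)) ** beta
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=S.index, columns=S.columns)


def choose_beta(
    S: pd.DataFrame,
    beta_grid=range(1, 13),
    r2_min: float = 0.8,
    n_bins: int = 10,
    return_profile: bool = False,
):
    """Smallest soft-threshold power giving an approximately scale-free
    weighted network (fit index >= r2_min); falls back to the argmax fit
    with a warning when no power reaches the target."""
    grid = list(beta_grid)
    if not grid:
        raise ValueError("beta grid is empty")
    if sorted(grid) != grid or any(b < 1 for b in grid):
        raise ValueError("beta grid must be ascending and >= 1")
    absS = np.abs(S.to_numpy(dtype=float))
    np.fill_diagonal(absS, 0.0)
    profile = []
    chosen = None
    for b in grid:
        k = (absS**b).sum(axis=1)
        r2 = scale_free_fit(k, n_bins=n_bins)
        profile.append((b, r2))
        if chosen is None and r2 >= r2_min:
            chosen = b
    if chosen is None:
        chosen = max(profile, key=lambda t: t[1])[0]
        warnings.warn(
            f"no power in the grid reached scale-free fit {r2_min}; "
            f"using argmax beta={chosen}",
            stacklevel=2,
        )
    if return_profile:
        return chosen, pd.DataFrame(profile, columns=["beta", "r2"])
    return chosen


def tom(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of a weighted adjacency in [0,1] with zero
    diagonal: TOM_ij = (l_ij + a_ij) / (min(k_i,k_j) + 1 - a_ij), with
    l_ij the shared-neighbor weight sum; TOM_ii = 1."""
    a = adjacency.to_numpy(dtype=float)
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if (a < 0).any() or (a > 1).any():
        raise ValueError("adjacency entries must lie in [0,1]")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    l = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    t = (l + a) / denom
    np.fill_diagonal(t, 1.0)
    return pd.DataFrame(t, index=adjacency.index, columns=adjacency.columns)


# ---------------------------------------------------------------------------
# module detection and driver enrichment
# ---------------------------------------------------------------------------

def detect_modules(
    tom_matrix: pd.DataFrame,
    min_module_size: int = 30,
    cut_height_quantile: float | None = None,
) -> pd.Series:
    """Average-linkage clustering on 1 - TOM with a fixed-height tree cut.

    By default the tree is cut at the midpoint of the largest gap in the
    upper half of its merge heights — TOM dissimilarities saturate near 1,
    so a fixed quantile of merge heights lands inside the background merge
    plateau and returns one giant cluster; the largest-gap rule separates
    the module merges from that plateau deterministically.  Passing
    ``cut_height_quantile`` overrides this with a plain quantile cut.
    Clusters smaller than ``min_module_size`` are pooled into the
    'unassigned' module.  Assigned modules are labelled M1, M2, ... by
    decreasing size (ties by smallest member id).
    """
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    genes = list(tom_matrix.index)
    if len(genes) < min_module_size:
        return pd.Series(UNASSIGNED, index=genes, name="module")
    d = 1.0 - tom_matrix.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    Z = linkage(squareform(d, checks=False), method="average")
    heights = Z[:, 2]
    if cut_height_quantile is not None:
        cut = float(np.quantile(heights, cut_height_quantile))
    else:
        hs = np.sort(heights)
        start = len(hs) // 2
        gaps = np.diff(hs[start:])
        gi = start + int(np.argmax(gaps))
        cut = float((hs[gi] + hs[gi + 1]) / 2.0)
    raw = fcluster(Z, t=cut, criterion="distance")

    members: dict[int, list[str]] = {}
    for g, lab in zip(genes, raw):
        members.setdefault(int(lab), []).append(g)
    big = [m for m in members.values() if len(m) >= min_module_size]
    big.sort(key=lambda m: (-len(m), min(m)))
    assignment = pd.Series(UNASSIGNED, index=genes, name="module")
    for rank, m in enumerate(big, start=1):
        assignment.loc[m] = f"M{rank}"
    return assignment


def module_driver_enrichment(
    partition: pd.Series,
    drivers: DriverSet | set[str],
    universe: set[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Binomial overrepresentation of driver genes per module.

    For a module of size n holding x drivers, p = P(X >= x) with
    X ~ Binomial(n, q) and q the driver fraction of the universe; BH across
    modules; enriched means adjusted p < alpha.
    """
    driver_genes = drivers.genes if isinstance(drivers, DriverSet) else set(drivers)
    if universe is None:
        universe = set(partition.index)
    universe = set(universe)
    driver_genes = driver_genes & universe
    if not universe:
        raise ValueError("empty universe")
    q = len(driver_genes) / len(universe)

    rows = []
    for label, genes in partition.groupby(partition).groups.items():
        genes = set(genes) & universe
        x = len(genes & driver_genes)
        p = 1.0 if not genes else binom_tail(x, len(genes), q)
        rows.append({"module": label, "size": len(genes), "n_drivers": x, "p": p})
    out = pd.DataFrame(rows).sort_values("module", kind="mergesort").reset_index(drop=True)
    out["p_adjusted"] = bh_adjust(out["p"])
    out["enriched"] = out["p_adjusted"] < alpha
    return out


def build_seed_set(
    drivers: DriverSet,
    hidegs: set[str] | pd.Series,
    partition: pd.Series,
    enriched_modules: set[str],
) -> tuple[set[str], pd.DataFrame]:
    """Seed genes = drivers plus Hi-DEGs that fall in enriched modules.

    Returns the seed set and a provenance table (gene, is_driver, is_hideg,
    module).
    """
    hideg_genes = set(hidegs.index) if isinstance(hidegs, pd.Series) else set(hidegs)
    enriched_genes = set(partition.index[partition.isin(set(enriched_modules))])
    seed = set(drivers.genes) | (hideg_genes & enriched_genes)
    rows = [
        {
            "gene": g,
            "is_driver": g in drivers.genes,
            "is_hideg": g in hideg_genes,
            "module": partition.get(g, UNASSIGNED),
        }
        for g in sorted(seed)
    ]
    return seed, pd.DataFrame(rows)
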