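"""Differential expression and co-expression module machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from disconet.expression import (
    UNASSIGNED,
    bicor_matrix,
    build_seed_set,
    choose_beta,
    de_test,
    detect_modules,
    module_driver_enrichment,
    scale_free_fit,
    select_hidegs,
    select_top_genes,
    soft_threshold,
    tom,
)
from disconet.expression import _exact_nb_p
from disconet.seeds import assemble_drivers


def _toy_counts(rng, n_genes=30, n1=5, n2=5, mean=50.0):
    counts = pd.DataFrame(
        rng.poisson(mean, size=(n_genes, n1 + n2)),
        index=[f"G{i:03d}" for i in range(n_genes)],
        columns=[f"T{i}" for i in range(n1)] + [f"N{i}" for i in range(n2)],
    )
    groups = pd.Series(
        ["tumour"] * n1 + ["normal"] * n2, index=counts.columns
    )
    return counts, groups


class TestDeTest:
    def test_identical_groups_give_null_result(self):
        rng = np.random.default_rng(0)
        counts, groups = _toy_counts(rng, n1=4, n2=4)
        # tumour and normal columns carry identical counts for every gene,
        # so normalization cannot introduce a spurious group difference
        counts.iloc[:, 4:] = counts.iloc[:, :4].to_numpy()
        de = de_test(counts, groups, dispersion=0.1)
        assert np.allclose(de["log2fc"], 0.0)
        assert np.allclose(de["p_value"], 1.0)

    def test_all_zero_gene(self):
        rng = np.random.default_rng(1)
        counts, groups = _toy_counts(rng)
        counts.iloc[3] = 0
        de = de_test(counts, groups, dispersion=0.1)
        assert de.iloc[3]["log2fc"] == 0.0
        assert de.iloc[3]["p_value"] == 1.0

    def test_zero_dispersion_limit_is_conditional_binomial(self):
        """As dispersion -> 0 the NB conditional test becomes the exact
        binomial test of the group-1 sum given the total."""
        rng = np.random.default_rng(2)
        for _ in range(25):
            n1, n2 = int(rng.integers(2, 8)), int(rng.integers(2, 8))
            s = int(rng.integers(1, 150))
            y1 = int(rng.integers(0, s + 1))
            p_nb = _exact_nb_p(y1, s, n1, n2, 1e-8)
            pmf = binom.pmf(np.arange(s + 1), s, n1 / (n1 + n2))
            p_bin = pmf[pmf <= pmf[y1] * (1 + 1e-10)].sum()
            assert p_nb == pytest.approx(p_bin, abs=1e-6)

    def test_requires_two_groups(self):
        rng = np.random.default_rng(3)
        counts, groups = _toy_counts(rng)
        with pytest.raises(ValueError):
            de_test(counts, pd.Series("tumour", index=counts.columns))


class TestHidegSelection:
    def _de(self):
        return pd.DataFrame(
            {
                "log2fc": [4.2, -4.2, 3.9, 5.0],
                "p_value": [1e-4] * 4,
                "p_adjusted": [0.001, 0.001, 0.001, 0.5],
            },
            index=["up", "down", "smallfc", "notsig"],
        )

    def test_selection_and_direction(self):
        sel = select_hidegs(self._de(), lfc_min=4, alpha=0.01)
        assert dict(sel) == {"up": "up", "down": "down"}

    def test_top_gene_ranking_by_absolute_fc(self):
        # |4.2| ties |-4.2|; ties break lexicographically ("down" < "up")
        top = select_top_genes(self._de(), 2)
        assert top == ["notsig", "down"]


class TestBicor:
    @staticmethod
    def _bicor_reference(x, y):
        """Straight-line transcription of the biweight midcorrelation
        definition, independent of the vectorized implementation."""

        def weighted(v):
            med = np.median(v)
            mad = np.median(np.abs(v - med))
            u = (v - med) / (9 * mad)
            w = (1 - u**2) ** 2 * (np.abs(u) < 1)
            return (v - med) * w

        a, b = weighted(x), weighted(y)
        return np.sum(a * b) / (np.sqrt(np.sum(a**2)) * np.sqrt(np.sum(b**2)))

    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(1, 15))
        S = bicor_matrix(pd.DataFrame(np.vstack([x, x]), index=["a", "b"]))
        assert S.loc["a", "b"] == pytest.approx(1.0)

    def test_affine_equivariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=15)
        df = pd.DataFrame(np.vstack([x, 3 - 2 * x]), index=["a", "b"])
        assert bicor_matrix(df).loc["a", "b"] == pytest.approx(-1.0)

    def test_matches_reference_formula(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 20))
        df = pd.DataFrame(X, index=[f"g{i}" for i in range(10)])
        S = bicor_matrix(df)
        for i in range(10):
            for j in range(i + 1, 10):
                assert S.iloc[i, j] == pytest.approx(
                    self._bicor_reference(X[i], X[j]), abs=1e-10
                )

    def test_zero_mad_falls_back_to_pearson(self):
        x = np.array([1.0, 1, 1, 1, 1, 1, 1, 9])  # MAD = 0
        y = np.arange(8.0)
        df = pd.DataFrame(np.vstack([x, y]), index=["flat", "lin"])
        S = bicor_matrix(df)
        expected = np.corrcoef(x, y)[0, 1]
        assert S.loc["flat", "lin"] == pytest.approx(expected, abs=1e-10)


class TestScaleFree:
    def test_exact_power_law_fits_well(self):
        # degree histogram drawn exactly from p(k) ~ k^-2
        ks = np.arange(1, 51)
        freq = np.round(1e5 * ks**-2.0).astype(int)
        connectivity = np.repeat(ks, freq)
        assert scale_free_fit(connectivity) >= 0.95

    def test_constant_connectivity_degenerate(self):
        assert scale_free_fit([5.0] * 100) == 0.0

    def test_invariant_to_duplicating_nodes(self):
        rng = np.random.default_rng(0)
        k = rng.pareto(2.0, 500) + 1
        r1 = scale_free_fit(k)
        r2 = scale_free_fit(np.concatenate([k, k]))
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestChooseBeta:
    def _S(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 30))
        X[:20] += rng.normal(size=30) * 1.5  # one correlated block
        return bicor_matrix(pd.DataFrame(X, index=[f"g{i:02d}" for i in range(60)]))

    def test_equals_exhaustive_scan(self):
        S = self._S()
        grid = list(range(1, 13))
        chosen = choose_beta(S, grid, r2_min=0.5)
        absS = np.abs(S.to_numpy())
        np.fill_diagonal(absS, 0.0)
        fits = {b: scale_free_fit((absS**b).sum(axis=1)) for b in grid}
        passing = [b for b in grid if fits[b] >= 0.5]
        expected = passing[0] if passing else max(grid, key=lambda b: fits[b])
        assert chosen == expected

    def test_zero_requirement_returns_smallest(self):
        assert choose_beta(self._S(), [2, 4, 6], r2_min=0.0) == 2

    def test_monotone_in_r2_min(self):
        S = self._S()
        betas = [choose_beta(S, range(1, 13), r2_min=r) for r in (0.0, 0.3, 0.6)]
        assert betas == sorted(betas)

    def test_empty_grid_raises(self):
        with pytest.raises(ValueError):
            choose_beta(self._S(), [])


class TestTom:
    def test_triangle_and_path_hand_values(self):
        tri = pd.DataFrame(1.0 - np.eye(3), index=list("abc"), columns=list("abc"))
        t = tom(tri)
        assert np.allclose(t.to_numpy(), 1.0)
        path = pd.DataFrame(
            [[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float,
            index=list("iuj"), columns=list("iuj"),
        )
        assert tom(path).loc["i", "j"] == pytest.approx(0.5)

    def test_zero_adjacency(self):
        z = pd.DataFrame(np.zeros((4, 4)), index=list("abcd"), columns=list("abcd"))
        t = tom(z)
        assert np.allclose(t.to_numpy() - np.eye(4), 0.0)

    def test_matches_brute_force_on_random_adjacency(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(0, 1, size=(8, 8))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        df = pd.DataFrame(a, index=[f"g{i}" for i in range(8)], columns=[f"g{i}" for i in range(8)])
        t = tom(df).to_numpy()
        k = a.sum(axis=1)
        for i in range(8):
            for j in range(8):
                if i == j:
                    assert t[i, j] == 1.0
                    continue
                l_ij = sum(a[i, u] * a[u, j] for u in range(8))
                expected = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
                assert t[i, j] == pytest.approx(expected, abs=1e-12)
        assert (t >= 0).all() and (t <= 1 + 1e-12).all()


class TestDetectModules:
    def _perfect_blocks(self, n_per=10):
        genes = [f"a{i}" for i in range(n_per)] + [f"b{i}" for i in range(n_per)]
        t = np.zeros((2 * n_per, 2 * n_per))
        t[:n_per, :n_per] = 1.0
        t[n_per:, n_per:] = 1.0
        np.fill_diagonal(t, 1.0)
        return pd.DataFrame(t, index=genes, columns=genes)

    def test_two_perfect_blocks(self):
        part = detect_modules(self._perfect_blocks(), min_module_size=3)
        labels = part.groupby(part).groups
        assert len(labels) == 2
        assert set(map(len, labels.values())) == {10}

    def test_gene_order_invariance(self):
        t = self._perfect_blocks()
        part1 = detect_modules(t, 3)
        order = list(t.index[::-1])
        part2 = detect_modules(t.loc[order, order], 3)
        # same partition up to labels
        for g1 in t.index:
            for g2 in t.index:
                assert (part1[g1] == part1[g2]) == (part2[g1] == part2[g2])

    def test_too_few_genes_all_unassigned(self):
        t = self._perfect_blocks(2)
        part = detect_modules(t, min_module_size=30)
        assert (part == UNASSIGNED).all()


class TestEnrichmentAndSeeds:
    def test_binomial_enrichment_exact_example(self):
        # one module of 10 genes with 4 drivers, universe 100 with q=0.1
        partition = pd.Series(
            ["M1"] * 10 + [UNASSIGNED] * 90,
            index=[f"g{i:03d}" for i in range(100)],
        )
        drivers = {f"g{i:03d}" for i in range(4)} | {f"g{i:03d}" for i in range(50, 56)}
        out = module_driver_enrichment(partition, drivers)
        row = out[out["module"] == "M1"].iloc[0]
        exact = 1 - sum(
            binom.pmf(i, 10, 0.1) for i in range(4)
        )
        assert row["p"] == pytest.approx(exact, rel=1e-10)

    def test_zero_drivers_p_one(self):
        partition = pd.Series(["M1"] * 5 + ["M2"] * 5, index=[f"g{i}" for i in range(10)])
        out = module_driver_enrichment(partition, {"g0", "g1"})
        assert out[out["module"] == "M2"].iloc[0]["p"] == 1.0

    def test_build_seed_set_rule(self):
        drv = assemble_drivers({"A", "B"}, set(), set())
        partition = pd.Series(
            {"B": "M1", "C": "M1", "D": "M2", "A": UNASSIGNED}
        )
        seed, prov = build_seed_set(drv, {"B", "C", "D"}, partition, {"M1"})
        assert seed == {"A", "B", "C"}
        assert len(prov) == 3

    def test_no_enriched_modules_returns_drivers(self):
        drv = assemble_drivers({"A"}, {"B"}, set())
        partition = pd.Series({"C": "M1"})
        seed, _ = build_seed_set(drv, {"C"}, partition, set())
        assert seed == {"A", "B"}

    def test_seed_size_arithmetic(self):
        drv = assemble_drivers({"A", "B", "C"}, set(), set())
        partition = pd.Series({"D": "M1", "E": "M1", "B": "M1"})
        seed, _ = build_seed_set(drv, {"B", "D", "E"}, partition, {"M1"})
        new_hidegs = {"D", "E"}  # Hi-DEGs in enriched modules, not drivers
        assert len(seed) == len(drv.genes) + len(new_hidegs)
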