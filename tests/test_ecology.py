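"""Abundance normalization, Spearman correlation, size factors and
depth-differential expression."""

import itertools

import numpy as np
import pandas as pd
import pytest

from dlhscan.ecology import (
    AbundanceTable,
    EcologyError,
    depth_differential,
    fold_change,
    percent_mapped_reads,
    size_factors,
    spearman,
    taxon_region_correlations,
)
from dlhscan.synthetic import AbundanceSpec, generate_abundance_dataset


class TestPercentMappedReads:
    def _counts(self, data, samples):
        return pd.DataFrame(data, index=[f"g{i}" for i in range(len(data))], columns=samples)

    def test_basic_arithmetic(self):
        counts = self._counts([[5]], ["s1"])
        out = percent_mapped_reads(counts, pd.Series({"s1": 1000}))
        assert out.iloc[0, 0] == pytest.approx(0.5)

    def test_upper_bound(self):
        counts = self._counts([[1000]], ["s1"])
        out = percent_mapped_reads(counts, pd.Series({"s1": 1000}))
        assert out.iloc[0, 0] == pytest.approx(100.0)

    def test_scale_invariance(self):
        counts = self._counts([[5, 7], [3, 2]], ["s1", "s2"])
        totals = pd.Series({"s1": 100, "s2": 50})
        a = percent_mapped_reads(counts, totals)
        b = percent_mapped_reads(2 * counts, 2 * totals)
        assert np.allclose(a.to_numpy(), b.to_numpy())

    def test_zero_total_gives_na_with_warning(self):
        counts = self._counts([[0, 5]], ["s1", "s2"])
        with pytest.warns(UserWarning):
            out = percent_mapped_reads(counts, pd.Series({"s1": 0, "s2": 100}))
        assert np.isnan(out.loc["g0", "s1"]) and out.loc["g0", "s2"] == pytest.approx(5)

    def test_exhaustive_table_sums_to_at_most_100(self):
        counts = self._counts([[40, 10], [50, 20]], ["s1", "s2"])
        out = percent_mapped_reads(counts, pd.Series({"s1": 100, "s2": 100}))
        assert (out.sum(axis=0) <= 100 + 1e-9).all()


def spearman_rank_formula(x, y):
    """1 - 6*sum(d^2)/(n(n^2-1)) — valid without ties."""
    n = len(x)
    rx = np.argsort(np.argsort(x))
    ry = np.argsort(np.argsort(y))
    d = rx - ry
    return 1 - 6 * float(d @ d) / (n * (n * n - 1))


class TestSpearman:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ((1, 2, 3), (10, 20, 30), 1.0),
            ((1, 2, 3), (3, 2, 1), -1.0),
            ((1, 2, 3, 4), (2, 1, 4, 3), 0.6),
        ],
    )
    def test_examples(self, x, y, expected):
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(expected)

    def test_exhaustive_permutations_match_rank_formula(self):
        x = np.arange(1.0, 7.0)
        for perm in itertools.permutations(range(6)):
            y = x[list(perm)]
            rho, _ = spearman(x, y)
            assert rho == pytest.approx(spearman_rank_formula(x, y), abs=1e-12)

    def test_pairwise_deletion(self):
        rho, _ = spearman([1, 2, np.nan, 4], [1, 2, 3, 4])
        assert rho == pytest.approx(1.0)

    def test_constant_vector_na(self):
        rho, p = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(rho) and np.isnan(p)

    def test_too_few_pairs_error(self):
        with pytest.raises(EcologyError):
            spearman([1, np.nan, 3], [1, 2, 3])


class TestTaxonRegionCorrelations:
    def test_planted_monotone_rho_one(self, abundance_dataset):
        _, table, _, _ = abundance_dataset
        # overwrite one taxon's abundance with a monotone function of NO3
        t = table.values.copy()
        genes = table.gene_taxa.index[table.gene_taxa == "Diatoms"]
        t.loc[genes] = 0.0
        t.loc[genes[0]] = table.meta["NO3"].to_numpy() ** 2 / 1000
        table2 = AbundanceTable(values=t, gene_taxa=table.gene_taxa, meta=table.meta)
        df = taxon_region_correlations(table2, ["Diatoms"], ["NO3"])
        assert df["rho"].iloc[0] == pytest.approx(1.0)

    def test_all_missing_variable_na(self, abundance_dataset):
        _, table, _, _ = abundance_dataset
        meta = table.meta.copy()
        meta["Fe"] = np.nan
        table2 = AbundanceTable(values=table.values, gene_taxa=table.gene_taxa, meta=meta)
        df = taxon_region_correlations(table2, ["Dinophyceae"], ["Fe"])
        assert df["rho"].isna().all()

    def test_bh_adjustment_present(self, abundance_dataset):
        _, table, _, _ = abundance_dataset
        df = taxon_region_correlations(
            table, ["Dinophyceae", "Haptophyceae"], ["temperature", "NO3"]
        )
        ok = df["p"].notna()
        assert (df.loc[ok, "p_adj"] >= df.loc[ok, "p"] - 1e-12).all()

    def test_missing_variable_column_error(self, abundance_dataset):
        _, table, _, _ = abundance_dataset
        with pytest.raises(EcologyError):
            taxon_region_correlations(table, ["Dinophyceae"], ["salinity"])


class TestSizeFactors:
    def test_identical_samples_unity(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        assert np.allclose(size_factors(counts), 1.0)

    def test_pure_scaling_ratio(self):
        rng = np.random.default_rng(1)
        base = rng.integers(10, 1000, size=50)
        counts = pd.DataFrame({"a": base, "b": 3 * base})
        sf = size_factors(counts)
        assert sf["b"] / sf["a"] == pytest.approx(3.0)

    def test_five_gene_toy_hand_computed(self):
        counts = pd.DataFrame({"s1": [10, 20, 30, 40, 50], "s2": [20, 10, 60, 40, 100]})
        ref = np.exp(np.mean(np.log(counts.to_numpy()), axis=1))
        expected = np.median(counts.to_numpy() / ref[:, None], axis=0)
        sf = size_factors(counts)
        assert np.allclose(sf.to_numpy(), expected)

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.integers(1, 500, size=(30, 4)))
        shuffled = counts.sample(frac=1, random_state=0)
        assert np.allclose(size_factors(counts), size_factors(shuffled))

    def test_scaling_one_sample_scales_its_factor(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.integers(1, 500, size=(40, 3)), columns=list("abc"))
        scaled = counts.copy()
        scaled["b"] = 5 * scaled["b"]
        f0, f1 = size_factors(counts), size_factors(scaled)
        # relative to an unscaled sample (factors carry an arbitrary scale)
        assert (f1["b"] / f1["a"]) / (f0["b"] / f0["a"]) == pytest.approx(5.0)

    def test_no_reference_gene_error(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(EcologyError):
            size_factors(counts)


class TestFoldChange:
    def test_identical_groups_unity(self):
        rng = np.random.default_rng(4)
        base = rng.integers(10, 500, size=20)
        counts = pd.DataFrame({"a1": base, "a2": base, "b1": base, "b2": base})
        fc = fold_change(counts, ["a1", "a2"], ["b1", "b2"])
        assert np.allclose(fc, 1.0)

    def test_zero_gene_pseudocount(self):
        counts = pd.DataFrame({"a": [0, 100], "b": [0, 100]})
        fc = fold_change(counts, ["a"], ["b"])
        assert fc.iloc[0] == pytest.approx(1.0)

    def test_planted_eightfold(self, abundance_dataset):
        # negative-binomial noise makes single-gene estimates wobble; the
        # mean over the planted genes should sit near the true fold
        spec, table, counts, manifest = abundance_dataset
        eu = manifest["euphotic_samples"]
        me = manifest["mesopelagic_samples"]
        fc = fold_change(counts, me, eu, factors=pd.Series(1.0, index=counts.columns))
        planted = list(manifest["fold_changes"])
        assert 6 <= fc[planted].mean() <= 10
        others = [g for g in counts.index if g not in planted]
        assert 0.5 <= fc[others].mean() <= 2.0

    def test_overlapping_groups_error(self):
        counts = pd.DataFrame({"a": [1], "b": [2]})
        with pytest.raises(EcologyError):
            fold_change(counts, ["a"], ["a"])


class TestDepthDifferential:
    def test_planted_genes_called_mesopelagic(self, abundance_dataset):
        spec, table, counts, manifest = abundance_dataset
        df = depth_differential(
            counts, table.meta["depth"], n_permutations=2000, seed=11, normalize=True
        )
        called = set(df.index[df["zone"] == "mesopelagic"])
        assert called == set(manifest["fold_changes"])

    def test_boundary_above_all_depths_error(self, abundance_dataset):
        _, table, counts, _ = abundance_dataset
        with pytest.raises(EcologyError):
            depth_differential(counts, table.meta["depth"], boundary_m=5000)

    def test_seed_reproducibility(self, abundance_dataset):
        _, table, counts, _ = abundance_dataset
        a = depth_differential(counts, table.meta["depth"], n_permutations=500, seed=3)
        b = depth_differential(counts, table.meta["depth"], n_permutations=500, seed=3)
        assert np.allclose(a["p"], b["p"])


class TestAbundanceTableIO:
    def test_tsv_round_trip(self, tmp_path, abundance_dataset):
        _, table, _, _ = abundance_dataset
        vp, mp = tmp_path / "a.tsv", tmp_path / "m.tsv"
        table.write(vp, mp)
        back = AbundanceTable.read(vp, mp)
        assert np.allclose(back.values.to_numpy(), table.values.to_numpy())
        assert list(back.gene_taxa) == list(table.gene_taxa)
        assert list(back.meta["region"]) == list(table.meta["region"])
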