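"""Distances, neighbor joining, bootstrap, PCA, heterozygosity, pi and the
LOD selection scan."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radpop import (
    GenotypeMatrix,
    bootstrap_support,
    group_pi,
    heterozygosity_rate,
    lod_selection_scan,
    neighbor_joining,
    pairwise_distance_matrix,
    pca_coordinates,
    rad_genome_size_mb,
)
from radpop.popgen import DistanceMatrix

from conftest import random_additive_tree


def matrix_from(calls, **kwargs):
    return GenotypeMatrix.from_calls(pd.DataFrame(calls), **kwargs)


class TestDistances:
    def test_hom_vs_het_is_half(self):
        m = matrix_from({"i": [0], "j": [1]})
        dm = pairwise_distance_matrix(m)
        assert dm[("i", "j")] == 0.5

    def test_identical_vectors_zero(self):
        m = matrix_from({"i": [0, 1, 2], "j": [0, 1, 2]})
        assert pairwise_distance_matrix(m)[("i", "j")] == 0.0

    def test_mixed_four_locus_example(self):
        # opposite homozygotes at 2 loci, identical at 2 -> (1+1+0+0)/4
        m = matrix_from({"i": [0, 0, 1, 2], "j": [2, 2, 1, 2]})
        assert pairwise_distance_matrix(m)[("i", "j")] == 0.5

    def test_symmetry_zero_diagonal_and_range(self):
        rng = np.random.default_rng(3)
        calls = pd.DataFrame(
            rng.integers(-1, 3, size=(50, 6)),
            columns=[f"a{i}" for i in range(6)],
        )
        dm = pairwise_distance_matrix(GenotypeMatrix.from_calls(calls))
        assert np.allclose(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0)
        assert (dm.values >= 0).all() and (dm.values <= 1).all()

    def test_no_shared_loci_fails_naming_pair(self):
        m = matrix_from({"i": [0, -1], "j": [-1, 2]})
        with pytest.raises(ValueError, match="i.*j"):
            pairwise_distance_matrix(m)

    def test_missing_pairs_excluded_from_mean(self):
        m = matrix_from({"i": [0, 0], "j": [2, -1]})
        assert pairwise_distance_matrix(m)[("i", "j")] == 1.0


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
        tree = neighbor_joining(DistanceMatrix(["a", "b", "c"], D, D))
        lengths = {l.name: l.length for l in tree.leaves()}
        assert lengths == {"a": 2.0, "b": 3.0, "c": 7.0}

    def test_fewer_than_three_taxa_rejected(self):
        D = np.zeros((2, 2))
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["a", "b"], D, D))

    def test_recovers_random_additive_tree(self, rng):
        true = random_additive_tree(8, rng)
        pd_true = true.patristic_distances()
        labels = list(pd_true.index)
        dm = DistanceMatrix(labels, pd_true.to_numpy(), pd_true.to_numpy())
        recovered = neighbor_joining(dm)
        assert recovered.bipartitions() == true.bipartitions()
        pd_rec = recovered.patristic_distances().loc[labels, labels]
        assert np.allclose(pd_rec.to_numpy(), pd_true.to_numpy(), atol=1e-9)

    def test_newick_round_trip_parses(self):
        import io

        from Bio import Phylo

        true = random_additive_tree(6, np.random.default_rng(0))
        newick = true.to_newick()
        tree = Phylo.read(io.StringIO(newick), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == sorted(
            true.leaf_names()
        )


class TestBootstrap:
    def test_identical_columns_give_full_support(self):
        # every locus identical: each replicate reproduces the same
        # distance matrix, so every reference bipartition appears in all
        # replicates
        column = np.array([[0, 0, 1, 1, 2, 2, 0, 2]])
        calls = pd.DataFrame(
            np.repeat(column, 50, axis=0), columns=[f"a{i}" for i in range(8)]
        )
        m = GenotypeMatrix.from_calls(calls)
        bs = bootstrap_support(m, n_reps=20, seed=1)
        assert all(v == 100.0 for v in bs.supports.values())

    def test_single_replicate_supports_binary(self):
        rng = np.random.default_rng(6)
        calls = pd.DataFrame(
            rng.integers(0, 3, size=(40, 8)), columns=[f"a{i}" for i in range(8)]
        )
        bs = bootstrap_support(GenotypeMatrix.from_calls(calls), n_reps=1, seed=2)
        assert set(bs.supports.values()) <= {0.0, 100.0}

    def test_leaf_clades_trivially_supported(self):
        rng = np.random.default_rng(7)
        calls = pd.DataFrame(
            rng.integers(0, 3, size=(30, 6)), columns=[f"a{i}" for i in range(6)]
        )
        bs = bootstrap_support(GenotypeMatrix.from_calls(calls), n_reps=5, seed=3)
        assert bs.clade_support(["a0"]) == 100.0


class TestPca:
    def test_rank_one_matrix_single_component(self):
        m = matrix_from({"a": [0], "b": [2], "c": [0], "d": [2]})
        res = pca_coordinates(m)
        assert (res.eigenvalues[1:] < 1e-12).all()
        assert res.eigenvalues[0] > 0

    def test_eigenvalue_sum_equals_total_variance(self):
        rng = np.random.default_rng(8)
        calls = pd.DataFrame(
            rng.integers(0, 3, size=(60, 7)), columns=[f"a{i}" for i in range(7)]
        )
        m = GenotypeMatrix.from_calls(calls)
        res = pca_coordinates(m)
        X = m.dosage_values()
        Xc = X - X.mean(axis=0)
        total = (Xc**2).sum() / (X.shape[1] - 1)
        assert np.isclose(res.eigenvalues.sum(), total)

    def test_two_planted_clusters_separate_on_pc1(self):
        rng = np.random.default_rng(9)
        left = rng.choice([0, 1], p=[0.9, 0.1], size=(100, 5))
        right = rng.choice([1, 2], p=[0.1, 0.9], size=(100, 5))
        calls = pd.DataFrame(
            np.hstack([left, right]), columns=[f"a{i}" for i in range(10)]
        )
        res = pca_coordinates(GenotypeMatrix.from_calls(calls))
        pc1 = res.coordinates["PC1"].to_numpy()
        # sign-invariant: the two groups fall on opposite sides
        assert len(set(np.sign(pc1[:5]))) == 1
        assert len(set(np.sign(pc1[5:]))) == 1
        assert np.sign(pc1[0]) != np.sign(pc1[5])


class TestHeterozygosity:
    def test_zero_hets(self):
        m = matrix_from({"a": [0, 2, 0], "b": [0, 0, 0]})
        assert heterozygosity_rate(m, "a").per_kb == 0.0

    def test_worked_example_100_of_1000(self):
        calls = pd.DataFrame({"a": [1] * 100 + [0] * 900, "b": [0] * 1000})
        m = GenotypeMatrix.from_calls(calls)
        rec = heterozygosity_rate(m, "a")
        assert rec.l_rad_genome == 41000
        assert round(rec.per_kb, 2) == 2.44

    def test_upper_bound_all_het(self):
        m = matrix_from({"a": [1] * 10, "b": [0] * 10})
        assert round(heterozygosity_rate(m, "a").per_kb, 2) == 24.39

    def test_all_missing_fails(self):
        m = matrix_from({"a": [-1], "b": [0]})
        with pytest.raises(ValueError):
            heterozygosity_rate(m, "a")

    def test_rad_genome_size(self):
        assert rad_genome_size_mb(1000) == 0.041


class TestGroupPi:
    def brute_pi(self, codes):
        vals = [c / 2 for c in codes if c >= 0]
        if len(vals) < 3:
            return None
        pairs = list(itertools.combinations(vals, 2))
        return sum(abs(a - b) for a, b in pairs) / len(pairs)

    def test_four_four_split(self):
        m = matrix_from({f"a{i}": [0 if i < 4 else 2] for i in range(8)})
        pi = group_pi(m, [f"a{i}" for i in range(8)], m.loci[0])
        assert pi == pytest.approx(16 / 28)

    def test_seven_hom_one_het(self):
        m = matrix_from({f"a{i}": [0 if i < 7 else 1] for i in range(8)})
        pi = group_pi(m, [f"a{i}" for i in range(8)], m.loci[0])
        assert pi == pytest.approx(3.5 / 28)

    def test_monomorphic_group_zero(self):
        m = matrix_from({f"a{i}": [2] for i in range(5)})
        assert group_pi(m, [f"a{i}" for i in range(5)], m.loci[0]) == 0.0

    def test_too_few_genotyped_undefined(self):
        m = matrix_from({"a": [0], "b": [2], "c": [-1], "d": [-1]})
        assert group_pi(m, ["a", "b", "c", "d"], m.loci[0]) is None

    def test_unknown_group_fails(self):
        m = matrix_from({"a": [0], "b": [0], "c": [0]})
        with pytest.raises(ValueError):
            group_pi(m, "nonexistent", m.loci[0])

    @given(
        codes=st.lists(
            st.integers(min_value=-1, max_value=2), min_size=2, max_size=6
        )
    )
    @settings(max_examples=200, derandomize=True)
    def test_matches_brute_force_pair_loop(self, codes):
        m = matrix_from({f"a{i}": [c] for i, c in enumerate(codes)})
        got = group_pi(m, list(m.accessions), m.loci[0])
        expected = self.brute_pi(codes)
        if expected is None:
            assert got is None
        else:
            assert got == pytest.approx(expected)


class TestLodScan:
    GROUPS = {
        **{f"c{i}": "cult" for i in range(9)},
        **{f"w{i}": "wild" for i in range(8)},
    }
    CLASSES = {"cult": "cultivated", "wild": "wild"}

    def scan_one(self, cult_codes, wild_codes):
        calls = {f"c{i}": [g] for i, g in enumerate(cult_codes)}
        calls.update({f"w{i}": [g] for i, g in enumerate(wild_codes)})
        m = GenotypeMatrix.from_calls(
            pd.DataFrame(calls), group_of=self.GROUPS, class_of_group=self.CLASSES
        )
        return lod_selection_scan(m).iloc[0]

    def test_fixation_case_lod_one_selected(self):
        row = self.scan_one([0] * 9, [0, 0, 0, 0, 2, 2, 2, 2])
        assert row["lod"] == 1.0 and row["selected"]

    def test_equal_diversity_lod_zero(self):
        row = self.scan_one([0, 2] * 4 + [0], [0, 2] * 4)
        assert row["lod"] == pytest.approx(0.0, abs=0.06)
        assert not row["selected"]

    def test_partial_loss(self):
        # pi_c = 0.1 vs pi_w = 0.4 -> LOD = 0.75 (constructed via pi values)
        calls = {f"c{i}": [0 if i < 8 else 1] for i in range(9)}  # pi ~ 0.111
        calls.update({f"w{i}": [0 if i < 4 else 2] for i in range(8)})
        m = GenotypeMatrix.from_calls(
            pd.DataFrame(calls), group_of=self.GROUPS, class_of_group=self.CLASSES
        )
        row = lod_selection_scan(m).iloc[0]
        assert row["lod"] == pytest.approx(1 - row["pi_cultivated"] / row["pi_wild"])
        assert not row["selected"]

    def test_monomorphic_wild_undefined(self):
        row = self.scan_one([0, 2] * 4 + [0], [0] * 8)
        assert np.isnan(row["lod"]) and not row["selected"]

    def test_overlapping_groups_rejected(self):
        m = matrix_from({"a": [0], "b": [0], "c": [0]})
        with pytest.raises(ValueError):
            lod_selection_scan(m, cultivated=["a", "b"], wild=["b", "c"])
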