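"""Diversity closed forms, accumulation curves, dissimilarity, dendrogram,
and habitat-exclusivity classification."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from viropop.ecology import (
    accumulation_curve,
    bray_curtis,
    classify_distribution,
    hierarchical_cluster,
    jackknife2_richness,
    pielou_evenness,
)
from viropop.recruitment_abundance import AbundanceMatrix


def matrix(data, samples):
    return AbundanceMatrix(pd.DataFrame(data, columns=samples, index=[f"p{i}" for i in range(len(data))], dtype=float))


class TestPielou:
    def test_uniform_is_one(self):
        assert pielou_evenness([0.25] * 4) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        # H' = -(0.5 ln 0.5 + 2 * 0.25 ln 0.25) = 1.0397; J = H'/ln 3
        j = pielou_evenness([0.5, 0.25, 0.25])
        assert j == pytest.approx(1.0397 / math.log(3), abs=1e-4)

    def test_single_population_undefined(self):
        assert pielou_evenness([1.0]) is None

    def test_renormalizes_internally(self):
        assert pielou_evenness([2, 2, 2, 2]) == pytest.approx(1.0)

    def test_zero_sum_rejected(self):
        with pytest.raises(ValueError):
            pielou_evenness([0.0, 0.0])

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=1e-9, max_value=1e6, allow_nan=False), min_size=2, max_size=50)
    )
    def test_bounded_on_any_positive_vector(self, abundances):
        j = pielou_evenness(abundances)
        assert 0.0 <= j <= 1.0 + 1e-12


class TestJackknife2:
    def test_no_rare_populations(self):
        inc = np.ones((10, 4), dtype=bool)
        assert jackknife2_richness(inc) == pytest.approx(10.0)

    def test_hand_case_six_samples(self):
        # S=10, Q1=4, Q2=2, n=6 -> 10 + 4*9/6 - 2*16/30 = 14.9333
        inc = np.zeros((10, 6), dtype=bool)
        inc[:4, 0] = True               # four singletons
        inc[4:6, :2] = True             # two doubletons
        inc[6:, :3] = True              # the rest in three samples
        assert jackknife2_richness(inc) == pytest.approx(14.9333, abs=1e-4)

    def test_hand_case_two_samples(self):
        # n=2: S=5, Q1=2 -> 5 + 2*(2n-3)/n = 6.0; the Q2 term vanishes
        # because (n-2)^2 = 0
        inc = np.array([[1, 0], [0, 1], [1, 1], [1, 1], [1, 1]], dtype=bool)
        assert jackknife2_richness(inc) == pytest.approx(6.0)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            jackknife2_richness(np.ones((3, 1), dtype=bool))


class TestAccumulation:
    def test_identical_samples_flat(self):
        inc = np.ones((7, 4), dtype=bool)
        mean, sd, rate = accumulation_curve(inc, permutations=20, seed=0)
        assert mean.tolist() == [7, 7, 7, 7]
        assert sd.max() == 0
        assert rate == 0.0

    def test_final_mean_equals_observed_richness(self):
        rng = np.random.default_rng(1)
        inc = rng.random((30, 5)) < 0.4
        mean, _, _ = accumulation_curve(inc, permutations=50, seed=2)
        assert mean[-1] == pytest.approx(int(inc.any(axis=1).sum()))
        assert (np.diff(mean) >= -1e-12).all()  # monotone non-decreasing

    def test_disjoint_samples_exact_by_symmetry(self):
        inc = np.zeros((30, 3), dtype=bool)
        inc[:10, 0] = inc[10:20, 1] = inc[20:, 2] = True
        mean, _, rate = accumulation_curve(inc, permutations=60, seed=3)
        assert mean.tolist() == [10, 20, 30]
        assert rate == pytest.approx(1 / 3)


class TestBrayCurtis:
    def test_identical_columns_zero(self):
        m = matrix([[1, 1], [2, 2]], ["s1", "s2"])
        assert bray_curtis(m).loc["s1", "s2"] == pytest.approx(0.0)

    def test_disjoint_support_one(self):
        m = matrix([[1, 0], [0, 2]], ["s1", "s2"])
        assert bray_curtis(m).loc["s1", "s2"] == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        m = matrix([[1, 1], [0, 2]], ["s1", "s2"])
        assert bray_curtis(m).loc["s1", "s2"] == pytest.approx(0.5)

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(4)
        m = matrix(rng.random((10, 4)), ["a", "b", "c", "d"])
        d = bray_curtis(m)
        assert np.allclose(d.values, d.values.T)
        assert ((d.values >= 0) & (d.values <= 1)).all()

    def test_two_all_zero_columns_flagged(self):
        m = matrix([[0, 0, 1], [0, 0, 2]], ["s1", "s2", "s3"])
        d = bray_curtis(m)
        assert np.isnan(d.loc["s1", "s2"])


class TestDendrogram:
    def test_identical_samples_merge_at_zero(self):
        m = matrix([[1, 1], [2, 2]], ["s1", "s2"])
        assert hierarchical_cluster(m) == "(s1:0,s2:0);"

    def test_closest_pair_merges_first(self):
        # Manhattan distances: d(a,b)=2, d(a,c)=10, d(b,c)=10
        m = matrix([[0, 2, 10], [0, 0, 2]], ["a", "b", "c"])
        newick = hierarchical_cluster(m)
        assert "(a:1,b:1)" in newick

    def test_leaves_exactly_once(self):
        rng = np.random.default_rng(5)
        names = [f"s{i}" for i in range(6)]
        m = matrix(rng.random((8, 6)) * 10, names)
        newick = hierarchical_cluster(m)
        for name in names:
            assert newick.count(name) == 1

    def test_cophenetic_distances_match_scipy(self):
        """Dual-route check: cophenetic distances read off our Newick agree
        with scipy's average-linkage cophenetic matrix on Manhattan
        distances (up to the x2 between merge height and ultrametric leaf
        depth)."""
        import dendropy
        from scipy.cluster.hierarchy import cophenet, linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(6)
        cols = rng.random((8, 5)) * 10
        names = [f"s{i}" for i in range(5)]
        m = matrix(cols, names)
        newick = hierarchical_cluster(m)
        tree = dendropy.Tree.get(data=newick, schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        z = linkage(cols.T, method="average", metric="cityblock")
        expected = squareform(cophenet(z))
        for i in range(5):
            for j in range(i + 1, 5):
                got = pdm.patristic_distance(taxa[names[i]], taxa[names[j]])
                assert got == pytest.approx(expected[i, j], rel=1e-6)

    def test_unsupported_metric_rejected(self):
        m = matrix([[1, 1], [2, 2]], ["s1", "s2"])
        with pytest.raises(ValueError):
            hierarchical_cluster(m, metric="euclidean")


class TestDistribution:
    ZONES = {"s_ox": "oxic", "s_rc": "redoxcline", "s_eu": "euxinic"}

    def m(self, rows):
        return AbundanceMatrix(
            pd.DataFrame(rows, columns=["s_ox", "s_rc", "s_eu"], index=[f"p{i}" for i in range(len(rows))], dtype=float)
        )

    def test_euxinic_only_endemic(self):
        m = self.m([[0, 0, 5]])
        (c,) = classify_distribution(m, self.ZONES, {"p0": False})
        assert c.endemic and c.exclusivity == "euxinic_only"

    def test_cosmopolitan_when_in_reference(self):
        m = self.m([[5, 1, 1]])
        (c,) = classify_distribution(m, self.ZONES, {"p0": True})
        assert not c.endemic and c.exclusivity == "cosmopolitan"

    def test_oxygenated_only_when_endemic(self):
        m = self.m([[5, 0, 0]])
        (c,) = classify_distribution(m, self.ZONES, {"p0": False})
        assert c.endemic and c.exclusivity == "oxygenated_only"

    def test_redoxcline_and_euxinic(self):
        m = self.m([[0, 2, 5]])
        (c,) = classify_distribution(m, self.ZONES)
        assert c.exclusivity == "redoxcline_and_euxinic"

    def test_below_epsilon_indeterminate(self):
        m = self.m([[0.01, 0.01, 0.01]])
        (c,) = classify_distribution(m, self.ZONES, epsilon=0.05)
        assert c.exclusivity == "indeterminate"

    def test_classes_partition_populations(self):
        rng = np.random.default_rng(7)
        m = self.m((rng.random((20, 3)) < 0.5) * rng.random((20, 3)))
        classes = classify_distribution(m, self.ZONES)
        assert len(classes) == 20
        assert len({c.population_id for c in classes}) == 20
        for c in classes:
            assert c.exclusivity in (
                "cosmopolitan",
                "oxygenated_only",
                "euxinic_only",
                "redoxcline_only",
                "redoxcline_and_euxinic",
                "indeterminate",
            )

    def test_unknown_zone_rejected(self):
        m = self.m([[1, 1, 1]])
        with pytest.raises(ValueError):
            classify_distribution(m, {"s_ox": "oxic", "s_rc": "abyssal", "s_eu": "euxinic"})


def test_planted_exclusivity_recovery(small_virome):
    """Populations recover their planted habitat-exclusivity classes."""
    from conftest import abundance_from_virome

    plan, contigs, alignments, _, truth = small_virome
    m = abundance_from_virome(plan, contigs, alignments, truth)
    zone_of = {s.sample_id: s.zone for s in plan.zones}
    rep_of = truth.representative_of_population
    reference = {rep_of[p]: cls == "cosmopolitan" for p, cls in truth.exclusivity_of_population.items()}
    expected_label = {
        "cosmopolitan": "cosmopolitan",
        "cariaco_only": "oxygenated_only",
        "euxinic_only": "euxinic_only",
        "redoxcline_only": "redoxcline_only",
        "redoxcline_and_euxinic": "redoxcline_and_euxinic",
        "undetectable": "indeterminate",
    }
    got = {c.population_id: c.exclusivity for c in classify_distribution(m, zone_of, reference)}
    hits = sum(
        got[rep_of[p]] == expected_label[cls]
        for p, cls in truth.exclusivity_of_population.items()
    )
    assert hits == len(rep_of)
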