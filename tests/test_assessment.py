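import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from oracles import ari_pair_counting, exclusive_cells_bruteforce, nmi_plugin
from wmc.assessment import (
    DegeneratePartitionError,
    GeneSetCollection,
    ari,
    find_markers,
    intersection_analysis,
    nmi,
    pairwise_concordance,
)


class TestPartitionMetrics:
    def test_identity_gives_one(self, rng):
        labels = rng.integers(0, 4, size=50)
        assert ari(labels, labels) == 1.0
        assert nmi(labels, labels) == 1.0

    def test_hand_derived_crossed_pair(self):
        """The maximally crossed 2x2 case: ARI -0.5, NMI 0."""
        a = [1, 1, 2, 2]
        b = [1, 2, 1, 2]
        assert np.isclose(ari(a, b), -0.5)
        assert np.isclose(nmi(a, b), 0.0)

    def test_label_permutation_invariance(self, rng):
        a = rng.integers(0, 5, size=40)
        b = rng.integers(0, 3, size=40)
        sigma = {k: 10 - k for k in range(5)}
        a2 = np.array([sigma[x] for x in a])
        assert np.isclose(ari(a, b), ari(a2, b))
        assert np.isclose(nmi(a, b), nmi(a2, b))
        assert np.isclose(nmi(a, b), nmi(b, a))

    def test_against_bruteforce_and_sklearn(self, rng):
        """200 random label pairs agree with pair counting / plug-in
        entropy oracles and with scikit-learn, to 1e-12."""
        for _ in range(200):
            n = int(rng.integers(5, 30))
            a = rng.integers(0, int(rng.integers(2, 5)), size=n)
            b = rng.integers(0, int(rng.integers(2, 5)), size=n)
            if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
                continue
            assert abs(ari(a, b) - ari_pair_counting(a, b)) < 1e-12
            assert abs(nmi(a, b) - nmi_plugin(a, b)) < 1e-12
            assert abs(ari(a, b) - adjusted_rand_score(a, b)) < 1e-10
            assert abs(
                nmi(a, b)
                - normalized_mutual_info_score(a, b, average_method="geometric")
            ) < 1e-10

    def test_degenerate_cases(self):
        one = np.zeros(6, dtype=int)
        assert ari(one, one) == 1.0
        assert nmi(one, one) == 1.0
        singletons = np.arange(6)
        assert ari(singletons, singletons) == 1.0
        two = np.array([0, 0, 0, 1, 1, 1])
        with pytest.raises(DegeneratePartitionError):
            nmi(one, two)
        # single-cluster vs all-singletons has a nonzero ARI denominator
        assert ari(one, singletons) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ari([0, 1], [0, 1, 2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_bounds_property(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 3, size=20)
        b = rng.integers(0, 3, size=20)
        if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
            return
        assert -1.0 <= ari(a, b) <= 1.0
        assert 0.0 <= nmi(a, b) <= 1.0


class TestMarkers:
    def test_perfect_separation(self):
        """A gene at 5.0 in one cluster and 0.0 elsewhere is a marker."""
        rng = np.random.default_rng(1)
        X = np.zeros((20, 40))
        labels = np.repeat([0, 1], 20)
        X[7, labels == 1] = 5.0
        res = find_markers(X + rng.normal(0, 1e-6, X.shape),
                           [f"g{i}" for i in range(20)], labels)
        assert "g7" in res.genes

    def test_cell_permutation_invariance(self, rng):
        X = rng.normal(size=(30, 50))
        X[3, :25] += 2.0
        labels = np.repeat([0, 1], 25)
        ids = [f"g{i}" for i in range(30)]
        base = find_markers(X, ids, labels).genes
        perm = rng.permutation(50)
        assert find_markers(X[:, perm], ids, labels[perm]).genes == base

    def test_null_false_positive_rate(self):
        """Pure-noise data: BH keeps the marker fraction at or below the
        nominal level on average (global-null FDR control)."""
        fracs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(500, 60))
            labels = rng.integers(0, 2, size=60)
            while len(np.unique(labels)) < 2:
                labels = rng.integers(0, 2, size=60)
            res = find_markers(X, [f"g{i}" for i in range(500)], labels,
                               alpha=0.05, min_abs_effect=0.0)
            fracs.append(len(res.genes) / 500)
        assert np.mean(fracs) <= 0.05

    def test_single_cluster_errors(self, rng):
        X = rng.normal(size=(10, 20))
        with pytest.raises(ValueError):
            find_markers(X, [f"g{i}" for i in range(10)], np.zeros(20, dtype=int))

    def test_exclude_mask(self, rng):
        X = rng.normal(size=(10, 40))
        X[9, 20:] += 50.0
        labels = np.repeat([0, 1], 20)
        excl = np.zeros(10, dtype=bool)
        excl[9] = True
        res = find_markers(X, [f"g{i}" for i in range(10)], labels, exclude=excl)
        assert "g9" not in res.genes


class TestIntersection:
    def test_worked_three_set_example(self):
        G = GeneSetCollection(
            sets=({"a", "b", "c"}, {"b", "c", "d"}, {"c", "e"}),
            universe={"a", "b", "c", "d", "e"},
        )
        rep = intersection_analysis(G)
        assert rep.entries[frozenset({1})] == {"d"}
        assert rep.entries[frozenset({0, 1, 2})] == {"c"}
        assert rep.entries[frozenset({1, 2})] == frozenset()
        assert sum(len(g) for g in rep.entries.values()) == 5

    def test_partition_property_random(self, rng):
        """Exclusive cells are disjoint and cover the union exactly,
        matching per-gene brute-force enumeration."""
        universe = [f"g{i}" for i in range(30)]
        for _ in range(200):
            m = int(rng.integers(2, 5))
            sets = [set(rng.choice(universe, size=rng.integers(0, 15),
                                   replace=False)) for _ in range(m)]
            rep = intersection_analysis(
                GeneSetCollection(tuple(sets), frozenset(universe)))
            brute = exclusive_cells_bruteforce(sets)
            assert {L: set(v) for L, v in rep.entries.items()} == brute
            union = set().union(*sets)
            cells = list(rep.entries.values())
            assert sum(len(c) for c in cells) == len(union)
            for i in range(len(cells)):
                for j in range(i + 1, len(cells)):
                    assert not (cells[i] & cells[j])

    def test_identical_sets_concentrate_in_full_subset(self):
        s = {"x", "y"}
        rep = intersection_analysis(
            GeneSetCollection((s, s, s), frozenset(s)))
        for L, genes in rep.entries.items():
            assert bool(genes) == (L == frozenset({0, 1, 2}))
        assert rep.leakage == 0

    def test_leakage_diagnostic(self):
        rep = intersection_analysis(GeneSetCollection(
            sets=(set(), {"a", "b"}, {"a"}), universe={"a", "b"}))
        assert rep.leakage == 1  # "a" shared by views 1,2 but absent in 0


class TestConcordance:
    def test_two_views_one_pair(self):
        rep = pairwise_concordance({"low": [0, 0, 1, 1], "high": [0, 1, 0, 1]},
                                   include_original=True)
        assert len(rep.table) == 1
        assert np.isclose(rep.table["ARI"][0], -0.5)

    def test_four_band_pair_count(self, rng):
        views = {f"h{i}": rng.integers(0, 3, size=30) for i in range(4)}
        rep = pairwise_concordance(views)
        assert len(rep.table) == 6

    def test_identical_views_all_one(self):
        lab = np.repeat([0, 1, 2], 10)
        rep = pairwise_concordance({"a": lab, "b": lab, "c": lab})
        assert np.allclose(rep.table["ARI"], 1.0)
        assert np.allclose(rep.table["NMI"], 1.0)

    def test_degenerate_pairs_become_nan(self):
        """A zero-entropy view leaves NMI undefined (NaN) while ARI,
        whose denominator is nonzero there, is still reported."""
        rep = pairwise_concordance({"a": np.zeros(6, int),
                                    "b": np.repeat([0, 1], 3)})
        assert rep.table["ARI"][0] == 0.0
        assert np.isnan(rep.table["NMI"][0])
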