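import numpy as np
import pandas as pd
import pytest

from benthoscape import stats_compare as st
from benthoscape.grids import Grid
from benthoscape.stratify import LabelMap
from benthoscape.survey import PresenceAbsenceMatrix


def two_groups(sep=10.0, n=30, d=5, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, (n, d))
    b = rng.normal(sep, 1.0, (n, d))
    return np.vstack([a, b]), np.repeat([1, 2], n)


class TestPermanova:
    def test_sum_of_squares_decomposition(self):
        data, labels = two_groups(sep=2.0)
        from scipy.spatial.distance import pdist, squareform
        d2 = squareform(pdist(data)) ** 2
        n = len(data)
        ss_total = d2[np.triu_indices(n, 1)].sum() / n
        ss_within = 0.0
        for g in (1, 2):
            idx = np.nonzero(labels == g)[0]
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
        # pseudo-F implied by the decomposition must match the statistic
        f_manual = ((ss_total - ss_within) / 1) / (ss_within / (n - 2))
        res = st.permanova(data, labels, n_permutations=9, seed=0)
        assert res.pseudo_f == pytest.approx(f_manual)

    def test_widely_separated_groups_reach_minimum_p(self):
        data, labels = two_groups(sep=10.0)
        res = st.permanova(data, labels, n_permutations=999, seed=1)
        assert res.p_raw == pytest.approx(1 / 1000)

    def test_null_pseudo_f_is_near_one_on_average(self):
        rng = np.random.default_rng(2)
        fs = []
        for i in range(60):
            data = rng.normal(size=(24, 4))
            labels = np.repeat([1, 2], 12)
            fs.append(st.permanova(data, labels, n_permutations=9,
                                   seed=i).pseudo_f)
        assert np.mean(fs) == pytest.approx(1.0, abs=0.15)

    def test_exact_enumeration_bounds_monte_carlo(self):
        data, labels = two_groups(sep=3.0, n=4, d=2, seed=4)
        p_exact = st.permanova_exact(data, labels)
        res = st.permanova(data, labels, n_permutations=999, seed=5)
        # Monte-Carlo p (with +1 correction) within binomial error
        se = np.sqrt(p_exact * (1 - p_exact) / 999)
        assert abs(res.p_raw - p_exact) < 3 * se + 1 / 1000

    def test_matches_reference_implementation(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as skbio_permanova
        data, labels = two_groups(sep=1.0, n=15, seed=6)
        from scipy.spatial.distance import pdist, squareform
        dm = skbio.DistanceMatrix(squareform(pdist(data)))
        expected = skbio_permanova(dm, grouping=[str(g) for g in labels],
                                   permutations=99)
        res = st.permanova(data, labels, n_permutations=99, seed=0)
        assert res.pseudo_f == pytest.approx(expected["test statistic"])

    def test_tiny_group_rejected(self):
        data = np.zeros((4, 2))
        with pytest.raises(ValueError, match="fewer than 2"):
            st.permanova(data, np.array([1, 1, 1, 2]))


class TestPairwisePermanova:
    def test_three_separated_groups_all_significant_at_0003(self):
        rng = np.random.default_rng(7)
        data = np.vstack([rng.normal(10.0 * g, 1.0, (40, 8))
                          for g in range(3)])
        labels = np.repeat([1, 2, 3], 40)
        results = st.pairwise_permanova(data, labels, n_permutations=999,
                                        seed=0)
        assert len(results) == 3
        for r in results:
            assert r.p_raw == pytest.approx(0.001)
            assert r.p_adjusted == pytest.approx(0.003)

    def test_two_groups_need_no_adjustment(self):
        data, labels = two_groups(sep=5.0)
        (res,) = st.pairwise_permanova(data, labels, n_permutations=99,
                                       seed=0)
        assert res.p_adjusted == res.p_raw

    def test_homogeneous_data_rarely_significant(self):
        rng = np.random.default_rng(8)
        hits = 0
        for i in range(20):
            data = rng.normal(size=(36, 3))
            labels = np.repeat([1, 2, 3], 12)
            results = st.pairwise_permanova(data, labels, n_permutations=99,
                                            seed=i)
            hits += any(r.p_adjusted <= 0.05 for r in results)
        assert hits <= 2


class TestComposition:
    def _matrix(self, columns, index):
        return PresenceAbsenceMatrix(
            pd.DataFrame(columns, index=pd.Index(index, name="image_id")))

    def test_exclusive_morphotype_has_unit_fraction(self):
        m = self._matrix({"oph": [1, 1, 0, 0]}, list("abcd"))
        comp = st.composition_fractions(m, [1, 1, 2, 3])
        assert comp.loc["oph", ("fraction", 1)] == 1.0
        assert comp.loc["oph", ("fraction", 2)] == 0.0

    def test_fraction_arithmetic(self):
        m = self._matrix({"m": [1, 1, 1, 1, 1, 1, 1, 1]}, range(8))
        comp = st.composition_fractions(m, [1, 1, 2, 2, 3, 3, 3, 3])
        assert comp.loc["m", ("fraction", 1)] == pytest.approx(0.25)
        assert comp.loc["m", ("fraction", 3)] == pytest.approx(0.5)

    def test_counts_reconstruct_totals_and_rows_sum_to_one(self):
        rng = np.random.default_rng(9)
        vals = rng.integers(0, 2, (30, 5))
        m = self._matrix({f"m{j}": vals[:, j] for j in range(5)}, range(30))
        groups = rng.integers(1, 4, 30)
        comp = st.composition_fractions(m, groups)
        for mtp in comp.index:
            assert comp.loc[mtp, "count"].sum() == m.values[mtp].sum()
            assert comp.loc[mtp, "fraction"].sum() == pytest.approx(1.0)

    def test_zero_occurrence_morphotypes_excluded(self):
        m = self._matrix({"seen": [1, 0], "unseen": [0, 0]}, ["a", "b"])
        comp = st.composition_fractions(m, [1, 2])
        assert "unseen" not in comp.index


class TestAssemblageSummary:
    def _setup(self):
        labels = np.ones((4, 4))
        labels[:, 2:] = 2.0
        amap = LabelMap(Grid(labels, 10.0, 0.0, 40.0), 2)
        table = pd.DataFrame({
            "image_id": ["a", "b", "c"],
            "x": [5.0, 15.0, 35.0], "y": [5.0, 15.0, 35.0],
            "area_m2": 4.0, "depth_m": [4000.0, 4000.0, 3500.0],
            "cruise": "C1", "m1": [2, 0, 1], "m2": [0, 0, 3]})
        from benthoscape.survey import to_presence_absence
        return amap, table, to_presence_absence(table)

    def test_partition_conserves_images_and_specimens(self):
        amap, table, matrix = self._setup()
        out = st.assemblage_summary(amap, table, matrix)
        assert out["n_images"].sum() == len(table)
        assert out["n_specimens"].sum() == 6

    def test_richness_and_depth_statistics(self):
        amap, table, matrix = self._setup()
        out = st.assemblage_summary(amap, table, matrix).set_index("assemblage")
        assert out.loc[1, "total_richness"] == 1  # only m1 in assemblage 1
        assert out.loc[2, "total_richness"] == 2
        assert out.loc[1, "depth_sd_m"] == 0.0


class TestHabitatAgreement:
    def _map(self, labels, k):
        return LabelMap(Grid(np.array(labels, float), 10.0, 0.0,
                             10.0 * len(labels)), k)

    def test_identical_maps_agree_fully(self):
        m = self._map([[1, 1], [2, 2]], 2)
        report = st.habitat_agreement(m, m)
        assert report.agreement == 1.0
        assert (report.difference_map.values == 1.0).all()

    def test_label_permutation_matched_away(self):
        a = self._map([[1, 1], [2, 2]], 2)
        b = self._map([[2, 2], [1, 1]], 2)
        report = st.habitat_agreement(a, b)
        assert report.agreement == 1.0
        assert report.matching == {1: 2, 2: 1}

    def test_toy_maps_best_agreement_three_quarters(self):
        a = self._map([[1, 1], [2, 2]], 2)
        b = self._map([[1, 2], [2, 2]], 2)
        report = st.habitat_agreement(a, b)
        # enumerate both matchings by hand: identity gives 3/4, swap 1/4
        assert report.agreement == pytest.approx(0.75)
        assert report.confusion.to_numpy().sum() == 4

    def test_optimal_matching_beats_any_fixed_matching(self):
        rng = np.random.default_rng(10)
        a = self._map(rng.integers(1, 4, (6, 6)), 3)
        b = self._map(rng.integers(1, 4, (6, 6)), 3)
        report = st.habitat_agreement(a, b)
        from itertools import permutations
        best_fixed = 0.0
        conf = report.confusion.to_numpy()
        for perm in permutations(range(3)):
            best_fixed = max(best_fixed,
                             sum(conf[i, perm[i]] for i in range(3)) / 36)
        assert report.agreement == pytest.approx(best_fixed)

    def test_geometry_mismatch_rejected(self):
        a = self._map([[1, 1], [2, 2]], 2)
        b = LabelMap(Grid(np.ones((3, 3)), 10.0, 0.0, 30.0), 1)
        with pytest.raises(ValueError, match="geometry"):
            st.habitat_agreement(a, b)
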