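import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

from breathlink import (
    FeatureTable,
    SampleMetadata,
    TableError,
    bh_adjust,
    bray_curtis,
    differential_abundance,
    nmds,
    permanova,
    summarize_cohort,
    summarize_vocs,
    wilcoxon_rank_sum,
)
from breathlink.community import DistanceMatrix


def table_of(rows, ids=None):
    rows = np.asarray(rows, dtype=float)
    ids = ids or [f"s{i}" for i in range(rows.shape[0])]
    return FeatureTable(pd.DataFrame(rows, index=ids), "voc")


class TestBrayCurtis:
    def test_hand_example(self):
        d = bray_curtis(table_of([[2, 0, 1], [0, 2, 1]]))
        assert d.values[0, 1] == pytest.approx(4 / 6)

    def test_identical_and_disjoint(self):
        d = bray_curtis(table_of([[1, 2, 0], [1, 2, 0], [0, 0, 7]]))
        assert d.values[0, 1] == 0.0
        assert d.values[0, 2] == 1.0

    def test_scale_invariance(self, rng):
        x = rng.lognormal(0, 1, (6, 10))
        d1 = bray_curtis(table_of(x))
        d2 = bray_curtis(table_of(x * 37.5))
        np.testing.assert_allclose(d1.values, d2.values, atol=1e-12)

    def test_all_zero_sample_rejected(self):
        with pytest.raises(TableError, match="all-zero"):
            bray_curtis(table_of([[1, 1], [0, 0]]))

    def test_range_and_symmetry(self, rng):
        d = bray_curtis(table_of(rng.lognormal(0, 1, (8, 12))))
        assert (d.values >= 0).all() and (d.values <= 1).all()
        np.testing.assert_allclose(d.values, d.values.T)


class TestNmds:
    def square(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        return squareform(pdist(pts))

    def test_embeddable_configuration_reaches_near_zero_stress(self):
        d = DistanceMatrix(list("abcd"), self.square())
        out = nmds(d, k=2, n_restarts=20, seed=0)
        assert out.stress < 1e-3
        np.testing.assert_allclose(out.coordinates.mean(axis=0), 0.0, atol=1e-9)

    def test_rank_invariance_under_monotone_transform(self):
        d = DistanceMatrix(list("abcd"), self.square() ** 2)
        out = nmds(d, k=2, n_restarts=20, seed=0)
        assert out.stress < 1e-3

    def test_equidistant_points_cannot_embed_in_2d(self):
        d = DistanceMatrix(list("abcd"), np.ones((4, 4)) - np.eye(4))
        out = nmds(d, k=2, n_restarts=10, seed=0)
        assert out.stress > 0.01

    def test_k_bounds(self):
        d = DistanceMatrix(list("abc"), np.ones((3, 3)) - np.eye(3))
        with pytest.raises(TableError):
            nmds(d, k=3)


class TestPermanova:
    def perfect(self):
        d = np.zeros((6, 6))
        d[:3, 3:] = 1.0
        d[3:, :3] = 1.0
        return DistanceMatrix(list("abcdef"), d)

    def test_exact_enumeration_on_perfect_separation(self):
        # brute-force oracle: enumerate all C(6,3)=20 relabelings directly
        d2 = self.perfect().values ** 2

        def f_stat(labels):
            labels = np.asarray(labels)
            n = 6
            ss_t = d2.sum() / (2 * n)
            ss_w = sum(
                d2[np.ix_(np.flatnonzero(labels == g), np.flatnonzero(labels == g))].sum()
                / (2 * 3)
                for g in ("x", "y")
            )
            return np.inf if ss_w == 0 else (ss_t - ss_w) / (ss_w / 4)

        obs = f_stat(["x"] * 3 + ["y"] * 3)
        exceed = sum(
            f_stat(lab) >= obs
            for pos in itertools.combinations(range(6), 3)
            for lab in [["x" if i in pos else "y" for i in range(6)]]
        )
        oracle_p = exceed / 20

        res = permanova(self.perfect(), np.array(["x"] * 3 + ["y"] * 3))
        assert res.exact and res.n_permutations == 20
        assert res.p_value == pytest.approx(oracle_p)
        # the complement relabeling ties with the observed one
        assert res.p_value == pytest.approx(2 / 20)

    def test_r2_is_one_on_perfect_separation(self):
        res = permanova(self.perfect(), np.array(["x"] * 3 + ["y"] * 3))
        assert res.r2 == pytest.approx(1.0)

    def test_r2_matches_sum_of_squares_oracle(self, rng):
        x = rng.lognormal(0, 1, (10, 6))
        t = table_of(x)
        d = bray_curtis(t)
        labels = np.array(["a"] * 5 + ["b"] * 5)
        res = permanova(d, labels, n_permutations=99, seed=0)
        d2 = d.values**2
        ss_t = d2.sum() / 20
        ss_w = sum(d2[i, j] for i in range(5) for j in range(5)) / 10 + sum(
            d2[i, j] for i in range(5, 10) for j in range(5, 10)
        ) / 10
        assert res.r2 == pytest.approx(1 - ss_w / ss_t)

    def test_matches_skbio_pseudo_f(self, rng):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        x = rng.lognormal(0, 1, (12, 8))
        d = bray_curtis(table_of(x))
        labels = ["a"] * 6 + ["b"] * 6
        res = permanova(d, np.array(labels), n_permutations=99, seed=0)
        sk = skbio_stats.permanova(
            skbio_stats.DistanceMatrix(d.values, d.sample_ids),
            grouping=labels,
            permutations=0,
        )
        assert res.pseudo_f == pytest.approx(sk["test statistic"], rel=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(TableError, match="2 groups"):
            permanova(self.perfect(), np.array(["x"] * 6))


class TestWilcoxon:
    def test_exact_toy(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(2 / 20)

    def test_identical_samples_p_near_one(self):
        _, p = wilcoxon_rank_sum([1.0, 2.0, 3.0, 4.0] * 8, [1.0, 2.0, 3.0, 4.0] * 8)
        assert p > 0.9

    def test_symmetry(self, rng):
        x, y = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
        _, p1 = wilcoxon_rank_sum(x, y)
        _, p2 = wilcoxon_rank_sum(y, x)
        assert p1 == pytest.approx(p2)

    def test_empty_sample_rejected(self):
        with pytest.raises(TableError):
            wilcoxon_rank_sum([], [1.0])


class TestBhAdjust:
    def test_hand_examples(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        np.testing.assert_allclose(bh_adjust([0.02, 0.02, 0.02]), [0.02, 0.02, 0.02])
        np.testing.assert_allclose(bh_adjust([0.5]), [0.5])

    def test_matches_quadratic_oracle_on_random_lists(self, rng):
        for _ in range(10):
            p = rng.uniform(0.001, 1.0, rng.integers(1, 30))
            order = np.argsort(p)
            m = len(p)
            q_sorted = [
                min(min(p[order[j]] * m / (j + 1) for j in range(i, m)), 1.0)
                for i in range(m)
            ]
            oracle = np.empty(m)
            oracle[order] = q_sorted
            np.testing.assert_allclose(bh_adjust(p), oracle, rtol=1e-12)

    def test_q_at_least_p(self, rng):
        p = rng.uniform(0.001, 1.0, 40)
        assert (bh_adjust(p) >= p - 1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(TableError):
            bh_adjust([0.0, 0.5])


class TestSummaries:
    # group means printed in the study's descriptive table; the pooled "All"
    # mean must equal the 16/33 sample-size-weighted mean of the group means
    PRINTED = {
        "1-Decanol": (353430.063, 385288.212, 374885.551),
        "1-Dodecene": (123288.563, 283119.212, 230929.612),
        "Methacrolein": (204225.125, 256452.03, 239398.347),
        "dl-erythro-1-phenyl-1,2-propanediol": (124073.063, 118816.939, 120533.224),
        "n-Hexane": (105393.813, 374209.303, 286432.816),
    }

    def test_pooled_mean_weighted_identity(self):
        from breathlink.community import pooled_mean

        for name, (cancer, control, allmean) in self.PRINTED.items():
            got = pooled_mean(
                {"cancer": cancer, "control": control}, {"cancer": 16, "control": 33}
            )
            assert round(got, 3) == pytest.approx(allmean, abs=1e-3), name

    def test_equal_group_sizes_pooled_is_midpoint(self, small_dataset):
        out = summarize_vocs(small_dataset)
        mid = (out["mean_cancer"] + out["mean_control"]) / 2
        np.testing.assert_allclose(out["mean_all"], mid)

    def test_summarize_vocs_matches_direct_computation(self, small_dataset):
        out = summarize_vocs(small_dataset)
        direct = small_dataset.voc.data["VOC_a"].mean()
        assert out.at["VOC_a", "mean_all"] == pytest.approx(direct)

    def test_cohort_percentages(self):
        meta = SampleMetadata(
            pd.DataFrame(
                {
                    "group": ["cancer"] * 16 + ["control"] * 33,
                    "sex": ["female"] * 10 + ["male"] * 6
                    + ["female"] * 24 + ["male"] * 9,
                },
                index=pd.Index([f"s{i}" for i in range(49)], name="sample_id"),
            )
        )
        table = summarize_cohort(meta)
        female = table[table["category"] == "female"].iloc[0]
        male = table[table["category"] == "male"].iloc[0]
        assert female["total"] == "34 (69.4%)"
        assert male["total"] == "15 (30.6%)"

    def test_all_one_sex_is_100_percent(self):
        meta = SampleMetadata(
            pd.DataFrame(
                {"group": ["cancer", "control", "control"], "sex": ["female"] * 3},
                index=pd.Index(["a", "b", "c"], name="sample_id"),
            )
        )
        table = summarize_cohort(meta)
        assert table.iloc[0]["total"] == "3 (100.0%)"


class TestDifferentialAbundance:
    def test_q_at_least_p_and_columns(self, small_dataset):
        out = differential_abundance(small_dataset)
        assert (out["q_value"] >= out["p_value"] - 1e-15).all()
        assert {"statistic", "p_value", "q_value"} <= set(out.columns)


@settings(max_examples=20, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_bray_curtis_triangle_of_bounds(seed):
    rng = np.random.default_rng(seed)
    x = rng.lognormal(0, 1, (5, 7))
    d = bray_curtis(table_of(x)).values
    assert (d >= -1e-12).all() and (d <= 1 + 1e-12).all()
    assert np.allclose(np.diag(d), 0)
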