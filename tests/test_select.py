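import numpy as np
import pandas as pd
import pytest
import scipy.stats

from breathlink import (
    FeatureTable,
    SampleMetadata,
    StudyDataset,
    SyntheticConfig,
    TableError,
    apply_threshold,
    backward_eliminate,
    cluster_heatmap_table,
    cross_block_correlations,
    generate_cohort,
    null_cohort,
)
from breathlink.select import AssociationMatrix, SelectionResult, choose_penalty, transform_block


def single_group_dataset(rng, n=40, p=8, q=10, link=True):
    """One-group dataset where VOC_link duplicates taxon t_link (pre-closure)."""
    samples = [f"s{i}" for i in range(n)]
    shared = rng.lognormal(2.0, 1.0, n)
    voc = pd.DataFrame(
        rng.lognormal(3.0, 1.0, (n, p)), index=samples,
        columns=[f"VOC_{j}" for j in range(p)],
    )
    if link:
        voc["VOC_link"] = shared
    taxa_raw = pd.DataFrame(
        rng.lognormal(0.0, 1.0, (n, q)), index=samples,
        columns=[f"t_{j}" for j in range(q)],
    )
    if link:
        taxa_raw["t_link"] = shared
    taxa = taxa_raw.div(taxa_raw.sum(axis=1), axis=0)
    meta = SampleMetadata(
        pd.DataFrame({"group": ["cancer"] * n}, index=pd.Index(samples, name="sample_id"))
    )
    return StudyDataset(FeatureTable(voc, "voc"), FeatureTable(taxa, "taxon"), meta)


class TestBackwardEliminate:
    def test_perfect_pair_survives(self, rng):
        ds = single_group_dataset(rng)
        sel, trace = backward_eliminate(
            ds, min_features=(1, 1), n_permutations=99, seed=0
        )
        assert sel.significant
        assert "VOC_link" in sel.voc_retained
        assert "t_link" in sel.taxa_retained

    def test_null_input_flagged_non_significant(self):
        flagged = 0
        n_rep = 20
        for seed in range(n_rep):
            ds, _ = null_cohort(
                SyntheticConfig(n_cancer=49, n_control=0, p_voc=20, q_taxa=24, seed=seed)
            )
            sel, trace = backward_eliminate(ds, n_permutations=99, seed=seed)
            if not sel.significant and not trace:
                flagged += 1
        assert flagged >= 0.9 * n_rep

    def test_recovers_planted_signatures(self):
        cfg = SyntheticConfig(
            n_cancer=150, n_control=0, p_voc=40, q_taxa=60,
            sig_voc=8, sig_taxa=10, rho=0.9, seed=0,
        )
        ds, truth = generate_cohort(cfg)
        sel, trace = backward_eliminate(
            ds, min_features=(8, 10), n_permutations=199, seed=0
        )
        tv, tt = set(truth.voc_signature["cancer"]), set(truth.taxa_signature["cancer"])
        got = set(sel.voc_retained) | set(sel.taxa_retained)
        sens = len(got & (tv | tt)) / 18
        assert sens >= 0.8
        assert sel.significant

    def test_trace_is_strictly_ordered_with_unique_removals(self, rng):
        ds = single_group_dataset(rng)
        _, trace = backward_eliminate(ds, min_features=(3, 3), n_permutations=99, seed=0)
        steps = [s.step for s in trace]
        assert steps == list(range(1, len(steps) + 1))
        removed = [s.removed for s in trace]
        assert len(removed) == len(set(removed))

    def test_max_r1_rule_trace_is_auditable(self, rng):
        # under the max_r1 rule every committed removal attains the maximum
        # refit r1 among significant candidates at its step; spot-check the
        # first step by brute force
        ds = single_group_dataset(rng, n=30, p=4, q=5)
        sel, trace = backward_eliminate(
            ds, min_features=(4, 5), n_permutations=99, seed=0, rule="max_r1"
        )
        if trace:
            from breathlink.select import _scan_p, fit_group_cca

            voc_block = transform_block(ds.voc, ("log10_pseudo", "zscore"))
            taxa_block = transform_block(ds.taxa, ("clr_with_zero_replacement",))
            fits = [
                fit_group_cca(voc_block.drop(columns=[c]), taxa_block, seed=0)
                for c in voc_block.columns
            ] + [
                fit_group_cca(voc_block, taxa_block.drop(columns=[c]), seed=0)
                for c in taxa_block.columns
            ]
            significant = [f.r1 for f in fits if _scan_p(f) < 0.05]
            assert trace[0].r1 == pytest.approx(max(significant), abs=1e-9)

    def test_multi_group_dataset_rejected(self, small_dataset):
        with pytest.raises(TableError, match="single-group"):
            backward_eliminate(small_dataset)


class TestCrossBlockCorrelations:
    def test_identical_columns_give_unit_entry(self, rng):
        ds = single_group_dataset(rng)
        sel = SelectionResult(
            "cancer", ["VOC_link"], ["t_link"], 1.0, 0.01, True, 0.05
        )
        # spearman is invariant to the closure and log transforms, so the
        # planted identical pair correlates perfectly... up to closure noise
        out = cross_block_correlations(ds, sel, method="spearman")
        assert out.matrix.at["VOC_link", "t_link"] > 0.9

    def test_spearman_monotone_invariance(self, rng):
        ds = single_group_dataset(rng)
        sel = SelectionResult(
            "cancer", ["VOC_0", "VOC_1"], ["t_0", "t_1"], 1.0, 0.01, True, 0.05
        )
        a = cross_block_correlations(ds, sel, method="spearman")
        ds2 = StudyDataset(
            FeatureTable(ds.voc.data**3, "voc"), ds.taxa, ds.metadata
        )
        b = cross_block_correlations(ds2, sel, method="spearman")
        np.testing.assert_allclose(a.matrix.to_numpy(), b.matrix.to_numpy(), atol=1e-12)

    def test_matches_bruteforce_spearman(self, rng):
        ds = single_group_dataset(rng)
        sel = SelectionResult(
            "cancer", ["VOC_0", "VOC_1", "VOC_2"], ["t_0", "t_1"], 1.0, 0.01, True, 0.05
        )
        out = cross_block_correlations(ds, sel, method="spearman")
        voc = transform_block(ds.voc, ("log10_pseudo", "zscore"))
        for v in sel.voc_retained:
            for t in sel.taxa_retained:
                expected = scipy.stats.spearmanr(
                    voc[v], ds.taxa.data[t]
                ).statistic
                assert out.matrix.at[v, t] == pytest.approx(expected, abs=1e-12)

    def test_empty_selection_rejected(self, rng):
        ds = single_group_dataset(rng)
        sel = SelectionResult("cancer", [], ["t_0"], 0.0, 1.0, False, 0.05)
        with pytest.raises(TableError, match="empty"):
            cross_block_correlations(ds, sel)


class TestApplyThreshold:
    def matrix(self, values, vocs, taxa):
        return AssociationMatrix(pd.DataFrame(values, index=vocs, columns=taxa), "spearman")

    def test_simple_threshold(self):
        m = self.matrix([[0.4, 0.6], [-0.7, 0.1]], ["v1", "v2"], ["t1", "t2"])
        out, pairs = apply_threshold(m, tau=0.5)
        assert set(map(tuple, pairs[["voc", "taxon"]].to_numpy())) == {
            ("v1", "t2"),
            ("v2", "t1"),
        }
        assert out.threshold == 0.5

    def test_tau_one_keeps_only_exact_unit(self):
        m = self.matrix([[1.0, 0.99], [-1.0, 0.5]], ["v1", "v2"], ["t1", "t2"])
        _, pairs = apply_threshold(m, tau=1.0)
        assert sorted(pairs["r"].tolist()) == [-1.0, 1.0]

    def test_featureless_rows_dropped(self):
        m = self.matrix([[0.9, 0.1], [0.2, 0.1]], ["keep", "drop"], ["t1", "t2"])
        out, _ = apply_threshold(m, tau=0.5)
        assert list(out.matrix.index) == ["keep"]
        assert list(out.matrix.columns) == ["t1"]

    def test_count_matches_bruteforce_on_random(self, rng):
        for _ in range(10):
            vals = rng.uniform(-1, 1, (6, 7))
            m = self.matrix(vals, [f"v{i}" for i in range(6)], [f"t{j}" for j in range(7)])
            _, pairs = apply_threshold(m, tau=0.5)
            assert len(pairs) == int((np.abs(vals) >= 0.5).sum())


class TestClusterHeatmap:
    def test_identical_features_merge_first(self, rng):
        base = rng.lognormal(3, 1, 10)
        data = pd.DataFrame(
            {"a": base, "b": base, "c": rng.lognormal(3, 1, 10)},
            index=[f"s{i}" for i in range(10)],
        )
        out = cluster_heatmap_table(FeatureTable(data, "voc"))
        # first merge joins the two identical (z-scored) features at height 0
        assert out.feature_linkage[0, 2] == pytest.approx(0.0, abs=1e-9)

    def test_merge_heights_invariant_to_feature_order(self, rng):
        data = pd.DataFrame(
            rng.lognormal(3, 1, (12, 6)),
            index=[f"s{i}" for i in range(12)],
            columns=[f"f{j}" for j in range(6)],
        )
        t1 = cluster_heatmap_table(FeatureTable(data, "voc"))
        t2 = cluster_heatmap_table(FeatureTable(data[data.columns[::-1]], "voc"))
        np.testing.assert_allclose(
            np.sort(t1.feature_linkage[:, 2]), np.sort(t2.feature_linkage[:, 2]),
            atol=1e-9,
        )

    def test_rows_are_zscored(self, rng):
        data = pd.DataFrame(rng.lognormal(3, 1, (15, 5)))
        out = cluster_heatmap_table(FeatureTable(data, "voc"))
        np.testing.assert_allclose(out.matrix.mean(axis=1), 0.0, atol=1e-10)

    def test_constant_feature_named_in_error(self, rng):
        data = pd.DataFrame(
            {"ok": rng.lognormal(3, 1, 8), "flat": np.full(8, 2.0)}
        )
        with pytest.raises(TableError, match="flat"):
            cluster_heatmap_table(FeatureTable(data, "voc"))


class TestChoosePenalty:
    def test_returns_grid_member_and_log(self, rng):
        ds = single_group_dataset(rng, n=45)
        voc = transform_block(ds.voc, ("log10_pseudo", "zscore"))
        taxa = transform_block(ds.taxa, ("clr_with_zero_replacement",))
        pen, log = choose_penalty(voc, taxa, grid=(0.0, 0.3), seed=0)
        assert pen in (0.0, 0.3)
        assert set(log) <= {0.0, 0.3}
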