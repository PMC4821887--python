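"""Preprocessing stages: formulas, printed thresholds, pipeline order."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cortexscreen import preprocess as pp
from cortexscreen.preprocess import (
    PipelineOrderError,
    as_expression_matrix,
    batch_variance_fraction,
    combine_replicates,
    compute_rpkm,
    filter_expressed_genes,
    log_quantile_normalize,
    median_center_genes,
    remove_batch_effects,
    variability_filter,
)


def ann_frame(lengths, mito=None):
    n = len(lengths)
    return pd.DataFrame(
        {
            "length_bp": lengths,
            "is_mitochondrial": mito if mito is not None else [False] * n,
            "baseline_log10_expr": [1.0] * n,
        },
        index=pd.Index([f"g{i}" for i in range(n)], name="gene_id"),
    )


def design_frame(samples, chemicals=None, cb=None, sb=None, vehicle=None):
    n = len(samples)
    return pd.DataFrame(
        {
            "chemical": chemicals or [f"c{i}" for i in range(n)],
            "concentration_um": 10.0,
            "replicate": 1,
            "is_vehicle": [s == vehicle for s in (chemicals or samples)],
            "culture_batch": cb or ["b0"] * n,
            "sequencing_batch": sb or ["s0"] * n,
        },
        index=pd.Index(samples, name="sample_id"),
    )


class TestRpkm:
    @pytest.mark.parametrize(
        "count,length,total,expected",
        [
            (100, 1_000, 1_000_000, 100.0),
            (0, 1_000, 1_000_000, 0.0),
            (50, 2_500, 10_000_000, 2.0),
        ],
    )
    def test_formula(self, count, length, total, expected):
        counts = pd.DataFrame(
            {"s1": [count, total - count]},
            index=pd.Index(["g0", "g1"], name="gene_id"),
        )
        ann = ann_frame([length, 1_000])
        rpkm = compute_rpkm(counts, ann).values
        assert rpkm.loc["g0", "s1"] == pytest.approx(expected)

    def test_zero_total_sample_named_in_error(self):
        counts = pd.DataFrame({"good": [5, 5], "empty": [0, 0]},
                              index=pd.Index(["g0", "g1"], name="gene_id"))
        with pytest.raises(ValueError, match="empty"):
            compute_rpkm(counts, ann_frame([1000, 1000]))


class TestExpressedFilter:
    def make(self, row, length):
        counts = pd.DataFrame(
            [row, [10] * len(row)],
            index=pd.Index(["target", "keeper"], name="gene_id"),
            columns=[f"s{i}" for i in range(len(row))],
        )
        ann = ann_frame([length, 10_000])
        ann.index = counts.index
        return filter_expressed_genes(compute_rpkm(counts, ann))

    def test_gene_nonzero_in_exactly_90pct_removed(self):
        row = [1] * 9 + [0]  # 90% of 10 samples, not more
        out = self.make(row, 10_000)
        assert "target" not in out.values.index

    def test_gene_of_length_500_removed(self):
        out = self.make([1] * 10, 500)
        assert "target" not in out.values.index

    def test_gene_501bp_everywhere_expressed_retained(self):
        out = self.make([1] * 10, 501)
        assert "target" in out.values.index

    def test_empty_result_is_error(self):
        counts = pd.DataFrame({"s1": [1], "s2": [1]},
                              index=pd.Index(["g0"], name="gene_id"))
        with pytest.raises(ValueError, match="threshold"):
            filter_expressed_genes(compute_rpkm(counts, ann_frame([400])))


def brute_force_quantile_normalize(x):
    """Independent oracle: rank/mean construction with explicit loops."""
    n, m = x.shape
    ref = np.mean(np.stack([np.sort(x[:, j]) for j in range(m)], axis=1), axis=1)
    out = np.empty_like(x, dtype=float)
    for j in range(m):
        ranks = stats.rankdata(x[:, j], method="average")
        for i in range(n):
            r = ranks[i]
            lo, hi = int(np.floor(r)) - 1, int(np.ceil(r)) - 1
            out[i, j] = (ref[lo] + ref[hi]) / 2
    return out


class TestQuantileNormalize:
    def lognorm(self, arr):
        counts = pd.DataFrame(
            arr, index=pd.Index([f"g{i}" for i in range(arr.shape[0])], name="gene_id"),
            columns=[f"s{j}" for j in range(arr.shape[1])],
        )
        m = as_expression_matrix(counts.astype(float), stage="rpkm")
        return log_quantile_normalize(m).values.to_numpy()

    def test_permuted_samples_share_sorted_columns(self):
        rng = np.random.default_rng(0)
        col = rng.lognormal(1, 1, size=50)
        arr = np.stack([col, rng.permutation(col)], axis=1)
        out = self.lognorm(arr)
        assert np.allclose(np.sort(out[:, 0]), np.sort(out[:, 1]), atol=1e-12)

    def test_single_sample_is_log_only(self):
        arr = np.array([[1.0], [10.0], [100.0]])
        out = self.lognorm(arr)
        assert np.allclose(out[:, 0], np.log10(arr[:, 0] + pp.LOG_OFFSET))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        arr = rng.lognormal(0.5, 1.0, size=(11, 4))
        arr[3, 1] = arr[5, 1]  # force a tie within one sample
        logged = np.log10(arr + pp.LOG_OFFSET)
        expected = brute_force_quantile_normalize(logged)
        assert np.allclose(self.lognorm(arr), expected, atol=1e-12)

    def test_worked_3x2_example(self):
        arr = np.array([[2.0, 4.0], [5.0, 8.0], [3.0, 1.0]])
        logged = np.log10(arr + pp.LOG_OFFSET)
        expected = brute_force_quantile_normalize(logged)
        assert np.allclose(self.lognorm(arr), expected, atol=1e-12)


class TestMedianCenter:
    def centre(self, arr):
        counts = pd.DataFrame(
            arr, index=pd.Index([f"g{i}" for i in range(arr.shape[0])], name="gene_id"),
            columns=[f"s{j}" for j in range(arr.shape[1])],
        )
        m = as_expression_matrix(counts.astype(float), stage="log_qnorm")
        m.provenance = ["log_qnorm"]
        return median_center_genes(m)

    def test_constant_row_becomes_zero(self):
        out = self.centre(np.full((1, 4), 7.0))
        assert np.allclose(out.values.to_numpy(), 0.0)

    def test_simple_row(self):
        out = self.centre(np.array([[1.0, 2.0, 3.0]]))
        assert np.allclose(out.values.to_numpy(), [[-1.0, 0.0, 1.0]])

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=9))
    def test_row_median_is_zero_and_idempotent(self, row):
        out = self.centre(np.array([row]))
        vals = out.values.to_numpy()[0]
        assert np.isclose(np.median(vals), 0.0, atol=1e-9)
        assert np.allclose(vals - np.median(vals), vals, atol=1e-9)


class TestBatchRemoval:
    def staged(self, values, design):
        m = as_expression_matrix(values, design=design, stage="median_center")
        m.provenance = ["median_center"]
        return m

    def test_pure_batch_shift_removed(self):
        rng = np.random.default_rng(1)
        samples = [f"s{i}" for i in range(8)]
        cb = ["A"] * 4 + ["B"] * 4
        base = rng.normal(0, 1, size=(20, 8))
        shifted = base.copy()
        shifted[:, 4:] += 3.0
        values = pd.DataFrame(shifted, columns=samples,
                              index=pd.Index([f"g{i}" for i in range(20)], name="gene_id"))
        design = design_frame(samples, cb=cb, sb=["s0"] * 8)
        out = remove_batch_effects(self.staged(values, design), design)
        got = out.values.to_numpy()
        mean_a = got[:, :4].mean(axis=1)
        mean_b = got[:, 4:].mean(axis=1)
        assert np.allclose(mean_a, mean_b, atol=1e-9)

    def test_single_level_factors_leave_input_unchanged(self):
        samples = [f"s{i}" for i in range(4)]
        values = pd.DataFrame(np.arange(8.0).reshape(2, 4), columns=samples,
                              index=pd.Index(["g0", "g1"], name="gene_id"))
        design = design_frame(samples)
        out = remove_batch_effects(self.staged(values, design), design)
        assert np.allclose(out.values.to_numpy(), values.to_numpy(), atol=1e-12)

    def test_grand_means_conserved(self, tiny_screen):
        cfg, ann, design, truth, counts = tiny_screen
        m = compute_rpkm(as_expression_matrix(counts, annotation=ann, design=design))
        m = median_center_genes(log_quantile_normalize(filter_expressed_genes(m)))
        out = remove_batch_effects(m)
        before = m.values.mean(axis=1)
        after = out.values.mean(axis=1)
        assert np.allclose(before, after, atol=1e-9)

    def test_planted_batch_variance_drops_below_1pct(self, tiny_screen):
        cfg, ann, design, truth, counts = tiny_screen
        m = compute_rpkm(as_expression_matrix(counts, annotation=ann, design=design))
        m = median_center_genes(log_quantile_normalize(filter_expressed_genes(m)))
        out = remove_batch_effects(m)
        for factor in ("culture_batch", "sequencing_batch"):
            assert batch_variance_fraction(out.values, design, factor) < 0.01

    def test_aliased_factors_rejected(self):
        samples = [f"s{i}" for i in range(6)]
        cb = ["A", "A", "A", "B", "B", "B"]
        values = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 6)),
                              columns=samples,
                              index=pd.Index([f"g{i}" for i in range(5)], name="gene_id"))
        design = design_frame(samples, cb=cb, sb=cb)  # sequencing copies culture
        with pytest.raises(ValueError, match="confounded"):
            remove_batch_effects(self.staged(values, design), design)

    def test_single_sample_level_warns(self):
        samples = [f"s{i}" for i in range(5)]
        cb = ["A", "A", "B", "B", "C"]
        values = pd.DataFrame(np.random.default_rng(0).normal(size=(4, 5)),
                              columns=samples,
                              index=pd.Index([f"g{i}" for i in range(4)], name="gene_id"))
        design = design_frame(samples, cb=cb, sb=["s0", "s1", "s0", "s1", "s0"])
        with pytest.warns(UserWarning, match="single-sample"):
            remove_batch_effects(self.staged(values, design), design)

    def test_shrinkage_removes_less_than_full_subtraction(self):
        rng = np.random.default_rng(3)
        samples = [f"s{i}" for i in range(12)]
        cb = ["A", "B", "C"] * 4
        values = pd.DataFrame(rng.normal(0, 1, size=(30, 12)), columns=samples,
                              index=pd.Index([f"g{i}" for i in range(30)], name="gene_id"))
        design = design_frame(samples, cb=cb, sb=["s0"] * 12)
        anova = remove_batch_effects(self.staged(values, design), design, method="anova")
        shrunk = remove_batch_effects(self.staged(values, design), design, method="shrinkage")
        move_anova = np.abs(anova.values.to_numpy() - values.to_numpy()).sum()
        move_shrunk = np.abs(shrunk.values.to_numpy() - values.to_numpy()).sum()
        assert move_shrunk <= move_anova


class TestVariabilityFilter:
    def staged(self, rows):
        values = pd.DataFrame(
            rows, index=pd.Index([f"g{i}" for i in range(len(rows))], name="gene_id"),
            columns=[f"s{j}" for j in range(len(rows[0]))],
        )
        m = as_expression_matrix(values.astype(float), stage="median_center_2")
        m.provenance = ["median_center_2"]
        return m

    def test_boundary_sd_removed_and_clear_cases(self):
        # row with sd exactly 0.1 (n-1 denominator), a constant row, and
        # an alternating +-1 row
        x = 0.1 / np.sqrt(2)
        rows = [
            [-x, 0.0, x, 0.0][:3] + [0.0],   # placeholder replaced below
        ]
        boundary = np.array([-0.1, 0.0, 0.1, 0.0])
        boundary = boundary * (0.1 / boundary.std(ddof=1))
        rows = [list(boundary), [5.0] * 4, [1.0, -1.0, 1.0, -1.0]]
        out = variability_filter(self.staged(rows))
        assert list(out.values.index) == ["g2"]


class TestCombineReplicates:
    def staged(self, values, design):
        m = as_expression_matrix(values, design=design, stage="sd_filter")
        m.provenance = ["sd_filter"]
        return m

    def test_median_conventions(self):
        samples = ["a1", "a2", "a3", "b1", "b2", "v1"]
        chems = ["A", "A", "A", "B", "B", "vehicle"]
        values = pd.DataFrame(
            [[1.0, 2.0, 10.0, 4.0, 6.0, 0.5]],
            index=pd.Index(["g0"], name="gene_id"), columns=samples,
        )
        design = design_frame(samples, chemicals=chems, vehicle="vehicle")
        prof = combine_replicates(self.staged(values, design), design)
        assert prof.values.loc["g0", "A"] == pytest.approx(2.0)    # odd count
        assert prof.values.loc["g0", "B"] == pytest.approx(5.0)    # mean of middle two
        assert prof.values.loc["g0", "vehicle"] == pytest.approx(0.5)  # single replicate
        assert prof.vehicle == "vehicle"


class TestPipelineOrder:
    def test_out_of_order_call_raises(self, tiny_screen):
        cfg, ann, design, truth, counts = tiny_screen
        m = as_expression_matrix(counts, annotation=ann, design=design)
        with pytest.raises(PipelineOrderError):
            variability_filter(m)
        with pytest.raises(PipelineOrderError):
            median_center_genes(m)
        rpkm = compute_rpkm(m)
        with pytest.raises(PipelineOrderError):
            compute_rpkm(rpkm)
        with pytest.raises(PipelineOrderError):
            remove_batch_effects(rpkm)

    def test_full_pipeline_provenance(self, tiny_profiles):
        assert tiny_profiles.provenance == [
            "counts", "rpkm", "expressed_filter", "log_qnorm", "median_center",
            "batch_corrected", "median_center_2", "sd_filter", "combine_replicates",
        ]

    def test_signature_genes_mostly_retained(self, tiny_screen, tiny_profiles):
        _, _, _, truth, _ = tiny_screen
        sig = {g for k, v in truth.signature_genes.items() if k > 0 for g, _ in v}
        kept = len(sig & set(tiny_profiles.retained_gene_ids)) / len(sig)
        assert kept >= 0.8
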