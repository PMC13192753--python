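import numpy as np
import pandas as pd
import pytest

from gutlink import (FeatureTable, clr, filter_genes, filter_taxa_prevalence,
                     frequency_contaminant_score, log_cpm, tss, variance_filter)
from gutlink.synthetic import SynthConfig, generate_cohort


def _table(vals, kind="counts"):
    vals = np.asarray(vals)
    return FeatureTable(
        pd.DataFrame(vals, index=[f"f{i}" for i in range(vals.shape[0])],
                     columns=[f"s{j}" for j in range(vals.shape[1])]),
        kind,
    )


class TestPrevalenceFilter:
    def test_feature_above_thresholds_retained(self):
        # 0.02% relative abundance everywhere clears the 0.01% threshold
        n = 10
        rare = np.full(n, 2)  # 2 / 10000 = 2e-4
        bulk = np.full(n, 9998)
        t = _table(np.vstack([rare, bulk]))
        out = filter_taxa_prevalence(t, 1e-4, 0.10)
        assert out.feature_ids == ["f0", "f1"]

    def test_absent_feature_removed(self):
        t = _table([[0] * 10, [100] * 10])
        out = filter_taxa_prevalence(t)
        assert out.feature_ids == ["f1"]

    def test_single_qualifying_sample_meets_ceil(self):
        # ceil(0.10 * 10) = 1, so one qualifying sample suffices
        vals = np.full((2, 10), 0)
        vals[0, 0] = 5  # 5/10000 = 5e-4 in exactly one sample
        vals[1] = 9995
        vals[1, 0] = 9995
        t = _table(vals)
        out = filter_taxa_prevalence(t, 1e-4, 0.10)
        assert "f0" in out.feature_ids

    def test_empty_result_errors(self):
        t = _table([[50] * 10, [50] * 10])
        with pytest.raises(ValueError, match="no features"):
            filter_taxa_prevalence(t, min_rel_abund=0.999)


class TestGeneFilter:
    def test_examples(self):
        n = 10
        g_pass = [10] * 4 + [0] * 6  # >= 10 counts in 40% of samples
        g_fail = [9] * n  # never reaches 10
        t = _table([g_pass, g_fail])
        out = filter_genes(t, 10, 0.33)
        assert out.feature_ids == ["f0"]

    def test_exact_ceil_boundary(self):
        # n=30: ceil(0.33 * 30) = 10, so 10 qualifying samples retain
        row10 = [10] * 10 + [0] * 20
        row9 = [10] * 9 + [0] * 21
        t = _table([row10, row9])
        out = filter_genes(t, 10, 0.33)
        assert out.feature_ids == ["f0"]


class TestVarianceFilter:
    def test_quantile_threshold_sort_oracle(self):
        rng = np.random.default_rng(0)
        # per-feature variances approximately 1..100 via scaled noise
        base = rng.standard_normal((100, 200))
        base = (base - base.mean(1, keepdims=True)) / base.std(1, ddof=1, keepdims=True)
        vals = base * np.sqrt(np.arange(1, 101))[:, None]
        t = _table(vals, kind="residual")
        out = variance_filter(t, 0.25)
        variances = vals.var(axis=1, ddof=1)
        cutoff = np.quantile(variances, 0.25)
        expected = [f"f{i}" for i in np.flatnonzero(variances >= cutoff)]
        assert out.feature_ids == expected
        assert len(out.feature_ids) in (75, 76)

    def test_quantile_zero_is_identity(self, counts_table):
        assert variance_filter(counts_table, 0.0).feature_ids == counts_table.feature_ids

    def test_tied_variances_all_kept(self):
        t = _table(np.tile([1.0, 2.0, 3.0], (5, 1)), kind="residual")
        assert variance_filter(t, 0.25).shape[0] == 5


class TestTss:
    def test_example_column(self):
        out = tss(_table([[2], [2], [4]]))
        assert np.allclose(out.values().ravel(), [0.25, 0.25, 0.5])

    def test_zero_column_names_sample(self):
        with pytest.raises(ValueError, match="s1"):
            tss(_table([[1, 0], [2, 0]]))

    def test_idempotent(self, counts_table):
        once = tss(counts_table)
        twice = tss(once)
        assert np.allclose(once.values(), twice.values())


class TestClr:
    def test_uniform_column_is_zero(self):
        out = clr(_table([[1], [1], [1], [1]]), pseudocount=0.01)
        assert np.allclose(out.values(), 0.0)

    def test_small_pseudocount_limit(self):
        out = clr(_table([[2], [1], [1]]), pseudocount=1e-12)
        assert np.allclose(out.values().ravel(), [0.462, -0.231, -0.231], atol=1e-3)

    def test_scale_invariance_pre_pseudocount(self):
        a = clr(_table([[3, 30], [5, 50], [7, 70]]), pseudocount=1e-9)
        assert np.allclose(a.values()[:, 0], a.values()[:, 1], atol=1e-6)

    def test_clr_of_tss_equals_clr_of_counts(self, counts_table):
        t = FeatureTable(counts_table.data + 1, "counts")
        direct = clr(t, 1e-6)
        via_tss = clr(tss(t), 1e-6)
        assert np.allclose(direct.values(), via_tss.values())

    def test_nonpositive_pseudocount_rejected(self, counts_table):
        with pytest.raises(ValueError):
            clr(counts_table, pseudocount=0.0)

    def test_columns_sum_to_zero(self, counts_table):
        out = clr(FeatureTable(counts_table.data + 1, "counts"))
        assert np.allclose(out.values().sum(axis=0), 0.0, atol=1e-9)


class TestLogCpm:
    def test_formula_example(self):
        vals = np.zeros((2, 1))
        vals[0, 0] = 1000
        vals[1, 0] = 999_000
        out = log_cpm(_table(vals), prior=1e-9)
        assert np.isclose(out.values()[0, 0], np.log2(1000), atol=1e-3)

    def test_monotone_within_sample(self):
        out = log_cpm(_table([[1], [5], [25]]))
        col = out.values().ravel()
        assert col[0] < col[1] < col[2]

    def test_equal_counts_equal_depths_equal_values(self):
        out = log_cpm(_table([[10, 10], [90, 90]]))
        assert np.allclose(out.values()[:, 0], out.values()[:, 1])


def _f_score_oracle(freq, conc):
    """Independent restatement of the frequency-method score."""
    import scipy.stats
    y, x = np.log10(freq), np.log10(conc)
    m = len(y)
    ss1 = np.sum((y + x - np.mean(y + x)) ** 2)
    ss0 = np.sum((y - np.mean(y)) ** 2)
    return scipy.stats.f.cdf(ss1 / ss0, m - 1, m - 1)


class TestContaminantScoring:
    def _build(self, freqs, conc, depth=100_000):
        counts = np.round(np.asarray(freqs) * depth).astype(int)
        filler = depth - counts
        t = _table(np.vstack([counts, filler]))
        return t, np.asarray(conc, float)

    def test_inverse_frequency_feature_scores_low(self):
        rng = np.random.default_rng(1)
        conc = rng.lognormal(0, 1, 20)
        freq = 0.001 / conc
        t, conc = self._build(freq, conc)
        report = frequency_contaminant_score(t, conc)
        score = report.table.loc["f0", "score"]
        assert score < 0.05
        assert np.isclose(score, _f_score_oracle(freq, conc), atol=1e-6)

    def test_constant_frequency_scores_high(self):
        rng = np.random.default_rng(2)
        conc = rng.lognormal(0, 1, 20)
        freq = np.full(20, 0.001)
        t, conc = self._build(freq, conc)
        report = frequency_contaminant_score(t, conc)
        assert report.table.loc["f0", "score"] > 0.5

    def test_sparse_feature_not_evaluable(self):
        vals = np.zeros((2, 10), dtype=int)
        vals[0, :3] = 5
        vals[1] = 100
        t = _table(vals)
        report = frequency_contaminant_score(t, np.ones(10))
        row = report.table.loc["f0"]
        assert not row["evaluable"] and not row["flagged"]

    def test_synthetic_contaminant_recovery(self):
        config = SynthConfig(
            n_samples_per_region=30, n_regions=2, n_patients=60,
            n_genes=50, n_taxa=80, n_latent_factors=0, n_direct_pairs=0,
            n_contaminants=20, n_negative_controls=0,
            sequencing_depth_mean=30_000, seed=21,
        )
        cohort = generate_cohort(config)
        meta = cohort.samples.data
        report = frequency_contaminant_score(cohort.microbiome, meta["dna_conc"])
        contam = set(cohort.truth.contaminant_ids)
        flagged = set(report.flagged_ids)
        hit = len(flagged & contam) / len(contam)
        evaluable = set(report.table.index[report.table["evaluable"]])
        clean = evaluable - contam
        false = len(flagged & clean) / len(clean)
        assert hit >= 0.9
        assert false <= 0.1
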