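import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from gutlink import FeatureTable, alpha_diversity, beta_distance, rarefy, rarefied_alpha
from gutlink.diversity import read_tree

STAR5 = "((a:1,b:1,c:1,d:1,e:1):0):0;"


def _table(vals):
    vals = np.asarray(vals)
    return FeatureTable(
        pd.DataFrame(vals, index=list("abcde")[: vals.shape[0]],
                     columns=[f"s{j}" for j in range(vals.shape[1])]),
        "counts",
    )


class TestRarefy:
    def test_depth_equal_to_total_is_identity(self, counts_table):
        depth = int(counts_table.values().sum(axis=0).min())
        sub = rarefy(counts_table, depth, seed=0)
        full_col = np.argmin(counts_table.values().sum(axis=0))
        assert sub.values()[:, full_col].sum() == depth

    def test_depth_one_single_read(self):
        t = _table([[5, 3], [5, 7]])
        sub = rarefy(t, 1, seed=1)
        assert (sub.values().sum(axis=0) == 1).all()
        assert ((sub.values() == 1).sum(axis=0) == 1).all()

    def test_insufficient_depth_names_sample(self):
        t = _table([[5, 1], [5, 1]])
        with pytest.raises(ValueError, match="s1"):
            rarefy(t, 5)

    def test_mean_matches_hypergeometric(self):
        # expected rarefied count of a feature is depth * n_i / N
        t = _table([[30], [70]])
        depth = 40
        draws = np.array([rarefy(t, depth, seed=s).values()[0, 0]
                          for s in range(1000)])
        expect = depth * 0.3
        var = depth * 0.3 * 0.7 * (100 - depth) / 99
        se = np.sqrt(var / 1000)
        assert abs(draws.mean() - expect) < 3 * se


class TestAlphaDiversity:
    def test_uniform_shannon_and_simpson(self):
        t = _table([[10], [10], [10], [10]])
        assert np.isclose(alpha_diversity(t, "shannon").iloc[0], np.log(4))
        assert np.isclose(alpha_diversity(t, "simpson").iloc[0], 0.75)

    def test_star_tree_faith_pd(self):
        t = _table([[1], [1], [1], [0], [0]])
        pd_val = alpha_diversity(t, "faith_pd", tree=STAR5).iloc[0]
        assert pd_val == 3.0

    def test_fisher_alpha_matches_bisection_oracle(self):
        # S = alpha * ln(1 + N / alpha) with S=20, N=100
        counts = np.zeros(20, dtype=int)
        counts[:] = 5  # 20 species, 100 reads
        t = FeatureTable(pd.DataFrame(counts[:, None], index=[f"x{i}" for i in range(20)],
                                      columns=["s"]), "counts")
        got = alpha_diversity(t, "fisher_alpha").iloc[0]

        def f(a):
            return a * np.log(1 + 100 / a) - 20

        lo, hi = 1e-6, 1e6
        for _ in range(200):
            mid = (lo + hi) / 2
            if f(mid) < 0:
                lo = mid
            else:
                hi = mid
        assert abs(got - mid) < 1e-6

    def test_missing_tips_listed(self):
        t = _table([[1], [1], [1], [1], [1]])
        with pytest.raises(ValueError, match="missing tips"):
            alpha_diversity(t, "faith_pd", tree="((a:1,b:1):1,(c:1,d:1):1):0;")

    def test_richness_counts_positive_features(self):
        t = _table([[3], [0], [1]])
        assert alpha_diversity(t, "richness").iloc[0] == 2


class TestRarefiedAlpha:
    def test_depth_equals_total_reduces_to_single_draw(self):
        t = _table([[6], [4]])
        res = rarefied_alpha(t, 10, "shannon", n_iter=5, seed=0)
        assert np.isclose(res.values.iloc[0], alpha_diversity(t, "shannon").iloc[0])

    def test_seed_determinism(self):
        t = _table([[30, 10], [20, 40]])
        a = rarefied_alpha(t, 20, "richness", n_iter=3, seed=9)
        b = rarefied_alpha(t, 20, "richness", n_iter=3, seed=9)
        pd.testing.assert_series_equal(a.values, b.values)

    def test_mean_richness_matches_closed_form(self):
        counts = np.array([40, 30, 20, 10])
        t = _table(counts[:, None].repeat(1, axis=1))
        depth, n_iter = 25, 400
        res = rarefied_alpha(t, depth, "richness", n_iter=n_iter, seed=4)
        N = counts.sum()
        expect = sum(1 - comb(N - c, depth) / comb(N, depth) for c in counts)
        # per-iteration variance bounded by sum of inclusion variances
        p_inc = np.array([1 - comb(N - c, depth) / comb(N, depth) for c in counts])
        se = np.sqrt(np.sum(p_inc * (1 - p_inc)) / n_iter)
        assert abs(res.values.iloc[0] - expect) < 3 * se + 1e-9


class TestBetaDistance:
    @pytest.mark.parametrize("metric", ["bray_curtis", "aitchison",
                                        "unweighted_unifrac", "weighted_unifrac"])
    def test_identical_columns_give_zero(self, metric):
        t = _table([[5, 5], [3, 3], [2, 2], [0, 0], [1, 1]])
        dm = beta_distance(t, metric, tree=STAR5)
        assert np.allclose(dm.data, 0.0, atol=1e-9)

    def test_disjoint_supports(self):
        t = _table([[5, 0], [5, 0], [0, 5], [0, 5], [0, 0]])
        bc = beta_distance(t, "bray_curtis")
        uu = beta_distance(t, "unweighted_unifrac", tree=STAR5)
        assert np.isclose(bc[0, 1], 1.0)
        assert np.isclose(uu[0, 1], 1.0)

    def test_two_sample_toy_formulas(self):
        x = np.array([2, 3, 5], dtype=float)
        y = np.array([1, 6, 3], dtype=float)
        t = _table(np.column_stack([x, y]))
        px, py = x / x.sum(), y / y.sum()
        bc_expect = np.abs(px - py).sum() / (px + py).sum()
        bc = beta_distance(t, "bray_curtis")
        assert np.isclose(bc[0, 1], bc_expect, atol=1e-12)

        eps = 1e-6
        lx = np.log(px + eps) - np.log(px + eps).mean()
        ly = np.log(py + eps) - np.log(py + eps).mean()
        ait = beta_distance(t, "aitchison")
        assert np.isclose(ait[0, 1], np.linalg.norm(lx - ly), atol=1e-12)

    def test_weighted_unifrac_star_tree_formula(self):
        # star tree with unit branches: normalized weighted UniFrac reduces
        # to sum |p_i - q_i| / sum (p_i + q_i)
        x = np.array([2, 3, 5, 0, 0], dtype=float)
        y = np.array([1, 6, 3, 0, 0], dtype=float)
        t = _table(np.column_stack([x, y]))
        p, q = x / x.sum(), y / y.sum()
        expect = np.abs(p - q).sum() / (p + q).sum()
        wu = beta_distance(t, "weighted_unifrac", tree=STAR5)
        assert np.isclose(wu[0, 1], expect, atol=1e-12)

    def test_unifrac_requires_tree(self):
        t = _table([[1, 2], [3, 4]])
        with pytest.raises(ValueError, match="tree"):
            beta_distance(t, "weighted_unifrac")

    def test_symmetry_and_bounds(self, counts_table):
        inner = ",".join(f"{i}:1" for i in counts_table.feature_ids)
        tree = read_tree(f"(({inner}):0.5):0;")
        for metric in ("bray_curtis", "unweighted_unifrac", "weighted_unifrac"):
            dm = beta_distance(FeatureTable(counts_table.data + 1, "counts"),
                               metric, tree=tree)
            assert np.allclose(dm.data, dm.data.T)
            assert (dm.data >= -1e-12).all() and (dm.data <= 1 + 1e-12).all()
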