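import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from castemeth import integration_stats as istats


class TestExpressionByMethBin:
    def _frames(self, values_by_bin):
        genes, bins, fpkm = [], [], []
        i = 0
        for b, vals in values_by_bin.items():
            for v in vals:
                genes.append(f"g{i}")
                bins.append(b)
                fpkm.append(v)
                i += 1
        bin_df = pd.DataFrame({"gene_id": genes, "bin": bins})
        expr_df = pd.DataFrame({"gene_id": genes, "fpkm": fpkm})
        return bin_df, expr_df

    def test_identical_expression_gives_h_zero(self):
        bin_df, expr_df = self._frames({"none": [5, 5, 5], "low": [5, 5, 5]})
        out = istats.expression_by_meth_bin(bin_df, expr_df)
        assert out["H"] == 0.0

    def test_h_matches_rank_based_closed_form(self):
        # log-expression groups {1,2,3} and {10,11,12}: ranks 1-3 vs 4-6,
        # H = 12/(N(N+1)) * sum(R^2/n) - 3(N+1) = 3.857...
        vals_a = np.exp([1, 2, 3]) - istats.FPKM_LOG_OFFSET
        vals_b = np.exp([10, 11, 12]) - istats.FPKM_LOG_OFFSET
        bin_df, expr_df = self._frames({"low": vals_a, "high": vals_b})
        out = istats.expression_by_meth_bin(bin_df, expr_df)
        h_oracle = 12 / (6 * 7) * (6**2 / 3 + 15**2 / 3) - 3 * 7
        assert out["H"] == pytest.approx(h_oracle, rel=1e-9)
        # the extreme pair's Dunn contrast is the only one, with |z| > 0
        assert len(out["pairwise"]) == 1
        assert abs(out["pairwise"]["z"].iloc[0]) > 0

    def test_suppressed_bin_has_lower_mean(self):
        rng = np.random.default_rng(0)
        bin_df, expr_df = self._frames(
            {"none": rng.lognormal(3, 0.3, 200), "low": rng.lognormal(1, 0.3, 200)}
        )
        out = istats.expression_by_meth_bin(bin_df, expr_df)
        s = out["summaries"].set_index("bin")["mean"]
        assert s["low"] < s["none"]
        assert out["p"] < 0.01

    def test_small_bin_excluded_with_warning(self):
        bin_df, expr_df = self._frames(
            {"none": [1, 2, 3], "low": [4, 5, 6], "high": [9]}
        )
        with pytest.warns(UserWarning, match="excluding"):
            out = istats.expression_by_meth_bin(bin_df, expr_df)
        assert set(out["summaries"]["bin"]) == {"none", "low"}


class TestMethExpressionModel:
    def _data(self, w_slope=2.0, caste_shift=0.0, seed=0, n_genes=2000):
        rng = np.random.default_rng(seed)
        rows = []
        w = rng.uniform(0, 1, n_genes)
        for colony in ("C1", "C2", "C3"):
            colony_eff = rng.normal(0, 0.2)
            for caste in ("reproductive", "sterile"):
                noise = rng.normal(0, 1.0, n_genes)
                expr = (
                    1.0 + w_slope * w + colony_eff + noise
                    + (caste_shift if caste == "reproductive" else 0.0)
                )
                rows.append(
                    pd.DataFrame(
                        {
                            "log_expr": expr, "W": w, "caste": caste,
                            "colony": colony,
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)

    def test_constant_w_flagged_inestimable(self):
        data = self._data()
        data["W"] = 0.5
        out = istats.meth_expression_model(data)
        assert out.loc[0, "method"] == "inestimable"

    def test_w_slope_detected_caste_null_retained(self):
        out = istats.meth_expression_model(self._data(w_slope=2.0, caste_shift=0.0))
        terms = out.set_index("term")
        w_p = terms.loc["W", "p"]
        caste_p = [p for t, p in terms["p"].items() if "caste" in t.lower()]
        assert w_p < 0.01
        assert min(caste_p) > 0.05

    def test_permuted_caste_labels_mostly_null(self):
        rng = np.random.default_rng(1)
        n_sig = 0
        for i in range(20):
            data = self._data(w_slope=1.0, seed=i, n_genes=300)
            data["caste"] = rng.permutation(data["caste"].to_numpy())
            out = istats.meth_expression_model(data).set_index("term")
            caste_p = min(
                p for t, p in out["p"].items()
                if "caste" in t.lower() and ":" not in t
            )
            n_sig += caste_p < 0.05
        assert n_sig <= 2


class TestGroupMethylationContrast:
    def _data(self, group_shift=0.0, seed=0, n=500):
        rng = np.random.default_rng(seed)
        rows = []
        for group in (True, False):
            for caste in ("reproductive", "sterile"):
                w = rng.beta(2, 8, n) + (group_shift if group else 0.0)
                rows.append(pd.DataFrame({"W": w, "group": group, "caste": caste}))
        return pd.concat(rows, ignore_index=True)

    def test_identical_w_distributions_give_zero_group_f(self):
        # both groups carry literally the same W values: group SS is 0
        rng = np.random.default_rng(7)
        w = rng.beta(2, 8, 400)
        rows = []
        for group in (True, False):
            for caste in ("reproductive", "sterile"):
                rows.append(pd.DataFrame({"W": w, "group": group, "caste": caste}))
        data = pd.concat(rows, ignore_index=True)
        out = istats.group_methylation_contrast(data).set_index("comparison")
        assert out.loc["group_effect", "F"] == pytest.approx(0.0, abs=1e-9)
        assert out.loc["group_effect", "p"] > 0.999

    def test_shifted_group_detected_caste_not(self):
        out = istats.group_methylation_contrast(self._data(-0.05)).set_index("comparison")
        assert out.loc["group_effect", "p"] < 1e-6
        assert out.loc["caste_effect", "p"] > 0.05

    def test_f_statistics_match_residual_algebra(self):
        # 30-unit toy: F = ((RSS_r - RSS_f)/ddf) / (RSS_f/df_f) from raw residuals
        rng = np.random.default_rng(2)
        data = pd.DataFrame(
            {
                "W": rng.random(30),
                "group": rng.integers(0, 2, 30).astype(bool),
                "caste": rng.choice(["reproductive", "sterile"], 30),
            }
        )
        out = istats.group_methylation_contrast(data).set_index("comparison")

        def rss(design_cols):
            x = np.column_stack([np.ones(30)] + design_cols)
            y = data["W"].to_numpy()
            beta, *_ = np.linalg.lstsq(x, y, rcond=None)
            return ((y - x @ beta) ** 2).sum()

        g = data["group"].to_numpy().astype(float)
        c = (data["caste"] == "sterile").to_numpy().astype(float)
        rss_full = rss([g, c, g * c])
        rss_main = rss([g, c])
        f_int = ((rss_main - rss_full) / 1) / (rss_full / (30 - 4))
        assert out.loc["interaction_vs_main", "F"] == pytest.approx(f_int, rel=1e-9)
        rss_nogroup = rss([c])
        f_group = ((rss_nogroup - rss_main) / 1) / (rss_main / (30 - 3))
        assert out.loc["group_effect", "F"] == pytest.approx(f_group, rel=1e-9)


class TestOverlapTest:
    def test_disjoint_singletons_give_p_one(self):
        res = istats.overlap_test({"a"}, {"b"}, {"a", "b"})
        assert res.overlap == 0
        assert res.p == 1.0

    def test_full_overlap_exact_probability(self):
        universe = set(range(6))
        a = {0, 1, 2}
        res = istats.overlap_test(a, a, universe)
        assert res.p == pytest.approx(1 / comb(6, 3), rel=1e-12)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(3)
        universe = list(range(20))
        for _ in range(10):
            a = set(rng.choice(universe, size=rng.integers(1, 8), replace=False).tolist())
            b_size = int(rng.integers(1, 8))
            b = set(rng.choice(universe, size=b_size, replace=False).tolist())
            res = istats.overlap_test(a, b, universe)
            k = len(a & b)
            hits = sum(
                1 for draw in itertools.combinations(universe, b_size)
                if len(a & set(draw)) >= k
            )
            assert res.p == pytest.approx(hits / comb(20, b_size), rel=1e-9)

    def test_non_subset_rejected(self):
        with pytest.raises(ValueError):
            istats.overlap_test({"x"}, {"a"}, {"a", "b"})


class TestDmDeRelationship:
    def test_collinear_toy_r2_one(self):
        dw = np.linspace(0.1, 0.9, 10)
        out = istats.dm_de_relationship(dw, 2 * dw)
        assert out["r2"] == pytest.approx(1.0)
        assert out["slope"] == pytest.approx(2.0)

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(4)
        n_sig = 0
        for _ in range(100):
            out = istats.dm_de_relationship(rng.random(50), rng.normal(size=50))
            n_sig += out["p"] < 0.05
        assert 1 <= n_sig <= 10

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            istats.dm_de_relationship([0.1, 0.2], [1.0, 2.0])


class TestSamplePca:
    def test_identical_samples_identical_coordinates(self):
        m = pd.DataFrame(
            [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [4.0, 0.0, 1.0]],
            index=["a", "b", "c"],
        )
        out = istats.sample_pca(m)
        coords = out["coordinates"]
        np.testing.assert_allclose(coords.loc["a"], coords.loc["b"], atol=1e-12)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(rng.normal(size=(6, 40)))
        out = istats.sample_pca(m, n_components=3)
        v = out["loadings"].to_numpy()
        np.testing.assert_allclose(v.T @ v, np.eye(3), atol=1e-10)

    def test_colony_structure_dominates_when_sigma_large(self):
        from castemeth import synthetic_data as sd

        cfg = sd.SimConfig(
            n_sites=3000, n_genes=60, frac_methylated_sites=0.1, n_dm_sites=0,
            n_dm_genes=0, dm_effect=0.0, colony_sd=0.8, seed=9,
        )
        sim = sd.simulate_wgbs(cfg)
        mat = pd.DataFrame(
            {
                s: t["n_meth"] / t["n_total"].clip(lower=1)
                for s, t in sim.samples.items()
            }
        ).T
        out = istats.sample_pca(mat, n_components=2)
        meta = sim.metadata.set_index("sample_id")
        coords = out["coordinates"]
        sil_colony = istats.silhouette_by_label(
            coords, meta.loc[coords.index, "colony"]
        )
        sil_caste = istats.silhouette_by_label(
            coords, meta.loc[coords.index, "caste"]
        )
        assert sil_colony > sil_caste
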