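import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from castemeth import diff_methylation as dmod
from conftest import make_counts

META6 = pd.DataFrame(
    {
        "sample_id": [f"C{i}_{c}" for i in (1, 2, 3) for c in ("r", "s")],
        "caste": ["reproductive", "sterile"] * 3,
        "colony": [f"C{i}" for i in (1, 2, 3) for _ in range(2)],
    }
)


def tables_from_matrix(k, n):
    """k, n: arrays (n_sites, 6) -> per-sample count tables."""
    out = {}
    for j, sample in enumerate(META6["sample_id"]):
        out[sample] = make_counts(
            "chr1", np.arange(1, k.shape[0] + 1), k[:, j], n[:, j]
        )
    return out


def statsmodels_lrt(k_row, n_row, meta):
    """Independent maximum-likelihood oracle for the caste LRT."""
    x_full, x_red = dmod._design_matrices(meta)
    endog = np.column_stack([k_row, n_row - k_row])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = sm.GLM(endog, x_full, family=sm.families.Binomial()).fit()
        red = sm.GLM(endog, x_red, family=sm.families.Binomial()).fit()
    lrt = max(2 * (full.llf - red.llf), 0.0)
    return stats.chi2.sf(lrt, 1)


class TestDmSites:
    def test_identical_castes_not_dm(self):
        k = np.tile([[5, 5, 5, 5, 5, 5]], (3, 1))
        n = np.full((3, 6), 20)
        res = dmod.dm_sites(tables_from_matrix(k, n), META6)
        assert (res["meth_diff"] == 0).all()
        assert not res["is_dm"].any()

    def test_strong_effect_detected_and_p_matches_independent_mle(self):
        k = np.array([[18, 2, 17, 3, 19, 1], [10, 9, 11, 10, 9, 11]])
        n = np.full((2, 6), 20)
        res = dmod.dm_sites(tables_from_matrix(k, n), META6)
        strong = res.set_index("pos").loc[1]
        assert strong["is_dm"]
        assert strong["meth_diff"] == pytest.approx((18 + 17 + 19) / 60 - 6 / 60)
        for i in range(2):
            p_oracle = statsmodels_lrt(k[i], n[i], META6)
            assert res.set_index("pos").loc[i + 1, "p"] == pytest.approx(
                p_oracle, abs=1e-6
            )

    def test_lrt_matches_statsmodels_on_random_toys(self):
        rng = np.random.default_rng(9)
        n = rng.integers(10, 40, size=(30, 6))
        k = rng.binomial(n, rng.uniform(0.1, 0.9, size=(30, 1)))
        res = dmod.dm_sites(tables_from_matrix(k, n), META6)
        res = res.set_index("pos")
        for i in range(30):
            if res.loc[i + 1, "degenerate"]:
                continue
            assert res.loc[i + 1, "p"] == pytest.approx(
                statsmodels_lrt(k[i], n[i], META6), abs=1e-6
            )

    def test_caste_label_swap_flips_sign_only(self):
        rng = np.random.default_rng(10)
        n = rng.integers(10, 40, size=(20, 6))
        k = rng.binomial(n, 0.5)
        res = dmod.dm_sites(tables_from_matrix(k, n), META6)
        swapped_meta = META6.copy()
        swapped_meta["caste"] = swapped_meta["caste"].map(
            {"reproductive": "sterile", "sterile": "reproductive"}
        )
        res_swapped = dmod.dm_sites(tables_from_matrix(k, n), swapped_meta)
        np.testing.assert_allclose(
            res["meth_diff"], -res_swapped["meth_diff"], atol=1e-12
        )
        np.testing.assert_allclose(res["p"], res_swapped["p"], atol=1e-9)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(11)
        n = rng.integers(10, 40, size=(10, 6))
        k = rng.binomial(n, 0.4)
        tables = tables_from_matrix(k, n)
        res1 = dmod.dm_sites(tables, META6)
        perm = META6.iloc[[3, 0, 5, 2, 1, 4]].reset_index(drop=True)
        res2 = dmod.dm_sites(tables, perm)
        np.testing.assert_allclose(res1["p"], res2["p"], atol=1e-9)
        np.testing.assert_allclose(res1["meth_diff"], res2["meth_diff"], atol=1e-12)

    def test_is_dm_rule(self):
        rng = np.random.default_rng(12)
        n = rng.integers(10, 40, size=(50, 6))
        k = rng.binomial(n, rng.uniform(0, 1, size=(50, 1)))
        res = dmod.dm_sites(tables_from_matrix(k, n), META6, alpha=0.05, min_diff=0.10)
        expected = (res["q"] < 0.05) & (res["meth_diff"].abs() >= 0.10)
        assert (res["is_dm"] == expected).all()

    def test_bh_q_monotone_in_p_rank(self):
        rng = np.random.default_rng(13)
        n = rng.integers(10, 40, size=(50, 6))
        k = rng.binomial(n, rng.uniform(0, 1, size=(50, 1)))
        res = dmod.dm_sites(tables_from_matrix(k, n), META6)
        ordered = res.sort_values("p")
        assert (np.diff(ordered["q"]) >= -1e-12).all()

    def test_caste_separation_flagged(self):
        # all methylated reads in one caste: chi2 approximation invalid
        k = np.array([[2, 0, 1, 0, 2, 0]])
        n = np.full((1, 6), 20)
        res = dmod.dm_sites(tables_from_matrix(k, n), META6)
        assert res.loc[0, "degenerate"]
        assert res.loc[0, "p"] == 1.0

    def test_requires_two_samples_per_caste(self):
        meta = META6.iloc[:3]
        k = np.full((2, 3), 5)
        n = np.full((2, 3), 20)
        tables = {
            s: make_counts("chr1", [1, 2], k[:, j], n[:, j])
            for j, s in enumerate(meta["sample_id"])
        }
        with pytest.raises(ValueError):
            dmod.dm_sites(tables, meta)


class TestDmGenes:
    def _caste_w(self, w_r, w_s):
        return pd.DataFrame(
            {
                "gene_id": ["g1", "g1"],
                "caste": ["reproductive", "sterile"],
                "W": [w_r, w_s],
            }
        )

    def _site_res(self, is_dm):
        return pd.DataFrame(
            {
                "chrom": ["chr1"],
                "pos": [10],
                "strand": ["+"],
                "meth_diff": [0.2],
                "p": [0.001],
                "q": [0.01],
                "is_dm": [is_dm],
                "degenerate": [False],
            }
        )

    GENE_MAP = pd.DataFrame({"chrom": ["chr1"], "pos": [10], "gene_id": ["g1"]})

    def test_dm_cpg_but_small_delta_w_not_dm_gene(self):
        res = dmod.dm_genes(self._site_res(True), self.GENE_MAP, self._caste_w(0.30, 0.25))
        assert not res.loc[0, "is_dm_gene"]

    def test_large_delta_w_but_no_dm_cpg_not_dm_gene(self):
        res = dmod.dm_genes(self._site_res(False), self.GENE_MAP, self._caste_w(0.8, 0.3))
        assert not res.loc[0, "is_dm_gene"]

    def test_both_criteria_met_is_dm_gene_with_direction(self):
        res = dmod.dm_genes(self._site_res(True), self.GENE_MAP, self._caste_w(0.8, 0.3))
        assert res.loc[0, "is_dm_gene"]
        assert res.loc[0, "hyper_in"] == "reproductive"


class TestDirectionTest:
    @pytest.mark.parametrize(
        "a,b,expected_chi2",
        [(63, 48, 2.027), (50, 50, 0.0), (33, 50, 3.4819), (172, 162, 0.2994)],
    )
    def test_chi2_values(self, a, b, expected_chi2):
        chi2, df, p = dmod.direction_test(a, b)
        assert df == 1
        assert chi2 == pytest.approx(expected_chi2, abs=5e-5)

    def test_p_value_for_dm_gene_counts(self):
        _, _, p = dmod.direction_test(63, 48)
        assert p == pytest.approx(0.1545, abs=1e-4)

    def test_both_zero_is_error(self):
        with pytest.raises(ValueError):
            dmod.direction_test(0, 0)


class TestPermutationNull:
    def _data(self):
        rng = np.random.default_rng(14)
        n = rng.integers(12, 30, size=(40, 6))
        k = rng.binomial(n, rng.uniform(0.2, 0.8, size=(40, 1)))
        return tables_from_matrix(k, n)

    def test_zero_permutations_empty_distribution(self):
        with pytest.warns(UserWarning, match="not a calibrated test"):
            null = dmod.permutation_null(self._data(), META6, n_perm=0, seed=0)
        assert len(null.counts) == 0

    def test_enumeration_mode_covers_all_balanced_labelings(self):
        with pytest.warns(UserWarning):
            null = dmod.permutation_null(
                self._data(), META6, enumerate_distinct=True
            )
        assert null.labelings == 20  # C(6,3)
        # the observed labeling is one of the enumerated ones
        assert null.observed in null.counts

    def test_fixed_seed_reproducible(self):
        with pytest.warns(UserWarning):
            a = dmod.permutation_null(self._data(), META6, n_perm=15, seed=3)
        with pytest.warns(UserWarning):
            b = dmod.permutation_null(self._data(), META6, n_perm=15, seed=3)
        np.testing.assert_array_equal(a.counts, b.counts)
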