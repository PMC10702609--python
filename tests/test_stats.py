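import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import _oracles as orc
import strucnet as sn
from strucnet.stats import (StatsConfig, compare_network_params,
                            compare_roi_params, enumerate_and_filter_pairs,
                            split_hemispheres)

p_vectors = st.lists(st.floats(min_value=0.0, max_value=1.0,
                               allow_nan=False), min_size=1, max_size=40)


class TestLogTransform:
    def test_known_values(self):
        assert sn.log_pseudocount_transform(0.0) == pytest.approx(0.0)
        assert sn.log_pseudocount_transform(np.e - 1.0) == pytest.approx(1.0)

    def test_vector_matches_elementwise_oracle(self):
        x = np.array([0.0, 9.0, 99.0])
        assert np.allclose(sn.log_pseudocount_transform(x),
                           [np.log(v + 1.0) for v in x])

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            sn.log_pseudocount_transform([-1.0])

    def test_base_choice_does_not_change_t(self):
        """Affine invariance: any log base yields the same t statistic."""
        rng = np.random.default_rng(0)
        a, b = rng.poisson(40, 9), rng.poisson(50, 10)
        t_nat = sn.pooled_t_test(np.log(a + 1.0), np.log(b + 1.0)).t
        t_ten = sn.pooled_t_test(np.log10(a + 1.0), np.log10(b + 1.0)).t
        assert t_nat == pytest.approx(t_ten, rel=1e-12)


class TestPooledT:
    def test_study_degrees_of_freedom(self):
        rng = np.random.default_rng(1)
        res = sn.pooled_t_test(rng.normal(size=9), rng.normal(size=10))
        assert res.df == 17

    def test_identical_groups(self):
        res = sn.pooled_t_test([1, 2, 3], [1, 2, 3])
        assert res.t == 0.0 and res.p == 1.0 and not res.degenerate

    def test_closed_form_example(self):
        res = sn.pooled_t_test([1, 2, 3], [2, 3, 4])
        assert res.t == pytest.approx(-np.sqrt(1.5), rel=1e-12)  # −1.2247
        assert res.df == 4
        assert res.p == pytest.approx(2 * sps.t.sf(np.sqrt(1.5), 4), rel=1e-12)
        assert res.p == pytest.approx(0.288, abs=5e-4)

    def test_degenerate_zero_variance_unequal_means(self):
        res = sn.pooled_t_test([1.0, 1.0], [2.0, 2.0])
        assert res.p == 0.0 and res.degenerate

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            sn.pooled_t_test([1.0], [1.0, 2.0])

    def test_matches_scipy_on_regular_data(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=9), rng.normal(0.5, 1, size=10)
        res = sn.pooled_t_test(a, b)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert res.t == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-12)


class TestBH:
    def test_single_p_unchanged(self):
        adj, rej = sn.bh_adjust([0.03], 0.05)
        assert adj[0] == pytest.approx(0.03) and rej[0]

    def test_all_ones(self):
        adj, rej = sn.bh_adjust(np.ones(5), 0.05)
        assert np.all(adj == 1.0) and not rej.any()

    def test_stepup_enumeration_example(self):
        adj, _ = sn.bh_adjust([0.01, 0.02, 0.03, 0.04], 0.05)
        assert np.allclose(adj, 0.04)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            sn.bh_adjust([0.5, 1.2], 0.05)

    @given(p_vectors)
    @settings(max_examples=150, deadline=None)
    def test_matches_literal_oracle_and_monotonicity(self, p):
        p = np.array(p)
        adj, rej = sn.bh_adjust(p, 0.05)
        assert np.allclose(adj, orc.oracle_bh_adjusted(p), atol=1e-12)
        assert np.array_equal(rej, orc.oracle_bh(p, 0.05))
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(adj[order]) >= -1e-15)

    @given(p_vectors, st.randoms(use_true_random=False))
    @settings(max_examples=50, deadline=None)
    def test_rejection_set_order_invariant(self, p, rnd):
        p = np.array(p)
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        _, rej = sn.bh_adjust(p, 0.05)
        _, rej_p = sn.bh_adjust(p[perm], 0.05)
        assert np.array_equal(rej[perm], rej_p)


class TestBKY:
    def test_all_ones_rejects_nothing(self):
        res = sn.bky_two_stage(np.ones(6), 0.05)
        assert not res.reject.any() and res.stage1_rejections == 0

    def test_all_tiny_rejects_all_via_m0_zero(self):
        res = sn.bky_two_stage(np.full(5, 1e-6), 0.05)
        assert res.reject.all() and res.m0 == 0

    def test_two_stage_example(self):
        # stage 1 at q' = 0.05/1.05 rejects 3 → m0 = 1 → stage 2 at 4q'
        res = sn.bky_two_stage([0.001, 0.01, 0.02, 0.8], 0.05)
        assert list(res.reject) == [True, True, True, False]
        assert res.m0 == 1 and res.stage1_rejections == 3

    @given(p_vectors)
    @settings(max_examples=150, deadline=None)
    def test_matches_literal_two_stage_oracle(self, p):
        p = np.array(p)
        assert np.array_equal(sn.bky_two_stage(p, 0.05).reject,
                              orc.oracle_bky(p, 0.05))

    @given(p_vectors)
    @settings(max_examples=100, deadline=None)
    def test_bky_dominates_bh_when_stage1_rejects(self, p):
        p = np.array(p)
        res = sn.bky_two_stage(p, 0.05)
        _, bh = sn.bh_adjust(p, 0.05)
        if res.stage1_rejections >= 1:
            assert np.all(res.reject | ~bh)  # BKY ⊇ BH

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(4)
        for _ in range(100):
            m = int(rng.integers(1, 40))
            p = np.concatenate([rng.uniform(0, 1, m // 2),
                                rng.uniform(0, 0.03, m - m // 2)])
            assert np.array_equal(sn.bky_two_stage(p, 0.05).reject,
                                  multipletests(p, 0.05, "fdr_tsbky")[0])
            adj, rej = sn.bh_adjust(p, 0.05)
            smr, smadj = multipletests(p, 0.05, "fdr_bh")[:2]
            assert np.allclose(adj, smadj) and np.array_equal(rej, smr)


class TestPairFilter:
    def test_pair_count_for_36_regions(self, atlas):
        from strucnet.connectome import scope_pairs
        assert len(scope_pairs("ipsi-L", atlas)) == 630

    def test_zero_fraction_boundary(self):
        # 10 zeros of 19 (52.6%) excluded; exactly half of 10 included
        c19 = np.zeros((19, 1))
        c19[:9, 0] = 5.0
        assert not enumerate_and_filter_pairs(c19)["included"][0]
        c10 = np.zeros((10, 1))
        c10[:5, 0] = 5.0
        assert enumerate_and_filter_pairs(c10)["included"][0]


class TestEdgewise:
    def test_df_constant_and_excluded_pairs_missing(self, default_cohort, atlas):
        res = sn.edgewise_compare(default_cohort, "ipsi-L", atlas)
        tab = res.table
        assert (tab["df"] == 17).all()
        excl = tab[~tab["included"]]
        assert excl["p"].isna().all() and excl["p_adj"].isna().all()
        inc = tab[tab["included"]]
        assert (inc["p_adj"] >= inc["p"] - 1e-12).all()

    def test_signed_matrix_antisymmetric_under_group_swap(self, default_cohort,
                                                          atlas):
        swapped = [sn.SubjectConnectome(s.subject_id,
                                        "KO" if s.group == "WT" else "WT",
                                        s.counts)
                   for s in default_cohort]
        a = sn.edgewise_compare(default_cohort, "ipsi-L", atlas).signed_p
        b = sn.edgewise_compare(swapped, "ipsi-L", atlas).signed_p
        av, bv = a.to_numpy(), b.to_numpy()
        mask = ~np.isnan(av)
        assert np.array_equal(mask, ~np.isnan(bv))
        assert np.allclose(av[mask], -bv[mask])

    def test_all_zero_cohort_tests_nothing(self, atlas):
        zeros = np.zeros((72, 72), dtype=int)
        subs = ([sn.SubjectConnectome(f"w{i}", "WT", zeros) for i in range(2)]
                + [sn.SubjectConnectome(f"k{i}", "KO", zeros) for i in range(2)])
        res = sn.edgewise_compare(subs, "ipsi-L", atlas)
        assert not res.table["included"].any()
        assert res.signed_p.isna().all().all()

    def test_contralateral_signed_matrix_is_cross_block(self, default_cohort,
                                                        atlas):
        res = sn.edgewise_compare(default_cohort, "contra-L", atlas)
        assert res.signed_p.shape == (36, 36)
        assert res.signed_p.index[0] == "CC" and res.signed_p.columns[0] == "RCC"

    def test_one_group_missing_rejected(self, atlas):
        zeros = np.zeros((72, 72), dtype=int)
        subs = [sn.SubjectConnectome(f"w{i}", "WT", zeros) for i in range(4)]
        with pytest.raises(ValueError, match="2 subjects per group"):
            sn.edgewise_compare(subs, "ipsi-L", atlas)


class TestCompareNetworkParams:
    def make_tidy(self, wt, ko, metric="global_efficiency"):
        rows = [{"group": "WT", "metric": metric, "value": v} for v in wt]
        rows += [{"group": "KO", "metric": metric, "value": v} for v in ko]
        return pd.DataFrame(rows)

    def test_identical_groups_not_significant(self):
        res = compare_network_params(self.make_tidy([1, 2, 3], [1, 2, 3]))
        row = res.iloc[0]
        assert row["t"] == 0.0 and row["p"] == 1.0 and not row["significant"]

    def test_matches_pooled_t_component(self):
        wt = [0.021, 0.025, 0.018, 0.022, 0.020]
        ko = [0.015, 0.017, 0.013, 0.016, 0.014]
        res = compare_network_params(self.make_tidy(wt, ko))
        ref = sn.pooled_t_test(wt, ko)
        row = res.iloc[0]
        assert row["t"] == pytest.approx(ref.t) and row["p"] == pytest.approx(ref.p)
        assert row["df"] == 8
        assert row["wt_summary"].startswith("0.021")

    def test_power_matches_noncentral_t_prediction(self):
        """Monte-Carlo power at a 1.5-pooled-SD shift agrees with the
        analytic two-sample noncentral-t power at n = 9/10."""
        rng = np.random.default_rng(10)
        n1, n2, shift, n_rep = 9, 10, 1.5, 400
        rejections = 0
        for _ in range(n_rep):
            res = sn.pooled_t_test(rng.normal(0, 1, n1), rng.normal(shift, 1, n2))
            rejections += res.p < 0.05
        rate = rejections / n_rep
        delta = shift / np.sqrt(1 / n1 + 1 / n2)
        crit = sps.t.ppf(0.975, n1 + n2 - 2)
        power = (sps.nct.sf(crit, n1 + n2 - 2, delta)
                 + sps.nct.cdf(-crit, n1 + n2 - 2, delta))
        assert rate == pytest.approx(power, abs=2.5 * np.sqrt(power * (1 - power) / n_rep))

    def test_missing_values_warn_and_drop(self):
        tidy = self.make_tidy([1.0, 2.0, np.nan, 3.0], [2.0, 3.0, 4.0])
        with pytest.warns(UserWarning, match="missing"):
            res = compare_network_params(tidy)
        assert res.iloc[0]["n_wt"] == 3


class TestCompareRoiParams:
    def test_identical_tables_all_null(self, atlas):
        tbl = sn.generate_diffusion_table(sn.CohortConfig(rng_seed=3))
        wt = tbl[tbl.group == "WT"]
        res = compare_roi_params(wt, wt.copy())
        assert np.allclose(res["p"], 1.0)
        assert not res["reject"].any()

    def test_spiked_roi_recovered(self, atlas):
        tbl = sn.generate_diffusion_table(sn.CohortConfig(rng_seed=3))
        wt = tbl[tbl.group == "WT"].copy()
        ko = tbl[tbl.group == "KO"].copy()
        ko.loc[ko["roi"] == "CA1", "FA"] += 0.15
        res = compare_roi_params(wt, ko)
        fa = res[res["metric"] == "FA"].set_index("roi")
        assert bool(fa.loc["CA1", "reject"])

    def test_roi_set_mismatch_rejected(self, atlas):
        tbl = sn.generate_diffusion_table(sn.CohortConfig(rng_seed=3))
        wt = tbl[tbl.group == "WT"]
        ko = tbl[(tbl.group == "KO") & (tbl.roi != "CC")]
        with pytest.raises(ValueError, match="ROI sets"):
            compare_roi_params(wt, ko)

    def test_split_hemispheres_rekeys_right_rois(self, atlas):
        tbl = sn.generate_diffusion_table(sn.CohortConfig(rng_seed=3))
        left, right = split_hemispheres(tbl, atlas)
        assert set(left["roi"]) == set(right["roi"])
        assert all(atlas.hemisphere_of(r) == "L" for r in left["roi"].unique())
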