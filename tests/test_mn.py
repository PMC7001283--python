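"""Micronucleus / relative-survival statistics: closed forms, calibration."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_wells
from genotox import delta_method_backtransform, exclude_cytotoxic, \
    fit_gee_binomial_log, fit_gee_normal_identity, mn_call, mn_frequency, \
    relative_survival, select_concentrations
from oracles import pair_spacing_search


def rs_wells(vehicle_ratios, treated):
    """Flow wells with chosen nuclei/bead ratios (beads fixed at 1000)."""
    rows = []
    for rep, r in enumerate(vehicle_ratios, 1):
        rows.append(dict(chemical="X", concentration_index=0, replicate=rep,
                         scored_cells=20000, mn_events=0,
                         nuclei_count=int(r * 1000), bead_count=1000,
                         is_vehicle=True))
    for conc, ratios in treated.items():
        for rep, r in enumerate(ratios, 1):
            rows.append(dict(chemical="X", concentration_index=conc,
                             replicate=rep, scored_cells=20000, mn_events=0,
                             nuclei_count=int(r * 1000), bead_count=1000,
                             is_vehicle=False))
    return pd.DataFrame(rows)


def simulate_mn_wells(rng, fold, n_wells=2, cells=20000, baseline=0.006):
    rows = []
    for conc, rate in ((0, baseline), (1, baseline * fold)):
        for rep in range(n_wells):
            n = int(rng.normal(cells, cells / 30))
            rows.append(dict(chemical="X", concentration_index=conc,
                             replicate=rep + 1, scored_cells=n,
                             mn_events=int(rng.binomial(n, rate)),
                             nuclei_count=10000, bead_count=5000,
                             is_vehicle=conc == 0))
    return pd.DataFrame(rows)


class TestSimpleEndpoints:
    @pytest.mark.parametrize("events,cells,expected", [
        (120, 20000, 0.6),
        (0, 15000, 0.0),
        (155, 19876, 100 * 155 / 19876),
    ])
    def test_mn_frequency(self, events, cells, expected):
        assert mn_frequency(events, cells) == pytest.approx(expected)

    def test_mn_frequency_rejects_empty_well(self):
        with pytest.raises(ValueError):
            mn_frequency(0, 0)

    def test_relative_survival_arithmetic(self):
        wells = rs_wells([1.5, 1.5], {1: [1.2, 1.2]})
        assert relative_survival(wells)[1] == pytest.approx(80.0)

    def test_relative_survival_identity(self):
        wells = rs_wells([2.0, 2.0], {1: [2.0, 2.0]})
        assert relative_survival(wells)[1] == pytest.approx(100.0)

    def test_relative_survival_mean_of_ratios(self):
        wells = rs_wells([2.0, 2.0], {1: [1.0, 1.4]})
        assert relative_survival(wells)[1] == pytest.approx(60.0)

    def test_missing_vehicle_errors(self):
        wells = rs_wells([2.0], {1: [1.0]})
        with pytest.raises(ValueError, match="vehicle"):
            relative_survival(wells[~wells["is_vehicle"]])


class TestBinomialLogGEE:
    def test_saturated_fit_gives_pooled_proportions(self):
        wells = make_wells([100, 110], {1: [420, 400]})
        fit = fit_gee_binomial_log(wells)
        assert np.exp(fit.params["intercept"]) == pytest.approx(
            210 / 40000, rel=1e-10)
        fold = fit.table.loc[0, "fold"]
        assert fold == pytest.approx(820 / 210, rel=1e-8)

    def test_identical_groups_give_unit_fold(self):
        wells = make_wells([100, 110], {1: [100, 110]})
        fit = fit_gee_binomial_log(wells)
        assert fit.params["conc_1"] == pytest.approx(0.0, abs=1e-10)
        assert fit.table.loc[0, "fold"] == pytest.approx(1.0)

    def test_matches_statsmodels_glm(self):
        """Independent route: GLM binomial log-link with cluster-robust cov."""
        import statsmodels.api as sm

        wells = make_wells([100, 110], {1: [420, 400], 2: [150, 170]})
        fit = fit_gee_binomial_log(wells)

        conc = wells["concentration_index"].to_numpy()
        X = np.column_stack([np.ones(len(wells)), (conc == 1).astype(float),
                             (conc == 2).astype(float)])
        n = wells["scored_cells"].to_numpy(float)
        y = wells["mn_events"].to_numpy(float) / n
        glm = sm.GLM(y, X, family=sm.families.Binomial(
            link=sm.families.links.Log()), var_weights=n).fit()
        assert np.allclose(fit.params.to_numpy(), glm.params, atol=1e-8)
        assert np.allclose(np.sqrt(np.diag(fit.cov_naive)), glm.bse, rtol=1e-5)

    def test_zero_event_group_continuity_adjusted(self):
        wells = make_wells([100, 110], {1: [0, 0]})
        fit = fit_gee_binomial_log(wells)
        assert fit.continuity_adjusted == [1]
        assert np.isfinite(fit.params["conc_1"])
        assert fit.table.loc[0, "fold"] == pytest.approx(
            0.5 / 210, rel=1e-6)

    def test_fold_invariant_to_well_size_scaling(self):
        a = make_wells([(60, 10000), (66, 10000)], {1: [(252, 10000),
                                                        (240, 10000)]})
        b = make_wells([(180, 30000), (198, 30000)], {1: [(756, 30000),
                                                          (720, 30000)]})
        fa = fit_gee_binomial_log(a).table.loc[0, "fold"]
        fb = fit_gee_binomial_log(b).table.loc[0, "fold"]
        assert fa == pytest.approx(fb, rel=1e-10)

    def test_null_rejection_rate_calibrated(self):
        """Model-based Wald test holds its level on binomial-truth nulls."""
        rng = np.random.default_rng(11)
        rejections = 0
        n_rep = 300
        for _ in range(n_rep):
            fit = fit_gee_binomial_log(simulate_mn_wells(rng, fold=1.0))
            p = delta_method_backtransform(fit, se="naive").loc[0, "p_value"]
            rejections += p < 0.01
        assert rejections / n_rep <= 0.025

    def test_null_positive_call_rate_near_zero(self):
        """The twofold gate makes false positive calls essentially impossible."""
        rng = np.random.default_rng(13)
        positives = 0
        n_rep = 300
        for _ in range(n_rep):
            fit = fit_gee_binomial_log(simulate_mn_wells(rng, fold=1.0))
            positives += mn_call(fit).positive
        assert positives / n_rep <= 0.02


class TestNormalIdentityGEE:
    def test_group_means_recovered(self):
        wells = rs_wells([2.0, 2.0], {1: [1.2, 1.24]})
        fit = fit_gee_normal_identity(wells)
        assert fit.params["intercept"] == pytest.approx(100.0)
        assert fit.params["conc_1"] == pytest.approx(61.0 - 100.0)

    def test_identical_groups_give_p_near_one(self):
        wells = rs_wells([2.0, 2.1], {1: [2.0, 2.1]})
        fit = fit_gee_normal_identity(wells)
        assert fit.params["conc_1"] == pytest.approx(0.0, abs=1e-10)
        assert fit.table.loc[0, "p_value"] > 0.99

    def test_matches_statsmodels_ols_cluster(self):
        import statsmodels.api as sm

        wells = rs_wells([2.0, 2.2], {1: [1.5, 1.7], 2: [1.0, 1.1]})
        fit = fit_gee_normal_identity(wells)
        conc = wells["concentration_index"].to_numpy()
        X = np.column_stack([np.ones(len(wells)), (conc == 1).astype(float),
                             (conc == 2).astype(float)])
        ratio = (wells["nuclei_count"] / wells["bead_count"]).to_numpy()
        y = 100.0 * ratio / ratio[conc == 0].mean()
        ols = sm.OLS(y, X).fit()
        assert np.allclose(fit.params.to_numpy(), ols.params, atol=1e-10)

    def test_single_well_rejected(self):
        wells = rs_wells([2.0], {})
        with pytest.raises(ValueError):
            fit_gee_normal_identity(wells)

    def test_null_rejection_rate_within_small_sample_band(self):
        """Naive-covariance RS test: level ~0.05 with duplicate wells."""
        rng = np.random.default_rng(17)
        rejections = 0
        n_rep = 300
        for _ in range(n_rep):
            v = rng.normal(2.0, 0.05, 2)
            t = rng.normal(2.0, 0.05, 2)
            fit = fit_gee_normal_identity(rs_wells(list(v), {1: list(t)}))
            p = delta_method_backtransform(fit, se="naive").loc[0, "p_value"]
            rejections += p < 0.05
        assert 0.01 <= rejections / n_rep <= 0.12


class TestDeltaMethod:
    def test_log_link_formula(self):
        """beta = ln 2, SE 0.1 back-transforms to 2.0 +/- 0.2."""
        eta, se = np.log(2.0), 0.1
        assert np.exp(eta) == pytest.approx(2.0)
        assert np.exp(eta) * se == pytest.approx(0.2)

    def test_identity_passthrough(self):
        wells = rs_wells([2.0, 2.1], {1: [1.5, 1.6]})
        fit = fit_gee_normal_identity(wells)
        eta = fit.params["intercept"] + fit.params["conc_1"]
        assert fit.table.loc[0, "estimate"] == pytest.approx(eta)

    def test_se_matches_finite_difference(self):
        """Delta-method SE vs numeric propagation through exp(eta)."""
        wells = make_wells([100, 110], {1: [420, 400], 2: [260, 250]})
        fit = fit_gee_binomial_log(wells)
        cov = fit.cov_robust.to_numpy()
        beta = fit.params.to_numpy()
        h = 1e-6
        for row in fit.table.itertuples():
            j = list(fit.params.index).index(f"conc_{row.concentration_index}")
            grad = np.zeros(len(beta))
            for k in (0, j):
                bp, bm = beta.copy(), beta.copy()
                bp[k] += h
                bm[k] -= h
                grad[k] = (np.exp(bp[0] + bp[j]) - np.exp(bm[0] + bm[j])) / (2 * h)
            numeric = np.sqrt(grad @ cov @ grad)
            assert row.se == pytest.approx(numeric, rel=0.02)


class TestDecisionRules:
    @pytest.mark.parametrize("fold,p,expected", [
        (2.9, 0.001, True),    # significant and over twofold
        (1.9, 1e-6, False),    # fold gate
        (2.5, 0.02, False),    # alpha gate
    ])
    def test_positivity_gates(self, fold, p, expected):
        table = pd.DataFrame([dict(concentration_index=1, estimate=0.01,
                                   se=0.001, fold=fold, fold_se=0.1,
                                   p_value=p)])
        from genotox.mn import GEEFit
        fit = GEEFit(endpoint="MN", link="log",
                     params=pd.Series([0.0, 0.0], index=["intercept", "conc_1"]),
                     cov_robust=pd.DataFrame(np.eye(2),
                                             index=["intercept", "conc_1"],
                                             columns=["intercept", "conc_1"]),
                     cov_naive=pd.DataFrame(np.eye(2),
                                            index=["intercept", "conc_1"],
                                            columns=["intercept", "conc_1"]),
                     table=table, converged=True, n_iter=1)
        assert mn_call(fit).positive is expected

    def test_positivity_monotone_in_fold_and_p(self):
        rng = np.random.default_rng(3)
        wells_weak = simulate_mn_wells(rng, fold=1.0)
        wells_strong = simulate_mn_wells(rng, fold=5.0)
        weak = mn_call(fit_gee_binomial_log(wells_weak))
        strong = mn_call(fit_gee_binomial_log(wells_strong))
        assert strong.positive >= weak.positive

    def test_excluded_concentration_carries_no_call(self):
        wells = make_wells([100, 110], {1: [420, 400], 2: [500, 520]})
        fit = fit_gee_binomial_log(wells)
        result = mn_call(fit, excluded={2})
        t = result.table.set_index("concentration_index")
        assert bool(t.loc[2, "excluded"]) and not bool(t.loc[2, "positive"])
        assert bool(t.loc[1, "positive"])


class TestCytotoxicityAndSelection:
    def test_exclusion_rule(self):
        rs = pd.Series([98, 95, 88, 72, 55, 31], index=range(1, 7))
        retained, removed = exclude_cytotoxic(rs)
        assert removed == [6]
        assert retained == [1, 2, 3, 4, 5]

    def test_no_exclusion_when_all_survive(self):
        rs = pd.Series([98, 95, 88, 72, 55, 44], index=range(1, 7))
        assert exclude_cytotoxic(rs)[1] == []

    def test_all_cytotoxic_errors(self):
        with pytest.raises(ValueError, match="analyzable"):
            exclude_cytotoxic(pd.Series([10, 20], index=[1, 2]))

    def test_top_dose_exclusion_pattern(self):
        """A profile cytotoxic only at the top dose keeps doses 1-5."""
        rs = pd.Series([99, 97, 92, 85, 60, 25], index=range(1, 7))
        retained, removed = exclude_cytotoxic(rs)
        assert removed == [6] and len(retained) == 5

    def test_cap_limits_high(self):
        doses = pd.Series({1: 1.0, 2: 2.0, 3: 3.0, 4: 5.0, 5: 10.0})
        sel = select_concentrations(doses, cap=10.0)
        assert sel["high"] == 5

    def test_exactly_three_returned_in_order(self):
        doses = pd.Series({2: 0.25, 4: 1.0, 5: 2.5})
        assert select_concentrations(doses) == {"low": 2, "mid": 4, "high": 5}

    def test_spacing_matches_exhaustive_search(self):
        doses = pd.Series({1: 0.1, 2: 0.25, 3: 0.5, 4: 1.0, 5: 2.5})
        sel = select_concentrations(doses)
        below = doses.iloc[:-1]
        a, b = pair_spacing_search(np.log(below.to_numpy()),
                                   float(np.log(doses.iloc[-1])))
        assert (sel["low"], sel["mid"]) == (int(below.index[a]),
                                            int(below.index[b]))
        assert sel["high"] == 5

    def test_too_few_retained_errors(self):
        with pytest.raises(ValueError, match="three"):
            select_concentrations(pd.Series({1: 1.0, 2: 2.0}))
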