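"""MR estimators: printed-table anchors for the Wald ratio and interaction
test, simulation oracles for the one-sample pipeline, and the two-sample
IVW / Egger / weighted-median machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import erfc

from polymr import cohort as coh
from polymr import mr
from polymr import regression as reg
from polymr import simulate as sim
from polymr.regression import Estimate

PRIMARY = ["age", "sex", "education", "apoe4", "pc1", "pc2", "pc3", "pc4", "pc5"]


def one_sample_fit(params, covariates=PRIMARY, subset_idx=0):
    g = sim.generate_genotypes(params)
    w, true = sim.generate_weights(g, params)
    c = sim.generate_cohort(g, true, params)
    from polymr import pgs

    aligned, _ = pgs.harmonize_weights(w, g.variants)
    sv = pgs.standardize(pgs.compute_score(g, aligned), c["ancestry"])
    c = c.copy()
    c["pgs"] = sv.standardized
    cc, _ = coh.apply_exclusions(coh.classify_cohort(c))
    s = coh.make_subsets(cc)[subset_idx]
    data = pd.concat([s.data, s.outcome.rename("_y")], axis=1)
    return mr.OneSampleMR(
        data, outcome="_y", exposure="t2dm", instrument="pgs", covariates=covariates
    ).fit()


class TestEstimateFromCI:
    def test_printed_first_stage_row(self):
        est = mr.estimate_from_ci(1.64, 1.54, 1.75)
        assert est.beta == pytest.approx(0.4947, abs=1e-4)
        assert est.se == pytest.approx(0.0326, abs=1e-4)

    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValueError):
            mr.estimate_from_ci(1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            mr.estimate_from_ci(1.2, 1.3, 1.1)

    def test_round_trip_reproduces_printed_values(self):
        # printed CIs are not exactly symmetric about ln(OR), so the
        # reconstruction is exact only at the table's printed precision
        est = mr.estimate_from_ci(1.64, 1.54, 1.75)
        lo, hi = est.or_conf_int()
        assert (round(est.odds_ratio, 2), round(lo, 2), round(hi, 2)) == (
            1.64, 1.54, 1.75)


class TestWaldRatio:
    def test_printed_mr_row_reproduced(self):
        """First stage OR 1.64 (1.54, 1.75), reduced form 1.02 (0.95, 1.10)
        pool to causal OR 1.04 with 95% CI (0.90, 1.21)."""
        res = mr.wald_ratio(
            mr.estimate_from_ci(1.64, 1.54, 1.75), mr.estimate_from_ci(1.02, 0.95, 1.10)
        )
        lo, hi = res.or_conf_int()
        assert round(res.odds_ratio, 2) == 1.04
        assert (round(lo, 2), round(hi, 2)) == (0.90, 1.21)

    def test_zero_reduced_form_gives_unit_or(self):
        res = mr.wald_ratio(Estimate(0.5, 0.05), Estimate(0.0, 0.04))
        assert res.estimate.beta == 0.0
        assert res.odds_ratio == 1.0

    def test_exact_first_stage_limit(self):
        res = mr.wald_ratio(Estimate(0.5, 0.0), Estimate(0.2, 0.04))
        assert res.estimate.se == pytest.approx(0.04 / 0.5)

    def test_ratio_times_first_stage_recovers_reduced_form(self):
        fs, rf = Estimate(0.43, 0.03), Estimate(0.11, 0.05)
        res = mr.wald_ratio(fs, rf)
        assert res.estimate.beta * fs.beta == pytest.approx(rf.beta, rel=1e-12)

    def test_weak_first_stage_attaches_warning(self):
        res = mr.wald_ratio(Estimate(0.05, 0.04), Estimate(0.02, 0.04))
        assert res.weak_instrument

    def test_zero_first_stage_rejected(self):
        with pytest.raises(ZeroDivisionError):
            mr.wald_ratio(Estimate(0.0, 0.03), Estimate(0.1, 0.03))


class TestHeterogeneity:
    def test_printed_adjusted_rows(self):
        a = mr.estimate_from_ci(1.30, 1.10, 1.52)
        b = mr.estimate_from_ci(1.04, 0.90, 1.21)
        assert round(mr.heterogeneity_test(a, b).pvalue, 2) == 0.05
        a2 = mr.estimate_from_ci(1.30, 1.09, 1.54)
        b2 = mr.estimate_from_ci(1.01, 0.87, 1.18)
        assert round(mr.heterogeneity_test(a2, b2).pvalue, 2) == 0.03

    def test_identical_estimates(self):
        e = Estimate(0.3, 0.1)
        res = mr.heterogeneity_test(e, e)
        assert res.z == 0.0 and res.pvalue == pytest.approx(1.0)

    @given(
        st.floats(-1, 1), st.floats(0.01, 0.5), st.floats(-1, 1), st.floats(0.01, 0.5)
    )
    def test_symmetry_and_normal_tail(self, b1, s1, b2, s2):
        r1 = mr.heterogeneity_test(Estimate(b1, s1), Estimate(b2, s2))
        r2 = mr.heterogeneity_test(Estimate(b2, s2), Estimate(b1, s1))
        assert r1.z == pytest.approx(-r2.z)
        assert r1.pvalue == pytest.approx(r2.pvalue)
        # two-sided normal tail via the complementary error function
        assert r1.pvalue == pytest.approx(float(erfc(abs(r1.z) / np.sqrt(2))), rel=1e-9)


class TestOneSampleModel:
    def test_causal_effect_shifts_ratio_distribution_positive(self):
        """A large exposure->outcome effect shifts the Wald ratio clearly
        above zero across replicates (the ratio of log-ORs for a binary
        exposure is attenuated relative to the latent effect, so the check
        aggregates rather than testing one replicate)."""
        betas = []
        for i in range(10):
            res = one_sample_fit(sim.SimParams(theta=np.log(3.0), seed=100 + i))
            assert not res.relevance.weak_instrument
            betas.append(res.estimate.beta)
        betas = np.asarray(betas)
        t = betas.mean() / (betas.std(ddof=1) / np.sqrt(len(betas)))
        assert betas.mean() > 0 and t > 2.0

    def test_pleiotropy_violation_detected(self):
        """A direct score->outcome path (exclusion-restriction violation)
        shifts the ratio away from zero at large n."""
        rejected = 0
        for i in range(20):
            res = one_sample_fit(sim.SimParams(delta_pleio=0.1, seed=200 + i))
            rejected += res.mr.pvalue < 0.05
        assert rejected > 0.05 * 20 * 2  # well above the nominal error rate

    def test_instrument_relevance_attached(self):
        res = one_sample_fit(sim.SimParams(seed=303))
        assert res.relevance.statistic > 10
        assert res.first_stage_fit.n == res.reduced_form_fit.n == res.n

    def test_identical_complete_case_sample(self):
        res = one_sample_fit(sim.SimParams(seed=404), covariates=["age", "sex"])
        assert res.first_stage_fit.n == res.reduced_form_fit.n

    def test_unusable_subset_rejected(self):
        df = pd.DataFrame(
            {
                "age": [70.0] * 4, "proxy": [0] * 4, "prior_wave_dementia": [0] * 4,
                "cognition_score": [20, 21, 22, 23], "t2dm": [0, 1, 0, 1],
            }
        )
        subset = coh.make_subsets(df)[0]
        with pytest.raises(ValueError):
            mr.OneSampleMR.from_subset(subset, instrument="t2dm")


class TestNegativeControl:
    def test_null_in_unexposed_under_valid_instrument(self):
        p = sim.SimParams(seed=77)
        g = sim.generate_genotypes(p)
        w, true = sim.generate_weights(g, p)
        c = sim.generate_cohort(g, true, p)
        from polymr import pgs

        aligned, _ = pgs.harmonize_weights(w, g.variants)
        c = c.copy()
        c["pgs"] = pgs.standardize(pgs.compute_score(g, aligned), c["ancestry"]).standardized
        s = coh.make_subsets(coh.classify_cohort(c))[0]
        fit = mr.negative_control(s.data, s.outcome, covariates=["age", "sex"])
        assert abs(fit["pgs"].z) < 3.0

    def test_pleiotropic_path_shows_up_in_unexposed(self):
        p = sim.SimParams(n_individuals=20_000, delta_pleio=0.2, seed=78)
        g = sim.generate_genotypes(p)
        w, true = sim.generate_weights(g, p)
        c = sim.generate_cohort(g, true, p)
        from polymr import pgs

        aligned, _ = pgs.harmonize_weights(w, g.variants)
        c = c.copy()
        c["pgs"] = pgs.standardize(pgs.compute_score(g, aligned), c["ancestry"]).standardized
        s = coh.make_subsets(coh.classify_cohort(c))[0]
        fit = mr.negative_control(s.data, s.outcome)
        assert fit["pgs"].pvalue < 0.05 and fit["pgs"].beta > 0

    def test_empty_restriction_flagged(self):
        df = pd.DataFrame({"t2dm": [1, 1], "pgs": [0.1, -0.2]})
        assert mr.negative_control(df, [0, 1]) is None


class TestScoreCorrelation:
    def test_identical_and_reversed_vectors(self):
        assert mr.score_correlation([1, 2, 3], [1, 2, 3])[0] == pytest.approx(1.0)
        assert mr.score_correlation([1, 2, 3], [3, 2, 1])[0] == pytest.approx(-1.0)

    def test_independent_scores_have_near_zero_correlation(self):
        rng = np.random.default_rng(15)
        small = 0
        for _ in range(100):
            r, _ = mr.score_correlation(rng.normal(size=8000), rng.normal(size=8000))
            small += abs(r) < 0.04
        assert small >= 95

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            mr.score_correlation([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            mr.score_correlation([1, 2], [1, 2])


def make_pair(beta_exp, se_exp, beta_out, se_out):
    m = len(beta_exp)
    return pd.DataFrame(
        {
            "snp": [f"s{j}" for j in range(m)],
            "beta_exp": beta_exp, "se_exp": se_exp,
            "beta_out": beta_out, "se_out": se_out,
        }
    )


def make_stats(betas, ses, a1=None, a2=None):
    m = len(betas)
    return pd.DataFrame(
        {
            "snp": [f"s{j}" for j in range(m)],
            "chr": 1, "bp": range(m),
            "a1": a1 if a1 is not None else ["A"] * m,
            "a2": a2 if a2 is not None else ["G"] * m,
            "beta": betas, "se": ses,
            "p": [0.01] * m,
        }
    )


class TestHarmonizeTwoSample:
    def test_aligned_tables_unchanged(self):
        e = make_stats([0.1, 0.2], [0.01, 0.01])
        o = make_stats([0.05, 0.07], [0.02, 0.02])
        pair, report = mr.harmonize_two_sample(e, o)
        assert report["n_flipped"] == 0
        np.testing.assert_allclose(pair["beta_out"], [0.05, 0.07])

    def test_swapped_alleles_flip_outcome_beta_and_leave_ivw_invariant(self):
        e = make_stats([0.1, 0.2, 0.3], [0.01] * 3)
        o = make_stats([0.05, 0.07, 0.09], [0.02] * 3)
        base = mr.ivw(mr.harmonize_two_sample(e, o)[0])
        o_flipped = o.copy()
        o_flipped.loc[1, ["a1", "a2"]] = ["G", "A"]
        o_flipped.loc[1, "beta"] = -0.07
        flipped = mr.ivw(mr.harmonize_two_sample(e, o_flipped)[0])
        assert flipped.estimate.beta == pytest.approx(base.estimate.beta, rel=1e-12)

    def test_zero_overlap_raises(self):
        e = make_stats([0.1], [0.01])
        o = make_stats([0.1], [0.01])
        o["snp"] = ["other"]
        with pytest.raises(ValueError):
            mr.harmonize_two_sample(e, o)


class TestIVW:
    def test_single_variant_reduces_to_wald_ratio(self):
        pair = make_pair([0.4], [0.03], [0.08], [0.02])
        res = mr.ivw(pair)
        wald = mr.wald_ratio(Estimate(0.4, 0.0), Estimate(0.08, 0.02))
        assert res.estimate.beta == pytest.approx(wald.estimate.beta)
        assert res.estimate.se == pytest.approx(wald.estimate.se)

    def test_equal_weight_hand_computation(self):
        pair = make_pair([0.2, 0.2], [0.01, 0.01], [0.02, 0.06], [0.02, 0.02])
        res = mr.ivw(pair)  # ratios 0.1 and 0.3 with equal weights
        assert res.estimate.beta == pytest.approx(0.2)

    def test_invariant_to_variant_order(self):
        rng = np.random.default_rng(2)
        bx = rng.uniform(0.1, 0.4, 20)
        pair = make_pair(bx, rng.uniform(0.01, 0.03, 20),
                         0.2 * bx + rng.normal(0, 0.01, 20), rng.uniform(0.01, 0.03, 20))
        shuffled = pair.sample(frac=1, random_state=4).reset_index(drop=True)
        assert mr.ivw(shuffled).estimate.beta == pytest.approx(
            mr.ivw(pair).estimate.beta, rel=1e-12)

    def test_null_simulation_within_three_se(self):
        p = sim.SimParams(n_variants=50, n_causal=50, n_gwas=10_000,
                          true_effect_sd=0.15, seed=31)
        exp_stats, out_stats = sim.generate_summary_stats(p)
        pair, _ = mr.harmonize_two_sample(exp_stats, out_stats)
        strong = pair["beta_exp"].abs() > 5 * pair["se_exp"]
        res = mr.ivw(pair.loc[strong])
        assert abs(res.estimate.beta) < 3 * res.estimate.se

    def test_zero_exposure_beta_excluded_with_warning(self):
        pair = make_pair([0.0, 0.2], [0.01, 0.01], [0.05, 0.04], [0.02, 0.02])
        res = mr.ivw(pair)
        assert res.n_snps == 1 and "excluded_zero_exposure_beta" in res.flags

    def test_coverage_of_true_effect(self):
        """Pooled IVW CI covers the generating causal slope across seeded
        replicates (50 instruments, two disjoint samples)."""
        theta = np.log(1.3)
        covered = 0
        reps = 50
        for i in range(reps):
            p = sim.SimParams(n_variants=50, n_causal=50, n_gwas=20_000,
                              true_effect_sd=0.15, theta=theta, seed=5_000 + i)
            exp_stats, out_stats = sim.generate_summary_stats(p)
            pair, _ = mr.harmonize_two_sample(exp_stats, out_stats)
            res = mr.ivw(pair)
            lo, hi = res.estimate.conf_int()
            covered += lo <= theta <= hi
        assert covered >= 0.85 * reps


class TestEgger:
    def test_exact_linear_data(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        slope, intercept = mr.egger(make_pair(bx, [0.01] * 4, 0.2 * bx, [0.02] * 4))
        assert slope.beta == pytest.approx(0.2, abs=1e-10)
        assert intercept.beta == pytest.approx(0.0, abs=1e-10)

    def test_directional_pleiotropy_constant_recovered(self):
        rng = np.random.default_rng(8)
        bx = rng.uniform(0.1, 0.5, 50)
        se_out = np.full(50, 0.01)
        by = 0.25 * bx + 0.03 + rng.normal(0, 0.01, 50)
        slope, intercept = mr.egger(make_pair(bx, np.full(50, 0.005), by, se_out))
        assert intercept.beta == pytest.approx(0.03, abs=0.01)
        assert slope.beta == pytest.approx(0.25, abs=0.05)

    def test_null_intercept_calibrated(self):
        rng = np.random.default_rng(9)
        ok = 0
        for _ in range(100):
            bx = rng.uniform(0.1, 0.5, 50)
            by = 0.2 * bx + rng.normal(0, 0.01, 50)
            _, intercept = mr.egger(make_pair(bx, np.full(50, 0.005), by,
                                              np.full(50, 0.01)))
            ok += abs(intercept.z) < 1.96
        assert ok >= 90

    def test_requires_three_variants(self):
        with pytest.raises(ValueError):
            mr.egger(make_pair([0.1, 0.2], [0.01] * 2, [0.02, 0.04], [0.01] * 2))


class TestWeightedMedian:
    def test_equal_weight_median(self):
        pair = make_pair([0.2] * 3, [0.01] * 3, [0.02, 0.04, 0.06], [0.02] * 3)
        res = mr.weighted_median(pair, n_boot=50, seed=1)
        assert res.estimate.beta == pytest.approx(0.2)  # ratios 0.1/0.2/0.3

    def test_robust_to_forty_percent_invalid_instruments(self):
        """With 40% of instruments carrying large positive pleiotropy the
        weighted median stays closer to the truth than IVW."""
        rng = np.random.default_rng(12)
        m, theta = 50, 0.2
        bx = rng.uniform(0.2, 0.5, m)
        by = theta * bx + rng.normal(0, 0.005, m)
        by[:20] += 0.15  # invalid instruments
        pair = make_pair(bx, np.full(m, 0.005), by, np.full(m, 0.01))
        wm = mr.weighted_median(pair, n_boot=200, seed=3)
        pooled = mr.ivw(pair)
        assert abs(wm.estimate.beta - theta) < abs(pooled.estimate.beta - theta)

    def test_bootstrap_se_deterministic_given_seed(self):
        pair = make_pair([0.2, 0.3, 0.4], [0.01] * 3, [0.04, 0.07, 0.09], [0.02] * 3)
        a = mr.weighted_median(pair, n_boot=200, seed=42)
        b = mr.weighted_median(pair, n_boot=200, seed=42)
        assert a.estimate.se == b.estimate.se > 0

    def test_requires_three_variants(self):
        with pytest.raises(ValueError):
            mr.weighted_median(make_pair([0.1], [0.01], [0.02], [0.01]))


class TestTwoSampleModel:
    def test_fit_returns_all_methods_and_intercept(self):
        rng = np.random.default_rng(14)
        bx = rng.uniform(0.1, 0.4, 30)
        e = make_stats(bx, np.full(30, 0.01))
        o = make_stats(0.2 * bx + rng.normal(0, 0.01, 30), np.full(30, 0.01))
        res = mr.TwoSampleMR.from_summary_stats(e, o).fit(seed=5)
        frame = res.to_frame()
        assert set(frame["method"]) == {"ivw", "egger", "weighted_median",
                                        "egger_intercept"}
        assert res["ivw"].estimate.beta == pytest.approx(0.2, abs=0.05)
        assert "ivw" in res.summary()


class TestReverseMR:
    def _subsets(self, alpha_ad, seed):
        p = sim.SimParams(alpha_ad=alpha_ad, seed=seed)
        g = sim.generate_genotypes(p)
        w, true = sim.generate_weights(g, p)
        c = sim.generate_cohort(g, true, p)
        cc, _ = coh.apply_exclusions(coh.classify_cohort(c))
        return coh.make_subsets(cc)

    def test_ad_score_instruments_dementia_subset(self):
        subsets = {s.label: s for s in self._subsets(alpha_ad=0.4, seed=55)}
        res = mr.reverse_mr(subsets["dementia_vs_normal"],
                            covariates=["age", "sex", "education"])
        assert res.relevance.statistic > 10
        assert not res.relevance.weak_instrument

    def test_null_reverse_effect_consistent_with_zero(self):
        subsets = {s.label: s for s in self._subsets(alpha_ad=0.4, seed=56)}
        res = mr.reverse_mr(subsets["dementia_vs_normal"],
                            covariates=["age", "sex", "education"])
        # cognition does not cause T2DM in the generator
        assert res.mr.pvalue > 0.05

    def test_weak_instrument_flagged_when_ad_score_uninformative(self):
        subsets = {s.label: s for s in self._subsets(alpha_ad=0.0, seed=57)}
        res = mr.reverse_mr(subsets["cind_vs_normal"],
                            covariates=["age", "sex", "education"])
        assert res.weak_instrument
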