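import numpy as np
import pandas as pd
import pytest

from pssubgroup import (Scenario, SimulationConfig, estimate_both_subsets,
                        estimate_ps, build_ps_specification, fit_marginal_cox,
                        generate_cohort, match, overlap_weights, smrw_weights)
from pssubgroup.dgm import Cohort
from pssubgroup.estimators import EffectEstimate, MatchedSet, WeightVector
from pssubgroup.propensity import PSResult


from _helpers import greedy_match_oracle, ps_cohort as _ps_cohort


class TestMatch:
    def test_identical_ps_matches_all_treated(self):
        res, cohort = _ps_cohort(np.zeros(8), [1, 1, 1, 0, 0, 0, 0, 0])
        ms = match(res, cohort, caliper_sd=0.2, with_replacement=False,
                   rng_state=0)
        assert ms.n_pairs == 3
        assert ms.unmatched_treated == []

    def test_control_exhaustion(self):
        res, cohort = _ps_cohort(np.zeros(4), [1, 1, 1, 0])
        ms = match(res, cohort, caliper_sd=50.0, with_replacement=False,
                   rng_state=0)
        assert ms.n_pairs == 1
        assert len(ms.unmatched_treated) == 2

    def test_no_controls_errors(self):
        res, cohort = _ps_cohort(np.zeros(3), [1, 1, 1])
        with pytest.raises(ValueError, match="no controls"):
            match(res, cohort, 0.2, False, 0)

    @pytest.mark.parametrize("with_replacement", [False, True])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_agrees_with_exhaustive_oracle(self, with_replacement, seed):
        rng = np.random.default_rng(100 + seed)
        lps = np.round(rng.normal(size=20), 2)
        Z = np.r_[np.ones(10, dtype=int), np.zeros(10, dtype=int)]
        res, cohort = _ps_cohort(lps, Z)
        caliper_sd = 0.5
        ms = match(res, cohort, caliper_sd=caliper_sd,
                   with_replacement=with_replacement, rng_state=seed)
        # reproduce the seeded processing order the implementation uses
        order = np.random.default_rng(seed).permutation(10)
        caliper = caliper_sd * np.std(res.logit_ps, ddof=1)
        expected = greedy_match_oracle(res.logit_ps, Z, caliper, order,
                                       with_replacement)
        assert sorted(ms.pairs) == expected

    def test_pairs_within_caliper_and_injective(self, small_cohort):
        res = estimate_ps(small_cohort, build_ps_specification("true_ps"),
                          "across")
        ms = match(res, small_cohort, 0.2, False, 7,
                   pool=small_cohort.subset == 2)
        controls = [c for _, c in ms.pairs]
        assert len(controls) == len(set(controls))
        for t, c in ms.pairs:
            assert abs(res.logit_ps[t] - res.logit_ps[c]) <= ms.caliper_width

    def test_caliper_monotonicity(self, small_cohort):
        res = estimate_ps(small_cohort, build_ps_specification("true_ps"),
                          "across")
        for s in (1, 2):
            pool = small_cohort.subset == s
            wide = match(res, small_cohort, 0.2, False, 7, pool=pool)
            narrow = match(res, small_cohort, 0.1, False, 7, pool=pool)
            assert narrow.n_pairs <= wide.n_pairs

    def test_replacement_use_counts(self):
        res, cohort = _ps_cohort([0.0, 0.1, 0.2, 0.0], [1, 1, 1, 0])
        ms = match(res, cohort, 50.0, True, 0)
        assert ms.n_pairs == 3
        assert ms.control_use_counts == {3: 3}


class TestWeights:
    def test_smrw_control_odds(self):
        res, cohort = _ps_cohort([0.0, 0.0], [1, 0])
        wv = smrw_weights(res, cohort, stabilize=False)
        assert wv.weights[0] == 1.0
        assert wv.weights[1] == pytest.approx(1.0)  # odds at ps=0.5

    def test_smrw_stabilization_is_mean_one_constant(self):
        lps = np.log(0.8 / 0.2) * np.ones(5)
        res, cohort = _ps_cohort(lps, [1, 0, 0, 0, 0])
        raw = smrw_weights(res, cohort, stabilize=False)
        np.testing.assert_allclose(raw.weights[1:], 4.0)
        stab = smrw_weights(res, cohort, stabilize=True)
        np.testing.assert_allclose(stab.weights[1:], 1.0)

    def test_smrw_infinite_weight_flagged(self):
        res, cohort = _ps_cohort([0.0, 40.0], [1, 0])  # control ps ~ 1
        res.ps[1] = 1.0
        wv = smrw_weights(res, cohort)
        assert not wv.valid

    def test_overlap_symmetric_point(self):
        res, cohort = _ps_cohort([0.0, 0.0], [1, 0])
        wv = overlap_weights(res, cohort)
        np.testing.assert_allclose(wv.weights, 0.5)

    def test_overlap_extreme_ps_gets_no_weight(self):
        res, cohort = _ps_cohort([30.0, 0.0], [1, 0])
        wv = overlap_weights(res, cohort)
        assert wv.weights[0] == pytest.approx(0.0, abs=1e-10)


@pytest.fixture(scope="module")
def two_arm_exponential():
    """50k patients per arm, rates lambda vs 2*lambda, no censoring."""
    rng = np.random.default_rng(31)
    n = 50_000
    t0 = rng.exponential(100.0, n)
    t1 = rng.exponential(50.0, n)
    Z = np.r_[np.ones(n, dtype=int), np.zeros(n, dtype=int)]
    time = np.r_[t1, t0]
    return _ps_cohort(np.zeros(2 * n), Z, time=time,
                      event=np.ones(2 * n, dtype=int))


class TestMarginalCox:

    def test_recovers_log_two(self, two_arm_exponential):
        _, cohort = two_arm_exponential
        wv = WeightVector(np.ones(cohort.n), "unit")
        est = fit_marginal_cox(cohort, 1, wv, method="smrw")
        assert est.converged
        assert est.log_hr == pytest.approx(np.log(2), abs=0.02)

    def test_weight_scale_invariance(self, two_arm_exponential):
        _, cohort = two_arm_exponential
        idx = np.random.default_rng(5).choice(cohort.n, 3000, replace=False)
        sub = Cohort(cohort.covariates.iloc[idx].reset_index(drop=True),
                     cohort.subset[idx], cohort.treatment[idx],
                     cohort.time[idx], cohort.event[idx])
        w = np.random.default_rng(6).uniform(0.5, 2.0, sub.n)
        a = fit_marginal_cox(sub, 1, WeightVector(w, "unit"), method="smrw")
        b = fit_marginal_cox(sub, 1, WeightVector(2 * w, "unit"),
                             method="smrw")
        assert a.log_hr == pytest.approx(b.log_hr, abs=1e-8)

    def test_no_events_flags_nonconvergence(self):
        res, cohort = _ps_cohort(np.zeros(40),
                                 np.r_[np.ones(20), np.zeros(20)],
                                 event=np.zeros(40))
        est = fit_marginal_cox(cohort, 1, overlap_weights(res, cohort))
        assert not est.converged
        assert np.isnan(est.log_hr)

    def test_invalid_weights_flag_nonconvergence(self):
        res, cohort = _ps_cohort(np.zeros(4), [1, 1, 0, 0])
        wv = smrw_weights(res, cohort)
        wv.valid = False
        est = fit_marginal_cox(cohort, 1, wv)
        assert not est.converged

    def test_ci_brackets_estimate(self, small_cohort):
        res = estimate_ps(small_cohort, build_ps_specification("true_ps"),
                          "across")
        est = fit_marginal_cox(small_cohort, 2, overlap_weights(res, small_cohort))
        assert est.converged
        assert est.ci_low <= est.log_hr <= est.ci_high
        assert est.se > 0

    def test_bootstrap_variance_close_to_robust(self, sc1):
        """On a moderate cohort the bootstrap SE and the sandwich SE agree
        to within a factor ~1.5 (both estimate the same sampling SD)."""
        cfg = SimulationConfig(n=800)
        cohort = generate_cohort(cfg, sc1, 21)
        spec = build_ps_specification("true_ps")
        ps = estimate_ps(cohort, spec, "across")
        wv = smrw_weights(ps, cohort)
        robust = fit_marginal_cox(cohort, 2, wv, variance_mode="robust")
        boot = fit_marginal_cox(cohort, 2, wv, variance_mode="bootstrap",
                                ps_context=(spec, "across"), n_boot=60,
                                rng_state=3)
        assert boot.converged
        assert boot.log_hr == robust.log_hr  # point estimate unchanged
        assert 0.6 < boot.se / robust.se < 1.6


class TestEstimateBothSubsets:
    def test_null_scenario_centered_at_zero(self, null_effect_config):
        from dataclasses import replace
        rng_means = {1: [], 2: []}
        cfg = replace(null_effect_config, n=1500)
        for seed in range(30):
            cohort = generate_cohort(cfg, Scenario.sc4(), seed)
            e1, e2 = estimate_both_subsets(cohort, "across", "true_ps",
                                           "overlap", rng_state=seed)
            rng_means[1].append(e1.log_hr)
            rng_means[2].append(e2.log_hr)
        assert abs(np.mean(rng_means[1])) < 0.06
        assert abs(np.mean(rng_means[2])) < 0.04

    def test_estimand_tags(self, small_cohort):
        e1, _ = estimate_both_subsets(small_cohort, "across", "true_ps",
                                      "overlap", rng_state=1)
        assert e1.estimand == "ATO"
        m1, _ = estimate_both_subsets(small_cohort, "across", "true_ps",
                                      "match_replace", rng_state=1)
        assert m1.estimand == "ATT"

    def test_nonconverged_ps_propagates(self):
        # subset 1 entirely treated -> within-strategy PS cannot converge
        rng = np.random.default_rng(8)
        n = 400
        cov = pd.DataFrame({f"X{j}": rng.normal(size=n) if j <= 2 else
                            rng.integers(0, 2, n).astype(float)
                            for j in range(1, 11)})
        subset = np.r_[np.ones(100, dtype=int), np.full(300, 2, dtype=int)]
        Z = np.r_[np.ones(100, dtype=int), rng.integers(0, 2, 300)]
        cohort = Cohort(cov, subset, Z,
                        rng.exponential(30, n).clip(0.1, 60),
                        rng.integers(0, 2, n))
        e1, e2 = estimate_both_subsets(cohort, "within", "true_ps", "smrw",
                                       variance_mode="robust", rng_state=2)
        assert not e1.converged
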