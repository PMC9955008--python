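"""Scenario generation, truth construction, and error summaries."""

import numpy as np
import pytest

from codmi import (
    ScenarioConfig,
    ScenarioResult,
    SurvivalSample,
    fit_km,
    run_scenario,
    run_study,
    summarize,
)
from codmi.simulation import (
    _truncated_draw,
    generate_truth,
    simulate_doc_times,
    simulate_standard_data,
)


class TestStandardBootstrap:
    def test_stratified_counts_exact(self, arm_a):
        rng = np.random.default_rng(0)
        for _ in range(5):
            z, _ = simulate_standard_data(arm_a.standard, 100, rng)
            # arm A holds 42 deaths among 51 records
            assert z.n_deaths == round(100 * 42 / 51)
            assert len(z) == 100

    def test_single_record_seed(self):
        s = SurvivalSample(np.array([5.0]), np.array([1]))
        z, tmd = simulate_standard_data(s, 7, np.random.default_rng(1))
        assert np.all(z.times == 5.0) and z.n_deaths == 7
        assert tmd == 5.0

    def test_no_censorings_seed(self):
        s = SurvivalSample(np.array([1.0, 2.0]), np.array([1, 1]))
        z, _ = simulate_standard_data(s, 10, np.random.default_rng(2))
        assert z.n_deaths == 10

    def test_invalid_n(self, arm_a):
        with pytest.raises(ValueError):
            simulate_standard_data(arm_a.standard, 0, np.random.default_rng(0))


class TestDocTimes:
    def test_theta_strictly_below_tau0(self, arm_b):
        rng = np.random.default_rng(3)
        tau0, theta = simulate_doc_times(arm_b.standard, 1776.0, 50, rng)
        assert np.all(theta < tau0)
        assert np.all(theta > 0)
        assert np.all(tau0 <= 1776.0)

    def test_degenerate_single_death_time(self):
        s = SurvivalSample(np.array([8.0, 9.0]), np.array([1, 0]))
        rng = np.random.default_rng(4)
        tau0, theta = simulate_doc_times(s, 8.0, 5, rng)
        assert np.all(tau0 == 8.0)

    def test_m_zero(self, arm_a):
        tau0, theta = simulate_doc_times(arm_a.standard, 1417.0, 0, np.random.default_rng(0))
        assert tau0.size == theta.size == 0

    def test_uniform_thinning_mean(self, arm_a):
        rng = np.random.default_rng(5)
        tau0, theta = simulate_doc_times(arm_a.standard, 1417.0, 4000, rng)
        assert np.mean(theta / tau0) == pytest.approx(0.5, abs=3 * 0.289 / np.sqrt(4000))

    def test_no_eligible_death_raises(self):
        s = SurvivalSample(np.array([8.0]), np.array([0]))
        with pytest.raises(ValueError, match="eligible"):
            simulate_doc_times(s, 5.0, 1, np.random.default_rng(0))


class TestTruth:
    def test_single_atom_beyond_theta(self):
        z = SurvivalSample(np.array([2.0, 4.0]), np.array([1, 1]))
        tau, theta = generate_truth(
            z, np.array([3.0]), np.array([3.5]), 3, "death", np.random.default_rng(0)
        )
        assert tau.tolist() == [4.0]

    def test_fixed_point_insensitive_to_n_iter(self):
        # {(2,1),(4,1)} with theta=1, tau0=3 is a finite-time fixed point, so
        # the pre-sampling state is identical and the single final draw
        # consumes the same stream
        z = SurvivalSample(np.array([2.0, 4.0]), np.array([1, 1]))
        out1, _ = generate_truth(z, np.array([1.0]), np.array([3.0]), 1, "death",
                                 np.random.default_rng(42))
        out2, _ = generate_truth(z, np.array([1.0]), np.array([3.0]), 2, "death",
                                 np.random.default_rng(42))
        assert out1.tolist() == out2.tolist()

    def test_sampling_mean_matches_truncated_expectation(self, arm_a):
        km = fit_km(arm_a.standard, complete=True)
        rng = np.random.default_rng(6)
        theta = 300.0
        draws = np.array([_truncated_draw(km, theta, rng) for _ in range(4000)])
        expected = theta + km.life_expectancy(theta)
        sem = draws.std(ddof=1) / np.sqrt(len(draws))
        assert draws.mean() == pytest.approx(expected, abs=3 * sem)

    def test_censored_regime_draws_from_reverse_mass(self, arm_b):
        z, _ = simulate_standard_data(arm_b.standard, 60, np.random.default_rng(7))
        rng = np.random.default_rng(8)
        tau0, theta = simulate_doc_times(arm_b.standard, 1776.0, 5, rng)
        tau, theta = generate_truth(z, theta, tau0, 5, "censored", rng)
        assert np.all(tau > theta)


class TestScenarioAndSummary:
    def test_m_zero_scenario_trivially_converges(self, arm_a):
        cfg = ScenarioConfig(n_sim=30, m_sim=0, n_iter=2)
        res = run_scenario(cfg, arm_a.standard, np.random.default_rng(0))
        assert res.converged
        assert res.e_codmi.size == 0

    def test_reproducibility_bit_for_bit(self, arm_a):
        cfg = ScenarioConfig(n_sim=40, m_sim=3, n_iter=3)
        r1 = run_study(cfg, arm_a.standard, 10, seed=11)
        r2 = run_study(cfg, arm_a.standard, 10, seed=11)
        for a, b in zip(r1, r2):
            assert a.converged == b.converged
            np.testing.assert_array_equal(a.e_true, b.e_true)
            np.testing.assert_array_equal(a.e_codmi, b.e_codmi)

    def test_summarize_hand_arithmetic(self):
        mk = lambda err: ScenarioResult(
            theta=np.array([10.0]),
            e_true=np.array([5.0 + err]),
            e_codmi=np.array([5.0]),
            e_naive_dod=np.array([4.0]),
            e_naive_cen=np.array([3.0]),
            converged=True,
        )
        s = summarize([mk(+1.0), mk(-1.0)])
        assert s.overall["mean_error"] == pytest.approx(0.0)
        assert s.overall["sem"] == pytest.approx(1.0)
        assert s.n_convergent == 2

    def test_summarize_all_zero_errors(self):
        r = ScenarioResult(
            theta=np.array([1.0, 2.0]),
            e_true=np.array([3.0, 4.0]),
            e_codmi=np.array([3.0, 4.0]),
            e_naive_dod=np.array([3.0, 4.0]),
            e_naive_cen=np.array([3.0, 4.0]),
            converged=True,
        )
        s = summarize([r, r, r])
        assert s.overall["mean_error"] == 0.0
        assert s.overall["sem"] == 0.0
        assert s.per_j["mean_error"].tolist() == [0.0, 0.0]

    def test_summarize_requires_convergent_scenarios(self):
        r = ScenarioResult(*(np.array([np.nan]),) * 5, converged=False)
        with pytest.raises(ValueError, match="convergent"):
            summarize([r])

    def test_nonconvergent_excluded_from_means(self):
        good = ScenarioResult(
            theta=np.array([1.0]), e_true=np.array([2.0]), e_codmi=np.array([1.5]),
            e_naive_dod=np.array([1.0]), e_naive_cen=np.array([1.0]), converged=True,
        )
        bad = ScenarioResult(*(np.array([np.nan]),) * 5, converged=False)
        s = summarize([good, bad, good])
        assert s.n_convergent == 2
        assert np.isfinite(s.overall["mean_error"])

    def test_sem_scales_inverse_sqrt_n(self, arm_a):
        cfg = ScenarioConfig(n_sim=40, m_sim=3, n_iter=3)
        results = run_study(cfg, arm_a.standard, 120, seed=13)
        conv = [r for r in results if r.converged]
        s_half = summarize(conv[: len(conv) // 2])
        s_full = summarize(conv)
        ratio = s_half.overall["sem"] / s_full.overall["sem"]
        assert ratio == pytest.approx(np.sqrt(2), rel=0.35)

    def test_per_j_table_shape(self, arm_b):
        cfg = ScenarioConfig(n_sim=40, m_sim=4, n_iter=2)
        s = summarize(run_study(cfg, arm_b.standard, 30, seed=17))
        assert list(s.per_j.index) == [1, 2, 3, 4]
        assert {"theta_mean", "sem", "min_error", "max_error"} <= set(s.per_j.columns)
        assert {"naive_dod", "naive_cen"} <= set(s.blocks)

    def test_censored_regime_produces_unadjusted_block(self, arm_a):
        cfg = ScenarioConfig(n_sim=40, m_sim=3, n_iter=3, truth_endpoint="censored")
        s = summarize(run_study(cfg, arm_a.standard, 30, seed=19))
        assert "unadjusted" in s.blocks
        # without the adjustment the bias is grossly positive
        assert (
            s.blocks["unadjusted"]["relative_error_pct"]
            > s.overall["relative_error_pct"]
        )

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            ScenarioConfig(tolerance=0.0)
        with pytest.raises(ValueError):
            ScenarioConfig(truth_endpoint="other")
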