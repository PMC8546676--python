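"""Tracer kinetics: forward models, single-time-point estimators,
replicate summaries and between-site ANOVA."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.integrate import solve_ivp

from perihg.kinetics import (
    KineticParams,
    RateEstimate,
    TracerIncubation,
    TracerKineticsModel,
    TracerSpike,
    compare_sites_anova,
    estimate_kd,
    estimate_km,
    simulate_coupled_tracers,
    simulate_simplified_tracers,
    summarize_site_rates,
)

SPIKE = TracerSpike(4.0, 4.0)


def make_inc(mm200=0.05, mm198=0.1, t=2.0, lod=0.01, censored=False):
    return TracerIncubation(
        "wetland", "r1", SPIKE, mm200, mm198, t, lod, censored=censored
    )


class TestForwardModels:
    def test_no_reaction_leaves_pools_unchanged(self):
        mm200, ihg200, mm198, ihg198 = simulate_coupled_tracers(
            KineticParams(0.0, 0.0), SPIKE, 2.0
        )
        assert (mm200, ihg200, mm198, ihg198) == (0.0, 4.0, 4.0, 0.0)

    def test_coupled_product_matches_ode_integration(self):
        # independent oracle: numerical integration of the linear system
        km, kd, t = 5.9e-3, 1.78, 2.0
        sol = solve_ivp(
            lambda _, y: [-km * y[0] + kd * y[1], km * y[0] - kd * y[1]],
            [0, t],
            [SPIKE.ihg200_0, 0.0],
            rtol=1e-12,
            atol=1e-14,
        )
        mm200, *_ = simulate_coupled_tracers(KineticParams(km, kd), SPIKE, t)
        assert mm200 == pytest.approx(0.0128432257338, rel=1e-9)
        assert mm200 == pytest.approx(sol.y[1, -1], rel=1e-8)

    def test_equal_rates_equilibrate_each_pool_to_half(self):
        mm200, ihg200, mm198, ihg198 = simulate_coupled_tracers(
            KineticParams(0.7, 0.7), SPIKE, 1e4
        )
        assert mm200 == pytest.approx(2.0, abs=1e-9)
        assert mm198 == pytest.approx(2.0, abs=1e-9)
        assert ihg200 == pytest.approx(2.0, abs=1e-9)

    @pytest.mark.parametrize(
        "params, expected_mm200, expected_mm198",
        [
            (KineticParams(0.0, 1.78), 0.0, 4 * math.exp(-3.56)),
            (KineticParams(5.9e-3, 1.78), 0.0469226121310, 0.1137552988567),
        ],
    )
    def test_simplified_forward_values(self, params, expected_mm200, expected_mm198):
        mm200, mm198 = simulate_simplified_tracers(params, SPIKE, 2.0)
        assert mm200 == pytest.approx(expected_mm200, abs=1e-12)
        assert mm198 == pytest.approx(expected_mm198, abs=1e-12)

    @pytest.mark.parametrize("fn", [simulate_coupled_tracers, simulate_simplified_tracers])
    def test_negative_time_rejected(self, fn):
        with pytest.raises(ValueError):
            fn(KineticParams(0.1, 0.1), SPIKE, -1.0)


class TestEstimators:
    def test_km_round_trip(self):
        mm200, _ = simulate_simplified_tracers(KineticParams(5.9e-3, 0.0), SPIKE, 2.0)
        est = estimate_km(make_inc(mm200=mm200))
        assert est.detected
        assert est.value == pytest.approx(5.9e-3, rel=1e-12)

    def test_km_at_detection_limit_is_nondetect(self):
        est = estimate_km(make_inc(mm200=0.01, lod=0.01))
        assert not est.detected and est.value is None

    def test_km_product_above_spike_is_an_error(self):
        with pytest.raises(ValueError, match="logarithm undefined"):
            estimate_km(make_inc(mm200=4.1))

    def test_kd_round_trip(self):
        _, mm198 = simulate_simplified_tracers(KineticParams(0.0, 1.78), SPIKE, 2.0)
        est = estimate_kd(make_inc(mm198=mm198))
        assert est.value == pytest.approx(1.78, rel=1e-12)

    def test_kd_no_decay_gives_zero(self):
        assert estimate_kd(make_inc(mm198=4.0)).value == 0.0

    def test_kd_zero_concentration_is_an_error(self):
        with pytest.raises(ValueError):
            estimate_kd(make_inc(mm198=0.0))

    def test_kd_apparent_gain_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            est = estimate_kd(make_inc(mm198=4.5))
        assert est.value == 0.0

    def test_km_small_signal_equals_linear_rate_to_first_order(self):
        inc = make_inc(mm200=4e-4, t=2.0, lod=1e-6)
        linear = inc.mmhg200_t / (SPIKE.ihg200_0 * inc.t)
        assert estimate_km(inc).value == pytest.approx(linear, rel=1e-4)


class TestSummaries:
    def test_identical_triplicate(self):
        ests = [RateEstimate(2e-3, "methylation", f"r{i}") for i in range(3)]
        s = summarize_site_rates(ests, "wetland")
        assert s.mean == pytest.approx(2e-3) and s.se == 0.0
        assert (s.n_detected, s.n_total) == (3, 3)

    def test_wetland_like_triplet_mean_and_se(self):
        # hand-computed: mean 5.9e-3, sd 3.4e-3, se = sd/sqrt(3)
        vals = [2.5e-3, 5.9e-3, 9.3e-3]
        ests = [RateEstimate(v, "methylation", f"r{i}") for i, v in enumerate(vals)]
        s = summarize_site_rates(ests, "wetland")
        assert s.mean == pytest.approx(5.9e-3, rel=1e-12)
        assert s.se == pytest.approx(3.4e-3 / math.sqrt(3), rel=1e-12)

    def test_single_detection_among_nondetects(self):
        ests = [
            RateEstimate(None, "methylation", "r1", detected=False),
            RateEstimate(None, "methylation", "r2", detected=False),
            RateEstimate(2.6e-3, "methylation", "r3"),
        ]
        s = summarize_site_rates(ests, "natural")
        assert s.mean == pytest.approx(2.6e-3)
        assert (s.n_detected, s.n_total) == (1, 3)

    def test_all_nondetect_has_undefined_mean(self):
        ests = [RateEstimate(None, "methylation", "r1", detected=False)]
        s = summarize_site_rates(ests, "flooded")
        assert s.mean is None and s.n_detected == 0

    def test_nondetects_as_zero_policy(self):
        ests = [
            RateEstimate(None, "methylation", "r1", detected=False),
            RateEstimate(3e-3, "methylation", "r2"),
        ]
        s = summarize_site_rates(ests, "x", include_nondetect_as_zero=True)
        assert s.mean == pytest.approx(1.5e-3)

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            summarize_site_rates([], "x")


class TestAnova:
    def test_identical_groups_give_f_zero(self):
        f, p, _ = compare_sites_anova({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert f == 0.0 and p == 1.0

    def test_two_group_hand_computed_f(self):
        # SSB = 3*(2-3.5)^2 + 3*(5-3.5)^2 = 13.5; SSW = 4; F(1,4) = 13.5
        f, p, pairwise = compare_sites_anova({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert f == pytest.approx(13.5, rel=1e-12)
        assert p == pytest.approx(stats.f.sf(13.5, 1, 4), rel=1e-9)
        assert p == pytest.approx(0.0213, abs=2e-4)
        assert pairwise[("a", "b")] == pytest.approx(p, rel=1e-3)

    def test_small_group_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            f, p, pairwise = compare_sites_anova(
                {"a": [1, 2, 3], "b": [4, 5, 6], "c": [7]}
            )
        assert set(pairwise) == {("a", "b")}

    def test_too_few_usable_groups_is_an_error(self):
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                compare_sites_anova({"a": [1, 2], "b": [5]})

    def test_type_i_error_rate_near_alpha(self, rng):
        # Monte-Carlo: three null-normal groups of 3, nominal alpha 0.05
        n_sim, rejections = 2000, 0
        for _ in range(n_sim):
            groups = rng.normal(size=(3, 3))
            _, p = stats.f_oneway(*groups)
            f, p_ours, _ = compare_sites_anova(
                {f"g{i}": list(groups[i]) for i in range(3)}
            )
            assert p_ours == pytest.approx(p, rel=1e-9)
            rejections += p_ours < 0.05
        assert rejections / n_sim == pytest.approx(0.05, abs=0.015)


class TestModelInterface:
    def make_df(self):
        rows = []
        truth = {"natural": (2.6e-3, 1.4), "wetland": (5.9e-3, 1.8)}
        for site, (km, kd) in truth.items():
            mm200, mm198 = simulate_simplified_tracers(
                KineticParams(km, kd), SPIKE, 2.0
            )
            for rep in range(3):
                rows.append(
                    {
                        "site_id": site,
                        "replicate_id": f"{site}_r{rep}",
                        "ihg200_0": 4.0,
                        "mmhg198_0": 4.0,
                        "mmhg200_t": mm200,
                        "mmhg198_t": mm198,
                        "t_days": 2.0,
                        "lod_mmhg": 0.01,
                    }
                )
        return pd.DataFrame(rows), truth

    def test_fit_recovers_noise_free_truth(self):
        df, truth = self.make_df()
        results = TracerKineticsModel.from_dataframe(df).fit()
        for summ in results.summaries["km"]:
            assert summ.mean == pytest.approx(truth[summ.site_id][0], rel=1e-12)
        for summ in results.summaries["kd"]:
            assert summ.mean == pytest.approx(truth[summ.site_id][1], rel=1e-12)

    def test_summary_lists_sites_and_anova(self):
        df, _ = self.make_df()
        text = TracerKineticsModel.from_dataframe(df).fit().summary()
        assert "wetland" in text and "kd" in text and "ANOVA" in text

    def test_missing_column_is_an_error(self):
        with pytest.raises(ValueError, match="missing columns"):
            TracerKineticsModel.from_dataframe(pd.DataFrame({"site_id": ["a"]}))

    def test_simulate_matches_forward_model(self):
        df, truth = self.make_df()
        model = TracerKineticsModel.from_dataframe(df)
        params = {s: KineticParams(*truth[s]) for s in truth}
        sim = model.simulate(params, mode="simplified")
        assert np.allclose(sim["mmhg200_t"], df["mmhg200_t"])
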