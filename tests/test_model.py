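import numpy as np
import pytest

from aspdyn.model import (
    ModelParams,
    ModelState,
    Scenario,
    atcase_rate,
    crossover_time,
    derivatives,
    growth_rate,
    scenario_preset,
    simulate,
    steady_state,
)
from aspdyn.timecourse import characterize_rebound


class TestAtcaseRate:
    def test_half_saturation_without_inhibitors(self):
        p = ModelParams()
        v = atcase_rate(p.Km_atc, 0.0, 0.0, p)
        assert v == pytest.approx(p.Vmax_atc / 2, rel=1e-12)

    def test_competitive_inhibition_is_surmountable(self):
        p = ModelParams()
        v = atcase_rate(1e7, 20.0, 0.0, p)
        assert v == pytest.approx(p.Vmax_atc, rel=1e-3)

    def test_apparent_km_scales_linearly_in_succinate(self):
        p = ModelParams()
        for succ in (0.5, 2.0, 10.0):
            km_app = p.Km_atc * (1 + succ / p.Ki_succ)
            assert atcase_rate(km_app, succ, 0.0, p) == pytest.approx(
                p.Vmax_atc / 2, rel=1e-9
            )

    def test_velocity_ratio_baseline_vs_sdh_inhibited_concentrations(self):
        # baseline (asp 1.5 mM, succ 0.2 mM) against SDH-inhibited
        # (asp 0.2 mM, succ 14 mM) with Km=2, Ki=0.75 and no feedback
        p = ModelParams(Km_atc=2.0, Ki_succ=0.75, Kfb_utp=1e12)
        ratio = atcase_rate(1.5, 0.2, 0.0, p) / atcase_rate(0.2, 14.0, 0.0, p)
        assert ratio == pytest.approx(73.5, abs=0.1)

    def test_utp_feedback_halves_rate_at_kfb(self):
        p = ModelParams()
        v0 = atcase_rate(1.0, 0.0, 0.0, p)
        assert atcase_rate(1.0, 0.0, p.Kfb_utp, p) == pytest.approx(v0 / 2, rel=1e-12)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            atcase_rate(-1.0, 0.0, 0.0, ModelParams())


class TestGrowthRate:
    def test_saturated_growth_reaches_mu_max(self):
        p = ModelParams()
        assert growth_rate(1e6, 1e6, p) == pytest.approx(p.mu_max, rel=1e-4)

    def test_zero_utp_stops_growth(self):
        assert growth_rate(10.0, 0.0, ModelParams()) == 0.0

    def test_never_exceeds_single_substrate_terms(self):
        p = ModelParams()
        for asp, utp in [(0.1, 5.0), (5.0, 0.1), (1.0, 1.0)]:
            mu = growth_rate(asp, utp, p)
            assert mu <= p.mu_max * asp / (asp + p.Ka_asp) + 1e-15
            assert mu <= p.mu_max * utp / (utp + p.Ku_utp) + 1e-15


class TestDerivatives:
    def test_vehicle_fixed_point_has_zero_derivatives(self):
        p = ModelParams()
        fixed = steady_state(p, "vehicle")
        d = derivatives(fixed, scenario_preset("vehicle"), p)
        assert np.allclose(d[:3], 0.0, atol=1e-8)

    def test_sdh_block_accumulates_succinate_immediately(self):
        p = ModelParams()
        d = derivatives(ModelState.default_initial(), scenario_preset("aa5"), p)
        assert d[1] > 0

    def test_uridine_adds_exactly_the_salvage_flux(self):
        p = ModelParams()
        state = ModelState(1.0, 5.0, 0.3)
        base = derivatives(state, Scenario(sdh_activity=0.0), p)
        plus = derivatives(state, Scenario(sdh_activity=0.0, uridine=True), p)
        assert plus[2] - base[2] == pytest.approx(p.uridine_salvage, rel=1e-12)
        assert plus[0] == base[0] and plus[1] == base[1]


class TestScenarioPresets:
    def test_vehicle_has_full_sdh_and_no_supplements(self):
        s = scenario_preset("vehicle")
        assert s.sdh_activity == 1.0
        assert not (s.ci_inhibited or s.uridine or s.aspartate_supplement)
        assert s.succinate_supplement == 0.0

    def test_aa5_blocks_sdh(self):
        assert scenario_preset("aa5").sdh_activity == 0.0

    def test_succinate_arm_combines_all_three(self):
        s = scenario_preset("aa5_rot_succinate")
        assert s.sdh_activity == 0.0 and s.ci_inhibited and s.succinate_supplement > 0

    def test_unknown_preset_lists_options(self):
        with pytest.raises(ValueError, match="vehicle"):
            scenario_preset("nope")


class TestSimulate:
    def test_vehicle_holds_its_steady_state(self, trajectories):
        v = trajectories["vehicle"]
        assert np.all(np.abs(v.asp / v.asp[0] - 1) < 0.20)

    def test_all_presets_stay_non_negative(self, trajectories):
        for name, tr in trajectories.items():
            for var in ("asp", "succ", "utp", "cell_volume"):
                assert np.all(tr.variable(var) >= 0), f"{name}:{var}"

    def test_aa5_aspartate_is_non_monotonic_with_rebound(self, trajectories):
        tr = trajectories["aa5"]
        desc = characterize_rebound(tr.times, tr.asp)
        assert not desc.monotonic
        assert desc.rebound_fraction > 0.3

    def test_aa5_has_single_interior_minimum_and_atcase_recovers(self, trajectories):
        tr = trajectories["aa5"]
        from aspdyn.timecourse import _moving_average

        smoothed = _moving_average(tr.asp, 3)
        interior = [
            i
            for i in range(1, len(smoothed) - 1)
            if smoothed[i] < smoothed[i - 1] and smoothed[i] <= smoothed[i + 1]
        ]
        assert len(interior) == 1
        nadir_idx = interior[0]
        assert tr.v_atc[-1] > tr.v_atc[nadir_idx]

    def test_uridine_flips_aa5_to_monotonic_depletion(self, trajectories):
        desc = characterize_rebound(
            trajectories["aa5_uridine"].times, trajectories["aa5_uridine"].asp
        )
        assert desc.monotonic

    def test_succinate_supplement_restores_rebound_and_uridine_reabolishes(
        self, trajectories
    ):
        restored = characterize_rebound(
            trajectories["aa5_rot_succinate"].times, trajectories["aa5_rot_succinate"].asp
        )
        abolished = characterize_rebound(
            trajectories["aa5_rot_succ_uridine"].times,
            trajectories["aa5_rot_succ_uridine"].asp,
        )
        assert not restored.monotonic and restored.rebound_fraction > 0.3
        assert abolished.monotonic

    def test_vehicle_steady_state_is_stable_to_50pct_perturbations(self):
        p = ModelParams()
        fixed = steady_state(p, "vehicle")
        for factor in (0.5, 1.5):
            perturbed = ModelState(fixed.asp * factor, fixed.succ, fixed.utp)
            tr = simulate(p, "vehicle", initial=perturbed)
            assert abs(tr.asp[-1] - fixed.asp) / fixed.asp < 0.05

    def test_reporting_grid_and_determinism(self):
        a = simulate(scenario="aa5", t_end=24.0, dt_report=0.5)
        b = simulate(scenario="aa5", t_end=24.0, dt_report=0.5)
        assert np.allclose(a.times, np.arange(0, 24.1, 0.5))
        assert np.array_equal(a.asp, b.asp)

    def test_invalid_horizon_rejected(self):
        with pytest.raises(ValueError):
            simulate(scenario="aa5", t_end=-1.0)


class TestCrossover:
    def test_identical_trajectories_have_no_crossover(self, trajectories):
        assert crossover_time(trajectories["aa5"], trajectories["aa5"], "asp") is None

    def test_analytic_crossing_interpolated(self, trajectories):
        base = trajectories["aa5"]
        import dataclasses

        a = dataclasses.replace(base, asp=base.times.astype(float))
        b = dataclasses.replace(base, asp=48.0 - base.times)
        assert crossover_time(a, b, "asp") == pytest.approx(24.0, abs=1e-9)

    def test_aa5_overtakes_rotenone_cotreatment(self, trajectories):
        t = crossover_time(trajectories["aa5"], trajectories["aa5_rotenone"], "asp")
        assert t is not None and 0 < t < 72

    def test_mismatched_grids_rejected(self, trajectories):
        short = simulate(scenario="aa5", t_end=24.0)
        with pytest.raises(ValueError, match="grid"):
            crossover_time(trajectories["aa5"], short, "asp")


class TestParams:
    def test_negative_parameter_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(J_asp=-1.0)

    def test_km_range_enforced(self):
        with pytest.raises(ValueError):
            ModelParams(Km_atc=150.0)

    def test_overrides_produce_new_instance(self):
        p = ModelParams().with_overrides(Km_atc=3.0)
        assert p.Km_atc == 3.0
        assert ModelParams().Km_atc == 2.0
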