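"""Quasi-static balance solver, trials, cycle averaging and trace IO."""

from dataclasses import replace

import numpy as np
import pytest

import kneespring as ks
from kneespring.errors import InstabilityError, UnstableTrialError, ValidationError
from kneespring.simulation_engine import solve_timepoint
from kneespring.spring_model import Axis, SpringCondition, SpringHalf

from conftest import grid_law_specimen, noise_free


def linear_restraint(k):
    return lambda d: -k * np.asarray(d)


class TestSolveTimepoint:
    def test_linear_restraint_closed_form(self):
        d = solve_timepoint(100.0, linear_restraint(50.0), None, limit=25.0)
        assert d == pytest.approx(2.0, abs=1e-3)

    def test_zero_load_balances_at_origin(self):
        d = solve_timepoint(0.0, linear_restraint(37.0), None, limit=25.0)
        assert d == pytest.approx(0.0, abs=1e-3)

    def test_dead_zone_spring_closed_form(self):
        spring = SpringCondition(Axis.AP, SpringHalf(20.0, 1.0), SpringHalf(20.0, 1.0))
        d = solve_timepoint(100.0, lambda d: np.zeros_like(np.asarray(d, float)), spring.load, limit=25.0)
        assert d == pytest.approx(6.0, abs=1e-3)  # 100 = 20 * (d - 1)

    def test_unresisted_load_raises_instability(self):
        with pytest.raises(InstabilityError):
            solve_timepoint(100.0, lambda d: np.zeros_like(np.asarray(d, float)), None, limit=25.0)

    def test_agrees_with_fine_displacement_scan(self):
        """Independent oracle: brute-force scan at 1e-3 resolution over
        random monotone restraint/spring pairs."""
        rng = np.random.default_rng(2026)
        grid = np.arange(-25.0, 25.0, 1e-3)
        for _ in range(25):
            k = rng.uniform(5.0, 80.0)
            rate = rng.uniform(5.0, 60.0)
            gap = rng.uniform(0.0, 3.0)
            load = rng.uniform(-200.0, 200.0)
            spring = SpringCondition(Axis.AP, SpringHalf(rate, gap), SpringHalf(rate, gap))
            restraint = linear_restraint(k)
            d = solve_timepoint(load, restraint, spring.load, limit=25.0)
            residual = np.abs(load + restraint(grid) + spring.load(grid))
            d_scan = grid[np.argmin(residual)]
            assert d == pytest.approx(d_scan, abs=2e-3)


class TestRunTrial:
    def test_self_match_spring_reproduces_intact_trace(self, profile):
        ap_truth = SpringCondition(Axis.AP, SpringHalf(35.0, 1.0), SpringHalf(30.0, 0.0))
        tr_truth = SpringCondition(Axis.TR, SpringHalf(0.3, 0.0), SpringHalf(0.7, 0.0))
        specimen = grid_law_specimen(ap_truth, tr_truth)
        intact, resected = ks.make_matched_pair(specimen)
        cfg = ks.TrialConfig(ks.Mode.AP_TR_FORCE, n_cycles=1, seed=0, tolerance=1e-6)
        ref = ks.average_cycles(ks.run_trial(intact, profile, cfg))
        cand = ks.average_cycles(
            ks.run_trial(resected, profile, cfg, ap_spring=ap_truth, tr_spring=tr_truth)
        )
        np.testing.assert_allclose(cand.ap_mm, ref.ap_mm, atol=1e-4)
        np.testing.assert_allclose(cand.tr_deg, ref.tr_deg, atol=1e-4)

    def test_free_resected_knee_is_flagged_unstable(self, profile, fixture_donors):
        specimen = replace(
            fixture_donors[0], residual_stiffness_ap=0.0, residual_stiffness_tr=0.0
        )
        _, resected = ks.make_matched_pair(specimen)
        trace = ks.run_trial(resected, profile, ks.TrialConfig(ks.Mode.AP_TR_FORCE, seed=0))
        assert trace.n_stable == 0
        with pytest.raises(UnstableTrialError):
            ks.average_cycles(trace)

    def test_mode_input_contract(self, profile, fixture_donors):
        intact, _ = ks.make_matched_pair(fixture_donors[0])
        with pytest.raises(ValidationError):
            ks.run_trial(
                intact,
                profile,
                ks.TrialConfig(ks.Mode.AP_TR_FORCE, seed=0),
                tr_displacement_input=np.zeros(profile.n_points),
            )
        with pytest.raises(ValidationError):
            ks.run_trial(
                intact,
                profile,
                ks.TrialConfig(ks.Mode.AP_FORCE_ONLY, seed=0),
                tr_displacement_input=np.zeros(10),  # wrong length
            )

    def test_displacement_controlled_tr_is_reproduced_exactly(self, profile, fixture_donors):
        intact, _ = ks.make_matched_pair(fixture_donors[0])
        imposed = np.sin(2 * np.pi * profile.time_s)
        trace = ks.run_trial(
            intact,
            profile,
            ks.TrialConfig(ks.Mode.AP_FORCE_ONLY, n_cycles=3, seed=5),
            tr_displacement_input=imposed,
        )
        for c in range(3):
            np.testing.assert_array_equal(trace.tr_deg[c], imposed)

    def test_identical_seeds_give_bit_identical_traces(self, profile, fixture_donors):
        intact, _ = ks.make_matched_pair(fixture_donors[1])
        cfg = ks.TrialConfig(ks.Mode.AP_TR_FORCE, seed=99)
        a = ks.run_trial(intact, profile, cfg)
        b = ks.run_trial(intact, profile, cfg)
        np.testing.assert_array_equal(a.ap_mm, b.ap_mm)
        np.testing.assert_array_equal(a.tr_deg, b.tr_deg)
        c = ks.run_trial(intact, profile, replace(cfg, seed=100))
        assert not np.array_equal(a.ap_mm, c.ap_mm)

    def test_trace_csv_round_trip(self, profile, fixture_donors, tmp_path):
        intact, _ = ks.make_matched_pair(fixture_donors[0])
        trace = ks.run_trial(intact, profile, ks.TrialConfig(ks.Mode.AP_TR_FORCE, n_cycles=2, seed=1))
        path = tmp_path / "trace.csv"
        trace.to_csv(path)
        back = ks.KinematicTrace.from_csv(path)
        np.testing.assert_allclose(back.ap_mm, trace.ap_mm)
        np.testing.assert_allclose(back.tr_deg, trace.tr_deg)
        np.testing.assert_array_equal(back.stable, trace.stable)
        assert back.provenance["mode"] == "AP_TR_FORCE"


class TestAverageCycles:
    def test_identical_cycles_average_to_any_cycle(self, profile, fixture_donors):
        specimen = noise_free(fixture_donors[2])
        intact, _ = ks.make_matched_pair(specimen)
        trace = ks.run_trial(intact, profile, ks.TrialConfig(ks.Mode.AP_TR_FORCE, n_cycles=4, seed=0))
        mean = ks.average_cycles(trace)
        np.testing.assert_allclose(mean.ap_mm, trace.ap_mm[0])

    def test_symmetric_values_average_to_zero(self):
        trace = ks.KinematicTrace(
            ap_mm=np.array([[1.5, -2.0], [-1.5, 2.0]]),
            tr_deg=np.zeros((2, 2)),
            stable=np.array([True, True]),
            provenance={},
        )
        np.testing.assert_allclose(ks.average_cycles(trace).ap_mm, [0.0, 0.0])

    def test_unstable_cycles_are_excluded_from_the_mean(self):
        trace = ks.KinematicTrace(
            ap_mm=np.array([[1.0, 1.0], [np.nan, np.nan], [3.0, 3.0]]),
            tr_deg=np.zeros((3, 2)),
            stable=np.array([True, False, True]),
            provenance={},
        )
        np.testing.assert_allclose(ks.average_cycles(trace).ap_mm, [2.0, 2.0])

    def test_ten_cycle_mean_tracks_noise_free_trace(self, profile, fixture_donors):
        """Per-point error of the 10-cycle mean stays within 4 sigma/sqrt(10)
        of the deterministic trace."""
        sd = 0.2
        specimen = replace(fixture_donors[0], cycle_noise_sd_ap_mm=sd, cycle_noise_sd_tr_deg=0.0)
        intact, _ = ks.make_matched_pair(specimen)
        clean = ks.average_cycles(
            ks.run_trial(
                ks.make_matched_pair(noise_free(specimen))[0],
                profile,
                ks.TrialConfig(ks.Mode.AP_TR_FORCE, n_cycles=1, seed=0),
            )
        ).ap_mm
        for seed in range(5):
            noisy = ks.average_cycles(
                ks.run_trial(intact, profile, ks.TrialConfig(ks.Mode.AP_TR_FORCE, n_cycles=10, seed=seed))
            ).ap_mm
            assert np.max(np.abs(noisy - clean)) < 4 * sd / np.sqrt(10)
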