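"""Synthetic cohort generator tests: surfaces, sessions, EMG, outcomes."""

import numpy as np
import pytest

from mapresponder.emg import extract_mep
from mapresponder.mapping import GridSpec, build_map, cog_displacement, percent_change
from mapresponder.synthetic import (
    ExcitabilitySurface,
    FrameSpec,
    ParticipantScenario,
    generate_cohort,
    make_scenarios,
    simulate_emg_frame,
    simulate_outcomes,
    simulate_session,
    simulate_surface,
    slope_for_target_r,
)


def _scenario(**kw):
    base = ExcitabilitySurface(1.5, (3.5, 2.5), 1.0)
    defaults = dict(participant_id="P1", group="experimental", baseline_surface=base)
    defaults.update(kw)
    return ParticipantScenario(**defaults)


class TestSurfaces:
    def test_identity_when_gain_one_no_shift(self):
        sc = _scenario(day2_gain=1.0, day2_shift=(0.0, 0.0))
        assert simulate_surface(sc, "day2") == simulate_surface(sc, "baseline")

    def test_gain_doubles_center_value_at_zero_floor(self):
        base = ExcitabilitySurface(1.5, (3.5, 2.5), 1.0, floor=0.0)
        sc = _scenario(baseline_surface=base, day2_gain=2.0)
        b, d = simulate_surface(sc, "baseline"), simulate_surface(sc, "day2")
        assert d.value(3.5, 2.5) == pytest.approx(2.0 * b.value(3.5, 2.5))

    def test_shift_three_four_five(self):
        sc = _scenario(day2_shift=(3.0, 4.0))
        b, d = simulate_surface(sc, "baseline"), simulate_surface(sc, "day2")
        dist = np.hypot(d.center[0] - b.center[0], d.center[1] - b.center[1])
        assert dist == pytest.approx(5.0)

    def test_unknown_timepoint_raises(self):
        with pytest.raises(ValueError):
            simulate_surface(_scenario(), "day7")

    def test_surface_positive_and_maximal_at_center(self):
        s = ExcitabilitySurface(2.0, (3.0, 2.0), 0.8, floor=0.01)
        xs, ys = np.meshgrid(np.linspace(0, 7, 30), np.linspace(0, 5, 30))
        vals = s.value(xs, ys)
        assert np.all(vals > 0)
        assert s.value(3.0, 2.0) >= vals.max()


class TestSessions:
    def test_protocol_count_and_bounds(self, grid):
        events = simulate_session(_scenario().baseline_surface, grid, 90, seed=1)
        assert len(events) == 90
        assert all(0 <= e.x <= 7 and 0 <= e.y <= 5 for e in events)

    def test_every_site_stimulated(self, grid):
        events = simulate_session(
            _scenario().baseline_surface, grid, 90, seed=2, jitter_cm=0.0
        )
        coords = {(round(e.x, 3), round(e.y, 3)) for e in events}
        sites = {(round(x, 3), round(y, 3)) for x, y in grid.site_coordinates()}
        assert sites <= coords

    def test_undersized_session_raises(self, grid):
        with pytest.raises(ValueError, match="cover"):
            simulate_session(_scenario().baseline_surface, grid, 47, seed=1)

    def test_noise_free_amplitudes_equal_surface(self, grid):
        surface = _scenario().baseline_surface
        events = simulate_session(surface, grid, 90, seed=3, trial_noise_sigma=0.0)
        for e in events:
            assert e.amplitude == pytest.approx(float(surface.value(e.x, e.y)))

    def test_lognormal_trial_noise_mean(self, grid):
        # E[S * eps] = S * exp(sigma^2 / 2) for eps ~ LogNormal(0, sigma^2)
        surface = ExcitabilitySurface(1.0, (3.5, 2.5), 2.0, floor=0.5)
        sigma = 0.3
        events = simulate_session(
            surface, grid, 10_000, seed=4, trial_noise_sigma=sigma, jitter_cm=0.0
        )
        ratios = [e.amplitude / float(surface.value(e.x, e.y)) for e in events]
        assert np.mean(ratios) == pytest.approx(np.exp(sigma**2 / 2), rel=0.02)


class TestEmgFrames:
    def test_zero_amplitude_background_only(self):
        spec = FrameSpec(background_rms_mv=0.05)
        frame = simulate_emg_frame(0.0, spec, seed=1)
        m = extract_mep(frame)
        # peak-to-peak of pure background stays within a few RMS multiples
        assert m.amplitude < 8 * spec.background_rms_mv
        assert m.pre_stim_rms == pytest.approx(0.05, rel=0.35)

    def test_noise_free_round_trip_exact(self):
        frame = simulate_emg_frame(1.0, FrameSpec(background_rms_mv=0.0), seed=1)
        assert extract_mep(frame).amplitude == pytest.approx(1.0, abs=1e-12)

    def test_mean_recovery_under_background_noise(self):
        spec = FrameSpec(background_rms_mv=0.05)
        recovered = [
            extract_mep(simulate_emg_frame(1.0, spec, seed=s)).amplitude
            for s in range(500)
        ]
        assert np.mean(recovered) == pytest.approx(1.0, rel=0.10)

    def test_stim_onset_recorded(self):
        frame = simulate_emg_frame(0.5, FrameSpec(), seed=0)
        assert frame.stim_onset_index == 200  # 100 ms at 2 kHz
        assert frame.sampling_rate == 2000.0


class TestOutcomes:
    def test_control_day2_pain_profile(self):
        sc = _scenario(group="control")
        for seed in range(30):
            panel = simulate_outcomes(sc, 5.0, seed=seed)
            assert panel["day2"]["nrs_rest"] == 0.0
            assert panel["day2"]["soreness"] in (0.0, 1.0)
            assert 0 <= panel["day2"]["lefs"] <= 80

    def test_experimental_ranges_respected(self):
        sc = _scenario()
        for seed in range(30):
            panel = simulate_outcomes(sc, 100.0, seed=seed)
            d = panel["day2"]
            assert 0 <= d["nrs_rest"] <= 10 and 0 <= d["nrs_reach"] <= 10
            assert 0 <= d["soreness"] <= 6 and d["soreness"] == int(d["soreness"])
            assert 0 <= d["lefs"] <= 80
            assert d["pain_area"] >= 0

    def test_zero_slope_gives_null_correlation(self):
        sc = _scenario(ppt_slope=0.0)
        rng = np.random.default_rng(7)
        dv = rng.normal(0, 100, 500)
        dppt = []
        for i, v in enumerate(dv):
            p = simulate_outcomes(sc, v, seed=1000 + i)
            dppt.append(p["day2"]["ppt_kpa"] - p["baseline"]["ppt_kpa"])
        r = np.corrcoef(dv, dppt)[0, 1]
        assert abs(r) < 0.1  # sampling error band at n = 500

    def test_slope_for_target_r_recovers_programmed_correlation(self):
        # bivariate sampling oracle: mean sample r over 100 replicates of
        # n = 200 should recover the programmed population r within 0.05
        target, sd_dv, sd_noise = -0.56, 120.0, 80.0
        slope = slope_for_target_r(target, sd_dv, sd_noise)
        sc = _scenario(ppt_slope=slope, ppt_noise_sd=sd_noise)
        rng = np.random.default_rng(11)
        rs = []
        for _ in range(100):
            dv = rng.normal(0, sd_dv, 200)
            dppt = slope * dv + rng.normal(0, sd_noise, 200)
            rs.append(np.corrcoef(dv, dppt)[0, 1])
        assert np.mean(rs) == pytest.approx(target, abs=0.05)
        # and through the full outcome generator
        dppt2 = []
        dv = rng.normal(0, sd_dv, 200)
        for i, v in enumerate(dv):
            p = simulate_outcomes(sc, v, seed=5000 + i)
            dppt2.append(p["day2"]["ppt_kpa"] - p["baseline"]["ppt_kpa"])
        r = np.corrcoef(dv, dppt2)[0, 1]
        assert r == pytest.approx(target, abs=0.15)


class TestCohort:
    def test_fixed_seed_reproduces_cohort_exactly(self):
        def build():
            scens = make_scenarios(3, 2, seed=5)
            return generate_cohort(scens, seed=11, with_emg=True)

        c1, c2 = build(), build()
        for key in c1["events"]:
            a1 = [(e.x, e.y, e.amplitude) for e in c1["events"][key]]
            a2 = [(e.x, e.y, e.amplitude) for e in c2["events"][key]]
            assert a1 == a2
        for key in c1["frames"]:
            for f1, f2 in zip(c1["frames"][key], c2["frames"][key]):
                assert np.array_equal(f1.samples, f2.samples)
        assert c1["outcomes"] == c2["outcomes"]

    def test_group_sizes_and_regime_mix(self):
        scens = make_scenarios(26, 10, seed=0)
        assert sum(s.group == "experimental" for s in scens) == 26
        assert sum(s.group == "control" for s in scens) == 10
        regimes = [s.regime for s in scens if s.group == "experimental"]
        assert regimes.count("facilitation") == 12
        assert regimes.count("depression") == 12
        assert regimes.count("none") == 2
        for s in scens:
            assert s.day2_gain > 0 and s.day2_spread_factor > 0

    def test_noise_free_pipeline_recovers_gain_as_volume_ratio(self, grid):
        # zero-floor surface: everything scales, so the volume ratio is exact
        base = ExcitabilitySurface(1.5, (3.5, 2.5), 1.0, floor=0.0)
        for gain in (0.5, 2.0):
            sc = _scenario(baseline_surface=base, day2_gain=gain)
            vols = {}
            for tp in ("baseline", "day2"):
                events = simulate_session(
                    simulate_surface(sc, tp), grid, seed=9, trial_noise_sigma=0.0
                )
                frames = [
                    simulate_emg_frame(e.amplitude, FrameSpec(background_rms_mv=0.0), seed=0)
                    for e in events
                ]
                amps = [extract_mep(f).amplitude for f in frames]
                rebuilt = [
                    type(e)(x=e.x, y=e.y, amplitude=a, trial=e.trial)
                    for e, a in zip(events, amps)
                ]
                vols[tp] = build_map(rebuilt, grid).volume
            assert vols["day2"] / vols["baseline"] == pytest.approx(gain, rel=0.05)

    def test_programmed_cog_shift_recovered(self, grid):
        sc = _scenario(
            baseline_surface=ExcitabilitySurface(1.5, (3.1, 2.2), 0.9),
            day2_shift=(0.8, 0.6),
        )
        cogs = {}
        for tp in ("baseline", "day2"):
            events = simulate_session(
                simulate_surface(sc, tp), grid, seed=13, trial_noise_sigma=0.0
            )
            cogs[tp] = build_map(events, grid).cog
        ed = cog_displacement(cogs["baseline"], cogs["day2"]).ed
        assert ed == pytest.approx(1.0, abs=0.15)
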