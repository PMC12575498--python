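"""Compression and walking scenarios: protocols, invariants and reporting."""

import json

import numpy as np
import pandas as pd
import pytest

from gelshell import (
    GAIT_PRESETS,
    LoadingSignal,
    ScenarioConfig,
    build_walking_signal,
    report_scenario,
    run_compression,
    run_walking,
    scenario_default_profile,
)
from gelshell.scenarios import StressTimeSeries, load_config, solve_resting_state


@pytest.fixture(scope="module")
def config():
    return ScenarioConfig(profile=scenario_default_profile(48))


@pytest.fixture(scope="module")
def compression16(config):
    return run_compression(config, n_steps=16)


@pytest.fixture(scope="module")
def compression32(config):
    return run_compression(config, n_steps=32)


@pytest.fixture(scope="module")
def walking_medium(config):
    preset = GAIT_PRESETS["medium"]
    signal = build_walking_signal(
        preset, duration=1.0 + 3 * preset.T_period, dt=preset.T_period / 24
    )
    return run_walking(config, signal)


class TestScenarioConfig:
    def test_validation(self):
        prof = scenario_default_profile(48)
        with pytest.raises(ValueError):
            ScenarioConfig(profile=prof, tilt_deg=95.0)
        with pytest.raises(ValueError):
            ScenarioConfig(profile=prof, ribcage_radius=-1.0)
        with pytest.raises(ValueError):
            ScenarioConfig(profile=prof, tracked_points={"bad": 1.5})
        with pytest.raises(ValueError):
            ScenarioConfig(profile=prof, confinement_pressure=-0.1)

    def test_cover_radius_from_area(self):
        cfg = ScenarioConfig(
            profile=scenario_default_profile(48), covered_area=np.pi * 60.0**2
        )
        assert cfg.cover_radius == pytest.approx(60.0)

    def test_tilt_reduces_axial_gravity(self, config):
        assert config.axial_gravity_factor == pytest.approx(
            np.sin(np.deg2rad(15.0))
        )

    def test_resting_state_height_reduction_in_calibration_band(self, config):
        """Stage 1 wrap: confinement + gravity reduce the implant height by
        5-15% relative to the free shape."""
        st = solve_resting_state(config)
        reduction = 1.0 - st.summary()[0] / 35.0
        assert 0.05 < reduction < 0.15


class TestCompression:
    def test_epochs_ordered_within_cycle(self, compression16):
        e = compression16.epochs
        assert e["t0"] < e["t1"] < e["t2"] <= 2.0

    def test_maximum_depth_is_ten_mm(self, compression16):
        assert compression16.drive.max() == pytest.approx(10.0, abs=1e-9)
        assert compression16.drive.min() == 0.0

    def test_contact_and_detachment_alternate(self, compression32):
        # raised-cosine travel: the device is clear of the implant for the
        # first/last quarter of each cycle and indents in between
        d = compression32.drive
        assert np.any(d == 0.0) and np.any(d > 0.0)
        assert d[0] == 0.0 and d[-1] == 0.0

    def test_detached_phase_recovers_resting_stress(self, compression16):
        for s in compression16.stresses.values():
            detached = compression16.drive <= 0
            assert np.max(np.abs(s[detached] - s[0])) < 1e-6

    def test_front_rear_stress_crossover_under_gravity(self, compression32):
        """Shallow contact loads the rear point more; deep indentation makes
        the front ring point dominate."""
        s1 = compression32.stresses["node1"]
        s2 = compression32.stresses["node2"]
        d = compression32.drive
        shallow = (d > 0.0) & (d < 3.0)
        deep = d > 9.0
        assert np.any(shallow) and np.any(deep)
        assert np.any(s1[shallow] < s2[shallow])
        assert np.all(s1[deep] > s2[deep])

    def test_peak_stress_monotone_in_depth(self, config):
        peaks = []
        for depth in (2.0, 5.0, 10.0):
            series = run_compression(config, depth_max=depth, n_steps=12)
            peaks.append(max(s.max() for s in series.stresses.values()))
        assert peaks[0] <= peaks[1] + 1e-9
        assert peaks[1] <= peaks[2] + 1e-9

    def test_quasi_static_step_consistency(self, compression16, compression32):
        peak16 = max(s.max() for s in compression16.stresses.values())
        peak32 = max(s.max() for s in compression32.stresses.values())
        assert abs(peak32 - peak16) / peak16 < 0.01

    def test_volume_conserved_every_step(self, compression16):
        assert np.all(compression16.volume_error < 1e-3)

    def test_all_steps_converged(self, compression16):
        assert compression16.converged.all()

    def test_snapshots_at_epochs(self, compression16):
        assert set(compression16.snapshots) == {"t0", "t1", "t2"}
        t0_T = compression16.snapshots["t0"].summary()[0]
        t2_T = compression16.snapshots["t2"].summary()[0]
        assert t2_T < t0_T  # deepest contact flattens the implant


class TestWalking:
    def test_static_limit_constant_stress(self, config):
        preset = GAIT_PRESETS["slow"]
        base = build_walking_signal(preset, duration=1.5, dt=preset.T_period / 24)
        still = LoadingSignal(
            time=base.time,
            Dx=base.Dx,
            Dy=np.zeros_like(base.Dy),
            d2Dy=np.zeros_like(base.d2Dy),
            preset=preset,
        )
        series = run_walking(config, still)
        for s in series.stresses.values():
            np.testing.assert_allclose(s, s[0], atol=1e-6)

    def test_post_transient_periodicity(self, walking_medium):
        """After the transient window the node-3 stress is periodic with the
        gait period (autocorrelation peak within 1%)."""
        T = GAIT_PRESETS["medium"].T_period
        t = walking_medium.time
        s = walking_medium.stresses["node3"]
        mask = t >= 1.0
        ts, ss = t[mask], s[mask] - np.mean(s[mask])
        dense_t = np.arange(ts[0], ts[-1], T / 200)
        dense_s = np.interp(dense_t, ts, ss)
        lags = np.arange(int(0.8 * 200), int(1.2 * 200))
        ac = [
            np.corrcoef(dense_s[: -lag or None], dense_s[lag:])[0, 1]
            for lag in lags
        ]
        best_lag = lags[int(np.argmax(ac))] * (T / 200)
        assert best_lag == pytest.approx(T, rel=0.01)

    def test_post_transient_stats_reported(self, walking_medium):
        stats = walking_medium.post_transient["node3"]
        assert stats["mean_kPa"] > 0
        assert 0 < stats["fluctuation_amplitude_kPa"] < stats["mean_kPa"]

    def test_effective_gravity_drive_matches_signal(self, walking_medium, config):
        preset = GAIT_PRESETS["medium"]
        omega2 = (2 * np.pi / preset.T_period) ** 2
        g_expected = (
            config.gravity + omega2 * preset.A * np.cos(
                2 * np.pi * walking_medium.time / preset.T_period
            )
        ) * config.axial_gravity_factor
        np.testing.assert_allclose(walking_medium.drive, g_expected, rtol=1e-9)

    def test_volume_conserved_every_step(self, walking_medium):
        assert np.all(walking_medium.volume_error < 1e-3)


class TestReporting:
    def test_round_trip_and_summary_consistency(self, compression16, tmp_path):
        files = report_scenario(compression16, tmp_path / "out")
        frame = pd.read_csv(files["csv"])
        for label, s in compression16.stresses.items():
            np.testing.assert_allclose(frame[f"vm_{label}_kPa"], s, atol=1e-12)
        summary = json.loads(files["json"].read_text())
        csv_peak = max(
            frame[f"vm_{k}_kPa"].max() for k in compression16.stresses
        )
        assert summary["peak_stress_kPa"] == pytest.approx(csv_peak, abs=1e-9)
        assert summary["all_steps_converged"] is True
        assert (tmp_path / "out" / "shape_t2.stl").exists()

    def test_empty_series_rejected(self, tmp_path):
        empty = StressTimeSeries(
            time=np.empty(0),
            stresses={},
            drive=np.empty(0),
            drive_label="depth_mm",
            converged=np.empty(0, dtype=bool),
        )
        with pytest.raises(ValueError, match="empty"):
            report_scenario(empty, tmp_path / "out")


class TestYamlConfig:
    def test_load_config_blocks(self, tmp_path):
        cfg_text = """
geometry:
  radius_mm: 40.0
  height_mm: 30.0
  volume_cc: 100.0
  n_samples: 48
  label: test100
materials:
  C10_shell_kPa: 95.0
scenario:
  gel_fraction: 0.95
  tilt_deg: 10.0
  confinement_kPa: 0.8
  tracked_points: {apex: 0.0, ring: 0.4}
"""
        path = tmp_path / "cfg.yaml"
        path.write_text(cfg_text)
        cfg = load_config(path)
        assert cfg.profile.implant_id == "test100"
        assert cfg.profile.enclosed_volume() == pytest.approx(100_000.0, rel=1e-3)
        assert cfg.materials.C10_shell == 95.0
        assert cfg.gel_fraction == 0.95
        assert cfg.tilt_deg == 10.0
        assert cfg.tracked_points == {"apex": 0.0, "ring": 0.4}

    def test_empty_config_gives_defaults(self, tmp_path):
        path = tmp_path / "empty.yaml"
        path.write_text("")
        cfg = load_config(path)
        assert cfg.profile.implant_id == "125cc"
        assert cfg.ribcage_radius == 97.5
        assert cfg.confinement_pressure == 0.5
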