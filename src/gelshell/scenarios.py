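"""Loading scenarios: sinusoidal compression and walking.

Both scenarios place the implant in a simplified anatomical environment:
it rests on the ribcage, modeled as a rigid sphere of radius 97.5 mm, under
a fat/muscle cover reduced to a uniform inward confinement pressure on the
free shell surface.  The implant axis is tilted 15 deg from the ground
plane in the standing position; in the axisymmetric reduction the tilt
enters as the gravity component along the symmetry axis.

Compression: a rigid flat-bottomed disc of radius 45 mm starts 10 mm above
the wrapped implant (Stage 1 resting state) and travels with a raised-cosine
profile of 20 mm peak travel, alternating contact/detachment with a maximum
indentation depth of 10 mm.  Walking: the support's vertical oscillation
Dy(t) = A cos(2 pi t / T) is rendered as an effective axial gravity
g_eff(t) = g + (2 pi / T)^2 A cos(2 pi t / T) in the implant frame (the
uniform forward velocity Dx = v t contributes no acceleration).

Each scenario is a warm-started quasi-static sweep of the equilibrium
solver, recording von Mises stress histories at tracked material points on
the shell (arc-length fractions of the reference meridian).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .gait import LoadingSignal
from .geometry import AxisymProfile, build_reference_profile
from .materials import GelFill, MaterialSet
from .solver import (
    DeformedState,
    EquilibriumError,
    GRAVITY,
    Indenter,
    ObstacleSet,
    SolverOptions,
    Sphere,
    solve_equilibrium,
    stress_at,
)

__all__ = [
    "ScenarioConfig",
    "StressTimeSeries",
    "run_compression",
    "run_walking",
    "report_scenario",
    "scenario_default_profile",
    "load_config",
]

logger = logging.getLogger("gelshell")

#: Default tracked material points (arc-length fractions, apex -> base
#: center): front of the dome under the device, rear side near the ribcage,
#: and the bottom region.
DEFAULT_TRACKED_POINTS = {"node1": 0.33, "node2": 0.70, "node3": 0.95}


def scenario_default_profile(n_samples: int = 64) -> AxisymProfile:
    """Representative 125 cc implant for the loading scenarios.

    Radius/height follow the aspect ratio of the characterization sizes;
    shell thickness varies linearly from 0.4 mm at the apex to 0.6 mm at
    the base (non-uniform by design).
    """
    prof = build_reference_profile(
        radius=42.0,
        height=35.0,
        nominal_volume=125_000.0,
        n_samples=n_samples,
        implant_id="125cc",
    )
    t = 0.4 + 0.2 * prof.arc_fractions()
    return replace(prof, shell_thickness=t)


@dataclass
class ScenarioConfig:
    """Anatomical environment and tracking configuration for both scenarios."""

    profile: AxisymProfile
    materials: MaterialSet = MaterialSet()
    gel_fraction: float = 1.0
    ribcage_radius: float = 97.5  # mm
    tilt_deg: float = 15.0
    confinement_pressure: float = 0.5  # kPa
    cover_fraction: float = 0.35  # meridian arc fraction under the cover
    covered_area: Optional[float] = None  # mm^2 (metadata)
    tracked_points: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRACKED_POINTS)
    )
    gravity: float = GRAVITY
    solver_options: SolverOptions = SolverOptions()

    def __post_init__(self) -> None:
        if not 0.0 <= self.tilt_deg < 90.0:
            raise ValueError("tilt angle must lie in [0, 90) degrees")
        if self.ribcage_radius <= 0:
            raise ValueError("ribcage radius must be positive")
        for name, frac in self.tracked_points.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"tracked point '{name}' fraction outside [0, 1]")
        if self.confinement_pressure < 0:
            raise ValueError("confinement pressure must be non-negative")

    @property
    def axial_gravity_factor(self) -> float:
        """Component of a vertical acceleration along the tilted implant axis."""
        return float(np.sin(np.deg2rad(self.tilt_deg))) if self.tilt_deg else 1.0

    @property
    def cover_radius(self) -> Optional[float]:
        """Equivalent cover radius sqrt(A/pi) of the fat/muscle plate, mm."""
        if self.covered_area is None:
            return None
        return float(np.sqrt(self.covered_area / np.pi))

    @property
    def fill(self) -> GelFill:
        return GelFill(self.gel_fraction, self.profile.nominal_volume)

    def ribcage(self) -> Sphere:
        """Support sphere with its top point at z = 0."""
        return Sphere(center_z=-self.ribcage_radius, radius=self.ribcage_radius)


@dataclass
class StressTimeSeries:
    """Stress histories at tracked points over a quasi-static sweep.

    ``drive`` is the scenario driving quantity per step: indenter depth (mm)
    for compression, effective axial gravity (mm/s^2) for walking.
    """

    time: np.ndarray
    stresses: dict[str, np.ndarray]  # label -> von Mises kPa
    drive: np.ndarray
    drive_label: str
    converged: np.ndarray
    volume_error: np.ndarray = field(default_factory=lambda: np.empty(0))
    epochs: dict[str, float] = field(default_factory=dict)
    post_transient: dict[str, dict[str, float]] = field(default_factory=dict)
    snapshots: dict[str, DeformedState] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.time.size
        if self.drive.size != n or self.converged.size != n:
            raise ValueError("drive/converged must match the time grid")
        for label, s in self.stresses.items():
            if s.size != n:
                raise ValueError(f"stress series '{label}' length mismatch")
        if self.epochs:
            t0, t1, t2 = (self.epochs[k] for k in ("t0", "t1", "t2"))
            if not t0 < t1 < t2:
                raise ValueError("epochs must satisfy t0 < t1 < t2")

    def peak(self) -> tuple[str, float, float]:
        """(point label, time, value) of the global stress maximum."""
        best = None
        for label, s in self.stresses.items():
            i = int(np.argmax(s))
            if best is None or s[i] > best[2]:
                best = (label, float(self.time[i]), float(s[i]))
        return best

    def to_frame(self) -> pd.DataFrame:
        cols = {"time_s": self.time, self.drive_label: self.drive}
        for label, s in self.stresses.items():
            cols[f"vm_{label}_kPa"] = s
        cols["converged"] = self.converged.astype(int)
        return pd.DataFrame(cols)


def _sweep(
    config: ScenarioConfig,
    times: np.ndarray,
    obstacles_at,
    gravity_at,
    init: DeformedState,
    drive: np.ndarray,
    drive_label: str,
) -> StressTimeSeries:
    """Warm-started quasi-static sweep; halves increments on failed steps."""
    stresses = {k: np.empty(times.size) for k in config.tracked_points}
    converged = np.zeros(times.size, dtype=bool)
    vol_err = np.zeros(times.size)
    v_gel = config.gel_fraction * config.profile.nominal_volume
    state = init
    prev_t = None
    for i, t in enumerate(times):
        try:
            state = _solve_step(config, obstacles_at(t), gravity_at(t), state)
        except EquilibriumError:
            # retry through intermediate sub-steps with halved increments
            if prev_t is None:
                raise
            ok = False
            for n_sub in (2, 4, 8):
                try:
                    sub_state = state
                    for tau in np.linspace(prev_t, t, n_sub + 1)[1:]:
                        sub_state = _solve_step(
                            config, obstacles_at(tau), gravity_at(tau), sub_state
                        )
                    state = sub_state
                    ok = True
                    break
                except EquilibriumError:
                    continue
            if not ok:
                partial = StressTimeSeries(
                    time=times[:i],
                    stresses={k: v[:i] for k, v in stresses.items()},
                    drive=drive[:i],
                    drive_label=drive_label,
                    converged=converged[:i],
                )
                raise EquilibriumError(
                    f"step {i} (t = {t:.4g} s) failed to converge after "
                    "increment halving"
                ) from None
        for label, frac in config.tracked_points.items():
            stresses[label][i] = stress_at(state, frac)
        converged[i] = state.converged
        vol_err[i] = abs(state.volume - v_gel) / v_gel
        prev_t = t
        logger.info(
            "step %d/%d t=%.4g %s=%.4g max_vm=%.4g kPa",
            i + 1,
            times.size,
            t,
            drive_label,
            drive[i],
            max(s[i] for s in stresses.values()),
        )
    return StressTimeSeries(
        time=times,
        stresses=stresses,
        drive=drive,
        drive_label=drive_label,
        converged=converged,
        volume_error=vol_err,
    )


def _solve_step(config, obstacles, gravity, init):
    return solve_equilibrium(
        config.profile,
        config.materials,
        config.fill,
        obstacles,
        gravity=gravity,
        confinement_pressure=config.confinement_pressure,
        init=init,
        options=config.solver_options,
        cover_fraction=config.cover_fraction,
    )


def solve_resting_state(config: ScenarioConfig) -> DeformedState:
    """Stage 1: settle the implant on the ribcage under gravity and
    confinement (the wrapped, clinically implanted configuration)."""
    g_ax = config.gravity * config.axial_gravity_factor
    obstacles = ObstacleSet([config.ribcage()])
    # ramp confinement/gravity robustly from the reference shape
    return solve_equilibrium(
        config.profile,
        config.materials,
        config.fill,
        obstacles,
        gravity=g_ax,
        confinement_pressure=config.confinement_pressure,
        options=config.solver_options,
        cover_fraction=config.cover_fraction,
    )


def run_compression(
    config: ScenarioConfig,
    depth_max: float = 10.0,
    standoff: float = 10.0,
    indenter_radius: float = 45.0,
    period: float = 2.0,
    n_steps: int = 32,
    n_periods: int = 1,
) -> StressTimeSeries:
    """Two-stage sinusoidal compression protocol.

    Stage 1 settles the implant between ribcage and cover; Stage 2 drives a
    flat-bottomed rigid disc with raised-cosine travel
    ``travel(t) = (standoff + depth_max)/2 * (1 - cos(2 pi t / period))``
    starting ``standoff`` mm above the wrapped implant, so the device
    alternately contacts and detaches with maximum depth ``depth_max``.

    The device is farthest at t0 = 0, deepest at t2 = period/2; t1 is the
    midpoint of the descending contact phase.
    """
    if depth_max <= 0 or standoff < 0 or period <= 0:
        raise ValueError("depth_max, standoff and period must be positive")
    stage1 = solve_resting_state(config)
    z_top = stage1.summary()[0]
    g_ax = config.gravity * config.axial_gravity_factor
    ribcage = config.ribcage()

    times = np.linspace(0.0, n_periods * period, n_periods * n_steps + 1)
    amp = 0.5 * (standoff + depth_max)

    def travel(t: float) -> float:
        return amp * (1.0 - np.cos(2.0 * np.pi * t / period))

    def bottom(t: float) -> float:
        return z_top + standoff - travel(t)

    depth = np.array([max(0.0, z_top - bottom(t)) for t in times])
    series = _sweep(
        config,
        times,
        obstacles_at=lambda t: ObstacleSet(
            [ribcage, Indenter(indenter_radius, bottom(t))]
        ),
        gravity_at=lambda t: g_ax,
        init=stage1,
        drive=depth,
        drive_label="depth_mm",
    )
    # epoch markers within the first cycle: contact begins when travel =
    # standoff, i.e. cos(2 pi t/Tc) = 1 - 2 standoff/(standoff+depth)
    t_contact = (
        period / (2.0 * np.pi) * np.arccos(1.0 - standoff / amp)
        if standoff < 2 * amp
        else period / 4.0
    )
    series.epochs = {
        "t0": 0.0,
        "t1": 0.5 * (t_contact + period / 2.0),
        "t2": period / 2.0,
    }
    for name in ("t0", "t1", "t2"):
        i = int(np.argmin(np.abs(times - series.epochs[name])))
        series.snapshots[name] = _resolve_snapshot(
            config, ribcage, indenter_radius, bottom(times[i]), g_ax, stage1
        )
    return series


def _resolve_snapshot(config, ribcage, r_ind, bottom_z, g_ax, init):
    return _solve_step(
        config,
        ObstacleSet([ribcage, Indenter(r_ind, bottom_z)]),
        g_ax,
        init,
    )


def run_walking(
    config: ScenarioConfig,
    signal: LoadingSignal,
    transient_window: float = 1.0,
) -> StressTimeSeries:
    """Walking sweep: effective axial gravity from the vertical gait harmonic.

    The support's prescribed motion Dy(t) adds its frame acceleration to
    gravity, g_eff(t) = g - d2Dy(t) = g + (2 pi/T)^2 A cos(2 pi t/T); the
    axial component loads the axisymmetric model.  The uniform forward
    velocity adds no acceleration and is carried as trajectory metadata
    only.  Post-transient mean and fluctuation amplitude (half peak-to-peak)
    per tracked point are reported with the configurable transient window.
    """
    stage1 = solve_resting_state(config)
    g_eff = config.gravity - signal.d2Dy  # vertical effective gravity
    g_ax = g_eff * config.axial_gravity_factor
    ribcage_set = ObstacleSet([config.ribcage()])
    times = signal.time
    if times.size < 2:
        raise ValueError("loading signal must cover at least two time steps")

    g_interp = lambda t: float(np.interp(t, times, g_ax))  # noqa: E731
    series = _sweep(
        config,
        times,
        obstacles_at=lambda t: ribcage_set,
        gravity_at=g_interp,
        init=stage1,
        drive=g_ax,
        drive_label="g_eff_mm_s2",
    )
    mask = times >= transient_window
    if np.any(mask):
        for label, s in series.stresses.items():
            post = s[mask]
            series.post_transient[label] = {
                "mean_kPa": float(np.mean(post)),
                "fluctuation_amplitude_kPa": float(0.5 * (post.max() - post.min())),
            }
    return series


def report_scenario(
    series: StressTimeSeries,
    out_path: Union[str, Path],
    write_snapshots: bool = True,
) -> dict[str, Path]:
    """Write CSV time series, JSON summary and optional shape snapshots.

    Returns a dict of the written file paths.  The JSON summary contains the
    peak stress and its location/time, the epoch markers and post-transient
    statistics where available.
    """
    if series.time.size == 0:
        raise ValueError("empty stress time series")
    out = Path(out_path)
    try:
        out.mkdir(parents=True, exist_ok=True)
        files: dict[str, Path] = {}
        csv_path = out / "stress_timeseries.csv"
        series.to_frame().to_csv(csv_path, index=False)
        files["csv"] = csv_path
        label, t_peak, v_peak = series.peak()
        summary = {
            "peak_stress_kPa": v_peak,
            "peak_point": label,
            "peak_time_s": t_peak,
            "drive_label": series.drive_label,
            "epochs_s": series.epochs,
            "post_transient": series.post_transient,
            "all_steps_converged": bool(np.all(series.converged)),
        }
        json_path = out / "summary.json"
        json_path.write_text(json.dumps(summary, indent=2))
        files["json"] = json_path
        if write_snapshots:
            for name, state in series.snapshots.items():
                mesh_path = out / f"shape_{name}.stl"
                state.to_mesh().save(mesh_path)
                files[f"snapshot_{name}"] = mesh_path
        return files
    except OSError as err:
        raise OSError(f"failed writing scenario report under '{out}': {err}") from err


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

def load_config(path: Union[str, Path]) -> ScenarioConfig:
    """Build a ScenarioConfig from a YAML file.

    Recognized blocks: ``geometry:`` (radius/height/volume_cc or the
    default 125 cc implant), ``materials:`` (Table-style coefficient names)
    and ``scenario:`` (environment and tracked points).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    geo = raw.get("geometry", {})
    if geo:
        prof = build_reference_profile(
            radius=float(geo["radius_mm"]),
            height=float(geo["height_mm"]),
            nominal_volume=float(geo["volume_cc"]) * 1000.0,
            n_samples=int(geo.get("n_samples", 64)),
            shell_thickness=geo.get("thickness_mm", 0.5),
            implant_id=str(geo.get("label", "")),
        )
    else:
        prof = scenario_default_profile()
    mat = raw.get("materials", {})
    materials = MaterialSet(
        C10_shell=float(mat.get("C10_shell_kPa", 100.702)),
        C10_gel=float(mat.get("C10_gel_kPa", 0.025)),
        E_tissue=float(mat.get("E_tissue_kPa", 208.0)),
        nu_tissue=float(mat.get("nu_tissue", 0.47)),
        gel_density=float(mat.get("gel_density_tonne_mm3", 9.7e-10)),
        shell_thickness=float(mat.get("shell_thickness_mm", 0.5)),
    )
    sc = raw.get("scenario", {})
    return ScenarioConfig(
        profile=prof,
        materials=materials,
        gel_fraction=float(sc.get("gel_fraction", 1.0)),
        ribcage_radius=float(sc.get("ribcage_radius_mm", 97.5)),
        tilt_deg=float(sc.get("tilt_deg", 15.0)),
        confinement_pressure=float(sc.get("confinement_kPa", 0.5)),
        cover_fraction=float(sc.get("cover_fraction", 0.35)),
        covered_area=(
            float(sc["covered_area_mm2"]) if sc.get("covered_area_mm2") else None
        ),
        tracked_points=dict(sc.get("tracked_points", DEFAULT_TRACKED_POINTS)),
    )
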