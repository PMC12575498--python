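"""Gait trajectories and single-harmonic walking load signals.

Vertical chest-marker trajectories during walking are quasi-periodic; the
walking scenarios load the implant with their dominant harmonic only.  The
pipeline is: FFT of the de-meaned vertical position, pick the dominant
non-DC spectral bin (with 3-point quadratic refinement for off-bin
frequencies), then linear least squares of the signal onto {cos, sin} at
that frequency to get amplitude and phase.  The walking displacement
functions are

    Dx(t) = v * t,          Dy(t) = A * cos(2 pi t / T)

with the forward velocity v and the (A, T) presets per walking speed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

__all__ = [
    "GaitTrace",
    "GaitPreset",
    "LoadingSignal",
    "GAIT_PRESETS",
    "extract_main_component",
    "build_walking_signal",
    "generate_synthetic_gait",
]


@dataclass(frozen=True)
class GaitPreset:
    """Single-harmonic walking condition: forward velocity, vertical
    amplitude and period."""

    label: str
    v: float  # forward velocity, mm/s
    A: float  # vertical amplitude, mm
    T_period: float  # s

    def __post_init__(self) -> None:
        if self.v <= 0 or self.A <= 0 or self.T_period <= 0:
            raise ValueError("v, A and T_period must be positive")


#: Walking presets per speed (forward velocity mm/s, vertical amplitude mm,
#: period s) extracted from chest-marker gait data.
GAIT_PRESETS: dict[str, GaitPreset] = {
    "slow": GaitPreset("slow", v=240.0, A=6.385, T_period=1.474),
    "medium": GaitPreset("medium", v=549.0, A=11.070, T_period=0.851),
    "fast": GaitPreset("fast", v=986.0, A=17.313, T_period=0.609),
}


@dataclass
class GaitTrace:
    """Uniformly sampled vertical (and optional forward) marker trajectory."""

    time: np.ndarray  # s
    y: np.ndarray  # vertical position, mm
    x: np.ndarray | None = None  # forward position, mm

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.y.shape:
            raise ValueError("time and y must be 1-D arrays of equal length")
        if self.time.size < 8:
            raise ValueError("trace too short")
        dt = np.diff(self.time)
        if np.max(np.abs(dt - dt[0])) > 1e-9:
            raise ValueError("sampling grid must be uniform")
        if dt[0] <= 0:
            raise ValueError("time must be strictly increasing")
        if self.x is not None:
            self.x = np.asarray(self.x, dtype=float)
            if self.x.shape != self.time.shape:
                raise ValueError("x must match the time grid")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def to_csv(self, path: Union[str, Path]) -> None:
        cols = {"time_s": self.time, "y_mm": self.y}
        if self.x is not None:
            cols["x_mm"] = self.x
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "GaitTrace":
        df = pd.read_csv(path)
        if "time_s" not in df or "y_mm" not in df:
            raise ValueError("gait CSV requires 'time_s' and 'y_mm' columns")
        x = df["x_mm"].to_numpy() if "x_mm" in df else None
        return cls(df["time_s"].to_numpy(), df["y_mm"].to_numpy(), x)


@dataclass
class LoadingSignal:
    """Time-sampled walking displacement functions and the analytic vertical
    acceleration d2Dy = -(2 pi / T)^2 * Dy."""

    time: np.ndarray
    Dx: np.ndarray
    Dy: np.ndarray
    d2Dy: np.ndarray
    preset: GaitPreset

    def __post_init__(self) -> None:
        n = self.time.size
        if not (self.Dx.size == self.Dy.size == self.d2Dy.size == n):
            raise ValueError("signal arrays must share the time grid")


def extract_main_component(trace: GaitTrace) -> tuple[float, float]:
    """Dominant-harmonic (amplitude mm, period s) of a vertical trajectory.

    The signal is de-meaned, the magnitude spectrum's largest non-DC bin is
    refined by quadratic interpolation over its neighbours, and the
    amplitude follows from least squares of y(t) onto cos/sin at the refined
    frequency.

    Raises
    ------
    ValueError
        If no dominant component stands out of the spectrum (peak-to-median
        magnitude ratio below 3), e.g. for a flat signal.
    """
    y = trace.y - np.mean(trace.y)
    n = y.size
    dt = trace.dt
    mag = np.abs(np.fft.rfft(y))
    if mag.size < 3:
        raise ValueError("trace too short for spectral analysis")
    k = int(np.argmax(mag[1:])) + 1
    med = float(np.median(mag[1:]))
    if med <= 0 or mag[k] / med < 3.0:
        raise ValueError("no dominant component in the spectrum")
    # 3-point quadratic refinement of the peak location (off-bin frequencies)
    if 1 <= k - 1 and k + 1 < mag.size:
        y1, y2, y3 = mag[k - 1], mag[k], mag[k + 1]
        denom = y1 - 2.0 * y2 + y3
        delta = 0.0 if denom == 0 else 0.5 * (y1 - y3) / denom
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0

    def _fit(freq: float):
        w = 2.0 * np.pi * freq * trace.time
        basis = np.column_stack([np.cos(w), np.sin(w)])
        coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
        resid = y - basis @ coef
        return coef, float(resid @ resid)

    # polish the frequency by minimizing the least-squares residual around
    # the refined bin (the magnitude-peak estimate is leakage-biased off-bin)
    df = 1.0 / (n * dt)
    f0 = (k + delta) * df
    lo = max(0.5 * df, f0 - 0.6 * df)
    hi = f0 + 0.6 * df
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        lambda f: _fit(f)[1],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-12 * max(f0, 1.0)},
    )
    freq = float(res.x)
    # snap to the exact bin when it fits at least as well (on-bin exactness)
    coef_bin, r_bin = _fit(k * df)
    coef, r_opt = _fit(freq)
    if r_bin <= r_opt * (1.0 + 1e-12):
        freq, coef = k * df, coef_bin
    amplitude = float(np.hypot(*coef))
    return amplitude, 1.0 / freq


def build_walking_signal(
    preset: GaitPreset, duration: float, dt: float
) -> LoadingSignal:
    """Evaluate Dx(t) = v t and Dy(t) = A cos(2 pi t / T) on a uniform grid.

    ``dt`` must resolve the period (dt <= T/20); the grid starts at t = 0 so
    the cosine extremes +-A are attained at t = 0 and t = T/2.
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    if dt > preset.T_period / 20.0:
        raise ValueError(
            f"dt = {dt} s too coarse for period {preset.T_period} s "
            "(need dt <= T/20)"
        )
    n = int(np.floor(duration / dt)) + 1
    t = np.arange(n) * dt
    omega = 2.0 * np.pi / preset.T_period
    Dy = preset.A * np.cos(omega * t)
    return LoadingSignal(
        time=t,
        Dx=preset.v * t,
        Dy=Dy,
        d2Dy=-(omega**2) * Dy,
        preset=preset,
    )


def generate_synthetic_gait(
    preset: GaitPreset,
    harmonics: int = 3,
    noise_sd: float = 0.0,
    duration: float = 10.0,
    dt: float = 0.01,
    seed: int | None = None,
) -> GaitTrace:
    """Synthesize a noisy quasi-periodic vertical trajectory.

    The fundamental has the preset's (A, T); higher harmonics decay as
    A / 3^k; white Gaussian noise of SD ``noise_sd`` mm is added.  Emulates
    the chest-marker data the walking presets were derived from.
    """
    if harmonics < 1:
        raise ValueError("harmonics must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    t = np.arange(int(np.floor(duration / dt)) + 1) * dt
    y = np.zeros_like(t)
    for k in range(harmonics):
        y += (preset.A / 3.0**k) * np.cos(2.0 * np.pi * (k + 1) * t / preset.T_period)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=t.size)
    x = preset.v * t
    return GaitTrace(time=t, y=y, x=x)
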