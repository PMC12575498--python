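"""Inverse identification of shell stiffness and gel volume fractions.

An implant resting flat on the ground under gravity deforms into a flattened
dome whose height T and width R depend on the shell's neo-Hookean
coefficient and on how full the shell is.  Given scanned (T, R) summaries
for one or more implant sizes, the characterization loop searches the
property vector

    x = (C10_shell, fraction_1, ..., fraction_n)

minimizing the weighted absolute shape mismatch

    f(x) = sum_i ( w_T |T_i(x) - That_i| + w_R |R_i(x) - Rhat_i| )

by bounded derivative-free Nelder-Mead search; each evaluation runs the
forward equilibrium solver once per implant size (warm-started from the
previous evaluation of that size).  The objective is non-smooth (absolute
values) and each evaluation is expensive, which rules out gradient methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .geometry import AxisymProfile, ShapeSummary
from .materials import GelFill, MaterialSet
from .solver import (
    DeformedState,
    EquilibriumError,
    GRAVITY,
    ObstacleSet,
    Plane,
    SolverOptions,
    solve_equilibrium,
)

__all__ = [
    "PropertyVector",
    "ObjectiveSpec",
    "CharacterizationResult",
    "ForwardConfig",
    "ForwardModel",
    "objective",
    "characterize",
    "INITIAL_C10_ESTIMATE",
]

#: Shell C10 estimate from tensile testing, kPa (starting point of the search).
INITIAL_C10_ESTIMATE = 91.547


@dataclass(frozen=True)
class PropertyVector:
    """Optimization unknowns: shared shell C10 plus one gel fraction per size."""

    C10_shell: float
    volume_fractions: tuple[float, ...]

    def __init__(self, C10_shell: float, volume_fractions: Sequence[float]):
        object.__setattr__(self, "C10_shell", float(C10_shell))
        object.__setattr__(
            self, "volume_fractions", tuple(float(v) for v in volume_fractions)
        )
        if self.C10_shell <= 0:
            raise ValueError("C10_shell must be positive")
        for v in self.volume_fractions:
            if not 0.0 < v <= 1.0:
                raise ValueError(f"volume fraction {v} outside (0, 1]")

    def to_array(self) -> np.ndarray:
        return np.array([self.C10_shell, *self.volume_fractions])

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "PropertyVector":
        return cls(arr[0], arr[1:])


@dataclass(frozen=True)
class ObjectiveSpec:
    """Weights and convergence controls of the shape-mismatch objective."""

    w_T: float = 1.0
    w_R: float = 1.0
    tolerance: float = 0.5
    max_iterations: int = 2000
    fatol: float = 1e-4
    xatol: float = 2e-4
    n_restarts: int = 3

    def __post_init__(self) -> None:
        if self.w_T < 0 or self.w_R < 0 or (self.w_T == 0 and self.w_R == 0):
            raise ValueError("weights must be non-negative and not both zero")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class CharacterizationResult:
    x_star: PropertyVector
    objective_value: float
    objective_trace: np.ndarray
    residuals: dict[str, tuple[float, float]]  # size label -> (dT, dR) mm
    converged: bool
    n_evaluations: int


@dataclass(frozen=True)
class ForwardConfig:
    """Configuration of the flat-resting forward simulation used by Eq.-style
    shape matching: each implant rests on the ground plane under gravity."""

    gravity: float = GRAVITY
    solver_options: SolverOptions = SolverOptions()
    confinement_pressure: float = 0.0


class ForwardModel:
    """Runs the flat-resting forward simulation per implant size.

    Holds a warm-start cache per size so that successive evaluations at
    nearby property vectors converge in a few solver iterations.
    """

    def __init__(self, profiles: Sequence[AxisymProfile], config: ForwardConfig = ForwardConfig()):
        if len(profiles) == 0:
            raise ValueError("at least one implant profile is required")
        self.profiles = list(profiles)
        self.config = config
        self.obstacles = ObstacleSet([Plane(0.0)])
        self._warm: list[Optional[DeformedState]] = [None] * len(self.profiles)
        self.n_solves = 0

    @property
    def labels(self) -> list[str]:
        return [
            p.implant_id or f"size{i}" for i, p in enumerate(self.profiles)
        ]

    def simulate(self, x: PropertyVector) -> list[ShapeSummary]:
        """Forward-simulate all sizes at the property vector x."""
        if len(x.volume_fractions) != len(self.profiles):
            raise ValueError(
                f"property vector has {len(x.volume_fractions)} fractions for "
                f"{len(self.profiles)} implant sizes"
            )
        out = []
        for i, prof in enumerate(self.profiles):
            mats = MaterialSet(C10_shell=x.C10_shell)
            fill = GelFill(x.volume_fractions[i], prof.nominal_volume)
            try:
                st = solve_equilibrium(
                    prof,
                    mats,
                    fill,
                    self.obstacles,
                    gravity=self.config.gravity,
                    confinement_pressure=self.config.confinement_pressure,
                    init=self._warm[i],
                    options=self.config.solver_options,
                )
            except EquilibriumError as err:
                raise EquilibriumError(
                    f"forward solve failed for implant '{self.labels[i]}' at "
                    f"C10={x.C10_shell:.4g} kPa, fraction="
                    f"{x.volume_fractions[i]:.4g}: {err}",
                    state=err.state,
                ) from err
            self._warm[i] = st
            self.n_solves += 1
            T, R = st.summary()
            out.append(ShapeSummary(T=T, R=R, implant_id=self.labels[i]))
        return out


def _residuals(
    simulated: Sequence[ShapeSummary], scans: Sequence[ShapeSummary]
) -> dict[str, tuple[float, float]]:
    return {
        sim.implant_id
        or scan.implant_id
        or str(i): (sim.T - scan.T, sim.R - scan.R)
        for i, (sim, scan) in enumerate(zip(simulated, scans))
    }


def eq1_value(
    residuals: dict[str, tuple[float, float]], w_T: float, w_R: float
) -> float:
    """Weighted absolute-error sum over sizes from stored (dT, dR) residuals."""
    return float(
        sum(w_T * abs(dT) + w_R * abs(dR) for dT, dR in residuals.values())
    )


def objective(
    x: PropertyVector,
    scans: Sequence[ShapeSummary],
    spec: ObjectiveSpec,
    forward: ForwardModel,
) -> float:
    """Shape-mismatch objective f(x) >= 0; zero iff simulations match scans."""
    if len(scans) != len(forward.profiles):
        raise ValueError("one scan summary per implant size is required")
    simulated = forward.simulate(x)
    return eq1_value(_residuals(simulated, scans), spec.w_T, spec.w_R)


def characterize(
    scans: Sequence[ShapeSummary],
    spec: ObjectiveSpec,
    x0: PropertyVector,
    bounds: Optional[tuple] = None,
    forward: Optional[ForwardModel] = None,
    profiles: Optional[Sequence[AxisymProfile]] = None,
) -> CharacterizationResult:
    """Bounded derivative-free minimization of the shape mismatch.

    Parameters
    ----------
    scans : sequence of ShapeSummary
        Measured (T, R) per implant size, aligned with the forward model's
        profiles.
    spec : ObjectiveSpec
        Weights and convergence controls.
    x0 : PropertyVector
        Starting point (must respect the bounds).
    bounds : ((C10_lo, C10_hi), (frac_lo, frac_hi)), optional
        Box bounds; default C10 in [30, 400] kPa, fractions in [0.6, 1.0].
    forward : ForwardModel, optional
        Reusable forward model (else built from ``profiles``).

    Returns
    -------
    CharacterizationResult
        Best-found property vector with the running-best objective trace;
        ``converged`` is False (not an exception) when ``max_iterations``
        is exhausted above ``spec.tolerance``.

    Notes
    -----
    Deterministic for fixed inputs: the simplex search has no random
    component and forward solves warm-start along the search path.
    """
    if forward is None:
        if profiles is None:
            raise ValueError("either forward or profiles must be given")
        forward = ForwardModel(profiles)
    n = len(forward.profiles)
    if len(x0.volume_fractions) != n:
        raise ValueError("x0 fraction count does not match implant sizes")
    if bounds is None:
        bounds = ((30.0, 400.0), (0.6, 1.0))
    (c_lo, c_hi), (f_lo, f_hi) = bounds
    if not (c_lo <= x0.C10_shell <= c_hi) or not all(
        f_lo <= v <= f_hi for v in x0.volume_fractions
    ):
        raise ValueError("x0 violates the bounds")

    # scaled variables: C10/100 and fractions, so simplex steps are comparable
    c_scale = 100.0
    u0 = x0.to_array()
    u0[0] /= c_scale
    lb = np.array([c_lo / c_scale] + [f_lo] * n)
    ub = np.array([c_hi / c_scale] + [f_hi] * n)

    trace: list[float] = []
    best = [np.inf]

    def fun(u: np.ndarray) -> float:
        uu = np.clip(u, lb, ub)
        x = PropertyVector(uu[0] * c_scale, uu[1:])
        f = objective(x, scans, spec, forward)
        best[0] = min(best[0], f)
        trace.append(best[0])
        return f

    # simplex search with restarts: each restart rebuilds a smaller simplex
    # around the incumbent, escaping collapsed-simplex stalls in the flat
    # valley where C10 and the fractions partly compensate
    u_best, f_best = u0.copy(), np.inf
    step0 = 1.0
    for restart in range(spec.n_restarts + 1):
        budget = spec.max_iterations - len(trace)
        if budget <= 10:
            break
        res = minimize(
            fun,
            u_best,
            method="Nelder-Mead",
            bounds=np.column_stack([lb, ub]),
            options={
                "maxfev": budget,
                "fatol": spec.fatol,
                "xatol": spec.xatol,
                "adaptive": True,
                "initial_simplex": _initial_simplex(u_best, lb, ub, step0),
            },
        )
        if res.fun < f_best - 1e-12:
            improved = f_best - res.fun
            u_best, f_best = np.clip(res.x, lb, ub), float(res.fun)
            if improved < spec.fatol:
                break
        else:
            break
        step0 *= 0.25
    u_star = u_best
    x_star = PropertyVector(u_star[0] * c_scale, u_star[1:])
    simulated = forward.simulate(x_star)
    residuals = _residuals(simulated, scans)
    f_star = eq1_value(residuals, spec.w_T, spec.w_R)
    converged = bool(res.success) or f_star <= spec.tolerance
    return CharacterizationResult(
        x_star=x_star,
        objective_value=f_star,
        objective_trace=np.asarray(trace),
        residuals=residuals,
        converged=converged,
        n_evaluations=len(trace),
    )


def _initial_simplex(
    u0: np.ndarray, lb: np.ndarray, ub: np.ndarray, scale: float = 1.0
) -> np.ndarray:
    """Simplex around u0 with steps sized to the expected parameter scales."""
    n = u0.size
    steps = np.full(n, 0.03 * scale)
    steps[0] = 0.08 * scale  # C10/100: probe ~8 kPa initially
    simplex = np.tile(u0, (n + 1, 1))
    for i in range(n):
        step = steps[i] if u0[i] + steps[i] <= ub[i] else -steps[i]
        simplex[i + 1, i] = np.clip(u0[i] + step, lb[i], ub[i])
    return simplex
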