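"""Constitutive models for the implant components.

The shell is an incompressible neo-Hookean membrane with a single stiffness
coefficient ``C10`` (kPa).  The silicone gel filling is far softer than the
shell (its ``C10`` is bounded at 1/100 of the shell's) and stores negligible
strain energy; inside the equilibrium solver it is treated as an
incompressible hydrostatic medium whose only mechanical role is the enclosed
volume constraint and its weight.  The surrounding fat/muscle cover is linear
elastic and enters the scenarios only through a confinement pressure.

Unit system: mm - N - MPa-derived, i.e. lengths in mm, stresses and moduli in
kPa (1 kPa = 1e-3 N/mm^2), densities in tonne/mm^3, accelerations in mm/s^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MaterialSet",
    "GelFill",
    "neo_hookean_energy",
    "membrane_stress",
    "effective_gel_volume",
    "DEFAULT_MATERIALS",
]

#: Maximum allowed gel/shell stiffness ratio (the gel must be liquid-like).
GEL_SHELL_RATIO_LIMIT = 1.0 / 100.0

#: Default gel density, tonne/mm^3 (0.97 g/cm^3, typical cohesive silicone gel).
DEFAULT_GEL_DENSITY = 9.7e-10


@dataclass(frozen=True)
class MaterialSet:
    """Material coefficients for shell, gel and surrounding tissue.

    Parameters
    ----------
    C10_shell : float
        Neo-Hookean coefficient of the silicone-elastomer shell, kPa.
    C10_gel : float
        Neo-Hookean coefficient of the gel, kPa.  Must be below
        ``C10_shell / 100`` unless ``allow_stiff_gel`` is set.
    gel_density : float
        Gel (and effectively whole-implant) density, tonne/mm^3.
    E_tissue : float
        Young's modulus of the combined fat/muscle cover, kPa.
    nu_tissue : float
        Poisson ratio of the cover, in (0, 0.5).
    shell_thickness : float
        Reference shell thickness, mm.
    allow_stiff_gel : bool
        Explicit override of the gel/shell stiffness-ratio check.
    """

    C10_shell: float = 100.702
    C10_gel: float = 0.025
    gel_density: float = DEFAULT_GEL_DENSITY
    E_tissue: float = 208.0
    nu_tissue: float = 0.47
    shell_thickness: float = 0.5
    allow_stiff_gel: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        for name in ("C10_shell", "C10_gel", "E_tissue", "shell_thickness"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not 0.0 < self.nu_tissue < 0.5:
            raise ValueError(f"nu_tissue must lie in (0, 0.5), got {self.nu_tissue}")
        if self.gel_density <= 0:
            raise ValueError("gel_density must be positive")
        ratio = self.C10_gel / self.C10_shell
        if ratio >= GEL_SHELL_RATIO_LIMIT and not self.allow_stiff_gel:
            raise ValueError(
                f"C10_gel/C10_shell = {ratio:.4g} violates the liquid-like gel "
                f"assumption (< {GEL_SHELL_RATIO_LIMIT}); pass allow_stiff_gel=True "
                "to override"
            )


#: Finalized coefficients used for the anatomical-environment simulations.
DEFAULT_MATERIALS = MaterialSet()


@dataclass(frozen=True)
class GelFill:
    """Gel fill level of an implant.

    ``volume_fraction`` is the ratio of actual gel volume to the volume
    enclosed by the undeformed shell; 1.0 is the ideal fully-filled case,
    values below 1 describe under-filled implants.
    """

    volume_fraction: float
    nominal_volume: float

    def __post_init__(self) -> None:
        if not 0.0 < self.volume_fraction <= 1.0:
            raise ValueError(
                f"volume_fraction must lie in (0, 1], got {self.volume_fraction}"
            )
        if self.nominal_volume <= 0:
            raise ValueError("nominal_volume must be positive")


def effective_gel_volume(fill: GelFill) -> float:
    """Actual gel volume in mm^3: fraction times nominal enclosed volume."""
    return fill.volume_fraction * fill.nominal_volume


def neo_hookean_energy(lambda1, lambda2, C10: float):
    """Incompressible neo-Hookean strain-energy density per reference volume.

    W = C10 * (I1 - 3) with I1 = l1^2 + l2^2 + l3^2 and the incompressibility
    closure l3 = 1/(l1*l2).  Returns kPa (energy per unit reference volume).
    Accepts scalars or arrays.
    """
    l1 = np.asarray(lambda1, dtype=float)
    l2 = np.asarray(lambda2, dtype=float)
    if np.any(l1 <= 0) or np.any(l2 <= 0):
        raise ValueError("stretches must be positive")
    if C10 <= 0:
        raise ValueError("C10 must be positive")
    i1 = l1**2 + l2**2 + 1.0 / (l1**2 * l2**2)
    w = C10 * (i1 - 3.0)
    return w if w.shape else float(w)


def membrane_stress(lambda1, lambda2, C10: float, thickness_ref: float):
    """Plane-stress Cauchy stresses of an incompressible neo-Hookean membrane.

    The through-thickness stress is zero; eliminating the pressure gives the
    principal in-plane Cauchy stresses

        sigma_i = 2*C10*(lambda_i^2 - 1/(lambda1^2 lambda2^2)),  i = 1, 2

    Returns ``(sigma1, sigma2, von_mises, thickness)`` with stresses in kPa
    and the current thickness ``thickness_ref/(lambda1*lambda2)`` in mm.
    """
    l1 = np.asarray(lambda1, dtype=float)
    l2 = np.asarray(lambda2, dtype=float)
    if np.any(l1 <= 0) or np.any(l2 <= 0):
        raise ValueError("stretches must be positive")
    if C10 <= 0 or thickness_ref <= 0:
        raise ValueError("C10 and thickness_ref must be positive")
    inv = 1.0 / (l1**2 * l2**2)
    s1 = 2.0 * C10 * (l1**2 - inv)
    s2 = 2.0 * C10 * (l2**2 - inv)
    vm = np.sqrt(s1**2 - s1 * s2 + s2**2)
    t = thickness_ref / (l1 * l2)
    if np.ndim(lambda1) == 0 and np.ndim(lambda2) == 0:
        return float(s1), float(s2), float(vm), float(t)
    return s1, s2, vm, t
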