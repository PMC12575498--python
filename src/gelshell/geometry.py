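"""Axisymmetric implant geometry, scan meshes and shape summaries.

An implant at rest is modeled as a solid of revolution: its meridian (the
generating curve in the r-z plane) runs from the apex on the symmetry axis,
down the dome-shaped side, and across the flat base back to the axis.  The
reference geometries for the four characterization sizes (200/250/400/560 cc)
are built from their printed radius, height and nominal volume; deformed
shapes — from the equilibrium solver or from a 3D surface scan — are reduced
to the (T, R) height/width summaries the characterization objective uses.

Coordinates: z up, ground plane z = 0, lengths in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import trimesh
from scipy.optimize import brentq

__all__ = [
    "AxisymProfile",
    "ScanMesh",
    "ShapeSummary",
    "InfeasibleGeometryError",
    "build_reference_profile",
    "summarize_shape",
    "generate_synthetic_scan",
    "enclosed_volume",
    "IMPLANT_SIZES",
]

#: Printed nominal geometry of the four characterization sizes:
#: label -> (radius mm, height mm, nominal volume mm^3).
IMPLANT_SIZES: dict[str, tuple[float, float, float]] = {
    "200cc": (52.87, 45.7, 200_000.0),
    "250cc": (52.97, 57.4, 250_000.0),
    "400cc": (62.82, 61.6, 400_000.0),
    "560cc": (62.51, 77.5, 560_000.0),
}


class InfeasibleGeometryError(ValueError):
    """No meridian in the profile family satisfies radius/height/volume."""


def enclosed_volume(r: np.ndarray, z: np.ndarray) -> float:
    """Volume of the solid of revolution bounded by a closed meridian.

    The meridian is the polyline (r_i, z_i) from apex to base-center; the
    closing segment along the axis contributes nothing.  Signed: positive
    for apex-to-base traversal.  Each linear segment is a conical frustum,
    for which

        dV = pi/3 * (r_a^2 + r_a r_b + r_b^2) * (z_a - z_b)

    is exact, so the quadrature is exact for the polyline geometry.
    """
    ra, rb = r[:-1], r[1:]
    za, zb = z[:-1], z[1:]
    return float(np.pi / 3.0 * np.sum((ra**2 + ra * rb + rb**2) * (za - zb)))


@dataclass
class AxisymProfile:
    """Ordered meridian samples (apex -> base center) of a closed shell.

    Attributes
    ----------
    r, z : ndarray
        Radial / axial sample coordinates in mm.  ``r[0] == r[-1] == 0``
        (the meridian starts and ends on the symmetry axis).
    nominal_volume : float
        Design volume of the implant, mm^3 (metadata; the *current* enclosed
        volume is :meth:`enclosed_volume`).
    shell_thickness : float or ndarray
        Reference shell thickness in mm, scalar or per-sample.
    """

    r: np.ndarray
    z: np.ndarray
    nominal_volume: float
    shell_thickness: Union[float, np.ndarray] = 0.5
    implant_id: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.r.ndim != 1 or self.r.shape != self.z.shape:
            raise ValueError("r and z must be 1-D arrays of equal length")
        if self.r.size < 4:
            raise ValueError("need at least 4 meridian samples")
        if not (np.all(np.isfinite(self.r)) and np.all(np.isfinite(self.z))):
            raise ValueError("meridian samples must be finite")
        if np.any(self.r < -1e-12):
            raise ValueError("radial coordinates must be non-negative")
        if abs(self.r[0]) > 1e-9 or abs(self.r[-1]) > 1e-9:
            raise ValueError("meridian must start and end on the axis (r = 0)")
        self.r[0] = 0.0
        self.r[-1] = 0.0
        seg = np.hypot(np.diff(self.r), np.diff(self.z))
        if np.any(seg <= 1e-12):
            raise ValueError("degenerate (zero-length) meridian segment")
        if self.nominal_volume <= 0:
            raise ValueError("nominal_volume must be positive")

    @property
    def n_samples(self) -> int:
        return self.r.size

    def enclosed_volume(self) -> float:
        """Current enclosed volume in mm^3 by frustum quadrature.

        Unsigned: independent of the sampling direction of the meridian.
        """
        return abs(enclosed_volume(self.r, self.z))

    def arc_lengths(self) -> np.ndarray:
        """Cumulative arc length along the meridian, starting at 0."""
        seg = np.hypot(np.diff(self.r), np.diff(self.z))
        return np.concatenate(([0.0], np.cumsum(seg)))

    def arc_fractions(self) -> np.ndarray:
        """Arc-length fractions in [0, 1] of each sample (material coordinate)."""
        s = self.arc_lengths()
        return s / s[-1]

    def to_csv(self, path: Union[str, Path]) -> None:
        arr = np.column_stack([self.r, self.z])
        np.savetxt(path, arr, delimiter=",", header="r_mm,z_mm", comments="")

    @classmethod
    def from_csv(
        cls,
        path: Union[str, Path],
        nominal_volume: float | None = None,
        shell_thickness: Union[float, np.ndarray] = 0.5,
        implant_id: str = "",
    ) -> "AxisymProfile":
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        r, z = arr[:, 0], arr[:, 1]
        if nominal_volume is None:
            nominal_volume = abs(enclosed_volume(r, z))
        return cls(r, z, nominal_volume, shell_thickness, implant_id)


@dataclass
class ScanMesh:
    """Triangulated surface scan of an implant resting on the ground plane."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be an (m, 3) triangle array")
        if self.vertices.shape[0] == 0:
            raise ValueError("empty mesh")

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    def save(self, path: Union[str, Path]) -> None:
        """Write as STL or PLY (chosen from the file extension)."""
        self.to_trimesh().export(str(path))

    @classmethod
    def load(cls, path: Union[str, Path]) -> "ScanMesh":
        m = trimesh.load(str(path), force="mesh", process=False)
        return cls(np.asarray(m.vertices), np.asarray(m.faces))


@dataclass(frozen=True)
class ShapeSummary:
    """Height/width pair of a deformed implant shape.

    T is the maximal axial extent above the ground plane (mm); R is the
    maximal radial extent from the symmetry axis (mm) — i.e. half the overall
    width.
    """

    T: float
    R: float
    implant_id: str = ""

    def __post_init__(self) -> None:
        if not (self.T > 0 and self.R > 0):
            raise ValueError(f"T and R must be positive, got T={self.T}, R={self.R}")


# ---------------------------------------------------------------------------
# Reference profile construction
# ---------------------------------------------------------------------------

def _superellipse_meridian(
    radius: float, height: float, p: float, n_samples: int
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the dome meridian r(z) = R*(1-(z/H)^p)^(1/p) plus the flat base.

    Samples are approximately uniform in arc length; the apex (0, H), the
    base edge (R, 0) and the base center (0, 0) are sample points exactly.
    """
    # dense side polyline, apex (z=H) first, grid refined near the apex
    u = np.linspace(0.0, 1.0, 4001)
    zd = height * (1.0 - u**1.5)
    rd = radius * (1.0 - (zd / height) ** p) ** (1.0 / p)
    seg = np.hypot(np.diff(rd), np.diff(zd))
    s = np.concatenate(([0.0], np.cumsum(seg)))
    L_side, L_base = s[-1], radius
    n_base = max(2, int(round((n_samples - 1) * L_base / (L_side + L_base))))
    n_side = n_samples - n_base
    if n_side < 8:
        raise ValueError("n_samples too small to resolve the dome side")
    st = np.linspace(0.0, L_side, n_side)
    r_side = np.interp(st, s, rd)
    z_side = np.interp(st, s, zd)
    r_side[0], z_side[0] = 0.0, height
    r_side[-1], z_side[-1] = radius, 0.0
    r_base = np.linspace(radius, 0.0, n_base + 1)[1:]
    z_base = np.zeros(n_base)
    return np.concatenate([r_side, r_base]), np.concatenate([z_side, z_base])


def build_reference_profile(
    radius: float,
    height: float,
    nominal_volume: float,
    n_samples: int = 64,
    shell_thickness: Union[float, np.ndarray] = 0.5,
    implant_id: str = "",
) -> AxisymProfile:
    """Build the axisymmetric reference meridian for an implant size.

    The meridian family is a flat-based superellipse dome
    ``r(z) = R*(1 - (z/H)^p)**(1/p)`` whose shape exponent ``p`` is solved so
    that the *discrete* frustum-quadrature volume of the sampled meridian
    equals ``nominal_volume``; the printed radius and height are preserved
    exactly.  ``p = 2`` reproduces a hemisphere.

    Raises
    ------
    InfeasibleGeometryError
        If no exponent in the family encloses the requested volume; the
        message names the achievable volume range for this radius/height.
    """
    if radius <= 0 or height <= 0 or nominal_volume <= 0:
        raise ValueError("radius, height and nominal_volume must be positive")
    if n_samples < 16:
        raise ValueError("n_samples must be at least 16")

    def vol(p: float) -> float:
        r, z = _superellipse_meridian(radius, height, p, n_samples)
        return enclosed_volume(r, z)

    p_lo, p_hi = 0.25, 80.0
    v_lo, v_hi = vol(p_lo), vol(p_hi)
    if not v_lo < nominal_volume < v_hi:
        raise InfeasibleGeometryError(
            f"requested volume {nominal_volume:.6g} mm^3 is outside the "
            f"achievable range ({v_lo:.6g}, {v_hi:.6g}) mm^3 for "
            f"radius {radius} mm, height {height} mm"
        )
    p_star = brentq(lambda p: vol(p) - nominal_volume, p_lo, p_hi, xtol=1e-12)
    r, z = _superellipse_meridian(radius, height, p_star, n_samples)
    return AxisymProfile(r, z, nominal_volume, shell_thickness, implant_id)


# ---------------------------------------------------------------------------
# Shape summaries
# ---------------------------------------------------------------------------

def summarize_shape(
    shape: Union[AxisymProfile, ScanMesh, trimesh.Trimesh],
    implant_id: str | None = None,
) -> ShapeSummary:
    """Reduce a deformed shape to its (T, R) height/width summary.

    For meshes the symmetry axis is taken vertical through the vertex
    centroid and the support plane at z = 0; T is the maximum z over
    vertices, R the maximum planar distance from the axis.  Deterministic and
    invariant to vertex order and to rotation about the axis.
    """
    if isinstance(shape, AxisymProfile):
        T = float(np.max(shape.z))
        R = float(np.max(shape.r))
        label = implant_id if implant_id is not None else shape.implant_id
        return ShapeSummary(T=T, R=R, implant_id=label)

    if isinstance(shape, trimesh.Trimesh):
        verts = np.asarray(shape.vertices, dtype=float)
    elif isinstance(shape, ScanMesh):
        verts = shape.vertices
    else:
        raise TypeError(f"cannot summarize object of type {type(shape).__name__}")
    if verts.shape[0] == 0:
        raise ValueError("empty mesh")
    z = verts[:, 2]
    if np.ptp(z) < 1e-9:
        raise ValueError("degenerate mesh: all vertices coplanar with the ground")
    cx, cy = verts[:, 0].mean(), verts[:, 1].mean()
    T = float(z.max())
    R = float(np.max(np.hypot(verts[:, 0] - cx, verts[:, 1] - cy)))
    return ShapeSummary(T=T, R=R, implant_id=implant_id or "")


# ---------------------------------------------------------------------------
# Synthetic scan generation
# ---------------------------------------------------------------------------

def _meridian_normals(r: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Outward unit normals (n_r, n_z) of the meridian at each sample."""
    dr = np.gradient(r)
    dz = np.gradient(z)
    n = np.column_stack([-dz, dr])
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    return n


def generate_synthetic_scan(
    profile_deformed: AxisymProfile,
    noise_sd: float,
    seed: int | None = None,
    n_theta: int = 96,
) -> ScanMesh:
    """Emulate a 3D scan: revolve a deformed meridian and add surface noise.

    Vertices are perturbed along their outward normals by zero-mean Gaussian
    noise of standard deviation ``noise_sd`` (mm).  Reproducible for a fixed
    ``seed``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if n_theta < 8:
        raise ValueError("n_theta must be at least 8")
    r, z = profile_deformed.r, profile_deformed.z
    n2d = _meridian_normals(r, z)
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    ct, st = np.cos(theta), np.sin(theta)

    # vertices: apex pole, interior rings, base pole
    verts = [np.array([[0.0, 0.0, z[0]]])]
    normals = [np.array([[n2d[0, 0] * 0.0, 0.0, np.sign(n2d[0, 1]) or 1.0]])]
    ring_start = np.empty(r.size, dtype=int)
    ring_start[0] = 0
    idx = 1
    for i in range(1, r.size - 1):
        ring_start[i] = idx
        verts.append(np.column_stack([r[i] * ct, r[i] * st, np.full(n_theta, z[i])]))
        normals.append(
            np.column_stack(
                [n2d[i, 0] * ct, n2d[i, 0] * st, np.full(n_theta, n2d[i, 1])]
            )
        )
        idx += n_theta
    ring_start[-1] = idx
    verts.append(np.array([[0.0, 0.0, z[-1]]]))
    normals.append(np.array([[0.0, 0.0, np.sign(n2d[-1, 1]) or -1.0]]))
    vertices = np.concatenate(verts, axis=0)
    vnormals = np.concatenate(normals, axis=0)
    vnormals /= np.linalg.norm(vnormals, axis=1, keepdims=True)

    faces = []
    first = ring_start[1]
    for j in range(n_theta):  # apex fan
        faces.append([0, first + j, first + (j + 1) % n_theta])
    for i in range(1, r.size - 2):  # quad strips
        a, b = ring_start[i], ring_start[i + 1]
        for j in range(n_theta):
            jn = (j + 1) % n_theta
            faces.append([a + j, b + j, b + jn])
            faces.append([a + j, b + jn, a + jn])
    last_ring = ring_start[r.size - 2]
    pole = ring_start[-1]
    for j in range(n_theta):  # base fan
        faces.append([last_ring + j, pole, last_ring + (j + 1) % n_theta])

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vertices = vertices + vnormals * rng.normal(
            0.0, noise_sd, size=(vertices.shape[0], 1)
        )
    return ScanMesh(vertices, np.asarray(faces, dtype=np.int64))
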