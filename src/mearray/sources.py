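"""Applied (primary) magnetic field evaluators.

Two excitation kinds are supported at the quasi-static working
frequency (default 848 Hz):

* a homogeneous field ``H0`` applied to the whole model space, and
* an electric current dipole (moment ``Q`` in A*m at position ``r0``)
  either in an unbounded homogeneous conductor or inside a spherically
  symmetric volume conductor (the head stand-in), where the exterior
  field follows the Sarvas closed form and is independent of the radial
  conductivity profile.

Magnetically the tissue is transparent (mu_r = 1), so B = mu0 H at every
probe point outside the sensors.  An optional secondary stabilization
dipole (1 uA*m, 2 mm below the main one, same orientation) can be
superposed; it exists for fidelity with the original numerical setup and
is disabled by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .head import HeadModel

__all__ = [
    "MU0",
    "SourceSpec",
    "FieldSolution",
    "eval_homogeneous",
    "eval_dipole_infinite",
    "eval_dipole_sphere",
    "evaluate",
]

MU0 = 4e-7 * np.pi


@dataclass(frozen=True)
class SourceSpec:
    """Excitation specification.

    ``kind`` is "homogeneous" (uses ``H0``, A/m) or "dipole" (uses the
    moment ``Q`` in A*m and position ``r0`` in m).
    """

    kind: str
    H0: np.ndarray = field(default_factory=lambda: np.zeros(3))
    Q: np.ndarray = field(default_factory=lambda: np.zeros(3))
    r0: np.ndarray = field(default_factory=lambda: np.zeros(3))
    frequency: float = 848.0
    secondary: bool = False
    secondary_moment: float = 1e-6
    secondary_offset: float = 2e-3

    def __post_init__(self):
        for name in ("H0", "Q", "r0"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.kind not in ("homogeneous", "dipole"):
            raise ValueError(
                f"unknown excitation kind {self.kind!r}; valid kinds: homogeneous, dipole"
            )
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.kind == "dipole" and np.linalg.norm(self.Q) == 0:
            raise ValueError("dipole excitation needs a non-zero moment Q")

    def scaled(self, k: float) -> "SourceSpec":
        """Same source with amplitude scaled by ``k``."""
        from dataclasses import replace

        return replace(self, H0=self.H0 * k, Q=self.Q * k, secondary_moment=self.secondary_moment * k)

    def _dipoles(self):
        """[(moment, position)] including the optional secondary."""
        out = [(self.Q, self.r0)]
        if self.secondary:
            qn = np.linalg.norm(self.Q)
            out.append(
                (
                    self.Q / qn * self.secondary_moment,
                    self.r0 - np.array([0.0, 0.0, self.secondary_offset]),
                )
            )
        return out


@dataclass(frozen=True)
class FieldSolution:
    """Fields sampled at probe points (B in T, H in A/m)."""

    points: np.ndarray
    B: np.ndarray
    H: np.ndarray
    E: Optional[np.ndarray] = None
    D: Optional[np.ndarray] = None


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[None, :]
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"points must have shape (n, 3), got {pts.shape}")
    return pts


def eval_homogeneous(spec: SourceSpec, points) -> FieldSolution:
    """Constant H = H0 everywhere; B = mu0 H in air."""
    if spec.kind != "homogeneous":
        raise ValueError(f"expected homogeneous excitation, got {spec.kind!r}")
    pts = _as_points(points)
    H = np.broadcast_to(spec.H0, pts.shape).copy()
    return FieldSolution(points=pts, B=MU0 * H, H=H)


def _dipole_B(Q, r0, pts) -> np.ndarray:
    a = pts - r0
    an = np.linalg.norm(a, axis=1)
    if np.any(an < 1e-12):
        raise ValueError("field requested at the dipole position (singularity)")
    return MU0 / (4 * np.pi) * np.cross(Q, a) / an[:, None] ** 3


def eval_dipole_infinite(spec: SourceSpec, points) -> FieldSolution:
    """Current dipole in an unbounded homogeneous conductor.

    In that limit the volume currents are magnetically silent and
    B(r) = mu0/(4 pi) Q x (r - r0) / |r - r0|^3.
    """
    if spec.kind != "dipole":
        raise ValueError(f"expected dipole excitation, got {spec.kind!r}")
    pts = _as_points(points)
    B = np.zeros_like(pts)
    for q, r0 in spec._dipoles():
        B += _dipole_B(q, r0, pts)
    return FieldSolution(points=pts, B=B, H=B / MU0)


def _sarvas_B(Q, r0, pts, center) -> np.ndarray:
    """Sarvas (1987) exterior field of a dipole in a spherical conductor."""
    r0 = r0 - center
    pts = pts - center
    r = pts
    rn = np.linalg.norm(r, axis=1)
    a = r - r0
    an = np.linalg.norm(a, axis=1)
    if np.any(an < 1e-12):
        raise ValueError("field requested at the dipole position (singularity)")
    ar = np.einsum("ij,j->i", r, r0)
    adotr = np.einsum("ij,ij->i", a, r)
    F = an * (rn * an + rn**2 - ar)
    gF = (
        (an**2 / rn + adotr / an + 2 * an + 2 * rn)[:, None] * r
        - (an + 2 * rn + adotr / an)[:, None] * r0
    )
    Qxr0 = np.cross(Q, r0)
    return MU0 / (4 * np.pi * F[:, None] ** 2) * (
        F[:, None] * Qxr0 - (pts @ Qxr0)[:, None] * gF
    )


def eval_dipole_sphere(spec: SourceSpec, head: HeadModel, points) -> FieldSolution:
    """Exterior field of a dipole inside the spherical head stand-in.

    The result depends only on the geometry (dipole position relative to
    the sphere center), not on the shells' conductivity profile --
    the defining property of spherically symmetric conductors.  Radial
    dipole components are magnetically silent.
    """
    if spec.kind != "dipole":
        raise ValueError(f"expected dipole excitation, got {spec.kind!r}")
    pts = _as_points(points)
    r0_rel = np.linalg.norm(spec.r0 - head.center)
    if r0_rel >= head.inner_radius:
        raise ValueError(
            f"dipole at radius {r0_rel:.4f} m is not strictly inside the innermost "
            f"shell (radius {head.inner_radius:.4f} m)"
        )
    outside = np.linalg.norm(pts - head.center, axis=1) > head.outer_radius
    if not outside.all():
        raise ValueError("all probe points must lie outside the head surface")
    B = np.zeros_like(pts)
    for q, r0 in spec._dipoles():
        B += _sarvas_B(q, r0, pts, head.center)
    return FieldSolution(points=pts, B=B, H=B / MU0)


def evaluate(spec: SourceSpec, points, head: Optional[HeadModel] = None) -> FieldSolution:
    """Dispatch on excitation kind (dipole uses the head when given)."""
    if spec.kind == "homogeneous":
        return eval_homogeneous(spec, points)
    if head is not None:
        return eval_dipole_sphere(spec, head, points)
    return eval_dipole_infinite(spec, points)
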