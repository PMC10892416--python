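"""Head stand-in: a parametric three-shell spherical volume conductor.

The shells emulate a skin / skull / white-matter segmentation: a
white-matter ball, a skull shell of configurable thickness (default
3 mm), and a skin shell out to the outer radius (default 0.10 m, i.e. a
20 cm head).  Conductivities default to the standard tissue values
(skin 1.00 S/m, skull 0.05 S/m, white matter 0.43 S/m).  Triangulated
STL surfaces can be attached for geometry inspection (standoff
placement, nesting checks); field evaluation itself always uses the
spherical or infinite-medium closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

__all__ = ["Shell", "HeadModel", "make_sphere_head", "load_head_surfaces", "TISSUE_DEFAULTS"]

#: (conductivity S/m, relative permittivity) per tissue.  The skull
#: permittivity is quoted in the literature as a wide range (4e4..1e6);
#: the geometric mean 2e5 is stored as the default.
TISSUE_DEFAULTS: Dict[str, tuple] = {
    "skin": (1.00, 1.2e6),
    "skull": (0.05, 2.0e5),
    "white_matter": (0.43, 3.0e7),
}


@dataclass(frozen=True)
class Shell:
    """One tissue compartment bounded by its outer surface."""

    name: str
    outer_radius: float
    sigma: float
    eps_r: float
    mesh: Optional[object] = None  # trimesh.Trimesh when loaded from STL

    def __post_init__(self):
        if self.outer_radius <= 0:
            raise ValueError(f"shell {self.name!r}: outer radius must be positive")
        if self.sigma < 0:
            raise ValueError(f"shell {self.name!r}: conductivity must be >= 0")


@dataclass(frozen=True)
class HeadModel:
    """Ordered shells, outermost first, plus the head center position."""

    shells: List[Shell]
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        radii = [s.outer_radius for s in self.shells]
        if any(a <= b for a, b in zip(radii, radii[1:])):
            raise ValueError(f"shells must be strictly nested, got radii {radii}")

    @property
    def outer_radius(self) -> float:
        return self.shells[0].outer_radius

    @property
    def inner_radius(self) -> float:
        return self.shells[-1].outer_radius

    def contains(self, points, shell: Optional[str] = None) -> np.ndarray:
        """Boolean mask of points inside the outer surface (or a named shell's)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        r = np.linalg.norm(points - self.center, axis=1)
        radius = self.outer_radius
        if shell is not None:
            radius = next(s.outer_radius for s in self.shells if s.name == shell)
        return r < radius

    def distance_to_surface(self, points) -> np.ndarray:
        """Unsigned distance from points to the outer surface.

        Uses the attached triangle mesh when present, otherwise the
        sphere closed form.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        outer = self.shells[0]
        if outer.mesh is not None:
            return _mesh_distance(outer.mesh, points)
        return np.abs(np.linalg.norm(points - self.center, axis=1) - outer.outer_radius)

    def scaled_conductivities(self, factor: float) -> "HeadModel":
        shells = [
            Shell(s.name, s.outer_radius, s.sigma * factor, s.eps_r, s.mesh)
            for s in self.shells
        ]
        return HeadModel(shells=shells, center=self.center)


def make_sphere_head(
    outer_radius: float = 0.100,
    skull_thickness: float = 0.003,
    inner_radius: Optional[float] = None,
    properties: Optional[Dict[str, tuple]] = None,
    center=(0.0, 0.0, 0.0),
) -> HeadModel:
    """Three concentric spherical shells: skin, skull, white matter.

    The skull occupies ``[inner_radius, inner_radius + skull_thickness]``
    and the skin extends from there to ``outer_radius``.  Defaults give
    shell boundaries at 0.100 / 0.097 / 0.094 m.
    """
    if skull_thickness <= 0:
        raise ValueError("skull thickness must be positive")
    if inner_radius is None:
        inner_radius = outer_radius - 2 * skull_thickness
    if not (0 < inner_radius < inner_radius + skull_thickness < outer_radius):
        raise ValueError(
            f"radii not nested: inner={inner_radius}, skull thickness="
            f"{skull_thickness}, outer={outer_radius}"
        )
    props = {**TISSUE_DEFAULTS, **(properties or {})}
    shells = [
        Shell("skin", outer_radius, *props["skin"]),
        Shell("skull", inner_radius + skull_thickness, *props["skull"]),
        Shell("white_matter", inner_radius, *props["white_matter"]),
    ]
    return HeadModel(shells=shells, center=np.asarray(center, dtype=float))


def load_head_surfaces(
    stl_files: Dict[str, "str | Path"],
    properties: Optional[Dict[str, tuple]] = None,
    center=(0.0, 0.0, 0.0),
    nesting_samples: int = 200,
) -> HeadModel:
    """Build a head model from watertight STL surfaces, one per tissue.

    ``stl_files`` maps tissue name (skin / skull / white_matter) to an
    STL path, outermost first.  Surfaces must be watertight; nesting is
    verified by containment sampling of each inner surface's vertices in
    the enclosing one.  Field evaluation still uses the spherical
    evaluators -- the meshes serve distance queries and inspection.
    """
    import trimesh

    props = {**TISSUE_DEFAULTS, **(properties or {})}
    center = np.asarray(center, dtype=float)
    shells: List[Shell] = []
    meshes = []
    for name, path in stl_files.items():
        path = Path(path)
        if not path.exists() or path.stat().st_size == 0:
            raise ValueError(f"STL file for {name!r} is missing or empty: {path}")
        mesh = trimesh.load_mesh(str(path), file_type="stl")
        if mesh.is_empty or len(mesh.faces) == 0:
            raise ValueError(f"STL file for {name!r} contains no triangles: {path}")
        if not mesh.is_watertight:
            raise ValueError(f"surface for {name!r} is not watertight: {path}")
        radius = float(np.linalg.norm(mesh.vertices - center, axis=1).mean())
        sigma, eps_r = props.get(name, (0.0, 1.0))
        shells.append(Shell(name, radius, sigma, eps_r, mesh=mesh))
        meshes.append(mesh)
    for outer, inner in zip(meshes, meshes[1:]):
        verts = inner.vertices
        if len(verts) > nesting_samples:
            idx = np.linspace(0, len(verts) - 1, nesting_samples).astype(int)
            verts = verts[idx]
        if not _mesh_contains(outer, verts).all():
            raise ValueError("surfaces are not strictly nested")
    return HeadModel(shells=shells, center=center)


# ---------------------------------------------------------------------------
# triangle-mesh geometry helpers (kept dependency-light: no spatial index)
# ---------------------------------------------------------------------------


def _mesh_distance(mesh, points: np.ndarray) -> np.ndarray:
    """Unsigned distance from each point to the closest mesh triangle."""
    tri = mesh.triangles  # (F, 3, 3)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    out = np.empty(len(points))
    for i, p in enumerate(points):
        ap = p - a
        # project into each triangle's plane using barycentric coordinates
        d00 = np.einsum("ij,ij->i", ab, ab)
        d01 = np.einsum("ij,ij->i", ab, ac)
        d11 = np.einsum("ij,ij->i", ac, ac)
        d20 = np.einsum("ij,ij->i", ap, ab)
        d21 = np.einsum("ij,ij->i", ap, ac)
        denom = d00 * d11 - d01 * d01
        v = (d11 * d20 - d01 * d21) / denom
        w = (d00 * d21 - d01 * d20) / denom
        # clamp to the triangle (projects edge/vertex regions onto edges)
        v = np.clip(v, 0.0, 1.0)
        w = np.clip(w, 0.0, 1.0)
        scale = np.clip(v + w, 1.0, None)
        v /= scale
        w /= scale
        closest = a + v[:, None] * ab + w[:, None] * ac
        out[i] = np.linalg.norm(p - closest, axis=1).min()
    return out


def _mesh_contains(mesh, points: np.ndarray) -> np.ndarray:
    """Point-in-mesh test by the generalized winding number (sum of
    signed solid angles; ~4 pi inside a watertight surface)."""
    tri = mesh.triangles
    inside = np.empty(len(points), dtype=bool)
    for i, p in enumerate(points):
        a = tri[:, 0] - p
        b = tri[:, 1] - p
        c = tri[:, 2] - p
        la = np.linalg.norm(a, axis=1)
        lb = np.linalg.norm(b, axis=1)
        lc = np.linalg.norm(c, axis=1)
        num = np.einsum("ij,ij->i", a, np.cross(b, c))
        den = (
            la * lb * lc
            + np.einsum("ij,ij->i", a, b) * lc
            + np.einsum("ij,ij->i", b, c) * la
            + np.einsum("ij,ij->i", c, a) * lb
        )
        omega = 2 * np.arctan2(num, den)
        inside[i] = abs(omega.sum()) > 2 * np.pi
    return inside
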