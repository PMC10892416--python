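"""Mutual magnetostatic response of the high-permeability sensor layers.

The magnetostrictive films are soft-magnetic (mu_r >> 1); in an applied
field each film magnetizes, and its stray (demagnetizing) field alters
the flux inside its neighbors -- the crosstalk mechanism.  The films are
discretized into rectangular cells carrying uniform magnetization M.
The field of a uniformly magnetized rectangular prism has a closed form
(surface "magnetic charge" on its faces), which yields a dense linear
interaction operator; the self-consistency condition

    M_i = chi_i [ H_applied(r_i) + sum_j K_ij M_j ]

is solved directly (or by damped fixed-point iteration).  The flux
density inside a cell is B = mu0 (H_applied + H_demag + M).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Sequence, Tuple

import numpy as np

from .geometry import ArrayLayout
from .sources import MU0

__all__ = [
    "MagnetizationGrid",
    "InteractionOperator",
    "MagnetostaticSolution",
    "ConvergenceError",
    "prism_field_tensor",
    "dipole_field_tensor",
    "build_grid",
    "assemble_interaction",
    "solve_magnetization",
    "mean_flux_density",
    "flux_concentration_ratio",
]


class ConvergenceError(RuntimeError):
    """Fixed-point magnetization solve failed to reach tolerance."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


# ---------------------------------------------------------------------------
# field kernels
# ---------------------------------------------------------------------------

_PERMS = {0: (1, 2, 0), 1: (2, 0, 1), 2: (0, 1, 2)}
_INVS = {ax: tuple(np.argsort(p)) for ax, p in _PERMS.items()}


def _charged_faces_field(p: np.ndarray, h: Sequence[float]) -> np.ndarray:
    """H at points ``p`` from unit magnetic surface charge on the two
    z-faces of a prism [-hx,hx]x[-hy,hy]x[-hz,hz] (the +z face carries
    +1, the -z face -1); i.e. the field of unit magnetization along z."""
    n = p.shape[0]
    out = np.zeros((n, 3))
    for s, zf in ((1.0, h[2]), (-1.0, -h[2])):
        x = p[:, 0]
        y = p[:, 1]
        z = p[:, 2] - zf
        Hx = np.zeros(n)
        Hy = np.zeros(n)
        Hz = np.zeros(n)
        for i, ai in enumerate((-h[0], h[0])):
            for j, bj in enumerate((-h[1], h[1])):
                sg = 1.0 if (i + j) % 2 == 0 else -1.0
                u = x - ai
                v = y - bj
                R = np.sqrt(u * u + v * v + z * z)
                Hx += sg * np.log(v + R)
                Hy += sg * np.log(u + R)
                # principal-branch arctan: correct solid-angle branch on
                # both sides of the face plane
                with np.errstate(divide="ignore", invalid="ignore"):
                    t = np.arctan(u * v / (z * R))
                Hz += sg * np.nan_to_num(t)
        c = s / (4 * np.pi)
        out[:, 0] -= c * Hx
        out[:, 1] -= c * Hy
        out[:, 2] += c * Hz
    return out


def prism_field_tensor(d: np.ndarray, half: Sequence[float]) -> np.ndarray:
    """Exact interaction tensor K(d) of a uniformly magnetized prism.

    ``d`` (n, 3) are displacements target-point minus prism-center for a
    prism with half-extents ``half``; the return (n, 3, 3) satisfies
    H(d) = K(d) @ M for any uniform magnetization M, valid inside and
    outside the prism (at the prism center, K = -N with N the
    point-demagnetizing tensor; exactly -I/3 for a cube).
    """
    d = np.atleast_2d(np.asarray(d, dtype=float))
    K = np.empty((d.shape[0], 3, 3))
    for ax in range(3):
        perm = _PERMS[ax]
        inv = _INVS[ax]
        hp = [half[k] for k in perm]
        H = _charged_faces_field(d[:, perm], hp)
        K[:, :, ax] = H[:, inv]
    return K


def dipole_field_tensor(d: np.ndarray, volume: float) -> np.ndarray:
    """Point-dipole approximation of the prism tensor (far field)."""
    d = np.atleast_2d(np.asarray(d, dtype=float))
    r2 = np.einsum("ij,ij->i", d, d)
    if np.any(r2 == 0):
        raise ValueError("dipole kernel is singular at zero separation")
    r5 = r2**2.5
    K = 3 * d[:, :, None] * d[:, None, :] - r2[:, None, None] * np.eye(3)
    return volume / (4 * np.pi) * K / r5[:, None, None]


# ---------------------------------------------------------------------------
# grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MagnetizationGrid:
    """Rectangular cell partition of every MS layer in a layout.

    All cells share the same half-extents; ``layer_of`` maps each cell to
    the index of its sensor in ``labels``.
    """

    centers: np.ndarray      # (N, 3)
    half: np.ndarray         # (3,)
    chi: np.ndarray          # (N,)
    layer_of: np.ndarray     # (N,) int
    labels: Tuple[str, ...]
    resolution: Tuple[int, int, int]

    def __post_init__(self):
        if np.any(self.chi < 0):
            raise ValueError("susceptibility must be >= 0")

    @property
    def n_cells(self) -> int:
        return len(self.centers)

    @property
    def cell_volume(self) -> float:
        return float(np.prod(2 * self.half))

    def with_chi(self, chi: float) -> "MagnetizationGrid":
        from dataclasses import replace

        return replace(self, chi=np.full(self.n_cells, float(chi)))

    def layer_mask(self, label: str) -> np.ndarray:
        return self.layer_of == self.labels.index(label)


def build_grid(
    layout: ArrayLayout,
    resolution: Tuple[int, int, int] = (24, 6, 1),
    mu_r: Optional[float] = None,
) -> MagnetizationGrid:
    """Tile each sensor's MS layer with nx x ny x nz cells.

    ``mu_r`` overrides the MS material permeability (e.g. 1.0 for the
    air-reference validation solve).
    """
    nx, ny, nz = resolution
    if min(nx, ny, nz) < 1:
        raise ValueError("grid resolution must be >= 1 in every direction")
    centers = []
    chis = []
    layer_of = []
    half = None
    for idx, (label, sensor) in enumerate(layout):
        origin, size = sensor.world_box("ms")
        h = size / np.array([2 * nx, 2 * ny, 2 * nz])
        if half is None:
            half = h
        elif not np.allclose(h, half):
            raise ValueError("all MS layers must share identical dimensions")
        gx = origin[0] + (np.arange(nx) + 0.5) * size[0] / nx
        gy = origin[1] + (np.arange(ny) + 0.5) * size[1] / ny
        gz = origin[2] + (np.arange(nz) + 0.5) * size[2] / nz
        c = np.stack(np.meshgrid(gx, gy, gz, indexing="ij"), axis=-1).reshape(-1, 3)
        centers.append(c)
        material_chi = sensor.layers["ms"].material.chi if mu_r is None else mu_r - 1.0
        chis.append(np.full(len(c), material_chi))
        layer_of.append(np.full(len(c), idx, dtype=int))
    return MagnetizationGrid(
        centers=np.concatenate(centers),
        half=np.asarray(half),
        chi=np.concatenate(chis),
        layer_of=np.concatenate(layer_of),
        labels=tuple(layout.labels),
        resolution=(nx, ny, nz),
    )


# ---------------------------------------------------------------------------
# interaction operator and solve
# ---------------------------------------------------------------------------


@dataclass
class InteractionOperator:
    """Dense linear map M (N,3) -> demagnetizing field H_d (N,3)."""

    matrix: np.ndarray  # (3N, 3N)

    def apply(self, M: np.ndarray) -> np.ndarray:
        return (self.matrix @ M.reshape(-1)).reshape(-1, 3)


def assemble_interaction(
    grid: MagnetizationGrid,
    dipole_cutoff: Optional[float] = None,
    block: int = 192,
) -> InteractionOperator:
    """Assemble the cell-to-cell interaction operator.

    Every pair uses the exact uniformly-magnetized-prism field (self-term
    included).  When ``dipole_cutoff`` is given, pairs farther apart than
    ``dipole_cutoff`` times the cell diagonal use the point-dipole kernel
    instead (cheap far-field approximation).
    """
    c = grid.centers
    N = grid.n_cells
    # coincident centers make the linear system singular
    _, counts = np.unique(np.round(c / max(grid.half.min(), 1e-12) * 4).astype(np.int64), axis=0, return_counts=True)
    if np.any(counts > 1):
        raise ValueError("coincident cell centers in the magnetization grid")
    vol = grid.cell_volume
    diag = 2 * np.linalg.norm(grid.half)
    Kb = np.empty((N, 3, N, 3))
    for i0 in range(0, N, block):
        i1 = min(i0 + block, N)
        d = (c[i0:i1, None, :] - c[None, :, :]).reshape(-1, 3)
        if dipole_cutoff is None:
            K = prism_field_tensor(d, grid.half)
        else:
            r = np.linalg.norm(d, axis=1)
            far = r > dipole_cutoff * diag
            K = np.empty((len(d), 3, 3))
            if np.any(~far):
                K[~far] = prism_field_tensor(d[~far], grid.half)
            if np.any(far):
                K[far] = dipole_field_tensor(d[far], vol)
        Kb[i0:i1] = K.reshape(i1 - i0, N, 3, 3).transpose(0, 2, 1, 3)
    return InteractionOperator(matrix=Kb.reshape(3 * N, 3 * N))


@dataclass
class MagnetostaticSolution:
    """Solved magnetization state over the grid."""

    grid: MagnetizationGrid
    M: np.ndarray       # (N, 3) magnetization, A/m
    H_applied: np.ndarray
    H_demag: np.ndarray
    B: np.ndarray       # (N, 3) flux density inside cells, T
    residual: float

    def layer_mean_abs(self, label: str, component: str = "x") -> float:
        return mean_flux_density(self, label, component)


_COMPONENTS = {"x": 0, "y": 1, "z": 2}


def solve_magnetization(
    layout_or_grid,
    field_evaluator: Callable[[np.ndarray], np.ndarray],
    resolution: Tuple[int, int, int] = (24, 6, 1),
    method: str = "direct",
    tol: float = 1e-8,
    max_iter: int = 2000,
    relaxation: Optional[float] = None,
    operator: Optional[InteractionOperator] = None,
    dipole_cutoff: Optional[float] = None,
) -> MagnetostaticSolution:
    """Solve M = chi (H_applied + K M) over all MS-layer cells.

    ``field_evaluator`` maps an (N, 3) array of points to the applied H
    (A/m) at those points; a pre-assembled ``operator`` may be passed to
    reuse the interaction matrix across solves on the same grid.
    """
    if isinstance(layout_or_grid, MagnetizationGrid):
        grid = layout_or_grid
    else:
        grid = build_grid(layout_or_grid, resolution)
    Happ = np.asarray(field_evaluator(grid.centers), dtype=float)
    if Happ.shape != grid.centers.shape:
        raise ValueError("field evaluator must return an (N, 3) array")
    if not np.all(np.isfinite(Happ)):
        raise ValueError("applied field is not finite at all cell centers")
    if operator is None:
        operator = assemble_interaction(grid, dipole_cutoff=dipole_cutoff)
    N = grid.n_cells
    chi = grid.chi
    if np.all(chi == 0):
        M = np.zeros((N, 3))
        Hd = np.zeros((N, 3))
        residual = 0.0
    elif method == "direct":
        A = -chi.repeat(3)[:, None] * operator.matrix
        A[np.arange(3 * N), np.arange(3 * N)] += 1.0
        rhs = (chi[:, None] * Happ).reshape(-1)
        M = np.linalg.solve(A, rhs).reshape(N, 3)
        Hd = operator.apply(M)
        residual = float(
            np.linalg.norm(M - chi[:, None] * (Happ + Hd))
            / max(np.linalg.norm(M), 1e-300)
        )
    elif method == "fixed_point":
        # damped Picard iteration; the natural damping scale is
        # 1/(1 + chi/3) (self-term of a compact cell)
        omega = relaxation if relaxation is not None else 1.0 / (1.0 + chi.max() / 3.0)
        M = np.zeros((N, 3))
        residual = np.inf
        for _ in range(max_iter):
            target = chi[:, None] * (Happ + operator.apply(M))
            Mn = (1 - omega) * M + omega * target
            residual = float(
                np.linalg.norm(Mn - M) / max(np.linalg.norm(Mn), 1e-300)
            )
            M = Mn
            if residual < tol:
                break
        else:
            raise ConvergenceError(
                f"fixed-point magnetization solve did not converge in {max_iter} "
                f"iterations (relative residual {residual:.3e}, tolerance {tol:.1e})",
                residual,
            )
        Hd = operator.apply(M)
    else:
        raise ValueError(f"unknown solve method {method!r}")
    B = MU0 * (Happ + Hd + M)
    return MagnetostaticSolution(
        grid=grid, M=M, H_applied=Happ, H_demag=Hd, B=B, residual=residual
    )


def mean_flux_density(
    solution: MagnetostaticSolution, label: str, component: str = "x"
) -> float:
    """Volume-weighted mean of |B_component| (or |B| for ``norm``) over a layer."""
    grid = solution.grid
    if label not in grid.labels:
        raise KeyError(f"unknown layer {label!r}; known: {list(grid.labels)}")
    mask = grid.layer_mask(label)
    B = solution.B[mask]
    if component == "norm":
        vals = np.linalg.norm(B, axis=1)
    else:
        try:
            vals = np.abs(B[:, _COMPONENTS[component]])
        except KeyError:
            raise ValueError(f"component must be one of x, y, z, norm; got {component!r}")
    # cells are equal-volume, so the volume weighting is uniform
    return float(vals.mean())


def flux_concentration_ratio(
    solution: MagnetostaticSolution,
    air_reference: MagnetostaticSolution,
    label: str,
    component: str = "x",
) -> float:
    """Mean |Bx| with sensor material over mean |Bx| with chi = 0.

    Both solutions must live on identical grids (same cell centers).
    """
    if solution.grid.centers.shape != air_reference.grid.centers.shape or not np.allclose(
        solution.grid.centers, air_reference.grid.centers
    ):
        raise ValueError("solutions are not on identical grids")
    denom = mean_flux_density(air_reference, label, component)
    if denom == 0:
        raise ZeroDivisionError(f"air-reference mean |B{component}| is zero for {label}")
    return mean_flux_density(solution, label, component) / denom
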