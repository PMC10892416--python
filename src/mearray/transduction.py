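"""Linearized magnetoelectric transduction of the composite cantilever.

The sensor is a clamped-free three-layer beam (MS film / Si substrate /
AlN film) operated at its first flexural resonance.  The chain is:

1. the axial magnetic field H_x in the MS film produces an actuation
   stress sigma = e_h * H_x (linear small-signal piezomagnetic
   coupling), equivalent to a bending moment about the composite
   neutral axis;
2. the beam responds harmonically in its first clamped-free mode with
   structural damping (loss factor eta);
3. the bending strain in the AlN film generates an open-circuit voltage
   through the thickness (D3 = 0), reported as the mean absolute
   potential over the electrode with the bottom face grounded.

Section properties use the wide-beam (plate) moduli E/(1 - nu^2), since
every layer is far wider than thick.  Reduced-order single-mode
projection replaces a full 3-D model; a finite-difference modal solver
is provided as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import scipy.linalg

from .geometry import SensorGeometry, build_sensor
from .materials import EPS0, MU0, Material

__all__ = [
    "Layer",
    "CompositeBeam",
    "BeamState",
    "section_properties",
    "resonance_frequency",
    "beam_modes_fd",
    "magnetostrictive_drive",
    "harmonic_response",
    "piezo_voltage",
    "sensitivity",
    "CLAMPED_FREE_LAMBDA1",
]

#: First clamped-free Euler-Bernoulli eigenvalue (beta * L).
CLAMPED_FREE_LAMBDA1 = 1.8751040687119611


@dataclass(frozen=True)
class Layer:
    material: Material
    thickness: float
    width: float
    length: float
    z_bottom: float  # bottom face position in the stack, m


@dataclass(frozen=True)
class CompositeBeam:
    """Ordered stack bottom-to-top: MS, substrate, PE; clamp at x = 0."""

    layers: Tuple[Layer, Layer, Layer]
    length: float
    eta: float = 0.01

    def __post_init__(self):
        if len(self.layers) != 3:
            raise ValueError("composite stack must have exactly three layers")
        if self.length <= 0:
            raise ValueError("beam length must be positive")
        if self.eta < 0:
            raise ValueError("loss factor must be >= 0")

    @property
    def ms(self) -> Layer:
        return self.layers[0]

    @property
    def substrate(self) -> Layer:
        return self.layers[1]

    @property
    def pe(self) -> Layer:
        return self.layers[2]

    @classmethod
    def from_sensor(cls, sensor: Optional[SensorGeometry] = None, eta: float = 0.01) -> "CompositeBeam":
        if sensor is None:
            sensor = build_sensor()
        layers = []
        for key in ("ms", "substrate", "pe"):
            box = sensor.layers[key]
            layers.append(
                Layer(
                    material=box.material,
                    thickness=box.size[2],
                    width=box.size[1],
                    length=box.size[0],
                    z_bottom=box.origin[2],
                )
            )
        return cls(layers=tuple(layers), length=sensor.layers["substrate"].size[0], eta=eta)


def section_properties(beam: CompositeBeam) -> Tuple[float, float, float]:
    """Composite bending stiffness <EI>, mass per length <rhoA>, and the
    neutral-axis height z_n (from the substrate bottom face)."""
    EA = zEA = rhoA = 0.0
    for layer in beam.layers:
        E = layer.material.plate_modulus
        A = layer.width * layer.thickness
        zc = layer.z_bottom + layer.thickness / 2
        EA += E * A
        zEA += E * A * zc
        rhoA += layer.material.rho * A
    if EA <= 0 or rhoA <= 0:
        raise ValueError("non-positive section stiffness or mass")
    zn = zEA / EA
    EI = 0.0
    for layer in beam.layers:
        E = layer.material.plate_modulus
        A = layer.width * layer.thickness
        zc = layer.z_bottom + layer.thickness / 2
        EI += E * (layer.width * layer.thickness**3 / 12 + A * (zc - zn) ** 2)
    return EI, rhoA, zn


def resonance_frequency(beam: CompositeBeam) -> float:
    """First clamped-free flexural eigenfrequency, Hz.

    f1 = (lambda1^2 / 2 pi) sqrt(<EI>/<rhoA>) / L^2 with lambda1 = 1.8751.
    """
    EI, rhoA, _ = section_properties(beam)
    return CLAMPED_FREE_LAMBDA1**2 / (2 * np.pi * beam.length**2) * np.sqrt(EI / rhoA)


def beam_modes_fd(beam: CompositeBeam, n_points: int = 400, n_modes: int = 5) -> np.ndarray:
    """Clamped-free eigenfrequencies from a finite-difference discretization.

    Independent cross-check of the closed form: the fourth-order operator
    (EI w'')'' = omega^2 rhoA w is discretized on a uniform grid with the
    clamped (w = w' = 0) and free (w'' = w''' = 0) boundary conditions
    imposed through ghost points.
    """
    EI, rhoA, _ = section_properties(beam)
    n = n_points
    hgrid = beam.length / n
    # unknowns w_1..w_n at x = i*h (w_0 = 0 at clamp)
    A = np.zeros((n, n))
    stencil = np.array([1.0, -4.0, 6.0, -4.0, 1.0])

    def add(i, j, v):
        if 0 <= j < n:
            A[i, j] += v

    for i in range(n):
        xi = i + 1  # global index of unknown i (grid point)
        for k, s in zip(range(xi - 2, xi + 3), stencil):
            if k == 0:
                continue  # w = 0 at the clamp
            elif k == -1:
                # ghost from w'(0) = 0: w_{-1} = w_1
                add(i, 0, s)
            elif k == n + 1:
                # ghost from w''(L) = 0: w_{n+1} = 2 w_n - w_{n-1}
                add(i, n - 1, 2 * s)
                add(i, n - 2, -s)
            elif k == n + 2:
                # ghost from w'''(L) = 0: w_{n+2} = 2 w_{n+1} - 2 w_{n-1} + w_{n-2}
                add(i, n - 1, 4 * s)
                add(i, n - 2, -4 * s)
                add(i, n - 3, s)
            else:
                add(i, k - 1, s)
    A *= EI / hgrid**4
    w2 = np.sort(scipy.linalg.eigvals(A).real)
    w2 = w2[w2 > 0]
    return np.sqrt(w2[:n_modes] / rhoA) / (2 * np.pi)


def magnetostrictive_drive(beam: CompositeBeam, H_x: float) -> float:
    """Equivalent bending moment (N*m) of the magnetostrictive actuation.

    A mean axial field H_x in the MS film produces the axial actuation
    stress sigma = e_h11 * H_x; integrated over the film cross-section at
    its offset from the composite neutral axis this is the bending moment
    M0 = e_h11 H_x A_ms (z_ms - z_n), constant along the film's length.
    """
    ms = beam.ms
    e11 = ms.material.e_h_axial
    if e11 == 0.0:
        raise ValueError("MS material has no piezomagnetic coupling (e_h[0,0] = 0)")
    _, _, zn = section_properties(beam)
    A = ms.width * ms.thickness
    z_ms = ms.z_bottom + ms.thickness / 2
    return e11 * H_x * A * (z_ms - zn)


def _mode_shape(x: np.ndarray, L: float, lam: float = CLAMPED_FREE_LAMBDA1):
    """Clamped-free mode shape phi and derivatives phi', phi''."""
    b = lam / L
    alpha = (np.cosh(lam) + np.cos(lam)) / (np.sinh(lam) + np.sin(lam))
    bx = b * x
    phi = np.cosh(bx) - np.cos(bx) - alpha * (np.sinh(bx) - np.sin(bx))
    dphi = b * (np.sinh(bx) + np.sin(bx) - alpha * (np.cosh(bx) - np.cos(bx)))
    ddphi = b**2 * (np.cosh(bx) + np.cos(bx) - alpha * (np.sinh(bx) + np.sin(bx)))
    return phi, dphi, ddphi


@dataclass(frozen=True)
class BeamState:
    """Steady-state harmonic bending state (complex amplitudes)."""

    beam: CompositeBeam
    frequency: float
    x: np.ndarray
    displacement: np.ndarray  # complex w(x), m
    curvature: np.ndarray     # complex w''(x), 1/m
    modal_amplitude: complex

    @property
    def tip_displacement(self) -> complex:
        return self.displacement[-1]

    def axial_strain(self, z: float) -> np.ndarray:
        """Bending strain eps_1(x) at stack height z (Euler-Bernoulli)."""
        _, _, zn = section_properties(self.beam)
        return -(z - zn) * self.curvature


def harmonic_response(
    beam: CompositeBeam,
    drive_moment: float,
    frequency: float,
    n_points: int = 201,
) -> BeamState:
    """Single-mode steady-state response to the actuation moment.

    The distributed actuation moment (constant over the MS film length)
    projects onto the first mode as F1 = M0 phi'(L_ms); the modal
    equation with structural damping is
    (k1 (1 + i eta) - omega^2 m1) q = F1.
    """
    EI, rhoA, _ = section_properties(beam)
    L = beam.length
    f1 = resonance_frequency(beam)
    omega = 2 * np.pi * frequency
    if beam.eta == 0 and abs(frequency - f1) / f1 < 1e-9:
        raise ValueError("undamped resonance: eta = 0 exactly at f1 gives an unbounded response")
    x = np.linspace(0.0, L, n_points)
    phi, dphi, ddphi = _mode_shape(x, L)
    m1 = rhoA * np.trapezoid(phi**2, x)
    k1 = EI * np.trapezoid(ddphi**2, x)
    Lms = min(beam.ms.length, L)
    _, dphi_ms, _ = _mode_shape(np.array([Lms]), L)
    F1 = drive_moment * dphi_ms[0]
    q = F1 / (k1 * (1 + 1j * beam.eta) - omega**2 * m1)
    return BeamState(
        beam=beam,
        frequency=frequency,
        x=x,
        displacement=q * phi,
        curvature=q * ddphi,
        modal_amplitude=q,
    )


def piezo_voltage(state: BeamState, beam: Optional[CompositeBeam] = None) -> float:
    """Open-circuit electrode voltage: mean |V| over the PE top surface.

    Through-thickness open-circuit condition D3 = 0 gives
    E3 = -e31,f eps_1 / (eps0 eps_r), hence the local potential of the
    top electrode (bottom grounded) V(x) = e31,f eps_1(x) t_pe /
    (eps0 eps_r); reported is the mean absolute value over the electrode.
    """
    beam = beam or state.beam
    pe = beam.pe
    if pe.material.eps_r <= 0:
        raise ValueError("PE relative permittivity must be positive")
    z_pe = pe.z_bottom + pe.thickness / 2
    eps1 = state.axial_strain(z_pe)
    V = pe.material.e31_eff * eps1 * pe.thickness / (EPS0 * pe.material.eps_r)
    mask = state.x <= min(pe.length, beam.length)
    return float(np.mean(np.abs(V[mask])))


def sensitivity(beam: CompositeBeam, frequency: Optional[float] = None) -> float:
    """Voltage per tesla of mean axial flux density in the MS film (V/T).

    Computed for a unit mean H_x and converted through the in-material
    relation mean Bx = mu0 (1 + chi) mean Hx; by linearity the ratio is
    independent of excitation amplitude.
    """
    if frequency is None:
        frequency = resonance_frequency(beam)
    M0 = magnetostrictive_drive(beam, 1.0)
    state = harmonic_response(beam, M0, frequency)
    V = piezo_voltage(state, beam)
    B_per_H = MU0 * (1.0 + beam.ms.material.chi)
    if B_per_H == 0:
        raise ZeroDivisionError("zero mean flux density in the MS film")
    return V / B_per_H
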