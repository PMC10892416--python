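"""Layer materials for magnetoelectric composite cantilever sensors.

A sensor is a three-layer stack: an amorphous magnetostrictive film
(FeCoSiB), a silicon substrate, and a polycrystalline piezoelectric film
(AlN).  Each layer is described by its density, an elastic description
(either a full 6x6 Voigt stiffness matrix or an isotropic ``(E, nu)``
pair), the linearized small-signal coupling matrices -- piezomagnetic
``e_h`` in stress-magnetization form (units of tesla) and piezoelectric
``e_e`` in stress-charge form (C/m^2) -- and the relative permeability,
relative permittivity, conductivity and mechanical loss factor.

The module ships default materials with literature constants for the
FeCoSiB/Si/AlN stack; all of them can be overridden field by field.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "Material",
    "isotropic_stiffness",
    "fecosib",
    "silicon",
    "aln",
    "air",
]

EPS0 = 8.8541878128e-12
MU0 = 4e-7 * np.pi


def isotropic_stiffness(E: float, nu: float) -> np.ndarray:
    """6x6 Voigt stiffness matrix of an isotropic solid."""
    if E <= 0:
        raise ValueError(f"Young's modulus must be positive, got {E}")
    if not -1.0 < nu < 0.5:
        raise ValueError(f"Poisson ratio must lie in (-1, 0.5), got {nu}")
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    c = np.zeros((6, 6))
    c[:3, :3] = lam
    c[np.arange(3), np.arange(3)] = lam + 2 * mu
    c[np.arange(3, 6), np.arange(3, 6)] = mu
    return c


@dataclass(frozen=True)
class Material:
    """Constitutive constants of one sensor layer.

    Parameters
    ----------
    name:
        Human-readable identifier.
    rho:
        Mass density, kg/m^3. Must be positive.
    stiffness:
        6x6 Voigt elasticity matrix (Pa); ``None`` means build it from the
        isotropic pair ``(E, nu)``.
    E, nu:
        Isotropic Young's modulus (Pa) and Poisson ratio; ignored when a
        full stiffness matrix is supplied (they are then derived from it).
    e_h:
        3x6 piezomagnetic coupling in stress-magnetization form, tesla.
    e_e:
        3x6 piezoelectric coupling in stress-charge form, C/m^2.
    mu_r, eps_r, sigma, eta:
        Relative permeability, relative permittivity, conductivity (S/m)
        and mechanical loss factor.
    """

    name: str
    rho: float
    E: Optional[float] = None
    nu: Optional[float] = None
    stiffness: Optional[np.ndarray] = None
    e_h: np.ndarray = field(default_factory=lambda: np.zeros((3, 6)))
    e_e: np.ndarray = field(default_factory=lambda: np.zeros((3, 6)))
    mu_r: float = 1.0
    eps_r: float = 1.0
    sigma: float = 0.0
    eta: float = 0.0

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError(f"density must be positive, got {self.rho}")
        if self.mu_r < 1.0:
            raise ValueError(f"relative permeability must be >= 1, got {self.mu_r}")
        if self.eps_r <= 0:
            raise ValueError(f"relative permittivity must be positive")
        if self.eta < 0:
            raise ValueError(f"loss factor must be >= 0, got {self.eta}")
        if self.stiffness is None and (self.E is None or self.nu is None):
            raise ValueError(f"material {self.name!r} needs a stiffness matrix or (E, nu)")
        c = self.voigt_stiffness()
        if not np.allclose(c, c.T):
            raise ValueError("stiffness matrix must be symmetric")
        if np.linalg.eigvalsh(c).min() <= 0:
            raise ValueError("stiffness matrix must be positive definite")

    def voigt_stiffness(self) -> np.ndarray:
        if self.stiffness is not None:
            return np.asarray(self.stiffness, dtype=float)
        return isotropic_stiffness(self.E, self.nu)

    @property
    def compliance(self) -> np.ndarray:
        return np.linalg.inv(self.voigt_stiffness())

    @property
    def young(self) -> float:
        """Axial Young's modulus 1/s11 from the Voigt matrix."""
        return 1.0 / self.compliance[0, 0]

    @property
    def poisson(self) -> float:
        s = self.compliance
        return -s[0, 1] / s[0, 0]

    @property
    def plate_modulus(self) -> float:
        """E/(1-nu^2): axial modulus of a laterally wide thin layer."""
        return self.young / (1.0 - self.poisson**2)

    @property
    def chi(self) -> float:
        """Magnetic susceptibility mu_r - 1."""
        return self.mu_r - 1.0

    @property
    def e_h_axial(self) -> float:
        """Piezomagnetic coupling of axial field to axial stress, e_h[0,0] (T)."""
        return float(np.asarray(self.e_h)[0, 0])

    @property
    def e31_eff(self) -> float:
        """Thin-film effective piezoelectric constant e31,f (C/m^2).

        For a film free to relax through its thickness,
        e31,f = e31 - (c13/c33) e33; falls back to plain e31 when the
        stiffness matrix carries no c13/c33 anisotropy information.
        """
        e = np.asarray(self.e_e)
        c = self.voigt_stiffness()
        if c[2, 2] > 0:
            return float(e[2, 0] - c[0, 2] / c[2, 2] * e[2, 2])
        return float(e[2, 0])

    def with_(self, **changes) -> "Material":
        return replace(self, **changes)


def _fecosib_e_h(E: float = 150e9, d11: float = 3.8e-8) -> np.ndarray:
    """Piezomagnetic matrix from the small-signal strain coefficient.

    ``d11`` is the slope of magnetostrictive strain vs field at the bias
    point, in (A/m)^-1; amorphous FeCoSiB films biased near maximum slope
    show d ~ 30 ppm per saturation field of ~800 A/m.
    """
    e = np.zeros((3, 6))
    e[0, 0] = E * d11
    return e


def _aln_stiffness() -> np.ndarray:
    """Hexagonal (6mm) AlN stiffness, Pa (c-axis along z)."""
    c11, c12, c13, c33, c44 = 410e9, 149e9, 99e9, 389e9, 125e9
    c = np.zeros((6, 6))
    c[0, 0] = c[1, 1] = c11
    c[0, 1] = c[1, 0] = c12
    c[0, 2] = c[2, 0] = c[1, 2] = c[2, 1] = c13
    c[2, 2] = c33
    c[3, 3] = c[4, 4] = c44
    c[5, 5] = (c11 - c12) / 2
    return c


def _aln_e_e() -> np.ndarray:
    e = np.zeros((3, 6))
    e[2, 0] = e[2, 1] = -0.58
    e[2, 2] = 1.55
    e[0, 4] = e[1, 3] = -0.48
    return e


def fecosib(mu_r: float = 1000.0, eta: float = 0.01) -> Material:
    """Amorphous (Fe90Co10)78Si12B10 magnetostrictive film."""
    return Material(
        name="FeCoSiB",
        rho=7250.0,
        E=150e9,
        nu=0.33,
        e_h=_fecosib_e_h(),
        mu_r=mu_r,
        eps_r=1.0,
        sigma=7.7e5,
        eta=eta,
    )


def silicon(eta: float = 0.01) -> Material:
    """Silicon substrate (polysilicon-grade isotropic constants)."""
    return Material(name="Si", rho=2329.0, E=170e9, nu=0.28, eps_r=11.7, eta=eta)


def aln(eta: float = 0.01) -> Material:
    """Polycrystalline c-axis textured aluminum nitride film."""
    return Material(
        name="AlN",
        rho=3300.0,
        stiffness=_aln_stiffness(),
        e_e=_aln_e_e(),
        eps_r=9.0,
        eta=eta,
    )


def air() -> Material:
    """Air reference: mu_r = 1, used for the validation solves."""
    return Material(name="air", rho=1.2, E=1.0, nu=0.0, mu_r=1.0)
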