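"""Constitutive laws for the cochlear partition and window membranes.

The basilar membrane (BM) is an orthotropic elastic plate: its collagen
fibres run across the width (the X axis), so ``E_X`` dominates transverse
bending while ``E_Y`` (the longitudinal modulus) is two orders of magnitude
smaller.  Only the quantities the reduced-order solver consumes are derived
here: the three shear moduli from the orthotropic stress-strain relations,
the complementary Poisson ratios from the symmetry of the compliance tensor,
Rayleigh proportional damping, the velocity-proportional BM surface damping
pressure, and the stiffness scaling used to stage window pathologies
(x100 stiffening and full ossification at 200 GPa).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

__all__ = [
    "OrthotropicElasticity",
    "IsotropicElasticity",
    "DampingSpec",
    "FluidProperties",
    "shear_moduli",
    "complementary_poisson",
    "bm_damping_pressure",
    "rayleigh_damping",
    "apply_pathology",
    "PATHOLOGY_MODES",
    "OSSIFIED_YOUNGS_MODULUS",
]

#: Young's modulus of bone used to represent full ossification (Pa).
OSSIFIED_YOUNGS_MODULUS = 2.0e11

PATHOLOGY_MODES = ("normal", "x100", "ossified")


def _check_modulus(name: str, value: float) -> None:
    if not value > 0.0:
        raise ValueError(f"{name} must be strictly positive, got {value!r}")


def _check_poisson(name: str, value: float) -> None:
    if not (0.0 <= value < 0.5):
        raise ValueError(f"{name} must lie in [0, 0.5), got {value!r}")


def shear_moduli(
    E_X: float,
    E_Y: float,
    E_Z: float,
    nu_xy: float,
    nu_xz: float,
    nu_yz: float,
) -> tuple[float, float, float]:
    """Shear moduli of an orthotropic solid from its Young's moduli.

    G_ij = E_i * E_j / (E_i + E_j + 2 * E_j * nu_ij)

    In the isotropic limit (equal moduli, equal ratios) this reduces to the
    familiar G = E / (2 (1 + nu)).
    """
    for name, val in (("E_X", E_X), ("E_Y", E_Y), ("E_Z", E_Z)):
        _check_modulus(name, val)
    for name, val in (("nu_xy", nu_xy), ("nu_xz", nu_xz), ("nu_yz", nu_yz)):
        _check_poisson(name, val)
    g_xy = E_X * E_Y / (E_X + E_Y + 2.0 * E_Y * nu_xy)
    g_xz = E_X * E_Z / (E_X + E_Z + 2.0 * E_Z * nu_xz)
    g_yz = E_Y * E_Z / (E_Y + E_Z + 2.0 * E_Z * nu_yz)
    return g_xy, g_xz, g_yz


def complementary_poisson(
    E_X: float,
    E_Y: float,
    E_Z: float,
    nu_xy: float,
    nu_xz: float,
    nu_yz: float,
    *,
    printed_variant: bool = False,
) -> tuple[float, float, float]:
    """Complementary Poisson ratios from orthotropic symmetry.

    Standard compliance symmetry gives nu_ij / E_i = nu_ji / E_j, hence

        nu_yx = nu_xy * E_Y / E_X
        nu_zx = nu_xz * E_Z / E_X
        nu_zy = nu_yz * E_Z / E_Y   (standard form)

    ``printed_variant=True`` instead evaluates the third ratio as
    nu_zy = nu_yz * E_Y / E_Z, the transcription that circulates in some of
    the cochlear-modelling literature; the standard form is the default
    because only it satisfies the compliance-tensor symmetry.

    A resulting ratio >= 0.5 triggers a warning (thermodynamic
    admissibility) but is not fatal.
    """
    for name, val in (("E_X", E_X), ("E_Y", E_Y), ("E_Z", E_Z)):
        _check_modulus(name, val)
    for name, val in (("nu_xy", nu_xy), ("nu_xz", nu_xz), ("nu_yz", nu_yz)):
        _check_poisson(name, val)
    nu_yx = nu_xy * E_Y / E_X
    nu_zx = nu_xz * E_Z / E_X
    if printed_variant:
        nu_zy = nu_yz * E_Y / E_Z
    else:
        nu_zy = nu_yz * E_Z / E_Y
    for name, val in (("nu_yx", nu_yx), ("nu_zx", nu_zx), ("nu_zy", nu_zy)):
        if val >= 0.5:
            warnings.warn(
                f"derived {name} = {val:.4g} >= 0.5 is thermodynamically "
                "inadmissible for an isotropic pair; check the moduli",
                stacklevel=2,
            )
    return nu_yx, nu_zx, nu_zy


@dataclass(frozen=True)
class OrthotropicElasticity:
    """Orthotropic elasticity of the basilar membrane.

    Derived shear moduli and complementary Poisson ratios are filled on
    construction from the orthotropic relations above.
    """

    E_X: float
    E_Y: float
    E_Z: float
    nu_xy: float = 0.3
    nu_xz: float = 0.3
    nu_yz: float = 0.3
    G_xy: float = field(init=False)
    G_xz: float = field(init=False)
    G_yz: float = field(init=False)
    nu_yx: float = field(init=False)
    nu_zx: float = field(init=False)
    nu_zy: float = field(init=False)

    def __post_init__(self) -> None:
        g_xy, g_xz, g_yz = shear_moduli(
            self.E_X, self.E_Y, self.E_Z, self.nu_xy, self.nu_xz, self.nu_yz
        )
        nu_yx, nu_zx, nu_zy = complementary_poisson(
            self.E_X, self.E_Y, self.E_Z, self.nu_xy, self.nu_xz, self.nu_yz
        )
        object.__setattr__(self, "G_xy", g_xy)
        object.__setattr__(self, "G_xz", g_xz)
        object.__setattr__(self, "G_yz", g_yz)
        object.__setattr__(self, "nu_yx", nu_yx)
        object.__setattr__(self, "nu_zx", nu_zx)
        object.__setattr__(self, "nu_zy", nu_zy)


@dataclass(frozen=True)
class IsotropicElasticity:
    """Isotropic elasticity (round-window membrane, annular ligament)."""

    E: float
    nu: float

    def __post_init__(self) -> None:
        _check_modulus("E", self.E)
        # Ossified tissue is modelled with the same type; nu stays physical.
        if not (0.0 <= self.nu < 0.5):
            raise ValueError(f"nu must lie in [0, 0.5), got {self.nu!r}")

    @property
    def shear_modulus(self) -> float:
        return self.E / (2.0 * (1.0 + self.nu))


@dataclass(frozen=True)
class DampingSpec:
    """Damping constants.

    alpha : mass-proportional Rayleigh coefficient (1/s)
    beta  : stiffness-proportional Rayleigh coefficient (s)
    c     : BM surface damping coefficient (Pa per m/s); enters the partition
            impedance as a frequency-independent resistive term.
    """

    alpha: float = 100.0
    beta: float = 6.43e-7
    c: float = 5000.0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "c"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class FluidProperties:
    """Perilymph: incompressible viscous fluid."""

    rho: float = 1034.0  # kg/m^3
    mu: float = 0.0028  # Ns/m^2

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.mu <= 0:
            raise ValueError("fluid density and viscosity must be positive")


def bm_damping_pressure(v_bm: float, c: float) -> float:
    """Damping pressure on the BM surface, P = -c * V, opposing the velocity.

    In the frequency domain this contributes a real impedance ``c`` per unit
    area to the partition.
    """
    if c < 0:
        raise ValueError("damping coefficient c must be nonnegative")
    return -c * v_bm


def rayleigh_damping(alpha: float, beta: float, m: float, k: float) -> float:
    """Proportional (Rayleigh) damping term alpha*m + beta*k.

    With ``m`` and ``k`` the per-area BM mass and stiffness this is the
    resistive part r(x) of the partition impedance.
    """
    if min(alpha, beta, m, k) < 0:
        raise ValueError("rayleigh_damping arguments must be nonnegative")
    return alpha * m + beta * k


def apply_pathology(elasticity: IsotropicElasticity, mode: str) -> IsotropicElasticity:
    """Stage a window pathology by scaling the Young's modulus.

    normal   -> unchanged
    x100     -> E * 100 (stiffening by fibrosis / coupling layers)
    ossified -> E = 200 GPa (bone)
    """
    if mode == "normal":
        return elasticity
    if mode == "x100":
        return IsotropicElasticity(E=elasticity.E * 100.0, nu=elasticity.nu)
    if mode == "ossified":
        return IsotropicElasticity(E=OSSIFIED_YOUNGS_MODULUS, nu=elasticity.nu)
    raise ValueError(
        f"unknown pathology mode {mode!r}; valid modes: {', '.join(PATHOLOGY_MODES)}"
    )
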