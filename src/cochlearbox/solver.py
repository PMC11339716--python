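"""Reduced-order frequency-domain two-duct cochlea solver.

The cochlea is a straight box: two incompressible fluid ducts (scala
vestibuli above, scala tympani below) coupled along their length by a
locally reacting basilar-membrane partition and at the apex by the
helicotrema, terminated at the base by the two windows.  The oval window
is closed by the stapes footplate suspended in the annular ligament (SAL);
the round window by its membrane (RWM).  In the frequency domain the model
is a ladder network solved by nodal analysis:

* duct segments are series acoustic impedances i*w*rho*dx/A plus a
  Poiseuille viscous loss 8*pi*mu*dx/A^2;
* each BM segment is a shunt branch with the locally reacting partition
  impedance z_p(x, f) = i*w*m(x) + r(x) + c + k(x)/(i*w) divided by its
  wetted area w(x)*dx;
* the helicotrema is a fluid-plug shunt between the apical duct ends;
* each window is a lumped stiffness-mass-damping impedance in
  volume-velocity convention (Pa*s/m^3).

Forward stimulation applies a pressure source outside the oval window,
reverse stimulation outside the round window; the walls are rigid, so the
two windows are the only ports and volume velocity is conserved between
them to solver precision.

Sign conventions: x runs base (0) to apex (L); window volume velocities
are positive into the cochlea; BM displacement is positive toward the
scala tympani; phase is reported in cycles, negative = lag.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .calibration import default_calibration, spl_to_pressure, stimulus_force
from .fixtures import GeometrySpec, Materials, ScenarioSpec, default_geometry, default_materials, make_scenario
from .material_laws import (
    DampingSpec,
    FluidProperties,
    IsotropicElasticity,
    OrthotropicElasticity,
    apply_pathology,
    rayleigh_damping,
)
from .metrics import extract_cf, greenwood_position

__all__ = [
    "StimulusSpec",
    "SolutionField",
    "DiscreteCochlea",
    "CochleaModel",
    "partition_mass",
    "partition_stiffness",
    "partition_impedance",
    "window_boundary_impedance",
    "calibrated_stiffness_constant",
    "local_resonance_stiffness_constant",
    "assemble",
    "solve",
    "conservation_check",
    "make_stimulus",
    "solution_to_frame",
]

PATHWAYS = ("forward", "reverse")


@dataclass(frozen=True)
class StimulusSpec:
    """One pure-tone stimulus: pathway, frequency, level at the driven window."""

    pathway: str
    frequency: float
    level: float  # dB SPL at the driven window
    force: float  # N, delivered force (pressure * window area)

    def __post_init__(self) -> None:
        if self.pathway not in PATHWAYS:
            raise ValueError(f"pathway must be one of {PATHWAYS}, got {self.pathway!r}")
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")

    @property
    def pressure(self) -> float:
        return spl_to_pressure(self.level)


def make_stimulus(pathway: str, frequency: float, geometry: GeometrySpec | None = None) -> StimulusSpec:
    """Equal-force stimulus for a pathway at a frequency.

    Forward: 86 dB SPL over the oval-window membrane; reverse: the exact
    equal-force level over the round-window membrane (~93 dB SPL).
    """
    geometry = geometry or default_geometry()
    cal = default_calibration(geometry)
    if pathway == "forward":
        level, area = cal.level_owm, geometry.a_ow
    elif pathway == "reverse":
        level, area = cal.level_rwm, geometry.a_rw
    else:
        raise ValueError(f"pathway must be one of {PATHWAYS}, got {pathway!r}")
    return StimulusSpec(
        pathway=pathway,
        frequency=frequency,
        level=level,
        force=stimulus_force(level, area),
    )


# ---------------------------------------------------------------------------
# Partition (basilar membrane) impedance
# ---------------------------------------------------------------------------

def partition_mass(
    x: np.ndarray | float,
    geometry: GeometrySpec,
    *,
    bm_density: float = 1000.0,
    fluid: FluidProperties | None = None,
) -> np.ndarray | float:
    """Per-area BM mass m(x) (kg/m^2): structural mass plus fluid co-mass.

    The near-field fluid loading of a strip of width w scales with rho*w;
    the long-wave duct inertia is carried separately by the series duct
    impedances, so only this local co-mass is added here.
    """
    fluid = fluid or FluidProperties()
    x_hat = np.asarray(x) / geometry.bm_length
    t = geometry.bm_thickness(x_hat)
    w = geometry.bm_width(x_hat)
    return bm_density * t + fluid.rho * w


def partition_stiffness(
    x: np.ndarray | float,
    geometry: GeometrySpec,
    bm: OrthotropicElasticity,
    *,
    stiffness_const: float,
) -> np.ndarray | float:
    """Per-area BM stiffness k(x) (Pa/m) from clamped-beam bending across
    the width: k = C * E_X * t(x)^3 / w(x)^4.

    E_X governs because the collagen fibres run across the width; C is a
    single global constant fixed by the Greenwood place-frequency
    calibration at 1 kHz (see :func:`calibrated_stiffness_constant`).
    """
    x_hat = np.asarray(x) / geometry.bm_length
    t = geometry.bm_thickness(x_hat)
    w = geometry.bm_width(x_hat)
    return stiffness_const * bm.E_X * t**3 / w**4


def partition_impedance(
    x: np.ndarray | float,
    f: float,
    bm: OrthotropicElasticity,
    geometry: GeometrySpec,
    damping: DampingSpec,
    *,
    stiffness_const: float,
    bm_density: float = 1000.0,
    fluid: FluidProperties | None = None,
) -> np.ndarray | complex:
    """Locally reacting partition impedance per unit area (Pa*s/m).

    z_p(x, f) = i*2*pi*f*m(x) + [r(x) + c] + k(x) / (i*2*pi*f)
    with r(x) = alpha*m(x) + beta*k(x) (Rayleigh) and c the BM surface
    damping coefficient.  At resonance the impedance is purely resistive,
    Re z_p = r + c.
    """
    if f <= 0:
        raise ValueError("frequency must be positive")
    omega = 2.0 * np.pi * f
    m = partition_mass(x, geometry, bm_density=bm_density, fluid=fluid)
    k = partition_stiffness(x, geometry, bm, stiffness_const=stiffness_const)
    r = damping.alpha * np.asarray(m) + damping.beta * np.asarray(k)
    return 1j * omega * m + (r + damping.c) + k / (1j * omega)


# ---------------------------------------------------------------------------
# Window boundary impedances
# ---------------------------------------------------------------------------

def window_boundary_impedance(
    membrane: IsotropicElasticity,
    area: float,
    thickness: float,
    kind: str,
    f: float,
    attached_mass: float = 0.0,
    *,
    fluid: FluidProperties | None = None,
    membrane_density: float = 1000.0,
    damping: DampingSpec | None = None,
    annulus_width: float | None = None,
) -> complex:
    """Lumped window impedance in volume-velocity convention (Pa*s/m^3).

    ``kind='RWM-plate'``: the round-window membrane as a clamped circular
    plate of equivalent radius a = sqrt(area/pi).  Under uniform pressure q
    the deflection shape is w0*(1 - (r/a)^2)^2 with centre deflection
    w0 = q*a^4/(64 D), D = E t^3 / (12 (1 - nu^2)); the volume compliance is
    C_a = pi*a^6/(192 D), i.e. acoustic stiffness K_a = 192 D / (pi a^6).
    The acoustic mass combines the shape-weighted membrane mass
    9*rho_m*t/(5*pi*a^2), the baffled-piston radiation co-mass
    8*rho_f/(3*pi^2*a), and any attached structural mass / area^2.

    ``kind='SAL-annulus'``: the stapes footplate as a rigid piston of area
    ``area`` suspended in an annular ligament of width ``annulus_width``
    and depth ``thickness`` loaded in shear: mechanical stiffness
    k = G * perimeter * thickness / width with G = E/(2(1+nu)).  The
    moving mass is the attached mass (stapes) plus the one-sided piston
    radiation co-mass (8/3)*rho_f*a^3.

    Rayleigh damping (alpha, beta) applied to the lumped mass and stiffness
    supplies the resistive part.  In the ossified limit (E -> 200 GPa) the
    stiffness term dominates and the window becomes effectively rigid.
    """
    if area <= 0 or thickness <= 0 or f <= 0 or attached_mass < 0:
        raise ValueError("window impedance inputs must be physical (positive)")
    fluid = fluid or FluidProperties()
    omega = 2.0 * np.pi * f
    a = np.sqrt(area / np.pi)
    if kind == "RWM-plate":
        D = membrane.E * thickness**3 / (12.0 * (1.0 - membrane.nu**2))
        K_a = 192.0 * D / (np.pi * a**6)
        M_a = (
            9.0 * membrane_density * thickness / (5.0 * np.pi * a**2)
            + 8.0 * fluid.rho / (3.0 * np.pi**2 * a)
            + attached_mass / area**2
        )
    elif kind == "SAL-annulus":
        if annulus_width is None or annulus_width <= 0:
            raise ValueError("SAL-annulus requires a positive annulus_width")
        perimeter = 2.0 * np.pi * a
        k_mech = membrane.shear_modulus * perimeter * thickness / annulus_width
        K_a = k_mech / area**2
        M_a = (attached_mass + (8.0 / 3.0) * fluid.rho * a**3) / area**2
    else:
        raise ValueError(f"unknown window kind {kind!r}; use 'SAL-annulus' or 'RWM-plate'")
    if damping is not None:
        r_a = rayleigh_damping(damping.alpha, damping.beta, M_a, K_a)
    else:
        r_a = 0.0
    return 1j * omega * M_a + r_a + K_a / (1j * omega)


# ---------------------------------------------------------------------------
# Assembly and solution
# ---------------------------------------------------------------------------

@dataclass
class DiscreteCochlea:
    """Assembled discrete model at one frequency.

    Nodal unknowns are the scala-vestibuli and scala-tympani pressures at
    the segment centers; ``matrix`` is the complex symmetric nodal
    admittance matrix (2n x 2n).
    """

    geometry: GeometrySpec
    frequency: float
    x: np.ndarray  # segment centers (m)
    m: np.ndarray  # per-area BM mass (kg/m^2)
    k: np.ndarray  # per-area BM stiffness (Pa/m)
    r: np.ndarray  # per-area Rayleigh resistance (Pa*s/m)
    z_p: np.ndarray  # partition impedance per area (Pa*s/m)
    z_ow: complex
    z_rw: complex
    z_heli: complex | None
    fluid: FluidProperties
    matrix: sp.csc_matrix
    interior_matrix: sp.csc_matrix  # window-free network, grounded at st0
    y_duct_sv: complex
    y_duct_st: complex
    y_bm: np.ndarray

    def __post_init__(self) -> None:
        if np.real(self.z_ow) < 0 or np.real(self.z_rw) < 0:
            raise ValueError("window impedances must be passive (Re >= 0)")
        if np.any(self.r < 0):
            raise ValueError("partition resistance must be nonnegative")
        if np.any(np.diff(self.k) >= 0):
            raise ValueError("k(x) must be strictly decreasing base->apex")

    @property
    def n(self) -> int:
        return self.geometry.n_segments


@dataclass
class SolutionField:
    """Solved complex field at one frequency for one stimulus."""

    frequency: float
    pathway: str
    x: np.ndarray  # segment centers (m)
    d: np.ndarray  # complex BM displacement (m), + toward scala tympani
    p_diff: np.ndarray  # complex transpartition pressure p_sv - p_st (Pa)
    p_sv: np.ndarray  # scala vestibuli pressure (Pa)
    p_st: np.ndarray  # scala tympani pressure (Pa)
    u_ow: complex  # oval-window volume velocity, inward positive (m^3/s)
    u_rw: complex  # round-window volume velocity, inward positive (m^3/s)
    p_sv_probe: complex  # vestibule pressure 200 um from the OW (Pa)
    d_stapes: complex  # footplate piston displacement (m)
    geometry: GeometrySpec
    residual: float  # relative linear-system residual


def _duct_segment_impedance(fluid: FluidProperties, area: float, dx: float, omega: float) -> complex:
    """Series acoustic impedance of a duct segment: inertance + Poiseuille loss."""
    return (1j * omega * fluid.rho / area + 8.0 * np.pi * fluid.mu / area**2) * dx


def assemble(
    geometry: GeometrySpec,
    materials: Materials,
    f: float,
    *,
    scenario: ScenarioSpec | None = None,
    stiffness_const: float | None = None,
    include_helicotrema: bool = True,
    z_ow: complex | None = None,
    z_rw: complex | None = None,
) -> DiscreteCochlea:
    """Assemble the complex nodal system for one frequency.

    Window impedances follow the scenario's pathology staging unless given
    explicitly.  ``stiffness_const`` defaults to the Greenwood-calibrated
    value for this geometry/materials pair.
    """
    if f <= 0:
        raise ValueError("frequency must be positive")
    scenario = scenario or make_scenario("normal")
    if stiffness_const is None:
        stiffness_const = calibrated_stiffness_constant(geometry, materials)
    omega = 2.0 * np.pi * f
    n = geometry.n_segments
    dx = geometry.bm_length / n
    x = geometry.segment_centers()

    m = np.asarray(
        partition_mass(x, geometry, bm_density=materials.bm_density, fluid=materials.fluid)
    )
    k = np.asarray(partition_stiffness(x, geometry, materials.bm, stiffness_const=stiffness_const))
    r = materials.damping.alpha * m + materials.damping.beta * k
    z_p = np.asarray(
        partition_impedance(
            x,
            f,
            materials.bm,
            geometry,
            materials.damping,
            stiffness_const=stiffness_const,
            bm_density=materials.bm_density,
            fluid=materials.fluid,
        )
    )

    if z_ow is None:
        sal = apply_pathology(
            IsotropicElasticity(
                E=materials.sal.E * materials.sal_calibration, nu=materials.sal.nu
            ),
            scenario.sal_stiffness_mode,
        )
        z_ow = window_boundary_impedance(
            sal,
            geometry.a_fp,
            geometry.sal_thickness,
            "SAL-annulus",
            f,
            attached_mass=geometry.stapes_mass,
            fluid=materials.fluid,
            damping=materials.damping,
            annulus_width=geometry.sal_annulus_width,
        )
    if z_rw is None:
        rwm = apply_pathology(materials.rwm, scenario.rwm_stiffness_mode)
        z_rw = window_boundary_impedance(
            rwm,
            geometry.a_rw,
            geometry.rwm_thickness,
            "RWM-plate",
            f,
            fluid=materials.fluid,
            membrane_density=materials.rwm_density,
            damping=materials.damping,
        )

    # Branch admittances
    y_duct_sv = 1.0 / _duct_segment_impedance(materials.fluid, geometry.scala_vestibuli_area, dx, omega)
    y_duct_st = 1.0 / _duct_segment_impedance(materials.fluid, geometry.scala_tympani_area, dx, omega)
    w = np.asarray(geometry.bm_width(x / geometry.bm_length))
    y_bm = w * dx / z_p  # shunt rung admittance per segment
    y_ow = 1.0 / z_ow
    y_rw = 1.0 / z_rw

    # Nodal admittance matrix: nodes 0..n-1 = SV centers, n..2n-1 = ST centers.
    rows: list[int] = []
    cols: list[int] = []
    vals: list[complex] = []

    def add(i: int, j: int, y: complex) -> None:
        # branch of admittance y between nodes i, j (j = -1 means ground)
        rows.append(i)
        cols.append(i)
        vals.append(y)
        if j >= 0:
            rows.extend((j, i, j))
            cols.extend((j, j, i))
            vals.extend((y, -y, -y))

    for i in range(n - 1):
        add(i, i + 1, y_duct_sv)
        add(n + i, n + i + 1, y_duct_st)
    for i in range(n):
        add(i, n + i, y_bm[i])
    if include_helicotrema:
        z_heli = _duct_segment_impedance(
            materials.fluid, geometry.helicotrema_area, geometry.helicotrema_length, omega
        )
        add(n - 1, 2 * n - 1, 1.0 / z_heli)
    else:
        z_heli = None

    # Interior (window-free) network, grounded at the basal ST node: drives
    # the loop-flow solution in `solve`.  Its entries are uniformly scaled,
    # unlike the window admittances, which span ~10 orders of magnitude
    # across pathology stages.
    interior = sp.coo_matrix(
        (vals, (rows, cols)), shape=(2 * n, 2 * n), dtype=complex
    ).tolil()
    interior[n, :] = 0.0
    interior[n, n] = 1.0
    interior_matrix = sp.csc_matrix(interior)

    add(0, -1, y_ow)  # OW couples SV base to the exterior
    add(n, -1, y_rw)  # RW couples ST base to the exterior

    matrix = sp.csc_matrix(
        sp.coo_matrix((vals, (rows, cols)), shape=(2 * n, 2 * n), dtype=complex)
    )
    if not np.all(np.isfinite(matrix.data)):
        raise RuntimeError(f"non-finite assembly at f = {f} Hz")
    return DiscreteCochlea(
        geometry=geometry,
        frequency=f,
        x=x,
        m=m,
        k=k,
        r=r,
        z_p=z_p,
        z_ow=z_ow,
        z_rw=z_rw,
        z_heli=z_heli,
        fluid=materials.fluid,
        matrix=matrix,
        interior_matrix=interior_matrix,
        y_duct_sv=y_duct_sv,
        y_duct_st=y_duct_st,
        y_bm=y_bm,
    )


def solve(model: DiscreteCochlea, stimulus: StimulusSpec) -> SolutionField:
    """Solve the assembled system for one stimulus and fill all probes.

    With rigid walls the two windows are the only ports of the interior
    network, so the exact solution is a single loop flow u through
    OW -> interior -> RW.  The interior network is solved once for a unit
    volume-velocity injection (all its entries are uniformly scaled); the
    loop flow then follows from the two-terminal divider

        u = (p_ext_ow - p_ext_rw) / (z_ow + z_rw + Z_net),

    with Z_net the interior transfer impedance from the unit solve.  This
    keeps window flows accurate across ossified (near-rigid) stages, where
    a direct pressure-source solve loses them to cancellation, and makes
    volume-velocity conservation structural, exactly as incompressibility
    with rigid walls demands.  The returned field satisfies the full
    assembled pressure-source system; ``residual`` records how well.
    """
    if abs(stimulus.frequency - model.frequency) > 1e-9 * model.frequency:
        raise ValueError(
            f"stimulus frequency {stimulus.frequency} Hz does not match the "
            f"assembled model ({model.frequency} Hz)"
        )
    n = model.n
    omega = 2.0 * np.pi * model.frequency
    p_src = stimulus.pressure
    p_ext_ow = p_src if stimulus.pathway == "forward" else 0.0
    p_ext_rw = p_src if stimulus.pathway == "reverse" else 0.0

    b_unit = np.zeros(2 * n, dtype=complex)
    b_unit[0] = 1.0  # unit volume velocity into sv0; returns via grounded st0
    try:
        p_unit = spla.splu(model.interior_matrix).solve(b_unit)
    except Exception as exc:  # pragma: no cover - singular assembly
        raise RuntimeError(f"singular system at f = {model.frequency} Hz") from exc
    if not np.all(np.isfinite(p_unit)):
        raise RuntimeError(f"non-finite solution at f = {model.frequency} Hz")
    z_net = p_unit[0]  # interior impedance between sv0 and st0 (ground)

    u = (p_ext_ow - p_ext_rw) / (model.z_ow + model.z_rw + z_net)
    offset = p_ext_rw + model.z_rw * u  # absolute pressure of the st0 node
    pressures = u * p_unit + offset
    u_ow = u
    u_rw = -u

    # Residual of the reconstructed field in the full pressure-source system.
    b = np.zeros(2 * n, dtype=complex)
    if stimulus.pathway == "forward":
        b[0] = p_src / model.z_ow
    else:
        b[n] = p_src / model.z_rw
    b_norm = np.linalg.norm(b)
    residual = (
        float(np.linalg.norm(model.matrix @ pressures - b) / b_norm)
        if b_norm > 0
        else float(np.linalg.norm(model.matrix @ pressures - b))
    )

    p_sv = pressures[:n]
    p_st = pressures[n:]
    p_diff = p_sv - p_st
    v_bm = p_diff / model.z_p  # per-area BM velocity, + toward scala tympani
    d = v_bm / (1j * omega)
    # Vestibule probe: linear interpolation of the SV pressure at 200 um.
    xp = model.geometry.probe_distance_ow
    p_probe = complex(
        np.interp(xp, model.x, p_sv.real) + 1j * np.interp(xp, model.x, p_sv.imag)
    )
    d_stapes = u_ow / (model.geometry.a_fp * 1j * omega)
    return SolutionField(
        frequency=model.frequency,
        pathway=stimulus.pathway,
        x=model.x,
        d=d,
        p_diff=p_diff,
        p_sv=p_sv,
        p_st=p_st,
        u_ow=u_ow,
        u_rw=u_rw,
        p_sv_probe=p_probe,
        d_stapes=d_stapes,
        geometry=model.geometry,
        residual=residual,
    )


def conservation_check(solution: SolutionField) -> float:
    """Relative volume-velocity imbalance between the two windows.

    With rigid walls the windows are the only ports (the helicotrema is an
    internal connection, not a leak), so inward OW and RW volume velocities
    must cancel: |u_ow + u_rw| / max(|u_ow|, |u_rw|) ~ 0.
    """
    denom = max(abs(solution.u_ow), abs(solution.u_rw))
    if denom == 0:
        return 0.0
    return abs(solution.u_ow + solution.u_rw) / denom


# ---------------------------------------------------------------------------
# Greenwood stiffness calibration
# ---------------------------------------------------------------------------

def local_resonance_stiffness_constant(
    geometry: GeometrySpec,
    materials: Materials,
    *,
    target_frequency: float = 1000.0,
) -> float:
    """Initial stiffness constant from the local-resonance approximation.

    Chooses C so that sqrt(k/m)/(2*pi) equals ``target_frequency`` at the
    Greenwood place of that frequency.
    """
    x_hat = greenwood_position(target_frequency)
    x = x_hat * geometry.bm_length
    m = float(
        partition_mass(x, geometry, bm_density=materials.bm_density, fluid=materials.fluid)
    )
    t = float(geometry.bm_thickness(x_hat))
    w = float(geometry.bm_width(x_hat))
    omega0 = 2.0 * np.pi * target_frequency
    return omega0**2 * m * w**4 / (materials.bm.E_X * t**3)


def _solved_cf_location(
    geometry: GeometrySpec, materials: Materials, stiffness_const: float, f: float
) -> float:
    model = assemble(geometry, materials, f, stiffness_const=stiffness_const)
    sol = solve(model, make_stimulus("forward", f, geometry))
    loc, _ = extract_cf(np.abs(sol.d))
    return loc


@functools.lru_cache(maxsize=32)
def calibrated_stiffness_constant(
    geometry: GeometrySpec,
    materials: Materials,
    *,
    target_frequency: float = 1000.0,
    tol: float = 5e-4,
    max_iter: int = 12,
) -> float:
    """Stiffness constant C placing the solved 1-kHz CF at the Greenwood place.

    Starts from the local-resonance estimate and refines by a secant
    iteration on log C against the traveling-wave peak location of the
    normal forward model (the peak sits slightly basal of the local
    resonance because of damping).  Deterministic for a given
    geometry/materials pair; cached.
    """
    x_target = greenwood_position(target_frequency)
    c0 = local_resonance_stiffness_constant(
        geometry, materials, target_frequency=target_frequency
    )
    lc0 = np.log(c0)
    g0 = _solved_cf_location(geometry, materials, c0, target_frequency) - x_target
    if abs(g0) < tol:
        return c0
    lc1 = lc0 + (0.3 if g0 < 0 else -0.3)
    g1 = _solved_cf_location(geometry, materials, np.exp(lc1), target_frequency) - x_target
    for _ in range(max_iter):
        if abs(g1) < tol or g1 == g0:
            break
        lc_next = lc1 - g1 * (lc1 - lc0) / (g1 - g0)
        lc0, g0 = lc1, g1
        lc1 = lc_next
        g1 = _solved_cf_location(geometry, materials, np.exp(lc1), target_frequency) - x_target
    return float(np.exp(lc1))


class CochleaModel:
    """Convenience wrapper binding geometry, materials and a scenario.

    Calibrates the BM stiffness constant once (on the baseline materials —
    pathologies only move window impedances) and assembles/solves per
    frequency and pathway.
    """

    def __init__(
        self,
        geometry: GeometrySpec | None = None,
        materials: Materials | None = None,
        scenario: str | ScenarioSpec = "normal",
    ) -> None:
        self.geometry = geometry or default_geometry()
        self.materials = materials or default_materials()
        self.scenario = scenario if isinstance(scenario, ScenarioSpec) else make_scenario(scenario)
        self.stiffness_const = calibrated_stiffness_constant(self.geometry, self.materials)

    def assemble(self, f: float) -> DiscreteCochlea:
        return assemble(
            self.geometry,
            self.materials,
            f,
            scenario=self.scenario,
            stiffness_const=self.stiffness_const,
        )

    def solve(self, pathway: str, f: float) -> SolutionField:
        return solve(self.assemble(f), make_stimulus(pathway, f, self.geometry))


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

def solution_to_frame(solution: SolutionField):
    """One row per segment: x, Re d, Im d, |d|, phase in cycles re the base."""
    import pandas as pd

    from .metrics import phase_re_base_profile

    phase = phase_re_base_profile(solution.d)
    return pd.DataFrame(
        {
            "x_m": solution.x,
            "re_d_m": solution.d.real,
            "im_d_m": solution.d.imag,
            "abs_d_m": np.abs(solution.d),
            "phase_cycles_re_base": phase,
        }
    )
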