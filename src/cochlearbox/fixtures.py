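"""Model inputs: geometry, baseline materials, pathology scenarios, ensembles.

Everything the solver needs is generated here, with no external data.  The
five window/membrane areas (tympanic membrane 80 mm^2, oval-window membrane
5.1 mm^2, stapes footplate 4.2 mm^2, round-window membrane 2.3 mm^2, stapes
head 0.58 mm^2) are fixed model constants; the remaining geometry (BM
length and taper, duct areas, helicotrema) uses standard human box-model
values, every one of which can be overridden through a YAML config file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .material_laws import (
    DampingSpec,
    FluidProperties,
    IsotropicElasticity,
    OrthotropicElasticity,
)

__all__ = [
    "GeometrySpec",
    "ScenarioSpec",
    "Materials",
    "SCENARIO_NAMES",
    "PAPER_FREQUENCIES_HZ",
    "default_geometry",
    "default_materials",
    "make_scenario",
    "perturb_ensemble",
    "load_config",
    "resolved_config_dict",
    "dump_resolved_config",
]

#: Pure-tone frequencies of the reproduction run matrix (Hz).
PAPER_FREQUENCIES_HZ = (125.0, 250.0, 500.0, 1000.0, 2000.0, 4000.0)


@dataclass(frozen=True)
class GeometrySpec:
    """Straight two-duct cochlea geometry.

    Profiles are linear base->apex between the ``*_base`` / ``*_apex``
    values; ``profile`` methods evaluate them on normalized position
    x/L in [0, 1].
    """

    bm_length: float = 35e-3  # m
    n_segments: int = 500
    scala_vestibuli_area: float = 1.0e-6  # m^2, uniform
    scala_tympani_area: float = 1.0e-6  # m^2, uniform
    bm_width_base: float = 0.10e-3  # m
    bm_width_apex: float = 0.50e-3  # m
    bm_thickness_base: float = 7e-6  # m
    bm_thickness_apex: float = 2e-6  # m
    helicotrema_area: float = 0.3e-6  # m^2
    helicotrema_length: float = 1.0e-3  # m, effective fluid-plug length
    a_tm: float = 80.0e-6  # tympanic membrane (80 mm^2)
    a_ow: float = 5.1e-6  # oval-window membrane (5.1 mm^2)
    a_fp: float = 4.2e-6  # stapes footplate (4.2 mm^2)
    a_rw: float = 2.3e-6  # round-window membrane (2.3 mm^2)
    a_sh: float = 0.58e-6  # stapes head (0.58 mm^2)
    probe_distance_ow: float = 200e-6  # m, vestibule pressure probe
    rwm_thickness: float = 70e-6  # m
    sal_annulus_width: float = 0.1e-3  # m
    sal_thickness: float = 0.2e-3  # m
    stapes_mass: float = 3.3e-6  # kg

    def __post_init__(self) -> None:
        if self.n_segments < 2:
            raise ValueError("n_segments must be >= 2")
        for f in dataclasses.fields(self):
            if f.name == "n_segments":
                continue
            if not getattr(self, f.name) > 0.0:
                raise ValueError(f"geometry field {f.name} must be positive")
        if self.bm_width_apex < self.bm_width_base:
            raise ValueError("BM width must be nondecreasing base->apex")

    # -- profiles on normalized position x_hat = x / L ---------------------
    def bm_width(self, x_hat: np.ndarray | float) -> np.ndarray | float:
        return self.bm_width_base + (self.bm_width_apex - self.bm_width_base) * np.asarray(x_hat)

    def bm_thickness(self, x_hat: np.ndarray | float) -> np.ndarray | float:
        return self.bm_thickness_base + (
            self.bm_thickness_apex - self.bm_thickness_base
        ) * np.asarray(x_hat)

    def segment_centers(self) -> np.ndarray:
        """Segment-center coordinates (m), base at 0."""
        dx = self.bm_length / self.n_segments
        return (np.arange(self.n_segments) + 0.5) * dx


SCENARIO_NAMES = ("normal", "sal_x100", "sal_ossified", "rwm_x100", "rwm_ossified")

_SCENARIO_TABLE: dict[str, tuple[str, str]] = {
    "normal": ("normal", "normal"),
    "sal_x100": ("x100", "normal"),
    "sal_ossified": ("ossified", "normal"),
    "rwm_x100": ("normal", "x100"),
    "rwm_ossified": ("normal", "ossified"),
}


@dataclass(frozen=True)
class ScenarioSpec:
    """One named pathology variant of the window stiffnesses."""

    name: str
    sal_stiffness_mode: str
    rwm_stiffness_mode: str


def make_scenario(name: str) -> ScenarioSpec:
    """Build one of the five study scenarios by name."""
    try:
        sal, rwm = _SCENARIO_TABLE[name]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; valid scenarios: {', '.join(SCENARIO_NAMES)}"
        ) from None
    return ScenarioSpec(name=name, sal_stiffness_mode=sal, rwm_stiffness_mode=rwm)


@dataclass(frozen=True)
class Materials:
    """Baseline material set: BM, window membranes, fluid, damping."""

    bm: OrthotropicElasticity
    rwm: IsotropicElasticity
    sal: IsotropicElasticity
    fluid: FluidProperties
    damping: DampingSpec
    bm_density: float = 1000.0  # kg/m^3, soft tissue
    rwm_density: float = 1000.0  # kg/m^3
    #: Multiplicative calibration factor on the SAL baseline modulus; the
    #: default annulus model already places the middle-ear transfer function
    #: inside the plausibility band, so it is kept at 1.
    sal_calibration: float = 1.0


def default_materials() -> Materials:
    """Baseline material properties of the model.

    BM: orthotropic, E_X = E_Z = 2.0e6 Pa across the fibres and thickness,
    E_Y = 2.0e4 Pa longitudinally.  RWM: isotropic E = 5.0e6 Pa, nu = 0.49.
    SAL: the annular ligament's modulus is not an independently published
    constant for this model family; 1.0e5 Pa is a literature-range default,
    exposed in config.  Perilymph rho = 1034 kg/m^3, mu = 0.0028 Ns/m^2;
    Rayleigh alpha = 100 1/s, beta = 6.43e-7 s, BM surface damping c = 5000.
    """
    return Materials(
        bm=OrthotropicElasticity(E_X=2.0e6, E_Y=2.0e4, E_Z=2.0e6),
        rwm=IsotropicElasticity(E=5.0e6, nu=0.49),
        sal=IsotropicElasticity(E=1.0e5, nu=0.3),
        fluid=FluidProperties(),
        damping=DampingSpec(),
    )


def default_geometry() -> GeometrySpec:
    return GeometrySpec()


# ---------------------------------------------------------------------------
# Perturbation ensembles
# ---------------------------------------------------------------------------

def perturb_ensemble(
    base_params: Mapping[str, float],
    n: int,
    rel_sd: float,
    seed: int,
) -> list[dict[str, float]]:
    """Lognormal multiplicative perturbations of a parameter mapping.

    Each positive scalar is multiplied by an independent lognormal factor
    with unit median and relative spread ``rel_sd`` (sigma of the underlying
    normal is log(1 + rel_sd)).  Non-numeric or nonpositive entries pass
    through unchanged.  Reproducible for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rel_sd < 0:
        raise ValueError("rel_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    sigma = np.log1p(rel_sd)
    out: list[dict[str, float]] = []
    for _ in range(n):
        sample: dict[str, float] = {}
        for key, val in base_params.items():
            if isinstance(val, (int, float)) and not isinstance(val, bool) and val > 0:
                sample[key] = float(val) * float(np.exp(sigma * rng.standard_normal()))
            else:
                sample[key] = val
        out.append(sample)
    return out


# ---------------------------------------------------------------------------
# Config file support
# ---------------------------------------------------------------------------

def _apply_overrides(obj, overrides: Mapping[str, Any] | None):
    if not overrides:
        return obj
    valid = {f.name for f in dataclasses.fields(obj)}
    unknown = set(overrides) - valid
    if unknown:
        raise KeyError(
            f"unknown keys for {type(obj).__name__}: {sorted(unknown)}"
        )
    return replace(obj, **overrides)


def load_config(path: str | Path | None = None) -> tuple[GeometrySpec, Materials]:
    """Load geometry and materials, overriding defaults from a YAML file.

    The file holds nested key/value sections ``geometry``, ``bm``, ``rwm``,
    ``sal``, ``fluid``, ``damping``, ``materials``; any omitted key falls
    back to the documented default.
    """
    raw: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    geometry = _apply_overrides(default_geometry(), raw.get("geometry"))
    mats = default_materials()
    bm = _apply_overrides(mats.bm, raw.get("bm"))
    rwm = _apply_overrides(mats.rwm, raw.get("rwm"))
    sal = _apply_overrides(mats.sal, raw.get("sal"))
    fluid = _apply_overrides(mats.fluid, raw.get("fluid"))
    damping = _apply_overrides(mats.damping, raw.get("damping"))
    top = dict(raw.get("materials") or {})
    materials = Materials(
        bm=bm,
        rwm=rwm,
        sal=sal,
        fluid=fluid,
        damping=damping,
        bm_density=top.get("bm_density", mats.bm_density),
        rwm_density=top.get("rwm_density", mats.rwm_density),
        sal_calibration=top.get("sal_calibration", mats.sal_calibration),
    )
    return geometry, materials


def resolved_config_dict(geometry: GeometrySpec, materials: Materials) -> dict[str, Any]:
    """All effective parameter values as a plain nested dict."""

    def as_dict(obj, skip: tuple[str, ...] = ()) -> dict[str, Any]:
        return {
            f.name: getattr(obj, f.name)
            for f in dataclasses.fields(obj)
            if f.name not in skip
        }

    derived = ("G_xy", "G_xz", "G_yz", "nu_yx", "nu_zx", "nu_zy")
    return {
        "geometry": as_dict(geometry),
        "bm": as_dict(materials.bm, skip=derived),
        "bm_derived": {k: getattr(materials.bm, k) for k in derived},
        "rwm": as_dict(materials.rwm),
        "sal": as_dict(materials.sal),
        "fluid": as_dict(materials.fluid),
        "damping": as_dict(materials.damping),
        "materials": {
            "bm_density": materials.bm_density,
            "rwm_density": materials.rwm_density,
            "sal_calibration": materials.sal_calibration,
        },
    }


def dump_resolved_config(
    geometry: GeometrySpec, materials: Materials, path: str | Path | None = None
) -> str:
    """Emit the resolved config (every effective value) as YAML."""
    text = yaml.safe_dump(resolved_config_dict(geometry, materials), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text
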