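"""Diffusion-limited nutrient uptake and maximum osmotrophic growth rates.

The model chain:

1. Maximal diffusive uptake to a sphere,  rho = 4*pi*D*r0*(Cinf - C0)
   (C0 = 0 at the cell surface; concentrations nmol L^-1 are converted to
   nmol cm^-3, radii are in cm, so rho is in nmol s^-1).
2. A shape correction for elongated cells: the prolate-spheroid factor
   sqrt(E^2-1)/ln(E + sqrt(E^2-1)) with aspect ratio E = major/minor, or a
   finite-cylinder factor from the electrostatic-capacitance analogy
   (used in sensitivity analyses only).
3. Day/night weighting: ammonium (and urea, phosphate) is taken up around
   the clock (86400 s d^-1); nitrate and nitrite only during the 12-h
   photoperiod.
4. Division by the allometric N (or P) quota yields the maximum N- (P-)
   based osmotrophic growth rate in d^-1.

For a fixed aspect ratio the growth rate obeys an exact power law in cell
size, GR(alpha*esd) = alpha**(-1.511) * GR(esd) with 1.511 = 3*0.837 - 1,
which provides both a closed-form critical-size solution and an independent
check on the root-finder.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping

import numpy as np
from scipy.optimize import brentq
from scipy.special import ellipk

from . import allometry
from .errors import BracketError, ConfigurationError, DomainError, MissingDataError, NoSolutionError
from .physchem import SeawaterState, diffusion_coefficient, get_solute

__all__ = [
    "CellGeometry",
    "NutrientField",
    "ModelConfig",
    "GrowthPotential",
    "SCALING_EXPONENT",
    "N_SOLUTES",
    "sphere_max_uptake",
    "prolate_correction",
    "cylinder_correction",
    "shape_correction",
    "daily_nitrogen_uptake",
    "daily_phosphorus_uptake",
    "n_based_max_growth",
    "p_based_max_growth",
    "growth_potential",
    "critical_esd",
]

#: GR ~ esd**(-SCALING_EXPONENT) for fixed shape: flux ~ r0, quota ~ BV**0.837
SCALING_EXPONENT = 3.0 * allometry.LOG10_SLOPE - 1.0  # = 1.511

#: dissolved N species summed in the N-based growth rate (urea added when present)
N_SOLUTES = ("ammonium", "nitrite", "nitrate")

SECONDS_PER_DAY = 86400.0


@dataclass(frozen=True)
class CellGeometry:
    """Cell size and shape: equivalent spherical diameter (um), aspect ratio, shape class."""

    esd: float
    aspect_ratio: float = 1.0
    shape: str = "sphere"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.esd) and self.esd > 0):
            raise DomainError(f"esd must be finite and > 0 um, got {self.esd}")
        if not (np.isfinite(self.aspect_ratio) and self.aspect_ratio >= 1.0):
            raise DomainError(
                f"aspect ratio (major/minor) must be >= 1, got {self.aspect_ratio}"
            )
        if self.shape not in ("sphere", "prolate", "cylinder"):
            raise DomainError(f"unknown shape {self.shape!r}")
        if self.shape == "sphere" and self.aspect_ratio != 1.0:
            raise DomainError("sphere requires aspect_ratio == 1")

    @property
    def r0_cm(self) -> float:
        """Equivalent spherical radius in cm (esd/2 um -> cm)."""
        return self.esd / 2.0 * 1e-4

    @property
    def biovolume(self) -> float:
        """Biovolume (um^3) of the equivalent sphere, (pi/6)*esd^3."""
        return math.pi / 6.0 * self.esd**3


@dataclass(frozen=True)
class NutrientField:
    """Ambient dissolved concentrations (nmol L^-1); surface concentration fixed at 0.

    ``None`` marks a solute that was not measured; downstream operations that
    need it raise :class:`MissingDataError` rather than silently zero-filling.
    """

    ammonium: float | None = None
    nitrite: float | None = None
    nitrate: float | None = None
    phosphate: float | None = None
    urea: float | None = None

    #: dissolved concentration at the cell surface (model assumption)
    surface_concentration: float = 0.0

    def __post_init__(self) -> None:
        for name in ("ammonium", "nitrite", "nitrate", "phosphate", "urea"):
            v = getattr(self, name)
            if v is not None and not (np.isfinite(v) and v >= 0):
                raise DomainError(f"{name} concentration must be finite and >= 0, got {v}")
        if self.surface_concentration != 0.0:
            raise DomainError("the model assumes zero concentration at the cell surface")

    def require(self, name: str) -> float:
        v = getattr(self, name)
        if v is None:
            raise MissingDataError(f"no {name} concentration available")
        return float(v)

    @property
    def din(self) -> float:
        """Dissolved inorganic N (nmol L^-1): ammonium + nitrite + nitrate."""
        return sum(self.require(n) for n in N_SOLUTES)


@dataclass(frozen=True)
class ModelConfig:
    """Tunable model settings: photoperiod, uptake windows, thresholds, speciation."""

    photoperiod_hours: float = 12.0
    day_only_solutes: frozenset = frozenset({"nitrate", "nitrite"})
    round_the_clock_solutes: frozenset = frozenset({"ammonium", "urea", "phosphate"})
    redfield_np: float = 16.0
    growth_thresholds: tuple[float, ...] = (0.2, 0.6, 2.0)
    phosphate_species: str = "hpo4"
    pressure_bar: float = 1.0
    #: moles of N delivered per mole of urea taken up (CO(NH2)2 carries 2 N)
    urea_nitrogen_atoms: float = 2.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.photoperiod_hours <= 24.0):
            raise ConfigurationError("photoperiod must lie in [0, 24] h")
        if list(self.growth_thresholds) != sorted(set(self.growth_thresholds)):
            raise ConfigurationError("growth thresholds must be strictly increasing")
        overlap = self.day_only_solutes & self.round_the_clock_solutes
        if overlap:
            raise ConfigurationError(f"solutes in both uptake windows: {sorted(overlap)}")

    def uptake_window_s(self, solute: str) -> float:
        """Seconds per day during which a solute is taken up."""
        if solute in self.round_the_clock_solutes:
            return SECONDS_PER_DAY
        if solute in self.day_only_solutes:
            return self.photoperiod_hours * 3600.0
        raise ConfigurationError(f"no uptake window configured for solute {solute!r}")


@dataclass(frozen=True)
class GrowthPotential:
    """Per-cell model output: per-solute uptakes and N-/P-based growth rates."""

    max_uptake: Mapping[str, float]  # nmol s^-1, uncorrected sphere flux
    corrected_uptake: Mapping[str, float]  # nmol s^-1, after shape correction
    daily_n_uptake: float  # nmol N d^-1
    daily_p_uptake: float  # nmol P d^-1
    gr_n: float  # d^-1
    gr_p: float  # d^-1


def sphere_max_uptake(d: float, r0: float, c_ambient: float, c_surface: float = 0.0) -> float:
    """Maximal diffusive uptake to a sphere (nmol s^-1).

    ``d`` in cm^2 s^-1, ``r0`` in cm, concentrations in nmol L^-1 (converted
    to nmol cm^-3 internally).
    """
    if d <= 0 or r0 <= 0 or c_ambient < 0:
        raise DomainError("need D > 0, r0 > 0 and c_ambient >= 0")
    return 4.0 * math.pi * d * r0 * (c_ambient - c_surface) / 1000.0


def prolate_correction(aspect_ratio: float) -> float:
    """Prolate-spheroid enhancement of diffusive flux, sqrt(E^2-1)/ln(E+sqrt(E^2-1)).

    Returns exactly 1 at E = 1 (the analytic limit); strictly increasing in E.
    """
    e = float(aspect_ratio)
    if not (np.isfinite(e) and e >= 1.0):
        raise DomainError(f"aspect ratio must be >= 1, got {e}")
    if e == 1.0:
        return 1.0
    s = math.sqrt(e * e - 1.0)
    return s / math.log(e + s)


# --- finite-cylinder shape factor via the capacitance analogy -----------------
#
# Steady diffusion to an absorbing body is mathematically identical to the
# electrostatic capacitance problem; the flux enhancement of a body relative
# to the sphere flux evaluated at a reference radius is its capacitance in
# units of that radius.  Like the prolate formula above, the cylinder factor
# is expressed in units of the minor semi-axis (the cylinder radius), so the
# two are directly comparable for a cell of given length and diameter.

def _ring_potential(r: np.ndarray, z: np.ndarray, rp: np.ndarray, zp: np.ndarray) -> np.ndarray:
    """Potential at (r, z) from a unit charge spread on a coaxial ring at (rp, zp)."""
    r1 = np.sqrt((r + rp) ** 2 + (z - zp) ** 2)
    m = 4.0 * r * rp / r1**2
    return 2.0 / (np.pi * r1) * ellipk(m)


def _capacitance(rs: np.ndarray, zs: np.ndarray, widths: np.ndarray) -> float:
    """Capacitance of an axisymmetric conductor discretized into ring strips."""
    n = len(rs)
    m = np.empty((n, n))
    for i in range(n):
        m[i] = _ring_potential(rs[i], zs[i], rs, zs)
        # self-potential of a strip of width w at radius r (log-singular kernel
        # integrated analytically): V = sigma * 2w * (ln(16 r / w) + 1)
        m[i, i] = (np.log(16.0 * rs[i] / widths[i]) + 1.0) / (np.pi * rs[i])
    q = np.linalg.solve(m, np.ones(n))
    return float(q.sum())


@lru_cache(maxsize=128)
def _cylinder_capacitance(aspect: float, n_elements: int = 600) -> float:
    """Capacitance of a solid cylinder (radius 1, length/diameter = aspect), flat caps."""
    a = 1.0
    half_len = aspect * a  # L/d = aspect  =>  half-length = aspect * radius
    # generating curve: side wall of length 2*half_len plus two radial caps
    ds = (2.0 * half_len + 2.0 * a) / n_elements
    rs, zs, ws = [], [], []
    nside = max(4, round(2.0 * half_len / ds))
    zedges = np.linspace(-half_len, half_len, nside + 1)
    rs.extend([a] * nside)
    zs.extend(0.5 * (zedges[:-1] + zedges[1:]))
    ws.extend(np.diff(zedges))
    ncap = max(4, round(a / ds))
    redges = np.linspace(0.0, a, ncap + 1)
    for sign in (1.0, -1.0):
        rs.extend(0.5 * (redges[:-1] + redges[1:]))
        zs.extend([sign * half_len] * ncap)
        ws.extend(np.diff(redges))
    return _capacitance(np.asarray(rs), np.asarray(zs), np.asarray(ws))


def cylinder_correction(aspect_ratio: float) -> float:
    """Diffusive shape factor for a finite cylinder with length:diameter = E.

    Computed as the cylinder's electrostatic capacitance in units of its
    radius (boundary-element solution); exceeds the prolate factor for
    elongated cells.  Used only in sensitivity analyses.
    """
    e = float(aspect_ratio)
    if not (np.isfinite(e) and e > 1.0):
        raise DomainError(f"cylinder factor requires aspect ratio > 1, got {e}")
    return _cylinder_capacitance(e)


def shape_correction(geometry: CellGeometry) -> float:
    """Flux enhancement factor for a cell geometry; 1 for spheres."""
    if geometry.shape == "sphere" or geometry.aspect_ratio == 1.0:
        return 1.0
    if geometry.shape == "prolate":
        return prolate_correction(geometry.aspect_ratio)
    return cylinder_correction(geometry.aspect_ratio)


def _resolve_d(
    solute: str,
    state: SeawaterState,
    config: ModelConfig,
    diffusivity_override: float | Mapping[str, float] | None,
) -> float:
    if diffusivity_override is not None:
        if isinstance(diffusivity_override, Mapping):
            if solute in diffusivity_override:
                return float(diffusivity_override[solute])
        else:
            return float(diffusivity_override)
    descriptor = get_solute(solute, phosphate_species=config.phosphate_species)
    return diffusion_coefficient(
        descriptor, replace(state, pressure=config.pressure_bar)
    )


def _per_solute_uptakes(
    geometry: CellGeometry,
    fieldvals: Mapping[str, float],
    state: SeawaterState,
    config: ModelConfig,
    diffusivity_override,
) -> tuple[dict[str, float], dict[str, float]]:
    factor = shape_correction(geometry)
    raw: dict[str, float] = {}
    corr: dict[str, float] = {}
    for solute, conc in fieldvals.items():
        d = _resolve_d(solute, state, config, diffusivity_override)
        rho = sphere_max_uptake(d, geometry.r0_cm, conc)
        raw[solute] = rho
        corr[solute] = rho * factor
    return raw, corr


def daily_nitrogen_uptake(
    geometry: CellGeometry,
    nutrient_field: NutrientField,
    state: SeawaterState,
    config: ModelConfig = ModelConfig(),
    *,
    diffusivity_override: float | Mapping[str, float] | None = None,
) -> float:
    """Day/night-weighted diffusive N uptake (nmol N d^-1).

    Sums ammonium, nitrite and nitrate (urea too, when present in the field),
    each credited over its uptake window.  Raises MissingDataError when an
    inorganic N concentration is absent.
    """
    concs = {name: nutrient_field.require(name) for name in N_SOLUTES}
    if nutrient_field.urea is not None:
        concs["urea"] = nutrient_field.urea
    _, corr = _per_solute_uptakes(geometry, concs, state, config, diffusivity_override)
    total = 0.0
    for solute, rho in corr.items():
        n_atoms = config.urea_nitrogen_atoms if solute == "urea" else 1.0
        total += rho * config.uptake_window_s(solute) * n_atoms
    return total


def daily_phosphorus_uptake(
    geometry: CellGeometry,
    nutrient_field: NutrientField,
    state: SeawaterState,
    config: ModelConfig = ModelConfig(),
    *,
    diffusivity_override: float | Mapping[str, float] | None = None,
) -> float:
    """Diffusive phosphate uptake (nmol P d^-1), round-the-clock by default."""
    conc = nutrient_field.require("phosphate")
    _, corr = _per_solute_uptakes(
        geometry, {"phosphate": conc}, state, config, diffusivity_override
    )
    return corr["phosphate"] * config.uptake_window_s("phosphate")


def n_based_max_growth(
    geometry: CellGeometry,
    nutrient_field: NutrientField,
    state: SeawaterState,
    config: ModelConfig = ModelConfig(),
    *,
    diffusivity_override: float | Mapping[str, float] | None = None,
) -> float:
    """Maximum N-based osmotrophic growth rate (d^-1): daily N uptake / N quota."""
    uptake = daily_nitrogen_uptake(
        geometry, nutrient_field, state, config, diffusivity_override=diffusivity_override
    )
    return uptake / allometry.n_content(geometry.biovolume)


def p_based_max_growth(
    geometry: CellGeometry,
    nutrient_field: NutrientField,
    state: SeawaterState,
    config: ModelConfig = ModelConfig(),
    *,
    diffusivity_override: float | Mapping[str, float] | None = None,
) -> float:
    """Maximum P-based osmotrophic growth rate (d^-1): daily P uptake / P quota."""
    uptake = daily_phosphorus_uptake(
        geometry, nutrient_field, state, config, diffusivity_override=diffusivity_override
    )
    return uptake / allometry.p_content(geometry.biovolume)


def growth_potential(
    geometry: CellGeometry,
    nutrient_field: NutrientField,
    state: SeawaterState,
    config: ModelConfig = ModelConfig(),
    *,
    diffusivity_override: float | Mapping[str, float] | None = None,
) -> GrowthPotential:
    """Full per-cell model output (per-solute uptakes plus GR_N and GR_P)."""
    concs = {name: nutrient_field.require(name) for name in N_SOLUTES}
    if nutrient_field.urea is not None:
        concs["urea"] = nutrient_field.urea
    concs["phosphate"] = nutrient_field.require("phosphate")
    raw, corr = _per_solute_uptakes(geometry, concs, state, config, diffusivity_override)
    daily_n = sum(
        corr[s]
        * config.uptake_window_s(s)
        * (config.urea_nitrogen_atoms if s == "urea" else 1.0)
        for s in concs
        if s != "phosphate"
    )
    daily_p = corr["phosphate"] * config.uptake_window_s("phosphate")
    bv = geometry.biovolume
    return GrowthPotential(
        max_uptake=raw,
        corrected_uptake=corr,
        daily_n_uptake=daily_n,
        daily_p_uptake=daily_p,
        gr_n=daily_n / allometry.n_content(bv),
        gr_p=daily_p / allometry.p_content(bv),
    )


def critical_esd(
    target_gr: float,
    nutrient_field: NutrientField,
    state: SeawaterState,
    config: ModelConfig = ModelConfig(),
    aspect_ratio: float = 1.0,
    *,
    diffusivity_override: float | Mapping[str, float] | None = None,
    esd_bounds: tuple[float, float] = (0.2, 1e4),
    rtol: float = 1e-8,
) -> float:
    """Cell size (esd, um) at which the N-based maximum growth rate equals ``target_gr``.

    Cells larger than this cannot sustain ``target_gr`` by osmotrophy alone.
    Spheres use the closed-form power-law solution; elongated cells use
    monotone root-finding on log(esd) over ``esd_bounds``.
    """
    if not target_gr > 0:
        raise DomainError("target growth rate must be > 0")

    shape = "sphere" if aspect_ratio == 1.0 else "prolate"

    def gr_at(esd: float) -> float:
        geom = CellGeometry(esd=esd, aspect_ratio=aspect_ratio, shape=shape)
        return n_based_max_growth(
            geom, nutrient_field, state, config, diffusivity_override=diffusivity_override
        )

    gr_ref = gr_at(1.0)
    if gr_ref <= 0.0:
        raise NoSolutionError("all dissolved N concentrations are zero; no size limit exists")
    if aspect_ratio == 1.0:
        # GR(esd) = GR(1 um) * esd**(-1.511)  exactly, for spheres
        return (gr_ref / target_gr) ** (1.0 / SCALING_EXPONENT)

    lo, hi = esd_bounds
    f_lo, f_hi = gr_at(lo) - target_gr, gr_at(hi) - target_gr
    if f_lo < 0 or f_hi > 0:
        raise BracketError(
            "target growth rate unreachable within the esd bracket",
            lo=lo, hi=hi, f_lo=f_lo, f_hi=f_hi,
        )
    log_root = brentq(
        lambda x: gr_at(math.exp(x)) - target_gr,
        math.log(lo),
        math.log(hi),
        rtol=rtol / 10,
        xtol=1e-13,
    )
    return math.exp(log_root)
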