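"""Molecular diffusion coefficients of dissolved nutrients in seawater.

Freshwater (zero-salinity) diffusivities of the ionic N and P species are
linear functions of temperature, ``D0 = (m0 + m1*T) * 1e-6`` cm^2 s^-1, with
coefficients from Boudreau's (1997) linear ion-mobility tabulation.  The
salinity (and pressure) dependence is obtained by Stokes-Einstein scaling
with the dynamic viscosity of seawater:

    D(T, S, P) = D0(T) * mu(T, S=0, P) / mu(T, S, P)

Urea is carried as a constant-diffusivity solute (1.36e-5 cm^2 s^-1).
The viscosity correlation is the Kukulka-type polynomial fit (centipoise;
T in deg C, S practical salinity, P in bar).
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Literal

from .errors import ConfigurationError, DomainError

__all__ = [
    "SeawaterState",
    "SoluteDescriptor",
    "get_solute",
    "register_solute",
    "available_solutes",
    "freshwater_diffusivity",
    "seawater_viscosity",
    "diffusion_coefficient",
]

#: default phosphate species; HPO4(2-) dominates DIP at seawater pH ~8.1
DEFAULT_PHOSPHATE_SPECIES = "hpo4"


@dataclass(frozen=True)
class SeawaterState:
    """Temperature (deg C), practical salinity, and pressure (bar) of a water parcel."""

    temperature: float
    salinity: float = 35.0
    pressure: float = 1.0

    def __post_init__(self) -> None:
        if not (-2.0 <= self.temperature <= 40.0):
            raise DomainError(f"temperature {self.temperature} outside [-2, 40] degC")
        if not (0.0 <= self.salinity <= 42.0):
            raise DomainError(f"salinity {self.salinity} outside [0, 42]")
        if not self.pressure >= 1.0:
            raise DomainError(f"pressure {self.pressure} bar must be >= 1")


@dataclass(frozen=True)
class SoluteDescriptor:
    """Coefficients defining one solute's freshwater diffusivity.

    ``linear_ionic`` solutes use ``D0 = (m0 + m1*T)*1e-6`` cm^2/s; ``constant``
    solutes have a temperature-independent ``constant_d`` (cm^2/s).
    """

    name: str
    mode: Literal["linear_ionic", "constant"]
    m0: float | None = None  # 1e-6 cm2/s
    m1: float | None = None  # 1e-6 cm2/s per degC
    constant_d: float | None = None  # cm2/s
    citation: str = ""

    def __post_init__(self) -> None:
        if self.mode == "linear_ionic":
            if self.m0 is None or self.m1 is None or self.m0 <= 0 or self.m1 < 0:
                raise ConfigurationError(
                    f"linear_ionic solute {self.name!r} needs m0 > 0 and m1 >= 0"
                )
        elif self.mode == "constant":
            if self.constant_d is None or self.constant_d <= 0:
                raise ConfigurationError(
                    f"constant solute {self.name!r} needs constant_d > 0"
                )
        else:
            raise ConfigurationError(f"unknown solute mode {self.mode!r}")


def _load_builtin_registry() -> dict[str, SoluteDescriptor]:
    registry: dict[str, SoluteDescriptor] = {}
    with resources.files("osmolimit.data").joinpath("solutes.csv").open() as fh:
        for row in csv.DictReader(fh):
            registry[row["name"]] = SoluteDescriptor(
                name=row["name"],
                mode=row["mode"],  # type: ignore[arg-type]
                m0=float(row["m0"]) if row["m0"] else None,
                m1=float(row["m1"]) if row["m1"] else None,
                constant_d=float(row["constant_d"]) if row["constant_d"] else None,
                citation=row.get("citation", ""),
            )
    return registry


_REGISTRY: dict[str, SoluteDescriptor] = _load_builtin_registry()


def available_solutes() -> tuple[str, ...]:
    return tuple(sorted(_REGISTRY))


def register_solute(descriptor: SoluteDescriptor) -> None:
    """Register (or override) a solute; later lookups by name return it."""
    _REGISTRY[descriptor.name] = descriptor


def get_solute(
    name: str, phosphate_species: str = DEFAULT_PHOSPHATE_SPECIES
) -> SoluteDescriptor:
    """Look up a solute descriptor by name.

    ``"phosphate"`` resolves to the configured inorganic-phosphate species
    (``hpo4`` by default; ``h2po4`` and ``po4`` selectable).
    """
    if name == "phosphate":
        name = f"phosphate_{phosphate_species}"
    try:
        return _REGISTRY[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown solute {name!r}; known: {', '.join(available_solutes())}"
        ) from None


def freshwater_diffusivity(solute: SoluteDescriptor | str, temperature: float) -> float:
    """Zero-salinity molecular diffusivity (cm^2 s^-1) at ``temperature`` (deg C)."""
    if isinstance(solute, str):
        solute = get_solute(solute)
    if not (-2.0 <= temperature <= 40.0):
        raise DomainError(f"temperature {temperature} outside [-2, 40] degC")
    if solute.mode == "constant":
        return float(solute.constant_d)  # type: ignore[arg-type]
    d0 = (solute.m0 + solute.m1 * temperature) * 1e-6  # type: ignore[operator]
    if d0 <= 0:
        raise DomainError(f"non-positive diffusivity for {solute.name} at {temperature} degC")
    return d0


def seawater_viscosity(state: SeawaterState) -> float:
    """Dynamic viscosity of seawater (centipoise) from the Kukulka-type correlation."""
    t, s, p = state.temperature, state.salinity, state.pressure
    return (
        1.7910
        - 6.144e-2 * t
        + 1.4510e-3 * t**2
        - 1.6826e-5 * t**3
        - 1.5290e-4 * p
        + 8.3885e-8 * p**2
        + 2.4727e-3 * s
        + t * (6.0574e-6 * p - 2.6760e-9 * p**2)
        + s * (4.8429e-5 * t - 4.7172e-6 * t**2 + 7.5986e-8 * t**3)
    )


def diffusion_coefficient(solute: SoluteDescriptor | str, state: SeawaterState) -> float:
    """In-situ molecular diffusivity (cm^2 s^-1) at the given seawater state.

    Applies Stokes-Einstein viscosity scaling to the freshwater value;
    constant-mode solutes (urea) are returned unchanged.
    """
    if isinstance(solute, str):
        solute = get_solute(solute)
    if solute.mode == "constant":
        return float(solute.constant_d)  # type: ignore[arg-type]
    d0 = freshwater_diffusivity(solute, state.temperature)
    mu_fresh = seawater_viscosity(
        SeawaterState(state.temperature, 0.0, state.pressure)
    )
    return d0 * mu_fresh / seawater_viscosity(state)
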