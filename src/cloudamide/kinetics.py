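"""Collision-complex formation kinetics in warm dense molecular clouds.

Two polyatomic monomers that collide in a cloud interior can stick as a
hydrogen-bonded complex without a third body: the relative kinetic
energy of approach (3kT/2 on average) is redistributed over the
3(M+N-1) internal modes of the merged complex, raising the internal
temperature only by the factor (M+N)/(M+N-1).  For molecules the size
of amino acids that excess is a few percent and does not redissociate
the complex, so complex formation is an effective two-body process with
a gas-kinetic rate coefficient k2 ~ 2e-11 cm^3 s^-1 at 100 K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import yaml

from .profiles import SpeciesInfo
from .units import seconds_to_years

__all__ = [
    "UVClass",
    "CloudEnvironment",
    "KineticParameters",
    "StickingReport",
    "species_density",
    "collision_rate",
    "collision_timescale",
    "internal_mode_count",
    "internal_temperature_factor",
    "sticking_assessment",
    "gas_kinetic_rate_coefficient",
    "load_environment",
    "write_environment",
    "THERMAL_RELAXATION_TIMESCALE_S",
    "RADIATIVE_RELAXATION_FACTOR",
    "DEFAULT_STICKING_FACTOR_THRESHOLD",
]

#: Timescale (s) on which collisions with ambient He and H2 remove the
#: excess energy of complex formation.  Adopted as a stated constant of
#: the cloud model; the underlying collision model is not part of this
#: package.
THERMAL_RELAXATION_TIMESCALE_S: float = 1.0e4

#: Radiative equilibration with the cloud black-body field at 100 K is
#: taken to be two orders of magnitude slower than collisional
#: relaxation.  Stored constant, same caveat as above.
RADIATIVE_RELAXATION_FACTOR: float = 100.0

#: A collision complex is considered collisionally stable (two-body
#: sticking) when the internal-temperature factor stays at or below
#: this threshold.  The dichotomy between polyatomics (which stick) and
#: very small molecules (which need a third body) has no sharp printed
#: cutoff; 1.25 separates amino-acid-sized factors (~1.05) from
#: diatomic ones (4/3).
DEFAULT_STICKING_FACTOR_THRESHOLD: float = 1.25


class UVClass(str, Enum):
    """Ultraviolet radiation environment of the cloud."""

    DISM = "DISM"
    DC = "DC"
    NONE = "none"


@dataclass(frozen=True)
class CloudEnvironment:
    """Physical conditions of a molecular-cloud interior.

    Parameters
    ----------
    temperature : float
        Gas/radiation equilibrium temperature, K.
    n_h2 : float
        H2 number density, cm^-3 (warm dense clouds: 1e7-1e8).
    fractional_abundance : float
        Species number density as a fraction of ``n_h2``.
    uv_class : UVClass
        Radiation environment controlling monomer photodestruction.
    """

    temperature: float = 100.0
    n_h2: float = 1.0e7
    fractional_abundance: float = 1.0e-7
    uv_class: UVClass = UVClass.DC

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        if self.n_h2 < 0:
            raise ValueError(f"n_h2 must be non-negative, got {self.n_h2}")
        if not 0.0 <= self.fractional_abundance <= 1.0:
            raise ValueError(
                f"fractional_abundance must lie in [0, 1], got {self.fractional_abundance}"
            )


@dataclass(frozen=True)
class KineticParameters:
    """Rate parameters of complex formation and dissociation.

    ``k2`` is the bimolecular complex-formation coefficient (sigma * vbar),
    cm^3 s^-1.  ``a_low``/``a_high`` bracket the Arrhenius pre-exponential
    of unimolecular dissociation: 1e12 s^-1 for tight transition states,
    1e15 s^-1 for loose ones.
    """

    k2: float = 2.0e-11
    a_low: float = 1.0e12
    a_high: float = 1.0e15
    ea_convention: str = "from_binding"

    def __post_init__(self) -> None:
        if self.k2 <= 0:
            raise ValueError(f"k2 must be positive, got {self.k2}")
        if self.a_low > self.a_high:
            raise ValueError("a_low must not exceed a_high")
        if self.ea_convention not in ("from_binding", "explicit"):
            raise ValueError(f"unknown ea_convention {self.ea_convention!r}")


@dataclass(frozen=True)
class StickingReport:
    """Outcome of the internal-energy-redistribution assessment."""

    factor: float
    effective_internal_temperature_K: float
    two_body_sticking: bool


def species_density(env: CloudEnvironment) -> float:
    """Monomer number density, cm^-3 (n_H2 times fractional abundance)."""
    return env.n_h2 * env.fractional_abundance


def collision_rate(n_species: float, params: KineticParameters) -> float:
    """Per-monomer complex-formation rate, s^-1: k2 * n."""
    if n_species < 0:
        raise ValueError(f"n_species must be non-negative, got {n_species}")
    return params.k2 * n_species


def collision_timescale(n_species: float, params: KineticParameters) -> float:
    """Mean time for a monomer to form a hydrogen-bonded complex, years.

    Returns ``math.inf`` at zero density (no collisions ever).
    """
    rate = collision_rate(n_species, params)
    if rate == 0.0:
        return math.inf
    return seconds_to_years(1.0 / rate)


def _atom_count(species: SpeciesInfo | int) -> int:
    """Accept a species record or a bare atom count (for small molecules
    below the SpeciesInfo size floor)."""
    count = species.atom_count if isinstance(species, SpeciesInfo) else int(species)
    if count < 1:
        raise ValueError(f"atom count must be >= 1, got {count}")
    return count


def internal_mode_count(m: SpeciesInfo | int, n: SpeciesInfo | int) -> int:
    """Internal energy modes of the merged complex: 3(M+N-1)."""
    return 3 * (_atom_count(m) + _atom_count(n) - 1)


def internal_temperature_factor(m: SpeciesInfo | int, n: SpeciesInfo | int) -> float:
    """Fractional internal-temperature rise on sticking: (M+N)/(M+N-1).

    The pre-collision internal energy 3(M+N-1)kT/2 gains the mean
    collision energy 3kT/2, so the energy per mode rises by this factor.
    Always > 1; tends to 1 for large molecules; symmetric in (m, n).
    """
    total = _atom_count(m) + _atom_count(n)
    if total < 2:
        raise ValueError("a pair needs at least two atoms in total")
    return total / (total - 1)


def sticking_assessment(
    m: SpeciesInfo | int,
    n: SpeciesInfo | int,
    env: CloudEnvironment,
    factor_threshold: float = DEFAULT_STICKING_FACTOR_THRESHOLD,
) -> StickingReport:
    """Judge whether a collision complex survives its own formation heat.

    The effective internal temperature after the collision is
    ``T * (M+N)/(M+N-1)``; when the factor stays at or below
    ``factor_threshold`` the warming is too small to redissociate the
    complex before collisional cooling (~1e4 s) removes it, and complex
    formation proceeds as a two-body process.
    """
    factor = internal_temperature_factor(m, n)
    return StickingReport(
        factor=factor,
        effective_internal_temperature_K=env.temperature * factor,
        two_body_sticking=factor <= factor_threshold,
    )


def gas_kinetic_rate_coefficient(
    m: SpeciesInfo,
    n: SpeciesInfo,
    temperature: float,
    cross_section_cm2: float = 1.0e-15,
) -> float:
    """Optional sigma*vbar estimate, cm^3 s^-1, from masses and a cross-section.

    vbar is the mean relative thermal speed of the pair,
    sqrt(8 k T / (pi * mu)).  This is a cross-check utility only; the
    adopted default coefficient is :attr:`KineticParameters.k2`.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    amu_kg = 1.66053906660e-27
    mu = (m.mass * n.mass) / (m.mass + n.mass) * amu_kg
    k_b = 1.380649e-23
    vbar_cm_s = math.sqrt(8.0 * k_b * temperature / (math.pi * mu)) * 100.0
    return cross_section_cm2 * vbar_cm_s


# ---------------------------------------------------------------------------
# environment YAML


def load_environment(path: str | Path) -> CloudEnvironment:
    """Read a cloud-environment config from YAML.

    Keys: ``temperature_K``, ``n_h2_cm3``, ``fractional_abundance``,
    ``uv_class``; all optional, defaults are the warm-dense-cloud
    reference conditions.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: environment file must be a YAML mapping")
    known = {"temperature_K", "n_h2_cm3", "fractional_abundance", "uv_class"}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"{path}: unknown environment keys {sorted(unknown)}")
    kwargs: dict = {}
    if "temperature_K" in doc:
        kwargs["temperature"] = float(doc["temperature_K"])
    if "n_h2_cm3" in doc:
        kwargs["n_h2"] = float(doc["n_h2_cm3"])
    if "fractional_abundance" in doc:
        kwargs["fractional_abundance"] = float(doc["fractional_abundance"])
    if "uv_class" in doc:
        kwargs["uv_class"] = UVClass(doc["uv_class"])
    return CloudEnvironment(**kwargs)


def write_environment(env: CloudEnvironment, path: str | Path) -> None:
    """Write a cloud-environment config as YAML (round-trip safe)."""
    doc = {
        "temperature_K": env.temperature,
        "n_h2_cm3": env.n_h2,
        "fractional_abundance": env.fractional_abundance,
        "uv_class": env.uv_class.value,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)
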