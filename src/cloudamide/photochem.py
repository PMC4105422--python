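"""Ultraviolet photodestruction and its competition with dimerization.

Free amino acids are destroyed by short-wave UV with a half-life that
depends on the radiation environment: ~300 yr in the diffuse
interstellar medium (DISM), ~3e7 yr inside a dark cloud (DC).  Complex
formation at warm-dense-cloud densities is far faster (~1.6e3 yr), so a
monomer overwhelmingly ends up in a hydrogen-bonded complex before UV
destroys it.  Peptides themselves resist deep UV — measured destruction
quantum efficiencies are of order 1e-2 — but with no photon flux model
those efficiencies are surfaced as report data, not rates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

from .kinetics import UVClass
from .units import years_to_seconds

__all__ = [
    "UVEnvironmentData",
    "PeptidePhotoData",
    "PhotostabilityNote",
    "photolysis_rate",
    "dimerize_before_destruction",
    "peptide_photostability_note",
    "load_packaged_uv_data",
    "LOW_EFFICIENCY_THRESHOLD",
]

#: Destruction quantum efficiencies below this are flagged "low".
LOW_EFFICIENCY_THRESHOLD: float = 0.05


@dataclass(frozen=True)
class UVEnvironmentData:
    """Monomer photodestruction half-life for one UV environment class.

    The quoted value is interpreted as a first-order half-life (not a
    1/e lifetime); the two conventions differ by a factor ln 2.
    """

    uv_class: UVClass
    monomer_half_life_yr: float

    def __post_init__(self) -> None:
        if self.monomer_half_life_yr <= 0:
            raise ValueError(
                f"half-life must be positive, got {self.monomer_half_life_yr}"
            )


@dataclass(frozen=True)
class PeptidePhotoData:
    """Measured UV destruction quantum efficiency of a peptide."""

    species: str
    wavelength_nm: float
    destruction_quantum_efficiency: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.destruction_quantum_efficiency <= 1.0:
            raise ValueError(
                "destruction_quantum_efficiency must lie in [0, 1], "
                f"got {self.destruction_quantum_efficiency}"
            )


@dataclass(frozen=True)
class PhotostabilityNote:
    species: str
    wavelength_nm: float
    destruction_quantum_efficiency: float
    low_efficiency: bool


def photolysis_rate(env_data: UVEnvironmentData) -> float:
    """First-order photodestruction rate constant, s^-1: ln2 / half-life."""
    return math.log(2.0) / years_to_seconds(env_data.monomer_half_life_yr)


def dimerize_before_destruction(collision_rate: float, photolysis_rate: float) -> float:
    """Probability that a monomer forms a complex before UV destroys it.

    Two competing first-order channels: P = k_coll / (k_coll + k_phot).
    Raises ``ValueError`` when both rates vanish (no channel ever fires).
    """
    if collision_rate < 0 or photolysis_rate < 0:
        raise ValueError("rates must be non-negative")
    total = collision_rate + photolysis_rate
    if total == 0.0:
        raise ValueError("branching probability undefined: both rates are zero")
    return collision_rate / total


def peptide_photostability_note(data: PeptidePhotoData) -> PhotostabilityNote:
    """Echo a peptide's measured quantum efficiency, flagging low values."""
    return PhotostabilityNote(
        species=data.species,
        wavelength_nm=data.wavelength_nm,
        destruction_quantum_efficiency=data.destruction_quantum_efficiency,
        low_efficiency=data.destruction_quantum_efficiency < LOW_EFFICIENCY_THRESHOLD,
    )


def load_packaged_uv_data(
    path: str | Path | None = None,
) -> tuple[dict[UVClass, UVEnvironmentData], list[PeptidePhotoData]]:
    """Load the packaged UV fixture table.

    Returns the per-class monomer half-life records and the peptide
    quantum-efficiency records.
    """
    if path is None:
        path = Path(__file__).parent / "data" / "uv_photochemistry.json"
    with open(path) as fh:
        doc = json.load(fh)
    envs = {
        UVClass(rec["class"]): UVEnvironmentData(
            uv_class=UVClass(rec["class"]),
            monomer_half_life_yr=float(rec["half_life_yr"]),
        )
        for rec in doc["uv_environments"]
    }
    peptides = [
        PeptidePhotoData(
            species=str(rec["species"]),
            wavelength_nm=float(rec["wavelength_nm"]),
            destruction_quantum_efficiency=float(rec["qe"]),
        )
        for rec in doc["peptides"]
    ]
    return envs, peptides
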