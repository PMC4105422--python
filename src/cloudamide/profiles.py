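"""Five-state condensation-reaction energy profiles.

A condensation (amide- or ether-bond-forming) reaction between two
gas-phase monomers is summarised by the enthalpies of five molecular
states, all relative to the sum of the separated-monomer energies
(state 1, defined as zero):

1. separated monomers                                  (0 by convention)
2. hydrogen-bonded pair in proximity                   (``e_pair``)
3. transition state of the concerted bond formation    (``e_ts``)
4. bonded product with the water of condensation still
   hydrogen-bonded to it                               (``e_product_bound_water``)
5. bonded product with the water removed to infinity   (``e_product_free_water``)

The module provides the data model, a JSON reader/writer with
validation, accessor operations (binding energy, barrier heights, water
removal cost) and the low/high barrier classification that decides
whether condensation can proceed after a collision complex forms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .units import EV_AS_KJ_PER_MOL

__all__ = [
    "SpeciesKind",
    "BarrierReference",
    "BarrierClass",
    "SpeciesInfo",
    "ReactionProfile",
    "ProfileLibrary",
    "ProfileValidationError",
    "UnknownSpeciesError",
    "MissingStateError",
    "DEFAULT_BARRIER_THRESHOLD_KJ_MOL",
    "load_profiles",
    "write_profiles",
    "load_species_csv",
    "binding_energy",
    "barrier_height",
    "water_removal_energy",
    "classify_barrier",
    "packaged_profile_path",
    "load_packaged_profiles",
]

#: Default classification threshold: 0.6 eV expressed in kJ/mol.
DEFAULT_BARRIER_THRESHOLD_KJ_MOL: float = 0.6 * EV_AS_KJ_PER_MOL


class SpeciesKind(str, Enum):
    AMINO_ACID = "amino_acid"
    GLYCOL = "glycol"
    WATER = "water"
    POLYMER = "polymer"


class BarrierReference(str, Enum):
    """Zero point for a barrier height: separated monomers or the bound pair."""

    SEPARATED = "separated"
    BOUND_PAIR = "bound_pair"


class BarrierClass(str, Enum):
    LOW = "low"
    HIGH = "high"


class ProfileValidationError(ValueError):
    """A profile record violates the schema or a physical invariant."""


class UnknownSpeciesError(ProfileValidationError):
    """A profile references a species not declared in the library."""


class MissingStateError(ValueError):
    """A requested quantity needs a state the profile does not carry."""


@dataclass(frozen=True)
class SpeciesInfo:
    """A gas-phase monomer (or pre-formed oligomer treated as a unit).

    Parameters
    ----------
    name : str
        Text label, e.g. ``"Gly"`` or ``"ethylene_glycol"``.
    atom_count : int
        Number of atoms per molecule; sets the count of internal modes
        available to absorb collision energy.
    mass : float
        Molecular mass in unified atomic mass units.
    kind : SpeciesKind
        Chemical family of the species.
    """

    name: str
    atom_count: int
    mass: float
    kind: SpeciesKind = SpeciesKind.AMINO_ACID

    def __post_init__(self) -> None:
        if self.atom_count < 3:
            raise ProfileValidationError(
                f"species {self.name!r}: atom_count must be >= 3, got {self.atom_count}"
            )
        if self.mass <= 0:
            raise ProfileValidationError(
                f"species {self.name!r}: mass must be positive, got {self.mass}"
            )


@dataclass(frozen=True)
class ReactionProfile:
    """Five-state energy diagram of one condensation reaction.

    All energies are kJ/mol relative to the separated monomers (state 1
    at zero).  ``e_product_free_water`` may be ``None`` for reactions
    (e.g. glycol ether formation) where the water-at-infinity state was
    not evaluated.
    """

    pair_id: tuple[str, str]
    conformer_id: int
    e_pair: float
    e_ts: float
    e_product_bound_water: float
    e_product_free_water: float | None = None
    approximate: bool = False

    @property
    def key(self) -> tuple[tuple[str, str], int]:
        return (self.pair_id, self.conformer_id)

    @property
    def label(self) -> str:
        return f"{self.pair_id[0]}+{self.pair_id[1]}/c{self.conformer_id}"


@dataclass(frozen=True)
class ProfileLibrary:
    """A collection of reaction profiles with their species table."""

    profiles: tuple[ReactionProfile, ...]
    species: Mapping[str, SpeciesInfo]
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[tuple[str, str], int]] = set()
        for p in self.profiles:
            for name in p.pair_id:
                if name not in self.species:
                    raise UnknownSpeciesError(
                        f"profile {p.label}: unknown species {name!r}"
                    )
            if p.key in seen:
                raise ProfileValidationError(
                    f"profile {p.label}: duplicate (pair, conformer) key"
                )
            seen.add(p.key)

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self):
        return iter(self.profiles)

    def pair_kinds(self, profile: ReactionProfile) -> tuple[SpeciesKind, SpeciesKind]:
        a, b = profile.pair_id
        return (self.species[a].kind, self.species[b].kind)

    def is_amide(self, profile: ReactionProfile) -> bool:
        """True when both partners are amino acids or peptide oligomers."""
        return all(
            k in (SpeciesKind.AMINO_ACID, SpeciesKind.POLYMER)
            for k in self.pair_kinds(profile)
        )

    def select(
        self,
        kind: SpeciesKind | None = None,
        pair: Sequence[str] | None = None,
    ) -> "ProfileLibrary":
        """Sub-library restricted by partner kind and/or a specific pair."""
        keep = []
        for p in self.profiles:
            if kind is not None and not all(k == kind for k in self.pair_kinds(p)):
                continue
            if pair is not None and tuple(pair) != p.pair_id:
                continue
            keep.append(p)
        return ProfileLibrary(tuple(keep), self.species, self.metadata)


# ---------------------------------------------------------------------------
# accessor operations


def binding_energy(profile: ReactionProfile) -> float:
    """Depth of the hydrogen-bonded complex below the separated monomers.

    Returns ``e_pair`` (signed, kJ/mol); negative for any bound complex.
    """
    return profile.e_pair


def barrier_height(
    profile: ReactionProfile,
    reference: BarrierReference | str = BarrierReference.SEPARATED,
) -> float:
    """Transition-state barrier, kJ/mol, from the chosen zero point.

    ``separated`` measures from the separated-monomer zero (the
    convention behind the published low/high classification);
    ``bound_pair`` measures the escape barrier from the bottom of the
    hydrogen-bonded well, the quantity relevant to unimolecular passage
    once the collision complex exists.
    """
    reference = BarrierReference(reference)
    if reference is BarrierReference.SEPARATED:
        return profile.e_ts
    return profile.e_ts - profile.e_pair


def water_removal_energy(profile: ReactionProfile) -> float:
    """Cost, kJ/mol, of removing the water of condensation to infinity.

    Positive for every packaged amide profile: the product is strongly
    stabilised by keeping its water hydrogen-bonded.
    """
    if profile.e_product_free_water is None:
        raise MissingStateError(
            f"profile {profile.label}: water-at-infinity state not available"
        )
    return profile.e_product_free_water - profile.e_product_bound_water


def classify_barrier(
    profile: ReactionProfile,
    threshold: float = DEFAULT_BARRIER_THRESHOLD_KJ_MOL,
) -> BarrierClass:
    """Classify the condensation barrier as low or high.

    A barrier is low when the transition state (measured from the
    separated-monomer zero) is at or below ``threshold`` — by default
    0.6 eV = 57.891 kJ/mol, the typical hydrogen-bond association
    energy of an amino acid pair.  Condensation proceeds for
    low-barrier pairs; high-barrier pairs stall at the hydrogen-bonded
    complex.  The comparison is inclusive.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    h = barrier_height(profile, BarrierReference.SEPARATED)
    return BarrierClass.LOW if h <= threshold else BarrierClass.HIGH


# ---------------------------------------------------------------------------
# JSON input/output

_REQUIRED_PROFILE_KEYS = {"pair", "conformer", "e_pair", "e_ts", "e4"}
_REQUIRED_SPECIES_KEYS = {"name", "atom_count", "mass_u", "kind"}


def _validate_number(record: str, key: str, value: object, allow_none: bool = False):
    if value is None and allow_none:
        return None
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ProfileValidationError(f"{record}: field {key!r} must be a number, got {value!r}")
    return float(value)


def _species_from_record(rec: Mapping[str, object]) -> SpeciesInfo:
    missing = _REQUIRED_SPECIES_KEYS - set(rec)
    if missing:
        raise ProfileValidationError(
            f"species record {rec.get('name', '<unnamed>')!r}: missing keys {sorted(missing)}"
        )
    try:
        kind = SpeciesKind(rec["kind"])
    except ValueError as exc:
        raise ProfileValidationError(
            f"species record {rec['name']!r}: unknown kind {rec['kind']!r}"
        ) from exc
    return SpeciesInfo(
        name=str(rec["name"]),
        atom_count=int(rec["atom_count"]),  # type: ignore[arg-type]
        mass=float(rec["mass_u"]),  # type: ignore[arg-type]
        kind=kind,
    )


def _profile_from_record(rec: Mapping[str, object]) -> ReactionProfile:
    label = f"profile record {rec.get('pair', '<no pair>')!r}"
    missing = _REQUIRED_PROFILE_KEYS - set(rec)
    if missing:
        raise ProfileValidationError(f"{label}: missing keys {sorted(missing)}")
    pair = rec["pair"]
    if not (isinstance(pair, (list, tuple)) and len(pair) == 2):
        raise ProfileValidationError(f"{label}: 'pair' must be a two-element list")
    return ReactionProfile(
        pair_id=(str(pair[0]), str(pair[1])),
        conformer_id=int(rec["conformer"]),  # type: ignore[arg-type]
        e_pair=_validate_number(label, "e_pair", rec["e_pair"]),
        e_ts=_validate_number(label, "e_ts", rec["e_ts"]),
        e_product_bound_water=_validate_number(label, "e4", rec["e4"]),
        e_product_free_water=_validate_number(label, "e5", rec.get("e5"), allow_none=True),
        approximate=bool(rec.get("approximate", False)),
    )


def _check_physical_invariants(library: ProfileLibrary) -> None:
    for p in library.profiles:
        if p.e_pair >= 0:
            raise ProfileValidationError(
                f"profile {p.label}: e_pair must be negative "
                f"(hydrogen-bonded complexes are bound), got {p.e_pair}"
            )
        if library.is_amide(p):
            if p.e_product_free_water is None:
                raise ProfileValidationError(
                    f"profile {p.label}: amide profiles require state 5 (e5)"
                )
            if p.e_product_free_water <= p.e_product_bound_water:
                raise ProfileValidationError(
                    f"profile {p.label}: water removal must cost energy "
                    f"(e5 > e4), got e5={p.e_product_free_water}, "
                    f"e4={p.e_product_bound_water}"
                )


def load_profiles(path: str | Path) -> ProfileLibrary:
    """Read and validate a profile library from JSON.

    The file holds ``{"species": [...], "profiles": [...]}`` with
    energies in kJ/mol under the state-1-zero convention; any extra
    top-level keys are preserved as metadata.  Raises
    :class:`ProfileValidationError` naming the offending record on any
    schema or invariant violation, :class:`UnknownSpeciesError` for a
    dangling species reference.
    """
    path = Path(path)
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ProfileValidationError(f"{path}: not valid JSON: {exc}") from exc
    if not isinstance(doc, dict) or "species" not in doc or "profiles" not in doc:
        raise ProfileValidationError(
            f"{path}: top level must be an object with 'species' and 'profiles'"
        )
    species: dict[str, SpeciesInfo] = {}
    for rec in doc["species"]:
        info = _species_from_record(rec)
        if info.name in species:
            raise ProfileValidationError(f"species {info.name!r}: duplicate definition")
        species[info.name] = info
    profiles = tuple(_profile_from_record(rec) for rec in doc["profiles"])
    metadata = {k: v for k, v in doc.items() if k not in ("species", "profiles")}
    library = ProfileLibrary(profiles, species, metadata)
    _check_physical_invariants(library)
    return library


def write_profiles(library: ProfileLibrary, path: str | Path) -> None:
    """Serialise a library to the profile JSON schema (round-trip safe)."""
    doc: dict[str, object] = dict(library.metadata)
    doc["species"] = [
        {
            "name": s.name,
            "atom_count": s.atom_count,
            "mass_u": s.mass,
            "kind": s.kind.value,
        }
        for s in library.species.values()
    ]
    doc["profiles"] = [
        {
            "pair": list(p.pair_id),
            "conformer": p.conformer_id,
            "e_pair": p.e_pair,
            "e_ts": p.e_ts,
            "e4": p.e_product_bound_water,
            "e5": p.e_product_free_water,
            "approximate": p.approximate,
        }
        for p in library.profiles
    ]
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_species_csv(path: str | Path) -> dict[str, SpeciesInfo]:
    """Import a species table from CSV (columns name, atom_count, mass_u, kind)."""
    frame = pd.read_csv(path)
    missing = _REQUIRED_SPECIES_KEYS - set(frame.columns)
    if missing:
        raise ProfileValidationError(f"{path}: missing CSV columns {sorted(missing)}")
    out: dict[str, SpeciesInfo] = {}
    for rec in frame.to_dict("records"):
        info = _species_from_record(rec)
        out[info.name] = info
    return out


def packaged_profile_path() -> Path:
    """Path of the packaged reaction-profile fixture library."""
    return Path(__file__).parent / "data" / "reaction_profiles.json"


def load_packaged_profiles() -> ProfileLibrary:
    """Load the packaged library: 14 amide pairs, 7 glycol pairs, one 4-mer."""
    return load_profiles(packaged_profile_path())
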