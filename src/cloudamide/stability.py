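"""Arrhenius dissociation of the hydrogen-bonded complex and the
dimer/monomer equilibrium.

In the rapid-energy-exchange (thermalised) limit the complex
dissociates unimolecularly at k_D = A exp(-Ea/RT), with A between 1e12
s^-1 (tight transition state) and 1e15 s^-1 (loose) and Ea the depth of
the hydrogen-bonded well.  Balancing formation (k2 * n per monomer)
against dissociation gives the equilibrium dimer-to-monomer ratio
k2 * n / k_D.  For a typical amino acid pair (Ea = 60 kJ/mol, 100 K,
n = 1 cm^-3) that ratio is 1e5-1e9: nearly every monomer resides in a
complex, and the complex survives far longer than a million years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .kinetics import CloudEnvironment, KineticParameters, species_density
from .profiles import (
    BarrierClass,
    MissingStateError,
    ReactionProfile,
    binding_energy,
    classify_barrier,
    water_removal_energy,
)
from .units import R_J_PER_MOL_K, seconds_to_years

__all__ = [
    "DissociationSpec",
    "FeasibilityReport",
    "arrhenius_rate",
    "complex_lifetime",
    "equilibrium_dimer_ratio",
    "dissociation_spec_for_profile",
    "feasibility_report",
]


@dataclass(frozen=True)
class DissociationSpec:
    """Arrhenius parameters of one unimolecular dissociation channel.

    ``pre_exponential`` (A) in s^-1, ``activation_energy`` (Ea) in
    kJ/mol, ``temperature`` in K.
    """

    pre_exponential: float
    activation_energy: float
    temperature: float

    def __post_init__(self) -> None:
        if self.pre_exponential <= 0:
            raise ValueError(f"pre_exponential must be positive, got {self.pre_exponential}")
        if self.activation_energy < 0:
            raise ValueError(
                f"activation_energy must be non-negative, got {self.activation_energy}"
            )
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")


def arrhenius_rate(spec: DissociationSpec) -> float:
    """Unimolecular dissociation rate constant k_D = A exp(-Ea/RT), s^-1."""
    exponent = -spec.activation_energy * 1e3 / (R_J_PER_MOL_K * spec.temperature)
    return spec.pre_exponential * math.exp(exponent)


def complex_lifetime(spec: DissociationSpec) -> float:
    """Mean life 1/k_D of the complex against dissociation, years."""
    return seconds_to_years(1.0 / arrhenius_rate(spec))


def equilibrium_dimer_ratio(
    n_species: float,
    params: KineticParameters,
    spec: DissociationSpec,
) -> float:
    """Equilibrium dimer-to-monomer ratio k2 * n / k_D (dimensionless).

    ``n_species`` is the free-monomer number density, cm^-3.  Linear in
    ``n_species``; inversely proportional to the pre-exponential A.
    """
    if n_species < 0:
        raise ValueError(f"n_species must be non-negative, got {n_species}")
    return params.k2 * n_species / arrhenius_rate(spec)


def dissociation_spec_for_profile(
    profile: ReactionProfile,
    temperature: float,
    pre_exponential: float,
) -> DissociationSpec:
    """Dissociation spec of a complex with Ea = |e_pair| of its profile."""
    return DissociationSpec(
        pre_exponential=pre_exponential,
        activation_energy=abs(binding_energy(profile)),
        temperature=temperature,
    )


@dataclass(frozen=True)
class FeasibilityReport:
    """Verdict on whether a pair condenses to a covalent bond in a cloud.

    ``equilibrium_ratio_range`` holds the dimer/monomer ratio at the
    loose (a_high) and tight (a_low) pre-exponential endpoints, in that
    (low-ratio, high-ratio) order.  ``stabilized_by_water`` is None when
    the profile lacks the water-at-infinity state.
    """

    profile_label: str
    barrier_class: BarrierClass
    equilibrium_ratio_range: tuple[float, float]
    proceeds_to_bond: bool
    stabilized_by_water: bool | None


def feasibility_report(
    profile: ReactionProfile,
    env: CloudEnvironment,
    params: KineticParameters,
) -> FeasibilityReport:
    """Combine barrier class and complex equilibrium into one verdict.

    The complex's dissociation activation energy is the hydrogen-bond
    association depth |e_pair|; the ratio is evaluated at both
    pre-exponential endpoints.  A pair proceeds to a covalent bond only
    when its condensation barrier is low.
    """
    n = species_density(env)
    ratios = tuple(
        sorted(
            equilibrium_dimer_ratio(
                n,
                params,
                dissociation_spec_for_profile(profile, env.temperature, a),
            )
            for a in (params.a_high, params.a_low)
        )
    )
    try:
        stabilized: bool | None = water_removal_energy(profile) > 0
    except MissingStateError:
        stabilized = None
    barrier = classify_barrier(profile)
    return FeasibilityReport(
        profile_label=profile.label,
        barrier_class=barrier,
        equilibrium_ratio_range=ratios,  # type: ignore[arg-type]
        proceeds_to_bond=barrier is BarrierClass.LOW,
        stabilized_by_water=stabilized,
    )
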