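"""Seeded synthetic generators for profile libraries and cloud environments.

The generators emulate the statistical structure of the packaged
fixtures so every pipeline stage is testable at any scale without the
quantum-chemistry inputs: pair binding energies uniform on
[-100, -25] kJ/mol, transition states uniform on [-50, +300] kJ/mol,
bound-water products normal around -50 kJ/mol, water-removal costs
normal around +200 kJ/mol (clipped to the physical sign), and warm
dense cloud conditions (n_H2 log-uniform on [1e7, 1e8] cm^-3,
T uniform on [100, 200] K, fractional abundance 1e-7).  True
distributions over amino-acid pair space are unknown; these are the
minimally-informative choices and all ranges are configurable.
Identical seeds give byte-identical serialized output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinetics import CloudEnvironment, UVClass
from .profiles import ProfileLibrary, ReactionProfile, SpeciesInfo, SpeciesKind

__all__ = ["GeneratorConfig", "GeneratorConfigError", "generate_profiles", "generate_environment"]

GENERATOR_ALGORITHM = "cloudamide-synth-v1/numpy-PCG64"


class GeneratorConfigError(ValueError):
    """A generator range is impossible or degenerate."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Ranges and seed for synthetic profile/environment generation.

    Energy units kJ/mol; densities cm^-3; temperatures K.
    """

    n_profiles: int = 14
    seed: int = 0
    binding_range: tuple[float, float] = (-100.0, -25.0)
    ts_range: tuple[float, float] = (-50.0, 300.0)
    state4_center: float = -50.0
    state4_spread: float = 15.0
    water_removal_center: float = 200.0
    water_removal_spread: float = 30.0
    n_h2_range: tuple[float, float] = (1.0e7, 1.0e8)
    temperature_range: tuple[float, float] = (100.0, 200.0)
    fractional_abundance: float = 1.0e-7
    uv_class: UVClass = UVClass.DC

    def __post_init__(self) -> None:
        if self.n_profiles < 0:
            raise GeneratorConfigError("n_profiles must be non-negative")
        lo, hi = self.binding_range
        if not (lo < hi < 0.0):
            raise GeneratorConfigError(
                "binding_range must be strictly negative and non-degenerate "
                f"(bound complexes), got {self.binding_range}"
            )
        if not self.ts_range[0] < self.ts_range[1]:
            raise GeneratorConfigError(f"ts_range must be non-degenerate, got {self.ts_range}")
        if self.state4_spread <= 0 or self.water_removal_spread <= 0:
            raise GeneratorConfigError("spreads must be positive")
        if self.water_removal_center <= 0:
            raise GeneratorConfigError("water_removal_center must be positive")
        if not 0 < self.n_h2_range[0] < self.n_h2_range[1]:
            raise GeneratorConfigError(f"invalid n_h2_range {self.n_h2_range}")
        if not 0 < self.temperature_range[0] < self.temperature_range[1]:
            raise GeneratorConfigError(f"invalid temperature_range {self.temperature_range}")


def _synthetic_species(rng: np.random.Generator, index: int) -> SpeciesInfo:
    atom_count = int(rng.integers(10, 26))
    # roughly amino-acid-like mass growth with size
    mass = round(75.0 + 6.0 * (atom_count - 10) + rng.uniform(-3.0, 3.0), 2)
    return SpeciesInfo(
        name=f"syn{index:03d}",
        atom_count=atom_count,
        mass=mass,
        kind=SpeciesKind.AMINO_ACID,
    )


def generate_profiles(cfg: GeneratorConfig) -> ProfileLibrary:
    """Draw a seeded synthetic amide profile library.

    Every profile satisfies the five-state invariants (bound pair,
    water removal costs energy) and falls inside the configured ranges;
    the generator algorithm and config are recorded in the library
    metadata so output is reproducible across versions.
    """
    rng = np.random.default_rng(cfg.seed)
    n_species = max(2, min(2 * cfg.n_profiles, 20)) if cfg.n_profiles else 2
    species = {}
    for i in range(n_species):
        info = _synthetic_species(rng, i)
        species[info.name] = info
    names = list(species)
    profiles = []
    conformer_count: dict[tuple[str, str], int] = {}
    for _ in range(cfg.n_profiles):
        a, b = rng.choice(len(names), size=2, replace=False)
        pair = (names[int(a)], names[int(b)])
        conformer_count[pair] = conformer_count.get(pair, 0) + 1
        e_pair = float(rng.uniform(*cfg.binding_range))
        e_ts = float(rng.uniform(*cfg.ts_range))
        # clip state 4 to the bound side, water removal to positive cost
        e4 = float(min(rng.normal(cfg.state4_center, cfg.state4_spread), -1.0))
        w = float(max(rng.normal(cfg.water_removal_center, cfg.water_removal_spread), 1.0))
        profiles.append(
            ReactionProfile(
                pair_id=pair,
                conformer_id=conformer_count[pair],
                e_pair=round(e_pair, 3),
                e_ts=round(e_ts, 3),
                e_product_bound_water=round(e4, 3),
                e_product_free_water=round(e4 + w, 3),
                approximate=True,
            )
        )
    metadata = {
        "generator": {
            "algorithm": GENERATOR_ALGORITHM,
            "seed": cfg.seed,
            "n_profiles": cfg.n_profiles,
            "binding_range": list(cfg.binding_range),
            "ts_range": list(cfg.ts_range),
            "state4": [cfg.state4_center, cfg.state4_spread],
            "water_removal": [cfg.water_removal_center, cfg.water_removal_spread],
        }
    }
    return ProfileLibrary(tuple(profiles), species, metadata)


def generate_environment(cfg: GeneratorConfig) -> CloudEnvironment:
    """Draw a seeded warm-dense-cloud environment.

    n_H2 is log-uniform over its range (densities are scale variables);
    temperature is uniform.  A distinct stream from the profile
    generator is used so profile and environment draws do not interact.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    log_lo, log_hi = np.log10(cfg.n_h2_range[0]), np.log10(cfg.n_h2_range[1])
    n_h2 = float(10.0 ** rng.uniform(log_lo, log_hi))
    temperature = float(rng.uniform(*cfg.temperature_range))
    return CloudEnvironment(
        temperature=temperature,
        n_h2=n_h2,
        fractional_abundance=cfg.fractional_abundance,
        uv_class=cfg.uv_class,
    )
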