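"""Tabular report builders shared by the CLI and notebooks.

All numeric columns carry explicit units in the header; quantities in
this problem span more than thirty decades, so CSV output is formatted
in scientific notation with three significant figures.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .kinetics import (
    CloudEnvironment,
    KineticParameters,
    UVClass,
    collision_rate,
    collision_timescale,
    species_density,
)
from .photochem import dimerize_before_destruction, load_packaged_uv_data, photolysis_rate
from .profiles import (
    BarrierClass,
    BarrierReference,
    DEFAULT_BARRIER_THRESHOLD_KJ_MOL,
    MissingStateError,
    ProfileLibrary,
    barrier_height,
    binding_energy,
    classify_barrier,
    water_removal_energy,
)
from .stability import (
    complex_lifetime,
    dissociation_spec_for_profile,
    feasibility_report,
)

__all__ = [
    "profiles_table",
    "kinetics_table",
    "survival_probability",
    "write_table",
    "write_provenance",
]

CSV_FLOAT_FORMAT = "%.3e"


def _condensation_class(profile, library: ProfileLibrary, threshold: float) -> str:
    """Report-level class: high barrier, low barrier, or non-binding product.

    A pair whose barrier is low but whose bonded product (with bound
    water) sits above the separated monomers cannot hold a bond even
    though the transition state is accessible.
    """
    if classify_barrier(profile, threshold) is BarrierClass.HIGH:
        return "high"
    if profile.e_product_bound_water >= 0:
        return "non_binding"
    return "low"


def profiles_table(
    library: ProfileLibrary,
    threshold: float = DEFAULT_BARRIER_THRESHOLD_KJ_MOL,
) -> pd.DataFrame:
    rows = []
    for p in library:
        try:
            w = water_removal_energy(p)
        except MissingStateError:
            w = np.nan
        rows.append(
            {
                "pair": "-".join(p.pair_id),
                "conformer": p.conformer_id,
                "binding_kJ_mol": binding_energy(p),
                "barrier_from_separated_kJ_mol": barrier_height(p, BarrierReference.SEPARATED),
                "barrier_from_bound_pair_kJ_mol": barrier_height(p, BarrierReference.BOUND_PAIR),
                "water_removal_kJ_mol": w,
                "barrier_class": classify_barrier(p, threshold).value,
                "condensation_class": _condensation_class(p, library, threshold),
                "approximate": p.approximate,
            }
        )
    columns = [
        "pair",
        "conformer",
        "binding_kJ_mol",
        "barrier_from_separated_kJ_mol",
        "barrier_from_bound_pair_kJ_mol",
        "water_removal_kJ_mol",
        "barrier_class",
        "condensation_class",
        "approximate",
    ]
    return pd.DataFrame(rows, columns=columns)


def survival_probability(env: CloudEnvironment, params: KineticParameters) -> float:
    """Probability a monomer complexes before UV destruction in ``env``.

    1.0 when the environment has no UV field.
    """
    if env.uv_class is UVClass.NONE:
        return 1.0
    uv_envs, _ = load_packaged_uv_data()
    kc = collision_rate(species_density(env), params)
    kp = photolysis_rate(uv_envs[env.uv_class])
    return dimerize_before_destruction(kc, kp)


def kinetics_table(
    library: ProfileLibrary,
    env: CloudEnvironment,
    params: KineticParameters,
) -> pd.DataFrame:
    """Per-profile kinetic summary in the reference environment."""
    n = species_density(env)
    t_coll = collision_timescale(n, params)
    p_surv = survival_probability(env, params)
    rows = []
    for p in library:
        rep = feasibility_report(p, env, params)
        life = [
            complex_lifetime(dissociation_spec_for_profile(p, env.temperature, a))
            for a in (params.a_high, params.a_low)
        ]
        rows.append(
            {
                "pair": "-".join(p.pair_id),
                "conformer": p.conformer_id,
                "barrier_class": rep.barrier_class.value,
                "collision_timescale_yr": t_coll,
                "complex_lifetime_min_yr": min(life),
                "complex_lifetime_max_yr": max(life),
                "ratio_at_A1e12": rep.equilibrium_ratio_range[1],
                "ratio_at_A1e15": rep.equilibrium_ratio_range[0],
                "survival_probability": p_surv,
                "proceeds": rep.proceeds_to_bond,
                "stabilized_by_water": rep.stabilized_by_water,
            }
        )
    return pd.DataFrame(rows)


def write_table(frame: pd.DataFrame, path: Path, fmt: str = "csv") -> Path:
    """Write a report table as CSV (3-sig-fig scientific) or JSON records."""
    if fmt == "csv":
        out = path.with_suffix(".csv")
        frame.to_csv(out, index=False, float_format=CSV_FLOAT_FORMAT)
    elif fmt == "json":
        out = path.with_suffix(".json")
        frame.to_json(out, orient="records", indent=1)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return out


def write_provenance(path: Path, record: Mapping[str, object]) -> None:
    """Write the machine-readable run provenance next to the outputs."""
    doc = {"cloudamide_version": __version__, **record}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
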