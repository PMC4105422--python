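"""Physical constants and unit conversions.

All reaction energies in this package are molar enthalpies in kJ/mol,
relative to the separated-monomer zero.  Source texts in this field mix
kJ/mol and eV (per molecule), so a single conversion point lives here.
"""

from __future__ import annotations

#: Molar gas constant, J mol^-1 K^-1.
R_J_PER_MOL_K: float = 8.314462618

#: 1 eV per molecule expressed as kJ/mol (96.485 kJ/mol per eV).
EV_AS_KJ_PER_MOL: float = 96.485

#: Avogadro constant, mol^-1.
N_AVOGADRO: float = 6.02214076e23

#: Julian year in seconds.
YEAR_S: float = 3.15576e7


def ev_to_kj_per_mol(energy_ev: float) -> float:
    """Convert a per-molecule energy in eV to a molar energy in kJ/mol."""
    return energy_ev * EV_AS_KJ_PER_MOL


def kj_per_mol_to_ev(energy_kj_mol: float) -> float:
    """Convert a molar energy in kJ/mol to a per-molecule energy in eV."""
    return energy_kj_mol / EV_AS_KJ_PER_MOL


def kj_per_mol_to_j_per_molecule(energy_kj_mol: float) -> float:
    """Convert a molar energy in kJ/mol to joules per molecule."""
    return energy_kj_mol * 1e3 / N_AVOGADRO


def seconds_to_years(t_s: float) -> float:
    """Convert seconds to Julian years."""
    return t_s / YEAR_S


def years_to_seconds(t_yr: float) -> float:
    """Convert Julian years to seconds."""
    return t_yr * YEAR_S
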