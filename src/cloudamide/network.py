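"""Time-dependent polymerization network: monomer -> hydrogen-bonded
complex -> n-mers.

The network is a ladder of reversible association steps.  Monomers
associate pairwise into a length-2 species (k2 * n_i * n_j forward,
Arrhenius dissociation with Ea = |e_pair| backward).  When the
condensation barrier of the governing pair is low, the length-2 species
is a covalently bonded dimer and keeps growing by monomer addition up
to ``max_length``; when the barrier is high the chain stalls at the
hydrogen-bonded complex, unless a dimer+dimer channel (barrier
reduction on 4-mer formation) is available to open the gate at length
4.  Water of condensation is bookkept as bound to the growing polymer
and not tracked as a free species.  Deterministic rate equations are
integrated with a stiff-capable solver; the analytic detailed-balance
steady state serves as an independent check.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .kinetics import CloudEnvironment, KineticParameters, UVClass, species_density
from .photochem import load_packaged_uv_data, photolysis_rate as _photolysis_rate
from .profiles import (
    BarrierClass,
    ProfileLibrary,
    ReactionProfile,
    SpeciesKind,
    classify_barrier,
)
from .stability import DissociationSpec, arrhenius_rate

__all__ = [
    "Reaction",
    "NetworkSpec",
    "PopulationState",
    "Trajectory",
    "NetworkConfigurationError",
    "SolverError",
    "build_network",
    "simulate",
    "steady_state",
    "relaxation_time_estimate",
]


class NetworkConfigurationError(ValueError):
    """The requested network cannot be built from the given inputs."""


class SolverError(RuntimeError):
    """The ODE integrator failed; carries the failing time."""

    def __init__(self, message: str, t_fail: float):
        super().__init__(message)
        self.t_fail = t_fail


@dataclass(frozen=True)
class Reaction:
    """One reversible association step P_i + P_j <-> P_p.

    ``kf`` in cm^3 s^-1, ``kd`` in s^-1.  ``condensed`` records whether
    the product is covalently bonded (gate open) or a stalled
    hydrogen-bonded complex.
    """

    i: int
    j: int
    product: int
    kf: float
    kd: float
    condensed: bool = True

    def __post_init__(self) -> None:
        if self.kf < 0 or self.kd < 0:
            raise NetworkConfigurationError("rates must be non-negative")
        if self.i + self.j != self.product:
            raise NetworkConfigurationError(
                f"reaction {self.i}+{self.j}->{self.product} does not conserve monomers"
            )


@dataclass(frozen=True)
class NetworkSpec:
    """A polymerization network over species of length 1..max_length."""

    max_length: int
    reactions: tuple[Reaction, ...]
    photolysis_rate: float = 0.0
    n0_monomer: float = 1.0
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.max_length < 2:
            raise NetworkConfigurationError(f"max_length must be >= 2, got {self.max_length}")
        if self.photolysis_rate < 0:
            raise NetworkConfigurationError("photolysis_rate must be non-negative")
        for r in self.reactions:
            if r.product > self.max_length:
                raise NetworkConfigurationError(
                    f"reaction product length {r.product} exceeds max_length"
                )

    @property
    def lengths(self) -> tuple[int, ...]:
        return tuple(range(1, self.max_length + 1))


@dataclass(frozen=True)
class PopulationState:
    """Number densities (cm^-3) per species length at one instant."""

    lengths: tuple[int, ...]
    densities: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.lengths) != len(self.densities):
            raise ValueError("lengths and densities must align")
        if any(d < 0 for d in self.densities):
            raise ValueError("densities must be non-negative")

    @classmethod
    def pure_monomer(cls, network: NetworkSpec, n0: float | None = None) -> "PopulationState":
        n0 = network.n0_monomer if n0 is None else n0
        dens = [0.0] * network.max_length
        dens[0] = n0
        return cls(network.lengths, tuple(dens))

    def density(self, length: int) -> float:
        return self.densities[self.lengths.index(length)]

    @property
    def monomer_equivalents(self) -> float:
        return float(sum(l * d for l, d in zip(self.lengths, self.densities)))


@dataclass(frozen=True)
class Trajectory:
    """Integrated number densities over a time grid."""

    times_s: np.ndarray
    densities: np.ndarray  # shape (n_times, n_species)
    lengths: tuple[int, ...]

    def state(self, index: int = -1) -> PopulationState:
        return PopulationState(self.lengths, tuple(float(x) for x in self.densities[index]))

    def monomer_equivalents(self) -> np.ndarray:
        return self.densities @ np.asarray(self.lengths, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.densities,
            columns=[f"n{l}_cm3" for l in self.lengths],
        )
        frame.insert(0, "time_s", self.times_s)
        return frame


def build_network(
    library: ProfileLibrary,
    env: CloudEnvironment,
    params: KineticParameters,
    max_length: int = 2,
    pair: Sequence[str] | None = None,
    pre_exponential: float | None = None,
    ea_overrides: Mapping[int, float] | None = None,
    include_photolysis: bool = True,
) -> NetworkSpec:
    """Assemble a polymerization network from a profile library.

    The governing dimer profile is the lowest-conformer profile of
    ``pair`` (or the first profile in the library).  Dissociation rates
    follow the Arrhenius law with Ea = |e_pair| (per-length overrides
    via ``ea_overrides``, keyed by product length) and pre-exponential
    ``pre_exponential`` (default: the tight-limit ``params.a_low``).
    A low condensation barrier opens monomer-addition growth up to
    ``max_length``; a high barrier stalls the chain at the
    hydrogen-bonded complex, unless the library carries a
    polymer+polymer (dimer+dimer) profile with a low barrier and
    ``max_length >= 4``, which opens the 2+2->4 channel.  Monomer
    photolysis is attached from the environment's UV class.
    """
    if len(library) == 0:
        raise NetworkConfigurationError("profile library is empty")
    if pair is not None:
        candidates = [p for p in library if p.pair_id == tuple(pair)]
        if not candidates:
            raise NetworkConfigurationError(f"no profile for pair {tuple(pair)!r}")
    else:
        candidates = list(library)
    profile = min(candidates, key=lambda p: p.conformer_id)
    a_factor = params.a_low if pre_exponential is None else pre_exponential
    ea_overrides = dict(ea_overrides or {})

    def kd_for(p: ReactionProfile, product_length: int) -> float:
        ea = ea_overrides.get(product_length, abs(p.e_pair))
        return arrhenius_rate(
            DissociationSpec(
                pre_exponential=a_factor,
                activation_energy=ea,
                temperature=env.temperature,
            )
        )

    gate_open = classify_barrier(profile) is BarrierClass.LOW
    reactions = [
        Reaction(1, 1, 2, kf=params.k2, kd=kd_for(profile, 2), condensed=gate_open)
    ]
    if gate_open:
        for l in range(2, max_length):
            reactions.append(
                Reaction(l, 1, l + 1, kf=params.k2, kd=kd_for(profile, l + 1))
            )
    elif max_length >= 4:
        tetramer = [
            p
            for p in library
            if all(k is SpeciesKind.POLYMER for k in library.pair_kinds(p))
            and classify_barrier(p) is BarrierClass.LOW
        ]
        if tetramer:
            over = min(tetramer, key=lambda p: p.conformer_id)
            reactions.append(Reaction(2, 2, 4, kf=params.k2, kd=kd_for(over, 4)))

    kp = 0.0
    if include_photolysis and env.uv_class is not UVClass.NONE:
        uv_envs, _ = load_packaged_uv_data()
        kp = _photolysis_rate(uv_envs[env.uv_class])

    return NetworkSpec(
        max_length=max_length,
        reactions=tuple(reactions),
        photolysis_rate=kp,
        n0_monomer=species_density(env),
        metadata={
            "pair": list(profile.pair_id),
            "conformer": profile.conformer_id,
            "gate_open": gate_open,
            "pre_exponential_s": a_factor,
        },
    )


def _rhs(network: NetworkSpec):
    idx = {l: l - 1 for l in network.lengths}
    terms = [
        (idx[r.i], idx[r.j], idx[r.product], r.kf, r.kd) for r in network.reactions
    ]
    kp = network.photolysis_rate

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        dy = np.zeros_like(y)
        for i, j, p, kf, kd in terms:
            net = kf * y[i] * y[j] - kd * y[p]
            dy[i] -= net
            dy[j] -= net
            dy[p] += net
        if kp:
            dy[0] -= kp * y[0]
        return dy

    return rhs


def simulate(
    network: NetworkSpec,
    initial: PopulationState,
    t_end: float,
    rel_tol: float = 1e-8,
    abs_tol: float | None = None,
    n_out: int = 200,
) -> Trajectory:
    """Integrate the rate equations from ``initial`` to ``t_end`` seconds.

    Output times are log-spaced (plus t = 0).  ``abs_tol`` defaults to
    1e-15 times the total monomer-equivalent density; rates in this
    problem span tens of decades, so a stiff-capable method (LSODA) is
    used throughout.  Raises :class:`SolverError` with the failing time
    on integrator failure.
    """
    if t_end < 0:
        raise ValueError("t_end must be non-negative")
    if tuple(initial.lengths) != network.lengths:
        raise ValueError("initial state does not match network species")
    y0 = np.asarray(initial.densities, dtype=float)
    if t_end == 0:
        return Trajectory(np.array([0.0]), y0[None, :], network.lengths)
    total = max(initial.monomer_equivalents, 1e-300)
    if abs_tol is None:
        abs_tol = 1e-15 * total
    t_eval = np.concatenate([[0.0], np.geomspace(t_end * 1e-9, t_end, n_out)])
    sol = solve_ivp(
        _rhs(network),
        (0.0, t_end),
        y0,
        method="LSODA",
        t_eval=t_eval,
        rtol=rel_tol,
        atol=abs_tol,
    )
    if not sol.success:
        raise SolverError(f"ODE integration failed: {sol.message}", float(sol.t[-1]))
    dens = sol.y.T.copy()
    # solver noise can leave densities a hair below zero
    dens[(dens < 0) & (dens > -10 * abs_tol)] = 0.0
    if (dens < 0).any():
        raise SolverError("negative densities beyond solver tolerance", float(t_end))
    return Trajectory(sol.t, dens, network.lengths)


def steady_state(
    network: NetworkSpec,
    total_monomer_equivalents: float | None = None,
) -> PopulationState | None:
    """Algebraic fixed point of the rate equations.

    Uses detailed balance (the reaction graph is a tree): each species
    density follows from the monomer density through the equilibrium
    constants of its formation path; the monomer density is then fixed
    by monomer-equivalent conservation via a bracketed root solve in
    log density.  Species not reachable through an active (kf > 0)
    channel equilibrate at zero.

    Returns ``None`` (documented sentinel) when no finite equilibrium
    exists, i.e. some active formation channel has no dissociation.
    With photolysis active the only fixed point is total depletion and
    the all-zero state is returned.
    """
    total = (
        network.n0_monomer
        if total_monomer_equivalents is None
        else total_monomer_equivalents
    )
    if total < 0:
        raise ValueError("total monomer equivalents must be non-negative")
    zeros = PopulationState(network.lengths, (0.0,) * network.max_length)
    if network.photolysis_rate > 0:
        return zeros
    if total == 0:
        return zeros
    active = [r for r in network.reactions if r.kf > 0]
    if any(r.kd == 0 for r in active):
        return None

    # log equilibrium constant ln(kf/kd) per product, composed along the tree
    log_n: dict[int, float | None] = {1: 0.0}  # offsets relative to ln n1 = x
    coef: dict[int, int] = {1: 1}  # power of n1 per species
    changed = True
    while changed:
        changed = False
        for r in active:
            if r.product not in log_n and r.i in log_n and r.j in log_n:
                log_n[r.product] = (
                    np.log(r.kf / r.kd) + log_n[r.i] + log_n[r.j]  # type: ignore[operator]
                )
                coef[r.product] = coef[r.i] + coef[r.j]
                changed = True

    def total_at(x: float) -> float:
        s = 0.0
        for l in network.lengths:
            if l in log_n:
                expo = min(log_n[l] + coef[l] * x, 700.0)  # type: ignore[operator]
                s += l * np.exp(expo)
        return s

    hi = float(np.log(total)) + 1.0
    lo = hi - 1500.0
    x = brentq(lambda x: total_at(x) - total, lo, hi, xtol=1e-13, rtol=8.9e-16)
    dens = [0.0] * network.max_length
    for l in network.lengths:
        if l in log_n:
            dens[l - 1] = float(np.exp(log_n[l] + coef[l] * x))  # type: ignore[operator]
    return PopulationState(network.lengths, tuple(dens))


def relaxation_time_estimate(network: NetworkSpec) -> float:
    """Crude e-folding time (s) of the approach to equilibrium.

    Linearised around the analytic steady state: the slowest active
    channel relaxes at about kd + 4 kf n1_eq.  Used to choose t_end for
    runs that must reach steady state.  The monomer density is taken
    from the photolysis-free equilibrium (with photolysis the fixed
    point is zero and carries no rate information).
    """
    base = (
        network
        if network.photolysis_rate == 0
        else dataclasses.replace(network, photolysis_rate=0.0)
    )
    eq = steady_state(base)
    if eq is None:
        raise NetworkConfigurationError("no finite equilibrium to relax to")
    n1 = max(eq.density(1), 1e-300)
    rates = [r.kd + 4.0 * r.kf * n1 for r in network.reactions if r.kf > 0]
    if network.photolysis_rate > 0:
        rates.append(network.photolysis_rate)
    if not rates:
        return np.inf
    return 1.0 / min(rates)
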