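# Methods

## Model

`cloudamide` treats gas-phase peptide-bond formation as a three-stage
kinetic chain in a homogeneous cloud volume:

1. **Complex formation.**  Monomers of number density n (cm⁻³) form
   hydrogen-bonded pairs as a two-body process at rate k₂·n per
   monomer, k₂ = σ·v̄ ≈ 2×10⁻¹¹ cm³ s⁻¹ at 100 K.  Sticking without a
   third body is justified by internal-energy redistribution: merging
   M- and N-atom molecules spreads the mean collision energy 3kT/2
   over 3(M+N−1) internal modes, multiplying the internal temperature
   by (M+N)/(M+N−1) — 23/22 ≈ 1.045 for glycine + alanine.  The
   package exposes this factor and a configurable sticking threshold
   (default 1.25) that separates polyatomics from the very small
   molecules for which the argument fails (diatomics: 4/3).  The
   threshold is a modelling device to make the qualitative dichotomy
   testable; no sharp physical cutoff is claimed.

2. **Complex stability.**  In the rapid-energy-exchange (thermalised)
   limit the complex dissociates at k_D = A·exp(−E_a/RT) with
   A ∈ [10¹² s⁻¹ (tight), 10¹⁵ s⁻¹ (loose)] and E_a equal to the
   hydrogen-bond association depth |E_pair| of the governing reaction
   profile.  Balancing formation against dissociation gives the
   equilibrium dimer/monomer ratio k₂·n/k_D.  No RRKM or
   master-equation treatment is attempted — the thermalised limit is
   the model.

3. **Condensation gate.**  Passage through the transition state into a
   covalent bond is not assigned a rate of its own (none is derivable
   from the five-state enthalpies alone).  Instead a binary gate
   compares the transition-state enthalpy, measured from the
   separated-monomer zero, against a threshold of 0.6 eV
   (57.891 kJ/mol at 96.485 kJ/mol per eV), inclusive at the boundary.
   Low-barrier pairs condense as soon as the complex forms;
   high-barrier pairs stall at the hydrogen-bonded complex.  The
   alternative barrier reference — escape from the bound-pair well —
   is exposed (`barrier_height(..., reference="bound_pair")`) because
   the kinetic argument concerns a complex that already sits in the
   well; the separated-monomer convention is used for classification
   because it is the one that reproduces the published low/high lists.

UV photodestruction of free monomers is a competing first-order
channel with rate ln 2 / t₁/₂ (the quoted times are interpreted as
half-lives; a 1/e-lifetime reading would shift rates by ln 2).  The
probability of complexation before destruction is the two-channel
branching ratio k_c/(k_c + k_p).  Peptide (as opposed to monomer)
photodestruction is deliberately not modelled as a rate: only
destruction quantum efficiencies are available, and without a photon
flux they cannot be converted; they are surfaced in reports as data.

## Reaction-profile data

The five-state profiles (separated monomers ≡ 0, H-bonded pair,
transition state, dipeptide + bound water, dipeptide + free water) are
stored in kJ/mol in a JSON schema validated at load time: bound pairs
must have E_pair < 0, and amide profiles must show a positive
water-removal cost E₅ − E₄.  The packaged library encodes the
text-stated energetics — pair binding between −25 and −100 kJ/mol
(typical −60), bonded product with bound water near −50 kJ/mol, water
removal near +200 kJ/mol, Gly-Gly barrier 200 kJ/mol, ethylene glycol
−40 kJ/mol binding with barriers of either ~290 kJ/mol or ~0 — with
per-pair values placed inside those ranges and flagged
`approximate: true`, because no per-pair table exists in the source
data.  Tests therefore assert ranges and classifications, never
per-pair decimals.  Glycol profiles omit the water-at-infinity state;
their near-zero-barrier conformers carry an unbound product
(E₄ > 0), which the profile report surfaces as `non_binding`.

## Population dynamics

The network is a ladder of reversible steps over species of length
1..L: monomer + monomer ⇌ length-2 species, then (gate open)
length-ℓ + monomer ⇌ length-(ℓ+1) with the same k₂ and the same
E_a = |E_pair| convention unless a per-length override is supplied;
for a stalled (high-barrier) pair with L ≥ 4, a polymer+polymer
profile in the library opens the dimer+dimer ⇌ 4-mer channel instead,
reflecting the barrier reduction when two dimers join.  Water of
condensation travels with the polymer and is not tracked as a free
species, so monomer-equivalents Σ ℓ·n_ℓ are conserved when photolysis
is off.

Integration uses `scipy.integrate.solve_ivp` with LSODA at
rtol = 10⁻⁸ and atol = 10⁻¹⁵ × (total monomer equivalents); rate
constants span ~30 decades but remain comfortably inside double
range, so no log-transformed state is needed.  Output grids are
log-spaced.  The analytic steady state is computed independently by
detailed balance: the reaction graph is a tree, so each species is an
explicit power of the monomer density times its path equilibrium
constants, and conservation reduces to a scalar monotone root-find in
log monomer density (Brent's method; exponents clipped at 700 to keep
the bracket finite).  Networks with an active formation channel but
no dissociation have no finite equilibrium and `steady_state` returns
`None`; with photolysis on, the only fixed point is total depletion
and the all-zero state is returned.  `relaxation_time_estimate`
linearises around the photolysis-free equilibrium (slowest channel
rate ≈ k_d + 4·k_f·n₁) to pick integration horizons for
run-to-steady-state workflows.

## Synthetic data

The generator emulates the packaged library's statistical structure:
E_pair uniform on [−100, −25] kJ/mol, E_TS uniform on [−50, +300]
kJ/mol, E₄ normal (−50, 15) clipped below zero, water-removal cost
normal (+200, 30) clipped above zero; environments draw n_H2
log-uniform on [10⁷, 10⁸] cm⁻³ and T uniform on [100, 200] K with
fractional abundance 10⁻⁷.  Uniform/normal are minimally-informative
choices — the true distribution of barriers over amino-acid pair
space is unknown — and all ranges are configurable.  Draws use
numpy's PCG64 keyed by the config seed (a separate stream for the
environment), and the algorithm identifier plus full config are
written into the output metadata, so identical configs give
byte-identical serialized libraries.  What passing synthetic-data
tests show is that the pipeline is correct *under these stated
distributions*; they say nothing about real per-pair quantum
chemistry, conformer multiplicity, or correlations between binding
and barrier heights, none of which the generator models.

## Numerical and design choices

- Gas constant R = 8.314462618 J mol⁻¹ K⁻¹; energies per mole
  throughout; 1 eV ≡ 96.485 kJ/mol; Julian year = 3.15576×10⁷ s.
- Direct evaluation of the equilibrium ratio at E_a = 60 kJ/mol,
  T = 100 K, n = 1 cm⁻³ gives 4.4×10⁸ (A = 10¹²) and 4.4×10⁵
  (A = 10¹⁵); the commonly quoted 3×10⁸/3×10⁵ round-number endpoints
  agree to within a factor ≈1.5, i.e. at order-of-magnitude level,
  which is how those endpoints are asserted.  The glycol endpoints
  (E_a = 40 kJ/mol) evaluate to 0.0156 and 1.56×10⁻⁵, within 10% of
  the quoted 0.015/1.5×10⁻⁵.
- The collisional (10⁴ s) and radiative (×100) relaxation timescales
  of a freshly formed complex are stored as documented constants, not
  derived: the package contains no collision or radiation model that
  could compute them.
- The two-body sticking verdict, the condensation gate and the
  barrier-classification threshold are deliberately binary: the model
  has no data to support anything smoother.
- Degenerate inputs: zero species density gives an infinite collision
  timescale (a sentinel, not an exception); a zero-rate network leaves
  densities constant; `t_end = 0` echoes the initial state; both
  branching rates zero raises, since the probability is undefined.

## Problem sizes

The test suite and the acceptance script run two- to four-species
networks, parameter sweeps of ≲16 points, 5 randomized ODE-vs-analytic
draws, and one 10⁴-draw generator-coverage check — desk-scale
computations chosen because the model's claims are themselves
closed-form or few-species; nothing in the science calls for larger
grids.

## Limitations

- No spatial structure, grain-surface chemistry, accretion of other
  ices, or radiative association; the cloud is a homogeneous box.
- The transition-state passage rate is not modelled; the gate treats
  low-barrier condensation as instantaneous relative to complex
  formation.
- n-mer energetics beyond the packaged 4-mer override reuse the dimer
  E_a convention for lack of data.
- Per-pair fixture energies are representative placements inside
  stated ranges, not measured values; conclusions that depend on a
  specific pair's exact barrier should not be drawn from them.
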