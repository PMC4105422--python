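# cloudamide

Kinetics of gas-phase amino acid polymerization in warm, dense
molecular clouds.

Could peptides — hydrophobic polymer amide — have been among the first
solid-density materials to form in space?  The question turns on
whether two free amino acids that collide in a cloud interior
(n_H2 ≈ 10⁷–10⁸ cm⁻³, T ≳ 100 K) can stick, survive, and condense into
a covalently bonded dimer before ultraviolet light destroys them.
`cloudamide` implements the kinetic argument end to end for
astrochemists and origin-of-life modellers:

- **Five-state reaction-energy profiles** — separated monomers (zero),
  hydrogen-bonded pair (E_pair), transition state (E_TS), dipeptide
  with bound water of condensation, dipeptide with water removed to
  infinity — as a validated JSON data model, with a packaged library
  of 14 amino-acid pairs, 7 ethylene glycol pairs and one
  dimer+dimer (4-mer) profile.
- **Collision kinetics** — complex formation at k₂·n per monomer with
  k₂ ≈ 2×10⁻¹¹ cm³ s⁻¹, and the internal-energy-redistribution
  (sticking) criterion: a merged pair of M- and N-atom molecules heats
  internally by only (M+N)/(M+N−1), so amino-acid-sized molecules
  stick without a third body.
- **Arrhenius stability** — dissociation k_D = A·exp(−E_a/RT) in the
  thermalised limit, A ∈ [10¹², 10¹⁵] s⁻¹, E_a = |E_pair|; complex
  lifetime and the equilibrium dimer/monomer ratio k₂n/k_D.
- **UV competition** — first-order photodestruction (half-life 300 yr
  in the diffuse ISM, 3×10⁷ yr in a dark cloud) racing against complex
  formation.
- **Population dynamics** — a stiff ODE network
  monomer → H-bonded complex → n-mer with per-step condensation gates
  set by the barrier class, checked against the detailed-balance
  closed form.
- **Synthetic data** — seeded generators for profile libraries and
  cloud environments with the same statistical structure as the
  packaged fixtures.

## Worked example

```python
>>> import cloudamide as ca
>>> params = ca.KineticParameters()          # k2 = 2e-11 cm^3/s, A in [1e12, 1e15]
>>> env = ca.CloudEnvironment()              # 100 K, 1e7 H2 cm^-3, fraction 1e-7
>>> n = ca.species_density(env)              # monomer density, cm^-3
>>> n
1.0
>>> round(ca.collision_timescale(n, params))      # years to form an H-bonded pair
1584
>>> ca.internal_temperature_factor(10, 13)        # glycine + alanine heating factor
1.0454545454545454
>>> spec = ca.DissociationSpec(1e12, 60.0, 100.0) # tight TS, 60 kJ/mol well, 100 K
>>> f"{ca.arrhenius_rate(spec):.3g}"              # dissociation rate, s^-1
'4.57e-20'
>>> f"{ca.equilibrium_dimer_ratio(n, params, spec):.3g}"
'4.38e+08'
```

Read: at the reference cloud conditions a free amino acid finds a
partner in ~1.6×10³ yr; the collision heats the pair internally by
only 4.5%, so it sticks; the 60 kJ/mol hydrogen-bonded well then
dissociates so slowly (4.6×10⁻²⁰ s⁻¹) that at equilibrium dimers
outnumber monomers about 4×10⁸ to one (4×10⁵ at the loose-limit
A = 10¹⁵ s⁻¹).  Whether the pair condenses further into a covalent
peptide bond depends on its transition-state barrier: at the default
0.6 eV gate the packaged Glu-Ala, Asp-Ile, Ser-Leu and Asn-Pro
profiles proceed, while Lys-Phe, Phe-Gly, Ala-Ala, Gly-Gly and
Ala-Gly stall at the hydrogen-bonded complex — and ethylene glycol,
with −40 kJ/mol binding, reaches a dimer ratio of at most ~0.016 and
never bonds.

The same pipeline from a shell:

```sh
cloudamide profiles --out report/           # classify the packaged library
cloudamide kinetics --out report/           # timescales, lifetimes, ratios
cloudamide simulate --pair Glu,Ala --out run/ --set uv_class=none
cloudamide synth    --seed 1 --out synthetic/
```

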