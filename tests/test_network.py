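"""Polymerization network: ODE integration vs analytic steady state."""

import numpy as np
import pytest

from cloudamide.kinetics import CloudEnvironment, KineticParameters, UVClass
from cloudamide.network import (
    NetworkConfigurationError,
    NetworkSpec,
    PopulationState,
    Reaction,
    build_network,
    relaxation_time_estimate,
    simulate,
    steady_state,
)
from cloudamide.profiles import ProfileLibrary
from cloudamide.stability import DissociationSpec, arrhenius_rate


def two_species_network(ea=60.0, a=1e12, t=100.0, n0=1.0, k2=2e-11, kp=0.0):
    kd = arrhenius_rate(DissociationSpec(a, ea, t))
    return NetworkSpec(
        max_length=2,
        reactions=(Reaction(1, 1, 2, kf=k2, kd=kd),),
        photolysis_rate=kp,
        n0_monomer=n0,
    )


def run_to_steady_state(network, rel_tol=1e-8):
    tau = relaxation_time_estimate(network)
    initial = PopulationState.pure_monomer(network)
    return simulate(network, initial, 50.0 * tau, rel_tol=rel_tol)


class TestBuildNetwork:
    def test_low_barrier_pair_builds_open_chain(self, library, dark_cloud_no_uv, params):
        net = build_network(library, dark_cloud_no_uv, params, max_length=3, pair=("Glu", "Ala"))
        assert net.metadata["gate_open"]
        assert [(r.i, r.j, r.product) for r in net.reactions] == [(1, 1, 2), (2, 1, 3)]
        assert all(r.kd > 0 for r in net.reactions)

    def test_high_barrier_pair_stalls_at_complex(self, library, dark_cloud_no_uv, params):
        net = build_network(library, dark_cloud_no_uv, params, max_length=3, pair=("Gly", "Gly"))
        assert not net.metadata["gate_open"]
        assert [(r.i, r.j, r.product) for r in net.reactions] == [(1, 1, 2)]
        assert not net.reactions[0].condensed

    def test_tetramer_override_opens_dimer_dimer_gate(self, library, dark_cloud_no_uv, params):
        """Gly-Gly stalls as pairs, but the low-barrier 4-mer channel opens 2+2->4."""
        net = build_network(library, dark_cloud_no_uv, params, max_length=4, pair=("Gly", "Gly"))
        assert (2, 2, 4) in [(r.i, r.j, r.product) for r in net.reactions]

    def test_empty_library_is_configuration_error(self, dark_cloud_no_uv, params):
        empty = ProfileLibrary((), {})
        with pytest.raises(NetworkConfigurationError):
            build_network(empty, dark_cloud_no_uv, params)

    def test_uv_class_attaches_monomer_photolysis(self, library, warm_cloud, params):
        net = build_network(library, warm_cloud, params, pair=("Glu", "Ala"))
        assert net.photolysis_rate == pytest.approx(7.32e-16, rel=1e-2)

    def test_initial_density_from_environment(self, library, dark_cloud_no_uv, params):
        net = build_network(library, dark_cloud_no_uv, params, pair=("Glu", "Ala"))
        assert net.n0_monomer == pytest.approx(1.0)


class TestSteadyState:
    def test_two_species_closed_form(self, params):
        """The fixed point satisfies k2 n1^2 = kD n2 and monomer conservation."""
        net = two_species_network()
        eq = steady_state(net)
        kd = net.reactions[0].kd
        assert net.reactions[0].kf * eq.density(1) ** 2 == pytest.approx(kd * eq.density(2), rel=1e-9)
        assert eq.monomer_equivalents == pytest.approx(1.0, rel=1e-9)

    def test_two_species_ratio_equals_equilibrium_formula(self, params):
        """At the fixed point n2/n1 equals k2 n1 / kD, the closed-form ratio."""
        net = two_species_network()
        eq = steady_state(net)
        ratio = eq.density(2) / eq.density(1)
        assert ratio == pytest.approx(net.reactions[0].kf * eq.density(1) / net.reactions[0].kd, rel=1e-9)

    def test_no_formation_means_all_monomer(self):
        net = NetworkSpec(2, (Reaction(1, 1, 2, kf=0.0, kd=1e-5),), n0_monomer=1.0)
        eq = steady_state(net)
        assert eq.density(1) == pytest.approx(1.0)
        assert eq.density(2) == 0.0

    def test_no_dissociation_has_no_finite_equilibrium(self):
        net = NetworkSpec(2, (Reaction(1, 1, 2, kf=2e-11, kd=0.0),), n0_monomer=1.0)
        assert steady_state(net) is None

    def test_photolysis_fixed_point_is_depletion(self):
        net = two_species_network(kp=1e-15)
        eq = steady_state(net)
        assert all(d == 0.0 for d in eq.densities)

    def test_glycol_dimer_fraction_is_marginal(self, library, dark_cloud_no_uv, params):
        """Weak glycol binding leaves only ~1.5% of molecules paired."""
        net = build_network(
            library, dark_cloud_no_uv, params, max_length=2,
            pair=("ethylene_glycol", "ethylene_glycol"),
        )
        eq = steady_state(net)
        fraction = eq.density(2) / (eq.density(1) + eq.density(2))
        assert fraction == pytest.approx(0.0156 / 1.0156, rel=0.10)
        assert fraction <= 0.016


class TestSimulate:
    def test_ode_reaches_analytic_equilibrium(self):
        """Terminal dimer/monomer ratio matches the closed form within 1%."""
        net = two_species_network(a=1e12)
        eq = steady_state(net)
        final = run_to_steady_state(net).state()
        assert final.density(2) / final.density(1) == pytest.approx(
            eq.density(2) / eq.density(1), rel=1e-2
        )

    @pytest.mark.parametrize("seed", range(6))
    def test_ode_matches_closed_form_over_parameter_draws(self, seed):
        """Randomized (Ea, A, T, n) from the cloud ranges: every species density
        agrees with the detailed-balance fixed point to < 1%."""
        rng = np.random.default_rng(seed)
        net = two_species_network(
            ea=rng.uniform(25.0, 100.0),
            a=10 ** rng.uniform(12.0, 15.0),
            t=rng.uniform(100.0, 200.0),
            n0=10 ** rng.uniform(0.0, 1.0),
        )
        eq = steady_state(net)
        final = run_to_steady_state(net).state()
        for l in net.lengths:
            assert final.density(l) == pytest.approx(eq.density(l), rel=1e-2)

    def test_mass_conservation_without_photolysis(self):
        net = two_species_network()
        traj = run_to_steady_state(net)
        me = traj.monomer_equivalents()
        assert np.max(np.abs(me - me[0])) / me[0] < 1e-6

    def test_all_rates_zero_keeps_densities_constant(self):
        net = NetworkSpec(2, (Reaction(1, 1, 2, kf=0.0, kd=0.0),), n0_monomer=1.0)
        traj = simulate(net, PopulationState.pure_monomer(net), 1e15)
        assert np.allclose(traj.densities[:, 0], 1.0)
        assert np.allclose(traj.densities[:, 1], 0.0)

    def test_photolysis_only_is_exponential_decay(self):
        kp = 1e-15
        net = NetworkSpec(2, (), photolysis_rate=kp, n0_monomer=1.0)
        traj = simulate(net, PopulationState.pure_monomer(net), 3.0 / kp)
        expected = np.exp(-kp * traj.times_s)
        assert np.allclose(traj.densities[:, 0], expected, rtol=1e-6)

    def test_dimer_growth_is_monotone_from_pure_monomer(self):
        net = two_species_network()
        traj = run_to_steady_state(net)
        n2 = traj.densities[:, 1]
        assert np.all(np.diff(n2) >= -1e-9 * max(n2.max(), 1e-300))

    def test_densities_stay_non_negative(self):
        net = two_species_network(kp=1e-15)
        traj = simulate(net, PopulationState.pure_monomer(net), 1e16)
        assert (traj.densities >= 0).all()

    def test_t_end_zero_echoes_initial_state(self):
        net = two_species_network()
        initial = PopulationState.pure_monomer(net)
        traj = simulate(net, initial, 0.0)
        assert traj.state(0) == initial

    def test_stalled_chain_grows_nothing_past_the_complex(self, library, dark_cloud_no_uv, params):
        net = build_network(library, dark_cloud_no_uv, params, max_length=3, pair=("Gly", "Gly"))
        traj = run_to_steady_state(net)
        assert traj.state().density(3) == 0.0

    def test_tetramer_channel_populates_4mers(self, library, dark_cloud_no_uv, params):
        """With the dimer+dimer gate open, 4-mers dominate at steady state."""
        net = build_network(library, dark_cloud_no_uv, params, max_length=4, pair=("Gly", "Gly"))
        eq = steady_state(net)
        final = run_to_steady_state(net).state()
        assert final.density(4) > 0.1
        assert final.density(4) == pytest.approx(eq.density(4), rel=1e-2)

    def test_trajectory_frame_has_unit_labelled_columns(self):
        net = two_species_network()
        frame = simulate(net, PopulationState.pure_monomer(net), 1e10).to_frame()
        assert list(frame.columns) == ["time_s", "n1_cm3", "n2_cm3"]
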