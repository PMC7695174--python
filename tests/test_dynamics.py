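import numpy as np
import pytest

from capsidyn.dynamics import (LangevinParams, RestraintSpec, SimulationBlowUpError,
                               SimulationState, generate_disordered_tails,
                               initialize_velocities, run_langevin)
from capsidyn.structures import ChainAnnotation, MolecularStructure, radius_of_gyration
from capsidyn.topology import build_topology


def _free_particle_topology():
    s = MolecularStructure(
        elements=np.array(["C"]), atom_names=np.array(["CA"]),
        residue_indices=np.array([1]), residue_names=np.array(["GLY"]),
        chain_ids=np.array(["A"]), positions=np.zeros((1, 3)),
        chains=[ChainAnnotation("A", "A", (1, 1))],
        bonds=np.empty((0, 2), dtype=np.int64))
    return build_topology(s, bonds=s.bonds)


class TestInitializeVelocities:
    def test_zero_temperature_gives_zero_velocities(self):
        v = initialize_velocities(100, 0.0, seed=1)
        assert np.all(v == 0.0)

    def test_equipartition_at_production_temperature(self):
        # 10^4 unit-mass atoms: mean kinetic energy per degree of freedom
        # must equal T/2 within 2%
        temperature = 0.582
        v = initialize_velocities(10_000, temperature, seed=4)
        ke_per_dof = 0.5 * np.mean(v ** 2)
        assert ke_per_dof == pytest.approx(temperature / 2, rel=0.02)

    def test_deterministic_given_seed(self):
        a = initialize_velocities(50, 0.582, seed=9)
        b = initialize_velocities(50, 0.582, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_negative_temperature_rejected(self):
        with pytest.raises(ValueError):
            initialize_velocities(5, -0.1, seed=0)


class TestIntegrator:
    def test_nve_limit_conserves_energy_on_dimer(self, dimer):
        top = build_topology(dimer, bonds=dimer.bonds)
        state = SimulationState(dimer.positions.copy(),
                                initialize_velocities(2, 0.5, seed=1))
        traj = run_langevin(top, state, LangevinParams(
            reduced_temperature=0.0, timestep=0.0005, friction=0.0,
            n_steps=10_000, seed=1, save_interval=100))
        total = (np.array(traj.metadata["potential_energy"])
                 + np.array(traj.metadata["kinetic_energy"]))
        drift = (total.max() - total.min()) / abs(total.mean())
        assert drift < 1e-4

    def test_zero_steps_returns_initial_frame_only(self, dimer):
        top = build_topology(dimer, bonds=dimer.bonds)
        state = SimulationState(dimer.positions.copy(), np.zeros((2, 3)))
        traj = run_langevin(top, state, LangevinParams(n_steps=0, seed=0))
        assert traj.n_frames == 1
        np.testing.assert_array_equal(traj.positions[0], dimer.positions)

    def test_bitwise_reproducibility(self, dimer):
        top = build_topology(dimer, bonds=dimer.bonds)
        params = LangevinParams(n_steps=2000, seed=42, save_interval=100)
        runs = []
        for _ in range(2):
            state = SimulationState(dimer.positions.copy(),
                                    initialize_velocities(2, 0.582, seed=42))
            runs.append(run_langevin(top, state, params))
        np.testing.assert_array_equal(runs[0].positions, runs[1].positions)
        np.testing.assert_array_equal(runs[0].velocities, runs[1].velocities)

    def test_harmonic_well_positional_variance(self):
        # single restrained particle: Var(x) = T / k per coordinate
        top = _free_particle_topology()
        k = 5.0
        temperature = 0.582
        restraint = RestraintSpec(np.array([0]), np.zeros((1, 3)), k)
        state = SimulationState(np.zeros((1, 3)), np.zeros((1, 3)))
        traj = run_langevin(top, state, LangevinParams(
            reduced_temperature=temperature, timestep=0.002, friction=1.0,
            n_steps=400_000, seed=2, save_interval=20), restraints=restraint)
        var = np.var(traj.positions[1000:, 0, :])
        assert var == pytest.approx(temperature / k, rel=0.05)

    def test_contact_well_samples_boltzmann_distribution(self):
        # detailed-balance smoke test: a mobile bead in a single native
        # contact well around a pinned anchor; the sampled radial
        # distribution must match p(r) ~ r^2 exp(-U(r)/T)
        s = MolecularStructure(
            elements=np.array(["C", "C"]), atom_names=np.array(["CA", "CA"]),
            residue_indices=np.array([1, 1]),
            residue_names=np.array(["GLY", "GLY"]),
            chain_ids=np.array(["A", "B"]),
            positions=np.array([[0.0, 0, 0], [0.45, 0, 0]]),
            chains=[ChainAnnotation("A", "A", (1, 1)),
                    ChainAnnotation("B", "B", (1, 1))],
            bonds=np.empty((0, 2), dtype=np.int64))
        temperature = 0.30
        top = build_topology(s, scale_factor=1.0)
        sigma = float(top.contacts.sigma[0])
        # both beads softly confined to the origin so rare escapes from
        # the 1-eps well cannot wander off; the confinement term enters
        # the theoretical density below
        k_confine = 5.0
        anchor = RestraintSpec(np.array([0, 1]), np.zeros((2, 3)), k_confine)
        state = SimulationState(s.positions.copy(),
                                initialize_velocities(2, temperature, seed=3))
        traj = run_langevin(top, state, LangevinParams(
            reduced_temperature=temperature, n_steps=600_000, seed=3,
            save_interval=50), restraints=anchor)
        # the anchor is also confined; use the pair separation, for which
        # the confinement acts with the reduced spring constant k/2
        r = np.linalg.norm(traj.positions[200:, 1] - traj.positions[200:, 0],
                           axis=1)
        edges = np.linspace(0.40, 0.56, 5)
        inside = (r >= edges[0]) & (r < edges[-1])
        obs, _ = np.histogram(r[inside], bins=edges)
        assert obs.sum() > 2000, "bead did not stay in the well"
        obs = obs / obs.sum()
        grid = np.linspace(edges[0], edges[-1], 400)
        u = ((sigma / grid) ** 12 - 2 * (sigma / grid) ** 6
             + 0.5 * (k_confine / 2) * grid ** 2)
        dens = grid ** 2 * np.exp(-u / temperature)
        theory = np.array([
            np.trapezoid(dens[(grid >= lo) & (grid < hi)],
                         grid[(grid >= lo) & (grid < hi)])
            for lo, hi in zip(edges[:-1], edges[1:])])
        theory = theory / theory.sum()
        np.testing.assert_allclose(obs, theory, atol=0.05)

    def test_blow_up_reports_step_number(self):
        # topology built at a sane contact distance, but started from a
        # configuration with the pair crushed to 1e-3 nm: the repulsive
        # wall force is astronomically large and the integrator diverges
        s = MolecularStructure(
            elements=np.array(["C", "C"]), atom_names=np.array(["CA", "CA"]),
            residue_indices=np.array([1, 1]),
            residue_names=np.array(["GLY", "GLY"]),
            chain_ids=np.array(["A", "B"]),
            positions=np.array([[0.0, 0, 0], [0.4, 0, 0]]),
            chains=[ChainAnnotation("A", "A", (1, 1)),
                    ChainAnnotation("B", "B", (1, 1))],
            bonds=np.empty((0, 2), dtype=np.int64))
        top = build_topology(s)
        crushed = np.array([[0.0, 0, 0], [1e-3, 0, 0]])
        state = SimulationState(crushed, np.zeros((2, 3)))
        with pytest.raises(SimulationBlowUpError) as err:
            run_langevin(top, state, LangevinParams(n_steps=2000, seed=0,
                                                    save_interval=10))
        assert err.value.step > 0


class TestDisorderedTails:
    def test_sample_count_and_restraint_bound(self, small_pair, small_topology):
        # restrain the body at the (strain-free) expanded reference so
        # the harmonic-restraint fluctuation bound applies cleanly; the
        # 5 sigma margin covers the maximum over ~10^4 correlated
        # Gaussian samples (3 sigma applies per coordinate, not to the
        # extreme of the whole ensemble)
        restraint_k = 500.0
        temperature = 1.0
        ref = small_pair.expanded_reference
        samples, manifest = generate_disordered_tails(
            ref, small_topology, n_samples=4,
            high_temperature=temperature, restraint_k=restraint_k, seed=5,
            equilibration_steps=1500, stride_steps=1500)
        assert len(samples) == 4
        body = np.ones(ref.n_atoms, dtype=bool)
        for ann in small_pair.annotations:
            body[ref.tail_atom_indices(ann.chain_id)] = False
        bound = 5 * np.sqrt(temperature / restraint_k)
        for conf in samples:
            disp = np.linalg.norm(conf.positions[body]
                                  - ref.positions[body], axis=1)
            assert np.max(disp) < bound

    def test_samples_are_decorrelated(self, small_pair, small_topology):
        samples, _ = generate_disordered_tails(
            small_pair.compact, small_topology, n_samples=3,
            restraint_k=500.0, seed=6,
            equilibration_steps=2000, stride_steps=2000)
        ann = small_pair.annotations[0]
        idx = small_pair.compact.tail_atom_indices(ann.chain_id)
        # thermal fluctuation scale of a free tail bead ~ sqrt(T / k_bond)
        # is well under 0.1 nm; decorrelated samples differ by much more
        rmsds = []
        for a in range(len(samples)):
            for b in range(a + 1, len(samples)):
                diff = samples[a].positions[idx] - samples[b].positions[idx]
                rmsds.append(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))
        assert min(rmsds) > 0.2

    def test_short_stride_warns(self, small_pair, small_topology):
        with pytest.warns(UserWarning, match="autocorrelation"):
            generate_disordered_tails(
                small_pair.compact, small_topology, n_samples=2,
                restraint_k=500.0, seed=7,
                equilibration_steps=200, stride_steps=40)
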