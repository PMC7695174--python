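"""Dihedral classification, parameter table and topology/energy tests."""

import numpy as np
import pytest

from capsidyn.dihedrals import classify_dihedrals, dihedral_angle
from capsidyn.kernels import evaluate_forces
from capsidyn.params import (ParameterLookupError, ParameterTable,
                             UnknownResidueError, is_sp2)
from capsidyn.structures import ChainAnnotation, MolecularStructure
from capsidyn.topology import build_topology, potential_energy


class TestDihedralClassification:
    def test_dipeptide_matches_hand_built_hybridization_table(self, dipeptide):
        # independent oracle: a dihedral is rigid iff both central-bond
        # atoms are flagged sp2/planar in this hand-built table for the
        # alanine fixture (backbone amide atoms only)
        sp2_atoms = {"N", "C", "O"}
        terms = classify_dihedrals(dipeptide)
        assert terms, "no dihedrals enumerated"
        for term in terms:
            _, j, k, _ = term.atoms
            expected = (str(dipeptide.atom_names[j]) in sp2_atoms
                        and str(dipeptide.atom_names[k]) in sp2_atoms)
            assert (term.kind == "rigid") == expected, term

    def test_omega_rigid_phi_psi_flexible(self, dipeptide):
        kinds = {}
        for term in classify_dihedrals(dipeptide):
            _, j, k, _ = term.atoms
            key = tuple(sorted([str(dipeptide.atom_names[j]),
                                str(dipeptide.atom_names[k])]))
            kinds[key] = term.kind
        assert kinds[("C", "N")] == "rigid"        # omega (peptide bond)
        assert kinds[("CA", "N")] == "flexible"    # phi
        assert kinds[("C", "CA")] == "flexible"    # psi

    def test_native_angle_matches_geometry(self, dipeptide):
        for term in classify_dihedrals(dipeptide):
            i, j, k, l = term.atoms
            phi = dihedral_angle(*dipeptide.positions[[i, j, k, l]])
            assert term.native_angle == pytest.approx(phi)

    def test_unknown_residue_raises(self, dipeptide):
        bad = dipeptide.select(np.ones(dipeptide.n_atoms, dtype=bool))
        bad.residue_names = np.full(bad.n_atoms, "XYZ")
        with pytest.raises(UnknownResidueError, match="XYZ"):
            classify_dihedrals(bad)

    def test_sp2_lookup(self):
        assert is_sp2("ALA", "C")
        assert is_sp2("PHE", "CZ")
        assert not is_sp2("ALA", "CB")
        assert not is_sp2("LYS", "NZ")


class TestParameterTable:
    def test_backbone_bond_lengths_cover_standard_residues(self):
        table = ParameterTable()
        for res in ("ALA", "GLY", "TRP", "PRO", "HIS"):
            assert table.bond_length(res, ("N", "CA")) == pytest.approx(0.1449)
            assert table.bond_length(res, ("CA", "C")) == pytest.approx(0.1522)
            assert table.bond_length(res, ("C", "O")) == pytest.approx(0.1229)

    def test_backbone_angle(self):
        table = ParameterTable()
        assert table.angle("ALA", ("N", "CA", "C")) == pytest.approx(
            np.radians(110.1))

    def test_lookup_failure_is_explicit(self):
        table = ParameterTable()
        with pytest.raises(ParameterLookupError):
            table.bond_length("ALA", ("N", "O"))
        with pytest.raises(UnknownResidueError):
            table.bond_length("FOO", ("N", "CA"))

    def test_extra_entries_override(self):
        table = ParameterTable(extra_bonds={("ALA", ("N", "CA")): 0.2})
        assert table.bond_length("ALA", ("N", "CA")) == 0.2


def _contact_dimer(separation):
    """Two free chains of one atom each, one contact between them."""
    return MolecularStructure(
        elements=np.array(["C", "C"]), atom_names=np.array(["CA", "CA"]),
        residue_indices=np.array([1, 1]), residue_names=np.array(["GLY", "GLY"]),
        chain_ids=np.array(["A", "B"]),
        positions=np.array([[0.0, 0, 0], [separation, 0, 0]]),
        chains=[ChainAnnotation("A", "A", (1, 1)),
                ChainAnnotation("B", "B", (1, 1))],
        bonds=np.empty((0, 2), dtype=np.int64),
    )


class TestTopology:
    def test_dipeptide_bond_count_matches_hand_enumeration(self, dipeptide):
        # heavy-atom covalent bonds of Ala-Ala: per residue N-CA, CA-C,
        # C-O, CA-CB (4 each) plus the peptide C-N link = 9
        top = build_topology(dipeptide)
        assert len(top.bonds) == 9

    def test_dipeptide_equilibria_come_from_parameter_table(self, dipeptide):
        top = build_topology(dipeptide)
        bond_names = {tuple(sorted([str(dipeptide.atom_names[a]),
                                    str(dipeptide.atom_names[b])])): r0
                      for (a, b), r0 in zip(top.bonds, top.bond_r0)}
        assert bond_names[("CA", "N")] == pytest.approx(0.1449)
        assert bond_names[("C", "N")] == pytest.approx(0.1335)

    def test_contact_at_scaled_minimum_contributes_minus_epsilon(self):
        s = _contact_dimer(0.5)
        top = build_topology(s, scale_factor=0.95)
        assert len(top.contacts) == 1
        pos = s.positions.copy()
        pos[1, 0] = top.contacts.sigma[0]   # compress to the scaled minimum
        eb = potential_energy(top, pos)
        assert eb.contact == pytest.approx(-top.epsilon)
        # and the configuration is a stationary point of the contact term
        f, _ = evaluate_forces(top, pos)
        assert np.max(np.abs(f)) < 1e-6

    def test_energy_breakdown_sums_to_total(self, small_pair, small_topology):
        rng = np.random.default_rng(0)
        pos = small_pair.expanded_reference.positions + rng.normal(0, 0.01, (
            small_topology.n_atoms, 3))
        eb = potential_energy(small_topology, pos)
        parts = eb.bond + eb.angle + eb.dihedral + eb.contact + eb.excluded_volume
        assert eb.total == pytest.approx(parts, rel=1e-12)

    def test_displaced_bond_energy_closed_form(self, dimer):
        top = build_topology(dimer, bonds=dimer.bonds)
        delta = 0.05
        pos = dimer.positions.copy()
        pos[1, 0] += delta
        eb = potential_energy(top, pos)
        assert eb.bond == pytest.approx(0.5 * top.bond_k[0] * delta ** 2)

    def test_kernel_energy_matches_reference_path(self, small_pair, small_topology):
        rng = np.random.default_rng(1)
        for _ in range(3):
            pos = (small_pair.expanded_reference.positions
                   + rng.normal(0, 0.02, (small_topology.n_atoms, 3)))
            eb = potential_energy(small_topology, pos)
            _, energies = evaluate_forces(small_topology, pos)
            assert sum(energies[:5]) == pytest.approx(eb.total, abs=1e-10)

    def test_forces_match_finite_differences(self, dipeptide):
        top = build_topology(dipeptide)
        rng = np.random.default_rng(2)
        pos = dipeptide.positions + rng.normal(0, 0.005, dipeptide.positions.shape)
        f, _ = evaluate_forces(top, pos)
        h = 1e-6
        for atom in range(0, top.n_atoms, 3):
            for c in range(3):
                dp = pos.copy()
                dm = pos.copy()
                dp[atom, c] += h
                dm[atom, c] -= h
                num = -(potential_energy(top, dp).total
                        - potential_energy(top, dm).total) / (2 * h)
                assert f[atom, c] == pytest.approx(num, abs=5e-4)

    def test_gaussian_contact_form(self):
        s = _contact_dimer(0.5)
        top = build_topology(s, contact_form="gaussian")
        pos = s.positions.copy()
        pos[1, 0] = top.contacts.sigma[0]
        eb = potential_energy(top, pos)
        assert eb.contact == pytest.approx(-1.0)

    def test_json_round_trip(self, tmp_path, dipeptide):
        from capsidyn.topology import ForceFieldTopology

        top = build_topology(dipeptide)
        p = tmp_path / "top.json"
        top.to_json(p)
        back = ForceFieldTopology.from_json(p)
        np.testing.assert_array_equal(back.bonds, top.bonds)
        np.testing.assert_allclose(back.dihedral_phi0, top.dihedral_phi0)
        assert back.exclusions == top.exclusions
        pos = dipeptide.positions
        assert potential_energy(back, pos).total == pytest.approx(
            potential_energy(top, pos).total)

    def test_gromacs_export_writes_sections(self, tmp_path, dipeptide):
        top = build_topology(dipeptide)
        p = tmp_path / "top.top"
        top.write_gromacs_top(p)
        text = p.read_text()
        for section in ("[ atoms ]", "[ bonds ]", "[ angles ]",
                        "[ dihedrals ]", "[ pairs ]", "[ exclusions ]"):
            assert section in text

    def test_mismatched_positions_shape_rejected(self, dipeptide):
        top = build_topology(dipeptide)
        with pytest.raises(ValueError, match="atom"):
            potential_energy(top, np.zeros((3, 3)))

    def test_missing_parameter_with_fallback_disabled(self, small_pair):
        with pytest.raises(ParameterLookupError):
            build_topology(small_pair.expanded_reference,
                           bonds=small_pair.bonds,
                           allow_reference_fallback=False)
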