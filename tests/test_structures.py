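import numpy as np
import pytest

from capsidyn.structures import (ChainAnnotation, EmptyStructureError,
                                 InvalidTransformError, MolecularStructure,
                                 expand_assembly, radius_of_gyration, rmsd)


def _simple_structure(positions, chain_ids=None):
    n = len(positions)
    chain_ids = np.full(n, "A") if chain_ids is None else np.asarray(chain_ids)
    return MolecularStructure(
        elements=np.full(n, "C"),
        atom_names=np.full(n, "CA"),
        residue_indices=np.arange(1, n + 1),
        residue_names=np.full(n, "GLY"),
        chain_ids=chain_ids,
        positions=np.asarray(positions, dtype=float),
        chains=[ChainAnnotation(str(c), "A", (1, 1))
                for c in dict.fromkeys(chain_ids.tolist())],
    )


class TestRadiusOfGyration:
    def test_single_atom_is_zero(self):
        assert radius_of_gyration(np.zeros((1, 3))) == 0.0

    def test_two_atoms_two_nm_apart(self):
        rg = radius_of_gyration(np.array([[0.0, 0, 0], [2.0, 0, 0]]))
        assert rg == pytest.approx(1.0)

    def test_cube_corners(self):
        # 8 equal-weight atoms on the corners of a cube of edge 2 nm:
        # every atom is sqrt(3) from the centre
        corners = np.array([[x, y, z] for x in (0, 2) for y in (0, 2)
                            for z in (0, 2)], dtype=float)
        assert radius_of_gyration(corners) == pytest.approx(np.sqrt(3.0))

    def test_empty_input_raises(self):
        with pytest.raises(EmptyStructureError):
            radius_of_gyration(np.empty((0, 3)))

    def test_rigid_motion_invariance(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(5)
        pos = rng.normal(0, 1, (40, 3))
        ref = radius_of_gyration(pos)
        for _ in range(10):
            rot = Rotation.random(random_state=rng).as_matrix()
            shift = rng.normal(0, 10, 3)
            assert radius_of_gyration(pos @ rot.T + shift) == pytest.approx(
                ref, abs=1e-9)

    def test_mass_weighting_changes_result(self):
        pos = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        unweighted = radius_of_gyration(pos)
        weighted = radius_of_gyration(pos, mass_weighted=True,
                                      masses=np.array([1.0, 3.0]))
        assert weighted != pytest.approx(unweighted)


class TestExpandAssembly:
    def test_identity_transform_preserves_coordinates(self):
        s = _simple_structure(np.random.default_rng(0).normal(0, 1, (10, 3)))
        out = expand_assembly(s, [(np.eye(3), np.zeros(3))])
        np.testing.assert_allclose(out.positions, s.positions)
        assert out.n_chains == 1

    def test_seven_chain_subunit_times_sixty_gives_420_chains(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(1)
        n_per = 3
        sub = MolecularStructure(
            elements=np.full(7 * n_per, "C"),
            atom_names=np.full(7 * n_per, "CA"),
            residue_indices=np.tile(np.arange(1, n_per + 1), 7),
            residue_names=np.full(7 * n_per, "GLY"),
            chain_ids=np.repeat(list("ABCDEFG"), n_per),
            positions=rng.normal(0, 1, (7 * n_per, 3)),
            chains=[ChainAnnotation(c, c, (1, 1)) for c in "ABCDEFG"],
        )
        transforms = [(Rotation.random(random_state=rng).as_matrix(),
                       rng.normal(0, 5, 3)) for _ in range(60)]
        out = expand_assembly(sub, transforms)
        assert out.n_chains == 420
        assert out.n_atoms == 60 * sub.n_atoms
        # position labels inherited by every copy
        assert sum(1 for a in out.chains if a.position_label == "G") == 60

    def test_inverse_consistency(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(2)
        s = _simple_structure(rng.normal(0, 1, (10, 3)))
        transforms = [(Rotation.random(random_state=rng).as_matrix(),
                       rng.normal(0, 3, 3)) for _ in range(2)]
        out = expand_assembly(s, transforms)
        assert out.n_atoms == 20
        for t_idx, (rot, trans) in enumerate(transforms):
            block = out.positions[t_idx * 10:(t_idx + 1) * 10]
            back = (block - trans) @ rot
            assert rmsd(back, s.positions) == pytest.approx(0.0, abs=1e-9)

    def test_intra_chain_distances_invariant(self):
        from scipy.spatial.distance import pdist
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(3)
        s = _simple_structure(rng.normal(0, 1, (15, 3)))
        rot = Rotation.random(random_state=rng).as_matrix()
        out = expand_assembly(s, [(rot, rng.normal(0, 2, 3))])
        np.testing.assert_allclose(pdist(out.positions), pdist(s.positions),
                                   atol=1e-6)

    def test_non_orthonormal_rotation_rejected(self):
        s = _simple_structure(np.zeros((2, 3)) + [[0, 0, 0], [1, 0, 0]])
        bad = np.eye(3)
        bad[0, 0] = 1.1
        with pytest.raises(InvalidTransformError):
            expand_assembly(s, [(bad, np.zeros(3))])

    def test_empty_structure_rejected(self):
        s = _simple_structure(np.zeros((1, 3)))
        sel = s.select(np.zeros(1, dtype=bool))
        with pytest.raises(EmptyStructureError):
            expand_assembly(sel, [(np.eye(3), np.zeros(3))])


class TestSelections:
    def test_tail_atom_indices_follow_annotation(self):
        s = _simple_structure(np.zeros((6, 3)))
        s.chains = [ChainAnnotation("A", "A", (2, 4))]
        np.testing.assert_array_equal(s.tail_atom_indices("A"), [1, 2, 3])

    def test_duplicate_chain_annotations_rejected(self):
        with pytest.raises(ValueError, match="duplicate chain"):
            MolecularStructure(
                elements=np.array(["C"]), atom_names=np.array(["CA"]),
                residue_indices=np.array([1]), residue_names=np.array(["GLY"]),
                chain_ids=np.array(["A"]), positions=np.zeros((1, 3)),
                chains=[ChainAnnotation("A", "A", (1, 1)),
                        ChainAnnotation("A", "B", (1, 1))])
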