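import numpy as np
import pytest

from capsidyn.contacts import ShadowParams, scale_contact_minima, shadow_contact_map
from capsidyn.structures import ChainAnnotation, MolecularStructure

from conftest import brute_force_shadow_oracle


def _cloud(positions, residue_step=5):
    n = len(positions)
    return MolecularStructure(
        elements=np.full(n, "C"), atom_names=np.full(n, "CA"),
        residue_indices=np.arange(n) * residue_step + 1,
        residue_names=np.full(n, "GLY"), chain_ids=np.full(n, "A"),
        positions=np.asarray(positions, dtype=float),
        chains=[ChainAnnotation("A", "A", (1, 1))],
        bonds=np.empty((0, 2), dtype=np.int64),
    )


class TestShadowMap:
    def test_two_isolated_atoms_form_one_contact(self):
        s = _cloud([[0, 0, 0], [0.4, 0, 0]])
        cmap = shadow_contact_map(s, ShadowParams(contact_cutoff=0.6))
        assert len(cmap) == 1
        assert cmap.r_native[0] == pytest.approx(0.4)

    def test_collinear_middle_atom_occludes_outer_pair(self):
        s = _cloud([[0, 0, 0], [0.3, 0, 0], [0.6, 0, 0]])
        cmap = shadow_contact_map(
            s, ShadowParams(contact_cutoff=0.7, shadow_radius=0.1))
        pairs = cmap.pair_set()
        assert (0, 1) in pairs and (1, 2) in pairs
        assert (0, 2) not in pairs

    def test_zero_shadow_radius_equals_plain_cutoff_map(self):
        rng = np.random.default_rng(7)
        s = _cloud(rng.uniform(0, 1.5, (30, 3)))
        plain = shadow_contact_map(s, ShadowParams(shadow_radius=0.0))
        from scipy.spatial import cKDTree

        expected = {(int(i), int(j)) for i, j in
                    cKDTree(s.positions).query_pairs(0.6)}
        assert plain.pair_set() == expected

    def test_shadow_map_is_subset_of_cutoff_map(self):
        rng = np.random.default_rng(8)
        s = _cloud(rng.uniform(0, 1.5, (40, 3)))
        shadowed = shadow_contact_map(s, ShadowParams())
        plain = shadow_contact_map(s, ShadowParams(shadow_radius=0.0))
        assert shadowed.pair_set() <= plain.pair_set()

    @pytest.mark.parametrize("knob,values", [
        ("shadow_radius", [0.0, 0.05, 0.1, 0.15, 0.2]),
        ("contact_cutoff", [0.4, 0.5, 0.6, 0.7, 0.8]),
    ])
    def test_contact_count_monotonicity(self, knob, values):
        rng = np.random.default_rng(9)
        s = _cloud(rng.uniform(0, 1.5, (35, 3)))
        counts = [len(shadow_contact_map(s, ShadowParams(**{knob: v})))
                  for v in values]
        if knob == "shadow_radius":
            assert counts == sorted(counts, reverse=True)
        else:
            assert counts == sorted(counts)

    def test_matches_brute_force_oracle_on_random_clouds(self):
        params = ShadowParams()
        for seed in range(25):
            rng = np.random.default_rng(1000 + seed)
            n = int(rng.integers(10, 51))
            s = _cloud(rng.uniform(0, 1.5, (n, 3)))
            got = shadow_contact_map(s, params).pair_set()
            expected = brute_force_shadow_oracle(s, params)
            assert got == expected, f"mismatch for cloud seed {seed}"

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            ShadowParams(contact_cutoff=0.05, shadow_radius=0.1)
        with pytest.raises(ValueError):
            ShadowParams(contact_cutoff=-1)
        with pytest.raises(ValueError):
            ShadowParams(min_residue_separation=0)

    def test_sequence_local_pairs_excluded(self):
        s = _cloud([[0, 0, 0], [0.4, 0, 0]], residue_step=1)
        cmap = shadow_contact_map(s, ShadowParams(min_residue_separation=3))
        assert len(cmap) == 0

    def test_interchain_pairs_not_sequence_filtered(self):
        s = _cloud([[0, 0, 0], [0.4, 0, 0]], residue_step=1)
        s.chain_ids = np.array(["A", "B"])
        s.chains = [ChainAnnotation("A", "A", (1, 1)),
                    ChainAnnotation("B", "B", (1, 1))]
        cmap = shadow_contact_map(s, ShadowParams(min_residue_separation=3))
        assert len(cmap) == 1
        assert bool(cmap.intermolecular[0])


class TestScaleContactMinima:
    def _map(self):
        s = _cloud([[0, 0, 0], [0.5, 0, 0]])
        return shadow_contact_map(s, ShadowParams())

    def test_default_scaling(self):
        scaled = scale_contact_minima(self._map(), 0.95)
        assert scaled.sigma[0] == pytest.approx(0.475)
        assert scaled.r_native[0] == pytest.approx(0.5)

    def test_identity_scaling(self):
        scaled = scale_contact_minima(self._map(), 1.0)
        np.testing.assert_allclose(scaled.sigma, scaled.r_native)

    def test_composition_is_multiplicative(self):
        twice = scale_contact_minima(scale_contact_minima(self._map(), 0.95), 0.95)
        assert twice.sigma[0] == pytest.approx(0.9025 * 0.5)

    def test_non_positive_factor_rejected(self):
        with pytest.raises(ValueError):
            scale_contact_minima(self._map(), 0.0)
        with pytest.raises(ValueError):
            scale_contact_minima(self._map(), 1.5)
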