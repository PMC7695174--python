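import numpy as np
import pytest

from capsidyn.pipeline import TOY_ANGLE_K, TOY_BOND_K
from capsidyn.topology import build_topology
from capsidyn.toyshell import (ORDERED_CAVITY_WIDTHS, ToyShellSpec,
                               make_toy_shell, make_unit_fixtures,
                               throat_contact_filter)


@pytest.fixture(scope="session")
def fixtures():
    return make_unit_fixtures()


@pytest.fixture(scope="session")
def dimer(fixtures):
    return fixtures["harmonic_dimer"]


@pytest.fixture(scope="session")
def cloud(fixtures):
    return fixtures["random_cloud"]


@pytest.fixture(scope="session")
def dipeptide(fixtures):
    return fixtures["dipeptide"]


@pytest.fixture(scope="session")
def toy_pair():
    """Default-size toy shell with strictly ordered cavity widths."""
    spec = ToyShellSpec(cavity_half_widths=dict(ORDERED_CAVITY_WIDTHS))
    return make_toy_shell(spec, seed=11)


@pytest.fixture(scope="session")
def toy_topology(toy_pair):
    return build_topology(toy_pair.expanded_reference, bonds=toy_pair.bonds,
                          bond_k=TOY_BOND_K, angle_k=TOY_ANGLE_K,
                          contact_filter=throat_contact_filter(toy_pair))


@pytest.fixture(scope="session")
def small_pair():
    """Small 2-class shell for fast dynamics tests."""
    spec = ToyShellSpec(n_position_classes=2, chains_per_class=2,
                        residues_per_chain=60, tail_length=6,
                        compact_radius=1.23, expanded_radius=1.40,
                        cavity_half_widths={"A": 0.40, "B": 0.45})
    return make_toy_shell(spec, seed=3)


@pytest.fixture(scope="session")
def small_topology(small_pair):
    return build_topology(small_pair.expanded_reference, bonds=small_pair.bonds,
                          bond_k=TOY_BOND_K, angle_k=TOY_ANGLE_K,
                          contact_filter=throat_contact_filter(small_pair))


def brute_force_shadow_oracle(structure, params, bonds=None):
    """Independent O(pairs x atoms) occlusion oracle, written directly from
    the screening definition: pair (i, j) within the cutoff is a contact
    iff no third atom k with |r_k - r_i| < r_ij lies within its occluding
    radius of the segment i->j.  Bonded neighbours occlude with the
    shrunken radius; sequence-local and 1-2/1-3/1-4 pairs are excluded.
    """
    from capsidyn.connectivity import bonded_exclusions, infer_bonds, neighbor_table
    from capsidyn.contacts import BONDED_OCCLUDER_RADIUS

    pos = structure.positions
    n = len(pos)
    bonds = infer_bonds(structure) if bonds is None else bonds
    excl = bonded_exclusions(bonds, n, structure.residue_indices)
    nb = neighbor_table(bonds, n)
    result = set()
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in excl:
                continue
            same_chain = structure.chain_ids[i] == structure.chain_ids[j]
            sep = abs(int(structure.residue_indices[i])
                      - int(structure.residue_indices[j]))
            if same_chain and sep < params.min_residue_separation:
                continue
            rij = np.linalg.norm(pos[j] - pos[i])
            if rij > params.contact_cutoff:
                continue
            occluded = False
            for k in range(n):
                if k in (i, j):
                    continue
                if np.linalg.norm(pos[k] - pos[i]) >= rij:
                    continue
                radius = (BONDED_OCCLUDER_RADIUS
                          if (k in nb[i] or k in nb[j])
                          else params.shadow_radius)
                # distance from atom k to the segment i -> j
                seg = pos[j] - pos[i]
                t = np.dot(pos[k] - pos[i], seg) / np.dot(seg, seg)
                t = min(1.0, max(0.0, t))
                d = np.linalg.norm(pos[k] - (pos[i] + t * seg))
                if d < radius:
                    occluded = True
                    break
            if not occluded:
                result.add((i, j))
    return result
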