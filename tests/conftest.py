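"""Shared fixtures: toy systems, conformer pools and precomputed profiles.

Expensive artifacts (Debye profiles of pools) are session-scoped so the
whole suite pays for them once.
"""

import numpy as np
import pytest

import saxsbm as sb
from saxsbm.structure import ConformationSet

DIPEPTIDE_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       1.988  -0.773  -1.199  1.00  0.00           C
ATOM      6  N   GLY A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      7  CA  GLY A   2       3.989   2.830   0.000  1.00  0.00           C
ATOM      8  C   GLY A   2       5.504   2.706   0.000  1.00  0.00           C
ATOM      9  O   GLY A   2       6.104   1.631   0.000  1.00  0.00           O
END
"""


@pytest.fixture(scope="session")
def dipeptide_pdb(tmp_path_factory):
    """Hand-written two-residue, nine-heavy-atom PDB fragment."""
    p = tmp_path_factory.mktemp("fixtures") / "dipeptide.pdb"
    p.write_text(DIPEPTIDE_PDB)
    return p


TOY_SEED = 5
FAMILY_SEED = 7
#: compact / middle / extended members of the 40-frame hinge family used as
#: ground-truth states throughout the recovery tests
ANCHOR_IDX = (0, 20, 39)


@pytest.fixture(scope="session")
def qgrid():
    return sb.default_qgrid()


@pytest.fixture(scope="session")
def toy():
    """Default three-domain toy structure (3x60 atoms, 16-atom linkers)."""
    return sb.toy_multidomain(seed=TOY_SEED)


@pytest.fixture(scope="session")
def family(toy):
    """40-frame hinge family spanning compact to extended arrangements."""
    return sb.conformer_family(toy, 40, seed=FAMILY_SEED)


@pytest.fixture(scope="session")
def family_curves(toy, family, qgrid):
    """Vacuum Debye profiles of every family frame, shape (40, 100)."""
    return np.stack(
        [
            sb.debye_profile(toy.with_coords(f), qgrid).intensity
            for f in family.frames
        ]
    )


@pytest.fixture(scope="session")
def state_pool(toy, family):
    """Discrete-state candidate library: 3 anchor states x 100 within-state
    samples (domain-rotation jitter: RMSD-distinct, near-identical curves)."""
    clusters = [
        sb.domain_rotation_jitter(
            toy.with_coords(family.frames[a]), 100, max_angle=1.0, seed=20 + i
        ).frames
        for i, a in enumerate(ANCHOR_IDX)
    ]
    return ConformationSet(toy, np.concatenate(clusters))


@pytest.fixture(scope="session")
def state_pool_curves(state_pool, qgrid):
    return np.stack(
        [
            sb.debye_profile(state_pool[i], qgrid).intensity
            for i in range(len(state_pool))
        ]
    )


@pytest.fixture(scope="session")
def small_topology():
    """Single-domain 20-atom toy and its SBM topology (for force tests)."""
    s = sb.toy_multidomain(1, 20, 1, seed=3)
    return s, sb.build_topology(s)


@pytest.fixture(scope="session")
def dimer_topology():
    """Two bonded carbons: the minimal one-degree-of-freedom system."""
    from saxsbm.forcefield import ForcefieldParams, Topology

    dimer = sb.Structure(
        elements=np.array(["C", "C"]),
        residue_index=np.array([1, 2]),
        chain_ids=np.array(["A", "A"]),
        coords=np.array([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0]]),
        domain_labels=np.array(["D1", "D1"]),
    )
    topo = Topology(
        params=ForcefieldParams(),
        elements=dimer.elements,
        domain_labels=dimer.domain_labels,
        native_coords=dimer.coords.copy(),
        bonds=np.array([[0, 1]]),
        bond_r0=np.array([1.5]),
        angles=np.zeros((0, 3), int),
        angle_theta0=np.zeros(0),
        impropers=np.zeros((0, 4), int),
        improper_xi0=np.zeros(0),
        dihedrals=np.zeros((0, 4), int),
        dihedral_phi0=np.zeros(0),
        dihedral_rigid=np.zeros(0, bool),
        dihedral_eligible=np.zeros(0, bool),
        dihedral_weight=np.zeros(0),
        contacts=np.zeros((0, 2), int),
        contact_r0=np.zeros(0),
        contact_eps=np.zeros(0),
        exclusions=np.array([[0, 1]]),
    )
    return dimer, topo
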