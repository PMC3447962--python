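"""Shadow contact map, topology construction and energy-weight assignment."""

import networkx as nx
import numpy as np
import pytest

import saxsbm as sb
from saxsbm.forcefield import (
    ContactMap,
    ForcefieldParams,
    assign_energy_weights,
    build_topology,
    infer_bonds,
    shadow_contacts,
)


def _structure(coords, residue_index=None, labels=None, elements=None):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    return sb.Structure(
        elements=np.full(n, "C") if elements is None else np.asarray(elements),
        residue_index=np.arange(1, n + 1) if residue_index is None else np.asarray(residue_index),
        chain_ids=np.full(n, "A"),
        coords=coords,
        domain_labels=np.full(n, "D1") if labels is None else np.asarray(labels),
    )


def brute_force_shadow(s, params):
    """Literal O(N^3) application of the three contact rules."""
    n = s.n_atoms
    out = set()
    for i in range(n):
        for j in range(i + 1, n):
            rij = np.linalg.norm(s.coords[j] - s.coords[i])
            if rij >= params.contact_cutoff:
                continue
            if (
                s.chain_ids[i] == s.chain_ids[j]
                and abs(int(s.residue_index[i]) - int(s.residue_index[j])) < params.min_seq_sep
            ):
                continue
            screened = False
            for k in range(n):
                if k in (i, j):
                    continue
                if (
                    np.linalg.norm(s.coords[k] - s.coords[i]) > params.contact_cutoff
                    or np.linalg.norm(s.coords[k] - s.coords[j]) > params.contact_cutoff
                ):
                    continue
                ab = s.coords[j] - s.coords[i]
                t = np.dot(s.coords[k] - s.coords[i], ab) / np.dot(ab, ab)
                if not 0.0 < t < 1.0:
                    continue
                perp = np.linalg.norm(s.coords[k] - (s.coords[i] + t * ab))
                if perp < params.shadow_radius:
                    screened = True
                    break
            if not screened:
                out.add((i, j))
    return out


class TestShadowContacts:
    params = ForcefieldParams()

    def test_pair_below_cutoff_with_sequence_separation_is_contact(self):
        s = _structure([[0, 0, 0], [5.0, 0, 0]], residue_index=[1, 6])
        assert shadow_contacts(s, self.params).as_set() == {(0, 1)}

    def test_insufficient_sequence_separation_is_not_contact(self):
        s = _structure([[0, 0, 0], [5.0, 0, 0]], residue_index=[1, 4])
        assert shadow_contacts(s, self.params).as_set() == set()

    def test_collinear_blocker_screens_the_pair(self):
        s = _structure(
            [[0, 0, 0], [5.0, 0, 0], [2.5, 0, 0]], residue_index=[1, 10, 20]
        )
        contacts = shadow_contacts(s, self.params).as_set()
        assert (0, 1) not in contacts

    def test_distance_at_cutoff_is_excluded(self):
        s = _structure([[0, 0, 0], [6.0, 0, 0]], residue_index=[1, 10])
        assert shadow_contacts(s, self.params).as_set() == set()

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_oracle_on_random_structures(self, seed):
        rng = np.random.default_rng(seed)
        s = _structure(rng.uniform(0, 12, size=(30, 3)))
        assert shadow_contacts(s, self.params).as_set() == brute_force_shadow(
            s, self.params
        )

    def test_permutation_invariant_under_atom_reordering(self):
        # one chain per atom so the sequence rule is permutation-neutral and
        # only the geometry is exercised
        rng = np.random.default_rng(99)
        coords = rng.uniform(0, 12, size=(30, 3))
        chains = np.array([f"C{i}" for i in range(30)])

        def make(c, ch):
            return sb.Structure(
                elements=np.full(30, "C"),
                residue_index=np.ones(30, dtype=int),
                chain_ids=ch,
                coords=c,
                domain_labels=np.full(30, "D1"),
            )

        perm = rng.permutation(30)
        got = {
            tuple(sorted((int(perm[i]), int(perm[j]))))
            for i, j in shadow_contacts(make(coords[perm], chains[perm]), self.params).pairs
        }
        assert got == shadow_contacts(make(coords, chains), self.params).as_set()


class TestConnectivityAndTerms:
    def test_dipeptide_counts_match_graph_enumeration_oracle(self, dipeptide_pdb):
        s = sb.read_pdb(dipeptide_pdb)
        topo = build_topology(s)
        g = nx.Graph(map(tuple, topo.bonds))
        g.add_nodes_from(range(s.n_atoms))
        # independent enumeration from the covalent graph
        n_angles = sum(d * (d - 1) // 2 for _, d in g.degree)
        n_dihedrals = sum(
            (g.degree[u] - 1) * (g.degree[v] - 1) for u, v in g.edges
        )
        n_impropers = sum(1 for _, d in g.degree if d >= 3)
        assert len(topo.bonds) == g.number_of_edges() == 8
        assert len(topo.angles) == n_angles
        assert len(topo.dihedrals) == n_dihedrals
        assert len(topo.impropers) == n_impropers

    def test_peptide_omega_bond_is_rigid(self, dipeptide_pdb):
        s = sb.read_pdb(dipeptide_pdb)
        topo = build_topology(s)
        names = s.atom_names
        omega = [
            m
            for m, (_, j, k, _) in enumerate(topo.dihedrals)
            if {names[j], names[k]} == {"C", "N"}
        ]
        assert omega and all(topo.dihedral_rigid[m] for m in omega)

    def test_disulfide_detected_from_distance(self):
        s = _structure(
            [[0, 0, 0], [1.5, 0, 0], [1.5, 2.05, 0], [0.0, 2.05, 0.0]],
            elements=["C", "S", "S", "C"],
        )
        bonds = {tuple(b) for b in infer_bonds(s)}
        assert (1, 2) in bonds

    def test_isolated_atom_raises_naming_residue(self):
        s = _structure([[0, 0, 0], [1.5, 0, 0], [50.0, 0, 0]])
        with pytest.raises(ValueError, match="residue"):
            infer_bonds(s)


class TestDomainRemoval:
    def test_interdomain_and_linker_contacts_removed(self, toy):
        params = ForcefieldParams()
        cmap = shadow_contacts(toy, params)
        topo = build_topology(toy, params, contact_map=cmap)
        labels = toy.domain_labels
        expected = sum(
            1
            for i, j in cmap.pairs
            if labels[i] == labels[j] and labels[i] != "linker"
        )
        assert len(topo.contacts) == expected
        assert all(
            labels[i] == labels[j] and labels[i] != "linker"
            for i, j in topo.contacts
        )

    def test_single_domain_keeps_every_shadow_contact(self):
        s = sb.toy_multidomain(1, 40, 1, seed=2)
        cmap = shadow_contacts(s)
        topo = build_topology(s, contact_map=cmap)
        assert {tuple(c) for c in topo.contacts} == cmap.as_set()

    def test_two_domain_toy_subtraction_count(self):
        """Removing k inter-domain contacts keeps exactly N - k."""
        s = sb.toy_multidomain(2, 30, 6, seed=8)
        cmap = shadow_contacts(s)
        labels = s.domain_labels
        crossing = sum(
            1
            for i, j in cmap.pairs
            if labels[i] != labels[j] or labels[i] == "linker"
        )
        topo = build_topology(s, contact_map=cmap)
        assert len(topo.contacts) == len(cmap) - crossing


class TestEnergyWeights:
    def _fake_topology(self, n_atoms, n_contacts, n_weighted_dihedrals):
        from saxsbm.forcefield import Topology

        d = n_weighted_dihedrals
        return Topology(
            params=ForcefieldParams(),
            elements=np.full(n_atoms, "C"),
            domain_labels=np.full(n_atoms, "D1"),
            native_coords=np.zeros((n_atoms, 3)),
            bonds=np.zeros((0, 2), int),
            bond_r0=np.zeros(0),
            angles=np.zeros((0, 3), int),
            angle_theta0=np.zeros(0),
            impropers=np.zeros((0, 4), int),
            improper_xi0=np.zeros(0),
            dihedrals=np.zeros((d, 4), int),
            dihedral_phi0=np.zeros(d),
            dihedral_rigid=np.zeros(d, bool),
            dihedral_eligible=np.ones(d, bool),
            dihedral_weight=np.zeros(d),
            contacts=np.zeros((n_contacts, 2), int),
            contact_r0=np.ones(n_contacts),
            contact_eps=np.zeros(n_contacts),
            exclusions=np.zeros((0, 2), int),
        )

    def test_two_to_one_split_of_total_stabilizing_energy(self):
        topo = assign_energy_weights(self._fake_topology(100, 30, 40))
        assert topo.contact_eps.sum() == pytest.approx(66.6667, abs=1e-3)
        assert topo.dihedral_weight.sum() == pytest.approx(33.3333, abs=1e-3)
        assert np.all(topo.contact_eps == topo.contact_eps[0])

    def test_zero_contacts_puts_everything_on_dihedrals(self):
        topo = assign_energy_weights(self._fake_topology(100, 0, 40))
        assert topo.dihedral_weight.sum() == pytest.approx(100.0)

    def test_weights_scale_linearly_with_atom_count(self):
        t1 = assign_energy_weights(self._fake_topology(100, 30, 40))
        t2 = assign_energy_weights(self._fake_topology(200, 30, 40))
        assert np.allclose(t2.contact_eps, 2 * t1.contact_eps)
        assert np.allclose(t2.dihedral_weight, 2 * t1.dihedral_weight)


class TestTopologySerialization:
    def test_json_roundtrip(self, tmp_path, small_topology):
        _, topo = small_topology
        path = tmp_path / "topo.json"
        topo.to_json(path)
        from saxsbm.forcefield import Topology

        back = Topology.from_json(path)
        assert np.array_equal(back.bonds, topo.bonds)
        assert np.allclose(back.bond_r0, topo.bond_r0)
        assert np.array_equal(back.contacts, topo.contacts)
        assert np.allclose(back.contact_eps, topo.contact_eps)
        assert np.array_equal(back.exclusions, topo.exclusions)

    def test_user_contact_list_override(self, toy):
        override = ContactMap(np.array([[0, 30]]), np.array([5.0]))
        topo = build_topology(toy, contact_map=override)
        assert {tuple(c) for c in topo.contacts} <= {(0, 30)}
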