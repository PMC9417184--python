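"""Contacts, hydrogen bonds, salt bridges, interface residues, and sequence
comparison — checked against brute-force all-pairs oracles on small models."""

import itertools

import numpy as np
import pytest

from oligoshift.interface import (atomic_contacts, differing_interface_sites,
                                  hydrogen_bonds, interface_residues,
                                  percent_identity, salt_bridges)
from oligoshift.structure import AssemblyModel, Atom, Chain, Residue

from conftest import single_atom_chain, two_group_model

# vocabulary for random oracle fixtures, with an independent role table
_VOCAB = [("GLY", "N", "N"), ("GLY", "CA", "C"), ("GLY", "C", "C"),
          ("GLY", "O", "O"), ("ARG", "NH1", "N"), ("ASP", "OD1", "O"),
          ("LYS", "NZ", "N"), ("GLU", "OE1", "O"), ("ALA", "CB", "C")]
_ORACLE_DONORS = {("GLY", "N"), ("ARG", "NH1"), ("LYS", "NZ")}
_ORACLE_ACCEPTORS = {("GLY", "O"), ("ASP", "OD1"), ("GLU", "OE1")}
_ORACLE_BASIC = {("ARG", "NH1"), ("LYS", "NZ")}
_ORACLE_ACIDIC = {("ASP", "OD1"), ("GLU", "OE1")}


def random_two_group_model(rng, n_atoms, box=20.0):
    chains = {"A": [], "B": []}
    for i in range(n_atoms):
        cid = "A" if i < n_atoms // 2 else "B"
        res_name, atom_name, element = _VOCAB[rng.integers(len(_VOCAB))]
        coords = rng.uniform(0, box, 3)
        chains[cid].append(Residue(len(chains[cid]) + 1, res_name, "",
                                   [Atom(atom_name, element, coords)]))
    return AssemblyModel([Chain("A", chains["A"]), Chain("B", chains["B"])],
                         {"A": "a", "B": "b"})


def brute_force_pairs(model, cutoff, role_filter=None):
    """Independent O(n^2) enumeration of cross-group pairs."""
    atoms = {"a": [], "b": []}
    for chain in model.chains:
        group = model.partition[chain.chain_id]
        for res in chain.residues:
            for atom in res.heavy_atoms():
                atoms[group].append((chain.chain_id, res.seq_id, res.name,
                                     atom.name, atom.coords))
    found = set()
    for (ca, sa, ra, na, xa), (cb, sb, rb, nb, xb) in itertools.product(
            atoms["a"], atoms["b"]):
        if np.linalg.norm(xa - xb) <= cutoff:
            if role_filter is None or role_filter((ra, na), (rb, nb)):
                found.add(((ca, sa, na), (cb, sb, nb)))
    return found


class TestAtomicContacts:
    def test_single_pair_within_cutoff(self):
        model = two_group_model(
            [single_atom_chain("A", "GLY", "CA", "C", [0, 0, 0])],
            [single_atom_chain("B", "GLY", "CA", "C", [4.0, 0, 0])])
        contacts = atomic_contacts(model, "a", "b", 5.5)
        assert len(contacts) == 1
        assert contacts[0].distance == pytest.approx(4.0)

    def test_boundary_excludes(self):
        model = two_group_model(
            [single_atom_chain("A", "GLY", "CA", "C", [0, 0, 0])],
            [single_atom_chain("B", "GLY", "CA", "C", [4.0, 0, 0])])
        assert atomic_contacts(model, "a", "b", 3.9) == []

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        model = random_two_group_model(rng, 200)
        got = {(c.atom_a, c.atom_b) for c in atomic_contacts(model, "a", "b", 5.5)}
        assert got == brute_force_pairs(model, 5.5)

    def test_symmetric_in_group_order(self):
        rng = np.random.default_rng(5)
        model = random_two_group_model(rng, 60)
        ab = {(c.atom_a, c.atom_b) for c in atomic_contacts(model, "a", "b", 6.0)}
        ba = {(c.atom_b, c.atom_a) for c in atomic_contacts(model, "b", "a", 6.0)}
        assert ab == ba

    def test_cutoff_monotonicity(self):
        rng = np.random.default_rng(9)
        model = random_two_group_model(rng, 120)
        sets = []
        for cutoff in (3.0, 4.5, 5.5, 7.0):
            sets.append({(c.atom_a, c.atom_b)
                         for c in atomic_contacts(model, "a", "b", cutoff)})
        for smaller, larger in zip(sets, sets[1:]):
            assert smaller <= larger

    def test_empty_group_errors(self):
        model = two_group_model(
            [single_atom_chain("A", "GLY", "CA", "C", [0, 0, 0])],
            [single_atom_chain("B", "GLY", "CA", "C", [4, 0, 0])])
        with pytest.raises(ValueError):
            atomic_contacts(model, "a", "nope", 5.5)


class TestHydrogenBonds:
    def test_backbone_o_to_arginine_nh1(self):
        model = two_group_model(
            [single_atom_chain("A", "GLY", "O", "O", [0, 0, 0])],
            [single_atom_chain("B", "ARG", "NH1", "N", [2.9, 0, 0])])
        assert len(hydrogen_bonds(model, "a", "b")) == 1

    def test_carbon_pair_is_not_a_bond(self):
        model = two_group_model(
            [single_atom_chain("A", "GLY", "CA", "C", [0, 0, 0])],
            [single_atom_chain("B", "GLY", "CA", "C", [3.0, 0, 0])])
        assert hydrogen_bonds(model, "a", "b") == []

    def test_guanidinium_carboxylate_is_bond_and_bridge(self):
        model = two_group_model(
            [single_atom_chain("A", "ARG", "NH1", "N", [0, 0, 0])],
            [single_atom_chain("B", "ASP", "OD1", "O", [3.2, 0, 0])])
        assert len(hydrogen_bonds(model, "a", "b")) == 1
        assert len(salt_bridges(model, "a", "b")) == 1

    def test_subset_of_contacts_at_equal_cutoff(self):
        rng = np.random.default_rng(11)
        model = random_two_group_model(rng, 150)
        hb = {(c.atom_a, c.atom_b) for c in hydrogen_bonds(model, "a", "b", 3.6)}
        contacts = {(c.atom_a, c.atom_b)
                    for c in atomic_contacts(model, "a", "b", 3.6)}
        assert hb <= contacts

    @pytest.mark.parametrize("seed", [3, 4])
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        model = random_two_group_model(rng, 200, box=12.0)
        got = {(c.atom_a, c.atom_b) for c in hydrogen_bonds(model, "a", "b")}

        def is_hbond(key_a, key_b):
            return ((key_a in _ORACLE_DONORS and key_b in _ORACLE_ACCEPTORS)
                    or (key_a in _ORACLE_ACCEPTORS and key_b in _ORACLE_DONORS))

        assert got == brute_force_pairs(model, 3.6, is_hbond)


class TestSaltBridges:
    def test_canonical_pair(self):
        model = two_group_model(
            [single_atom_chain("A", "ARG", "NH1", "N", [0, 0, 0])],
            [single_atom_chain("B", "ASP", "OD1", "O", [3.5, 0, 0])])
        assert len(salt_bridges(model, "a", "b")) == 1

    def test_beyond_cutoff(self):
        model = two_group_model(
            [single_atom_chain("A", "LYS", "NZ", "N", [0, 0, 0])],
            [single_atom_chain("B", "GLU", "OE1", "O", [4.5, 0, 0])])
        assert salt_bridges(model, "a", "b") == []

    def test_three_planted_bridges(self):
        left, right = [], []
        for i, (rn, an) in enumerate([("ARG", "NH1"), ("LYS", "NZ"), ("ARG", "NE")]):
            left.append(single_atom_chain(chr(65 + i), rn, an, "N",
                                          [0, 8.0 * i, 0]))
            right.append(single_atom_chain(chr(88 + i), "ASP", "OD1", "O",
                                           [3.4, 8.0 * i, 0]))
        model = two_group_model(left, right)
        assert len(salt_bridges(model, "a", "b")) == 3


class TestInterfaceResidues:
    def _residue(self, seq_id, ca, sc=None, name="GLN"):
        atoms = [Atom("CA", "C", np.array(ca, float))]
        if sc is not None:
            atoms.append(Atom("SC", "N", np.array(sc, float)))
        return Residue(seq_id, name if sc is not None else "GLY", "", atoms)

    def _model(self, residue):
        probe = single_atom_chain("B", "GLY", "CA", "C", [0, 0, 0])
        return AssemblyModel([Chain("A", [residue]), probe], {"A": "a", "B": "b"})

    def test_proximity_criterion(self):
        report = interface_residues(self._model(
            self._residue(1, [6.5, 0, 0], [5.0, 0, 0])), "a", "b")
        assert [r.criterion for r in report.residues_a] == ["proximity"]

    def test_orientation_criterion_pointing_toward(self):
        # side chain at 7 A from the probe, pointing straight at it
        report = interface_residues(self._model(
            self._residue(1, [9.5, 0, 0], [7.0, 0, 0])), "a", "b")
        assert [r.criterion for r in report.residues_a] == ["orientation"]

    def test_pointing_away_not_interfacial(self):
        # side-chain centroid within reach (8.5 A) but at 180 degrees
        report = interface_residues(self._model(
            self._residue(1, [7.0, 0, 0], [8.5, 0, 0])), "a", "b")
        assert report.residues_a == []

    def test_glycine_needs_proximity(self):
        # bare CA at 7 A: inside the 9 A reach but glycine has no side chain
        report = interface_residues(self._model(self._residue(1, [7.0, 0, 0])),
                                    "a", "b")
        assert report.residues_a == []

    def test_symmetric_under_group_swap(self, homolog_pair):
        template = homolog_pair.template
        fwd = interface_residues(template, "dimerA", "dimerB")
        rev = interface_residues(template, "dimerB", "dimerA")
        assert {(r.chain_id, r.seq_id) for r in fwd.residues_a} == \
               {(r.chain_id, r.seq_id) for r in rev.residues_b}
        assert fwd.summary["contacts"] == rev.summary["contacts"]


class TestPercentIdentity:
    def test_identical(self):
        assert percent_identity("GARFIELD"[:6], "GARFIELD"[:6]) == 100.0

    def test_three_quarters(self):
        assert percent_identity("AAAA", "AATA") == pytest.approx(75.0)

    def test_fully_different(self):
        assert percent_identity("AAA", "CCC") == 0.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            percent_identity("", "AAA")


class TestDifferingInterfaceSites:
    def test_identical_sequences_give_empty(self, homolog_pair):
        template = homolog_pair.template
        from oligoshift.structure import chain_sequence
        own = chain_sequence(template, "A")
        assert differing_interface_sites(template, own) == []

    def test_planted_sites_recovered_exactly(self, homolog_pair):
        sites = differing_interface_sites(homolog_pair.template,
                                          homolog_pair.candidate_seq)
        assert [s.position for s in sites] == \
               [s.position for s in homolog_pair.planted_interface_sites]

    def test_non_interfacial_differences_excluded(self, homolog_pair):
        sites = differing_interface_sites(homolog_pair.template,
                                          homolog_pair.candidate_seq)
        other = {s.position for s in homolog_pair.planted_other_sites}
        assert not ({s.position for s in sites} & other)
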