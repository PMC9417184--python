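"""Interface contact atlas: contacts, hydrogen bonds, salt bridges, and
interface-residue identification across a stated chain partition.

Hydrogen bonds are defined purely by a donor/acceptor-capable N/O pair within
a distance cutoff (default 3.6 A) — no angular term, no explicit hydrogens.
Interface residues satisfy either a proximity criterion (any heavy atom
within 5.5 A of the opposite group) or an orientation criterion (side-chain
centroid within 9 A of the opposite group and pointing toward it).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .structure import AssemblyModel, Atom, Residue, sidechain_element

CONTACT_CUTOFF = 5.5        # A, generic interfacial criterion
HBOND_CUTOFF = 3.6          # A, distance-only hydrogen-bond definition
SALT_BRIDGE_CUTOFF = 4.0    # A, charged-group heavy-atom pairs
ORIENTATION_DISTANCE = 9.0  # A, side-chain-centroid reach
ORIENTATION_ANGLE = 90.0    # degrees, CA->centroid vs CA->opposite-atom

_SIDECHAIN_DONORS = {
    "ARG": {"NE", "NH1", "NH2"}, "LYS": {"NZ"}, "HIS": {"ND1", "NE2"},
    "TRP": {"NE1"}, "ASN": {"ND2"}, "GLN": {"NE2"},
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
}
_SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}, "ASN": {"OD1"},
    "GLN": {"OE1"}, "HIS": {"ND1", "NE2"},
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
}
_BASIC_ATOMS = {"ARG": {"NE", "NH1", "NH2"}, "LYS": {"NZ"}, "HIS": {"ND1", "NE2"}}
_ACIDIC_ATOMS = {"ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}}

# coarse models carry one side-chain pseudo-atom named SC whose element
# encodes polarity (see structure.sidechain_element)
_SC_DONOR_AA = set("RKHWNQSTY")
_SC_ACCEPTOR_AA = set("DENQSTYH")
_SC_BASIC_AA = set("RKH")
_SC_ACIDIC_AA = set("DE")


def _atom_roles(res: Residue, atom: Atom) -> tuple[bool, bool, bool, bool]:
    """(donor, acceptor, basic, acidic) capability of a heavy atom."""
    name, rname, aa = atom.name, res.name, res.aa_type
    if name == "SC":  # coarse pseudo side chain
        polar = atom.element in ("N", "O")
        return (polar and aa in _SC_DONOR_AA, polar and aa in _SC_ACCEPTOR_AA,
                atom.element == "N" and aa in _SC_BASIC_AA,
                atom.element == "O" and aa in _SC_ACIDIC_AA)
    donor = (name == "N" and rname != "PRO") or name in _SIDECHAIN_DONORS.get(rname, ())
    acceptor = name in ("O", "OXT") or name in _SIDECHAIN_ACCEPTORS.get(rname, ())
    basic = name in _BASIC_ATOMS.get(rname, ())
    acidic = name in _ACIDIC_ATOMS.get(rname, ())
    return donor, acceptor, basic, acidic


@dataclass
class GroupAtoms:
    """Flattened heavy-atom view of one partition group."""
    coords: np.ndarray
    keys: list[tuple[str, int, str]]       # (chain_id, seq_id, atom name)
    donor: np.ndarray
    acceptor: np.ndarray
    basic: np.ndarray
    acidic: np.ndarray

    @property
    def tree(self) -> cKDTree:
        if not hasattr(self, "_tree"):
            self._tree = cKDTree(self.coords)
        return self._tree


def group_atoms(model: AssemblyModel, group: str) -> GroupAtoms:
    coords, keys, donor, acceptor, basic, acidic = [], [], [], [], [], []
    for chain in model.chains_in_group(group):
        for res in chain.residues:
            for atom in res.heavy_atoms():
                coords.append(atom.coords)
                keys.append((chain.chain_id, res.seq_id, atom.name))
                d, a, b, c = _atom_roles(res, atom)
                donor.append(d); acceptor.append(a); basic.append(b); acidic.append(c)
    if not coords:
        raise ValueError(f"group {group!r} has no heavy atoms")
    return GroupAtoms(np.vstack(coords), keys, np.array(donor), np.array(acceptor),
                      np.array(basic), np.array(acidic))


@dataclass(frozen=True)
class ContactRecord:
    atom_a: tuple[str, int, str]
    atom_b: tuple[str, int, str]
    distance: float
    kind: str  # contact | hydrogen_bond | salt_bridge

    def to_dict(self) -> dict:
        return {"atom_a": list(self.atom_a), "atom_b": list(self.atom_b),
                "distance": round(self.distance, 3), "kind": self.kind}


def _cross_pairs(ga: GroupAtoms, gb: GroupAtoms, cutoff: float):
    """Indices and distances of cross-group atom pairs within ``cutoff``."""
    pairs = ga.tree.query_ball_tree(gb.tree, r=cutoff)
    for i, js in enumerate(pairs):
        for j in js:
            d = float(np.linalg.norm(ga.coords[i] - gb.coords[j]))
            if d <= cutoff:
                yield i, j, d


def _records(model, group_a, group_b, cutoff, kind, predicate=None) -> list[ContactRecord]:
    ga = group_atoms(model, group_a)
    gb = group_atoms(model, group_b)
    out = []
    for i, j, d in _cross_pairs(ga, gb, cutoff):
        if predicate is None or predicate(ga, gb, i, j):
            out.append(ContactRecord(ga.keys[i], gb.keys[j], d, kind))
    out.sort(key=lambda r: (r.atom_a, r.atom_b))
    return out


def atomic_contacts(model: AssemblyModel, group_a: str, group_b: str,
                    cutoff: float = CONTACT_CUTOFF) -> list[ContactRecord]:
    """All heavy-atom cross-group pairs within ``cutoff`` (grid-accelerated)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    return _records(model, group_a, group_b, cutoff, "contact")


def _is_hbond(ga, gb, i, j) -> bool:
    return bool((ga.donor[i] and gb.acceptor[j]) or (ga.acceptor[i] and gb.donor[j]))


def _is_salt_bridge(ga, gb, i, j) -> bool:
    return bool((ga.basic[i] and gb.acidic[j]) or (ga.acidic[i] and gb.basic[j]))


def hydrogen_bonds(model: AssemblyModel, group_a: str, group_b: str,
                   cutoff: float = HBOND_CUTOFF) -> list[ContactRecord]:
    """Donor/acceptor N/O pairs within the distance cutoff (no angular term)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    return _records(model, group_a, group_b, cutoff, "hydrogen_bond", _is_hbond)


def salt_bridges(model: AssemblyModel, group_a: str, group_b: str,
                 cutoff: float = SALT_BRIDGE_CUTOFF) -> list[ContactRecord]:
    """Arg/Lys/His nitrogen vs Asp/Glu carboxylate oxygen pairs within cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    return _records(model, group_a, group_b, cutoff, "salt_bridge", _is_salt_bridge)


# ---------------------------------------------------------------------------
# Interface residues
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InterfaceResidue:
    chain_id: str
    seq_id: int
    res_name: str
    criterion: str  # proximity | orientation

    def to_dict(self) -> dict:
        return {"chain_id": self.chain_id, "seq_id": self.seq_id,
                "res_name": self.res_name, "criterion": self.criterion}


@dataclass
class InterfaceReport:
    group_a: str
    group_b: str
    contacts: list[ContactRecord]
    hydrogen_bonds: list[ContactRecord]
    salt_bridges: list[ContactRecord]
    residues_a: list[InterfaceResidue]
    residues_b: list[InterfaceResidue]
    warnings: list[str] = field(default_factory=list)

    @property
    def summary(self) -> dict[str, int]:
        return {
            "contacts": len(self.contacts),
            "hydrogen_bonds": len(self.hydrogen_bonds),
            "salt_bridges": len(self.salt_bridges),
            "interface_residues_a": len(self.residues_a),
            "interface_residues_b": len(self.residues_b),
        }

    def to_dict(self) -> dict:
        return {
            "groups": [self.group_a, self.group_b],
            "summary": self.summary,
            "contacts": [c.to_dict() for c in self.contacts],
            "hydrogen_bonds": [c.to_dict() for c in self.hydrogen_bonds],
            "salt_bridges": [c.to_dict() for c in self.salt_bridges],
            "interface_residues": {
                self.group_a: [r.to_dict() for r in self.residues_a],
                self.group_b: [r.to_dict() for r in self.residues_b],
            },
            "warnings": self.warnings,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def contacts_tsv(self) -> str:
        lines = ["chain_a\tseq_a\tatom_a\tchain_b\tseq_b\tatom_b\tdistance\tkind"]
        for rec in self.contacts + self.hydrogen_bonds + self.salt_bridges:
            (ca, sa, na), (cb, sb, nb) = rec.atom_a, rec.atom_b
            lines.append(f"{ca}\t{sa}\t{na}\t{cb}\t{sb}\t{nb}\t{rec.distance:.3f}\t{rec.kind}")
        return "\n".join(lines) + "\n"


def _interface_side(model: AssemblyModel, group: str, opposite: GroupAtoms,
                    contact_cutoff: float, orientation_distance: float,
                    orientation_angle: float, warnings: list[str]) -> list[InterfaceResidue]:
    found: list[InterfaceResidue] = []
    cos_limit = np.cos(np.deg2rad(orientation_angle))
    for chain in model.chains_in_group(group):
        for res in chain.residues:
            heavy = res.heavy_atoms()
            if not heavy:
                continue
            coords = np.vstack([a.coords for a in heavy])
            dmin = opposite.tree.query(coords, k=1)[0].min()
            if dmin <= contact_cutoff:
                found.append(InterfaceResidue(chain.chain_id, res.seq_id,
                                              res.name, "proximity"))
                continue
            side = res.sidechain_atoms()
            if not side:  # glycine: proximity only
                continue
            ca = res.get_atom("CA")
            if ca is None:
                warnings.append(
                    f"chain {chain.chain_id} residue {res.seq_id}: no CA, "
                    f"orientation criterion skipped")
                continue
            centroid = np.mean([a.coords for a in side], axis=0)
            dist, j = opposite.tree.query(centroid, k=1)
            if dist > orientation_distance:
                continue
            v_side = centroid - ca.coords
            v_opp = opposite.coords[j] - ca.coords
            norms = np.linalg.norm(v_side) * np.linalg.norm(v_opp)
            if norms <= 0:
                continue
            if (v_side @ v_opp) / norms >= cos_limit:
                found.append(InterfaceResidue(chain.chain_id, res.seq_id,
                                              res.name, "orientation"))
    return found


def interface_residues(model: AssemblyModel, group_a: str, group_b: str,
                       contact_cutoff: float = CONTACT_CUTOFF,
                       orientation_distance: float = ORIENTATION_DISTANCE,
                       orientation_angle: float = ORIENTATION_ANGLE) -> InterfaceReport:
    """Identify interface residues between two partition groups.

    A residue is interfacial if (i) any heavy atom is within
    ``contact_cutoff`` of the opposite group, or (ii) its side-chain centroid
    is within ``orientation_distance`` of the opposite group and points
    toward it (CA->centroid vs CA->nearest-opposite-atom angle within
    ``orientation_angle``).
    """
    ga = group_atoms(model, group_a)
    gb = group_atoms(model, group_b)
    warnings: list[str] = []
    residues_a = _interface_side(model, group_a, gb, contact_cutoff,
                                 orientation_distance, orientation_angle, warnings)
    residues_b = _interface_side(model, group_b, ga, contact_cutoff,
                                 orientation_distance, orientation_angle, warnings)
    return InterfaceReport(
        group_a, group_b,
        contacts=atomic_contacts(model, group_a, group_b, contact_cutoff),
        hydrogen_bonds=hydrogen_bonds(model, group_a, group_b),
        salt_bridges=salt_bridges(model, group_a, group_b),
        residues_a=residues_a, residues_b=residues_b, warnings=warnings)


# ---------------------------------------------------------------------------
# Sequence comparison
# ---------------------------------------------------------------------------

def _aligner():
    from Bio.Align import PairwiseAligner, substitution_matrices
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


def _aligned_columns(seq_a: str, seq_b: str) -> list[tuple[int, int]]:
    aln = _aligner().align(seq_a.replace("X", "A"), seq_b.replace("X", "A"))[0]
    pairs: list[tuple[int, int]] = []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        pairs.extend(zip(range(a0, a1), range(b0, b1)))
    return pairs


def percent_identity(seq_a: str, seq_b: str) -> float:
    """Identity percentage over aligned ungapped columns of a global
    alignment (BLOSUM62, gap open -11 / extend -1)."""
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    pairs = _aligned_columns(seq_a, seq_b)
    if not pairs:
        return 0.0
    matches = sum(1 for i, j in pairs if seq_a[i] == seq_b[j])
    return 100.0 * matches / len(pairs)


@dataclass(frozen=True)
class DifferingSite:
    position: int       # author residue number in the template
    template_aa: str
    candidate_aa: str

    def to_dict(self) -> dict:
        return {"position": self.position, "template_aa": self.template_aa,
                "candidate_aa": self.candidate_aa}


def template_interface_positions(template: AssemblyModel,
                                 chain_id: str | None = None,
                                 contact_cutoff: float = CONTACT_CUTOFF,
                                 orientation_distance: float = ORIENTATION_DISTANCE,
                                 orientation_angle: float = ORIENTATION_ANGLE) -> set[int]:
    """Interfacial residue numbers of one chain against all other groups."""
    if chain_id is None:
        chain_id = template.chains[0].chain_id
    own_group = template.partition[chain_id]
    positions: set[int] = set()
    for other in template.groups():
        if other == own_group:
            continue
        report = interface_residues(template, own_group, other, contact_cutoff,
                                    orientation_distance, orientation_angle)
        positions.update(r.seq_id for r in report.residues_a
                         if r.chain_id == chain_id)
    return positions


def differing_interface_sites(template: AssemblyModel, candidate_seq: str,
                              chain_id: str | None = None,
                              interface_positions: set[int] | None = None,
                              ) -> list[DifferingSite]:
    """Interfacial template positions whose aligned candidate residue differs.

    The template chain sequence is globally aligned against the candidate;
    gap columns are excluded.  ``interface_positions`` may be supplied to
    reuse a precomputed interface.
    """
    if not candidate_seq:
        raise ValueError("candidate sequence is empty")
    if chain_id is None:
        chain_id = template.chains[0].chain_id
    if interface_positions is None:
        interface_positions = template_interface_positions(template, chain_id)
    chain = template.get_chain(chain_id)
    residues = chain.sorted_residues()
    template_seq = "".join(r.aa_type for r in residues)
    sites: list[DifferingSite] = []
    for i, j in _aligned_columns(template_seq, candidate_seq):
        pos = residues[i].seq_id
        if pos in interface_positions and template_seq[i] != candidate_seq[j]:
            sites.append(DifferingSite(pos, template_seq[i], candidate_seq[j]))
    sites.sort(key=lambda s: s.position)
    return sites
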