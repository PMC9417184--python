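"""Hierarchical coordinate model (chains -> residues -> atoms) and PDB I/O.

The :class:`AssemblyModel` is the container every other module consumes.  It
carries a *partition*: a mapping from chain id to a group label (for example
``dimerA`` / ``dimerB``) that states which chains belong together when an
interface between sub-assemblies is analysed.  Partition labels survive a
write/read round trip through ``REMARK 400 GROUP`` records.

Hydrogens and ligand HETATM records are excluded from geometric analyses by
default; ligands are parked on :attr:`AssemblyModel.ligands`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from Bio.SeqUtils import molecular_weight

BACKBONE_ATOM_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # selenomethionine reads as methionine; every other non-standard -> X
    "MSE": "M",
}
ONE_TO_THREE = {one: three for three, one in THREE_TO_ONE.items() if three != "MSE"}
STANDARD_AA = frozenset(ONE_TO_THREE)

#: electrons per element for constant-form-factor scattering and Rg weighting
ELEMENT_ELECTRONS = {
    "H": 1, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16, "SE": 34,
}

_PDB_ATOM_LIMIT = 99999


class PDBFormatError(ValueError):
    """Raised for unreadable or out-of-contract PDB content."""


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: coords must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name!r}: occupancy outside [0, 1]")

    @property
    def is_sidechain(self) -> bool:
        return self.name not in BACKBONE_ATOM_NAMES

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    @property
    def electrons(self) -> int:
        try:
            return ELEMENT_ELECTRONS[self.element.upper()]
        except KeyError:
            raise ValueError(f"no electron count for element {self.element!r}") from None

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.coords.copy(), self.occupancy)


@dataclass
class Residue:
    seq_id: int
    name: str = "ALA"
    insertion_code: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def aa_type(self) -> str:
        """One-letter code; non-standard residues map to X (MSE -> M)."""
        return THREE_TO_ONE.get(self.name, "X")

    @property
    def key(self) -> tuple[int, str]:
        return (self.seq_id, self.insertion_code)

    def get_atom(self, name: str) -> Atom | None:
        for atom in self.atoms:
            if atom.name == name:
                return atom
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def sidechain_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_sidechain and not a.is_hydrogen]

    def copy(self) -> "Residue":
        return Residue(self.seq_id, self.name, self.insertion_code,
                       [a.copy() for a in self.atoms])


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def sorted_residues(self) -> list[Residue]:
        return sorted(self.residues, key=lambda r: r.key)

    def copy(self) -> "Chain":
        return Chain(self.chain_id, [r.copy() for r in self.residues])


@dataclass
class AssemblyModel:
    chains: list[Chain] = field(default_factory=list)
    partition: dict[str, str] = field(default_factory=dict)
    ligands: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.partition:
            self.partition = {c.chain_id: c.chain_id for c in self.chains}

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if not self.chains:
            raise ValueError("empty model: no chains")
        seen_ids: set[str] = set()
        for chain in self.chains:
            if chain.chain_id in seen_ids:
                raise ValueError(f"duplicate chain id {chain.chain_id!r}")
            seen_ids.add(chain.chain_id)
            if chain.n_atoms() == 0:
                raise ValueError(f"chain {chain.chain_id!r} has no atoms")
            keys = [r.key for r in chain.residues]
            if len(keys) != len(set(keys)):
                raise ValueError(f"chain {chain.chain_id!r}: duplicate residue ids")
            for res in chain.residues:
                names = [a.name for a in res.atoms]
                if len(names) != len(set(names)):
                    raise ValueError(
                        f"chain {chain.chain_id!r} residue {res.seq_id}: duplicate atom names")
        for cid in seen_ids:
            if cid not in self.partition:
                raise ValueError(f"chain {cid!r} missing from partition")

    # -- accessors --------------------------------------------------------
    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def get_chain(self, chain_id: str) -> Chain:
        for chain in self.chains:
            if chain.chain_id == chain_id:
                return chain
        raise KeyError(f"no chain {chain_id!r} in model")

    def groups(self) -> list[str]:
        out: list[str] = []
        for cid in self.chain_ids:
            g = self.partition[cid]
            if g not in out:
                out.append(g)
        return out

    def chains_in_group(self, group: str) -> list[Chain]:
        return [c for c in self.chains if self.partition[c.chain_id] == group]

    def n_atoms(self) -> int:
        return sum(c.n_atoms() for c in self.chains)

    def iter_atoms(self):
        for chain in self.chains:
            for res in chain.residues:
                for atom in res.atoms:
                    yield chain, res, atom

    def coordinates(self, heavy_only: bool = True) -> np.ndarray:
        coords = [a.coords for _, _, a in self.iter_atoms()
                  if not (heavy_only and a.is_hydrogen)]
        if not coords:
            return np.empty((0, 3))
        return np.vstack(coords)

    def copy(self) -> "AssemblyModel":
        return AssemblyModel([c.copy() for c in self.chains], dict(self.partition),
                             [r.copy() for r in self.ligands])


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _resolve_altlocs(atoms: list[tuple[str, gemmi.Atom]], policy: str) -> list[gemmi.Atom]:
    """Keep one conformer per atom name.

    ``highest_occupancy`` (default): highest occupancy wins, ties break to the
    alphabetically first altloc.  ``first``: first conformer encountered wins.
    """
    chosen: dict[str, tuple[tuple, gemmi.Atom]] = {}
    for order, (altloc, atom) in enumerate(atoms):
        if policy == "first":
            rank = (order,)
        elif policy == "highest_occupancy":
            rank = (-atom.occ, altloc or " ", order)
        else:
            raise ValueError(f"unknown altloc policy {policy!r}")
        if atom.name not in chosen or rank < chosen[atom.name][0]:
            chosen[atom.name] = (rank, atom)
    return [atom for _, atom in chosen.values()]


def _parse_group_remarks(text: str) -> dict[str, str]:
    partition: dict[str, str] = {}
    for line in text.splitlines():
        if line.startswith("REMARK 400 GROUP"):
            parts = line.split()
            # REMARK 400 GROUP <label> CHAINS <id> [<id> ...]
            if len(parts) >= 6 and parts[4] == "CHAINS":
                for cid in parts[5:]:
                    partition[cid] = parts[3]
    return partition


def read_pdb(path: str | Path, altloc_policy: str = "highest_occupancy",
             include_ligands: bool = True) -> AssemblyModel:
    """Read a PDB file into an :class:`AssemblyModel`.

    Protein ATOM records populate the chains; non-water HETATM residues are
    kept on ``model.ligands`` (excluded from geometric analyses).  Alternate
    locations are resolved per ``altloc_policy``.
    """
    path = Path(path)
    text = path.read_text()
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise PDBFormatError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise PDBFormatError(f"{path}: no models in file")

    chains: list[Chain] = []
    ligands: list[Residue] = []
    for gchain in st[0]:
        chain = Chain(gchain.name.strip() or "A")
        for gres in gchain:
            if gres.is_water():
                continue
            grouped: list[tuple[str, gemmi.Atom]] = [
                (gatom.altloc, gatom) for gatom in gres]
            picked = _resolve_altlocs(grouped, altloc_policy)
            res = Residue(
                seq_id=gres.seqid.num,
                name=gres.name.strip(),
                insertion_code=(gres.seqid.icode or " ").strip(),
                atoms=[Atom(a.name.strip(), a.element.name.upper(),
                            np.array([a.pos.x, a.pos.y, a.pos.z]),
                            min(max(a.occ, 0.0), 1.0))
                       for a in picked],
            )
            is_protein = gres.name.strip() in THREE_TO_ONE
            if is_protein:
                chain.residues.append(res)
            elif include_ligands:
                ligands.append(res)
        if chain.residues:
            chains.append(chain)

    if not chains:
        raise PDBFormatError(f"{path}: no protein ATOM records found")
    partition = _parse_group_remarks(text)
    model = AssemblyModel(chains, {}, ligands)
    if partition:
        for cid in model.chain_ids:
            if cid in partition:
                model.partition[cid] = partition[cid]
    model.validate()
    return model


def write_pdb(model: AssemblyModel, path: str | Path) -> None:
    """Write standard PDB ATOM records (3-decimal coordinates).

    Partition group labels are recorded as ``REMARK 400 GROUP`` lines so a
    round trip preserves them.
    """
    model.validate()
    if model.n_atoms() + sum(len(r.atoms) for r in model.ligands) > _PDB_ATOM_LIMIT:
        raise PDBFormatError(f"more than {_PDB_ATOM_LIMIT} atoms: PDB format limit")

    st = gemmi.Structure()
    st.add_model(gemmi.Model("1"))
    for chain in model.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.sorted_residues():
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seq_id, res.insertion_code or " ")
            gres.het_flag = "A"
            for atom in res.atoms:
                gatom = gemmi.Atom()
                gatom.name = atom.name
                gatom.element = gemmi.Element(atom.element)
                gatom.pos = gemmi.Position(*atom.coords)
                gatom.occ = atom.occupancy
                gres.add_atom(gatom)
            gchain.add_residue(gres)
        st[0].add_chain(gchain)
    if model.ligands:
        lchain = gemmi.Chain("Z" if "Z" not in model.chain_ids else "z")
        for res in model.ligands:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seq_id, res.insertion_code or " ")
            gres.het_flag = "H"
            for atom in res.atoms:
                gatom = gemmi.Atom()
                gatom.name = atom.name
                gatom.element = gemmi.Element(atom.element)
                gatom.pos = gemmi.Position(*atom.coords)
                gatom.occ = atom.occupancy
                gres.add_atom(gatom)
            lchain.add_residue(gres)
        st[0].add_chain(lchain)

    remarks = []
    by_group: dict[str, list[str]] = {}
    for cid in model.chain_ids:
        by_group.setdefault(model.partition[cid], []).append(cid)
    for group, cids in by_group.items():
        remarks.append(f"REMARK 400 GROUP {group} CHAINS {' '.join(cids)}")
    body = st.make_pdb_string()
    Path(path).write_text("\n".join(remarks) + ("\n" if remarks else "") + body)


# ---------------------------------------------------------------------------
# Sequences and masses
# ---------------------------------------------------------------------------

def chain_sequence(model: AssemblyModel, chain_id: str) -> str:
    """One-letter sequence of a chain, ordered by (seq_id, insertion code)."""
    chain = model.get_chain(chain_id)
    return "".join(res.aa_type for res in chain.sorted_residues())


def theoretical_mass(sequences: list[str]) -> float:
    """Mass in kDa of a set of chains from average residue masses.

    Each chain contributes the sum of its average residue masses plus one
    water; only the 20 standard one-letter codes are accepted.
    """
    total = 0.0
    for seq in sequences:
        for ch in seq:
            if ch not in STANDARD_AA:
                raise ValueError(f"non-standard amino acid code {ch!r}")
        if seq:
            total += molecular_weight(seq, seq_type="protein")
    return total / 1000.0


def sidechain_element(aa: str) -> str:
    """Element assigned to a one-bead side-chain pseudo-atom.

    Polar/basic nitrogen-bearing types get N, hydroxyl/carboxylate types get
    O, sulfur-bearing types S, the rest C.  This is what lets coarse models
    participate in hydrogen-bond and salt-bridge typing.
    """
    if aa in "RKHWNQ":
        return "N"
    if aa in "DESTY":
        return "O"
    if aa in "MC":
        return "S"
    return "C"


#: CA -> side-chain-centroid distance (Angstrom) per residue type, used to
#: place one-bead side chains on mutated or generated residues.
SIDECHAIN_CENTROID_DISTANCE = {
    "A": 1.5, "R": 4.1, "N": 2.5, "D": 2.5, "C": 2.1, "Q": 3.1, "E": 3.2,
    "G": 0.0, "H": 3.2, "I": 2.3, "L": 2.6, "K": 3.5, "M": 3.0, "F": 3.4,
    "P": 1.9, "S": 1.9, "T": 1.9, "W": 3.9, "Y": 3.8, "V": 2.0,
}


def residue_distance(res_a: Residue, res_b: Residue) -> float:
    """Minimum heavy-atom distance between two residues."""
    best = math.inf
    for a in res_a.heavy_atoms():
        for b in res_b.heavy_atoms():
            best = min(best, float(np.linalg.norm(a.coords - b.coords)))
    return best
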