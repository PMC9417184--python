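"""Rigid-body symmetry of homomeric assemblies.

A :class:`SymmetryDefinition` is an ordered set of rigid transforms that maps
a reference subunit onto every subunit position of an assembly (the first
transform is always the identity).  Definitions are derived from an existing
oligomer by CA-only least-squares superposition of the reference chain onto
every other chain, and applied to a subunit to rebuild full assemblies.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .structure import AssemblyModel, Chain, chain_sequence

_ORTHO_TOL = 1e-6
_CHAIN_ALPHABET = string.ascii_uppercase + string.ascii_lowercase + string.digits


@dataclass
class RigidTransform:
    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=_ORTHO_TOL):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=_ORTHO_TOL):
            raise ValueError("rotation determinant is not +1 (improper rotation)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self ∘ other)(x) = self(other(x))."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def is_identity(self, atol: float = 1e-9) -> bool:
        return (np.allclose(self.rotation, np.eye(3), atol=atol)
                and np.allclose(self.translation, 0.0, atol=atol))

    @property
    def angle(self) -> float:
        """Rotation angle in radians."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.arccos(np.clip(c, -1.0, 1.0)))

    @property
    def axis(self) -> np.ndarray:
        """Unit rotation axis (arbitrary for the identity)."""
        return Rotation.from_matrix(self.rotation).as_rotvec() / max(self.angle, 1e-12)


@dataclass
class SymmetryDefinition:
    transforms: list[RigidTransform]
    point_group_label: str = "C1"
    reference_chain: str = "A"
    rmsds: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.transforms:
            raise ValueError("symmetry definition needs at least one transform")
        if not self.transforms[0].is_identity(atol=1e-9):
            raise ValueError("first transform must be the identity")

    @property
    def order(self) -> int:
        return len(self.transforms)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "point_group_label": self.point_group_label,
            "reference_chain": self.reference_chain,
            "rmsds": [float(r) for r in self.rmsds],
            "transforms": [
                {"rotation": t.rotation.tolist(), "translation": t.translation.tolist()}
                for t in self.transforms
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, data: dict) -> "SymmetryDefinition":
        return cls(
            transforms=[RigidTransform(np.array(t["rotation"]), np.array(t["translation"]))
                        for t in data["transforms"]],
            point_group_label=data.get("point_group_label", "C1"),
            reference_chain=data.get("reference_chain", "A"),
            rmsds=list(data.get("rmsds", [])),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SymmetryDefinition":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares (Kabsch) transform mapping ``mobile`` onto ``target``.

    Returns the optimal rigid transform and the post-superposition RMSD.
    Raises on fewer than three points or (near-)collinear point sets, where
    the rotation is underdetermined.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for superposition")
    m_mean = mobile.mean(axis=0)
    t_mean = target.mean(axis=0)
    m_c = mobile - m_mean
    t_c = target - t_mean
    for label, pts in (("mobile", m_c), ("target", t_c)):
        sv = np.linalg.svd(pts, compute_uv=False)
        if sv[1] < 1e-8 * max(sv[0], 1.0):
            raise ValueError(f"{label} points are collinear or degenerate")
    rot, rssd = Rotation.align_vectors(t_c, m_c)
    rmat = rot.as_matrix()
    transform = RigidTransform(rmat, t_mean - rmat @ m_mean)
    rmsd = float(rssd) / np.sqrt(n)
    return transform, rmsd


# ---------------------------------------------------------------------------
# Deriving a definition from a reference oligomer
# ---------------------------------------------------------------------------

def _matched_ca_coords(ref_chain: Chain, other: Chain,
                       ref_seq: str, other_seq: str) -> tuple[np.ndarray, np.ndarray]:
    """CA coordinates matched by alignment position (ungapped when identical)."""
    ref_res = ref_chain.sorted_residues()
    oth_res = other.sorted_residues()
    if ref_seq == other_seq:
        pairs = [(i, i) for i in range(len(ref_res))]
    else:
        from Bio.Align import PairwiseAligner, substitution_matrices
        aligner = PairwiseAligner()
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11.0
        aligner.extend_gap_score = -1.0
        aligner.mode = "global"
        aln = aligner.align(ref_seq.replace("X", "A"), other_seq.replace("X", "A"))[0]
        pairs = []
        for (a0, a1), (b0, b1) in zip(*aln.aligned):
            pairs.extend(zip(range(a0, a1), range(b0, b1)))
    ref_ca, oth_ca = [], []
    for i, j in pairs:
        ca_r = ref_res[i].get_atom("CA")
        ca_o = oth_res[j].get_atom("CA")
        if ca_r is not None and ca_o is not None:
            ref_ca.append(ca_r.coords)
            oth_ca.append(ca_o.coords)
    if not ref_ca:
        return np.empty((0, 3)), np.empty((0, 3))
    return np.vstack(ref_ca), np.vstack(oth_ca)


def _sequence_identity(seq_a: str, seq_b: str) -> float:
    from .interface import percent_identity
    return percent_identity(seq_a, seq_b)


def infer_point_group(transforms: list[RigidTransform], atol: float = 1e-3) -> str:
    """Best-effort point-group label (Cn / Dn) from rotation angles and axes.

    The label is reported, never enforced: deposited structures are only
    approximately symmetric.
    """
    n = len(transforms)
    if n == 1:
        return "C1"
    rots = [t for t in transforms[1:] if t.angle > atol]
    if len(rots) < n - 1:  # extra near-identities: pure translations, no label
        return "unknown"
    axes = [t.axis for t in rots]
    pi_rots = [t for t in rots if abs(t.angle - np.pi) < 1e-2]
    # single common axis -> cyclic
    if all(abs(abs(ax @ axes[0]) - 1.0) < 1e-2 for ax in axes):
        return f"C{n}"
    if n % 2 == 0:
        m = n // 2
        non_pi = [t for t in rots if abs(t.angle - np.pi) >= 1e-2]
        if non_pi:
            principal = non_pi[0].axis
            perp = [t for t in pi_rots if abs(t.axis @ principal) < 1e-2]
            if len(non_pi) + 1 + len(perp) == n and len(perp) == m:
                return f"D{m}"
        elif len(pi_rots) == 3 and n == 4:
            # three mutually perpendicular two-folds
            dots = [abs(pi_rots[i].axis @ pi_rots[j].axis)
                    for i in range(3) for j in range(i + 1, 3)]
            if all(d < 1e-2 for d in dots):
                return "D2"
    return "unknown"


def derive_symmetry(reference: AssemblyModel, reference_chain: str,
                    rmsd_tolerance: float = 2.0, min_matched: int = 20,
                    min_identity: float = 70.0) -> SymmetryDefinition:
    """Derive the transforms mapping one chain onto every chain of a homomer.

    Each transform is the CA-only Kabsch superposition of the reference chain
    onto a target chain, residues matched by sequence alignment.  A per-chain
    RMSD above ``rmsd_tolerance`` indicates the chains are not symmetry mates
    and raises.
    """
    reference.validate()
    ref_chain = reference.get_chain(reference_chain)
    ref_seq = chain_sequence(reference, reference_chain)

    transforms: list[RigidTransform] = [RigidTransform.identity()]
    rmsds: list[float] = [0.0]
    for chain in reference.chains:
        if chain.chain_id == reference_chain:
            continue
        seq = chain_sequence(reference, chain.chain_id)
        ident = _sequence_identity(ref_seq, seq)
        if ident < min_identity:
            raise ValueError(
                f"chain {chain.chain_id!r} is only {ident:.1f}% identical to the "
                f"reference: not a homomer")
        ref_ca, oth_ca = _matched_ca_coords(ref_chain, chain, ref_seq, seq)
        if ref_ca.shape[0] < min_matched:
            raise ValueError(
                f"chain {chain.chain_id!r}: only {ref_ca.shape[0]} matched CA atoms "
                f"(need >= {min_matched})")
        transform, rmsd = superpose(ref_ca, oth_ca)
        if rmsd > rmsd_tolerance:
            raise ValueError(
                f"chain {chain.chain_id!r}: superposition RMSD {rmsd:.2f} A exceeds "
                f"tolerance {rmsd_tolerance} A")
        transforms.append(transform)
        rmsds.append(rmsd)

    # reorder so the reference chain sits first (it already does by construction)
    label = infer_point_group(transforms)
    return SymmetryDefinition(transforms, label, reference_chain, rmsds)


# ---------------------------------------------------------------------------
# Applying a definition to a subunit
# ---------------------------------------------------------------------------

def apply_symmetry(subunit: AssemblyModel, symdef: SymmetryDefinition,
                   group_labels: list[str] | None = None) -> AssemblyModel:
    """Build a full assembly: one copy of ``subunit`` per transform.

    Chains are relabelled deterministically (A, B, C, ...) and each copy gets
    its own partition group (``sub1``, ``sub2``, ... unless ``group_labels``
    is given, one label per copy).
    """
    subunit.validate()
    n_copies = symdef.order
    n_chains = len(subunit.chains) * n_copies
    if n_chains > len(_CHAIN_ALPHABET):
        raise ValueError(f"cannot relabel {n_chains} chains uniquely")
    if group_labels is not None and len(group_labels) != n_copies:
        raise ValueError("need one group label per transform")

    chains: list[Chain] = []
    partition: dict[str, str] = {}
    idx = 0
    for copy_i, transform in enumerate(symdef.transforms):
        label = group_labels[copy_i] if group_labels else f"sub{copy_i + 1}"
        for src in subunit.chains:
            new_chain = src.copy()
            new_chain.chain_id = _CHAIN_ALPHABET[idx]
            idx += 1
            for res in new_chain.residues:
                for atom in res.atoms:
                    atom.coords = transform.apply(atom.coords)
            chains.append(new_chain)
            partition[new_chain.chain_id] = label
    assembled = AssemblyModel(chains, partition)
    assembled.validate()
    return assembled
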