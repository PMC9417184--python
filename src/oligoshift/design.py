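"""Dimer-to-hexamer interface design screen.

The screen enumerates every combination of candidate interface mutations,
rebuilds a coarse mutant assembly under the template symmetry, scores each
mutant over repeated jittered samples with a transparent surrogate
interaction energy, ranks mutants by their best sample, and assesses the
top-ranked finalists by the number of interface hydrogen bonds.

The surrogate score is a pairwise sum over cross-group heavy-atom pairs
within 8 A: a soft-sphere clash penalty plus rewards for hydrogen-bond and
salt-bridge geometry.  It replaces a full molecular-mechanics energy: the
procedure (enumerate -> sample -> rank -> assess H-bonds) is the object of
interest and the score is pluggable through :class:`ScoreWeights`.
"""

from __future__ import annotations

import json
import warnings as _warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .interface import HBOND_CUTOFF, SALT_BRIDGE_CUTOFF, group_atoms, hydrogen_bonds
from .structure import (AssemblyModel, Atom, ONE_TO_THREE,
                        SIDECHAIN_CENTROID_DISTANCE, sidechain_element)
from .symmetry import SymmetryDefinition, apply_symmetry


@dataclass(frozen=True)
class MutationSite:
    position: int
    wild_aa: str
    mutant_aa: str

    def __post_init__(self) -> None:
        if self.wild_aa == self.mutant_aa:
            raise ValueError(f"site {self.position}: wild and mutant types are equal")
        for aa in (self.wild_aa, self.mutant_aa):
            if aa not in ONE_TO_THREE:
                raise ValueError(f"site {self.position}: unknown amino acid {aa!r}")

    @property
    def label(self) -> str:
        return f"{self.wild_aa}{self.position}{self.mutant_aa}"


@dataclass
class ScoreWeights:
    pair_cutoff: float = 8.0        # A, pairs beyond this do not contribute
    clash_distance: float = 3.0     # A, soft-sphere onset
    clash_weight: float = 10.0      # per A^2 of overlap
    hbond_weight: float = 1.0       # reward per donor/acceptor pair <= 3.6 A
    salt_bridge_weight: float = 2.0  # reward per charged pair <= 4.0 A

    def to_dict(self) -> dict:
        return asdict(self)


def enumerate_mutants(sites: list[MutationSite]) -> list[tuple[MutationSite, ...]]:
    """Full power set of mutation sites in binary-counter order.

    Subset ``k`` contains site ``j`` iff bit ``j`` of ``k`` is set; index 0
    is the wild type.
    """
    positions = [s.position for s in sites]
    if len(positions) != len(set(positions)):
        raise ValueError("duplicate mutation positions")
    out: list[tuple[MutationSite, ...]] = []
    for k in range(2 ** len(sites)):
        out.append(tuple(sites[j] for j in range(len(sites)) if k >> j & 1))
    return out


def mutate_subunit(subunit: AssemblyModel,
                   mutations: tuple[MutationSite, ...]) -> AssemblyModel:
    """Apply mutations to every chain of a subunit (coarse representation).

    The residue type is replaced and its side chain becomes a single
    pseudo-atom (name ``SC``) at the idealised centroid distance along the
    existing CA->side-chain direction, or radially outward from the subunit
    centroid when the wild type had no side chain (glycine).
    """
    mutated = subunit.copy()
    centroid = mutated.coordinates().mean(axis=0)
    for mut in mutations:
        hit = False
        for chain in mutated.chains:
            for res in chain.residues:
                if res.seq_id != mut.position:
                    continue
                hit = True
                ca = res.get_atom("CA")
                if ca is None:
                    raise ValueError(f"site {mut.position}: residue has no CA")
                side = res.sidechain_atoms()
                if side:
                    direction = np.mean([a.coords for a in side], axis=0) - ca.coords
                else:
                    direction = ca.coords - centroid
                norm = np.linalg.norm(direction)
                direction = direction / norm if norm > 1e-9 else np.array([0.0, 0.0, 1.0])
                res.name = ONE_TO_THREE[mut.mutant_aa]
                res.atoms = [a for a in res.atoms if not a.is_sidechain]
                dist = SIDECHAIN_CENTROID_DISTANCE[mut.mutant_aa]
                if dist > 0:
                    res.atoms.append(Atom("SC", sidechain_element(mut.mutant_aa),
                                          ca.coords + dist * direction))
        if not hit:
            raise ValueError(f"mutation position {mut.position} absent from subunit")
    return mutated


def build_mutant_assembly(subunit: AssemblyModel,
                          mutations: tuple[MutationSite, ...],
                          symdef: SymmetryDefinition,
                          group_labels: list[str] | None = None) -> AssemblyModel:
    """Mutated subunit propagated to every symmetry copy."""
    return apply_symmetry(mutate_subunit(subunit, mutations), symdef, group_labels)


# ---------------------------------------------------------------------------
# Surrogate scoring
# ---------------------------------------------------------------------------

@dataclass
class _FlatAssembly:
    coords: np.ndarray
    group_idx: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray
    basic: np.ndarray
    acidic: np.ndarray
    jitter_mask: np.ndarray


def _flatten(assembly: AssemblyModel, mutation_positions: set[int],
             relax_radius: float) -> _FlatAssembly:
    groups = assembly.groups()
    parts = [group_atoms(assembly, g) for g in groups]
    coords = np.vstack([p.coords for p in parts])
    group_idx = np.concatenate([np.full(len(p.keys), gi) for gi, p in enumerate(parts)])
    donor = np.concatenate([p.donor for p in parts])
    acceptor = np.concatenate([p.acceptor for p in parts])
    basic = np.concatenate([p.basic for p in parts])
    acidic = np.concatenate([p.acidic for p in parts])
    sidechain = np.concatenate(
        [np.array([k[2] not in ("N", "CA", "C", "O", "OXT") for k in p.keys])
         for p in parts])
    if mutation_positions:
        site_ca = [res.get_atom("CA").coords
                   for chain in assembly.chains for res in chain.residues
                   if res.seq_id in mutation_positions and res.get_atom("CA")]
        near = np.zeros(coords.shape[0], dtype=bool)
        if site_ca:
            tree = cKDTree(np.vstack(site_ca))
            dist = tree.query(coords, k=1)[0]
            near = dist <= relax_radius
        jitter_mask = sidechain & near
    else:
        jitter_mask = np.zeros(coords.shape[0], dtype=bool)
    return _FlatAssembly(coords, group_idx, donor, acceptor, basic, acidic, jitter_mask)


def _pair_score(flat: _FlatAssembly, coords: np.ndarray, w: ScoreWeights) -> float:
    pairs = cKDTree(coords).query_pairs(w.pair_cutoff, output_type="ndarray")
    if pairs.size == 0:
        return None  # caller decides how to report an empty interface
    cross = flat.group_idx[pairs[:, 0]] != flat.group_idx[pairs[:, 1]]
    pairs = pairs[cross]
    if pairs.size == 0:
        return None
    i, j = pairs[:, 0], pairs[:, 1]
    d = np.linalg.norm(coords[i] - coords[j], axis=1)
    overlap = np.maximum(0.0, w.clash_distance - d)
    score = w.clash_weight * float(np.sum(overlap ** 2))
    hb = ((flat.donor[i] & flat.acceptor[j]) | (flat.acceptor[i] & flat.donor[j]))
    score -= w.hbond_weight * float(np.sum(hb & (d <= HBOND_CUTOFF)))
    sb = ((flat.basic[i] & flat.acidic[j]) | (flat.acidic[i] & flat.basic[j]))
    score -= w.salt_bridge_weight * float(np.sum(sb & (d <= SALT_BRIDGE_CUTOFF)))
    return score


def surrogate_score(assembly: AssemblyModel, perturb_sigma: float = 0.3,
                    n_samples: int = 50, seed: int = 0,
                    mutation_positions: set[int] | frozenset[int] = frozenset(),
                    relax_radius: float = 12.0,
                    weights: ScoreWeights | None = None,
                    ) -> tuple[list[float], AssemblyModel]:
    """Sampled surrogate interaction scores of an assembly (lower is better).

    Side-chain pseudo-atoms within ``relax_radius`` of any mutation site get
    Gaussian positional jitter per sample; each sample is scored over
    cross-group heavy-atom pairs within the pair cutoff.  Returns the sample
    scores and a copy of the assembly holding the best (lowest-score) sample
    coordinates.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if perturb_sigma < 0:
        raise ValueError("perturb_sigma must be >= 0")
    w = weights or ScoreWeights()
    flat = _flatten(assembly, set(mutation_positions), relax_radius)
    rng = np.random.default_rng(seed)

    scores: list[float] = []
    best_coords = flat.coords
    best_score = np.inf
    empty = False
    n_jitter = int(flat.jitter_mask.sum())
    for _ in range(n_samples):
        coords = flat.coords
        if perturb_sigma > 0 and n_jitter:
            coords = coords.copy()
            coords[flat.jitter_mask] += rng.normal(0.0, perturb_sigma, (n_jitter, 3))
        score = _pair_score(flat, coords, w)
        if score is None:
            score, empty = 0.0, True
        scores.append(score)
        if score < best_score:
            best_score = score
            best_coords = coords
    if empty:
        _warnings.warn("no cross-group atom pairs within the pair cutoff: "
                       "empty interface scored as 0", stacklevel=2)

    best_assembly = assembly.copy()
    k = 0
    # traversal must mirror _flatten: group-major, then chains, residues, atoms
    for group in best_assembly.groups():
        for chain in best_assembly.chains_in_group(group):
            for res in chain.residues:
                for atom in res.heavy_atoms():
                    atom.coords = best_coords[k].copy()
                    k += 1
    return scores, best_assembly


# ---------------------------------------------------------------------------
# The screen
# ---------------------------------------------------------------------------

@dataclass
class DesignCandidate:
    index: int
    mutations: tuple[MutationSite, ...]
    sample_scores: list[float]
    best_score: float
    interface_hbonds: int | None = None
    rank: int | None = None

    @property
    def label(self) -> str:
        return "+".join(m.label for m in self.mutations) or "wild-type"

    def to_dict(self) -> dict:
        return {"index": self.index, "label": self.label,
                "mutations": [m.label for m in self.mutations],
                "best_score": self.best_score, "rank": self.rank,
                "interface_hbonds": self.interface_hbonds,
                "sample_scores": [round(s, 6) for s in self.sample_scores]}


@dataclass
class ScreenReport:
    candidates: list[DesignCandidate]
    finalists: list[int]          # candidate indices, rank order
    selected: int                 # candidate index
    seed: int
    config: dict = field(default_factory=dict)

    @property
    def selected_candidate(self) -> DesignCandidate:
        return next(c for c in self.candidates if c.index == self.selected)

    def to_dict(self) -> dict:
        return {"seed": self.seed, "config": self.config,
                "selected": self.selected,
                "selected_label": self.selected_candidate.label,
                "finalists": self.finalists,
                "candidates": [c.to_dict() for c in self.candidates]}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"

    def ranking_tsv(self) -> str:
        lines = ["rank\tindex\tlabel\tbest_score\tinterface_hbonds"]
        for cand in sorted(self.candidates, key=lambda c: c.rank):
            hb = "" if cand.interface_hbonds is None else str(cand.interface_hbonds)
            lines.append(f"{cand.rank}\t{cand.index}\t{cand.label}\t"
                         f"{cand.best_score:.6f}\t{hb}")
        return "\n".join(lines) + "\n"


def count_interface_hbonds(assembly: AssemblyModel,
                           cutoff: float = HBOND_CUTOFF) -> int:
    """Total hydrogen bonds across every pair of partition groups."""
    groups = assembly.groups()
    total = 0
    for gi in range(len(groups)):
        for gj in range(gi + 1, len(groups)):
            total += len(hydrogen_bonds(assembly, groups[gi], groups[gj], cutoff))
    return total


def run_screen(subunit: AssemblyModel, sites: list[MutationSite],
               symdef: SymmetryDefinition, seed: int = 0,
               n_samples: int = 50, n_finalists: int = 5,
               perturb_sigma: float = 0.3, relax_radius: float = 12.0,
               weights: ScoreWeights | None = None,
               group_labels: list[str] | None = None) -> ScreenReport:
    """Enumerate, build, score, rank, and select interface mutants.

    Mutants are ranked by their best (minimum) sample score; the top
    ``n_finalists`` are assessed by interface hydrogen-bond count on their
    best sample.  Selection: most H-bonds, ties broken by better score, then
    lower enumeration index.  A pure function of (inputs, seed).
    """
    w = weights or ScoreWeights()
    subsets = enumerate_mutants(sites)
    child_seeds = np.random.SeedSequence(seed).generate_state(len(subsets))

    candidates: list[DesignCandidate] = []
    best_assemblies: dict[int, AssemblyModel] = {}
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # empty wild-type interfaces are expected
        for idx, subset in enumerate(subsets):
            assembly = build_mutant_assembly(subunit, subset, symdef, group_labels)
            positions = {m.position for m in subset}
            scores, best = surrogate_score(
                assembly, perturb_sigma, n_samples, int(child_seeds[idx]),
                positions, relax_radius, w)
            candidates.append(DesignCandidate(idx, subset, scores, min(scores)))
            best_assemblies[idx] = best

    order = sorted(candidates, key=lambda c: (c.best_score, c.index))
    for rank, cand in enumerate(order, start=1):
        cand.rank = rank
    finalists = order[:min(n_finalists, len(order))]
    for cand in finalists:
        cand.interface_hbonds = count_interface_hbonds(best_assemblies[cand.index])
    selected = min(finalists,
                   key=lambda c: (-c.interface_hbonds, c.best_score, c.index))

    config = {"n_samples": n_samples, "n_finalists": n_finalists,
              "perturb_sigma": perturb_sigma, "relax_radius": relax_radius,
              "weights": w.to_dict(),
              "sites": [s.label for s in sites]}
    report = ScreenReport(candidates, [c.index for c in finalists],
                          selected.index, seed, config)
    report._best_assemblies = {c.index: best_assemblies[c.index] for c in finalists}
    return report
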