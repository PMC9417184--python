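"""Synthetic fixtures: coarse homomeric assemblies with exact point-group
symmetry, noisy scattering profiles, homolog pairs with planted interface
differences, and a deterministic dimer design fixture.

Subunits are chains of pseudo-residues — one CA bead plus (except glycine)
one side-chain pseudo-atom whose element encodes polarity — random-packed in
a sphere.  Assemblies are built by applying exact rotation groups to a
pre-offset subunit, so the generating transforms are recoverable to
numerical precision.  Every generator is a pure function of its parameters
and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .design import MutationSite, mutate_subunit
from .interface import DifferingSite, template_interface_positions
from .saxs import SAXSProfile, debye_profile
from .structure import (AssemblyModel, Atom, Chain, ONE_TO_THREE, Residue,
                        SIDECHAIN_CENTROID_DISTANCE, sidechain_element)
from .symmetry import RigidTransform, SymmetryDefinition, apply_symmetry

_AA20 = sorted(ONE_TO_THREE)
_MIN_SEPARATION = 3.5   # A between packed CA beads
_CLASH_DISTANCE = 2.5   # A minimum allowed cross-chain heavy-atom distance
_MAX_SIDECHAIN = max(SIDECHAIN_CENTROID_DISTANCE.values())

DEFAULT_Q_GRID = np.linspace(0.01, 0.46, 120)  # instrument-like range, A^-1


@dataclass
class SyntheticSpec:
    subunit_beads: int = 60
    subunit_radius: float = 12.0       # A
    point_group: str = "D3"            # C1 | C2 | D2 | D3
    tilt_angle: float = 30.0           # degrees; D2 dimer-of-dimers only
    ring_radius: float | None = None   # A; None -> clash-free default
    noise_rel: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subunit_beads < 1 or self.subunit_radius <= 0:
            raise ValueError("subunit_beads and subunit_radius must be positive")
        if not 0.0 <= self.noise_rel <= 0.5:
            raise ValueError("noise_rel must be within [0, 0.5]")
        if self.point_group not in ("C1", "C2", "D2", "D3"):
            raise ValueError(f"unknown point group {self.point_group!r}")

    def resolved_ring_radius(self) -> float:
        if self.ring_radius is not None:
            if self.ring_radius <= 0:
                raise ValueError("ring_radius must be positive")
            return self.ring_radius
        reach = self.subunit_radius + _MAX_SIDECHAIN
        if self.point_group == "D3":
            # adjacent same-height subunits sit ring*sqrt(3) apart
            return max(self.subunit_radius + 5.5,
                       (2 * reach + _CLASH_DISTANCE) / np.sqrt(3.0) + 0.3)
        return self.subunit_radius + 5.5


def _rz(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


_C2X = np.diag([1.0, -1.0, -1.0])


def make_subunit(spec: SyntheticSpec) -> AssemblyModel:
    """One chain of pseudo-residues random-packed in a sphere.

    CA beads keep a minimum separation of 3.5 A; side-chain beads sit at the
    residue-type centroid distance, radially outward.  The all-atom centroid
    is moved to the origin.
    """
    # pack inside a margin-reduced sphere so the post-centering subunit still
    # honours subunit_radius (the clash-free assembly spacing relies on it)
    pack_radius = spec.subunit_radius - 1.5
    if pack_radius <= 0:
        raise ValueError("subunit_radius too small for packing margin")
    max_tries = 300 * spec.subunit_beads
    for attempt in range(20):
        seed = np.random.SeedSequence((spec.seed, attempt)).generate_state(1)[0]
        rng = np.random.default_rng(seed)
        buf = np.empty((spec.subunit_beads, 3))
        count = 0
        tries = 0
        while count < spec.subunit_beads and tries <= max_tries:
            tries += 1
            p = rng.uniform(-pack_radius, pack_radius, 3)
            if p @ p > pack_radius ** 2:
                continue
            if count and np.min(np.einsum("ij,ij->i", buf[:count] - p,
                                          buf[:count] - p)) < _MIN_SEPARATION ** 2:
                continue
            buf[count] = p
            count += 1
        if count < spec.subunit_beads:
            continue
        points = list(buf)

        residues = []
        for i, p in enumerate(points):
            aa = _AA20[rng.integers(len(_AA20))]
            atoms = [Atom("CA", "C", p.copy())]
            dist = SIDECHAIN_CENTROID_DISTANCE[aa]
            if dist > 0:
                norm = np.linalg.norm(p)
                direction = p / norm if norm > 1e-9 else np.array([0.0, 0.0, 1.0])
                atoms.append(Atom("SC", sidechain_element(aa), p + dist * direction))
            residues.append(Residue(i + 1, ONE_TO_THREE[aa], "", atoms))

        model = AssemblyModel([Chain("A", residues)])
        centroid = model.coordinates().mean(axis=0)
        for _, _, atom in model.iter_atoms():
            atom.coords = atom.coords - centroid
        ca_radii = [np.linalg.norm(r.atoms[0].coords) for r in residues]
        if max(ca_radii) > spec.subunit_radius:
            continue  # centring pushed a bead past the declared radius
        model.validate()
        return model
    raise RuntimeError(
        f"packing failed for {spec.subunit_beads} beads in radius "
        f"{spec.subunit_radius}; increase subunit_radius")


def _group_transforms(spec: SyntheticSpec) -> tuple[list[RigidTransform],
                                                    np.ndarray, list[str]]:
    """(transforms, subunit pre-offset, per-copy group labels)."""
    ring = spec.resolved_ring_radius()
    h = spec.subunit_radius + 5.5
    tau = np.deg2rad(spec.tilt_angle)
    eye = RigidTransform.identity()
    if spec.point_group == "C1":
        return [eye], np.zeros(3), ["subA"]
    if spec.point_group == "C2":
        return ([eye, RigidTransform(_rz(np.pi), np.zeros(3))],
                np.array([ring, 0.0, 0.0]), ["subA", "subB"])
    if spec.point_group == "D2":
        mats = [np.eye(3), _rz(np.pi), _rz(tau) @ _C2X, _rz(np.pi + tau) @ _C2X]
        return ([RigidTransform(m, np.zeros(3)) for m in mats],
                np.array([ring, 0.0, h]),
                ["dimerA", "dimerA", "dimerB", "dimerB"])
    # D3: three vertical dimers at 120 degrees around z
    mats = []
    for k in range(3):
        mats.append(_rz(2 * np.pi * k / 3))
        mats.append(_rz(2 * np.pi * k / 3) @ _C2X)
    labels = ["dimerA", "dimerA", "dimerB", "dimerB", "dimerC", "dimerC"]
    return ([RigidTransform(m, np.zeros(3)) for m in mats],
            np.array([ring, 0.0, h]), labels)


def _check_clashes(assembly: AssemblyModel) -> None:
    coords, chain_idx = [], []
    for ci, chain in enumerate(assembly.chains):
        for res in chain.residues:
            for atom in res.heavy_atoms():
                coords.append(atom.coords)
                chain_idx.append(ci)
    coords = np.vstack(coords)
    chain_idx = np.asarray(chain_idx)
    pairs = cKDTree(coords).query_pairs(_CLASH_DISTANCE, output_type="ndarray")
    if pairs.size and np.any(chain_idx[pairs[:, 0]] != chain_idx[pairs[:, 1]]):
        raise ValueError(
            f"inter-subunit clash (< {_CLASH_DISTANCE} A); increase ring_radius")


def make_assembly(spec: SyntheticSpec) -> tuple[AssemblyModel, SymmetryDefinition]:
    """Exact point-group assembly plus the generating symmetry definition.

    C2: two copies related by a two-fold about z.  D3: three vertical dimers
    around z.  D2 (dimer-of-dimers): two C2 dimers whose two-fold axes are
    tilted by ``tilt_angle`` (0 degrees recovers the parallel, octamer-like
    stacking).  The subunit is pre-offset so the first transform is the
    identity and the returned transforms generate the assembly exactly.
    """
    subunit = make_subunit(spec)
    transforms, offset, labels = _group_transforms(spec)
    for _, _, atom in subunit.iter_atoms():
        atom.coords = atom.coords + offset
    symdef = SymmetryDefinition(transforms, spec.point_group, "A")
    assembly = apply_symmetry(subunit, symdef, labels)
    _check_clashes(assembly)
    return assembly, symdef


def offset_subunit(spec: SyntheticSpec) -> AssemblyModel:
    """The pre-offset reference subunit used by :func:`make_assembly`."""
    subunit = make_subunit(spec)
    _, offset, _ = _group_transforms(spec)
    for _, _, atom in subunit.iter_atoms():
        atom.coords = atom.coords + offset
    return subunit


def make_noisy_profile(model: AssemblyModel, q_grid: np.ndarray | None = None,
                       noise_rel: float = 0.02, seed: int = 0,
                       granularity: str = "residue",
                       label: str = "synthetic") -> SAXSProfile:
    """Debye profile with multiplicative Gaussian noise.

    sigma is set to the true noise level ``noise_rel * I``; ``noise_rel=0``
    returns the exact theoretical curve.
    """
    q = DEFAULT_Q_GRID if q_grid is None else np.asarray(q_grid, dtype=float)
    theo = debye_profile(model, q, granularity, label)
    if noise_rel == 0:
        return theo
    rng = np.random.default_rng(seed)
    sigma = noise_rel * theo.intensity
    noisy = theo.intensity + rng.normal(size=q.size) * sigma
    return SAXSProfile(q, noisy, sigma, label)


# ---------------------------------------------------------------------------
# Homolog pair with planted interface differences
# ---------------------------------------------------------------------------

@dataclass
class HomologPair:
    template: AssemblyModel
    symdef: SymmetryDefinition
    candidate_seq: str
    planted_interface_sites: list[DifferingSite]
    planted_other_sites: list[DifferingSite] = field(default_factory=list)


_PLANT_GAP = 4.5  # A, cross-subunit CA-CA distance of planted interface beads


def _plant_geometry(spec: SyntheticSpec, k: int,
                    z_shift: float) -> list[tuple[np.ndarray, np.ndarray]]:
    """Positions (and away-from-partner directions) of planted interface
    beads for the reference subunit, in the pre-offset assembly frame.

    Beads are placed across the transform pairing the reference subunit with
    a neighbouring group so each bead's symmetry image sits exactly
    ``_PLANT_GAP`` away: for an involution (C2, D2) at half the gap from the
    two-fold axis; for the D3 ring as two bead sets facing the two
    neighbouring dimers.
    """
    _, offset, _ = _group_transforms(spec)
    spread = (np.arange(k) - (k - 1) / 2) * 4.0 + z_shift
    out: list[tuple[np.ndarray, np.ndarray]] = []
    if spec.point_group == "C2":
        # partner via Rz(pi); beads at half-gap from the z axis
        for s in spread:
            pos = np.array([_PLANT_GAP / 2, 0.0, s])
            out.append((pos, np.array([1.0, 0.0, 0.0])))
    elif spec.point_group == "D2":
        # partner via Rz(tau)C2x: a two-fold about an in-plane axis
        tau = np.deg2rad(spec.tilt_angle)
        axis = np.array([np.cos(tau / 2), np.sin(tau / 2), 0.0])
        mid = (offset @ axis) * axis  # projection of the subunit centre
        for s in spread:
            pos = mid + np.array([0.0, 0.0, _PLANT_GAP / 2]) + axis * s
            out.append((pos, np.array([0.0, 0.0, 1.0])))
    elif spec.point_group == "D3":
        # two bead sets, one toward each neighbouring dimer on the ring
        for rot in (_rz(2 * np.pi / 3), _rz(4 * np.pi / 3)):
            centre_n = rot @ offset
            u = centre_n - offset
            half = np.linalg.norm(u) / 2
            u = u / (2 * half)
            for s in spread:
                pos = offset + u * (half - _PLANT_GAP / 2) + np.array([0.0, 0.0, s])
                out.append((pos, -u))
    else:
        raise ValueError(f"no interfaces to plant for point group {spec.point_group}")
    return out


def make_homolog_pair(spec: SyntheticSpec, n_interface_diffs: int = 7,
                      n_other_diffs: int = 7,
                      seed: int | None = None) -> HomologPair:
    """A template assembly and a homologous candidate sequence differing at
    exactly ``n_interface_diffs`` interfacial positions of the template's
    first chain (plus ``n_other_diffs`` non-interfacial differences).

    The interfacial positions are planted: extra beads added to the subunit
    across the inter-subunit two-folds at an exact cross-subunit distance
    (inside the proximity criterion, outside the clash radius), so the
    ground truth holds for every seed.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    transforms, offset, labels = _group_transforms(spec)

    for attempt in range(5):
        subunit = make_subunit(spec)
        for _, _, atom in subunit.iter_atoms():
            atom.coords = atom.coords + offset
        chain = subunit.chains[0]
        n0 = len(chain.residues)
        planted = _plant_geometry(spec, n_interface_diffs, z_shift=1.3 * attempt)
        plant_positions = []
        for idx, (pos, away) in enumerate(planted):
            aa = _AA20[rng.integers(len(_AA20))]
            atoms = [Atom("CA", "C", pos.copy())]
            dist = SIDECHAIN_CENTROID_DISTANCE[aa]
            if dist > 0:
                atoms.append(Atom("SC", sidechain_element(aa), pos + dist * away))
            chain.residues.append(Residue(n0 + idx + 1, ONE_TO_THREE[aa], "", atoms))
            if idx < n_interface_diffs:   # mutate only the first bead set
                plant_positions.append(n0 + idx + 1)
        symdef = SymmetryDefinition([t for t in transforms], spec.point_group, "A")
        template = apply_symmetry(subunit, symdef, labels)
        try:
            _check_clashes(template)
            break
        except ValueError:
            if attempt == 4:
                raise
            continue

    chain = template.chains[0]
    interfacial = template_interface_positions(template, chain.chain_id)
    missing = [p for p in plant_positions if p not in interfacial]
    if missing:
        raise RuntimeError(f"planted positions {missing} not detected as interfacial")
    residues = chain.sorted_residues()
    all_positions = [r.seq_id for r in residues]
    non_interfacial = [p for p in all_positions if p not in interfacial]
    if len(non_interfacial) < n_other_diffs:
        raise ValueError("not enough non-interfacial residues for planted differences")

    pick_other = sorted(rng.choice(non_interfacial, n_other_diffs, replace=False))
    by_pos = {r.seq_id: r for r in residues}
    seq = {r.seq_id: r.aa_type for r in residues}
    planted_if, planted_other = [], []
    for positions, bucket in ((plant_positions, planted_if), (pick_other, planted_other)):
        for pos in positions:
            old = by_pos[pos].aa_type
            new = _AA20[rng.integers(len(_AA20))]
            while new == old:
                new = _AA20[rng.integers(len(_AA20))]
            seq[pos] = new
            bucket.append(DifferingSite(int(pos), old, new))
    candidate_seq = "".join(seq[p] for p in all_positions)
    return HomologPair(template, symdef, candidate_seq, planted_if, planted_other)


# ---------------------------------------------------------------------------
# Deterministic dimer design fixture
# ---------------------------------------------------------------------------

@dataclass
class DesignFixture:
    template: AssemblyModel          # C2 assembly with the designed residues
    candidate_subunit: AssemblyModel  # glycines at the design sites, template frame
    symdef: SymmetryDefinition
    sites: list[MutationSite]
    candidate_seq: str
    template_seq: str


def make_design_fixture(n_sites: int = 7, n_scaffold: int = 17,
                        tip_gap: float = 3.05) -> DesignFixture:
    """A hand-laid-out C2 fixture where each design mutation plants exactly
    one cross-interface hydrogen bond.

    The candidate subunit carries glycines at the design sites; mutating a
    site to glutamine places a polar side-chain bead whose two-fold image
    sits ``tip_gap`` A away, inside the hydrogen-bond window and outside the
    clash radius.  Geometry is solved so the all-sites mutant is the known
    screen optimum.
    """
    if n_sites < 1 or n_scaffold < 3:
        raise ValueError("need at least one site and three scaffold residues")
    L = SIDECHAIN_CENTROID_DISTANCE["Q"]
    tip_y = 0.6
    tip_x = float(np.sqrt((tip_gap / 2) ** 2 - tip_y ** 2))
    z_vals = (np.arange(n_sites) - (n_sites - 1) / 2) * 4.0
    tips = np.column_stack([np.full(n_sites, tip_x),
                            np.full(n_sites, tip_y), z_vals])

    # scaffold block well behind the interface, on the +x side
    grid = []
    for x in (16.0, 20.0, 24.0):
        for y in (-4.0, 0.0, 4.0):
            for z in (-8.0, 0.0, 8.0):
                grid.append((x, y, z))
    scaffold = np.array(grid[:n_scaffold])
    if scaffold.shape[0] < n_scaffold:
        raise ValueError("scaffold grid too small")

    # fixed-point solve: CA = tip - L * unit(CA - centroid), with the
    # centroid recomputed from the candidate subunit (site CAs + scaffold)
    site_ca = tips - np.array([L, 0.0, 0.0])
    for _ in range(30):
        scaffold_atoms = np.vstack([scaffold, scaffold + np.array([1.5, 0.0, 0.0])])
        centroid = np.vstack([site_ca, scaffold_atoms]).mean(axis=0)
        u = site_ca - centroid
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        site_ca = tips - L * u

    residues: list[Residue] = []
    for i in range(n_sites):
        residues.append(Residue(i + 1, "GLY", "", [Atom("CA", "C", site_ca[i])]))
    for j in range(n_scaffold):
        ca = scaffold[j]
        residues.append(Residue(n_sites + j + 1, "ALA", "", [
            Atom("CA", "C", ca.copy()),
            Atom("SC", "C", ca + np.array([1.5, 0.0, 0.0]))]))
    candidate_subunit = AssemblyModel([Chain("A", residues)])
    candidate_subunit.validate()

    symdef = SymmetryDefinition(
        [RigidTransform.identity(), RigidTransform(_rz(np.pi), np.zeros(3))],
        "C2", "A")
    sites = [MutationSite(i + 1, "G", "Q") for i in range(n_sites)]
    template_subunit = mutate_subunit(candidate_subunit, tuple(sites))
    template = apply_symmetry(template_subunit, symdef, ["subA", "subB"])
    _check_clashes(template)

    candidate_seq = "G" * n_sites + "A" * n_scaffold
    template_seq = "Q" * n_sites + "A" * n_scaffold
    return DesignFixture(template, candidate_subunit, symdef, sites,
                         candidate_seq, template_seq)
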