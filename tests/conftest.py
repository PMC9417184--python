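"""Shared fixtures: a hand-written toy PDB, synthetic assemblies, and a
uniform-sphere bead model used by the scattering tests."""

import numpy as np
import pytest

from oligoshift.structure import AssemblyModel, Atom, Chain, Residue
from oligoshift.synthetic import (SyntheticSpec, make_assembly,
                                  make_design_fixture, make_homolog_pair)

TOY_PDB = """\
REMARK 400 GROUP left CHAINS A
REMARK 400 GROUP right CHAINS B
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00 20.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00 20.00           C
ATOM      3  C   GLY A   1       2.000   1.400   0.000  1.00 20.00           C
ATOM      4  O   GLY A   1       1.300   2.400   0.000  1.00 20.00           O
ATOM      5  N   ALA A   2       3.300   1.500   0.000  1.00 20.00           N
ATOM      6  CA AALA A   2       4.000   2.800   0.000  0.60 20.00           C
ATOM      7  CA BALA A   2       4.100   2.900   0.100  0.40 20.00           C
ATOM      8  CB  ALA A   2       5.500   2.600   0.000  1.00 20.00           C
HETATM    9  SE  MSE B   1      10.000   0.000   0.000  1.00 20.00          SE
HETATM   10  CA  MSE B   1      11.000   0.500   0.000  1.00 20.00           C
ATOM     11  CA  ARG B   2      12.500   1.000   0.000  1.00 20.00           C
ATOM     12 NH1  ARG B   2      14.000   1.500   0.000  1.00 20.00           N
TER
HETATM   13  P1  CAP B 501      20.000  20.000  20.000  1.00 30.00           P
END
"""


@pytest.fixture
def toy_pdb(tmp_path):
    path = tmp_path / "toy.pdb"
    path.write_text(TOY_PDB)
    return path


def single_atom_chain(chain_id, res_name, atom_name, element, xyz, seq_id=1):
    return Chain(chain_id, [Residue(seq_id, res_name, "",
                                    [Atom(atom_name, element, np.array(xyz, float))])])


def two_group_model(chains_a, chains_b):
    """Model whose partition splits the given chains into groups a / b."""
    partition = {c.chain_id: "a" for c in chains_a}
    partition.update({c.chain_id: "b" for c in chains_b})
    return AssemblyModel(list(chains_a) + list(chains_b), partition)


@pytest.fixture(scope="session")
def d3_assembly():
    return make_assembly(SyntheticSpec(point_group="D3", seed=1))


@pytest.fixture(scope="session")
def c2_assembly():
    return make_assembly(SyntheticSpec(point_group="C2", seed=1))


@pytest.fixture(scope="session")
def homolog_pair():
    return make_homolog_pair(SyntheticSpec(point_group="D3", seed=3),
                             n_interface_diffs=7, n_other_diffs=7)


@pytest.fixture(scope="session")
def design_fixture():
    return make_design_fixture()


@pytest.fixture(scope="session")
def sphere_model():
    """Uniform solid-sphere bead model, radius 30 A, 3 A grid spacing."""
    radius = 30.0
    grid = np.arange(-radius, radius + 1e-9, 3.0)
    points = [(x, y, z) for x in grid for y in grid for z in grid
              if x * x + y * y + z * z <= radius * radius]
    residues = [Residue(i + 1, "GLY", "", [Atom("CA", "C", np.array(p))])
                for i, p in enumerate(points)]
    return AssemblyModel([Chain("A", residues)]), radius


@pytest.fixture(scope="session")
def sphere_guinier(sphere_model):
    """Guinier fit of the sphere's Debye profile on a log-dense low-q grid."""
    from oligoshift.saxs import debye_profile, guinier_fit
    model, _ = sphere_model
    profile = debye_profile(model, np.geomspace(0.003, 0.08, 60), "residue")
    return guinier_fit(profile)
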