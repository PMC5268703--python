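"""Shared fixtures: tiny hand-written structures and synthetic ensembles."""

from __future__ import annotations

import numpy as np
import pytest

from helixbridge import (
    AnalysisConfig,
    SyntheticEnsembleConfig,
    generate_ensemble,
    load_generated_ensemble,
)
from helixbridge.io_core import Atom, StructureFrame, Topology

# A minimal 3-residue PDB (ASP-ARG-GLY) with complete charged side chains,
# used for parsing round-trips and selection tests.
TINY_PDB = """\
HELIX    1   1 ASP A    1  GLY A    3  1                                   3
ATOM      1  N   ASP A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ASP A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  CB  ASP A   1       2.009   1.421   0.000  1.00  0.00           C
ATOM      4  OD1 ASP A   1       3.100   1.500   0.600  1.00  0.00           O
ATOM      5  OD2 ASP A   1       1.500   2.400  -0.600  1.00  0.00           O
ATOM      6  N   ARG A   2       2.200  -1.000   0.500  1.00  0.00           N
ATOM      7  CA  ARG A   2       3.640  -1.200   0.550  1.00  0.00           C
ATOM      8  NE  ARG A   2       5.000   2.000   1.000  1.00  0.00           N
ATOM      9  NH1 ARG A   2       6.100   2.500   1.400  1.00  0.00           N
ATOM     10  NH2 ARG A   2       5.200   3.300   0.200  1.00  0.00           N
ATOM     11  N   GLY A   3       4.300  -2.300   1.100  1.00  0.00           N
ATOM     12  CA  GLY A   3       5.700  -2.500   1.200  1.00  0.00           C
END
"""

# One atom with two altlocs: B has the higher occupancy and must win.
ALTLOC_PDB = """\
ATOM      1  N   ASP A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA AASP A   1       1.000   0.000   0.000  0.40  0.00           C
ATOM      3  CA BASP A   1       2.000   0.000   0.000  0.60  0.00           C
END
"""


@pytest.fixture
def tiny_pdb(tmp_path):
    path = tmp_path / "tiny.pdb"
    path.write_text(TINY_PDB)
    return path


@pytest.fixture
def altloc_pdb(tmp_path):
    path = tmp_path / "altloc.pdb"
    path.write_text(ALTLOC_PDB)
    return path


def make_structure(atom_specs, coords) -> StructureFrame:
    """Build an in-memory structure from (name, resname, resnum, chain) specs."""
    atoms = [
        Atom(name=n, element=n[0], residue_name=rn, residue_number=ri, chain_id=ch)
        for n, rn, ri, ch in atom_specs
    ]
    return StructureFrame(Topology(atoms), np.asarray(coords, dtype=float))


def charged_pair_structure(o_coords, n_coords) -> StructureFrame:
    """ASP 1 / ARG 2 pseudo-structure with given O and N positions."""
    o_coords = np.asarray(o_coords, dtype=float)
    n_coords = np.asarray(n_coords, dtype=float)
    specs = [("OD1", "ASP", 1, "A"), ("OD2", "ASP", 1, "A")][: len(o_coords)]
    specs += [("NE", "ARG", 2, "A"), ("NH1", "ARG", 2, "A"), ("NH2", "ARG", 2, "A")][
        : len(n_coords)
    ]
    return make_structure(specs, np.vstack([o_coords, n_coords]))


@pytest.fixture(scope="session")
def wt_dataset(tmp_path_factory):
    """Default synthetic ensemble: 4 replicas x 500 frames, H9-H10 at 47.6°."""
    out = tmp_path_factory.mktemp("synth_wt")
    config = SyntheticEnsembleConfig(seed=1)
    manifest = generate_ensemble(config, out)
    ensemble, _ = load_generated_ensemble(out)
    return ensemble, manifest, out


@pytest.fixture(scope="session")
def shifted_dataset(tmp_path_factory):
    """Same system with the inter-helix angle moved to 49.0° (mutant-like)."""
    out = tmp_path_factory.mktemp("synth_shift")
    config = SyntheticEnsembleConfig(pair_angles=[49.0], seed=2)
    manifest = generate_ensemble(config, out)
    ensemble, _ = load_generated_ensemble(out)
    return ensemble, manifest, out


@pytest.fixture
def no_discard() -> AnalysisConfig:
    return AnalysisConfig(equilibration_ns=0.0)
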