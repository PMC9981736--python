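"""Shared fixtures: tiny hand-built structures and file-backed fixtures."""

from pathlib import Path

import numpy as np
import pytest

from relay.structure_io import AtomRecord, Structure

DATA_DIR = Path(__file__).resolve().parent.parent / "data" / "structures"


def atom(chain, resseq, name, xyz, resname="ALA", element=None, **kw):
    if element is None:
        element = name[0]
    return AtomRecord(
        chain=chain, resseq=resseq, icode="", resname=resname, atom=name,
        element=element, xyz=tuple(float(v) for v in xyz), **kw
    )


@pytest.fixture
def tripeptide():
    """Gly-Ala-Asp with mainchain, CB where present, and a side-chain tail."""
    atoms = [
        atom("A", 1, "N", (0, 0, 0), "GLY"),
        atom("A", 1, "CA", (1.5, 0, 0), "GLY"),
        atom("A", 1, "C", (2.2, 1.2, 0), "GLY"),
        atom("A", 1, "O", (1.7, 2.3, 0), "GLY"),
        atom("A", 2, "N", (3.5, 1.2, 0), "ALA"),
        atom("A", 2, "CA", (4.4, 2.3, 0), "ALA"),
        atom("A", 2, "C", (5.8, 1.8, 0), "ALA"),
        atom("A", 2, "O", (6.1, 0.6, 0), "ALA"),
        atom("A", 2, "CB", (4.3, 3.2, 1.2), "ALA"),
        atom("A", 3, "N", (6.7, 2.7, 0), "ASP"),
        atom("A", 3, "CA", (8.1, 2.4, 0), "ASP"),
        atom("A", 3, "C", (8.9, 3.7, 0), "ASP"),
        atom("A", 3, "O", (8.4, 4.8, 0), "ASP"),
        atom("A", 3, "CB", (8.6, 1.5, 1.1), "ASP"),
        atom("A", 3, "CG", (10.1, 1.3, 1.1), "ASP"),
        atom("A", 3, "OD1", (10.8, 2.3, 1.3), "ASP", element="O"),
        atom("A", 3, "OD2", (10.6, 0.15, 0.9), "ASP", element="O"),
    ]
    return Structure(atoms=atoms, id="tripeptide")


@pytest.fixture
def p2_crystal():
    """One atom at (1, 0, 0) in a P 1 2 1 cell (2-fold along b)."""
    from relay.structure_io import BUNDLED_SPACEGROUP_OPS

    return Structure(
        atoms=[atom("A", 1, "CA", (1.0, 0.0, 0.0))],
        cell=(10.0, 10.0, 10.0, 90.0, 90.0, 90.0),
        spacegroup="P 1 2 1",
        symmetry_ops=list(BUNDLED_SPACEGROUP_OPS["P 1 2 1"]),
        id="p2toy",
    )


def require_accession(name: str) -> Path:
    """Path of a locally provided deposited structure; fail the test if absent.

    These regression tests need coordinate files that cannot be fetched in an
    offline environment; place <id>.pdb under data/structures/ to enable them.
    """
    path = DATA_DIR / f"{name}.pdb"
    if not path.exists():
        pytest.fail(
            f"deposited structure {name}.pdb not available: this regression "
            f"requires the coordinate file at {path} (no network access to "
            "fetch it in this environment)",
            pytrace=False,
        )
    return path
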