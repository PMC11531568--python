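"""Shared fixtures: toy structures and simulation defaults."""

from __future__ import annotations

import numpy as np
import pytest

from fretarch.avsim import load_structure
from fretarch.simulate import make_toy_structure


def atom(name, chain, res_id, coord, element="C", res_name="UNK"):
    return {
        "name": name,
        "element": element,
        "chain": chain,
        "res_id": res_id,
        "res_name": res_name,
        "coord": coord,
    }


@pytest.fixture
def lone_site():
    """A single cysteine-like CB attachment atom at the origin."""
    _, text = make_toy_structure(
        [atom("CB", "A", 1, [0.0, 0.0, 0.0], res_name="CYS")]
    )
    return load_structure(text)


@pytest.fixture
def wall_site():
    """Attachment atom 1 Å in front of a dense planar wall of atoms."""
    atoms = [atom("CB", "A", 1, [0.0, 0.0, 0.0], res_name="CYS")]
    k = 0
    for x in np.arange(-18.0, 18.01, 1.5):
        for y in np.arange(-18.0, 18.01, 1.5):
            k += 1
            atoms.append(atom("X", "B", 100 + k, [x, y, -1.0], res_name="WAL"))
    _, text = make_toy_structure(atoms)
    return load_structure(text)


@pytest.fixture
def toy_dimer():
    """A mirror-symmetric two-protomer toy with two labelling sites each.

    Chains A and B carry CYS-like sites at residues 64 ("H") and 280
    ("T"); the assembly is symmetric under reflection through the x = 30
    plane, so mixed-pair predictions must be symmetric.
    """
    atoms = []
    for chain, x0, sgn in (("A", 0.0, 1.0), ("B", 60.0, -1.0)):
        for res, y0 in ((64, 0.0), (280, 30.0)):
            atoms.append(
                atom("CA", chain, res, [x0 + sgn * 1.5, y0, 0.0], res_name="CYS")
            )
            atoms.append(atom("CB", chain, res, [x0, y0, 0.0], res_name="CYS"))
        # a small body between the sites so each protomer has bulk
        for i, y in enumerate(np.arange(6.0, 25.0, 3.0)):
            atoms.append(
                atom("CA", chain, 100 + i, [x0 + sgn * 3.0, y, 0.0], res_name="GLY")
            )
    _, text = make_toy_structure(atoms)
    return load_structure(text)
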