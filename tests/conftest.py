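"""Shared fixtures and builders for the test suite.

All structural fixtures are generated programmatically — either through the
synthetic generators (which carry their ground truth) or by explicit
construction where a test needs hand-computable geometry.
"""

from __future__ import annotations

import numpy as np
import pytest

from ringstat.structure_io import AtomRecord, StructureModel

_ELEMENT_GUESS = {"N": "N", "O": "O", "S": "S", "C": "C", "H": "H"}


def atom(
    chain: str,
    resnum: int,
    resname: str,
    name: str,
    pos,
    element: str | None = None,
    **kw,
) -> AtomRecord:
    """Terse AtomRecord builder; element inferred from the atom-name head."""
    if element is None:
        element = _ELEMENT_GUESS.get(name[0], "C")
    return AtomRecord(
        chain_id=chain,
        residue_number=resnum,
        residue_name=resname,
        atom_name=name,
        element=element,
        position=tuple(float(c) for c in pos),
        **kw,
    )


def model_of(*atoms: AtomRecord, identifier: str = "test") -> StructureModel:
    return StructureModel(identifier=identifier, atoms=list(atoms))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
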