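"""Shared fixtures: handcrafted PDB text and small synthetic inputs."""

from __future__ import annotations

import numpy as np
import pytest

from traversal import synthgen


def atom_line(
    serial: int,
    resseq: int,
    x: float,
    y: float,
    z: float,
    altloc: str = " ",
    occupancy: float = 1.0,
    record: str = "ATOM",
    name: str = " CA ",
    resname: str = "ALA",
) -> str:
    return (
        f"{record:<6s}{serial:5d} {name}{altloc}{resname} A{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}  0.00           C"
    )


@pytest.fixture
def three_residue_pdb() -> str:
    lines = [
        atom_line(1, 1, 0.0, 0.0, 0.0),
        atom_line(2, 2, 3.8, 0.0, 0.0),
        atom_line(3, 3, 7.6, 0.0, 0.0),
        "END",
    ]
    return "\n".join(lines) + "\n"


@pytest.fixture
def compact_chain():
    return synthgen.gen_chain(30, compactness=0.8, seed=11)


@pytest.fixture
def random_maps():
    """Twelve random-chain contact maps of a 25-residue target."""
    from traversal.contactspace import contact_map

    return [
        contact_map(synthgen.gen_chain(25, 0.6, seed=100 + i)) for i in range(12)
    ]
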