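"""Packaged structure fixtures for the thiosemicarbazone series."""

from __future__ import annotations

from importlib import resources

from .molgraph import MolecularGraph, parse_structure

#: Printed molecular formulas of the synthesized series (HRMS section).
COMPOUND_FORMULAS = {
    "5a": "C28H26Cl2N4O3S2",
    "5b": "C28H27BrN4O3S2",
    "5c": "C28H28N4O3S2",
    "5d": "C29H30N4O4S2",
    "5e": "C28H27ClN4O3S2",
    "5f": "C26H32N4O3S2",
    "5g": "C26H32N4O3S3",
    "5h": "C29H27F3N4O3S2",
    "5i": "C28H27ClN4O3S2",
    "5j": "C30H32N4O3S2",
    "5k": "C29H30N4O4S2",
    "5l": "C28H27FN4O3S2",
    "5m": "C23H26N4O3S2",
    "5n": "C22H24N4O3S2",
    "5o": "C28H27N5O5S2",
    "5p": "C28H34N4O3S2",
    "5q": "C29H29ClN4O3S2",
    "5r": "C29H30N4O3S2",
    "5s": "C29H30N4O3S2",
    "5t": "C30H32N4O3S2",
    "5u": "C28H26Cl2N4O3S2",
}


def load_compound_structures(include_standards: bool = False) -> list[MolecularGraph]:
    """Parse the packaged structure fixture (5a-5u, optionally the standards)."""
    graphs = []
    text = (
        resources.files("thioqsar.data").joinpath("structures.smi").read_text()
    )
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        smiles, cid = line.split()
        if not include_standards and cid not in COMPOUND_FORMULAS:
            continue
        graphs.append(parse_structure(smiles, id=cid))
    return graphs
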