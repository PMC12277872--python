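"""Typed hydrogen-suppressed molecular graphs.

The descriptor engine works on heavy-atom graphs: hydrogens appear only as
per-atom counts, never as graph nodes. Structures come in as SMILES or SDF
(V2000) and are perceived with RDKit (rings, aromaticity, hybridization);
everything downstream consumes the plain :class:`MolecularGraph` container so
the counting semantics stay independent of the toolkit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path


class StructureError(ValueError):
    """Raised when a structure cannot be parsed or violates a precondition."""


#: IUPAC standard atomic weights (4 d.p. where defined), heavy atoms only.
ATOMIC_MASS = {
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.9984,
    "P": 30.9738,
    "S": 32.06,
    "Cl": 35.45,
    "Br": 79.904,
    "I": 126.9045,
}

_HYBRID_MAP = {
    Chem.HybridizationType.SP: "sp",
    Chem.HybridizationType.SP2: "sp2",
    Chem.HybridizationType.SP3: "sp3",
}


@dataclass(frozen=True)
class Atom:
    """One heavy atom of a hydrogen-suppressed graph."""

    element: str
    formal_charge: int
    n_hydrogens: int
    aromatic: bool
    in_ring: bool
    hybridization: str  # one of {"sp", "sp2", "sp3", "other"}
    index: int


@dataclass
class MolecularGraph:
    """Heavy-atom molecular graph with optional 3D coordinates (Å)."""

    atoms: list[Atom]
    bonds: list[tuple[int, int, float]]  # (i, j, bond order), i < j
    coords: Optional[np.ndarray] = None  # (n_atoms, 3) in Å
    name: str = ""
    _rdmol: Optional[Chem.Mol] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise StructureError(
                    f"{self.name or 'graph'}: bond ({i},{j}) references missing atom"
                )
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (n, 3):
                raise StructureError(
                    f"{self.name or 'graph'}: coords shape {self.coords.shape} "
                    f"does not match {n} atoms"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b, _ in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return out

    def translated(self, v: Sequence[float]) -> "MolecularGraph":
        if self.coords is None:
            raise StructureError(f"{self.name}: no coordinates to translate")
        return MolecularGraph(
            atoms=self.atoms,
            bonds=self.bonds,
            coords=self.coords + np.asarray(v, dtype=float),
            name=self.name,
            _rdmol=self._rdmol,
        )


def _graph_from_rdmol(mol: Chem.Mol, name: str) -> MolecularGraph:
    mol = Chem.RemoveHs(mol)
    frags = Chem.GetMolFrags(mol)
    if len(frags) != 1:
        raise StructureError(
            f"{name}: input has {len(frags)} fragments; expected one connected molecule"
        )
    atoms = []
    for a in mol.GetAtoms():
        atoms.append(
            Atom(
                element=a.GetSymbol(),
                formal_charge=a.GetFormalCharge(),
                n_hydrogens=a.GetTotalNumHs(),
                aromatic=a.GetIsAromatic(),
                in_ring=a.IsInRing(),
                hybridization="sp2"
                if a.GetIsAromatic()
                else _HYBRID_MAP.get(a.GetHybridization(), "other"),
                index=a.GetIdx(),
            )
        )
    bonds = []
    for b in mol.GetBonds():
        i, j = sorted((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        bonds.append((i, j, b.GetBondTypeAsDouble()))
    coords = None
    if mol.GetNumConformers() > 0:
        conf = mol.GetConformer()
        coords = np.array(
            [list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())]
        )
    return MolecularGraph(atoms=atoms, bonds=bonds, coords=coords, name=name, _rdmol=mol)


def parse_structure(text: str, id: str = "") -> MolecularGraph:
    """Parse a SMILES string or an SDF/MOL V2000 record into a graph.

    Hydrogens are suppressed (recorded only as counts); SDF coordinates are
    kept verbatim. Multi-fragment input is rejected.
    """
    is_sdf = "M  END" in text or "V2000" in text
    if is_sdf:
        mol = Chem.MolFromMolBlock(text, removeHs=True)
    else:
        mol = Chem.MolFromSmiles(text)
    if mol is None:
        kind = "SDF record" if is_sdf else "SMILES"
        raise StructureError(f"{id or text!r}: could not parse {kind}")
    return _graph_from_rdmol(mol, name=id)


def read_smi(path: str) -> list[MolecularGraph]:
    """Read a .smi file: whitespace-separated SMILES and id, '#' comments."""
    graphs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            smiles = parts[0]
            cid = parts[1] if len(parts) > 1 else f"line{lineno}"
            graphs.append(parse_structure(smiles, id=cid))
    return graphs


def read_sdf(path: str) -> list[MolecularGraph]:
    """Read an SDF file (V2000); molecule titles become compound ids."""
    graphs = []
    supplier = Chem.SDMolSupplier(path, removeHs=True)
    for k, mol in enumerate(supplier):
        if mol is None:
            raise StructureError(f"{path}: record {k + 1} failed to parse")
        cid = mol.GetProp("_Name") if mol.HasProp("_Name") else f"record{k + 1}"
        graphs.append(_graph_from_rdmol(mol, name=cid))
    return graphs


def bond_distance_matrix(g: MolecularGraph) -> np.ndarray:
    """All-pairs shortest-path bond counts (BFS on the heavy-atom graph)."""
    n = g.n_atoms
    if n == 0:
        return np.zeros((0, 0))
    rows, cols = [], []
    for i, j, _ in g.bonds:
        rows += [i, j]
        cols += [j, i]
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    d = shortest_path(adj, method="D", unweighted=True)
    if np.isinf(d).any():
        raise StructureError(f"{g.name}: graph is disconnected")
    return d


def center_of_mass(g: MolecularGraph) -> np.ndarray:
    """Mass-weighted mean heavy-atom position (Å), standard atomic weights."""
    if g.coords is None:
        raise StructureError(
            f"{g.name}: no 3D coordinates; call embed_3d first"
        )
    masses = np.array([ATOMIC_MASS[a.element] for a in g.atoms])
    return (masses[:, None] * g.coords).sum(axis=0) / masses.sum()


def embed_3d(g: MolecularGraph, seed: int = 42) -> MolecularGraph:
    """Generate one 3D conformer (ETKDG, deterministic per seed)."""
    if g._rdmol is None:
        raise StructureError(f"{g.name}: graph has no structure backing for embedding")
    mol = Chem.AddHs(Chem.Mol(g._rdmol))
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise StructureError(f"{g.name}: 3D embedding failed")
    mol = Chem.RemoveHs(mol)
    conf = mol.GetConformer()
    coords = np.array([list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())])
    return MolecularGraph(
        atoms=g.atoms, bonds=g.bonds, coords=coords, name=g.name, _rdmol=g._rdmol
    )


# ---------------------------------------------------------------------------
# Atom classes
# ---------------------------------------------------------------------------

Predicate = Callable[[Atom, MolecularGraph], bool]


def _is_donor(a: Atom, g: MolecularGraph) -> bool:
    # N or O bearing at least one hydrogen
    return a.element in ("N", "O") and a.n_hydrogens >= 1


def _is_acceptor(a: Atom, g: MolecularGraph) -> bool:
    # N or O with no positive charge, excluding pyrrole-type aromatic N-H
    if a.element not in ("N", "O") or a.formal_charge > 0:
        return False
    if a.element == "N" and a.aromatic and a.n_hydrogens >= 1:
        return False
    return True


def _is_hydrophobic_carbon(a: Atom, g: MolecularGraph) -> bool:
    if a.element != "C":
        return False
    return all(g.atoms[j].element == "C" for j in g.neighbors(a.index))


def default_atom_classes() -> dict[str, Predicate]:
    """The atom-class vocabulary used by the published models.

    Returned fresh each call so callers may override individual predicates
    (the donor/acceptor/hydrophobic conventions are deliberate, documented
    choices and are configurable).
    """
    return {
        "C": lambda a, g: a.element == "C",
        "Cl": lambda a, g: a.element == "Cl",
        "S": lambda a, g: a.element == "S",
        "O": lambda a, g: a.element == "O",
        "N": lambda a, g: a.element == "N",
        "notringC": lambda a, g: a.element == "C" and not a.in_ring,
        "notringS": lambda a, g: a.element == "S" and not a.in_ring,
        "sp2S": lambda a, g: a.element == "S" and a.hybridization == "sp2",
        "sp3C": lambda a, g: a.element == "C" and a.hybridization == "sp3",
        "aroC": lambda a, g: a.element == "C" and a.aromatic,
        "acc": _is_acceptor,
        "don": _is_donor,
        "Chyd": _is_hydrophobic_carbon,
    }


#: Class labels valid as descriptor source/target tokens (excludes 'com').
ATOM_CLASS_LABELS = tuple(default_atom_classes().keys())

#: Pseudo-source meaning the molecular center of mass (3D descriptors only).
COM = "com"


def classify_atom(
    g: MolecularGraph,
    i: int,
    cls: str,
    registry: Optional[dict[str, Predicate]] = None,
) -> bool:
    """Test whether atom ``i`` of ``g`` belongs to atom class ``cls``."""
    if cls == COM:
        raise ValueError("'com' is the molecular center of mass, not an atom class")
    registry = registry if registry is not None else default_atom_classes()
    if cls not in registry:
        raise KeyError(f"unknown atom class {cls!r}; valid: {sorted(registry)}")
    if not (0 <= i < g.n_atoms):
        raise IndexError(f"atom index {i} out of range for {g.n_atoms}-atom graph")
    return bool(registry[cls](g.atoms[i], g))


def class_mask(
    g: MolecularGraph,
    cls: str,
    registry: Optional[dict[str, Predicate]] = None,
) -> np.ndarray:
    """Boolean membership vector of ``cls`` over all atoms of ``g``."""
    registry = registry if registry is not None else default_atom_classes()
    if cls not in registry:
        raise KeyError(f"unknown atom class {cls!r}; valid: {sorted(registry)}")
    pred = registry[cls]
    return np.array([bool(pred(a, g)) for a in g.atoms])


def molecular_formula(g: MolecularGraph) -> str:
    """Hill-order molecular formula including suppressed hydrogens."""
    counts: dict[str, int] = {}
    n_h = 0
    for a in g.atoms:
        counts[a.element] = counts.get(a.element, 0) + 1
        n_h += a.n_hydrogens
    parts = []
    if "C" in counts:
        parts.append(("C", counts.pop("C")))
        if n_h:
            parts.append(("H", n_h))
            n_h = 0
    if n_h:
        counts["H"] = counts.get("H", 0) + n_h
    parts.extend(sorted(counts.items()))
    return "".join(f"{el}{n if n > 1 else ''}" for el, n in parts)
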