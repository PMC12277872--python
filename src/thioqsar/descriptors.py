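"""Typed atom-pair descriptor grammar and counting engine.

Two descriptor families over the heavy-atom graph:

* **occurrence** (``source_target_kB``, e.g. ``Cl_S_6B``): the number of
  target-class atoms that have at least one source-class atom within *k*
  bonds (each target atom counted once, however many sources reach it).
  With ``com`` as source (``com_sp3C_6A``) the source is the molecular
  center of mass and the cutoff is a Euclidean radius in Å.
* **frequency** (``f`` + source + target + ``kB``, e.g. ``fOS7B``): the
  number of ordered (source, target) atom pairs at *exactly* k bonds.

An atom may satisfy both classes but never pairs with itself. Frequency
names concatenate class tokens; the parser splits them greedily on the
longest known token, which uniquely resolves every name used by the
published models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .molgraph import (
    ATOM_CLASS_LABELS,
    COM,
    MolecularGraph,
    Predicate,
    bond_distance_matrix,
    center_of_mass,
    class_mask,
    default_atom_classes,
    embed_3d,
)


class DescriptorNameError(ValueError):
    """Raised for names outside the descriptor grammar."""


@dataclass(frozen=True)
class DescriptorSpec:
    """Parsed meaning of a descriptor name."""

    mode: str  # "occurrence" | "frequency"
    source_class: str  # atom class label, or "com" (occurrence/angstroms only)
    target_class: str
    distance: int
    space: str  # "bonds" | "angstroms"

    def __post_init__(self) -> None:
        if self.mode not in ("occurrence", "frequency"):
            raise DescriptorNameError(f"bad mode {self.mode!r}")
        if self.space not in ("bonds", "angstroms"):
            raise DescriptorNameError(f"bad space {self.space!r}")
        if self.space == "angstroms" and self.source_class != COM:
            raise DescriptorNameError("angstrom descriptors require source 'com'")
        if self.mode == "frequency" and self.space != "bonds":
            raise DescriptorNameError("frequency descriptors are bond-space only")
        if self.distance < 1:
            raise DescriptorNameError("distance must be a positive integer")

    @property
    def name(self) -> str:
        unit = "A" if self.space == "angstroms" else "B"
        if self.mode == "frequency":
            return f"f{self.source_class}{self.target_class}{self.distance}B"
        return f"{self.source_class}_{self.target_class}_{self.distance}{unit}"

    def describe(self) -> str:
        """Verbal rendering in the style of the model definitions."""
        if self.mode == "frequency":
            return (
                f"frequency of occurrence of {self.target_class} atoms exactly at "
                f"{self.distance} bonds from the {self.source_class} atoms"
            )
        if self.source_class == COM:
            return (
                f"occurrence of {self.target_class} atoms within {self.distance} "
                f"angstrom units from the center of mass of the molecule"
            )
        return (
            f"occurrence of {self.target_class} atoms within {self.distance} "
            f"bonds from the {self.source_class} atoms"
        )


# class tokens sorted longest-first for greedy matching
_TOKENS = sorted(ATOM_CLASS_LABELS, key=len, reverse=True)


def _split_frequency_body(body: str, name: str) -> tuple[str, str, int]:
    """Greedy longest-token split of e.g. 'notringSC7B' -> (notringS, C, 7)."""
    for src in _TOKENS:
        if not body.startswith(src):
            continue
        rest = body[len(src):]
        for tgt in _TOKENS:
            if not rest.startswith(tgt):
                continue
            tail = rest[len(tgt):]
            if tail.endswith("B") and tail[:-1].isdigit():
                return src, tgt, int(tail[:-1])
    raise DescriptorNameError(
        f"{name!r}: cannot split frequency name into class tokens; "
        f"valid tokens: {sorted(ATOM_CLASS_LABELS)}"
    )


def parse_descriptor_name(name: str) -> DescriptorSpec:
    """Parse a descriptor name into its spec; round-trips through ``.name``."""
    if not name:
        raise DescriptorNameError("empty descriptor name")
    if "_" in name:
        parts = name.split("_")
        if len(parts) != 3:
            raise DescriptorNameError(
                f"{name!r}: occurrence names are source_target_<dist>[AB]"
            )
        src, tgt, dist_tok = parts
        if not dist_tok[:-1].isdigit() or dist_tok[-1] not in ("A", "B"):
            raise DescriptorNameError(f"{name!r}: malformed distance token {dist_tok!r}")
        space = "angstroms" if dist_tok[-1] == "A" else "bonds"
        if src != COM and src not in ATOM_CLASS_LABELS:
            raise DescriptorNameError(
                f"{name!r}: unknown source class {src!r}; "
                f"valid: {sorted(ATOM_CLASS_LABELS) + [COM]}"
            )
        if tgt not in ATOM_CLASS_LABELS:
            raise DescriptorNameError(
                f"{name!r}: unknown target class {tgt!r}; "
                f"valid: {sorted(ATOM_CLASS_LABELS)}"
            )
        return DescriptorSpec("occurrence", src, tgt, int(dist_tok[:-1]), space)
    if name.startswith("f"):
        src, tgt, dist = _split_frequency_body(name[1:], name)
        return DescriptorSpec("frequency", src, tgt, dist, "bonds")
    raise DescriptorNameError(
        f"{name!r}: not a recognized descriptor name (expected 'f...' or 'a_b_kB')"
    )


def compute_descriptor(
    g: MolecularGraph,
    spec: DescriptorSpec | str,
    registry: Optional[dict[str, Predicate]] = None,
    _dmat: Optional[np.ndarray] = None,
) -> int:
    """Count one descriptor on one molecule (non-negative integer)."""
    if isinstance(spec, str):
        spec = parse_descriptor_name(spec)
    tgt = class_mask(g, spec.target_class, registry)
    if spec.space == "angstroms":
        if g.coords is None:
            raise ValueError(
                f"{g.name}: descriptor {spec.name} needs 3D coordinates; embed first"
            )
        com = center_of_mass(g)
        r = np.linalg.norm(g.coords - com, axis=1)
        return int(np.sum(tgt & (r <= spec.distance)))
    src = class_mask(g, spec.source_class, registry)
    if not src.any() or not tgt.any():
        return 0
    d = bond_distance_matrix(g) if _dmat is None else _dmat
    sub = d[np.ix_(src.nonzero()[0], tgt.nonzero()[0])]
    if spec.mode == "frequency":
        # ordered (source, target) pairs at exactly k bonds; d>0 excludes self
        return int(np.sum((sub == spec.distance) & (sub > 0)))
    reach = (sub <= spec.distance) & (sub > 0)
    return int(reach.any(axis=0).sum())


@dataclass
class DescriptorMatrix:
    """Compound x descriptor count table."""

    compound_ids: list[str]
    descriptor_names: list[str]
    values: np.ndarray  # (n_compounds, n_descriptors)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, columns=self.descriptor_names, dtype=int
        )
        df.insert(0, "compound_id", self.compound_ids)
        return df

    def to_csv(self, path: str) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def row(self, compound_id: str) -> dict[str, float]:
        i = self.compound_ids.index(compound_id)
        return dict(zip(self.descriptor_names, self.values[i]))


def compute_descriptor_matrix(
    molecules: Sequence[MolecularGraph],
    specs: Sequence[DescriptorSpec | str],
    seed: int = 42,
    registry: Optional[dict[str, Predicate]] = None,
) -> DescriptorMatrix:
    """Compute all descriptors for all molecules (rows keep input order).

    Molecules lacking coordinates are embedded with the given seed only if a
    3D (angstrom-space) descriptor is requested. Any per-molecule failure is
    re-raised naming the compound.
    """
    specs = [parse_descriptor_name(s) if isinstance(s, str) else s for s in specs]
    if not specs:
        raise ValueError("specs must be non-empty")
    needs_3d = any(s.space == "angstroms" for s in specs)
    values = np.zeros((len(molecules), len(specs)), dtype=int)
    ids = []
    for i, g in enumerate(molecules):
        try:
            if needs_3d and g.coords is None:
                g = embed_3d(g, seed=seed)
            dmat = bond_distance_matrix(g) if any(s.space == "bonds" for s in specs) else None
            for j, spec in enumerate(specs):
                values[i, j] = compute_descriptor(g, spec, registry, _dmat=dmat)
        except Exception as exc:
            raise RuntimeError(f"descriptor computation failed for {g.name!r}: {exc}") from exc
        ids.append(g.name)
    return DescriptorMatrix(ids, [s.name for s in specs], values)


def enumerate_grammar(
    max_bond_distance: int,
    max_radius: int,
    classes: Optional[Sequence[str]] = None,
) -> list[DescriptorSpec]:
    """All grammar combinations up to the given distance limits.

    Occurrence specs over every (source, target) class pair and bond distance
    1..max_bond_distance, plus center-of-mass radial specs for radii
    1..max_radius, plus frequency specs over the same bond range. With the
    full 13-class vocabulary and the default model distances this pool
    exceeds 1600 descriptors. ``max_radius=0`` omits 3D descriptors.
    """
    if max_bond_distance < 1:
        raise ValueError("max_bond_distance must be >= 1")
    if max_radius < 0:
        raise ValueError("max_radius must be >= 0")
    classes = list(classes) if classes is not None else list(ATOM_CLASS_LABELS)
    seen: dict[str, DescriptorSpec] = {}
    for src in classes:
        for tgt in classes:
            for k in range(1, max_bond_distance + 1):
                for spec in (
                    DescriptorSpec("occurrence", src, tgt, k, "bonds"),
                    DescriptorSpec("frequency", src, tgt, k, "bonds"),
                ):
                    seen.setdefault(spec.name, spec)
    for tgt in classes:
        for r in range(1, max_radius + 1):
            spec = DescriptorSpec("occurrence", COM, tgt, r, "angstroms")
            seen.setdefault(spec.name, spec)
    return list(seen.values())


def specs_to_json(specs: Sequence[DescriptorSpec], path: str) -> None:
    """Export descriptor specs for provenance."""
    payload = [
        {
            "name": s.name,
            "mode": s.mode,
            "source_class": s.source_class,
            "target_class": s.target_class,
            "distance": s.distance,
            "space": s.space,
        }
        for s in specs
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
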