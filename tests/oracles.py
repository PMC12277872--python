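"""Independent reference implementations used only by the test suite.

Each oracle deliberately uses a different algorithm from the library path it
checks: Floyd-Warshall instead of BFS, explicit normal equations instead of
lstsq, n refits instead of the hat-matrix identity, and a naive double loop
over atom pairs instead of vectorized mask arithmetic.
"""

from __future__ import annotations

import numpy as np

from thioqsar.descriptors import DescriptorSpec, parse_descriptor_name
from thioqsar.molgraph import ATOMIC_MASS, MolecularGraph, classify_atom


def floyd_warshall(n: int, edges: list[tuple[int, int]]) -> np.ndarray:
    """All-pairs shortest paths by triple relaxation."""
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i, j in edges:
        d[i, j] = d[j, i] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def graph_distances(g: MolecularGraph) -> np.ndarray:
    return floyd_warshall(g.n_atoms, [(i, j) for i, j, _ in g.bonds])


def brute_force_descriptor(
    g: MolecularGraph,
    spec: DescriptorSpec | str,
    dmat: np.ndarray | None = None,
) -> int:
    """Naive pair enumeration over the distance matrix."""
    if isinstance(spec, str):
        spec = parse_descriptor_name(spec)
    targets = [i for i in range(g.n_atoms) if classify_atom(g, i, spec.target_class)]
    if spec.space == "angstroms":
        masses = np.array([ATOMIC_MASS[a.element] for a in g.atoms])
        com = (masses[:, None] * g.coords).sum(axis=0) / masses.sum()
        count = 0
        for t in targets:
            if np.sqrt(((g.coords[t] - com) ** 2).sum()) <= spec.distance:
                count += 1
        return count
    d = graph_distances(g) if dmat is None else dmat
    sources = [i for i in range(g.n_atoms) if classify_atom(g, i, spec.source_class)]
    if spec.mode == "frequency":
        count = 0
        for s in sources:
            for t in targets:
                if s != t and d[s, t] == spec.distance:
                    count += 1
        return count
    count = 0
    for t in targets:
        for s in sources:
            if s != t and d[s, t] <= spec.distance:
                count += 1
                break
    return count


def normal_equations_fit(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """beta = (A'A)^-1 A'y with explicit inverse; column 0 is the intercept."""
    A = np.column_stack([np.ones(len(X)), X])
    return np.linalg.inv(A.T @ A) @ (A.T @ y)


def loo_q2_refits(X: np.ndarray, y: np.ndarray) -> float:
    """Q^2 from n explicit leave-one-out refits."""
    n = len(y)
    press = 0.0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        beta = normal_equations_fit(X[mask], y[mask])
        pred = beta[0] + X[i] @ beta[1:]
        press += (y[i] - pred) ** 2
    ss_tot = ((y - y.mean()) ** 2).sum()
    return 1.0 - press / ss_tot
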