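"""Synthetic inputs with the statistical structure the analysis assumes.

Two generators make every stage testable without external downloads:

* small toy molecules (chains, branches, rings over C/N/O/S/Cl) whose typed
  atom-pair descriptor values are hand-enumerable and are verified at
  generation time by an independent double-loop pair enumeration;
* descriptor-like count matrices with a planted sparse linear signal
  y = intercept + X[:, subset] @ beta + Gaussian noise, mimicking the
  n ~ 20, p >> n regime of the activity models. Counts are Poisson
  (non-negative, discrete, many zeros) rather than Gaussian to mirror
  fragment-count descriptor distributions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .molgraph import (
    MolecularGraph,
    bond_distance_matrix,
    classify_atom,
    parse_structure,
)
from .descriptors import DescriptorSpec, parse_descriptor_name


# ---------------------------------------------------------------------------
# Planted-signal descriptor matrices
# ---------------------------------------------------------------------------

#: Planted coefficients default to the printed model-1 values so recovery
#: experiments double as sign/magnitude sanity checks.
DEFAULT_BETA = (-0.214, -0.271, 0.249)
DEFAULT_INTERCEPT = 7.897


@dataclass
class PlantedDataset:
    X: np.ndarray  # (n, p) non-negative integer counts
    y: np.ndarray
    true_subset: tuple[int, ...]
    true_beta: np.ndarray
    true_intercept: float
    noise_sd: float
    seed: int

    def write(self, x_path: str, y_path: str, truth_path: str) -> None:
        np.savetxt(x_path, self.X, delimiter=",", fmt="%d",
                   header=",".join(f"d{j}" for j in range(self.X.shape[1])),
                   comments="")
        np.savetxt(y_path, self.y, delimiter=",", header="y", comments="")
        with open(truth_path, "w") as fh:
            json.dump(
                {
                    "true_subset": list(map(int, self.true_subset)),
                    "true_beta": [float(b) for b in self.true_beta],
                    "true_intercept": self.true_intercept,
                    "noise_sd": self.noise_sd,
                    "seed": self.seed,
                },
                fh,
                indent=1,
            )


def noise_sd_for_r2(
    X: np.ndarray, subset: Sequence[int], beta: Sequence[float], target_r2: float
) -> float:
    """Noise SD giving the requested population R^2 for the planted signal."""
    if not (0 < target_r2 < 1):
        raise ValueError("target_r2 must be in (0, 1)")
    signal = np.asarray(X, float)[:, list(subset)] @ np.asarray(beta, float)
    var_signal = float(signal.var())
    if var_signal == 0:
        raise ValueError("planted signal has zero variance")
    return float(np.sqrt(var_signal * (1 - target_r2) / target_r2))


def simulate_descriptor_dataset(
    n: int,
    p: int,
    k_true: int,
    beta: Sequence[float] = DEFAULT_BETA,
    intercept: float = DEFAULT_INTERCEPT,
    noise_sd: Optional[float] = None,
    seed: int = 0,
    target_r2: float = 0.9,
) -> PlantedDataset:
    """Poisson count matrix with a planted sparse linear response.

    Column rates are uniform in [0.5, 3]. Constant columns are redrawn
    deterministically until none remain. If ``noise_sd`` is None it is
    calibrated on the realized design so the planted signal explains
    ``target_r2`` of the response variance.
    """
    if k_true > p:
        raise ValueError(f"k_true={k_true} exceeds p={p}")
    if n <= k_true + 2:
        raise ValueError(f"need n > k_true + 2 (got n={n}, k_true={k_true})")
    if len(beta) != k_true:
        raise ValueError(f"beta has {len(beta)} entries for k_true={k_true}")
    rng = np.random.default_rng(seed)
    lam = rng.uniform(0.5, 3.0, size=p)
    X = rng.poisson(lam, size=(n, p))
    # deterministically redraw any constant column
    for _ in range(100):
        const = np.nonzero(X.std(axis=0) == 0)[0]
        if len(const) == 0:
            break
        X[:, const] = rng.poisson(lam[const], size=(n, len(const)))
    true_subset = tuple(sorted(int(j) for j in rng.choice(p, k_true, replace=False)))
    beta = np.asarray(beta, dtype=float)
    if noise_sd is None:
        noise_sd = noise_sd_for_r2(X, true_subset, beta, target_r2)
    y = intercept + X[:, list(true_subset)] @ beta + rng.normal(0.0, noise_sd, size=n)
    return PlantedDataset(
        X=X,
        y=y,
        true_subset=true_subset,
        true_beta=beta,
        true_intercept=float(intercept),
        noise_sd=float(noise_sd),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Toy molecules with oracle-verified descriptor values
# ---------------------------------------------------------------------------

#: Topological descriptors of the published models; the stated spec list for
#: which every toy molecule carries oracle-computed expected values.
TOY_SPEC_NAMES = (
    "Cl_S_6B",
    "fOS7B",
    "fnotringSC7B",
    "fsp2Ssp3C7B",
    "notringC_Cl_8B",
    "faccaroC6B",
    "Cl_notringC_6B",
    "fdonnotringC6B",
    "C_sp3C_9B",
)

# hand-enumerable chain/branch/ring templates over {C, N, O, S, Cl}
_TEMPLATES = (
    "ClCCCCCS",      # Cl and S exactly 6 bonds apart -> Cl_S_6B = 1
    "OCCCCCCS",      # O and S exactly 7 bonds apart -> fOS7B = 1
    "CCO",
    "CC(C)CO",
    "CSCCN",
    "OCC(N)CCl",
    "c1ccccc1CCl",
    "c1ccc(CCO)cc1",
    "c1ccsc1CC",
    "c1ccncc1CO",
    "CC(=S)NCCO",
    "ClCC(C)CCS",
)


def oracle_pair_count(g: MolecularGraph, spec: DescriptorSpec | str) -> int:
    """Independent double-loop enumeration over atom pairs.

    Reference implementation used to pin expected values: loops explicitly
    over every (source, target) atom pair with the bond-distance matrix,
    counting target atoms once (occurrence) or ordered pairs (frequency).
    Bond-space descriptors only.
    """
    if isinstance(spec, str):
        spec = parse_descriptor_name(spec)
    if spec.space != "bonds":
        raise ValueError("oracle covers bond-space descriptors only")
    d = bond_distance_matrix(g)
    n = g.n_atoms
    sources = [i for i in range(n) if classify_atom(g, i, spec.source_class)]
    targets = [i for i in range(n) if classify_atom(g, i, spec.target_class)]
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


@dataclass
class ToyMoleculeSet:
    smiles: list[str]
    graphs: list[MolecularGraph]
    spec_names: tuple[str, ...]
    expected: list[dict[str, int]] = field(default_factory=list)


def _random_chain_smiles(rng: np.random.Generator) -> str:
    """Random connected chain with optional Cl terminus and aryl cap."""
    length = int(rng.integers(3, 8))
    symbols = [str(rng.choice(["C", "C", "C", "N", "O", "S"])) for _ in range(length)]
    s = "".join(symbols)
    if rng.random() < 0.4:
        s = "Cl" + s
    if rng.random() < 0.35:
        s = s + str(rng.choice(["c1ccccc1", "c1ccsc1", "c1ccncc1"]))
    return s


def generate_toy_molecules(n: int, seed: int = 0) -> ToyMoleculeSet:
    """Emit n toy molecules with oracle-verified expected descriptor values."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    smiles = list(_TEMPLATES[:n])
    while len(smiles) < n:
        smiles.append(_random_chain_smiles(rng))
    graphs = [parse_structure(s, id=f"toy{i}") for i, s in enumerate(smiles)]
    expected = [
        {name: oracle_pair_count(g, name) for name in TOY_SPEC_NAMES} for g in graphs
    ]
    return ToyMoleculeSet(
        smiles=smiles, graphs=graphs, spec_names=TOY_SPEC_NAMES, expected=expected
    )
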