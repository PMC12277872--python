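#!/usr/bin/env python
"""Planted-signal recovery experiment for GA-MLR subset selection.

Simulates the small-n/large-p regime of the activity models (n=17 training
compounds, p=300 Poisson count descriptors, a 3-descriptor signal with the
printed model-1 coefficients, noise calibrated to R^2~0.9), runs GA subset
selection with Q^2_LOO fitness over 20 seeds, and reports how often the
planted descriptors are recovered exactly, plus OLS coefficient coverage on
the true subset over 100 replicates. Results go to results/ga_recovery.json.
"""

import json
from pathlib import Path

import numpy as np

from thioqsar.qsar import coefficient_standard_errors, fit_mlr, ga_select
from thioqsar.synthetic import simulate_descriptor_dataset

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    hits = []
    for seed in range(20):
        ds = simulate_descriptor_dataset(17, 300, 3, seed=seed)
        subset, _, q2 = ga_select(ds.X, ds.y, 3, seed=seed)
        hit = tuple(subset) == ds.true_subset
        hits.append(hit)
        print(f"seed {seed:2d}: {'recovered' if hit else 'missed   '} "
              f"(Q2_LOO of selected subset = {q2:.3f})")
    rate = sum(hits) / len(hits)
    print(f"\nGA recovery rate: {sum(hits)}/20 = {rate:.0%}")
    print("note: at this noise level chance subsets out-cross-validate the "
          "planted one in a large fraction of replicates (n=17 against "
          "~4.5M candidate subsets), so even exhaustive search cannot "
          "recover the truth every time")

    covered = np.zeros(3)
    n_rep = 100
    for seed in range(n_rep):
        ds = simulate_descriptor_dataset(17, 300, 3, seed=10_000 + seed)
        Xs = ds.X[:, list(ds.true_subset)].astype(float)
        m = fit_mlr(Xs, ds.y)
        se = coefficient_standard_errors(Xs, ds.y)
        covered += np.abs(m.coefficients - ds.true_beta) <= 2 * se
    coverage = (covered / n_rep).round(2).tolist()
    print(f"OLS +/-2 SE coverage per planted coefficient: {coverage}")

    OUT.mkdir(exist_ok=True)
    (OUT / "ga_recovery.json").write_text(json.dumps({
        "n": 17, "p": 300, "k_true": 3, "target_r2": 0.9,
        "ga_recovery_rate": rate,
        "ols_2se_coverage": coverage,
    }, indent=1))
    print(f"wrote {OUT / 'ga_recovery.json'}")


if __name__ == "__main__":
    main()
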