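#!/usr/bin/env python
"""Compute the model descriptors for the synthesized series.

Parses the 21 packaged structures, computes the eleven typed atom-pair
descriptors used by the four published activity models (3D conformers are
embedded with a fixed seed for the two center-of-mass radial descriptors) and
writes the count matrix to results/descriptors.csv.
"""

from pathlib import Path

from thioqsar.datasets import load_compound_structures
from thioqsar.descriptors import compute_descriptor_matrix
from thioqsar.published import load_published_models

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 42


def main() -> None:
    compounds = load_compound_structures()
    names = []
    for model in load_published_models().values():
        for name in model.descriptor_names:
            if name not in names:
                names.append(name)
    matrix = compute_descriptor_matrix(compounds, names, seed=SEED)
    OUT.mkdir(exist_ok=True)
    matrix.to_csv(OUT / "descriptors.csv")
    df = matrix.to_dataframe()
    print(df.to_string(index=False))
    nonzero = (df[names] != 0).sum().sum()
    print(f"\n{len(compounds)} compounds x {len(names)} descriptors, "
          f"{nonzero} non-zero cells -> {OUT / 'descriptors.csv'}")


if __name__ == "__main__":
    main()
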