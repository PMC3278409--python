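#!/usr/bin/env python
"""Normalize the simulated cohort and select the 1,000 discovery genes.

Quantile normalization aligns every sample's intensity distribution; the
variance filter keeps the 1,000 most variable genes whose technical
(within-duplicate-pair) variability is low. Samples are then partitioned
into the 82-sample training set and the 47-sample model-selection set, with
duplicate pairs kept on the same side.
"""

import sys
from pathlib import Path

from risis.io import read_duplicate_pairs, read_expression, write_expression, write_json
from risis.preprocess import (
    filter_variable_genes,
    quantile_normalize,
    split_train_model_selection,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 20260930
OUT = Path("results/analysis")


def main() -> None:
    pairs = read_duplicate_pairs(OUT / "duplicate_pairs.tsv")
    mat = read_expression(OUT / "expression.tsv", duplicate_pairs=pairs)
    mat = quantile_normalize(mat)
    keep = filter_variable_genes(mat, k=1000, dup_quantile=0.75)
    filtered = mat.subset_genes(keep)
    write_expression(filtered, OUT / "filtered.tsv")

    copies = {b for _, b in pairs}
    unique = [s for s in mat.samples if s not in copies]
    train, model = split_train_model_selection(unique, n_train=82, seed=SEED + 1)
    write_json({"train": train, "model_selection": model}, OUT / "sample_split.json")
    print(f"kept {len(keep)} of {mat.shape[0]} genes after the duplicate-aware "
          "variance filter")
    print(f"sample partition: {len(train)} training / {len(model)} model-selection")


if __name__ == "__main__":
    main()
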