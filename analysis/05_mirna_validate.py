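#!/usr/bin/env python
"""Cross-omics confirmation: predict each confirmed split from microRNAs.

A nearest-shrunken-centroid classifier with nested cross-validation (outer
10-fold for the unbiased error, inner 5-fold for the shrinkage level) tests
whether the independently measured microRNA profiles can predict each
mRNA-derived partition. Only split 1 carries planted microRNA support, so
its per-class errors should be low while the others sit near chance.
"""

import sys
from pathlib import Path

import pandas as pd

from risis.io import read_expression, read_json, write_json
from risis.isis import lda_predict, lda_train
from risis.pam import nested_cv
from risis.stability import StableSplit

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 20260930
OUT = Path("results/analysis")


def main() -> None:
    mirna = read_expression(OUT / "mirna.tsv")
    filtered = read_expression(OUT / "filtered.tsv")
    split_ids = read_json(OUT / "sample_split.json")
    train = filtered.subset_samples(split_ids["train"])
    full = filtered.subset_samples(mirna.samples)
    confirmed = [StableSplit.from_dict(d) for d in read_json(OUT / "stable.json").values()]

    out = {}
    for i, st in enumerate(confirmed):
        model = lda_train(train, st.base)
        labels, _ = lda_predict(model, full)
        labels = labels.map({0: "g0", 1: "g1"})
        conf, errors, consensus = nested_cv(mirna, labels, outer_k=10, inner_k=5,
                                            seed=SEED + 5 + i)
        out[f"S{i + 1}"] = {
            "confusion": {r: {c: int(conf.loc[r, c]) for c in conf.columns}
                          for r in conf.index},
            "per_class_error": {k: round(float(v), 3) for k, v in errors.items()},
            "n_consensus_mirnas": len(consensus),
        }
        print(f"split {i + 1}: miRNA nested-CV per-class errors "
              + ", ".join(f"{k}={v:.3f}" for k, v in errors.items())
              + f"; {len(consensus)} consensus microRNAs")
        print(conf.to_string())
    write_json(out, OUT / "mirna_validation.json")


if __name__ == "__main__":
    main()
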