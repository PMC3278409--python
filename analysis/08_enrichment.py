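#!/usr/bin/env python
"""Functional characterization of the signature module by over-representation.

With synthetic data the natural "annotation" is the planted truth: each
planted module becomes a gene set, plus random decoy sets. The discovered
split-1 module should be strongly over-represented in the planted split-1
set (q < 0.10) and nowhere else.
"""

import sys
from pathlib import Path

import numpy as np

from risis.enrichment import hypergeom_enrich
from risis.io import read_expression, read_json

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 20260930
OUT = Path("results/analysis")


def main() -> None:
    filtered = read_expression(OUT / "filtered.tsv")
    universe = filtered.genes
    signature = read_json(OUT / "signature.json")["genes"]
    truth = read_json(OUT / "truth_modules.json")["modules"]

    rng = np.random.default_rng(SEED + 8)
    sets = {
        f"planted_{name}": {"description": "planted module",
                            "genes": sorted(set(genes) & set(universe))}
        for name, genes in truth.items()
        if set(genes) & set(universe)
    }
    for i in range(10):
        sets[f"decoy_{i:02d}"] = {
            "description": "random decoy",
            "genes": list(rng.choice(universe, size=50, replace=False)),
        }
    module = sorted(set(signature) & set(universe))
    res = hypergeom_enrich(module, sets, universe, fdr=0.10)
    res.to_csv(OUT / "enrichment.tsv", sep="\t")
    sig = res[res["significant"]]
    print(f"{len(sig)} of {len(res)} sets significant at FDR < 10%:")
    for name, row in sig.iterrows():
        print(f"  {name}: overlap {row['overlap']}/{row['set_size']}, "
              f"p = {row['p']:.2e}, q = {row['q']:.2e}")


if __name__ == "__main__":
    main()
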