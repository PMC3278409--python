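#!/usr/bin/env python
"""Gate discovered partitions by bootstrap classification stability.

Each bootstrap replicate re-discovers partitions on a random 63% training
subset; matched rediscoveries train classifiers whose held-out predictions
are compared with the candidate labels. Partitions with stability > 95% are
retained and then re-confirmed against the untouched 47-sample
model-selection set.
"""

import sys
from pathlib import Path

from risis.io import read_expression, read_json, write_json
from risis.isis import Bipartition
from risis.stability import bootstrap_stability, confirm_on_holdout, retain_stable

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 20260930
OUT = Path("results/analysis")


def main() -> None:
    filtered = read_expression(OUT / "filtered.tsv")
    split_ids = read_json(OUT / "sample_split.json")
    train = filtered.subset_samples(split_ids["train"])
    model = filtered.subset_samples(split_ids["model_selection"])
    splits = [Bipartition.from_dict(d) for d in read_json(OUT / "splits.json").values()]

    stable = bootstrap_stability(train, splits, n_boot=100, seed=SEED + 3)
    retained = retain_stable(stable, threshold=0.95)
    confirmed = confirm_on_holdout(retained, train, model, n_boot=100,
                                   threshold=0.95, seed=SEED + 4)
    write_json({f"S{i + 1}": st.to_dict() for i, st in enumerate(confirmed)},
               OUT / "stable.json")
    print(f"training stability (n_boot=100):")
    for i, st in enumerate(stable):
        mark = "retained" if st in retained else "dropped"
        print(f"  S{i + 1}: stability={st.stability:.3f} "
              f"matched={st.matched_fraction:.2f} -> {mark}")
    print(f"{len(confirmed)} of {len(retained)} retained split(s) confirmed on the "
          "model-selection samples:")
    for i, st in enumerate(confirmed):
        print(f"  confirmed split {i + 1}: hold-out consistency {st.stability:.3f}")


if __name__ == "__main__":
    main()
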