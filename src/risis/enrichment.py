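"""Over-representation analysis of a gene module against named gene sets.

Hypergeometric upper-tail test of module/set overlap within a declared gene
universe, with Benjamini-Hochberg FDR control across sets (sets with
q < 0.10 flagged by default).
"""

from __future__ import annotations

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["hypergeom_enrich"]


def hypergeom_enrich(module, sets: dict[str, dict], universe,
                     fdr: float = 0.10) -> pd.DataFrame:
    """Test each gene set for over-representation in ``module``.

    ``sets`` maps set name to ``{"description": ..., "genes": [...]}`` (the
    shape :func:`risis.io.read_gmt` produces); sets are intersected with the
    universe first. Returns a DataFrame indexed by set name with columns
    ``set_size``, ``overlap``, ``p``, ``q`` and ``significant`` (q < fdr),
    sorted by p.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    module = set(module)
    if not module:
        raise ValueError("empty module")
    if not module <= universe:
        missing = sorted(module - universe)[:3]
        raise ValueError(f"module genes outside the universe, e.g. {missing}")
    N = len(universe)
    n = len(module)
    rows = []
    for name, entry in sets.items():
        members = set(entry["genes"]) & universe
        K = len(members)
        k = len(members & module)
        # upper tail: P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append((name, entry.get("description", ""), K, k, min(p, 1.0)))
    df = pd.DataFrame(
        rows, columns=["set", "description", "set_size", "overlap", "p"]
    ).set_index("set")
    if len(df):
        _, q, _, _ = multipletests(df["p"].to_numpy(), method="fdr_bh")
        df["q"] = q
        df["significant"] = df["q"] < fdr
    return df.sort_values(["p", "set_size"]).copy()
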