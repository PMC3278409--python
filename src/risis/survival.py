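"""Survival stratification and clinical association for subtype calls.

Kaplan-Meier curves and the two-sample logrank test, Cox proportional-hazards
hazard ratios with Wald CIs (Efron tie handling, via lifelines), Fisher exact
association tests (exact for 2x2, fixed-margin Monte Carlo for r x c), and
per-category subtype proportions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from scipy.special import gammaln
from scipy.stats import fisher_exact as _scipy_fisher

__all__ = [
    "km_logrank",
    "cox_hr",
    "fisher_exact",
    "subtype_proportions",
]


def _check_survival(df: pd.DataFrame) -> pd.DataFrame:
    for col in ("time", "event", "group"):
        if col not in df.columns:
            raise ValueError(f"survival table needs a {col!r} column")
    t = df["time"].to_numpy(dtype=float)
    if not np.isfinite(t).all() or (t < 0).any():
        raise ValueError("times must be finite and nonnegative")
    return df


def km_logrank(survival: pd.DataFrame):
    """Kaplan-Meier estimates per group plus the two-sample logrank test.

    Returns ``(curves, statistic, pvalue)`` with ``curves`` a dict mapping
    group label to a step-function DataFrame (columns ``time``, ``survival``).
    """
    df = _check_survival(survival)
    groups = sorted(pd.unique(df["group"]))
    if len(groups) != 2:
        raise ValueError(f"logrank comparison needs exactly 2 groups, got {len(groups)}")
    if int(df["event"].sum()) == 0:
        raise ValueError("no events observed")
    curves = {}
    for g in groups:
        sub = df[df["group"] == g]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"])
        sf = kmf.survival_function_
        curves[g] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    a = df[df["group"] == groups[0]]
    b = df[df["group"] == groups[1]]
    res = logrank_test(a["time"], b["time"], event_observed_A=a["event"],
                       event_observed_B=b["event"])
    return curves, float(res.test_statistic), float(res.p_value)


def cox_hr(survival: pd.DataFrame):
    """Cox proportional-hazards HR for a binary group.

    Returns ``(hr, (ci_low, ci_high), p)`` with the Wald 95% CI
    ``exp(beta +/- 1.96 se)``. Efron tie handling. Raises on a single group,
    non-convergence, or detected monotone likelihood (complete separation).
    """
    df = _check_survival(survival)
    groups = sorted(pd.unique(df["group"]))
    if len(groups) != 2:
        raise ValueError(f"Cox HR needs exactly 2 groups, got {len(groups)}")
    data = pd.DataFrame(
        {
            "time": df["time"].to_numpy(dtype=float),
            "event": df["event"].to_numpy(dtype=int),
            "x": (df["group"] == groups[1]).to_numpy(dtype=float),
        }
    )
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(data, duration_col="time", event_col="event")
    except ConvergenceError as exc:
        raise RuntimeError(f"Cox fit did not converge: {exc}") from exc
    beta = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    if not np.isfinite(beta) or not np.isfinite(se) or abs(beta) > 20:
        raise RuntimeError(
            f"monotone likelihood suspected (beta={beta:.3g}, se={se:.3g}); "
            "groups may be completely separated in risk"
        )
    hr = float(np.exp(beta))
    ci = (float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se)))
    p = float(cph.summary.loc["x", "p"])
    return hr, ci, p


def _fixed_margin_tables(rows: np.ndarray, cols: np.ndarray, n_mc: int, rng):
    """Sample r x c tables with the given margins by random pairing of row
    and column memberships."""
    r, c = rows.size, cols.size
    row_ids = np.repeat(np.arange(r), rows)
    col_ids = np.repeat(np.arange(c), cols)
    n = row_ids.size
    for _ in range(n_mc):
        perm = rng.permutation(n)
        table = np.zeros((r, c), dtype=np.int64)
        np.add.at(table, (row_ids, col_ids[perm]), 1)
        yield table


def _log_table_prob(table: np.ndarray) -> float:
    """Log probability of an r x c table under the fixed-margin
    (multivariate hypergeometric) null."""
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = table.sum()
    return float(
        gammaln(rows + 1).sum()
        + gammaln(cols + 1).sum()
        - gammaln(n + 1)
        - gammaln(table + 1).sum()
    )


def fisher_exact(table, n_mc: int = 20000, seed: int = 0) -> float:
    """Two-sided Fisher exact test p-value for a contingency table.

    2x2 tables use the exact hypergeometric two-sided p (sum of tables with
    probability <= observed). Larger tables use a fixed-margin Monte-Carlo
    estimate with add-one correction ``(k + 1) / (n_mc + 1)``. Zero-margin
    rows/columns are dropped with a warning; a table degenerate after
    dropping has p = 1.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        raise ValueError("table must hold nonnegative integer counts")
    arr = arr.astype(np.int64)
    keep_r = arr.sum(axis=1) > 0
    keep_c = arr.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        warnings.warn("dropping zero-margin rows/columns", stacklevel=2)
        arr = arr[keep_r][:, keep_c]
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        return 1.0
    if arr.shape == (2, 2):
        return float(_scipy_fisher(arr, alternative="two-sided")[1])
    rng = np.random.default_rng(seed)
    obs = _log_table_prob(arr)
    rows = arr.sum(axis=1)
    cols = arr.sum(axis=0)
    k = 0
    tol = 1e-9
    for t in _fixed_margin_tables(rows, cols, n_mc, rng):
        if _log_table_prob(t) <= obs + tol:
            k += 1
    return (k + 1) / (n_mc + 1)


def subtype_proportions(table) -> pd.Series:
    """Per-column percent of angiogenic samples, rounded to integers.

    Row order is (angiogenic, non-angiogenic). Zero-total columns yield NaN
    rather than an error.
    """
    df = table if isinstance(table, pd.DataFrame) else pd.DataFrame(np.asarray(table))
    if df.shape[0] != 2:
        raise ValueError("expected 2 rows: (angiogenic, non-angiogenic)")
    totals = df.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * df.iloc[0] / totals
    out = pct.where(totals > 0)
    return out.round(0)
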