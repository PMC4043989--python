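"""Report tables: category counts, model ranking, split series, uncertainty.

All totals and percentages are recomputed from the table cells at render
time rather than stored.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .split import EnsembleResult, aggregate_percentiles, uncertainty_decomposition

__all__ = [
    "category_table",
    "selection_table",
    "split_table",
    "decomposition_table",
]


def category_table(counts: dict) -> pd.DataFrame:
    """Catches per location-uncertainty category with shares and total.

    ``counts`` maps category name to catch count; shares are percentages
    of the recomputed grand total, rounded to whole percent.
    """
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("no catches to tabulate")
    rows = [(cat, n, round(100.0 * n / total))
            for cat, n in counts.items()]
    rows.append(("total", total, round(100.0 * total / total)))
    return pd.DataFrame(rows, columns=["category", "catches", "share_pct"])


def selection_table(ranking: pd.DataFrame) -> pd.DataFrame:
    """Model-ranking table: structure, df, delta-AICc, convergence flag."""
    cols = ["structure", "df", "loglik", "aicc", "delta_aicc", "converged"]
    return ranking[cols].copy()


def split_table(ensemble: EnsembleResult, round_counts: bool = True
                ) -> pd.DataFrame:
    """Per-year split percentiles, integer-rounded for reporting."""
    t = aggregate_percentiles(ensemble).table.copy()
    if round_counts:
        for c in t.columns[1:]:
            t[c] = np.rint(t[c]).astype(int)
    t["year"] = t["year"].astype(object)
    t.loc[t["year"] == -1, "year"] = "total"
    return t


def decomposition_table(interval_catch, interval_catch_stat, interval_full,
                        medians=None) -> pd.DataFrame:
    """Uncertainty-source comparison for total eastern catches.

    Rows are the nested ensembles (catch only; catch + statistical;
    catch + statistical + ecological) with their 95% intervals and each
    width as a cumulative percentage of the full width.
    """
    pcts = uncertainty_decomposition(interval_catch, interval_catch_stat,
                                     interval_full)
    names = ["catch", "catch+statistical", "catch+statistical+ecological"]
    intervals = [interval_catch, interval_catch_stat, interval_full]
    if medians is None:
        medians = [np.nan] * 3
    rows = [(nm, lo, md, hi, pc)
            for nm, (lo, hi), md, pc in zip(names, intervals, medians, pcts)]
    return pd.DataFrame(rows, columns=["source", "lo_2.5", "median",
                                       "hi_97.5", "cumulative_pct"])
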