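"""Length-based validation of the population split.

Western North Pacific blue whales are longer than eastern ones, so if the
acoustic split is right, catches assigned to the western population (low
predicted probability of being eastern) should be longer on average. For
each ensemble iteration the catches in a mature-female validation set are
assigned hard labels at probability 0.5, compared by a Welch two-sample
t-test on length, and the predicted probability is regressed on length by
ordinary least squares (a negative slope — longer means less likely
eastern — is the validation criterion). Percentile summaries over
iterations give the distribution of mean length differences and slopes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ValidationSummary",
    "select_validation_set",
    "length_tests",
    "summarize_validation",
]

#: default proxy for female sexual maturity when maturity is unrecorded
MATURITY_LENGTH_M = 21.0


def select_validation_set(catches: pd.DataFrame, sex: str = "F",
                          maturity: str = "mature",
                          min_length_m: float = MATURITY_LENGTH_M,
                          ) -> pd.DataFrame:
    """Mature females with recorded lengths.

    Records whose maturity is unrecorded qualify through the length proxy
    ``length_m >= min_length_m``. Raises if nothing qualifies — usually a
    sign the threshold needs review for the dataset at hand.
    """
    t = catches
    has_length = t["length_m"].notna()
    right_sex = t["sex"] == sex
    known = t["maturity"] == maturity
    proxy = (t["maturity"].isna() | (t["maturity"] == "unknown")) \
        & (t["length_m"] >= min_length_m)
    out = t[has_length & right_sex & (known | proxy)].copy()
    if len(out) == 0:
        raise ValueError(
            "no catches qualify for the length validation; review the sex/"
            f"maturity criteria (length threshold {min_length_m} m)")
    return out


def length_tests(samples: pd.DataFrame, probabilities: pd.DataFrame,
                 threshold: float = 0.5) -> pd.DataFrame:
    """Per-iteration two-sample test and probability-on-length regression.

    ``samples`` must carry ``catch_id`` and ``length_m``; ``probabilities``
    has one column per ensemble iteration, indexed by catch_id. For each
    iteration, catches with probability above ``threshold`` form the
    eastern group. The mean difference is reported as western minus
    eastern (positive when western whales are longer). Iterations where a
    group is empty, or lengths are constant, get ``undefined=True`` for
    the t-test; the regression is still computed whenever lengths vary.
    """
    ids = samples["catch_id"].to_numpy()
    lengths = samples.set_index("catch_id")["length_m"]
    rows = []
    for col in probabilities.columns:
        p = probabilities[col].reindex(ids)
        if p.isna().any():
            raise ValueError("probabilities missing for some validation catches")
        if ((p < 0) | (p > 1)).any():
            raise ValueError("probabilities outside [0, 1]")
        east = lengths[ids[(p > threshold).to_numpy()]]
        west = lengths[ids[(p <= threshold).to_numpy()]]
        length_var = float(np.var(lengths.to_numpy()))

        undefined = len(east) == 0 or len(west) == 0 or length_var == 0 \
            or np.var(east.to_numpy()) == 0 or np.var(west.to_numpy()) == 0
        if undefined:
            mean_diff = t_stat = t_p = np.nan
        else:
            mean_diff = float(west.mean() - east.mean())
            t_stat, t_p = stats.ttest_ind(west.to_numpy(), east.to_numpy(),
                                          equal_var=False)
        if length_var > 0:
            reg = stats.linregress(lengths.loc[ids].to_numpy(), p.to_numpy())
            slope, slope_p = float(reg.slope), float(reg.pvalue)
        else:
            slope = slope_p = np.nan
        rows.append((col, mean_diff, float(t_stat) if not undefined else np.nan,
                     float(t_p) if not undefined else np.nan,
                     slope, slope_p, undefined))
    return pd.DataFrame(rows, columns=["iteration", "mean_diff_m", "t_stat",
                                       "t_p", "slope", "slope_p",
                                       "undefined"])


@dataclass
class ValidationSummary:
    """Percentile summary of the per-iteration validation statistics."""

    median_diff_m: float
    diff_range_m: tuple  # 2.5 and 97.5 percentiles
    frac_t_significant: float  # fraction with t-test p < 0.001
    median_slope: float
    slope_range: tuple
    frac_negative_slope_significant: float  # slope < 0 and p < 0.05
    n_iterations: int
    n_undefined: int

    def summary(self) -> str:
        lo, hi = self.diff_range_m
        slo, shi = self.slope_range
        return "\n".join([
            "Length validation over ensemble iterations",
            "=" * 55,
            f"Iterations:                  {self.n_iterations} "
            f"({self.n_undefined} undefined, excluded)",
            f"Mean length difference (W-E): {self.median_diff_m:.2f} m "
            f"(95% range {lo:.2f}-{hi:.2f} m)",
            f"t-test p < 0.001:            {100 * self.frac_t_significant:.1f}%"
            " of iterations",
            f"Probability-vs-length slope:  {self.median_slope:.4f} per m "
            f"(95% range {slo:.4f}-{shi:.4f})",
            "Negative slope, p < 0.05:     "
            f"{100 * self.frac_negative_slope_significant:.1f}% of iterations",
        ])


def summarize_validation(results: pd.DataFrame) -> ValidationSummary:
    """Aggregate :func:`length_tests` output across iterations."""
    defined = results[~results["undefined"]]
    n_undef = int(results["undefined"].sum())
    if len(defined) == 0:
        raise ValueError("no defined iterations to summarize")
    if n_undef:
        warnings.warn(f"{n_undef} undefined iterations excluded from the "
                      "validation summary", stacklevel=2)
    diffs = defined["mean_diff_m"].to_numpy()
    slopes = defined["slope"].dropna().to_numpy()
    slope_p = defined["slope_p"].to_numpy()
    return ValidationSummary(
        median_diff_m=float(np.median(diffs)),
        diff_range_m=tuple(np.percentile(diffs, [2.5, 97.5])),
        frac_t_significant=float(np.mean(defined["t_p"] < 1e-3)),
        median_slope=float(np.median(slopes)),
        slope_range=tuple(np.percentile(slopes, [2.5, 97.5])),
        frac_negative_slope_significant=float(
            np.mean((defined["slope"] < 0) & (slope_p < 0.05))),
        n_iterations=len(results),
        n_undefined=n_undef,
    )
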