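"""Assigning conflated catches to populations and propagating uncertainty.

Given fitted occurrence models for the two call types, the probability
that a catch at position s and month m belonged to the eastern population
is

    P_E(s, m) = p_E(s, m) / (p_E(s, m) + lambda * p_W(s, m)),

where p_E and p_W are the fitted probabilities of hearing at least one
eastern / western song call in an hour, and lambda is the unknown scaling
between the ratio of call probabilities and the ratio of population
densities (base case 1; sensitivity drawn log-uniformly, one value per
iteration shared by all catches).

The ensemble algorithm repeats: (1) draw a realization of the uncertain
catch locations/months; (2) bootstrap-resample the acoustic station-month
rows and refit both occurrence models, discarding and redrawing the whole
iteration if either refit fails to converge; (3) draw lambda; (4) split
every catch; (5) aggregate by year. Percentiles over the retained
iterations quantify the combined uncertainty; running with pieces switched
off isolates the catch-only and catch+statistical contributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bbgam import (BetaBinomialGAM, BetaBinomialGAMResults, FitControl,
                    ModelStructure, bootstrap_refit)
from .imputation import CatchRealization, draw_realization

__all__ = [
    "PredictionModel",
    "SplitSeries",
    "EnsembleResult",
    "PercentileTable",
    "p_enp",
    "draw_lambda",
    "split_realization",
    "CatchSplitModel",
    "run_ensemble",
    "aggregate_percentiles",
    "uncertainty_decomposition",
]


@dataclass
class PredictionModel:
    """Paired east/west occurrence fits plus the density-ratio scaling."""

    fit_east: BetaBinomialGAMResults
    fit_west: BetaBinomialGAMResults
    lam: float = 1.0

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if not (self.fit_east.converged and self.fit_west.converged):
            raise ValueError("both occurrence fits must have converged")

    def p_enp(self, lon_east, lat, month):
        return p_enp(self, lon_east, lat, month)


def p_enp(model: PredictionModel, lon_east, lat, month):
    """Probability a catch at (lon, lat, month) is eastern.

    Returns 0.5 (with a warning) where both call probabilities underflow
    to zero — the data say nothing about such a location.
    """
    if model.lam <= 0:
        raise ValueError("lambda must be positive")
    pe = np.atleast_1d(model.fit_east.predict_mu(lon_east, lat, month))
    pw = np.atleast_1d(model.fit_west.predict_mu(lon_east, lat, month))
    denom = pe + model.lam * pw
    both_zero = denom <= 0
    if np.any(both_zero):
        warnings.warn("both call probabilities are zero at some locations; "
                      "assigning probability 0.5 there", stacklevel=2)
    out = np.where(both_zero, 0.5, pe / np.where(both_zero, 1.0, denom))
    return out if np.asarray(lon_east).ndim else float(out[0])


def draw_lambda(mode, rng_seed: int) -> float:
    """One scaling-factor draw per ensemble iteration.

    ``mode`` is ``("fixed", value)`` or ``("loguniform", (lo, hi))``; the
    log-uniform draw is ``exp(U(log lo, log hi))``, equally likely to be
    low or high on the log scale.
    """
    kind, arg = mode
    if kind == "fixed":
        if arg <= 0:
            raise ValueError("lambda must be positive")
        return float(arg)
    if kind == "loguniform":
        lo, hi = arg
        if not (0 < lo < hi):
            raise ValueError("need 0 < lo < hi for loguniform lambda")
        rng = np.random.default_rng(rng_seed)
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    raise ValueError(f"unknown lambda mode {kind!r}")


@dataclass
class SplitSeries:
    """One iteration's split: per-year expected counts for each population.

    Conservation holds by construction: for every year the eastern plus
    western counts equal the conflated total.
    """

    years: np.ndarray
    enp: np.ndarray
    wnp: np.ndarray
    probabilities: pd.Series  # per-catch P(eastern), indexed by catch_id
    catch_seed: int = -1
    bootstrap_seed: int = -1
    lam: float = 1.0

    @property
    def total_enp(self) -> float:
        return float(self.enp.sum())

    @property
    def total_wnp(self) -> float:
        return float(self.wnp.sum())


def split_realization(realization: CatchRealization, catches: pd.DataFrame,
                      model: PredictionModel, assignment: str = "expected",
                      rng_seed: int = 0) -> SplitSeries:
    """Split one realized catch series between the populations.

    ``expected`` mode sums assignment probabilities per year (and their
    complements for the western series); ``bernoulli`` mode draws hard
    labels. Conservation is exact in both.
    """
    if assignment not in ("expected", "bernoulli"):
        raise ValueError(f"unknown assignment mode {assignment!r}")
    t = realization.table
    if t["month"].isna().any():
        raise RuntimeError("realization contains missing months; "
                           "imputation contract violated")
    probs = np.atleast_1d(p_enp(model, t["lon_east"].to_numpy(),
                                t["lat"].to_numpy(),
                                t["month"].to_numpy(dtype=int)))
    years = catches.set_index("catch_id").loc[t["catch_id"], "year"].to_numpy()
    if assignment == "bernoulli":
        rng = np.random.default_rng(rng_seed)
        e_contrib = (rng.uniform(size=probs.size) < probs).astype(float)
    else:
        e_contrib = probs
    df = pd.DataFrame({"year": years, "e": e_contrib, "w": 1.0 - e_contrib})
    agg = df.groupby("year")[["e", "w"]].sum().sort_index()
    return SplitSeries(
        years=agg.index.to_numpy(), enp=agg["e"].to_numpy(),
        wnp=agg["w"].to_numpy(),
        probabilities=pd.Series(probs, index=t["catch_id"].to_numpy()),
        catch_seed=realization.realization_seed, lam=model.lam)


@dataclass
class EnsembleResult:
    """Retained iterations of the split algorithm plus failure accounting."""

    series: list[SplitSeries]
    attempts: int
    failures_east: int
    failures_west: int
    bootstrap: bool
    lam_mode: tuple
    assignment: str = "expected"
    seed: int = 0

    def __len__(self):
        return len(self.series)

    @property
    def totals_enp(self) -> np.ndarray:
        return np.array([s.total_enp for s in self.series])

    @property
    def lambdas(self) -> np.ndarray:
        return np.array([s.lam for s in self.series])

    def probability_matrix(self) -> pd.DataFrame:
        """Per-catch assignment probabilities, iterations in columns."""
        return pd.DataFrame({i: s.probabilities
                             for i, s in enumerate(self.series)})

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.series):
            for y, e, w in zip(s.years, s.enp, s.wnp):
                rows.append((i, int(y), e, w))
        return pd.DataFrame(rows, columns=["iteration", "year", "enp", "wnp"])

    def summary(self) -> str:
        pct = aggregate_percentiles(self)
        years = pct.table.loc[pct.table["year"] >= 0, "year"]
        tot = self.totals_enp
        lines = [
            "Catch split ensemble",
            "=" * 55,
            f"Iterations retained:  {len(self.series)} of {self.attempts} attempts",
            f"Refit failures:       east {self.failures_east}, "
            f"west {self.failures_west}",
            f"Bootstrap:            {self.bootstrap}",
            f"Lambda mode:          {self.lam_mode}",
            f"Assignment:           {self.assignment}",
            "-" * 55,
            "Total eastern catches: median {:.0f} (95% range {:.0f}-{:.0f})".format(
                np.median(tot), *np.percentile(tot, [2.5, 97.5])),
            f"Years covered:         {years.min()}-{years.max()}",
        ]
        return "\n".join(lines)


class CatchSplitModel:
    """The full two-stage split, statsmodels-style.

    Construct from the conflated catches, donor pool and the two acoustic
    tables; ``fit(n_iterations, seed)`` runs the ensemble algorithm and
    returns an :class:`EnsembleResult`.
    """

    def __init__(self, catches: pd.DataFrame, donors: pd.DataFrame,
                 acoustic_east: pd.DataFrame, acoustic_west: pd.DataFrame,
                 structure: ModelStructure | None = None,
                 bootstrap: bool = True,
                 lam_mode: tuple = ("fixed", 1.0),
                 assignment: str = "expected",
                 control: FitControl | None = None):
        self.catches = catches.reset_index(drop=True)
        self.donors = donors
        self.acoustic_east = acoustic_east
        self.acoustic_west = acoustic_west
        self.structure = structure or ModelStructure()
        self.bootstrap = bootstrap
        self.lam_mode = lam_mode
        self.assignment = assignment
        self.control = control or FitControl()
        # base fits on the full acoustic data must converge up front
        self.base_east = BetaBinomialGAM(acoustic_east, self.structure).fit(
            self.control)
        self.base_west = BetaBinomialGAM(acoustic_west, self.structure).fit(
            self.control)
        if not (self.base_east.converged and self.base_west.converged):
            raise RuntimeError("base occurrence fits did not converge")

    def fit(self, n_iterations: int = 1000, seed: int = 0) -> EnsembleResult:
        """Run the ensemble until ``n_iterations`` successes.

        A bootstrap iteration whose east or west refit fails to converge
        is discarded entirely — a fresh catch realization is drawn too —
        and failure counts are recorded. Aborts if more than half of a
        rolling 100-attempt window fails.
        """
        if n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        rng = np.random.default_rng(seed)
        refit_control = FitControl(n_starts=1, seed=self.control.seed)
        start_e = np.concatenate([self.base_east.beta_mu,
                                  self.base_east.beta_sigma])
        start_w = np.concatenate([self.base_west.beta_mu,
                                  self.base_west.beta_sigma])

        series: list[SplitSeries] = []
        attempts = 0
        fail_e = fail_w = 0
        window: list[bool] = []
        while len(series) < n_iterations:
            attempts += 1
            catch_seed = int(rng.integers(0, 2**31 - 1))
            boot_seed = int(rng.integers(0, 2**31 - 1))
            lam_seed = int(rng.integers(0, 2**31 - 1))
            assign_seed = int(rng.integers(0, 2**31 - 1))

            if self.bootstrap:
                fe = bootstrap_refit(self.acoustic_east, self.structure,
                                     boot_seed, refit_control, start_e)
                fw = bootstrap_refit(self.acoustic_west, self.structure,
                                     boot_seed + 1, refit_control, start_w)
                ok = fe.converged and fw.converged
                fail_e += not fe.converged
                fail_w += not fw.converged
            else:
                fe, fw = self.base_east, self.base_west
                ok = True

            window.append(not ok)
            if len(window) > 100:
                window.pop(0)
            if len(window) == 100 and sum(window) > 50:
                raise RuntimeError(
                    f"more than half of the last 100 attempts failed "
                    f"({sum(window)}/100); occurrence model too fragile "
                    "for this acoustic dataset")
            if not ok:
                continue

            lam = draw_lambda(self.lam_mode, lam_seed)
            model = PredictionModel(fe, fw, lam)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                realization = draw_realization(self.catches, self.donors,
                                               catch_seed)
            s = split_realization(realization, self.catches, model,
                                  self.assignment, assign_seed)
            s.bootstrap_seed = boot_seed if self.bootstrap else -1
            series.append(s)
        return EnsembleResult(series, attempts, fail_e, fail_w,
                              self.bootstrap, self.lam_mode,
                              self.assignment, seed)


def run_ensemble(catches, donors, acoustic_east, acoustic_west,
                 structure: ModelStructure | None = None,
                 n_iterations: int = 1000,
                 bootstrap: bool = True,
                 lam_mode: tuple = ("fixed", 1.0),
                 assignment: str = "expected",
                 rng_seed: int = 0,
                 control: FitControl | None = None) -> EnsembleResult:
    """Functional wrapper around :class:`CatchSplitModel`."""
    model = CatchSplitModel(catches, donors, acoustic_east, acoustic_west,
                            structure, bootstrap, lam_mode, assignment,
                            control)
    return model.fit(n_iterations, rng_seed)


@dataclass
class PercentileTable:
    """Per-year 2.5/50/97.5 percentiles for both populations, plus totals.

    The totals row holds percentiles of per-iteration totals — not sums of
    per-year percentiles, which would understate the spread."""

    table: pd.DataFrame

    def __post_init__(self):
        for pop in ("enp", "wnp"):
            lo, md, hi = (self.table[f"{pop}_lo"], self.table[f"{pop}_med"],
                          self.table[f"{pop}_hi"])
            if not ((lo <= md + 1e-9).all() and (md <= hi + 1e-9).all()):
                raise ValueError("percentile ordering violated")


def aggregate_percentiles(ensemble: EnsembleResult) -> PercentileTable:
    """Per-year percentile summary of an ensemble (linear interpolation)."""
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    long = ensemble.to_long_frame()
    wide_e = long.pivot(index="iteration", columns="year", values="enp").fillna(0.0)
    wide_w = long.pivot(index="iteration", columns="year", values="wnp").fillna(0.0)
    rows = []
    for year in wide_e.columns:
        e = wide_e[year].to_numpy()
        w = wide_w[year].to_numpy()
        rows.append((int(year), *np.percentile(e, [2.5, 50, 97.5]),
                     *np.percentile(w, [2.5, 50, 97.5])))
    te = wide_e.sum(axis=1).to_numpy()
    tw = wide_w.sum(axis=1).to_numpy()
    rows.append((-1, *np.percentile(te, [2.5, 50, 97.5]),
                 *np.percentile(tw, [2.5, 50, 97.5])))
    table = pd.DataFrame(rows, columns=["year", "enp_lo", "enp_med", "enp_hi",
                                        "wnp_lo", "wnp_med", "wnp_hi"])
    return PercentileTable(table)


def uncertainty_decomposition(interval_catch, interval_catch_stat,
                              interval_full):
    """Cumulative percentage of total interval width per uncertainty source.

    Each (lo, hi) interval's width is expressed as a rounded percentage of
    the full interval's width; the final entry is 100 by construction.
    """
    intervals = [tuple(interval_catch), tuple(interval_catch_stat),
                 tuple(interval_full)]
    for lo, hi in intervals:
        if hi < lo:
            raise ValueError("interval must have hi >= lo")
    full_width = intervals[-1][1] - intervals[-1][0]
    if full_width <= 0:
        raise ValueError("full interval has zero width")
    return tuple(int(round(100.0 * (hi - lo) / full_width))
                 for lo, hi in intervals)
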