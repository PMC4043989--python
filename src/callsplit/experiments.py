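"""Simulation studies that characterize the method on known-truth worlds.

Each study generates synthetic data with the generator defaults (or the
study-specific conditions documented per function), runs the relevant part
of the pipeline, and measures how well truth is recovered. The studies are
used by the test suite and by the reproduction script; they are sized to
run on one CPU in minutes.
"""

from __future__ import annotations

import warnings

import numpy as np
from .bbgam import (FitControl, ModelStructure, fit_occurrence_model,
                    select_model)
from .split import CatchSplitModel, PredictionModel, split_realization
from .imputation import draw_realization
from .synthetic import (DispersionField, OccurrenceSurface, WorldConfig,
                        _summer_offsets, default_stations, simulate_acoustic,
                        simulate_world)
from .validation import length_tests

__all__ = [
    "selection_world",
    "selection_study",
    "recovery_study",
    "coverage_study",
    "lambda_monotonicity",
    "interval_width_ordering",
    "validation_power_study",
]


def selection_world() -> WorldConfig:
    """Study conditions for model selection: strong, spatially curved and
    seasonally varying over-dispersion (sigma between ~0.3 and ~8) over
    moderately hot occurrence surfaces — the regime where the data can
    discriminate all six candidate structures."""
    return WorldConfig(
        surface_east=OccurrenceSurface(-1.3, 1.5, 0.25, -0.45, -0.5, 0.0,
                                       _summer_offsets(0.8, 8)),
        surface_west=OccurrenceSurface(-1.3, -1.5, 0.25, -0.45, -0.5, 0.0,
                                       _summer_offsets(0.8, 7)),
        dispersion_field=DispersionField(np.log(1.6), 0.6, -0.35, -0.9, -0.5,
                                         _summer_offsets(1.0, 9), floor=0.3))


def selection_study(n_seeds: int = 50, n_stations: int = 100,
                    seed0: int = 2000) -> dict:
    """How often AICc ranks the full beta-binomial structure first.

    Fits all six candidate structures to ``n_seeds`` independent acoustic
    datasets from :func:`selection_world` and counts wins for the
    beta-binomial additive/additive structure.
    """
    world = selection_world()
    wins = 0
    for seed in range(n_seeds):
        stations = default_stations(n_stations, seed=seed)
        ac = simulate_acoustic(world, stations, seed0 + seed)
        east = ac[ac.call_type == "east"].reset_index(drop=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = select_model(east, control=FitControl(n_starts=2,
                                                          seed=seed))
        wins += table.iloc[0]["structure"] == "Beta-Binomial / Additive / Additive"
    return {"wins": wins, "n_seeds": n_seeds}


def recovery_study(n_seeds: int = 5, n_stations: int = 25,
                   sigma: float = 0.3, seed0: int = 1000) -> dict:
    """Mean absolute error of the fitted occurrence surface.

    Smooth default-shape world at the reference dispersion level; roughly
    200 station-months per dataset. For each seed the candidate structures
    are ranked by AICc and the winner's surface is compared with truth on
    a 20 x 20 grid over the sampled (station bounding box) region,
    averaged over the 12 months.
    """
    world = WorldConfig(dispersion_field=DispersionField(np.log(sigma)))
    maes = []
    for seed in range(n_seeds):
        stations = default_stations(n_stations, seed=seed)
        ac = simulate_acoustic(world, stations, seed0 + seed)
        east = ac[ac.call_type == "east"].reset_index(drop=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table, fits = select_model(east, control=FitControl(seed=seed),
                                       return_fits=True)
        label = table.iloc[0]["structure"]
        fit = next(f for f in fits if f.structure.label == label)
        gl = np.linspace(east["lon_east"].min(), east["lon_east"].max(), 20)
        gt = np.linspace(east["lat"].min(), east["lat"].max(), 20)
        G0, G1 = np.meshgrid(gl, gt)
        errs = []
        for month in range(1, 13):
            mu_true = world.surface_east.mu(G0, G1, month)
            mu_hat = fit.predict_mu(G0.ravel(), G1.ravel(),
                                    np.full(G0.size, month)).reshape(G0.shape)
            errs.append(np.abs(mu_hat - mu_true).mean())
        maes.append(float(np.mean(errs)))
    return {"maes": maes, "mean_mae": float(np.mean(maes)),
            "n_station_months": len(east)}


def coverage_study(n_worlds: int = 20, n_iterations: int = 200,
                   n_catches: int = 800, seed0: int = 100) -> dict:
    """Does the ensemble 95% interval cover the true eastern catch total?

    Default worlds with known labels; per world the ensemble combines
    catch-realization draws, acoustic bootstrap refits (over-dispersion
    structure matched to the constant-sigma world) and hard Bernoulli
    assignment, so the interval is predictive of the realized count.
    Also verifies exact per-year conservation in every iteration.
    """
    structure = ModelStructure("beta_binomial", "additive", "constant")
    covered = []
    conservation_ok = True
    for w in range(n_worlds):
        world, ac, catches, donors = simulate_world(
            n_catches, n_stations=32, seed=seed0 + w)
        east = ac[ac.call_type == "east"].reset_index(drop=True)
        west = ac[ac.call_type == "west"].reset_index(drop=True)
        model = CatchSplitModel(catches, donors, east, west, structure,
                                bootstrap=True, lam_mode=("fixed", 1.0),
                                assignment="bernoulli")
        ens = model.fit(n_iterations, seed=w)
        lo, hi = np.percentile(ens.totals_enp, [2.5, 97.5])
        truth = int((catches["true_population"] == "east").sum())
        covered.append(bool(lo <= truth <= hi))
        counts = catches.groupby("year").size()
        for s in ens.series:
            if not np.allclose(s.enp + s.wnp, counts.loc[s.years].to_numpy(),
                               atol=1e-9):
                conservation_ok = False
    return {"covered": covered, "coverage": float(np.mean(covered)),
            "n_worlds": n_worlds, "conservation_ok": conservation_ok}


def lambda_monotonicity(seed: int = 7, n_catches: int = 500,
                        lams=(0.5, 1.0, 2.0)) -> dict:
    """Total eastern catches as a function of the density-ratio scaling.

    Fixed fits and one fixed catch realization; a larger lambda can only
    shrink every per-catch eastern probability, so the totals must be
    non-increasing.
    """
    structure = ModelStructure("beta_binomial", "additive", "constant")
    world, ac, catches, donors = simulate_world(n_catches, n_stations=25,
                                                seed=seed)
    east = ac[ac.call_type == "east"].reset_index(drop=True)
    west = ac[ac.call_type == "west"].reset_index(drop=True)
    fe = fit_occurrence_model(east, structure, FitControl(seed=0))
    fw = fit_occurrence_model(west, structure, FitControl(seed=0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        real = draw_realization(catches, donors, seed)
    totals = []
    for lam in lams:
        s = split_realization(real, catches, PredictionModel(fe, fw, lam))
        totals.append(s.total_enp)
    return {"lams": list(lams), "totals": totals,
            "monotone": bool(np.all(np.diff(totals) <= 1e-9))}


def interval_width_ordering(seed: int = 3, n_catches: int = 600,
                            n_iterations: int = 200) -> dict:
    """Nested uncertainty sources widen the interval monotonically.

    Three ensembles on one world: catch-only, catch + bootstrap, and
    catch + bootstrap + log-uniform lambda in (0.5, 2).
    """
    structure = ModelStructure("beta_binomial", "additive", "constant")
    world, ac, catches, donors = simulate_world(n_catches, n_stations=25,
                                                seed=seed)
    east = ac[ac.call_type == "east"].reset_index(drop=True)
    west = ac[ac.call_type == "west"].reset_index(drop=True)
    widths = {}
    medians = {}
    intervals = {}
    for name, boot, lam_mode in (
            ("catch", False, ("fixed", 1.0)),
            ("catch_stat", True, ("fixed", 1.0)),
            ("catch_stat_eco", True, ("loguniform", (0.5, 2.0)))):
        model = CatchSplitModel(catches, donors, east, west, structure,
                                bootstrap=boot, lam_mode=lam_mode)
        ens = model.fit(n_iterations, seed=seed)
        lo, md, hi = np.percentile(ens.totals_enp, [2.5, 50, 97.5])
        widths[name] = float(hi - lo)
        medians[name] = float(md)
        intervals[name] = (float(lo), float(hi))
    ordered = widths["catch"] <= widths["catch_stat"] <= \
        widths["catch_stat_eco"]
    return {"widths": widths, "medians": medians, "intervals": intervals,
            "ordered": bool(ordered)}


def validation_power_study(n_replicates: int = 200, n_per_group: int = 129,
                           effect_m: float = 0.91, sd_m: float = 1.0) -> dict:
    """Power of the length validation at the configured contrast.

    Per replicate: two populations of mature females with the given mean
    length difference, assignment probabilities concentrated on the right
    side of 0.5; counts how often the two-sample test is significant at
    0.1% with a negative probability-on-length slope.
    """
    import pandas as pd

    significant = negative = 0
    for seed in range(n_replicates):
        rng = np.random.default_rng(seed)
        n = 2 * n_per_group
        pop = np.array(["east"] * n_per_group + ["west"] * n_per_group)
        lengths = np.where(pop == "east", rng.normal(22.0, sd_m, n),
                           rng.normal(22.0 + effect_m, sd_m, n))
        probs = np.clip(np.where(pop == "east", 0.8, 0.2)
                        + rng.normal(0, 0.1, n), 0, 1)
        samples = pd.DataFrame({"catch_id": [f"C{i}" for i in range(n)],
                                "length_m": lengths})
        frame = pd.DataFrame({0: probs},
                             index=samples["catch_id"].to_numpy())
        res = length_tests(samples, frame)
        significant += res["t_p"].iloc[0] < 1e-3
        negative += res["slope"].iloc[0] < 0
    return {"n_replicates": n_replicates,
            "frac_significant": significant / n_replicates,
            "frac_negative_slope": negative / n_replicates}
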