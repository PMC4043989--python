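"""End-to-end pipeline: selection, base fits, ensembles, reports, validation.

``run_pipeline`` drives the whole analysis from a :class:`RunConfig`: read
(or simulate) the inputs, rank candidate model structures by AICc, fit the
base occurrence models, run the ensemble in up to three nested modes for
the uncertainty decomposition (catch uncertainty only; catch + bootstrap;
catch + bootstrap + log-uniform lambda), aggregate percentile tables, run
the length validation, and write everything with the seeds that produced
it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import io as csio
from .bbgam import FitControl, ModelStructure, TABLE_CANDIDATES, select_model
from .report import decomposition_table, selection_table, split_table
from .split import CatchSplitModel
from .validation import (MATURITY_LENGTH_M, length_tests,
                         select_validation_set, summarize_validation)

logger = logging.getLogger("callsplit")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    acoustic_path: str
    catches_path: str
    donors_path: str
    output_dir: str
    n_iterations: int = 1000
    seed: int = 0
    spline_df: int = 4
    select: bool = True  # rank candidates; otherwise use the full structure
    bootstrap: bool = True
    lam_lo: float = 0.5
    lam_hi: float = 2.0
    ecological: bool = True  # include the lambda-sensitivity ensemble
    decompose: bool = True  # also run the reduced-uncertainty ensembles
    assignment: str = "expected"
    validation_sex: str = "F"
    validation_min_length_m: float = MATURITY_LENGTH_M

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _stage(name):
    logger.info("stage: %s", name)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns a dict of output paths and key objects.

    Any stage error propagates with the stage name attached.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"config": config}
    stage = "read-inputs"
    try:
        acoustic = csio.read_acoustic(config.acoustic_path)
        catches = csio.read_catches(config.catches_path)
        donors = csio.read_donors(config.donors_path)
        east = acoustic[acoustic["call_type"] == "east"].reset_index(drop=True)
        west = acoustic[acoustic["call_type"] == "west"].reset_index(drop=True)

        stage = "model-selection"
        _stage(stage)
        structure = ModelStructure(spline_df=config.spline_df)
        control = FitControl(seed=config.seed)
        if config.select:
            candidates = [ModelStructure(c.family, c.mu_terms, c.sigma_terms,
                                         config.spline_df)
                          for c in TABLE_CANDIDATES]
            ranking = select_model(east, candidates, control)
            ranking_w = select_model(west, candidates, control)
            selection_table(ranking).to_csv(out / "selection_east.csv",
                                            index=False)
            selection_table(ranking_w).to_csv(out / "selection_west.csv",
                                              index=False)
            results["selection_east"] = ranking
            results["selection_west"] = ranking_w
            top = ranking.iloc[0]
            structure = ModelStructure(top["family"], top["mu_terms"],
                                       top["sigma_terms"], config.spline_df)

        stage = "ensembles"
        _stage(stage)
        modes = []
        if config.decompose:
            modes.append(("catch", False, ("fixed", 1.0)))
            modes.append(("catch_stat", True, ("fixed", 1.0)))
        if config.ecological:
            modes.append(("catch_stat_eco", True,
                          ("loguniform", (config.lam_lo, config.lam_hi))))
        if not modes:
            modes.append(("catch_stat", config.bootstrap, ("fixed", 1.0)))

        ensembles = {}
        for name, boot, lam_mode in modes:
            _stage(f"ensemble:{name}")
            model = CatchSplitModel(catches, donors, east, west, structure,
                                    bootstrap=boot and config.bootstrap,
                                    lam_mode=lam_mode,
                                    assignment=config.assignment,
                                    control=control)
            ens = model.fit(config.n_iterations, config.seed)
            ensembles[name] = ens
            logger.info("ensemble %s: %d/%d attempts succeeded; refit "
                        "failures east %d west %d", name, len(ens),
                        ens.attempts, ens.failures_east, ens.failures_west)
            split_table(ens).to_csv(out / f"split_{name}.csv", index=False)
            ens.to_long_frame().to_csv(out / f"ensemble_{name}.csv",
                                       index=False)
        results["ensembles"] = ensembles
        # per-catch probabilities of the main ensemble, one column per
        # iteration — the input to the length validation
        main_name = modes[-1][0]
        prob = ensembles[main_name].probability_matrix()
        prob.rename_axis("catch_id").to_csv(out / "probabilities.csv")

        stage = "decomposition"
        if config.decompose and config.ecological:
            _stage(stage)
            ivs = []
            meds = []
            for name in ("catch", "catch_stat", "catch_stat_eco"):
                tot = ensembles[name].totals_enp
                lo, md, hi = np.percentile(tot, [2.5, 50, 97.5])
                ivs.append((lo, hi))
                meds.append(md)
            dec = decomposition_table(*ivs, medians=meds)
            dec.to_csv(out / "uncertainty_decomposition.csv", index=False)
            results["decomposition"] = dec

        stage = "validation"
        _stage(stage)
        main = ensembles[modes[-1][0]]
        try:
            vset = select_validation_set(
                catches, sex=config.validation_sex,
                min_length_m=config.validation_min_length_m)
            tests = length_tests(vset, main.probability_matrix())
            tests.to_csv(out / "length_validation.csv", index=False)
            summary = summarize_validation(tests)
            (out / "length_validation.json").write_text(json.dumps({
                "median_diff_m": summary.median_diff_m,
                "diff_range_m": list(summary.diff_range_m),
                "frac_t_significant": summary.frac_t_significant,
                "median_slope": summary.median_slope,
                "slope_range": list(summary.slope_range),
                "frac_negative_slope_significant":
                    summary.frac_negative_slope_significant,
                "n_iterations": summary.n_iterations,
                "n_undefined": summary.n_undefined,
            }, indent=1))
            results["validation"] = summary
        except ValueError as err:
            logger.warning("length validation skipped: %s", err)

        stage = "metadata"
        meta = {
            "seed": config.seed,
            "n_iterations": config.n_iterations,
            "structure": structure.label,
            "attempts": {k: e.attempts for k, e in ensembles.items()},
            "failures_east": {k: e.failures_east for k, e in ensembles.items()},
            "failures_west": {k: e.failures_west for k, e in ensembles.items()},
            "lambda_draws": {k: list(map(float, e.lambdas))
                             for k, e in ensembles.items()},
        }
        (out / "run_metadata.json").write_text(json.dumps(meta, indent=1))
        results["output_dir"] = str(out)
        return results
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err
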