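import numpy as np
import pandas as pd
import pytest

import callsplit as cs


def make_constant_acoustic(mu=0.2, sigma=0.3, n_rows=100, n_hours=720,
                           seed=0, call_type="east"):
    """Station-month counts from a spatially constant beta-binomial world."""
    rng = np.random.default_rng(seed)
    if sigma > 0:
        p = rng.beta(mu / sigma, (1 - mu) / sigma, n_rows)
    else:
        p = np.full(n_rows, mu)
    k = rng.binomial(n_hours, p)
    return pd.DataFrame({
        "station_id": [f"s{i}" for i in range(n_rows)],
        "lon_east": rng.uniform(150, 250, n_rows),
        "lat": rng.uniform(22, 60, n_rows),
        "month": rng.integers(1, 13, n_rows),
        "n_hours": n_hours,
        "k_hours": k,
        "call_type": call_type,
    })


@pytest.fixture(scope="session")
def small_world():
    """A modest synthetic study system shared across read-only tests."""
    world, acoustic, catches, donors = cs.simulate_world(
        400, n_stations=25, seed=42)
    return {"world": world, "acoustic": acoustic, "catches": catches,
            "donors": donors,
            "east": acoustic[acoustic.call_type == "east"].reset_index(drop=True),
            "west": acoustic[acoustic.call_type == "west"].reset_index(drop=True)}


@pytest.fixture(scope="session")
def light_structure():
    return cs.ModelStructure("beta_binomial", "additive", "constant")


@pytest.fixture(scope="session")
def base_fits(small_world, light_structure):
    control = cs.FitControl(seed=0)
    fe = cs.fit_occurrence_model(small_world["east"], light_structure, control)
    fw = cs.fit_occurrence_model(small_world["west"], light_structure, control)
    assert fe.converged and fw.converged
    return fe, fw
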