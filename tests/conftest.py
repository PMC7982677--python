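import warnings

import numpy as np
import pandas as pd
import pytest

from hybridnorm.enviro import align_to_planting, build_W, omega as build_omega
from hybridnorm.io import DatasetBundle, PhenoTable
from hybridnorm.kernels import HybridSet, MarkerMatrix
from hybridnorm.simulate import simulate_dataset


@pytest.fixture(autouse=True)
def _quiet():
    """Silence the informational warnings the library emits on purpose."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def toy_bundle():
    """Tiny hand-built bundle: 2 hybrids x 2 environments, 3 parents."""
    markers = MarkerMatrix(
        np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0]]),
        ["A", "B", "T1"],
        ["L0", "L1", "L2"],
    )
    hybrids = HybridSet([("H1", "A", "T1"), ("H2", "B", "T1")])
    pheno = PhenoTable(
        pd.DataFrame(
            {
                "hybrid": ["H1", "H2", "H1", "H2"],
                "env": ["E1", "E1", "E2", "E2"],
                "year": [2014, 2014, 2015, 2015],
                "yield_kg_ha": [9000.0, 9500.0, 8000.0, 8700.0],
            }
        )
    )
    rng = np.random.default_rng(7)
    n_days = 4
    weather, planting = {}, {}
    for j, env in enumerate(["E1", "E2"]):
        start = pd.Timestamp(f"2014-05-0{j + 1}")
        ts = start + pd.to_timedelta(np.arange(n_days * 24), unit="h")
        df = pd.DataFrame({"timestamp": ts})
        for c in ["temp_c", "dewpoint_c", "rh_pct", "rain_mm", "wind_ms",
                  "wind_dir_deg", "gust_ms", "solar_wm2"]:
            df[c] = rng.normal(10 + 5 * j, 2, len(ts))
        weather[env] = df
        planting[env] = start
    return DatasetBundle(markers, hybrids, pheno, weather, planting)


@pytest.fixture(scope="session")
def small_bundle():
    """Desk-scale simulated dataset reused across integration tests."""
    bundle, truth = simulate_dataset(
        seed=42, n_p1=25, n_p2=5, m=200, n_hybrids=80, n_env=6,
        obs_fraction=0.5, n_days=20, min_hybrids_per_env=10,
    )
    return bundle, truth


@pytest.fixture(scope="session")
def small_omega(small_bundle):
    bundle, _ = small_bundle
    grids = {
        e: align_to_planting(bundle.weather[e], bundle.planting[e], n_days=20)
        for e in bundle.env_ids
    }
    return build_omega(build_W(grids))
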