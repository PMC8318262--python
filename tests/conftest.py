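import numpy as np
import pytest

from florachip.pipeline import AnalysisParams, run_pipeline
from florachip.synthio import SimConfig, generate_bundle

PIPELINE_SEEDS = tuple(range(1, 11))


@pytest.fixture(scope="session")
def multi_seed_results(tmp_path_factory):
    """Full pipeline runs at default study conditions for ten seeds.

    Shared across tests that measure seed-averaged recovery properties so the
    simulations run once per session.
    """
    root = tmp_path_factory.mktemp("runs")
    results = {}
    for seed in PIPELINE_SEEDS:
        results[seed] = run_pipeline(
            (SimConfig(seed=seed), AnalysisParams()), root / f"run{seed}"
        )
    return results


@pytest.fixture(scope="session")
def default_bundle():
    """One generated fixture bundle at default conditions (seed 7)."""
    return generate_bundle(SimConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
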