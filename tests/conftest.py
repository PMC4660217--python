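import numpy as np
import pytest

from mmra.pipeline import RunConfig, run_pipeline
from mmra.synthetic import SimConfig, simulate_dataset

# Scaled-down analysis settings used for the full synthetic runs: 50 regulon
# bootstraps, 200 randomized-set iterations, 20k null MI values. The dataset
# itself is the reference study condition (SimConfig defaults, seed 7).
SCALED = dict(mi_n_null=20_000, n_boot_regulon=50, n_iter_enrichment=200,
              max_null_regulons=8)


@pytest.fixture(scope="session")
def default_dataset():
    return simulate_dataset(SimConfig())


@pytest.fixture(scope="session")
def default_truth(default_dataset):
    return default_dataset[5]


def _run(default_dataset, seed):
    mrna, mirna, records, signatures, tmap, _ = default_dataset
    cfg = RunConfig(seed=seed, **SCALED)
    return run_pipeline(mrna, mirna, records, signatures, tmap, cfg)


@pytest.fixture(scope="session")
def pipeline_result(default_dataset):
    return _run(default_dataset, seed=1)


@pytest.fixture(scope="session")
def pipeline_result_repeat(default_dataset):
    return _run(default_dataset, seed=1)


@pytest.fixture(scope="session")
def pipeline_result_other_seed(default_dataset):
    return _run(default_dataset, seed=2)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
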