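import numpy as np
import pytest

from contactrank.config import RunConfig
from contactrank.geometry import ProteinRecord, contact_map
from contactrank.io_formats import PSSMProfile
from contactrank.pipeline import TargetData, train_models
from contactrank.synthetic import make_target


@pytest.fixture(scope="session")
def tiny_record():
    """5-residue chain along the x-axis, 4 A apart."""
    coords = np.array([[4.0 * k, 0.0, 0.0] for k in range(5)])
    return ProteinRecord(id="tiny", sequence="ACDEF", coords=coords)


@pytest.fixture(scope="session")
def tiny_cmap(tiny_record):
    return contact_map(tiny_record)


@pytest.fixture
def small_pssm():
    rng = np.random.default_rng(0)
    return PSSMProfile(
        scores=rng.integers(-5, 6, size=(5, 20)).astype(float),
        info_per_pos=np.array([0.5, 1.0, 1.5, 0.2, 0.8]),
        rel_weight=np.array([0.1, 0.2, 0.3, 0.4, 0.5]),
        sequence="ACDEF",
    )


@pytest.fixture(scope="session")
def fast_config():
    """Small forests, capped constraint sets and fixed C keep pipeline tests
    inside the budget."""
    return RunConfig(n_trees=40, C=1.0, seed=0, pair_cap=150, svm_tol=1e-6)


@pytest.fixture(scope="session")
def synthetic_targets():
    """Six mixed-signal synthetic targets, structure plus all input files."""
    return [make_target(70, seed, informativeness=0.8) for seed in range(6)]


@pytest.fixture(scope="session")
def trained_models(synthetic_targets, fast_config):
    data = [TargetData.from_synthetic(t) for t in synthetic_targets[:4]]
    return train_models(data, fast_config)
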