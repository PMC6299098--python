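import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import phogly as pg

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_bundle():
    return pg.make_worked_toy()


@pytest.fixture(scope="session")
def toy_dataset(toy_bundle):
    return pg.build_dataset(
        toy_bundle.proteins, toy_bundle.tables, toy_bundle.annotations, w=2
    )


@pytest.fixture(scope="session")
def null_bundle():
    """Small synthetic bundle with exchangeable classes (no planted signal)."""
    return pg.simulate(pg.SynthConfig(n_proteins=15, imbalance_ratio=8, seed=7))


@pytest.fixture(scope="session")
def signal_bundle():
    """Synthetic bundle with a strong ASA signal at offsets -1..1."""
    return pg.simulate(
        pg.SynthConfig(
            n_proteins=20, imbalance_ratio=10, delta=5.0,
            signal_tracks=("asa",), signal_offsets=(-1, 0, 1), seed=3,
        )
    )


def random_feature_dataset(rng, n_pos, n_neg, mask_size=2, w=1, spread=1.0):
    """Unstructured random dataset ((2w+1)*mask_size features) for resampling tests."""
    mask = pg.PROPERTIES[:mask_size]
    X = rng.normal(0.0, spread, size=(n_pos + n_neg, mask_size * (2 * w + 1)))
    y = np.array([1] * n_pos + [0] * n_neg)
    ids = [(f"p{i}", i) for i in range(n_pos + n_neg)]
    return pg.FeatureDataset(X=X, y=y, ids=ids, w=w, mask=mask)
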