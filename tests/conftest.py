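import numpy as np
import pytest

from adaclassfl.aggregation import ClientRoundStats
from adaclassfl.synthetic_data import LabeledDataset, SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def small_dataset() -> LabeledDataset:
    """300 easy 7-class images at 32 px, shared across tests."""
    return generate_dataset(SyntheticSpec(n_samples=300, image_size=32, seed=7))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_round_stats(rng: np.random.Generator, n_clients: int,
                       n_classes: int) -> list[ClientRoundStats]:
    """Random but valid per-client round statistics."""
    out = []
    for cid in range(n_clients):
        avail = rng.random(n_classes) < 0.8
        if not avail.any():
            avail[rng.integers(n_classes)] = True
        f1 = np.where(avail, rng.random(n_classes), 0.0)
        out.append(ClientRoundStats(cid, int(rng.integers(10, 1000)), f1, avail))
    return out
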