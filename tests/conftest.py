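import numpy as np
import pytest

import scatterbeat as sb


@pytest.fixture(scope="session")
def config():
    return sb.ScatteringConfig()


@pytest.fixture(scope="session")
def bank(config):
    return sb.build_filter_banks(config)


@pytest.fixture(scope="session")
def synth_beats():
    """Default synthetic study set: 200 beats per class."""
    return sb.generate_dataset(200, seed=0)


@pytest.fixture(scope="session")
def synth_tensors(synth_beats, config, bank):
    coeffs, labels = sb.transform_batch(synth_beats, config, bank=bank)
    return coeffs, labels


@pytest.fixture(scope="session")
def small_tensors(synth_tensors):
    """A 50-beat/class slice of the session tensors for cheap tests."""
    coeffs, labels = synth_tensors
    keep = np.concatenate([np.flatnonzero(labels == c)[:50] for c in "NSVF"])
    keep.sort()
    return coeffs[keep], labels[keep]
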