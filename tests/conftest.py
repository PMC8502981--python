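import numpy as np
import pytest

from apforecast.dataset import ResampleConfig
from apforecast.experiments import make_fk_dataset
from apforecast.ionic_models import (FKConfig, NobleLorenzConfig,
                                     StimulusProtocol, simulate_fk,
                                     simulate_noble_lorenz)


@pytest.fixture(scope="session")
def fk_series_slow():
    """Five well-separated FK action potentials on the raw Euler grid."""
    protocol = StimulusProtocol(50.0 + 1000.0 * np.arange(5), 2.0, 0.4)
    return simulate_fk(FKConfig(), protocol), protocol


@pytest.fixture(scope="session")
def fk_split_small():
    """Desk-scale FK forecasting dataset: 40 beats, 25 training, 10 test."""
    split, protocol = make_fk_dataset(
        seed=7, n_beats=40, n_warmup_beats=5, n_train_beats=25)
    return split, protocol


@pytest.fixture(scope="session")
def noble_series_short():
    """~30 s of the chaotic Noble-Lorenz voltage trace."""
    return simulate_noble_lorenz(NobleLorenzConfig(), 30000.0)
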