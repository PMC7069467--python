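import numpy as np
import pytest

from dynconn.preprocessing import EpochSet, Recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_recording():
    """Three named channels plus mastoid references, 20 s at 500 Hz."""
    rate = 500.0
    n = int(20 * rate)
    rng = np.random.default_rng(7)
    data = rng.standard_normal((5, n))
    events = [(int((2 + 1.5 * i) * rate), "standard" if i % 3 else "deviant")
              for i in range(10)]
    return Recording(data=data, rate=rate,
                     channel_labels=("Fz", "Cz", "Pz", "TP9", "TP10"),
                     events=events)


def make_epochs(data, rate=500.0, window_ms=(-200.0, 1000.0), condition=None,
                labels=None):
    n_tr, n_ch, _ = data.shape
    if condition is None:
        condition = np.array(["deviant"] * n_tr, dtype=object)
    if labels is None:
        labels = tuple(f"ch{i}" for i in range(n_ch))
    return EpochSet(data=np.asarray(data, dtype=float), window_ms=window_ms,
                    rate=rate, condition=np.asarray(condition, dtype=object),
                    channel_labels=labels)


@pytest.fixture
def epoch_factory():
    return make_epochs
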