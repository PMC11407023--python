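import numpy as np
import pandas as pd
import pytest

from hypercouple import (
    EpochSet,
    SimConfig,
    TFRSet,
    build_neighbors,
    make_montage,
)
from hypercouple.synth import CONDITIONS


@pytest.fixture(scope="session")
def montage():
    return make_montage()


@pytest.fixture(scope="session")
def adjacency(montage):
    return build_neighbors(montage)


@pytest.fixture
def small_config():
    """Fast generator profile: one pair, short epochs."""
    return SimConfig(n_pairs=1, epoch_window=(-1.3, 1.5), seed=0)


def make_epochs(data, sfreq=500.0, tmin=-1.0, labels=None, player_id=1):
    data = np.asarray(data, dtype=np.float32)
    if labels is None:
        labels = tuple(f"ch{i}" for i in range(data.shape[1]))
    return EpochSet(player_id=player_id, data=data, sfreq=sfreq, tmin=tmin,
                    channel_labels=tuple(labels))


def make_tfr(power, freqs=None, times=None, labels=None, mask=None):
    power = np.asarray(power, dtype=float)
    _, n_ch, n_f, n_t = power.shape
    return TFRSet(
        power=power,
        freqs=np.arange(4.0, 4.0 + n_f) if freqs is None else np.asarray(freqs, float),
        times=np.arange(n_t) * 0.1 if times is None else np.asarray(times, float),
        channel_labels=tuple(f"ch{i}" for i in range(n_ch)) if labels is None
        else tuple(labels),
        mask=mask,
    )


def random_trial_table(rng, n_trials=300, pair_id=0, threshold=0.25):
    """Random but internally consistent trial table for one pair."""
    conds = rng.choice(CONDITIONS, size=n_trials)
    rt1 = rng.uniform(0.3, 3.5, size=n_trials)
    rt2 = rt1 + rng.uniform(-1.0, 1.0, size=n_trials)
    rt2 = np.maximum(rt2, 0.05)
    delta = rt1 - rt2
    return pd.DataFrame({
        "pair_id": pair_id,
        "trial_index": np.arange(n_trials),
        "block": np.arange(n_trials) // max(n_trials // 10, 1),
        "condition": conds,
        "rt1": rt1,
        "rt2": rt2,
        "delta": delta,
        "abs_delta": np.abs(delta),
        "outcome": np.where(np.abs(delta) <= threshold, "success", "fail"),
    })
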