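import warnings

import numpy as np
import pytest

from interbrain.containers import EpochSet
from interbrain.pipeline import AnalysisConfig, extract_block_features
from interbrain.preprocess import PreprocessConfig
from interbrain.simulate import SimConfig, simulate_pair_session

warnings.filterwarnings("ignore", category=RuntimeWarning,
                        module="sklearn")


@pytest.fixture(scope="session")
def tiny_config():
    """Small, fast study conditions: short blocks, 2 dyads."""
    return SimConfig(n_pairs=2, n_trials_per_condition=10)


@pytest.fixture(scope="session")
def tiny_block(tiny_config):
    return simulate_pair_session(tiny_config, seed=7)


@pytest.fixture(scope="session")
def clean_config():
    """No bad channels / packet loss: for injection-recovery checks."""
    return SimConfig(n_pairs=1, n_trials_per_condition=12,
                     bad_channel_prob=0.0, packet_loss_prob=0.0,
                     blink_rate_per_min=0.0, artifact_rate_per_min=0.0)


@pytest.fixture(scope="session")
def analysis_config():
    return AnalysisConfig(min_trials=5,
                          preprocess=PreprocessConfig())


@pytest.fixture(scope="session")
def cohort_features(analysis_config):
    """Four preprocessed units at 20 trials/condition (slow: built once)."""
    cfg = SimConfig(n_pairs=2, n_trials_per_condition=20)
    feats = []
    for i, seed in enumerate([101, 102, 103, 104]):
        blk = simulate_pair_session(cfg, seed=seed, pair_id=i // 2 + 1,
                                    block_id=i % 2 + 1)
        feats.append((blk.ground_truth,
                      extract_block_features(blk, analysis_config)))
    return feats


def make_epochs(data, sfreq=500.0, channels=None, conditions=None, keep=None,
                window_ms=(-200.0, 1000.0)):
    """Convenience EpochSet constructor for hand-built arrays."""
    data = np.asarray(data, dtype=float)
    n_tr, n_ch, _ = data.shape
    if channels is None:
        channels = [f"ch{i}" for i in range(n_ch)]
    if conditions is None:
        conditions = np.array(["expected"] * n_tr)
    if keep is None:
        keep = np.ones(n_tr, dtype=bool)
    return EpochSet(data, sfreq, list(channels), np.asarray(conditions),
                    np.asarray(keep), window_ms=window_ms)
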