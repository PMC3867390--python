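import numpy as np
import pytest

from gibbonsong import songsim


@pytest.fixture(scope="session")
def small_dataset():
    """One small synthetic dataset with audio, shared across tests."""
    cfg = songsim.SimulationConfig(n_males=4, seed=11, snr_db=40.0,
                                   calls_per_song=(4, 7))
    return songsim.simulate_dataset(cfg, synth_audio=True)


@pytest.fixture(scope="session")
def clean_song():
    """A nearly noiseless song with its ground-truth elements."""
    profile = songsim.MaleProfile(
        male_id="m1", group_id="g1", status="pair_primary", age_class="adult",
        baseline_f0=700.0, androgen_mean=500.0, androgen_sd=150.0,
        n_recording_days=2)
    cfg = songsim.SimulationConfig(n_males=2, seed=0, snr_db=60.0)
    wave, elements = songsim.synthesize_song(profile, 4, seed=7, config=cfg)
    return wave, elements


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
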