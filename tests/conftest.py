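import numpy as np
import pytest

from earloop import synthetic_data as sd
from earloop.closed_loop import calibrate_from_bundle
from earloop.session_io import RunConfig

# Small-scale defaults used across the suite: 30-s songs, 200-song library.
SMALL = dict(n_songs=200, n_frames=31, sparsity=5, seed=1, eeg_effect=2.0)
SONG_LEN = 30.0


@pytest.fixture(scope="session")
def small_library():
    return sd.generate_song_library(**SMALL)


@pytest.fixture(scope="session")
def small_bundle(small_library):
    library, truth = small_library
    participant = sd.generate_participant(library, truth, seed=1)
    return sd.simulate_listening(participant, library, truth, song_len=SONG_LEN, seed=1)


@pytest.fixture(scope="session")
def small_cfg():
    return RunConfig(song_len=SONG_LEN, lambda_grid_size=50)


@pytest.fixture(scope="session")
def calib_state(small_bundle, small_cfg):
    return calibrate_from_bundle(
        small_bundle, small_cfg, max_pcs=40, lambda_grid_size=20, cv_model2=5, seed=1
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
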