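import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from songphys.sharpwave import SharpwaveConfig, run_sharpwave_detection
from songphys.songfeat import compute_feature_track
from songphys.synth import SynthLfpSpec, SynthSongSpec, gen_lfp, gen_song


@pytest.fixture(scope="session")
def small_night():
    """A short synthetic night with the degraded-song event parameters.

    60 s, 8 channels keeps the suite fast while leaving ~8 events for
    recovery statistics.
    """
    spec = SynthLfpSpec(duration=60.0, n_channels=8, event_rate=0.15, seed=3)
    raw, truth = gen_lfp(spec)
    result = run_sharpwave_detection(raw, cfg=SharpwaveConfig())
    return {"spec": spec, "raw": raw, "truth": truth, **result}


@pytest.fixture(scope="session")
def song_and_track():
    """Default three-syllable motif, three bouts, with its feature track."""
    spec = SynthSongSpec(seed=5)
    audio, truth = gen_song(spec)
    track = compute_feature_track(audio)
    return {"spec": spec, "audio": audio, "truth": truth, "track": track}


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
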