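import numpy as np
import pytest

from ragamood import synth


@pytest.fixture(scope="session")
def default_specs():
    return synth.default_raga_specs()


@pytest.fixture(scope="session")
def small_tracks(default_specs):
    """Ground-truth pitch tracks for short renders of every raga (no audio)."""
    return synth.render_stimulus_set(default_specs, duration_s=30.0, seed=11,
                                     render_audio=False)


@pytest.fixture(scope="session")
def stimulus_triples(default_specs):
    """(raga, mode, tonality) triples from the prescribed target ratios."""
    return [(s.name, m, s.target_tonality_ratio)
            for s in default_specs for m in ("alaap", "gat")]


@pytest.fixture(scope="session")
def null_table(stimulus_triples):
    """Survey table where both groups share one generative process."""
    params = synth.RatingSimParams(
        betas={"E": dict(synth.DEFAULT_BETAS_E),
               "NE": dict(synth.DEFAULT_BETAS_E)},
        familiarity={"E": (2.4, 1.05), "NE": (2.4, 1.05)},
        n_participants={"E": 60, "NE": 55},
        noise_sd=0.8, p_complete=1.0, seed=101)
    return synth.simulate_ratings(params, stimulus_triples)


@pytest.fixture(scope="session")
def contrast_table(stimulus_triples):
    """Survey table with tonality-dominant E and rhythm-dominant NE."""
    params = synth.RatingSimParams(n_participants={"E": 80, "NE": 70},
                                   p_complete=0.8, seed=202)
    return synth.simulate_ratings(params, stimulus_triples)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
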