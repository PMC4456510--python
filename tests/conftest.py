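import numpy as np
import pytest

from virduet import (DuetParams, WaveletSongSegmenter, simulate_duet)


@pytest.fixture(scope="session")
def trained_segmenter():
    """Segmenter trained on a simulated annotated recording with frequent
    overlaps (so the overlap class has examples)."""
    params = DuetParams(duration=60.0, overlap_probability=0.5)
    trace, truth = simulate_duet(params, seed=90_001)
    seg = WaveletSongSegmenter(random_state=0)
    seg.fit([(trace, truth)])
    return seg


@pytest.fixture(scope="session")
def duet_60s():
    """One minute of wild-type duet at the default generator settings."""
    return simulate_duet(DuetParams(duration=60.0), seed=1)


@pytest.fixture(scope="session")
def segmented_60s(trained_segmenter, duet_60s):
    trace, _ = duet_60s
    segments, pulses = trained_segmenter.predict(trace)
    return segments, pulses
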