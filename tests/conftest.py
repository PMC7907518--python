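import numpy as np
import pytest

import demscreen as ds


@pytest.fixture(scope="session")
def easy_corpus_small():
    """5 subjects per class, 30 s, clearly separated prosody profiles."""
    spec = ds.CorpusSpec(n_subjects_per_class=5, duration_s=30.0, seed=42)
    recordings, manifest = ds.generate_corpus(spec)
    return spec, recordings, manifest


@pytest.fixture(scope="session")
def standardized_tone():
    """A standardized 9.6 s, 16 kHz recording carrying a 200 Hz tone."""
    t = np.arange(int(9.6 * 16000)) / 16000
    rec = ds.AudioRecording("tone", 0.8 * np.sin(2 * np.pi * 200 * t), 16000, label="NONAD")
    return ds.standardize(rec)
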