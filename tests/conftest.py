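"""Shared fixtures: small synthetic corpora generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

import pcglearn as pl

ABNORMAL = ["VSD", "ASD", "PDA", "TOF", "PS", "AS"]


@pytest.fixture(scope="session")
def tiny_recordings():
    """12 normal + 12 abnormal two-second recordings with strong murmurs.

    Short duration keeps feature extraction and training fast while the
    murmur makes the classes cleanly separable (high SNR).
    """
    recs = []
    for i in range(12):
        recs.append(
            pl.synthesize_recording("normal", heart_rate=70 + 2 * i, duration=2.0, seed=100 + i)
        )
    for i, cond in enumerate(ABNORMAL * 2):
        recs.append(
            pl.synthesize_recording(cond, heart_rate=70 + 2 * i, duration=2.0, seed=200 + i)
        )
    return recs


@pytest.fixture(scope="session")
def tiny_labels(tiny_recordings):
    return np.array([r.label for r in tiny_recordings])


@pytest.fixture(scope="session")
def tiny_images(tiny_recordings):
    """64 x 64 x 3 STFT images of the tiny corpus (model3 input)."""
    ext = pl.SpectrogramImageExtractor(extractor="STFT", image_size=(64, 64))
    return ext.transform(tiny_recordings)


@pytest.fixture(scope="session")
def tiny_sequences(tiny_recordings):
    """Short MFCC sequences (50 ms frames / 50 ms hop -> ~40 timesteps)."""
    ext = pl.MFCCSequenceExtractor(frame_length_s=0.05, hop_length_s=0.05)
    return ext.transform(tiny_recordings)


@pytest.fixture(scope="session")
def study_corpus(tmp_path_factory):
    """The study-emulation corpus: 60 six-second WAVs, 30 per class."""
    out = tmp_path_factory.mktemp("corpus")
    config = pl.SynthDatasetConfig(seed=42)
    manifest = pl.generate_dataset(config, out)
    return manifest
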