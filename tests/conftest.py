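"""Shared fixtures: small deterministic corpora and elementary test signals."""

import numpy as np
import pytest

from crysig import (
    GeneratorConfig,
    PainEffect,
    generate_corpus,
    sample_baby_profiles,
)
from crysig.synth import CryRecording


def make_tone(freq, duration_s=1.5, sr=22050, amplitude=1.0, harmonics=1):
    """Harmonic stack (1/h rolloff) as a CryRecording."""
    t = np.arange(int(duration_s * sr)) / sr
    x = np.zeros_like(t)
    for h in range(1, harmonics + 1):
        if h * freq < 0.45 * sr:
            x += np.sin(2 * np.pi * h * freq * t) / h
    x = amplitude * x / np.max(np.abs(x))
    return CryRecording(x, sr, "B00", "M", "discomfort", "tone")


def make_noise(duration_s=1.5, sr=22050, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(int(duration_s * sr))
    return CryRecording(x / np.max(np.abs(x)), sr, "B00", "M", "discomfort", "noise")


@pytest.fixture(scope="session")
def profiles():
    return sample_baby_profiles(GeneratorConfig(seed=1))


def small_config(seed=0, **overrides):
    """Reduced corpus for feature/space tests: fewer, shorter, lower-rate cries."""
    base = dict(
        n_babies=8,
        pain_per_baby=3,
        discomfort_count_range=(3, 4),
        duration_mean_s=2.0,
        duration_sd_s=0.2,
        sample_rate=8000,
        seed=seed,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def small_corpus():
    cfg = small_config(seed=11)
    recs, meta = generate_corpus(cfg)
    return cfg, recs, meta


@pytest.fixture(scope="session")
def small_mps_features(small_corpus):
    from crysig.pipeline import corpus_mps_features

    _, recs, meta = small_corpus
    return corpus_mps_features(recs), meta
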