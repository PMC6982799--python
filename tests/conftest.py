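"""Shared fixtures: small synthetic clips and toy models."""

import numpy as np
import pytest

from apiscan.audio_io import AudioClip
from apiscan.synthetic_data import SceneSpec, synth_clip


@pytest.fixture(scope="session")
def tone_clip() -> AudioClip:
    """3 s of a clean 1 kHz tone at 16 kHz, half amplitude."""
    t = np.arange(48_000) / 16_000
    return AudioClip(samples=0.5 * np.sin(2 * np.pi * 1000 * t),
                     sample_rate_hz=16_000, label="unknown")


@pytest.fixture(scope="session")
def normal_clip() -> AudioClip:
    return synth_clip(SceneSpec("normal", seed=11))


@pytest.fixture(scope="session")
def swarm_clip() -> AudioClip:
    return synth_clip(SceneSpec("swarm", seed=22))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20_260_929)
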