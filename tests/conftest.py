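"""Shared fixtures: small synthetic sequences and datasets.

Everything is generated programmatically; session scope keeps the
slower multi-subject datasets from being rebuilt per test.
"""

from __future__ import annotations

import numpy as np
import pytest

import compens2d as c2


@pytest.fixture(scope="session")
def four_label_script() -> c2.CompensationScript:
    """One well-separated episode of every compensation category."""
    return c2.CompensationScript(episodes=(
        c2.Episode(label=0, start=20, end=40),
        c2.Episode(label=1, start=50, end=70),
        c2.Episode(label=2, start=80, end=100),
        c2.Episode(label=3, start=110, end=130),
    ))


@pytest.fixture(scope="session")
def s1_sequence(four_label_script):
    """Noiseless frontal trial with scripted compensation."""
    tpl = c2.SubjectTemplate(scenario="S1", affected_side="right",
                             noise_sigma=0.0)
    return c2.generate_sequence(tpl, four_label_script, 150, seed=11)


@pytest.fixture(scope="session")
def static_sequence():
    """Noiseless frontal trial with no compensation at all."""
    tpl = c2.SubjectTemplate(scenario="S1", affected_side="right",
                             noise_sigma=0.0)
    return c2.generate_sequence(tpl, c2.CompensationScript(), 60, seed=5)


@pytest.fixture(scope="session")
def small_noisy_dataset():
    """3 subjects x 4 trials, pixel noise on — for fast NN tests."""
    return c2.generate_dataset(n_subjects=3, exercise_id="E1", trials=4,
                               n_frames=100, seed=23, noise_sigma=2.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
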