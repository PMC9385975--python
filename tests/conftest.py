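"""Shared fixtures: small synthetic recordings and cohorts."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import depspeech as d

warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def reading():
    """A ~3.5 s synthetic reading: 10 vowels, 3 pauses, both E and O."""
    rng = np.random.default_rng(5)
    labels = ["E", "O", "i", "E", "o", "A:", "O", "u", "E", "O"]
    phons = [(lbl, d.PhonationSpec(f0_hz=float(rng.uniform(100, 200)),
                                   jitter_pct=1.0, shimmer_pct=3.0,
                                   duration_s=float(rng.uniform(0.15, 0.3))))
             for lbl in labels]
    return d.synthesize_reading(
        phons, pause_plan=[0, 0, 0.4, 0, 0, 0.5, 0, 0, 0.3, 0], seed=5)


@pytest.fixture(scope="session")
def reading_features(reading):
    return d.extract_features(reading)


@pytest.fixture(scope="session")
def small_cohort():
    """Deterministic 60-subject cohort with 4 loaded + 10 noise features."""
    spec = d.CohortSpec(n_subjects=60, female_fraction=0.5,
                        effect_vector=(3.0, 3.0, 3.0, 2.0),
                        n_noise_features=10, bdi_noise_sd=3.0,
                        hamd_subset_fraction=0.2, seed=11)
    return d.generate_cohort(spec)
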