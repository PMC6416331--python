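"""Shared fixtures: rendered synthetic movies and cohorts, generated at
test time so the suite ships no image data."""

from __future__ import annotations

import numpy as np
import pytest

from postforce.imaging import detect_sensors, register_drift
from postforce.synthetic import CohortSpec, MovieSpec, generate_cohort, render_movie


@pytest.fixture(scope="session")
def default_movie():
    """One rendered default movie (2 sites, noise + drift) with truth."""
    spec = MovieSpec(seed=11, drift_per_frame=(0.05, -0.03))
    stack, truth = render_movie(spec)
    return spec, stack, truth


@pytest.fixture(scope="session")
def clean_movie():
    """Noise-free, drift-free movie for exactness checks."""
    spec = MovieSpec(seed=7, read_noise_sd=0.0, photon_scale=0.0,
                     site_jitter=0.0)
    stack, truth = render_movie(spec)
    return spec, stack, truth


@pytest.fixture(scope="session")
def default_detection(default_movie):
    spec, stack, truth = default_movie
    det = detect_sensors(stack.structural[0], spec.geom, spec.pixel_size)
    offsets = register_drift(stack, det.sites, spec.geom)
    return det, offsets


@pytest.fixture(scope="session")
def trauma_cohort():
    """Default 120-subject synthetic trauma cohort."""
    return generate_cohort(CohortSpec(seed=42))


def match_site(truth, site):
    """Index of the ground-truth site nearest a detected site."""
    d = np.linalg.norm(truth.rest_positions_px - site.post_rest_position, axis=1)
    return int(np.argmin(d))
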