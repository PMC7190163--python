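"""Shared fixtures: synthetic experiments and pipeline runs reused across
the suite (session-scoped — full pipeline runs take seconds)."""

from __future__ import annotations

import time

import pytest

from fishcount.assignment import AssignmentParams
from fishcount.pipeline import RunConfig, run
from fishcount.spot_detection import DetectionParams
from fishcount.synth_fixtures import (
    CellType, FixtureParams, expected_spot_mass, generate_experiment,
    generate_spot_field,
)

# detection settings for the standard synthetic optics: min_mass at half
# the analytic integrated spot intensity, well above noise masses and well
# below every true spot's mass
STANDARD_MIN_MASS = 0.5 * expected_spot_mass(0.5, (1.0, 1.5, 1.5), 3)


def standard_detection_params() -> DetectionParams:
    return DetectionParams(
        spot_radius=3, min_mass=STANDARD_MIN_MASS, separation=2.0,
        percentile_floor=99.5,
    )


def standard_assignment_params(mode: str = "nascent") -> AssignmentParams:
    return AssignmentParams(
        marker_threshold={"GFP": 0.3, "mCherry": 0.3}, mode=mode
    )


@pytest.fixture(scope="session")
def standard_fixture():
    """6 nuclei, two cell types (3 GFP / 3 mCherry), HES1 means 8 vs 2."""
    params = FixtureParams(seed=7)
    exp, truth = generate_experiment(params)
    return exp, truth, params


@pytest.fixture(scope="session")
def standard_run(standard_fixture, tmp_path_factory):
    """Full nascent-mode pipeline run on the standard fixture, with QC
    images, plus its wall-clock runtime."""
    exp, truth, params = standard_fixture
    out = tmp_path_factory.mktemp("standard_run")
    cfg = RunConfig(
        out_dir=str(out),
        detect=standard_detection_params(),
        assign=standard_assignment_params(),
    )
    t0 = time.perf_counter()
    result = run(cfg, experiment=exp)
    elapsed = time.perf_counter() - t0
    return result, truth, cfg, elapsed


@pytest.fixture(scope="session")
def small_fixture():
    """3 nuclei, one cell type, low transcript counts — for fast pipeline
    plumbing tests (caching, metadata, edits)."""
    params = FixtureParams(
        image_shape=(16, 224, 224),
        n_nuclei=3,
        nucleus_radius=(14.0, 16.0),
        cell_types=(CellType("GFP", 1.0, {"HES1": 4.0}),),
        seed=11,
    )
    exp, truth = generate_experiment(params)
    return exp, truth, params


@pytest.fixture(scope="session")
def spot_field_100():
    """100 identical PSF spots, peak SNR 50, pairwise separation >= 6."""
    vol, truth = generate_spot_field(
        n_spots=100, shape=(16, 160, 160), peak=0.5, noise_sigma=0.01,
        min_separation=6.0, seed=1,
    )
    return vol, truth
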