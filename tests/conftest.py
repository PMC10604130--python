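import pytest
from hypothesis import HealthCheck, settings

from qpmorph import (
    SpermGroundTruth,
    StudyConfig,
    WHORanges,
    render_phase_image,
    simulate_study,
)

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def ranges():
    return WHORanges()


@pytest.fixture(scope="session")
def canonical_truth():
    """A comfortably WHO-normal cell: 4.5 x 3.0 um, ratio 1.5, 50% cap."""
    return SpermGroundTruth(
        cell_id="C0",
        subject_id="S0",
        head_length_um=4.5,
        head_width_um=3.0,
        lw_ratio=1.5,
        acrosome_pct=50.0,
    )


@pytest.fixture(scope="session")
def clean_image(canonical_truth):
    """Noiseless, unblurred render of the canonical cell at 0.05 um/px."""
    return render_phase_image(canonical_truth, pixel_size=0.05)


@pytest.fixture(scope="session")
def small_bundle():
    """A 6-subject study with default noise and exclusions, seed-fixed."""
    return simulate_study(StudyConfig(subjects=6, seed=7))


@pytest.fixture(scope="session")
def clean_bundle():
    """A small study with no exclusions (all cells analyzable)."""
    return simulate_study(StudyConfig(subjects=4, seed=11, exclusion_probabilities={}))
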