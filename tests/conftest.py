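import pytest

from glycoquant.cohort import CohortGenerator, GeneratorConfig
from glycoquant.synthetic_slides import SlideSynthesisConfig, synthesize_slide


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig()

@pytest.fixture(scope="session")
def calibrated_generator(default_config):
    """Default generator; calibration is done once for the whole session."""
    return CohortGenerator(default_config)


@pytest.fixture(scope="session")
def cohort_study_size(calibrated_generator):
    """One cohort at the study sample size (n=1819)."""
    return calibrated_generator.generate(123)


@pytest.fixture(scope="session")
def big_cohort():
    """Large-n cohort for marginal-calibration checks."""
    return CohortGenerator(GeneratorConfig(n=100_000)).generate(7)


@pytest.fixture(scope="session")
def diffuse_slide():
    """Mid-fraction diffuse slide with truth, shared across imaging tests."""
    cfg = SlideSynthesisConfig(
        target_fraction=0.25, canvas_size=(640, 640), pattern="diffuse", seed=7
    )
    return synthesize_slide(cfg)


@pytest.fixture(scope="session")
def hotspot_slide():
    cfg = SlideSynthesisConfig(
        target_fraction=0.25, canvas_size=(640, 640), pattern="hotspot",
        n_sections=2, seed=11
    )
    return synthesize_slide(cfg)
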