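import pytest

from sixmwt.cohort import generate_cohort, preset
from sixmwt.registry import LinearEquationSpec, SexFormula


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Sample-2-like cohort whose distances come from the published model exactly."""
    return generate_cohort(preset("sample2_like", seed=42, sigma_log=0.0))


@pytest.fixture(scope="session")
def noisy_cohort():
    """Sample-2-like cohort with the default multiplicative noise."""
    return generate_cohort(preset("sample2_like", seed=7))


@pytest.fixture(scope="session")
def evaluation_cohort():
    """Sample-1-like cohort (the stage-1/stage-3 evaluation sample)."""
    return generate_cohort(preset("sample1_like", seed=3))


@pytest.fixture
def toy_equation():
    """A generic height+mass+age linear equation with a male intercept bonus."""
    slopes = {"height_cm": 5.14, "age_years": -5.32, "mass_kg": -1.80}
    return LinearEquationSpec(
        name="toy",
        citation="synthetic test equation",
        male=SexFormula(intercept=218.0 + 51.31, terms=slopes),
        female=SexFormula(intercept=218.0, terms=slopes),
        age_range=(50.0, 85.0),
    )
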