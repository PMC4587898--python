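"""Log-linear OLS fit: exact recovery, oracle equivalence, sampling properties."""

import math

import numpy as np
import pytest

from sixmwt.cohort import generate_cohort, preset
from sixmwt.fitting import SingularDesignError, fit_allometric, percent_change_per_year
from sixmwt.models import PUBLISHED_SAMPLE2_MODEL, AllometricModel
from sixmwt.subjects import Subject

TRUE = PUBLISHED_SAMPLE2_MODEL


def test_noise_free_cohort_recovers_generating_model(noise_free_cohort):
    fit = fit_allometric(noise_free_cohort)
    m = fit.model
    assert m.a_male == pytest.approx(TRUE.a_male, rel=1e-6)
    assert m.a_female == pytest.approx(TRUE.a_female, rel=1e-6)
    assert m.b == pytest.approx(TRUE.b, rel=1e-6)
    assert m.c == pytest.approx(TRUE.c, rel=1e-6)
    assert m.d == pytest.approx(TRUE.d, rel=1e-6)
    assert fit.adjusted_r2 == pytest.approx(1.0, abs=1e-9)
    assert fit.sigma_log == pytest.approx(0.0, abs=1e-9)


def _normal_equations_oracle(cohort):
    """Independent closed-form OLS: solve X'X beta = X'y directly."""
    y = np.log([s.observed_6mwt for s in cohort])
    X = np.column_stack([
        np.ones(len(cohort)),
        [1.0 if s.sex == "female" else 0.0 for s in cohort],
        np.log([s.height_cm for s in cohort]),
        np.log([s.mass_kg for s in cohort]),
        [s.age for s in cohort],
    ])
    return np.linalg.solve(X.T @ X, X.T @ y)


@pytest.mark.parametrize("seed,n_male,n_female", [(1, 30, 40), (2, 123, 123), (3, 200, 300)])
def test_fit_matches_normal_equations_oracle(seed, n_male, n_female):
    cohort = generate_cohort(preset("sample2_like", seed=seed, n_male=n_male, n_female=n_female))
    beta = _normal_equations_oracle(cohort)
    m = fit_allometric(cohort).model
    assert m.a_male == pytest.approx(math.exp(beta[0]), rel=1e-8)
    assert m.a_female == pytest.approx(math.exp(beta[0] + beta[1]), rel=1e-8)
    assert m.b == pytest.approx(beta[2], rel=1e-8)
    assert m.c == pytest.approx(beta[3], rel=1e-8)
    assert m.d == pytest.approx(beta[4], rel=1e-8)


def test_scaling_distances_scales_only_intercepts(noisy_cohort):
    """Multiplying every distance by k multiplies a_male, a_female by k and
    leaves b, c, d and the log-scale diagnostics unchanged."""
    k = 3.7
    scaled = [s.with_observed(k * s.observed_6mwt) for s in noisy_cohort]
    f0, f1 = fit_allometric(noisy_cohort), fit_allometric(scaled)
    assert f1.model.a_male == pytest.approx(k * f0.model.a_male, rel=1e-10)
    assert f1.model.a_female == pytest.approx(k * f0.model.a_female, rel=1e-10)
    assert f1.model.b == pytest.approx(f0.model.b, rel=1e-10)
    assert f1.model.c == pytest.approx(f0.model.c, rel=1e-10)
    assert f1.model.d == pytest.approx(f0.model.d, rel=1e-10)
    assert f1.sigma_log == pytest.approx(f0.sigma_log, rel=1e-9)
    assert f1.adjusted_r2 == pytest.approx(f0.adjusted_r2, rel=1e-9)


def test_fitted_b_within_analytic_standard_errors(noisy_cohort):
    fit = fit_allometric(noisy_cohort)
    assert abs(fit.model.b - TRUE.b) < 3 * fit.model.se_b


def test_parameter_recovery_and_ci_coverage():
    """200 seeded replicates of the derivation-sample design: each parameter's
    mean estimate lies within 2 Monte-Carlo SEs of truth and the 95% CI
    coverage for b, c, d falls in [90%, 99%]."""
    fits = [fit_allometric(generate_cohort(preset("sample2_like", seed=s)))
            for s in range(1, 201)]
    for attr, se_attr, truth in (("b", "se_b", TRUE.b), ("c", "se_c", TRUE.c),
                                 ("d", "se_d", TRUE.d)):
        est = np.array([getattr(f.model, attr) for f in fits])
        mc_se = est.std(ddof=1) / math.sqrt(len(est))
        assert abs(est.mean() - truth) < 2 * mc_se, attr
        covered = np.mean([
            abs(getattr(f.model, attr) - truth) <= 1.96 * getattr(f.model, se_attr)
            for f in fits
        ])
        assert 0.90 <= covered <= 0.99, attr
    for attr, truth in (("a_male", TRUE.a_male), ("a_female", TRUE.a_female)):
        est = np.array([getattr(f.model, attr) for f in fits])
        # back-transformed intercepts: compare on the log scale where the
        # estimator is unbiased
        log_est = np.log(est)
        mc_se = log_est.std(ddof=1) / math.sqrt(len(est))
        assert abs(log_est.mean() - math.log(truth)) < 2 * mc_se, attr


def test_recovery_error_shrinks_with_sample_size():
    """Consistency: median |b_hat - b| over 50 replicates is smaller at
    n=2000 than at n=246."""
    err_small, err_large = [], []
    for s in range(1, 51):
        small = fit_allometric(generate_cohort(preset("sample2_like", seed=s)))
        large = fit_allometric(generate_cohort(
            preset("sample2_like", seed=s, n_male=600, n_female=1400)))
        err_small.append(abs(small.model.b - TRUE.b))
        err_large.append(abs(large.model.b - TRUE.b))
    assert np.median(err_large) < np.median(err_small)


def test_constant_height_is_singular(noise_free_cohort):
    flat = [Subject(s.id, s.sex, s.age, 170.0, s.mass_kg, s.observed_6mwt)
            for s in noise_free_cohort]
    with pytest.raises(SingularDesignError):
        fit_allometric(flat)


def test_single_sex_requires_opt_in(noise_free_cohort):
    females = [s for s in noise_free_cohort if s.sex == "female"]
    with pytest.raises(ValueError, match="single sex"):
        fit_allometric(females)
    fit = fit_allometric(females, allow_single_sex=True)
    assert fit.model.a_male == fit.model.a_female
    assert fit.model.a_female == pytest.approx(TRUE.a_female, rel=1e-6)
    assert fit.model.b == pytest.approx(TRUE.b, rel=1e-6)


def test_minimum_cohort_size_enforced(noise_free_cohort):
    with pytest.raises(ValueError, match="at least 5"):
        fit_allometric(noise_free_cohort[:4])


@pytest.mark.parametrize(
    "d, expected",
    [(-0.009, 0.8959621227116354), (0.0, 0.0), (-0.693147, 50.0)],
)
def test_percent_change_per_year(d, expected):
    model = AllometricModel(a_male=290.6, a_female=260.3, b=0.525, c=-0.317, d=d)
    assert percent_change_per_year(model) == pytest.approx(expected, abs=1e-4)


def test_percent_change_rounds_to_published_summary():
    """d = -0.009 corresponds to the reported 0.9% decline per year."""
    assert round(percent_change_per_year(PUBLISHED_SAMPLE2_MODEL), 1) == 0.9
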