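"""Log-linear estimation of the allometric walk-distance model.

Taking natural logs of

    distance = a_sex * height^b * mass^c * exp(d * age) * exp(eps)

gives the linear model

    log(distance) = log a_sex + b*log(height) + c*log(mass) + d*age + eps

which is fitted by ordinary least squares with a sex-specific intercept
(an overall intercept plus a female shift) and exponents b, c and age slope
d shared across sexes. The fitted intercepts are back-transformed with
``exp``; adjusted R-squared, coefficient standard errors and the residual SD
are all reported on the log scale, where the model is linear and errors are
assumed homoscedastic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .models import AllometricModel
from .subjects import Subject

__all__ = ["FitResult", "SingularDesignError", "fit_allometric", "percent_change_per_year"]

_N_PARAMS = 4  # log a, b, c, d (the female shift adds a fifth column when both sexes are present)


class SingularDesignError(ValueError):
    """The design matrix is rank-deficient (e.g. constant height, or a single
    sex without opting into a shared intercept)."""


@dataclass(frozen=True)
class FitResult:
    """A fitted allometric model plus log-scale diagnostics."""

    model: AllometricModel
    se_log_a_male: float
    se_log_a_female: float
    n: int
    adjusted_r2: float
    sigma_log: float  # residual SD on the natural-log scale
    f_p_value: float | None = None

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "se_log_a_male": self.se_log_a_male,
            "se_log_a_female": self.se_log_a_female,
            "n": self.n,
            "adjusted_r2": self.adjusted_r2,
            "sigma_log": self.sigma_log,
            "f_p_value": self.f_p_value,
            "percent_decline_per_year": percent_change_per_year(self.model),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    def report(self) -> str:
        m = self.model
        lines = [
            "Allometric walk-distance model (log-linear OLS fit)",
            f"  n = {self.n}, adjusted R^2 (log scale) = {self.adjusted_r2:.3f}, "
            f"residual log-SD = {self.sigma_log:.4f}",
            f"  distance (male)   = {m.a_male:.1f} * height_cm^{m.b:.3f} * "
            f"mass_kg^{m.c:.3f} * exp({m.d:.4f} * age)",
            f"  distance (female) = {m.a_female:.1f} * height_cm^{m.b:.3f} * "
            f"mass_kg^{m.c:.3f} * exp({m.d:.4f} * age)",
            f"  b = {m.b:.3f} (SE {m.se_b:.3f}); c = {m.c:.3f} (SE {m.se_c:.3f}); "
            f"d = {m.d:.4f} (SE {m.se_d:.4f})",
            f"  age effect: {percent_change_per_year(m):.1f}% decline in predicted "
            "distance per year of age",
        ]
        return "\n".join(lines)


def _design(cohort: Sequence[Subject], two_intercepts: bool) -> tuple[np.ndarray, np.ndarray]:
    y = np.array([math.log(s.observed_6mwt) for s in cohort])
    cols = [np.ones(len(cohort))]
    if two_intercepts:
        cols.append(np.array([1.0 if s.sex == "female" else 0.0 for s in cohort]))
    cols.append(np.array([math.log(s.height_cm) for s in cohort]))
    cols.append(np.array([math.log(s.mass_kg) for s in cohort]))
    cols.append(np.array([s.age for s in cohort]))
    return np.column_stack(cols), y


def fit_allometric(cohort: Sequence[Subject], *, allow_single_sex: bool = False) -> FitResult:
    """Fit the allometric model to a cohort with observed distances.

    Requires n >= 5, positive height/mass/distance throughout, and both sexes
    present unless ``allow_single_sex`` opts into one shared intercept (then
    ``a_male == a_female``).
    """
    cohort = list(cohort)
    n = len(cohort)
    if n < 5:
        raise ValueError(f"need at least 5 subjects to fit, got {n}")
    for s in cohort:
        if s.observed_6mwt is None:
            raise ValueError(f"subject {s.id!r} has no observed 6MWT distance")
    sexes = {s.sex for s in cohort}
    two_intercepts = len(sexes) == 2
    if not two_intercepts and not allow_single_sex:
        raise ValueError(
            "cohort contains a single sex; pass allow_single_sex=True to fit "
            "one shared intercept"
        )

    X, y = _design(cohort, two_intercepts)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError(
            "design matrix is rank-deficient (a covariate is constant or collinear)"
        )
    if n <= X.shape[1]:
        raise ValueError(f"n={n} leaves no residual degrees of freedom")

    res = sm.OLS(y, X).fit()
    params = res.params
    cov = res.cov_params()

    log_a_male = params[0]
    if two_intercepts:
        log_a_female = params[0] + params[1]
        var_f = cov[0, 0] + cov[1, 1] + 2 * cov[0, 1]
        se_log_a_female = math.sqrt(max(var_f, 0.0))
        k = 2
    else:
        log_a_female = params[0]
        se_log_a_female = float(res.bse[0])
        k = 1

    sigma_log = math.sqrt(float(res.scale))
    model = AllometricModel(
        a_male=math.exp(log_a_male),
        a_female=math.exp(log_a_female),
        b=float(params[k]),
        c=float(params[k + 1]),
        d=float(params[k + 2]),
        se_b=float(res.bse[k]),
        se_c=float(res.bse[k + 1]),
        se_d=float(res.bse[k + 2]),
        n_fit=n,
        adjusted_r2=float(res.rsquared_adj),
        sigma_log=sigma_log,
    )
    return FitResult(
        model=model,
        se_log_a_male=float(res.bse[0]),
        se_log_a_female=se_log_a_female,
        n=n,
        adjusted_r2=float(res.rsquared_adj),
        sigma_log=sigma_log,
        f_p_value=float(res.f_pvalue),
    )


def percent_change_per_year(model: AllometricModel) -> float:
    """Percent decline in predicted distance per year of age: 100*(1 - e^d).

    Positive for a model that declines with age (d < 0); negative (an
    increase) when d > 0; zero when age has no effect. With the published age
    coefficient d = -0.009 this is ~0.9% per year.
    """
    return 100.0 * (1.0 - math.exp(model.d))
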