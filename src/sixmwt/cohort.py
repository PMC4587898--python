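"""Synthetic cohorts of community-dwelling older adults.

The generator emulates the two study samples (Coventry: 62 male / 63 female,
age 65.3 +/- 7.5 y; Porto: 74 male / 172 female, age 68.3 +/- 5.3 y) whose
participant-level data were never deposited. Ages are truncated-normal on a
bounded range, (log height, log mass) are drawn jointly normal with a
configurable correlation, and walk distances follow the allometric model with
multiplicative lognormal noise:

    observed = a_sex * h**b * m**c * exp(d*age) * exp(eps),  eps ~ N(0, sigma_log^2)

so that log-linear OLS is the natural estimator on these cohorts. Each cohort
draws from a single ``numpy`` Generator seeded explicitly: the same config is
bit-reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import stats

from .models import AllometricModel, PUBLISHED_SAMPLE2_MODEL, predict_allometric
from .subjects import Subject

__all__ = ["SyntheticConfig", "generate_cohort", "preset", "PRESET_NAMES"]

PRESET_NAMES = ("sample1_like", "sample2_like")

# Plausible anthropometry for European adults aged 50-85; neither study
# sample reports height/mass summaries, so these are package defaults and
# fully overridable. Heights are (mean cm, sd cm); masses are
# (log-median kg, log-sd) of a lognormal.
DEFAULT_HEIGHT_PARAMS = {"male": (172.0, 7.0), "female": (159.0, 6.0)}
DEFAULT_MASS_PARAMS = {"male": (math.log(78.0), 0.15), "female": (math.log(68.0), 0.15)}
DEFAULT_LOG_CORRELATION = 0.4
DEFAULT_SIGMA_LOG = 0.12
DEFAULT_AGE_BOUNDS = (50.0, 85.0)


@dataclass(frozen=True)
class SyntheticConfig:
    """Full generative specification for one cohort."""

    n_male: int
    n_female: int
    age_mean: float
    age_sd: float
    age_bounds: tuple[float, float] = DEFAULT_AGE_BOUNDS
    height_params: dict = field(default_factory=lambda: dict(DEFAULT_HEIGHT_PARAMS))
    mass_params: dict = field(default_factory=lambda: dict(DEFAULT_MASS_PARAMS))
    height_mass_log_correlation: float = DEFAULT_LOG_CORRELATION
    generating_model: AllometricModel = PUBLISHED_SAMPLE2_MODEL
    sigma_log: float = DEFAULT_SIGMA_LOG
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_male < 0 or self.n_female < 0:
            raise ValueError("sex counts must be non-negative")
        if self.n_male + self.n_female < 4:
            raise ValueError("need at least 4 subjects to identify the 4-parameter model")
        lo, hi = self.age_bounds
        if not lo < hi:
            raise ValueError(f"empty age truncation interval [{lo}, {hi}]")
        if self.age_sd <= 0:
            raise ValueError("age_sd must be positive")
        # reject truncation windows the rejection sampler cannot realistically hit
        mass_in_window = stats.norm.cdf(hi, self.age_mean, self.age_sd) - stats.norm.cdf(
            lo, self.age_mean, self.age_sd
        )
        if mass_in_window < 1e-6:
            raise ValueError(
                f"age distribution N({self.age_mean}, {self.age_sd}^2) places "
                f"negligible mass in [{lo}, {hi}]"
            )
        for sex in ("male", "female"):
            mean, sd = self.height_params[sex]
            if mean <= 0 or sd <= 0:
                raise ValueError(f"{sex} height parameters must be positive")
            _, log_sd = self.mass_params[sex]
            if log_sd <= 0:
                raise ValueError(f"{sex} mass log-sd must be positive")
        rho = self.height_mass_log_correlation
        if not -1 < rho < 1:
            raise ValueError("height-mass log correlation must lie strictly in (-1, 1)")
        if self.sigma_log < 0:
            raise ValueError("sigma_log must be non-negative")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["age_bounds"] = list(self.age_bounds)
        d["generating_model"] = self.generating_model.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        d["age_bounds"] = tuple(d["age_bounds"])
        d["generating_model"] = AllometricModel.from_dict(d["generating_model"])
        d["height_params"] = {k: tuple(v) for k, v in d["height_params"].items()}
        d["mass_params"] = {k: tuple(v) for k, v in d["mass_params"].items()}
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "SyntheticConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def preset(name: str, seed: int = 0, **overrides) -> SyntheticConfig:
    """A ready-made config emulating one of the two study samples.

    ``sample1_like``: 62 male / 63 female, age 65.3 +/- 7.5 y (evaluation and
    cross-validation sample). ``sample2_like``: 74 male / 172 female, age
    68.3 +/- 5.3 y (derivation sample). Both use the published derivation-
    sample coefficients as generating truth. Keyword overrides replace any
    config field.
    """
    if name == "sample1_like":
        base = dict(n_male=62, n_female=63, age_mean=65.3, age_sd=7.5)
    elif name == "sample2_like":
        base = dict(n_male=74, n_female=172, age_mean=68.3, age_sd=5.3)
    else:
        raise ValueError(f"unknown preset {name!r}; expected one of {PRESET_NAMES}")
    base["seed"] = seed
    base.update(overrides)
    return SyntheticConfig(**base)


def _truncated_normal(rng: np.random.Generator, n: int, mean: float, sd: float,
                      bounds: tuple[float, float]) -> np.ndarray:
    """Truncated-normal draws by rejection sampling."""
    lo, hi = bounds
    out = np.empty(0)
    while out.size < n:
        draw = rng.normal(mean, sd, size=max(4 * (n - out.size), 16))
        out = np.concatenate([out, draw[(draw >= lo) & (draw <= hi)]])
    return out[:n]


def _lognormal_params_matching(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the lognormal whose mean and SD match the given values."""
    sigma2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def generate_cohort(config: SyntheticConfig) -> list[Subject]:
    """Draw one cohort; identical config (incl. seed) gives an identical cohort.

    Heights are matched in mean and SD to the configured per-sex normal via a
    lognormal, so that (log height, log mass) can be drawn jointly normal with
    the configured correlation. With ``sigma_log=0`` every observed distance
    equals the generating model's prediction exactly.
    """
    rng = np.random.default_rng(config.seed)
    rho = config.height_mass_log_correlation
    cohort: list[Subject] = []
    counter = 1
    for sex, n in (("male", config.n_male), ("female", config.n_female)):
        if n == 0:
            continue
        ages = _truncated_normal(rng, n, config.age_mean, config.age_sd, config.age_bounds)
        h_mean, h_sd = config.height_params[sex]
        mu_h, s_h = _lognormal_params_matching(h_mean, h_sd)
        mu_m, s_m = config.mass_params[sex]
        cov = np.array([[s_h**2, rho * s_h * s_m], [rho * s_h * s_m, s_m**2]])
        logs = rng.multivariate_normal([mu_h, mu_m], cov, size=n)
        heights = np.exp(logs[:, 0])
        masses = np.exp(logs[:, 1])
        eps = rng.normal(0.0, config.sigma_log, size=n) if config.sigma_log > 0 else np.zeros(n)
        for i in range(n):
            s = Subject(
                id=f"S{counter:04d}",
                sex=sex,
                age=float(ages[i]),
                height_cm=float(heights[i]),
                mass_kg=float(masses[i]),
            )
            d = predict_allometric(config.generating_model, s) * math.exp(eps[i])
            cohort.append(s.with_observed(d))
            counter += 1
    return cohort
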