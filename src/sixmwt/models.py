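"""The allometric six-minute-walk model.

The model is the multiplicative power law

    distance (m) = a_sex * height_cm**b * mass_kg**c * exp(d * age)

with sex entering only through the intercept ``a_sex``. On the natural-log
scale it is linear in (log height, log mass, age), which is how it is fitted
(see :mod:`sixmwt.fitting`). The age coefficient ``d`` is stored signed: a
negative ``d`` means walk distance declines with age.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

__all__ = ["AllometricModel", "predict_allometric", "PUBLISHED_SAMPLE2_MODEL"]


@dataclass(frozen=True)
class AllometricModel:
    a_male: float  # metres, multiplicative intercept
    a_female: float  # metres
    b: float  # height exponent
    c: float  # mass exponent
    d: float  # per-year log-scale age slope, signed (negative = decline)
    se_b: float | None = None
    se_c: float | None = None
    se_d: float | None = None
    n_fit: int | None = None
    adjusted_r2: float | None = None
    sigma_log: float | None = None  # residual SD on the log scale

    def __post_init__(self) -> None:
        if not (self.a_male > 0 and self.a_female > 0):
            raise ValueError("multiplicative intercepts must be positive")
        for name in ("se_b", "se_c", "se_d"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")
        # exp(d*age) must stay finite over the supported age range
        for age in (50.0, 85.0):
            if not math.isfinite(math.exp(self.d * age)):
                raise ValueError("exp(d*age) overflows on [50, 85]")

    def intercept(self, sex: str) -> float:
        if sex == "male":
            return self.a_male
        if sex == "female":
            return self.a_female
        raise ValueError(f"unknown sex {sex!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AllometricModel":
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "AllometricModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def predict_allometric(model: AllometricModel, subject) -> float:
    """Predicted walk distance (m) for one subject under ``model``.

    Equals ``exp(log a_sex + b*log height + c*log mass + d*age)``; raises on
    non-positive height or mass.
    """
    if not (subject.height_cm > 0 and subject.mass_kg > 0):
        raise ValueError("height and mass must be positive for an allometric prediction")
    a = model.intercept(subject.sex)
    return (
        a
        * subject.height_cm ** model.b
        * subject.mass_kg ** model.c
        * math.exp(model.d * subject.age)
    )


#: Coefficients of the allometric equation fitted to the Porto derivation
#: sample (n=246, 74 male / 172 female, mean age 68.3 y): the default
#: generating truth for the synthetic cohorts.
PUBLISHED_SAMPLE2_MODEL = AllometricModel(
    a_male=290.6,
    a_female=260.3,
    b=0.525,
    c=-0.317,
    d=-0.009,
    se_b=0.255,
    se_c=0.060,
    se_d=0.002,
    n_fit=246,
    adjusted_r2=0.526,
)
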