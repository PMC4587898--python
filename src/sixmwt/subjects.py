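"""Subject records and the cohort table format.

A cohort is a list of :class:`Subject` records, interchangeable with a CSV
table using the columns ``id, sex, age_years, height_cm, mass_kg, six_mwt_m``
(sex coded ``M``/``F``, missing walk distance left empty).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Subject",
    "SchemaError",
    "cohort_to_frame",
    "frame_to_cohort",
    "write_cohort_csv",
    "read_cohort_csv",
]

SEXES = ("male", "female")
_SEX_CODE = {"male": "M", "female": "F"}
_SEX_DECODE = {"M": "male", "F": "female"}

COHORT_COLUMNS = ["id", "sex", "age_years", "height_cm", "mass_kg", "six_mwt_m"]


class SchemaError(ValueError):
    """A cohort table violates the documented schema."""


@dataclass(frozen=True)
class Subject:
    """One participant: demographics, anthropometry and (optionally) the
    observed six-minute-walk distance in metres."""

    id: str
    sex: str  # "male" | "female"
    age: float  # years
    height_cm: float
    mass_kg: float
    observed_6mwt: float | None = None  # metres

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}; expected one of {SEXES}")
        if not self.height_cm > 0:
            raise ValueError(f"height must be positive, got {self.height_cm}")
        if not self.mass_kg > 0:
            raise ValueError(f"mass must be positive, got {self.mass_kg}")
        if self.observed_6mwt is not None and not self.observed_6mwt > 0:
            raise ValueError(f"observed 6MWT must be positive, got {self.observed_6mwt}")

    def with_observed(self, distance_m: float) -> "Subject":
        return replace(self, observed_6mwt=float(distance_m))


def cohort_to_frame(cohort: Sequence[Subject]) -> pd.DataFrame:
    rows = [
        {
            "id": s.id,
            "sex": _SEX_CODE[s.sex],
            "age_years": s.age,
            "height_cm": s.height_cm,
            "mass_kg": s.mass_kg,
            "six_mwt_m": s.observed_6mwt,
        }
        for s in cohort
    ]
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def frame_to_cohort(frame: pd.DataFrame) -> list[Subject]:
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"cohort table missing columns: {missing}")
    cohort: list[Subject] = []
    for i, row in frame.iterrows():
        code = str(row["sex"]).strip()
        if code not in _SEX_DECODE:
            raise SchemaError(f"row {i}, column 'sex': unknown code {code!r} (use M or F)")
        raw = row["six_mwt_m"]
        observed = None if pd.isna(raw) else float(raw)
        try:
            cohort.append(
                Subject(
                    id=str(row["id"]),
                    sex=_SEX_DECODE[code],
                    age=float(row["age_years"]),
                    height_cm=float(row["height_cm"]),
                    mass_kg=float(row["mass_kg"]),
                    observed_6mwt=observed,
                )
            )
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"row {i}: {exc}") from exc
    return cohort


def write_cohort_csv(cohort: Sequence[Subject], path: str | Path | io.TextIOBase) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


def read_cohort_csv(path: str | Path | io.TextIOBase) -> list[Subject]:
    try:
        frame = pd.read_csv(path, dtype={"id": str, "sex": str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise SchemaError(f"cannot parse cohort CSV: {exc}") from exc
    return frame_to_cohort(frame)


def split_actual(cohort: Iterable[Subject]) -> list[float]:
    """Observed distances of a cohort; raises if any are missing."""
    out = []
    for s in cohort:
        if s.observed_6mwt is None:
            raise ValueError(f"subject {s.id!r} has no observed 6MWT distance")
        out.append(s.observed_6mwt)
    return out
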