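"""Sex-stratified linear reference equations for the six-minute walk test.

Published reference equations predict walk distance (m) from some subset of
age, height and body mass, usually with separate male/female formulas (or a
sex dummy, which is folded into per-sex intercepts here). Coefficients are
data, not code: the shipped registry is a JSON document in which every entry
carries its citation and a provenance note, and users can load their own.

Only the closed covariate set {age_years, height_cm, mass_kg} is accepted —
units are fixed by the key names (equations written in metres of height must
be converted to cm before entry).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

from .subjects import Subject

__all__ = [
    "ALLOWED_COVARIATES",
    "LinearEquationSpec",
    "SexFormula",
    "RegistryError",
    "EquationApplicabilityWarning",
    "evaluate_equation",
    "evaluate_equation_cohort",
    "load_registry",
    "builtin_registry",
]

ALLOWED_COVARIATES = ("age_years", "height_cm", "mass_kg")


class RegistryError(ValueError):
    """A registry document is malformed."""


class EquationApplicabilityWarning(UserWarning):
    """An equation was evaluated outside its stated validity range, or
    produced a non-positive distance."""


@dataclass(frozen=True)
class SexFormula:
    intercept: float  # metres
    terms: Mapping[str, float]  # covariate key -> coefficient

    def __post_init__(self) -> None:
        bad = [k for k in self.terms if k not in ALLOWED_COVARIATES]
        if bad:
            raise RegistryError(
                f"unknown covariate keys {bad}; allowed: {list(ALLOWED_COVARIATES)}"
            )


@dataclass(frozen=True)
class LinearEquationSpec:
    name: str
    citation: str
    male: SexFormula
    female: SexFormula
    age_range: tuple[float, float]  # stated validity, years
    population: str = ""
    provenance: str = ""

    def formula(self, sex: str) -> SexFormula:
        if sex == "male":
            return self.male
        if sex == "female":
            return self.female
        raise ValueError(f"unknown sex {sex!r}")


def _covariate_value(subject: Subject, key: str) -> float:
    if key == "age_years":
        return subject.age
    if key == "height_cm":
        return subject.height_cm
    if key == "mass_kg":
        return subject.mass_kg
    raise KeyError(f"subject has no covariate {key!r}")


def evaluate_equation(spec: LinearEquationSpec, subject: Subject) -> float:
    """Predicted distance (m) for one subject.

    Warns (``EquationApplicabilityWarning``) — never errors — when the
    subject's age falls outside the equation's stated validity range or the
    prediction comes out non-positive: cross-population evaluation outside
    the source population is exactly the use case.
    """
    f = spec.formula(subject.sex)
    value = f.intercept + sum(
        coef * _covariate_value(subject, key) for key, coef in f.terms.items()
    )
    lo, hi = spec.age_range
    if not lo <= subject.age <= hi:
        warnings.warn(
            f"{spec.name}: subject age {subject.age:.1f} y outside the stated "
            f"validity range [{lo:g}, {hi:g}]",
            EquationApplicabilityWarning,
            stacklevel=2,
        )
    if value <= 0:
        warnings.warn(
            f"{spec.name}: non-positive predicted distance ({value:.1f} m)",
            EquationApplicabilityWarning,
            stacklevel=2,
        )
    return value


def evaluate_equation_cohort(spec: LinearEquationSpec, cohort: Sequence[Subject]) -> list[float]:
    """Vectorized evaluation with one summary warning per issue kind."""
    lo, hi = spec.age_range
    out: list[float] = []
    n_out_of_range = 0
    n_nonpositive = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", EquationApplicabilityWarning)
        for s in cohort:
            v = evaluate_equation(spec, s)
            n_out_of_range += not (lo <= s.age <= hi)
            n_nonpositive += v <= 0
            out.append(v)
    if n_out_of_range:
        warnings.warn(
            f"{spec.name}: {n_out_of_range}/{len(cohort)} subjects outside the "
            f"stated age range [{lo:g}, {hi:g}]",
            EquationApplicabilityWarning,
            stacklevel=2,
        )
    if n_nonpositive:
        warnings.warn(
            f"{spec.name}: {n_nonpositive}/{len(cohort)} non-positive predictions",
            EquationApplicabilityWarning,
            stacklevel=2,
        )
    return out


def _parse_formula(entry_name: str, raw: dict) -> SexFormula:
    try:
        intercept = float(raw["intercept"])
        terms = {str(k): float(v) for k, v in raw.get("terms", {}).items()}
    except (KeyError, TypeError, ValueError) as exc:
        raise RegistryError(f"entry {entry_name!r}: malformed formula: {exc}") from exc
    try:
        return SexFormula(intercept=intercept, terms=terms)
    except RegistryError as exc:
        raise RegistryError(f"entry {entry_name!r}: {exc}") from exc


def _parse_entries(doc: list) -> list[LinearEquationSpec]:
    registry: list[LinearEquationSpec] = []
    seen: set[str] = set()
    for raw in doc:
        name = str(raw.get("name", "<unnamed>"))
        if name in seen:
            raise RegistryError(f"duplicate equation name {name!r}")
        seen.add(name)
        for sex in ("male", "female"):
            if sex not in raw:
                raise RegistryError(f"entry {name!r}: missing {sex} formula")
        age_range = raw.get("age_range")
        if not (isinstance(age_range, (list, tuple)) and len(age_range) == 2):
            raise RegistryError(f"entry {name!r}: age_range must be [lo, hi]")
        registry.append(
            LinearEquationSpec(
                name=name,
                citation=str(raw.get("citation", "")),
                male=_parse_formula(name, raw["male"]),
                female=_parse_formula(name, raw["female"]),
                age_range=(float(age_range[0]), float(age_range[1])),
                population=str(raw.get("population", "")),
                provenance=str(raw.get("provenance", "")),
            )
        )
    return registry


def load_registry(path: str | Path) -> list[LinearEquationSpec]:
    """Load an ordered equation registry from a JSON document.

    The document is a list of entries, each with ``name``, ``citation``,
    ``male``/``female`` ``{intercept, terms}``, ``age_range`` and a
    ``provenance`` note. An empty list is a valid (empty) registry.
    """
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise RegistryError(f"cannot parse registry file: {exc}") from exc
    if doc is None or doc == "":
        return []
    if not isinstance(doc, list):
        raise RegistryError("registry document must be a JSON list of entries")
    return _parse_entries(doc)


def builtin_registry() -> list[LinearEquationSpec]:
    """The ten reference equations shipped with the package.

    See each entry's ``provenance`` field: some coefficient sets are
    transcriptions that have not been re-verified against the original
    publication and should be checked before any substantive use.
    """
    text = resources.files("sixmwt.data").joinpath("equations.json").read_text()
    return _parse_entries(json.loads(text))
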