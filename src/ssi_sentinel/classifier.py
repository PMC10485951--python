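"""High/low deep-SSI probability classification of component profiles.

A rule is declarative: a set of *required* components (all must be
present) plus a minimum number of *optional* components. This threshold
form expresses both published algorithms:

* ``original``  — microbiology culture required, plus at least one of the
  other four components (microbiology is necessary but not sufficient).
* ``adapted``   — no required component; at least two of the four
  non-microbiology components (the adaptation that drops the culture
  requirement, for settings where culturing suspected deep SSI is not
  routine practice).

In a semi-automated design, *high* probability means the record goes to
manual chart review; *low* means it is counted as no deep SSI without
review.
"""
from __future__ import annotations

from typing import Iterable, Literal, Sequence, Union

import pandas as pd
import yaml
from pydantic import BaseModel, model_validator

from .components import COMPONENT_NAMES, ComponentProfile

__all__ = [
    "AlgorithmRule",
    "Classification",
    "BUILTIN_RULES",
    "builtin_rule",
    "classify_surgery",
    "classify_cohort",
    "classify_frame",
    "load_rule",
]


class AlgorithmRule(BaseModel):
    name: str
    required: set[str] = set()
    optional: set[str] = set()
    min_optional: int = 0

    @model_validator(mode="after")
    def _validate(self) -> "AlgorithmRule":
        known = set(COMPONENT_NAMES)
        unknown = (self.required | self.optional) - known
        if unknown:
            raise ValueError(f"unknown component names: {sorted(unknown)}")
        if self.required & self.optional:
            raise ValueError(
                f"components in both required and optional: {sorted(self.required & self.optional)}"
            )
        if not 0 <= self.min_optional <= len(self.optional):
            raise ValueError(
                f"min_optional={self.min_optional} outside 0..{len(self.optional)}"
            )
        return self


class Classification(BaseModel):
    surgery_id: str
    algorithm: str
    probability_class: Literal["high", "low"]


BUILTIN_RULES: dict[str, AlgorithmRule] = {
    "original": AlgorithmRule(
        name="original",
        required={"microbiology"},
        optional={"admissions", "reoperation", "radiology", "antibiotics"},
        min_optional=1,
    ),
    "adapted": AlgorithmRule(
        name="adapted",
        required=set(),
        optional={"admissions", "reoperation", "radiology", "antibiotics"},
        min_optional=2,
    ),
}


def builtin_rule(name: str) -> AlgorithmRule:
    """Return a copy of a built-in rule (``original`` or ``adapted``)."""
    try:
        return BUILTIN_RULES[name].model_copy(deep=True)
    except KeyError:
        raise ValueError(
            f"unknown rule {name!r}; available: {sorted(BUILTIN_RULES)}"
        ) from None


def load_rule(source: Union[str, "AlgorithmRule"]) -> AlgorithmRule:
    """Resolve a rule from a built-in name, a YAML/JSON file path, or an
    AlgorithmRule instance."""
    if isinstance(source, AlgorithmRule):
        return source
    if source in BUILTIN_RULES:
        return builtin_rule(source)
    try:
        with open(source) as fh:
            payload = yaml.safe_load(fh)
    except FileNotFoundError:
        raise ValueError(
            f"unknown rule {source!r}: not a built-in ({sorted(BUILTIN_RULES)}) "
            "and no such file"
        ) from None
    return AlgorithmRule(**payload)


def classify_surgery(profile: ComponentProfile, rule: AlgorithmRule) -> Classification:
    """High iff all required components are true and at least
    ``min_optional`` of the optional components are true."""
    flags = profile.flags()
    high = all(flags[c] for c in rule.required) and (
        sum(flags[c] for c in rule.optional) >= rule.min_optional
    )
    return Classification(
        surgery_id=profile.surgery_id,
        algorithm=rule.name,
        probability_class="high" if high else "low",
    )


def classify_cohort(
    profiles: Iterable[ComponentProfile], rule: AlgorithmRule
) -> list[Classification]:
    """Element-wise classification preserving surgery order; duplicate
    surgery ids are rejected."""
    out: list[Classification] = []
    seen: set[str] = set()
    for p in profiles:
        if p.surgery_id in seen:
            raise ValueError(f"duplicate surgery_id {p.surgery_id!r}")
        seen.add(p.surgery_id)
        out.append(classify_surgery(p, rule))
    return out


def classify_frame(profiles: pd.DataFrame, rule: AlgorithmRule) -> pd.Series:
    """Vectorised classification of a profiles DataFrame (as produced by
    ``components.extract_profiles``); returns a boolean ``high`` Series
    aligned to the input index."""
    ok_required = pd.Series(True, index=profiles.index)
    for c in rule.required:
        ok_required &= profiles[c].astype(bool)
    n_opt = sum(
        (profiles[c].astype(int) for c in rule.optional),
        start=pd.Series(0, index=profiles.index),
    )
    return ok_required & (n_opt >= rule.min_optional)
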