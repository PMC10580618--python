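"""Condition registry and intervention-system taxonomy.

The survey instrument rates 47 conditions for implementation, organized in
seven categories (prime implementer, co-implementer(s), intervention, prime
implementer's organization, co-implementer's organization(s), broader
context, implementation strategy).  Each implemented intervention is
characterized by an *intervention system*: the triple of core behaviour
change method, main health theme and primary implementation setting.

This module owns:

* the closed enumerations for methods, themes and settings and the
  :class:`SystemKey` triple, with case-insensitive parsing;
* :class:`Condition` / :class:`ConditionRegistry` with the default 47-item
  registry and CSV loading for user-supplied registries;
* the free-text recode map used to fold written-in "most important"
  answers back onto pre-listed conditions (unmatchable answers are
  dropped, mirroring how unspecific write-ins are handled in practice).
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Optional, Union

import pandas as pd

logger = logging.getLogger("bottleneckscan")

__all__ = [
    "ValidationError",
    "Method",
    "Theme",
    "Setting",
    "SystemKey",
    "parse_system",
    "ConditionCategory",
    "Condition",
    "ConditionRegistry",
    "build_default_registry",
    "load_registry",
    "RecodeMap",
    "load_recode_map",
    "recode_added_condition",
    "DROPPED",
]


class ValidationError(ValueError):
    """Raised when survey inputs violate the taxonomy or schema."""


class Method(str, enum.Enum):
    """Core behaviour change method employed by an intervention."""

    EDUCATION = "education"
    REGULATION = "regulation"
    FACILITATION = "facilitation"
    CITIZEN_PARTICIPATION = "citizen_participation"
    CASE_FINDING = "case_finding"


class Theme(str, enum.Enum):
    """Main health theme addressed."""

    OVERWEIGHT = "overweight"
    ALCOHOL = "alcohol"
    OTHER = "other"


class Setting(str, enum.Enum):
    """Primary implementation setting."""

    SCHOOL = "school"
    OUTDOOR_PUBLIC = "outdoor_public"
    SPORTS_FACILITY = "sports_facility"
    HOME = "home"
    COMMERCIAL_BUILDING = "commercial_building"
    HEALTH_WELFARE_BUILDING = "health_welfare_building"
    PUBLIC_BUILDING = "public_building"


#: characteristic name -> enumeration, in reporting order
CHARACTERISTICS: dict[str, type[enum.Enum]] = {
    "method": Method,
    "theme": Theme,
    "setting": Setting,
}


class SystemKey(NamedTuple):
    """An intervention system: (method, theme, setting), stored as the
    enum value strings so keys group naturally in tabular output."""

    method: str
    theme: str
    setting: str

    def level(self, characteristic: str) -> str:
        """Return this system's level for ``method``/``theme``/``setting``."""
        if characteristic not in CHARACTERISTICS:
            raise ValidationError(f"unknown characteristic {characteristic!r}")
        return getattr(self, characteristic)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.method}|{self.theme}|{self.setting}"


def _normalize_token(token: str) -> str:
    return re.sub(r"[\s/-]+", "_", str(token).strip().lower()).strip("_")


def _parse_level(token: str, characteristic: str) -> str:
    enum_cls = CHARACTERISTICS[characteristic]
    norm = _normalize_token(token)
    values = {m.value for m in enum_cls}
    if norm not in values:
        raise ValidationError(
            f"unknown {characteristic} {token!r}; expected one of {sorted(values)}"
        )
    return norm


def parse_system(method: str, theme: str, setting: str) -> SystemKey:
    """Parse and validate an intervention-system triple (case-insensitive;
    spaces, hyphens and slashes are treated as underscores)."""
    return SystemKey(
        _parse_level(method, "method"),
        _parse_level(theme, "theme"),
        _parse_level(setting, "setting"),
    )


# --------------------------------------------------------------------------
# Condition registry
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConditionCategory:
    """One of the seven blocks of condition statements."""

    id: str
    label: str
    expected_count: int
    prefix: str


CATEGORIES: tuple[ConditionCategory, ...] = (
    ConditionCategory("implementer", "Prime implementer", 5, "imp"),
    ConditionCategory("co_implementer", "Co-implementer(s)", 5, "coimp"),
    ConditionCategory("intervention", "Intervention", 10, "int"),
    ConditionCategory("implementer_org", "Prime implementer's organization", 10, "org"),
    ConditionCategory("co_implementer_org", "Co-implementer's organization(s)", 11, "coorg"),
    ConditionCategory("broader_context", "Broader context", 4, "ctx"),
    ConditionCategory("implementation_strategy", "Implementation strategy", 2, "strategy"),
)

CATEGORY_IDS = tuple(c.id for c in CATEGORIES)
_CATEGORY_BY_ID = {c.id: c for c in CATEGORIES}

#: exemplar statement heading each category block
_EXEMPLARS = {
    "implementer": "I have sufficient skills to implement the intervention",
    "co_implementer": "Other professionals are capable enough to implement the intervention",
    "intervention": "The intervention is easy to carry out",
    "implementer_org": "The intervention fits my organization's policy",
    "co_implementer_org": "Other organizations sufficiently support the intervention's health theme",
    "broader_context": "There is enough administrative and political support for the intervention",
    "implementation_strategy": "Good materials required for implementation are available",
}


@dataclass(frozen=True)
class Condition:
    """A single condition for implementation (one survey statement)."""

    condition_id: str
    category: str
    statement: str
    prelisted: bool = True

    def __post_init__(self) -> None:
        if self.category not in _CATEGORY_BY_ID:
            raise ValidationError(
                f"condition {self.condition_id!r}: unknown category {self.category!r}"
            )


@dataclass(frozen=True)
class ConditionRegistry:
    """Ordered collection of conditions, validated on construction."""

    conditions: tuple[Condition, ...]
    _index: dict[str, Condition] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        index: dict[str, Condition] = {}
        for cond in self.conditions:
            if cond.condition_id in index:
                raise ValidationError(f"duplicate condition_id {cond.condition_id!r}")
            index[cond.condition_id] = cond
        object.__setattr__(self, "_index", index)

    def __len__(self) -> int:
        return len(self.conditions)

    def __iter__(self):
        return iter(self.conditions)

    def __contains__(self, condition_id: str) -> bool:
        return condition_id in self._index

    def __getitem__(self, condition_id: str) -> Condition:
        return self._index[condition_id]

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(c.condition_id for c in self.conditions)

    def category_of(self, condition_id: str) -> str:
        return self._index[condition_id].category

    def category_counts(self) -> dict[str, int]:
        counts = {c.id: 0 for c in CATEGORIES}
        for cond in self.conditions:
            counts[cond.category] += 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition_id": [c.condition_id for c in self.conditions],
                "category": [c.category for c in self.conditions],
                "statement": [c.statement for c in self.conditions],
            }
        )

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False)


def build_default_registry() -> ConditionRegistry:
    """Build the default 47-condition registry.

    Per-category counts are (5, 5, 10, 10, 11, 4, 2).  The first statement
    of each block is the published exemplar; the remaining statements are
    placeholders, since computations depend only on ids and categories.
    A user registry CSV can supply the full statement texts.
    """
    conditions = []
    for cat in CATEGORIES:
        for k in range(1, cat.expected_count + 1):
            statement = (
                _EXEMPLARS[cat.id]
                if k == 1
                else f"Condition {k} relating to: {cat.label.lower()}"
            )
            conditions.append(
                Condition(f"{cat.prefix}_{k:02d}", cat.id, statement, prelisted=True)
            )
    return ConditionRegistry(tuple(conditions))


DEFAULT_CATEGORY_COUNTS = {c.id: c.expected_count for c in CATEGORIES}


def load_registry(path: Union[str, Path]) -> ConditionRegistry:
    """Load a registry from CSV (columns: condition_id, category, statement).

    Arbitrary per-category counts are allowed (toy registries are useful in
    tests), but a deviation from the default (5,5,10,10,11,4,2) is logged.
    """
    frame = pd.read_csv(path, dtype=str)
    required = {"condition_id", "category", "statement"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"registry file missing columns: {sorted(missing)}")
    conditions = []
    seen: set[str] = set()
    for row_no, row in enumerate(frame.itertuples(index=False), start=2):
        cid = str(row.condition_id).strip()
        cat = str(row.category).strip()
        if cat not in _CATEGORY_BY_ID:
            raise ValidationError(
                f"registry row {row_no}: unknown category {cat!r} for condition {cid!r}"
            )
        if cid in seen:
            raise ValidationError(f"registry row {row_no}: duplicate condition_id {cid!r}")
        seen.add(cid)
        conditions.append(Condition(cid, cat, str(row.statement)))
    registry = ConditionRegistry(tuple(conditions))
    if registry.category_counts() != DEFAULT_CATEGORY_COUNTS:
        logger.warning(
            "registry at %s has category counts %s (default is %s)",
            path,
            registry.category_counts(),
            DEFAULT_CATEGORY_COUNTS,
        )
    return registry


# --------------------------------------------------------------------------
# Free-text recoding
# --------------------------------------------------------------------------

#: marker returned for write-in answers that cannot be recoded
DROPPED = None

RecodeMap = Mapping[str, str]


def _normalize_free_text(text: str) -> str:
    return re.sub(r"\s+", " ", str(text)).strip().casefold()


def load_recode_map(
    path: Union[str, Path], registry: Optional[ConditionRegistry] = None
) -> dict[str, str]:
    """Load a free-text -> condition_id recode map from CSV
    (columns: free_text, condition_id); keys are normalized."""
    frame = pd.read_csv(path, dtype=str)
    required = {"free_text", "condition_id"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"recode map missing columns: {sorted(missing)}")
    mapping: dict[str, str] = {}
    for row in frame.itertuples(index=False):
        cid = str(row.condition_id).strip()
        if registry is not None and cid not in registry:
            raise ValidationError(
                f"recode map references unknown condition_id {cid!r}"
            )
        mapping[_normalize_free_text(row.free_text)] = cid
    return mapping


def recode_added_condition(
    free_text: str, mapping: Optional[RecodeMap] = None
) -> Optional[str]:
    """Recode a written-in "most important" answer onto a pre-listed
    condition id, or return :data:`DROPPED` (``None``) when no exact
    (case-folded, whitespace-normalized) match exists.

    Matching is exact by design: the original recoding was a manual
    judgement and anything fuzzier would not be reproducible.
    """
    norm = _normalize_free_text(free_text)
    if not norm or mapping is None:
        return DROPPED
    return mapping.get(norm, DROPPED)
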