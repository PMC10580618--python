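"""Stratified bottleneck calling.

Strata come in three families: (a) *frequent intervention systems* — exact
(method, theme, setting) triples observed strictly more than ``min_count``
times (default 10); (b) *characteristic strata* — all systems sharing one
level of one characteristic (e.g. all systems using regulation); and (c)
the all-systems stratum.  Within a stratum, a condition is called a
bottleneck when it was flagged as one for strictly more than ``threshold``
(default 10%) of the stratum's member systems.

Both cuts are strict ("more than 10", "more than 10%"); the rate
comparison is done in exact rational arithmetic so that a stratum with
exactly 10% flagged is never called.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .flagging import FlagTable, InterventionRecord
from .registry import CHARACTERISTICS, SystemKey, ValidationError

__all__ = [
    "Stratum",
    "count_systems",
    "select_frequent_systems",
    "build_strata",
    "stratum_profile",
    "profiles_to_long",
    "DEFAULT_MIN_COUNT",
    "DEFAULT_THRESHOLD",
]

DEFAULT_MIN_COUNT = 10
DEFAULT_THRESHOLD = Fraction(1, 10)

StratumKey = Union[SystemKey, str]


@dataclass(frozen=True)
class Stratum:
    """A subset of intervention systems over which bottlenecks are called."""

    kind: str  # frequent_system | method | theme | setting | all
    key: StratumKey
    members: tuple  # intervention ids

    def __post_init__(self) -> None:
        if self.kind not in ("frequent_system", "method", "theme", "setting", "all"):
            raise ValidationError(f"unknown stratum kind {self.kind!r}")

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def label(self) -> str:
        return str(self.key)


def count_systems(records: Sequence[InterventionRecord]) -> dict[SystemKey, int]:
    """Exact multiset count of (method, theme, setting) triples."""
    return dict(Counter(r.system for r in records))


def select_frequent_systems(
    tally: Mapping[SystemKey, int], min_count: int = DEFAULT_MIN_COUNT
) -> set[SystemKey]:
    """Systems observed strictly more than ``min_count`` times."""
    return {key for key, n in tally.items() if n > min_count}


def build_strata(
    records: Sequence[InterventionRecord],
    frequent: Iterable[SystemKey],
    frequent_only: bool = False,
) -> list[Stratum]:
    """Build every stratum used in the analysis.

    Emits one stratum per frequent system (members share the exact triple),
    one per observed level of each characteristic, and the all-systems
    stratum.  Characteristic strata contain *all* records sharing the level;
    with ``frequent_only`` they are restricted to records belonging to a
    frequent system (sensitivity analysis).  Empty strata are omitted.
    """
    frequent = set(frequent)
    present = {r.system for r in records}
    missing = frequent - present
    if missing:
        raise ValidationError(f"frequent systems not present in records: {missing}")

    strata: list[Stratum] = []
    for key in sorted(frequent):
        members = tuple(r.intervention_id for r in records if r.system == key)
        strata.append(Stratum("frequent_system", key, members))

    char_pool = (
        [r for r in records if r.system in frequent] if frequent_only else list(records)
    )
    for characteristic, enum_cls in CHARACTERISTICS.items():
        for level in (m.value for m in enum_cls):
            members = tuple(
                r.intervention_id
                for r in char_pool
                if r.system.level(characteristic) == level
            )
            if members:
                strata.append(Stratum(characteristic, level, members))

    if records:
        strata.append(Stratum("all", "all", tuple(r.intervention_id for r in records)))
    return strata


def _as_fraction(threshold) -> Fraction:
    if isinstance(threshold, Fraction):
        return threshold
    if isinstance(threshold, int):
        return Fraction(threshold)
    # go through the decimal literal so 0.1 means exactly 1/10
    return Fraction(str(threshold))


def stratum_profile(
    stratum: Stratum,
    flag_table: FlagTable,
    threshold=DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Per-condition bottleneck rate and call within one stratum.

    ``rate = n_flagged / n_members``; ``is_bottleneck`` iff the exact
    rational rate strictly exceeds ``threshold``.
    """
    if stratum.size == 0:
        raise ValidationError(f"stratum {stratum.kind}:{stratum.label} is empty")
    thr = _as_fraction(threshold)
    flags = flag_table.bottleneck.loc[list(stratum.members)]
    n_members = stratum.size
    n_flagged = flags.sum()
    profile = pd.DataFrame(
        {
            "n_members": n_members,
            "n_flagged": n_flagged,
            "rate": n_flagged / n_members,
            "is_bottleneck": [
                Fraction(int(k), n_members) > thr for k in n_flagged
            ],
        }
    )
    profile.index.name = "condition_id"
    return profile


def profiles_to_long(
    profiles: Mapping[tuple[str, str], pd.DataFrame]
) -> pd.DataFrame:
    """Flatten {(kind, key label) -> profile} into one long table."""
    parts = []
    for (kind, key), profile in profiles.items():
        part = profile.reset_index()
        part.insert(0, "stratum_kind", kind)
        part.insert(1, "stratum_key", key)
        parts.append(part)
    if not parts:
        return pd.DataFrame(
            columns=[
                "stratum_kind", "stratum_key", "condition_id",
                "n_members", "n_flagged", "rate", "is_bottleneck",
            ]
        )
    return pd.concat(parts, ignore_index=True)
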