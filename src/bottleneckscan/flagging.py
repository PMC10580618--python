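"""Per-intervention flagging: sub-optimal, important, bottleneck.

The presence rating of each condition (five-point scale, 1 = strongly
disagree ... 5 = strongly agree) is dichotomized: a condition is *optimal*
only under strong agreement (rating 5) and *sub-optimal* for every other
answer.  A condition is *important* when the respondent placed it in the
top 5 of importance for that intervention, irrespective of rank.  A
condition is a *bottleneck* for an intervention when it is both sub-optimal
and important.

The deliberately harsh optimal/sub-optimal cut-off reflects the skewed
distribution of perceived presence typical of such surveys: any milder cut
would leave most bottlenecks undetected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .registry import (
    DROPPED,
    ConditionRegistry,
    RecodeMap,
    SystemKey,
    ValidationError,
    recode_added_condition,
)

__all__ = [
    "InterventionRecord",
    "FlagTable",
    "dichotomize_presence",
    "resolve_importance",
    "build_flag_table",
    "condition_profile",
    "profile_summary",
    "suboptimal_importance_correlation",
]

MAX_IMPORTANCE_SELECTIONS = 5


@dataclass(frozen=True)
class InterventionRecord:
    """One implemented intervention as reported by its prime implementer.

    ``ratings`` maps condition_id -> 1..5 (``None`` = missing answer);
    ``importance_selections`` holds the raw top-5 entries, each either a
    pre-listed condition id or free text to be recoded.
    """

    intervention_id: str
    project_id: str
    implementer_id: str
    system: SystemKey
    ratings: Mapping[str, Optional[int]]
    importance_selections: tuple = ()

    def validate(self, registry: ConditionRegistry) -> None:
        if len(self.importance_selections) > MAX_IMPORTANCE_SELECTIONS:
            raise ValidationError(
                f"record {self.intervention_id!r}: more than "
                f"{MAX_IMPORTANCE_SELECTIONS} importance selections"
            )
        for cid, rating in self.ratings.items():
            if cid not in registry:
                raise ValidationError(
                    f"record {self.intervention_id!r}: unknown condition {cid!r}"
                )
            _check_rating(rating, self.intervention_id, cid)


def _check_rating(rating, intervention_id="?", condition_id="?") -> None:
    if rating is None:
        return
    if not (isinstance(rating, (int, np.integer)) and 1 <= int(rating) <= 5):
        raise ValidationError(
            f"record {intervention_id!r}, condition {condition_id!r}: "
            f"rating {rating!r} outside 1-5"
        )


def dichotomize_presence(
    rating: Optional[int], impute_missing_as_suboptimal: bool = False
) -> tuple[bool, bool]:
    """Dichotomize one presence rating.

    Returns ``(suboptimal, rated)``: rating 5 -> (False, True); ratings
    1-4 -> (True, True); missing -> (False, False), i.e. missing answers
    never contribute to flag counts, so they can only deflate percentages.
    With ``impute_missing_as_suboptimal`` a missing answer is treated as
    sub-optimal instead (sensitivity analysis), still marked unrated.
    """
    _check_rating(rating)
    if rating is None:
        return (bool(impute_missing_as_suboptimal), False)
    return (int(rating) != 5, True)


def resolve_importance(
    record: InterventionRecord,
    registry: ConditionRegistry,
    mapping: Optional[RecodeMap] = None,
) -> tuple[frozenset, int]:
    """Resolve a record's raw top-5 entries to a set of condition ids.

    Pre-listed ids pass through; anything else is treated as a written-in
    answer and recoded via the map.  Returns ``(ids, n_dropped)`` where
    dropped counts the write-ins that could not be recoded.  Duplicates
    collapse: importance is an unordered set, rank is discarded.
    """
    resolved = set()
    n_dropped = 0
    for entry in record.importance_selections:
        entry_s = str(entry)
        if entry_s in registry:
            resolved.add(entry_s)
            continue
        recoded = recode_added_condition(entry_s, mapping)
        if recoded is DROPPED:
            n_dropped += 1
        else:
            if recoded not in registry:
                raise ValidationError(
                    f"recode map produced unknown condition {recoded!r}"
                )
            resolved.add(recoded)
    return frozenset(resolved), n_dropped


@dataclass
class FlagTable:
    """Boolean flags per (intervention x condition), in aligned wide frames
    (rows = intervention ids, columns = condition ids)."""

    suboptimal: pd.DataFrame
    important: pd.DataFrame
    bottleneck: pd.DataFrame
    rated: pd.DataFrame
    n_importance_selections: int = 0
    n_importance_dropped: int = 0

    @property
    def intervention_ids(self) -> pd.Index:
        return self.bottleneck.index

    @property
    def condition_ids(self) -> pd.Index:
        return self.bottleneck.columns

    def __len__(self) -> int:
        return len(self.bottleneck)

    def check_invariants(self) -> None:
        """bottleneck => suboptimal AND important, cell by cell."""
        if not (self.bottleneck <= (self.suboptimal & self.important)).all().all():
            raise AssertionError("bottleneck flag without suboptimal & important")

    def to_long(self) -> pd.DataFrame:
        """Long-format export: one row per (intervention, condition)."""
        parts = {
            "suboptimal": self.suboptimal,
            "important": self.important,
            "bottleneck": self.bottleneck,
            "rated": self.rated,
        }
        long = pd.concat(
            {name: frame.stack() for name, frame in parts.items()}, axis=1
        ).reset_index()
        long.columns = ["intervention_id", "condition_id", *parts.keys()]
        return long


def build_flag_table(
    records: Sequence[InterventionRecord],
    registry: ConditionRegistry,
    mapping: Optional[RecodeMap] = None,
    impute_missing_as_suboptimal: bool = False,
) -> FlagTable:
    """Build the full flag table for a set of validated records.

    One cell per (record x registry condition): unrated conditions have
    ``rated=False``; conditions outside the resolved importance set have
    ``important=False``; ``bottleneck = suboptimal & important``.
    """
    ids = [r.intervention_id for r in records]
    cols = list(registry.ids)
    n, m = len(records), len(cols)

    ratings = np.full((n, m), np.nan)
    important = np.zeros((n, m), dtype=bool)
    col_index = {cid: j for j, cid in enumerate(cols)}
    n_selections = 0
    n_dropped = 0
    for i, record in enumerate(records):
        record.validate(registry)
        for cid, rating in record.ratings.items():
            if rating is not None:
                ratings[i, col_index[cid]] = int(rating)
        resolved, dropped = resolve_importance(record, registry, mapping)
        n_selections += len(record.importance_selections)
        n_dropped += dropped
        for cid in resolved:
            important[i, col_index[cid]] = True

    rated = ~np.isnan(ratings)
    suboptimal = rated & (ratings != 5)
    if impute_missing_as_suboptimal:
        suboptimal = suboptimal | ~rated
    bottleneck = suboptimal & important

    def frame(values) -> pd.DataFrame:
        return pd.DataFrame(values, index=pd.Index(ids, name="intervention_id"),
                            columns=pd.Index(cols, name="condition_id"))

    return FlagTable(
        suboptimal=frame(suboptimal),
        important=frame(important),
        bottleneck=frame(bottleneck),
        rated=frame(rated),
        n_importance_selections=n_selections,
        n_importance_dropped=n_dropped,
    )


def condition_profile(
    flag_table: FlagTable, n_systems: Optional[int] = None
) -> pd.DataFrame:
    """Per-condition percentages of intervention systems flagged.

    The denominator is the number of systems (all of them, by default),
    matching the "percentage of all intervention systems" convention;
    missing ratings therefore deflate rather than redistribute.
    """
    if n_systems is None:
        n_systems = len(flag_table)
    if n_systems < 1:
        raise ValidationError("n_systems must be >= 1")
    profile = pd.DataFrame(
        {
            "pct_suboptimal": 100.0 * flag_table.suboptimal.sum() / n_systems,
            "pct_important": 100.0 * flag_table.important.sum() / n_systems,
            "pct_bottleneck": 100.0 * flag_table.bottleneck.sum() / n_systems,
        }
    )
    profile.index.name = "condition_id"
    return profile


def profile_summary(profile: pd.DataFrame) -> pd.DataFrame:
    """Mean and range of each percentage across conditions."""
    return pd.DataFrame(
        {"mean": profile.mean(), "min": profile.min(), "max": profile.max()}
    )


def suboptimal_importance_correlation(profile: pd.DataFrame) -> tuple[float, float]:
    """Cross-condition Pearson correlation between % sub-optimal and
    % important, with its two-sided p-value."""
    x = profile["pct_suboptimal"].to_numpy(dtype=float)
    y = profile["pct_important"].to_numpy(dtype=float)
    if len(x) < 3:
        raise ValidationError("correlation needs at least 3 conditions")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for a constant percentage vector")
    result = stats.pearsonr(x, y)
    return float(result.statistic), float(result.pvalue)
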