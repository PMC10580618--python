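"""Congruence labels: expectedly/unexpectedly present or absent bottlenecks.

For each (frequent system, condition) pair, compare the bottleneck call in
the frequent-system stratum with the calls in the characteristic strata
matching that system's method, theme and setting:

* **EPB** (expectedly present): bottleneck in the system AND in a matching
  characteristic stratum — the bottleneck is associated with the system's
  characteristics;
* **UPB** (unexpectedly present): bottleneck in the system but in none of
  its characteristic strata — it arose independent of the characteristics;
* **UAB** (unexpectedly absent): not a bottleneck in the system although a
  matching characteristic stratum calls it one;
* **concordant_absent**: no bottleneck anywhere.

By default "associated with the characteristics" is read existentially
(at least one of the three matching characteristic strata calls the
bottleneck); ``require_all_characteristics`` switches to the universal
reading (all three must call it).  Both readings are defensible and the
choice is exposed as a parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import pandas as pd

from .registry import ConditionRegistry, SystemKey, ValidationError

__all__ = [
    "EPB",
    "UPB",
    "UAB",
    "CONCORDANT_ABSENT",
    "CongruenceMatrix",
    "label_pair",
    "build_congruence_matrix",
    "congruence_summary",
]

EPB = "EPB"
UPB = "UPB"
UAB = "UAB"
CONCORDANT_ABSENT = "concordant_absent"
BOTTLENECK_LABELS = (EPB, UPB)

CharProfiles = Mapping[tuple[str, str], pd.DataFrame]


def _is_bottleneck(profile: pd.DataFrame, condition_id: str) -> bool:
    try:
        return bool(profile.loc[condition_id, "is_bottleneck"])
    except KeyError:
        raise ValidationError(f"condition {condition_id!r} missing from profile")


def label_pair(
    condition_id: str,
    system: SystemKey,
    system_profile: pd.DataFrame,
    characteristic_profiles: CharProfiles,
    require_all_characteristics: bool = False,
) -> tuple[str, tuple[str, ...]]:
    """Label one (frequent system, condition) pair.

    ``characteristic_profiles`` maps (characteristic, level) -> stratum
    profile and must contain the three strata matching this system's
    levels.  Returns ``(label, provenance)`` where provenance lists the
    characteristics whose stratum calls the condition a bottleneck.
    """
    in_system = _is_bottleneck(system_profile, condition_id)
    char_calls: dict[str, bool] = {}
    for characteristic in ("method", "theme", "setting"):
        key = (characteristic, system.level(characteristic))
        if key not in characteristic_profiles:
            raise ValidationError(
                f"missing characteristic stratum profile for {key}"
            )
        char_calls[characteristic] = _is_bottleneck(
            characteristic_profiles[key], condition_id
        )
    provenance = tuple(c for c, called in char_calls.items() if called)
    if require_all_characteristics:
        in_characteristics = all(char_calls.values())
    else:
        in_characteristics = any(char_calls.values())

    if in_system and in_characteristics:
        return EPB, provenance
    if in_system:
        return UPB, provenance
    if in_characteristics:
        return UAB, provenance
    return CONCORDANT_ABSENT, provenance


@dataclass
class CongruenceMatrix:
    """Labels for every (frequent system x condition) pair.

    ``labels``: wide frame, rows = condition ids, columns = systems.
    ``provenance``: (system, condition_id) -> characteristics that called
    the bottleneck, recorded for auditability.
    """

    labels: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def systems(self) -> list[SystemKey]:
        return list(self.labels.columns)

    def to_frame(self) -> pd.DataFrame:
        """Export analog of a shaded-cell table: EPB/UPB cells mark a
        bottleneck, UAB an unexpected absence, blank = concordant absent."""
        out = self.labels.replace({CONCORDANT_ABSENT: ""}).copy()
        out.columns = [str(c) for c in out.columns]
        out.index.name = "condition_id"
        return out


def build_congruence_matrix(
    frequent_profiles: Mapping[SystemKey, pd.DataFrame],
    characteristic_profiles: CharProfiles,
    registry: ConditionRegistry,
    require_all_characteristics: bool = False,
) -> CongruenceMatrix:
    """Apply :func:`label_pair` to every (frequent system x condition)."""
    condition_ids = list(registry.ids)
    systems = sorted(frequent_profiles)
    labels = pd.DataFrame(
        index=pd.Index(condition_ids, name="condition_id"),
        # tupleize_cols=False keeps SystemKey tuples as opaque column labels
        # instead of exploding them into a MultiIndex
        columns=pd.Index(systems, tupleize_cols=False),
        dtype=object,
    )
    provenance: dict = {}
    for system in systems:
        profile = frequent_profiles[system]
        for cid in condition_ids:
            label, prov = label_pair(
                cid, system, profile, characteristic_profiles,
                require_all_characteristics,
            )
            labels.loc[cid, system] = label
            provenance[(system, cid)] = prov
    return CongruenceMatrix(labels=labels, provenance=provenance)


def congruence_summary(
    matrix: CongruenceMatrix, registry: ConditionRegistry
) -> tuple[pd.DataFrame, dict]:
    """Per-system and overall counts.

    Per system: bottleneck count (= EPB + UPB), label counts, number of
    distinct condition categories represented among its bottlenecks, and
    the count of bottlenecks unique to it (not a bottleneck in any other
    frequent system).  Overall: totals, means and ranges across systems,
    and the number of conditions that are a bottleneck in at least one
    frequent system.
    """
    labels = matrix.labels
    rows = []
    bottleneck_mask = labels.isin(BOTTLENECK_LABELS)
    # per condition, in how many frequent systems it is a bottleneck
    n_systems_with = bottleneck_mask.sum(axis=1)
    for system in labels.columns:
        col = labels[system]
        bn_conditions = col.index[bottleneck_mask[system]]
        n_epb = int((col == EPB).sum())
        n_upb = int((col == UPB).sum())
        unique = [cid for cid in bn_conditions if n_systems_with[cid] == 1]
        rows.append(
            {
                "system": str(system),
                "n_bottlenecks": n_epb + n_upb,
                "n_EPB": n_epb,
                "n_UPB": n_upb,
                "n_UAB": int((col == UAB).sum()),
                "n_categories_represented": len(
                    {registry.category_of(cid) for cid in bn_conditions}
                ),
                "n_unique_bottlenecks": len(unique),
            }
        )
    per_system = pd.DataFrame(
        rows,
        columns=[
            "system", "n_bottlenecks", "n_EPB", "n_UPB", "n_UAB",
            "n_categories_represented", "n_unique_bottlenecks",
        ],
    ).set_index("system")

    n_conditions_ever = int(bottleneck_mask.any(axis=1).sum()) if len(labels.columns) else 0
    overall = {
        "n_frequent_systems": int(len(labels.columns)),
        "total_bottlenecks": int(per_system["n_bottlenecks"].sum()),
        "total_EPB": int(per_system["n_EPB"].sum()),
        "total_UPB": int(per_system["n_UPB"].sum()),
        "total_UAB": int(per_system["n_UAB"].sum()),
        "n_conditions_ever_bottleneck": n_conditions_ever,
    }
    if len(per_system):
        for col in ("n_bottlenecks", "n_EPB", "n_UPB", "n_UAB"):
            overall[f"mean_{col}"] = float(per_system[col].mean())
            overall[f"min_{col}"] = int(per_system[col].min())
            overall[f"max_{col}"] = int(per_system[col].max())
        overall["mean_n_categories_represented"] = float(
            per_system["n_categories_represented"].mean()
        )
    return per_system, overall
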