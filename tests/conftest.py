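"""Shared fixtures: registries, record builders, random small instances."""

import numpy as np
import pytest

from bottleneckscan import (
    Condition,
    ConditionRegistry,
    InterventionRecord,
    SystemKey,
    build_default_registry,
    parse_system,
)

METHODS = ["education", "regulation", "facilitation", "citizen_participation", "case_finding"]
THEMES = ["overweight", "alcohol", "other"]
SETTINGS = [
    "school", "outdoor_public", "sports_facility", "home",
    "commercial_building", "health_welfare_building", "public_building",
]


@pytest.fixture(scope="session")
def registry():
    return build_default_registry()


@pytest.fixture
def toy_registry():
    """Six conditions across three categories; small enough to enumerate."""
    return ConditionRegistry(
        (
            Condition("imp_01", "implementer", "skills"),
            Condition("imp_02", "implementer", "motivation"),
            Condition("int_01", "intervention", "ease"),
            Condition("int_02", "intervention", "fit"),
            Condition("coorg_01", "co_implementer_org", "support"),
            Condition("strategy_01", "implementation_strategy", "materials"),
        )
    )


def make_record(
    rec_id,
    system=("education", "overweight", "school"),
    ratings=None,
    importance=(),
    project="P01",
    implementer="R001",
):
    return InterventionRecord(
        intervention_id=str(rec_id),
        project_id=project,
        implementer_id=implementer,
        system=parse_system(*system),
        ratings=dict(ratings or {}),
        importance_selections=tuple(importance),
    )


@pytest.fixture
def make_records():
    """Build n records with identical ratings/importance for one system."""

    def _build(n, system=("education", "overweight", "school"), ratings=None,
               importance=(), prefix="I"):
        return [
            make_record(f"{prefix}{i:03d}", system, ratings, importance)
            for i in range(n)
        ]

    return _build


def random_small_instance(rng, toy_registry):
    """A random instance: <=10 conditions, <=30 records, as both package
    records and plain oracle tuples."""
    ids = list(toy_registry.ids)
    n_records = int(rng.integers(4, 31))
    records, plain = [], []
    for i in range(n_records):
        system = (
            METHODS[rng.integers(0, 3)],   # few levels => frequent systems happen
            THEMES[rng.integers(0, 2)],
            SETTINGS[rng.integers(0, 2)],
        )
        ratings = {
            cid: (None if rng.random() < 0.1 else int(rng.integers(1, 6)))
            for cid in ids
        }
        n_sel = int(rng.integers(0, 6))
        importance = tuple(
            str(rng.choice(ids)) if rng.random() < 0.8 else "a lack of time"
            for _ in range(n_sel)
        )
        records.append(make_record(f"I{i:03d}", system, ratings, importance))
        plain.append((f"I{i:03d}", system, ratings, importance))
    return records, plain
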