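"""Synthetic survey cohorts with known ground truth.

The raw survey data behind this kind of bottleneck analysis are typically
not public, so the package ships a generator that emulates the statistical
structure the analysis assumes, at the scale of the motivating study:
~243 implemented interventions reported by ~120 implementers across 30
projects, with method / theme / setting marginals matching the published
frequencies.

The generative model, per intervention:

* the system triple is drawn from the three marginal weight vectors
  independently (the joint distribution is not published; independence is
  the minimal assumption, and callers can post-stratify if they know the
  joint);
* perceived presence of condition *c* follows a latent-threshold ordinal
  model: ``latent = base_c + injected shifts + N(0, sd)``, cut at four
  increasing cutpoints into ratings 1-5.  Default cutpoints are
  right-skewed so "strongly agree" is the most common answer;
* the top-5 importance set is a softmax (Gumbel top-k) draw without
  replacement over conditions, with logit ``base_importance_c + injected
  boost + coupling * (5 - rating)``.  A negative coupling makes implementers
  nominate conditions they perceive as well-present, producing the negative
  cross-condition correlation between % sub-optimal and % important seen
  in practice;
* each top-5 slot is, with probability ``importance_dropout_rate``,
  reported as an unspecific write-in that cannot be recoded and is dropped
  downstream.

Injected ``(condition, characteristic level)`` effects shift presence down
and/or boost importance only for systems matching the level, planting
characteristic-linked bottlenecks whose recovery by the pipeline can be
measured (:func:`recovery_experiment`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .flagging import InterventionRecord, build_flag_table
from .registry import (
    CHARACTERISTICS,
    ConditionRegistry,
    SystemKey,
    ValidationError,
    build_default_registry,
)
from .stratify import (
    DEFAULT_MIN_COUNT,
    DEFAULT_THRESHOLD,
    Stratum,
    stratum_profile,
)

__all__ = [
    "InjectedEffect",
    "SimulationConfig",
    "GroundTruth",
    "sample_system_assignments",
    "sample_presence_ratings",
    "sample_importance",
    "generate_dataset",
    "recovery_experiment",
]

#: method marginal weights, enum order (education, regulation, facilitation,
#: citizen_participation, case_finding)
DEFAULT_METHOD_WEIGHTS = (137.0, 25.0, 57.0, 11.0, 13.0)
#: theme marginal weights (overweight, alcohol, other)
DEFAULT_THEME_WEIGHTS = (123.0, 102.0, 16.0)
#: setting marginal weights (school, outdoor_public, sports_facility, home,
#: commercial_building, health_welfare_building, public_building)
DEFAULT_SETTING_WEIGHTS = (75.0, 38.0, 24.0, 15.0, 24.0, 24.0, 38.0)

DEFAULT_CUTPOINTS = (-2.0, -1.2, -0.5, 0.16)

_UNSPECIFIC_WRITE_IN = "unspecific write-in (not codeable)"


@dataclass(frozen=True)
class InjectedEffect:
    """A planted (condition x characteristic level) bottleneck effect.

    ``presence_shift`` moves the latent presence of ``condition_id`` (a
    negative shift lowers ratings) and ``importance_boost`` raises its
    selection logit, for every intervention whose system matches
    ``level`` on ``characteristic``.
    """

    condition_id: str
    characteristic: str  # method | theme | setting
    level: str
    presence_shift: float = 0.0
    importance_boost: float = 0.0

    @property
    def pair(self) -> tuple[str, str, str]:
        return (self.condition_id, self.characteristic, self.level)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; defaults emulate the motivating study."""

    n_projects: int = 30
    n_interventions: int = 243
    n_implementers: int = 120
    method_weights: tuple = DEFAULT_METHOD_WEIGHTS
    theme_weights: tuple = DEFAULT_THEME_WEIGHTS
    setting_weights: tuple = DEFAULT_SETTING_WEIGHTS
    #: optional joint override: {(method, theme, setting): expected count}.
    #: Each record is drawn from this table with probability
    #: sum(counts)/n_interventions and from the independent marginals
    #: otherwise, so listed triples reach their expected counts while the
    #: remainder stays dispersed.  Lets a cohort concentrate on a handful
    #: of frequent systems the way real samples do.
    joint_system_weights: Union[None, dict] = None
    #: latent presence mean; scalar, per-condition mapping, or None for the
    #: built-in linear spread (-0.8 .. 0.45) across registry order
    presence_base: Union[None, float, dict] = None
    presence_sd: float = 1.0
    cutpoints: tuple = DEFAULT_CUTPOINTS
    #: importance logit baseline; None = built-in spread (-1.5 .. 1.5),
    #: assigned via a fixed stride permutation so it is decorrelated from
    #: the presence spread
    base_importance: Union[None, float, dict] = None
    importance_temperature: float = 1.0
    #: coupling applied to the sub-optimality gap (5 - rating); negative
    #: values make well-present conditions more likely to be nominated,
    #: inducing a negative % sub-optimal vs % important correlation
    importance_presence_coupling: float = -0.9
    #: probability a top-5 slot is an unspecific, uncodeable write-in
    importance_dropout_rate: float = 0.11
    missing_rate: float = 0.02
    injected_effects: tuple = ()
    seed: int = 0

    def validate(self, registry: ConditionRegistry) -> None:
        for name, weights, enum_cls in (
            ("method_weights", self.method_weights, CHARACTERISTICS["method"]),
            ("theme_weights", self.theme_weights, CHARACTERISTICS["theme"]),
            ("setting_weights", self.setting_weights, CHARACTERISTICS["setting"]),
        ):
            w = np.asarray(weights, dtype=float)
            if len(w) != len(enum_cls):
                raise ValidationError(f"{name} must have {len(enum_cls)} entries")
            if (w < 0).any() or w.sum() <= 0:
                raise ValidationError(f"{name} must be non-negative with positive sum")
        cp = np.asarray(self.cutpoints, dtype=float)
        if len(cp) != 4 or not (np.diff(cp) > 0).all():
            raise ValidationError("cutpoints must be 4 strictly increasing reals")
        if self.presence_sd <= 0:
            raise ValidationError("presence_sd must be > 0")
        if self.importance_temperature <= 0:
            raise ValidationError("importance_temperature must be > 0")
        if not (0 <= self.missing_rate < 1):
            raise ValidationError("missing_rate must be in [0, 1)")
        if not (0 <= self.importance_dropout_rate < 1):
            raise ValidationError("importance_dropout_rate must be in [0, 1)")
        if self.n_interventions < 0 or self.n_projects < 1 or self.n_implementers < 1:
            raise ValidationError("counts must be positive (n_interventions >= 0)")
        if self.joint_system_weights is not None:
            from .registry import parse_system

            mass = 0.0
            for triple, weight in self.joint_system_weights.items():
                parse_system(*triple)  # raises on invalid levels
                if weight < 0:
                    raise ValidationError("joint system weights must be non-negative")
                mass += float(weight)
            if mass <= 0:
                raise ValidationError("joint system weights must have positive sum")
            if self.n_interventions and mass > self.n_interventions:
                raise ValidationError(
                    "joint system weights sum exceeds n_interventions"
                )
        for eff in self.injected_effects:
            if eff.condition_id not in registry:
                raise ValidationError(
                    f"injected effect references unknown condition {eff.condition_id!r}"
                )
            if eff.characteristic not in CHARACTERISTICS:
                raise ValidationError(
                    f"injected effect: unknown characteristic {eff.characteristic!r}"
                )
            levels = {m.value for m in CHARACTERISTICS[eff.characteristic]}
            if eff.level not in levels:
                raise ValidationError(
                    f"injected effect: unknown {eff.characteristic} level {eff.level!r}"
                )


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted, for recovery experiments."""

    true_bottleneck_pairs: frozenset  # {(condition_id, characteristic, level)}
    latent_presence: np.ndarray  # (n_interventions, n_conditions)


# --------------------------------------------------------------------------
# parameter vectors
# --------------------------------------------------------------------------

def _coprime_stride(n: int) -> int:
    stride = max(2, round(0.4 * n))
    while math.gcd(stride, n) != 1:
        stride += 1
    return stride


def _per_condition_vector(
    value: Union[None, float, dict],
    registry: ConditionRegistry,
    default_span: tuple[float, float],
    permute: bool,
) -> np.ndarray:
    ids = registry.ids
    n = len(ids)
    if value is None:
        base = np.linspace(default_span[0], default_span[1], n) if n > 1 else np.array(
            [np.mean(default_span)]
        )
        if permute and n > 1:
            stride = _coprime_stride(n)
            order = (np.arange(n) * stride) % n
            base = base[order]
        return base
    if isinstance(value, dict):
        missing = [cid for cid in ids if cid not in value]
        if missing:
            raise ValidationError(f"per-condition values missing for {missing[:5]} ...")
        return np.array([float(value[cid]) for cid in ids])
    return np.full(n, float(value))


def presence_base_vector(config: SimulationConfig, registry: ConditionRegistry) -> np.ndarray:
    return _per_condition_vector(config.presence_base, registry, (-0.8, 0.45), permute=False)


def importance_base_vector(config: SimulationConfig, registry: ConditionRegistry) -> np.ndarray:
    return _per_condition_vector(config.base_importance, registry, (-1.5, 1.5), permute=True)


# --------------------------------------------------------------------------
# samplers
# --------------------------------------------------------------------------

def sample_system_assignments(
    config: SimulationConfig,
    rng: np.random.Generator,
    registry: Optional[ConditionRegistry] = None,
) -> pd.DataFrame:
    """Draw the system triple plus project / implementer ids per intervention.

    Method, theme and setting are drawn independently from their normalized
    weight vectors; projects are uniform; implementer ids are drawn with
    replacement from the implementer pool (one implementer may hold several
    interventions).
    """
    config.validate(registry or build_default_registry())
    n = config.n_interventions

    def draw(levels: list[str], weights) -> list:
        p = np.asarray(weights, dtype=float)
        # plain list: fixed-width numpy string dtype would truncate any
        # longer level substituted by the joint override below
        return rng.choice(levels, size=n, p=p / p.sum()).tolist()

    method = draw([m.value for m in CHARACTERISTICS["method"]], config.method_weights)
    theme = draw([m.value for m in CHARACTERISTICS["theme"]], config.theme_weights)
    setting = draw([m.value for m in CHARACTERISTICS["setting"]], config.setting_weights)

    if config.joint_system_weights and n:
        from .registry import parse_system

        triples = [parse_system(*t) for t in config.joint_system_weights]
        weights = np.asarray(
            [float(w) for w in config.joint_system_weights.values()], dtype=float
        )
        use_joint = rng.random(n) < weights.sum() / n
        joint_idx = rng.choice(len(triples), size=n, p=weights / weights.sum())
        for i in np.flatnonzero(use_joint):
            method[i], theme[i], setting[i] = triples[joint_idx[i]]

    frame = pd.DataFrame(
        {
            "intervention_id": [f"I{i + 1:03d}" for i in range(n)],
            "project_id": [f"P{j + 1:02d}" for j in rng.integers(0, config.n_projects, n)],
            "implementer_id": [
                f"R{j + 1:03d}" for j in rng.integers(0, config.n_implementers, n)
            ],
            "method": method,
            "theme": theme,
            "setting": setting,
        }
    )
    return frame


def _effect_matrices(
    config: SimulationConfig,
    registry: ConditionRegistry,
    systems: pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-(record x condition) presence shift and importance boost."""
    n = len(systems)
    m = len(registry)
    col = {cid: j for j, cid in enumerate(registry.ids)}
    shift = np.zeros((n, m))
    boost = np.zeros((n, m))
    for eff in config.injected_effects:
        rows = (systems[eff.characteristic] == eff.level).to_numpy()
        shift[rows, col[eff.condition_id]] += eff.presence_shift
        boost[rows, col[eff.condition_id]] += eff.importance_boost
    return shift, boost


def sample_presence_ratings(
    systems: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
    registry: Optional[ConditionRegistry] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Latent-threshold draw of the rating matrix.

    Returns ``(ratings, latent)``: ratings is float (n x n_conditions) with
    values 1..5 and NaN for missing; rating = 1 + number of cutpoints below
    the latent value.
    """
    registry = registry or build_default_registry()
    base = presence_base_vector(config, registry)
    shift, _ = _effect_matrices(config, registry, systems)
    n, m = shift.shape
    latent = base[None, :] + shift + rng.normal(0.0, config.presence_sd, size=(n, m))
    ratings = 1.0 + np.digitize(latent, np.asarray(config.cutpoints, dtype=float))
    if config.missing_rate > 0:
        missing = rng.random((n, m)) < config.missing_rate
        ratings = np.where(missing, np.nan, ratings)
    return ratings, latent


def sample_importance(
    ratings: np.ndarray,
    systems: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
    registry: Optional[ConditionRegistry] = None,
) -> list[tuple]:
    """Draw each record's raw top-5 list (ids and/or uncodeable write-ins).

    Softmax sampling without replacement via the Gumbel top-k trick: the 5
    highest ``logit/T + Gumbel`` keys per record are selected, which is
    equivalent to sequential sampling proportional to ``exp(logit/T)``.
    Missing-rated conditions stay eligible (a respondent can deem a
    condition important without having rated its presence).
    """
    registry = registry or build_default_registry()
    base = importance_base_vector(config, registry)
    _, boost = _effect_matrices(config, registry, systems)
    n, m = ratings.shape
    gap = np.where(np.isnan(ratings), 0.0, 5.0 - ratings)
    logits = base[None, :] + boost + config.importance_presence_coupling * gap
    keys = logits / config.importance_temperature + rng.gumbel(size=(n, m))
    k = min(5, m)
    top = np.argsort(-keys, axis=1)[:, :k]

    ids = np.array(registry.ids)
    dropped = rng.random((n, k)) < config.importance_dropout_rate
    selections = []
    for i in range(n):
        row = []
        for j in range(k):
            if dropped[i, j]:
                row.append(_UNSPECIFIC_WRITE_IN)
            else:
                row.append(str(ids[top[i, j]]))
        selections.append(tuple(row))
    return selections


def generate_dataset(
    config: SimulationConfig,
    registry: Optional[ConditionRegistry] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[InterventionRecord], GroundTruth]:
    """Generate a full synthetic cohort; deterministic given ``config.seed``."""
    registry = registry or build_default_registry()
    config.validate(registry)
    if rng is None:
        rng = np.random.default_rng(config.seed)

    systems = sample_system_assignments(config, rng, registry)
    ratings, latent = sample_presence_ratings(systems, config, rng, registry)
    selections = sample_importance(ratings, systems, config, rng, registry)

    ids = registry.ids
    records = []
    for i, row in enumerate(systems.itertuples(index=False)):
        rating_map = {
            cid: (None if np.isnan(ratings[i, j]) else int(ratings[i, j]))
            for j, cid in enumerate(ids)
        }
        records.append(
            InterventionRecord(
                intervention_id=row.intervention_id,
                project_id=row.project_id,
                implementer_id=row.implementer_id,
                system=SystemKey(row.method, row.theme, row.setting),
                ratings=rating_map,
                importance_selections=selections[i] if selections else (),
            )
        )
    truth = GroundTruth(
        true_bottleneck_pairs=frozenset(
            eff.pair
            for eff in config.injected_effects
            if eff.presence_shift != 0 or eff.importance_boost != 0
        ),
        latent_presence=latent,
    )
    return records, truth


# --------------------------------------------------------------------------
# recovery experiment
# --------------------------------------------------------------------------

def recovery_experiment(
    config: SimulationConfig,
    reps: int,
    registry: Optional[ConditionRegistry] = None,
    threshold=DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Measure how often each (condition, characteristic level) pair is
    called a bottleneck in its characteristic stratum across replicates.

    Each replicate generates a fresh cohort (child seed spawned from
    ``config.seed``), builds the flag table and calls bottlenecks in every
    characteristic stratum.  For injected pairs the call rate is the
    detection *sensitivity*; for all other pairs it is the *false-call
    rate*.  Pairs whose stratum is empty in a replicate are not evaluated
    in that replicate.
    """
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    registry = registry or build_default_registry()
    config.validate(registry)
    truth_pairs = {
        eff.pair
        for eff in config.injected_effects
        if eff.presence_shift != 0 or eff.importance_boost != 0
    }

    pairs = [
        (cid, characteristic, level.value)
        for characteristic, enum_cls in CHARACTERISTICS.items()
        for level in enum_cls
        for cid in registry.ids
    ]
    called = {p: 0 for p in pairs}
    evaluated = {p: 0 for p in pairs}

    seeds = np.random.SeedSequence(config.seed).spawn(reps)
    for rep in range(reps):
        rng = np.random.default_rng(seeds[rep])
        records, _ = generate_dataset(config, registry, rng=rng)
        flag_table = build_flag_table(records, registry)
        for characteristic in CHARACTERISTICS:
            groups: dict[str, list[str]] = {}
            for r in records:
                groups.setdefault(r.system.level(characteristic), []).append(
                    r.intervention_id
                )
            for level, members in groups.items():
                profile = stratum_profile(
                    Stratum(characteristic, level, tuple(members)),
                    flag_table,
                    threshold,
                )
                for cid, is_bn in profile["is_bottleneck"].items():
                    key = (cid, characteristic, level)
                    evaluated[key] += 1
                    called[key] += bool(is_bn)

    out = pd.DataFrame(
        {
            "condition_id": [p[0] for p in pairs],
            "characteristic": [p[1] for p in pairs],
            "level": [p[2] for p in pairs],
            "injected": [p in truth_pairs for p in pairs],
            "n_evaluated": [evaluated[p] for p in pairs],
            "n_called": [called[p] for p in pairs],
        }
    )
    out["call_rate"] = np.where(
        out["n_evaluated"] > 0, out["n_called"] / out["n_evaluated"], np.nan
    )
    return out
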