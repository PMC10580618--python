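"""End-to-end analysis as a scikit-learn style estimator.

:class:`BottleneckAnalysis` consumes a survey table (either a list of
:class:`~bottleneckscan.flagging.InterventionRecord` or a DataFrame in the
flat survey schema), flags each (intervention, condition) cell, selects
frequent systems, calls bottlenecks per stratum and labels congruence.
Everything learned from the data lands in trailing-underscore attributes;
thresholds and sensitivity switches are estimator parameters, so the whole
analysis composes with ``get_params`` / ``set_params`` and ``clone``.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Optional, Sequence, Union

import pandas as pd
from sklearn.base import BaseEstimator

from . import io as bio
from .congruence import build_congruence_matrix, congruence_summary
from .flagging import (
    InterventionRecord,
    build_flag_table,
    condition_profile,
    profile_summary,
    suboptimal_importance_correlation,
)
from .registry import ConditionRegistry, ValidationError, build_default_registry
from .stratify import (
    build_strata,
    count_systems,
    profiles_to_long,
    select_frequent_systems,
    stratum_profile,
)

__all__ = ["BottleneckAnalysis", "run_pipeline"]


class BottleneckAnalysis(BaseEstimator):
    """Stratified bottleneck identification for implementation surveys.

    Parameters
    ----------
    registry : ConditionRegistry, optional
        Condition registry; the default 47-condition registry if omitted.
    recode_map : mapping, optional
        Normalized free-text -> condition_id map for written-in importance
        answers; unmatched write-ins are dropped (and counted).
    min_count : int, default 10
        A system triple is *frequent* when observed strictly more than
        this many times.
    threshold : float or Fraction, default 0.1
        Stratum bottleneck cut: a condition is called when flagged for
        strictly more than this fraction of the stratum's members
        (compared in exact rational arithmetic).
    frequent_only : bool, default False
        Restrict characteristic strata to records in frequent systems.
    require_all_characteristics : bool, default False
        Universal instead of existential reading of "associated with the
        system's characteristics" when labelling congruence.
    impute_missing_as_suboptimal : bool, default False
        Sensitivity switch: treat missing presence ratings as sub-optimal.

    Attributes (after ``fit``)
    --------------------------
    records_, flag_table_, condition_profile_, correlation_,
    system_counts_, frequent_systems_, strata_, stratum_profiles_,
    congruence_, per_system_summary_, summary_
    """

    def __init__(
        self,
        registry: Optional[ConditionRegistry] = None,
        recode_map=None,
        min_count: int = 10,
        threshold: Union[float, Fraction] = 0.1,
        frequent_only: bool = False,
        require_all_characteristics: bool = False,
        impute_missing_as_suboptimal: bool = False,
    ):
        self.registry = registry
        self.recode_map = recode_map
        self.min_count = min_count
        self.threshold = threshold
        self.frequent_only = frequent_only
        self.require_all_characteristics = require_all_characteristics
        self.impute_missing_as_suboptimal = impute_missing_as_suboptimal

    # -- helpers ----------------------------------------------------------

    def _registry(self) -> ConditionRegistry:
        return self.registry if self.registry is not None else build_default_registry()

    def _coerce_records(self, X) -> list[InterventionRecord]:
        if isinstance(X, pd.DataFrame):
            return bio.frame_to_records(X, self._registry())
        records = list(X)
        if not all(isinstance(r, InterventionRecord) for r in records):
            raise ValidationError(
                "X must be a survey-schema DataFrame or a sequence of InterventionRecord"
            )
        return records

    # -- sklearn surface ---------------------------------------------------

    def fit(self, X, y=None) -> "BottleneckAnalysis":
        """Run the full stratified analysis on survey data ``X``."""
        registry = self._registry()
        records = self._coerce_records(X)
        if not records:
            raise ValidationError("cannot fit on an empty survey")

        flag_table = build_flag_table(
            records,
            registry,
            mapping=self.recode_map,
            impute_missing_as_suboptimal=self.impute_missing_as_suboptimal,
        )
        flag_table.check_invariants()
        profile = condition_profile(flag_table)
        try:
            corr = suboptimal_importance_correlation(profile)
        except ValidationError:
            corr = (float("nan"), float("nan"))

        tally = count_systems(records)
        frequent = select_frequent_systems(tally, self.min_count)
        strata = build_strata(records, frequent, frequent_only=self.frequent_only)
        stratum_profiles = {
            (s.kind, s.key): stratum_profile(s, flag_table, self.threshold)
            for s in strata
        }

        frequent_profiles = {
            key: prof
            for (kind, key), prof in stratum_profiles.items()
            if kind == "frequent_system"
        }
        characteristic_profiles = {
            (kind, key): prof
            for (kind, key), prof in stratum_profiles.items()
            if kind in ("method", "theme", "setting")
        }
        congruence = build_congruence_matrix(
            frequent_profiles,
            characteristic_profiles,
            registry,
            require_all_characteristics=self.require_all_characteristics,
        )
        per_system, overall = congruence_summary(congruence, registry)

        self.registry_ = registry
        self.records_ = records
        self.flag_table_ = flag_table
        self.condition_profile_ = profile
        self.correlation_ = corr
        self.system_counts_ = tally
        self.frequent_systems_ = frequent
        self.strata_ = strata
        self.stratum_profiles_ = stratum_profiles
        self.congruence_ = congruence
        self.per_system_summary_ = per_system
        self.summary_ = self._build_summary(overall)
        return self

    def transform(self, X) -> pd.DataFrame:
        """Per-(intervention x condition) bottleneck flags for ``X``.

        Stateless apart from the registry/recode parameters: the flags are
        intervention-level and do not depend on the fitted strata.
        """
        registry = self._registry()
        records = self._coerce_records(X)
        table = build_flag_table(
            records,
            registry,
            mapping=self.recode_map,
            impute_missing_as_suboptimal=self.impute_missing_as_suboptimal,
        )
        return table.bottleneck

    def fit_transform(self, X, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)

    # -- reporting ---------------------------------------------------------

    def _build_summary(self, overall: dict) -> dict:
        """JSON-safe run summary; every number is recomputable from the
        exported intermediate tables."""
        prof_summary = profile_summary(self.condition_profile_)
        n = len(self.records_)
        n_frequent_members = sum(
            self.system_counts_[k] for k in self.frequent_systems_
        )
        r, p = self.correlation_
        summary = {
            "n_records": n,
            "n_projects": len({rec.project_id for rec in self.records_}),
            "n_implementers": len({rec.implementer_id for rec in self.records_}),
            "n_conditions": len(self.registry_),
            "condition_profile": {
                metric: {
                    "mean": float(prof_summary.loc[metric, "mean"]),
                    "min": float(prof_summary.loc[metric, "min"]),
                    "max": float(prof_summary.loc[metric, "max"]),
                }
                for metric in self.condition_profile_.columns
            },
            "suboptimal_importance_pearson_r": r,
            "suboptimal_importance_pearson_p": p,
            "n_frequent_systems": len(self.frequent_systems_),
            "frequent_systems": sorted(str(k) for k in self.frequent_systems_),
            "frequent_system_coverage": n_frequent_members / n,
            "importance_selections_total": self.flag_table_.n_importance_selections,
            "importance_selections_dropped": self.flag_table_.n_importance_dropped,
            "importance_dropped_fraction": (
                self.flag_table_.n_importance_dropped
                / self.flag_table_.n_importance_selections
                if self.flag_table_.n_importance_selections
                else 0.0
            ),
            "per_system": self.per_system_summary_.reset_index().to_dict("records"),
            **overall,
            "settings": {
                "min_count": self.min_count,
                "threshold": float(Fraction(str(self.threshold))),
                "frequent_only": self.frequent_only,
                "require_all_characteristics": self.require_all_characteristics,
                "impute_missing_as_suboptimal": self.impute_missing_as_suboptimal,
            },
        }
        return summary

    def write_outputs(self, out_dir) -> dict:
        """Write flag table, stratum profiles, congruence matrix, summary
        and log to ``out_dir``; returns the content-hash manifest."""
        long_profiles = profiles_to_long(
            {(kind, str(key)): prof for (kind, key), prof in self.stratum_profiles_.items()}
        )
        log_lines = [
            f"records={self.summary_['n_records']}",
            f"frequent_systems={self.summary_['n_frequent_systems']}",
            f"importance_selections_dropped={self.summary_['importance_selections_dropped']}"
            f"/{self.summary_['importance_selections_total']}",
            f"settings={self.summary_['settings']}",
        ]
        return bio.write_outputs(
            self.flag_table_,
            long_profiles,
            self.congruence_.to_frame(),
            self.summary_,
            out_dir,
            log_lines=log_lines,
        )


def run_pipeline(
    survey_path,
    registry_path=None,
    recode_path=None,
    out_dir=None,
    **params,
) -> dict:
    """File-level convenience wrapper: read inputs, fit, optionally write
    artifacts; returns the run summary dict."""
    from .registry import load_recode_map, load_registry

    registry = load_registry(registry_path) if registry_path else build_default_registry()
    recode_map = load_recode_map(recode_path, registry) if recode_path else None
    records = bio.read_survey_csv(survey_path, registry)
    analysis = BottleneckAnalysis(registry=registry, recode_map=recode_map, **params)
    analysis.fit(records)
    if out_dir is not None:
        analysis.write_outputs(out_dir)
    return analysis.summary_
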