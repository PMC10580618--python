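"""Survey CSV schema, config serialization and result artifacts.

Survey CSV schema (UTF-8, comma-separated, header required, empty cell =
missing): ``intervention_id, project_id, implementer_id, method, theme,
setting, rating_<condition_id> x n_conditions, importance_1..importance_5``.
Rating cells are 1-5 or empty; importance cells are condition ids, free
text, or empty.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .flagging import FlagTable, InterventionRecord
from .registry import (
    ConditionRegistry,
    SystemKey,
    ValidationError,
    build_default_registry,
    parse_system,
)
from .simulate import InjectedEffect, SimulationConfig

logger = logging.getLogger("bottleneckscan")

__all__ = [
    "survey_columns",
    "records_to_frame",
    "frame_to_records",
    "read_survey_csv",
    "write_survey_csv",
    "load_simulation_config",
    "save_simulation_config",
    "write_outputs",
]

ID_COLUMNS = ("intervention_id", "project_id", "implementer_id")
SYSTEM_COLUMNS = ("method", "theme", "setting")
N_IMPORTANCE_COLUMNS = 5
IMPORTANCE_COLUMNS = tuple(f"importance_{k}" for k in range(1, N_IMPORTANCE_COLUMNS + 1))


def survey_columns(registry: ConditionRegistry) -> list[str]:
    return [
        *ID_COLUMNS,
        *SYSTEM_COLUMNS,
        *(f"rating_{cid}" for cid in registry.ids),
        *IMPORTANCE_COLUMNS,
    ]


def records_to_frame(
    records: Sequence[InterventionRecord], registry: ConditionRegistry
) -> pd.DataFrame:
    """Serialize records to the flat survey schema (missing -> empty)."""
    rows = []
    for r in records:
        row = {
            "intervention_id": r.intervention_id,
            "project_id": r.project_id,
            "implementer_id": r.implementer_id,
            "method": r.system.method,
            "theme": r.system.theme,
            "setting": r.system.setting,
        }
        for cid in registry.ids:
            rating = r.ratings.get(cid)
            row[f"rating_{cid}"] = "" if rating is None else str(int(rating))
        for k in range(N_IMPORTANCE_COLUMNS):
            row[IMPORTANCE_COLUMNS[k]] = (
                str(r.importance_selections[k])
                if k < len(r.importance_selections)
                else ""
            )
        rows.append(row)
    return pd.DataFrame(rows, columns=survey_columns(registry), dtype=str)


def _parse_rating_cell(cell, row_no: int, column: str):
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return None
    text = str(cell).strip()
    if text == "" or text.lower() == "nan":
        return None
    try:
        value = int(float(text))
        if not 1 <= value <= 5 or float(text) != value:
            raise ValueError
    except ValueError:
        raise ValidationError(
            f"row {row_no}, column {column!r}: malformed rating {cell!r} (expected 1-5 or empty)"
        )
    return value


def frame_to_records(
    frame: pd.DataFrame, registry: ConditionRegistry
) -> list[InterventionRecord]:
    """Parse a survey-schema frame into validated records.

    Row numbers in error messages count the header as line 1, matching what
    a user sees in the CSV file.
    """
    rating_cols = [f"rating_{cid}" for cid in registry.ids]
    expected = set(survey_columns(registry))
    unknown_ratings = [
        c for c in frame.columns if c.startswith("rating_") and c not in expected
    ]
    if unknown_ratings:
        raise ValidationError(
            f"unknown condition columns: {unknown_ratings[:5]} (not in registry)"
        )
    missing_cols = [c for c in (*ID_COLUMNS, *SYSTEM_COLUMNS, *rating_cols) if c not in frame.columns]
    if missing_cols:
        raise ValidationError(f"survey table missing columns: {missing_cols[:5]}")

    records = []
    for pos, row in enumerate(frame.to_dict("records")):
        row_no = pos + 2
        try:
            system = parse_system(row["method"], row["theme"], row["setting"])
        except ValidationError as exc:
            raise ValidationError(f"row {row_no}: {exc}") from exc
        ratings = {
            cid: _parse_rating_cell(row[f"rating_{cid}"], row_no, f"rating_{cid}")
            for cid in registry.ids
        }
        selections = []
        for col in IMPORTANCE_COLUMNS:
            cell = row.get(col)
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                continue
            text = str(cell).strip()
            if text:
                selections.append(text)
        records.append(
            InterventionRecord(
                intervention_id=str(row["intervention_id"]),
                project_id=str(row["project_id"]),
                implementer_id=str(row["implementer_id"]),
                system=system,
                ratings=ratings,
                importance_selections=tuple(selections),
            )
        )
    return records


def read_survey_csv(
    path: Union[str, Path], registry: Optional[ConditionRegistry] = None
) -> list[InterventionRecord]:
    registry = registry or build_default_registry()
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    return frame_to_records(frame, registry)


def write_survey_csv(
    records: Sequence[InterventionRecord],
    registry: ConditionRegistry,
    path: Union[str, Path],
) -> None:
    records_to_frame(records, registry).to_csv(path, index=False)


# --------------------------------------------------------------------------
# simulation config (flat YAML/JSON)
# --------------------------------------------------------------------------

def save_simulation_config(config: SimulationConfig, path: Union[str, Path]) -> None:
    data = asdict(config)
    data["injected_effects"] = [asdict(e) for e in config.injected_effects]
    for key in ("method_weights", "theme_weights", "setting_weights", "cutpoints"):
        data[key] = list(data[key])
    if config.joint_system_weights is not None:
        # tuple keys do not survive YAML; flatten to rows
        data["joint_system_weights"] = [
            [*triple, float(weight)]
            for triple, weight in config.joint_system_weights.items()
        ]
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_simulation_config(path: Union[str, Path]) -> SimulationConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    if "injected_effects" in data:
        data["injected_effects"] = tuple(
            InjectedEffect(**e) for e in data["injected_effects"]
        )
    for key in ("method_weights", "theme_weights", "setting_weights", "cutpoints"):
        if key in data and data[key] is not None:
            data[key] = tuple(data[key])
    if data.get("joint_system_weights") is not None:
        data["joint_system_weights"] = {
            (str(m), str(t), str(s)): float(w)
            for m, t, s, w in data["joint_system_weights"]
        }
    return SimulationConfig(**data)


# --------------------------------------------------------------------------
# result artifacts
# --------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def json_default(obj):
    """Make numpy scalars JSON-serializable."""
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_outputs(
    flag_table: FlagTable,
    stratum_profiles_long: pd.DataFrame,
    congruence_frame: pd.DataFrame,
    summary: dict,
    out_dir: Union[str, Path],
    log_lines: Sequence[str] = (),
) -> dict:
    """Write the standard artifact set and return a manifest.

    Files: flag_table.csv (long), stratum_profiles.csv, congruence_matrix.csv,
    summary.json, run.log, manifest.json.  Reruns on identical inputs yield
    identical content hashes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    flag_table.to_long().to_csv(out / "flag_table.csv", index=False)
    stratum_profiles_long.to_csv(out / "stratum_profiles.csv", index=False)
    congruence_frame.to_csv(out / "congruence_matrix.csv")
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=json_default)
    )
    (out / "run.log").write_text("\n".join(log_lines) + ("\n" if log_lines else ""))

    files = [
        "flag_table.csv",
        "stratum_profiles.csv",
        "congruence_matrix.csv",
        "summary.json",
        "run.log",
    ]
    manifest = {name: _sha256(out / name) for name in files}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
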