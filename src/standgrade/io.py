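"""Delimited-text and structured-file round-trips for pipeline artifacts.

Trees and boards travel as comma-separated tables with header rows; models
and configs as JSON/YAML.  Files may begin with ``#`` comment lines (the
pipeline stamps a config hash and seed there) which readers skip.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .moe_model import FitDiagnostics, LinearMOEModel, TreeRecord
from .msr_grades import BoardRecord, GradePassModel, MSRGrade, parse_grade

TREE_COLUMNS = [
    "tree_id",
    "plot_id",
    "tsf_class",
    "dbh_cm",
    "velocity_kms_d30",
    "velocity_kms_d15",
    "moe_observed",
    "moe_est",
]


def _write_csv(df: pd.DataFrame, path: Path | str, header_comment: str | None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        # %.17g guarantees binary round-trip of doubles through text
        df.to_csv(fh, index=False, float_format="%.17g")


def trees_to_frame(trees: Sequence[TreeRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(t) for t in trees], columns=TREE_COLUMNS)


def write_trees(
    trees: Sequence[TreeRecord], path: Path | str, header_comment: str | None = None
) -> None:
    _write_csv(trees_to_frame(trees), path, header_comment)


def read_trees(path: Path | str) -> list[TreeRecord]:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    trees = []
    for d in df.to_dict("records"):
        trees.append(
            TreeRecord(
                tree_id=str(d["tree_id"]),
                plot_id=str(d["plot_id"]),
                tsf_class=str(d["tsf_class"]),
                dbh_cm=float(d["dbh_cm"]),
                velocity_kms_d30=float(d["velocity_kms_d30"]),
                velocity_kms_d15=_opt(d.get("velocity_kms_d15")),
                moe_observed=_opt(d.get("moe_observed")),
                moe_est=_opt(d.get("moe_est")),
            )
        )
    return trees


def _opt(v) -> float | None:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return float(v)


def boards_to_frame(boards: Sequence[BoardRecord]) -> pd.DataFrame:
    rows = []
    for b in boards:
        row = {
            "board_id": b.board_id,
            "tree_id": b.tree_id,
            "moe_static_kn_mm2": b.moe_static,
            "visual_pass": b.visual_pass,
        }
        for grade, ok in b.grade_pass.items():
            row[f"pass_{grade}"] = ok
        rows.append(row)
    return pd.DataFrame(rows)


def write_boards(
    boards: Sequence[BoardRecord], path: Path | str, header_comment: str | None = None
) -> None:
    _write_csv(boards_to_frame(boards), path, header_comment)


def read_boards(path: Path | str) -> list[BoardRecord]:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    boards = []
    pass_cols = [c for c in df.columns if c.startswith("pass_")]
    for d in df.to_dict("records"):
        b = BoardRecord(
            board_id=str(d["board_id"]),
            tree_id=str(d["tree_id"]),
            moe_static=float(d["moe_static_kn_mm2"]),
            visual_pass=bool(d["visual_pass"]),
        )
        for c in pass_cols:
            b.grade_pass[c[len("pass_"):]] = bool(d[c])
        boards.append(b)
    return boards


def save_moe_model(model: LinearMOEModel, path: Path | str) -> None:
    payload = {
        "type": "linear_moe_model",
        "provenance": model.provenance,
        "coefficients": {
            "beta0": model.beta0,
            "beta1": model.beta1,
            "beta2": model.beta2,
            "beta3": model.beta3,
        },
        "centering": {"mean_v2": model.mean_v2, "mean_dbh": model.mean_dbh},
        "diagnostics": dataclasses.asdict(model.diagnostics)
        if model.diagnostics
        else None,
        "stderr": list(model.stderr) if model.stderr else None,
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_moe_model(path: Path | str) -> LinearMOEModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("type") != "linear_moe_model":
        raise ValueError(f"{path} is not a serialized tree-MOE model")
    c = payload["coefficients"]
    diag = payload.get("diagnostics")
    return LinearMOEModel(
        beta0=c["beta0"],
        beta1=c["beta1"],
        beta2=c["beta2"],
        beta3=c["beta3"],
        mean_v2=payload["centering"]["mean_v2"],
        mean_dbh=payload["centering"]["mean_dbh"],
        diagnostics=FitDiagnostics(**diag) if diag else None,
        stderr=tuple(payload["stderr"]) if payload.get("stderr") else None,
        provenance=payload.get("provenance", "fitted"),
    )


def save_grade_models(models: dict[str, GradePassModel], path: Path | str) -> None:
    payload = {
        "type": "grade_pass_models",
        "models": {name: dataclasses.asdict(m) for name, m in models.items()},
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_grade_models(path: Path | str) -> dict[str, GradePassModel]:
    payload = json.loads(Path(path).read_text())
    if payload.get("type") != "grade_pass_models":
        raise ValueError(f"{path} is not a serialized grade-model file")
    out = {}
    for name, d in payload["models"].items():
        d = dict(d)
        if d.get("stderr") is not None:
            d["stderr"] = tuple(d["stderr"])
        out[name] = GradePassModel(**d)
    return out


def save_grade_registry(grades: Iterable[MSRGrade], path: Path | str) -> None:
    """Grade registry as YAML: names plus derived metric thresholds."""
    payload = [
        {
            "name": g.name,
            "stiffness_mpsi": g.stiffness_mpsi,
            "strength_psi": g.strength_psi,
            "stiffness_required_gpa": g.stiffness_required_gpa,
            "strength_required_mpa": g.strength_required_mpa,
        }
        for g in grades
    ]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_grade_registry(path: Path | str) -> tuple[MSRGrade, ...]:
    payload = yaml.safe_load(Path(path).read_text())
    return tuple(parse_grade(entry["name"]) for entry in payload)


def read_hit_table(path: Path | str) -> pd.DataFrame:
    """Raw-hits table: tree_id, depth_cm, direction, hit1..hit8_us,
    distance_mm, plus optional probe_constant_us / sensor offset columns."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    required = (
        ["tree_id", "depth_cm", "direction", "distance_mm"]
        + [f"hit{i}_us" for i in range(1, 9)]
    )
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"hit table missing columns: {missing}")
    return df
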