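"""Pipeline driver: simulate → fit → grade → stand → integrate → report.

The stand-level procedure honours the three-stage order of the original
analysis: expand plot observations to a per-hectare basis, summarise the
normal MOE_est distribution per stratum, then integrate each distribution
against the per-grade logistic pass curves.  Every artifact is stamped with
the configuration hash and seed; a rerun with the same config is
bit-identical for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import enum
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io, msr_grades, pass_rate, report as report_mod, stand_model
from .moe_model import fit_moe_model, predict_all, preset_moe_model
from .synthetic_data import (
    PopulationConfig,
    attach_tree_mean_moe,
    generate_boards,
    generate_trees,
    select_destructive_sample,
)

logger = logging.getLogger(__name__)


class Stage(enum.IntEnum):
    """Pipeline stages; each maps to a distinct nonzero CLI exit code."""

    SIMULATE = 10
    FIT_MOE = 12
    GRADE = 13
    FIT_GRADES = 14
    STAND = 15
    PASS_RATES = 16
    REPORT = 17


class PipelineError(RuntimeError):
    def __init__(self, stage: Stage, cause: Exception):
        super().__init__(f"stage {stage.name} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Run configuration; serializable to/from YAML."""

    seed: int = 0
    outdir: str = "standgrade_out"
    simulate: bool = True
    trees_path: str | None = None  # used when simulate is off
    boards_path: str | None = None
    use_preset_moe: bool = False
    use_preset_grades: bool = False
    weighting: bool = True
    baf: float = 2.0
    renormalize: bool = True
    alpha: float = 0.05
    plots: bool = False
    mc_verify_draws: int = 100_000
    population: PopulationConfig = field(default_factory=PopulationConfig)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    def config_hash(self) -> str:
        plain = _as_plain(self)
        plain.pop("outdir", None)  # output location is not scientific config
        blob = json.dumps(plain, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def to_yaml(self, path: Path | str) -> None:
        Path(path).write_text(yaml.safe_dump(_as_plain(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        pop_raw = raw.pop("population", None)
        cfg = cls(**raw)
        if pop_raw is not None:
            classes = pop_raw.pop("classes", None)
            pop = PopulationConfig(
                **(
                    {"classes": tuple(_class_from(c) for c in classes)}
                    if classes
                    else {}
                ),
                **pop_raw,
            )
            cfg.population = pop
        return cfg


def _class_from(d: dict):
    from .synthetic_data import ClassConfig

    return ClassConfig(**d)


def _as_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full chain; returns the in-memory artifacts.

    Raises :class:`PipelineError` naming the failing stage; artifacts
    written before the failure are retained on disk.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = f"standgrade config_hash={config.config_hash()} seed={config.seed}"
    artifacts: dict = {"stamp": stamp}

    pop = dataclasses.replace(config.population, seed=config.seed)

    # -- simulate (or load) ------------------------------------------------
    try:
        if config.simulate:
            trees = generate_trees(pop)
            moe_gen = preset_moe_model()
            sample = select_destructive_sample(trees, pop)
            boards = generate_boards(trees, moe_gen, pop, sample=sample)
            attach_tree_mean_moe(trees, boards)
            io.write_trees(trees, outdir / "trees.csv", stamp)
            io.write_boards(boards, outdir / "boards.csv", stamp)
        else:
            if not config.trees_path or not config.boards_path:
                raise ValueError("trees_path and boards_path required when not simulating")
            trees = io.read_trees(config.trees_path)
            boards = io.read_boards(config.boards_path)
    except Exception as exc:
        raise PipelineError(Stage.SIMULATE, exc) from exc
    artifacts["trees"], artifacts["boards"] = trees, boards

    # -- fit / apply the tree-MOE model ------------------------------------
    try:
        if config.use_preset_moe:
            moe_model = preset_moe_model()
        else:
            moe_model = fit_moe_model(trees)
        predict_all(moe_model, trees)
        io.save_moe_model(moe_model, outdir / "moe_model.json")
        io.write_trees(trees, outdir / "trees.csv", stamp)
    except Exception as exc:
        raise PipelineError(Stage.FIT_MOE, exc) from exc
    artifacts["moe_model"] = moe_model

    # -- grade boards ------------------------------------------------------
    try:
        grades = msr_grades.default_grades()
        msr_grades.grade_boards(boards, grades)
        io.save_grade_registry(grades, outdir / "grades.yaml")
        io.write_boards(boards, outdir / "boards.csv", stamp)
    except Exception as exc:
        raise PipelineError(Stage.GRADE, exc) from exc
    artifacts["grades"] = grades

    # -- grade pass models -------------------------------------------------
    try:
        if config.use_preset_grades:
            grade_models = msr_grades.preset_grade_models()
        else:
            grade_models = msr_grades.fit_all_grade_models(
                boards, trees, grades, alpha=config.alpha
            )
        io.save_grade_models(grade_models, outdir / "grade_models.json")
    except Exception as exc:
        raise PipelineError(Stage.FIT_GRADES, exc) from exc
    artifacts["grade_models"] = grade_models

    # -- stand distributions + class comparison ----------------------------
    try:
        dists = stand_model.all_stand_distributions(
            trees, weighting=config.weighting, baf=config.baf
        )
        summary = stand_model.stand_summary_table(trees, alpha=config.alpha)
        with open(outdir / "stand_summary.csv", "w") as fh:
            fh.write(f"# {stamp}\n")
            summary.to_csv(fh, index=False)
        normality = stand_model.normality_report(trees)
    except Exception as exc:
        raise PipelineError(Stage.STAND, exc) from exc
    artifacts["distributions"] = dists
    artifacts["stand_summary"] = summary
    artifacts["normality"] = normality

    # -- pass-rate matrix + verification -----------------------------------
    try:
        usable = {n: m for n, m in grade_models.items() if m.usable}
        matrix = pass_rate.pass_rate_table(
            dists, usable, renormalize=config.renormalize
        )
        with open(outdir / "pass_rates.csv", "w") as fh:
            fh.write(f"# {stamp}\n")
            matrix.to_csv(fh)
        verify = pass_rate.verification_report(
            dists, usable, n_draws=config.mc_verify_draws, seed=config.seed
        )
        with open(outdir / "verification.csv", "w") as fh:
            fh.write(f"# {stamp}\n")
            verify.to_csv(fh, index=False)
    except Exception as exc:
        raise PipelineError(Stage.PASS_RATES, exc) from exc
    artifacts["pass_rates"] = matrix
    artifacts["verification"] = verify

    # -- report ------------------------------------------------------------
    try:
        text = report_mod.render_report(artifacts, config)
        (outdir / "report.txt").write_text(text)
        if config.plots:
            report_mod.render_panels(artifacts, outdir / "panels")
        manifest = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "stamp": stamp,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    except Exception as exc:
        raise PipelineError(Stage.REPORT, exc) from exc
    artifacts["report"] = text
    return artifacts
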