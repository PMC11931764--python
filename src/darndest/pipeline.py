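"""End-to-end pipeline: simulate/load -> calibrate -> triage -> evaluate -> econ.

:func:`run_pipeline` chains the library stages into one reproducible report
bundle written to an output directory:

* ``scores.csv`` — the input score table (written when simulated);
* ``cutoffs.json`` — the calibrated or overridden cutoff set;
* ``triage.csv`` — per-patient group, examination mode and final call;
* ``evaluation_<strategy>.json`` — diagnostics per strategy;
* ``comparisons.json`` — pairwise McNemar tests between strategies and
  DeLong AUC comparisons between score curves;
* ``econ.json`` — the hypothetical-cohort economics report;
* ``run_log.json`` — config hash and library versions.

The bundle is a pure function of the configuration (including its seed):
re-running the same config yields byte-identical files.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .cutoffs import (
    DEFAULT_SENS_FLOOR,
    CutoffSet,
    SecondaryCutoffResult,
    fuse_scores,
    select_secondary_cutoff,
    youden_cutoff,
)
from .economics import EconParams, EconReport, build_econ_report
from .metrics import ALPHA_PAIRWISE, delong_compare, mcnemar_test, roc_auc
from .score_io import ScoreTable, read_score_table, write_score_table
from .synthetic import SyntheticConfig, generate_cohort
from .triage import StrategyEvaluation, assign_table, evaluate_strategy

__all__ = ["StatConfig", "PipelineConfig", "PipelineResult", "run_pipeline", "calibrate_cutoffs"]

logger = logging.getLogger("darndest")

_SCORE_VECTORS = ("t1wi", "t2wi", "t1wic", "t1_t2")
_DELONG_PAIRS = (("t1wic", "t1wi"), ("t1wic", "t2wi"), ("t1wic", "t1_t2"))
_MCNEMAR_PAIRS = (
    ("t1_t2_only", "t1wic_only"),
    ("t1_t2_only", "darndest"),
    ("t1wic_only", "darndest"),
)


@dataclass(frozen=True)
class StatConfig:
    """Statistical conventions of a pipeline run."""

    alpha: float = ALPHA_PAIRWISE
    ci_level: float = 0.95
    mcnemar_correction: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError(f"ci_level must lie in (0, 1), got {self.ci_level}")

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "ci_level": self.ci_level,
            "mcnemar_correction": self.mcnemar_correction,
        }


@dataclass(frozen=True)
class PipelineConfig:
    """Full configuration of one pipeline run.

    Exactly one of ``input_path`` (a score-table CSV) and ``synthetic``
    (a generator configuration) must be given.  ``c1``/``c2``/``c3``
    override the corresponding calibrated cutoffs when not ``None``.
    """

    out_dir: str | Path
    input_path: str | Path | None = None
    synthetic: SyntheticConfig | None = None
    c1: float | None = None
    c2: float | None = None
    c3: float | None = None
    sens_floor: float = DEFAULT_SENS_FLOOR
    econ: EconParams = field(default_factory=EconParams)
    stat: StatConfig = field(default_factory=StatConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.synthetic is None):
            raise ValueError("exactly one of input_path and synthetic must be set")

    def to_dict(self) -> dict:
        # out_dir is deliberately excluded: the report is a function of the
        # analysis configuration and seed, not of where it is written
        return {
            "input_path": None if self.input_path is None else str(self.input_path),
            "synthetic": None
            if self.synthetic is None
            else {
                "n": self.synthetic.n,
                "prevalence": self.synthetic.prevalence,
                "auc_targets": list(self.synthetic.auc_targets),
                "correlation": self.synthetic.correlation,
                "seed": self.synthetic.seed,
            },
            "c1": self.c1,
            "c2": self.c2,
            "c3": self.c3,
            "sens_floor": self.sens_floor,
            "econ": self.econ.to_dict(),
            "stat": self.stat.to_dict(),
            "seed": self.seed,
        }


@dataclass
class PipelineResult:
    """In-memory view of a written report bundle."""

    table: ScoreTable
    cutoffs: CutoffSet
    secondary: SecondaryCutoffResult | None
    evaluations: dict[str, StrategyEvaluation]
    comparisons: dict
    econ: EconReport
    out_dir: Path
    paths: dict[str, Path]


def _json_default(obj):
    if isinstance(obj, float) and math.isinf(obj):
        return "infinity"
    raise TypeError(f"not JSON serialisable: {obj!r}")


def _write_json(path: Path, payload: dict) -> None:
    def clean(value):
        if isinstance(value, dict):
            return {k: clean(v) for k, v in value.items()}
        if isinstance(value, (list, tuple)):
            return [clean(v) for v in value]
        if isinstance(value, (np.floating, float)):
            v = float(value)
            return "infinity" if math.isinf(v) else v
        if isinstance(value, np.integer):
            return int(value)
        if isinstance(value, np.bool_):
            return bool(value)
        return value

    path.write_text(json.dumps(clean(payload), indent=2, sort_keys=True) + "\n", encoding="utf-8")


def calibrate_cutoffs(
    table: ScoreTable,
    *,
    c1: float | None = None,
    c2: float | None = None,
    c3: float | None = None,
    sens_floor: float = DEFAULT_SENS_FLOOR,
) -> tuple[CutoffSet, SecondaryCutoffResult | None]:
    """Derive the cutoff set from a calibration table, honouring overrides.

    ``c1`` and ``c3`` default to the Youden cutoffs of the fused and T1WIC
    scores; ``c2`` defaults to the sensitivity-floor search (collapsing to
    ``c1`` — an empty suspicious group — when the first level alone meets
    the floor, and to 0 with a logged warning when the floor is
    unattainable).
    """
    labels = table.labels
    fused = fuse_scores(table.t1wi, table.t2wi)
    c1_value = youden_cutoff(fused, labels) if c1 is None else float(c1)
    c3_value = youden_cutoff(table.t1wic, labels) if c3 is None else float(c3)
    secondary: SecondaryCutoffResult | None = None
    if c2 is None:
        secondary = select_secondary_cutoff(table, c1_value, c3_value, sens_floor)
        c2_value = secondary.resolve(c1_value)
        if not secondary.floor_met:
            logger.warning(
                "sensitivity floor %.2f unattainable: layered sensitivity tops out at %.4f",
                sens_floor,
                secondary.sensitivity,
            )
    else:
        c2_value = float(c2)
    return CutoffSet(c1=c1_value, c2=c2_value, c3=c3_value, sens_floor=sens_floor), secondary


def _strategy_calls(table: ScoreTable, cutoffs: CutoffSet, strategy: str) -> np.ndarray:
    fused = fuse_scores(table.t1wi, table.t2wi)
    if strategy == "t1_t2_only":
        return (fused >= cutoffs.c1).astype(int)
    if strategy == "t1wic_only":
        return (table.t1wic >= cutoffs.c3).astype(int)
    if strategy == "darndest":
        return np.array([o.final_call for o in assign_table(table, cutoffs)], dtype=int)
    raise ValueError(f"no calls defined for strategy {strategy!r}")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the whole pipeline and write the report bundle (see module doc)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    # --- input ------------------------------------------------------------
    if config.input_path is not None:
        logger.info("reading score table from %s", config.input_path)
        table = read_score_table(config.input_path)
    else:
        synth = config.synthetic
        assert synth is not None
        if synth.seed != config.seed:
            synth = SyntheticConfig(
                n=synth.n,
                prevalence=synth.prevalence,
                auc_targets=synth.auc_targets,
                correlation=synth.correlation,
                seed=config.seed,
            )
        logger.info("simulating cohort (n=%d, seed=%d)", synth.n, synth.seed)
        table = generate_cohort(synth)
        paths["scores"] = out_dir / "scores.csv"
        write_score_table(table, paths["scores"])

    # --- calibrate --------------------------------------------------------
    cutoffs, secondary = calibrate_cutoffs(
        table, c1=config.c1, c2=config.c2, c3=config.c3, sens_floor=config.sens_floor
    )
    logger.info("cutoffs: c1=%.4f c2=%.4f c3=%.4f", cutoffs.c1, cutoffs.c2, cutoffs.c3)
    paths["cutoffs"] = out_dir / "cutoffs.json"
    cutoff_payload = cutoffs.to_dict()
    if secondary is not None:
        cutoff_payload["secondary_search"] = {
            "needed": secondary.needed,
            "floor_met": secondary.floor_met,
            "sensitivity": secondary.sensitivity,
        }
    _write_json(paths["cutoffs"], cutoff_payload)

    # --- triage -----------------------------------------------------------
    outcomes = assign_table(table, cutoffs)
    paths["triage"] = out_dir / "triage.csv"
    with paths["triage"].open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["patient_id", "group", "mri_mode", "final_call"])
        for outcome in outcomes:
            writer.writerow([outcome.patient_id, outcome.group, outcome.mri_mode, outcome.final_call])

    # --- evaluate ---------------------------------------------------------
    evaluations: dict[str, StrategyEvaluation] = {}
    for strategy in ("t1_t2_only", "t1wic_only", "darndest", "conventional"):
        evaluation = evaluate_strategy(table, cutoffs, strategy)
        evaluations[strategy] = evaluation
        paths[f"evaluation_{strategy}"] = out_dir / f"evaluation_{strategy}.json"
        _write_json(paths[f"evaluation_{strategy}"], evaluation.to_dict())

    # --- comparisons ------------------------------------------------------
    labels = table.labels
    scores = {
        "t1wi": table.t1wi,
        "t2wi": table.t2wi,
        "t1wic": table.t1wic,
        "t1_t2": fuse_scores(table.t1wi, table.t2wi),
    }
    roc = {
        name: roc_auc(scores[name], labels, level=config.stat.ci_level)
        for name in _SCORE_VECTORS
    }
    comparisons = {
        "mcnemar": {
            f"{a}_vs_{b}": mcnemar_test(
                labels,
                _strategy_calls(table, cutoffs, a),
                _strategy_calls(table, cutoffs, b),
                correction=config.stat.mcnemar_correction,
                alpha=config.stat.alpha,
            ).to_dict()
            for a, b in _MCNEMAR_PAIRS
        },
        "auc": {
            name: {
                "auc": roc[name].auc,
                "ci_low": roc[name].auc_ci_low,
                "ci_high": roc[name].auc_ci_high,
            }
            for name in _SCORE_VECTORS
        },
        "delong": {
            f"{a}_vs_{b}": delong_compare(
                scores[a], scores[b], labels, alpha=config.stat.alpha
            ).to_dict()
            for a, b in _DELONG_PAIRS
        },
    }
    paths["comparisons"] = out_dir / "comparisons.json"
    _write_json(paths["comparisons"], comparisons)

    # --- economics --------------------------------------------------------
    econ = build_econ_report(evaluations["darndest"], config.econ)
    paths["econ"] = out_dir / "econ.json"
    _write_json(paths["econ"], econ.to_dict())

    # --- run log ----------------------------------------------------------
    config_dict = config.to_dict()
    config_json = json.dumps(config_dict, sort_keys=True)
    versions = {"darndest": __version__}
    for mod_name in ("numpy", "scipy", "pandas", "sklearn"):
        module = __import__(mod_name)
        versions[mod_name] = module.__version__
    paths["run_log"] = out_dir / "run_log.json"
    _write_json(
        paths["run_log"],
        {
            "config": config_dict,
            "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
            "versions": versions,
            "n_patients": len(table),
            "cohort_tag": table.cohort_tag,
        },
    )
    logger.info("report bundle written to %s", out_dir)
    return PipelineResult(table, cutoffs, secondary, evaluations, comparisons, econ, out_dir, paths)
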