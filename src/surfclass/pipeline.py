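"""End-to-end orchestration: features -> prune -> train -> interpret.

A :class:`RunConfig` fixes every input path, cutoff and the global seed;
``run_all`` executes the stages, writes each stage's artifact under the
output directory and finishes with a manifest (JSON) recording the config,
the derived per-stage seeds and the SHA-256 of every artifact, enough to
reproduce the run bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .descriptors import build_feature_table, prune_correlated
from .interpretation import threshold_report
from .rf_protocol import SplitSpec, prune_by_importance, run_protocol
from .structure_io import read_structure
from .surface_sasa import SasaParams
from .synthetic_data import PlantedTableSpec, make_planted_table

__all__ = ["RunConfig", "run_all", "StageError"]

log = logging.getLogger("surfclass")

_STAGES = ("features", "prune", "train", "interpret")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything one pipeline run depends on.

    Provide either ``structures`` + ``labels`` (paths) to build the feature
    table from 3D models, or ``feature_table`` (CSV path) to start from a
    precomputed table, or ``planted`` to generate a synthetic one.
    """

    out_dir: str | Path = "results/run"
    structures: list[str] | None = None
    labels: str | None = None
    feature_table: str | None = None
    planted: PlantedTableSpec | None = None
    sasa: SasaParams = field(default_factory=SasaParams)
    correlation_threshold: float = 0.85
    importance_floor: float = 0.02
    split: SplitSpec = field(default_factory=SplitSpec)
    rf_params: dict | None = None
    top_k_models: int = 7
    top_n_features: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.correlation_threshold < 1:
            raise ValueError("correlation_threshold must be in (0, 1)")
        if not 0 <= self.importance_floor < 1:
            raise ValueError("importance_floor must be in [0, 1)")
        sources = [self.structures, self.feature_table, self.planted]
        if sum(s is not None for s in sources) != 1:
            raise ValueError(
                "provide exactly one of structures+labels / feature_table / planted"
            )
        if self.structures is not None and self.labels is None:
            raise ValueError("structures input requires a labels table")
        for p in (self.structures or []) + ([self.labels] if self.labels else []):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        if self.feature_table and not Path(self.feature_table).exists():
            raise FileNotFoundError(self.feature_table)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "sasa" in raw:
            raw["sasa"] = SasaParams(**raw["sasa"])
        if "split" in raw:
            raw["split"] = SplitSpec(**raw["split"])
        if "planted" in raw:
            raw["planted"] = PlantedTableSpec(**raw["planted"])
        return cls(**raw)


def _stage_seeds(seed: int) -> dict[str, int]:
    """One recorded sub-seed per stage, derived from the global seed."""
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {
        name: int(child.generate_state(1)[0] % 2**31)
        for name, child in zip(_STAGES, children)
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_table(config: RunConfig) -> pd.DataFrame:
    if config.planted is not None:
        return make_planted_table(config.planted)
    if config.feature_table is not None:
        return pd.read_csv(config.feature_table, index_col=0)
    labels = pd.read_csv(config.labels, sep=None, engine="python", index_col=0)
    label_map = labels.iloc[:, 0].to_dict()
    inputs = []
    for path in config.structures:
        s = read_structure(path)
        if s.protein_id not in label_map:
            raise KeyError(f"no label for {s.protein_id}")
        inputs.append((s, str(label_map[s.protein_id])))
    return build_feature_table(inputs, config.sasa)


def run_all(config: RunConfig) -> dict:
    """Execute the pipeline; returns the manifest dict (also written to
    ``out_dir/manifest.json``). Any stage failure raises
    :class:`StageError` naming the stage; artifacts written before the
    failure are retained."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    artifacts: dict[str, str] = {}

    def emit(name: str, df: pd.DataFrame, sep: str = ",") -> Path:
        path = out / name
        df.to_csv(path, sep=sep, float_format="%.10g")
        artifacts[name] = _sha256(path)
        return path

    stage = "features"
    try:
        table = _load_table(config)
        emit("feature_table.csv", table)
        log.info("features: %d proteins x %d descriptors", len(table), table.shape[1] - 1)

        stage = "prune"
        pruned, removed = prune_correlated(table, config.correlation_threshold)
        emit("pruned_table.csv", pruned)
        (out / "removed_features.txt").write_text("\n".join(removed) + "\n")
        artifacts["removed_features.txt"] = _sha256(out / "removed_features.txt")
        log.info("prune: removed %d correlated features", len(removed))

        stage = "train"
        result = run_protocol(
            pruned, config.split, config.rf_params,
            seed=seeds["train"], top_k=config.top_k_models,
        )
        retained = prune_by_importance(result, config.importance_floor)
        if len(retained) < pruned.shape[1] - 1:
            final_table = pruned[retained + ["class"]]
            result = run_protocol(
                final_table, config.split, config.rf_params,
                seed=seeds["train"], top_k=config.top_k_models,
            )
        else:
            final_table = pruned
        metrics = pd.DataFrame(
            {
                "seed": [r.seed for r in result.runs],
                "accuracy": [r.metrics.accuracy for r in result.runs],
                "precision": [r.metrics.precision for r in result.runs],
                "recall": [r.metrics.recall for r in result.runs],
                "f1": [r.metrics.f1 for r in result.runs],
                "auc": [r.metrics.auc for r in result.runs],
            }
        )
        emit("run_metrics.tsv", metrics, sep="\t")
        emit(
            "mean_importances.tsv",
            result.mean_importances.sort_values(ascending=False).to_frame("importance"),
            sep="\t",
        )
        log.info(
            "train: best accuracy %.3f over %d iterations",
            result.best.metrics.accuracy, config.split.n_iterations,
        )

        stage = "interpret"
        report = threshold_report(result, final_table, config.top_n_features)
        emit("thresholds.tsv", report, sep="\t")
    except Exception as exc:
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config": _config_dict(config),
        "stage_seeds": seeds,
        "retained_features": retained,
        "best_accuracy": result.best.metrics.accuracy,
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["out_dir"] = str(d["out_dir"])
    if d.get("planted") and d["planted"].get("rules"):
        d["planted"]["rules"] = [list(r.values()) for r in d["planted"]["rules"]]
    return d
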