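"""End-to-end orchestration: read/simulate -> extract -> relevance -> classify.

Every run writes a manifest carrying the seed, a config hash and the
package version, so two runs with equal hashes produce identical
artifacts (up to timestamps, which are confined to the manifest).
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .chat_io import Transcript, read_chat, read_demographics_csv
from .classify import MODEL_NAMES, CVSummary, ModelSpec, evaluate_models
from .features import (
    FEATURE_NAMES,
    LEXSYN_FEATURES,
    FeatureExtractor,
    read_feature_table,
    transcripts_to_table,
)
from .relevance import relevance_report
from .resources import ResourcePaths

log = logging.getLogger(__name__)

#: models cheap enough for the default run; "ann" is opt-in
DEFAULT_MODELS = ("knn", "random_forest", "svm_linear", "svm_poly",
                  "svm_precomputed", "svm_rbf")

FEATURE_SETS = {"all": FEATURE_NAMES, "lexsyn": LEXSYN_FEATURES}


@dataclass
class PipelineConfig:
    """Validated configuration of one pipeline run."""

    input_dir: Path | None = None
    feature_csv: Path | None = None
    demographics_csv: Path | None = None
    output_dir: Path = Path("cookietalk_out")
    models: tuple[str, ...] = DEFAULT_MODELS
    folds: int = 10
    repeats: int = 10
    bins: int = 10
    alpha: float = 0.05
    seed: int = 0
    participant: str = "PAR"
    resources: ResourcePaths = field(default_factory=ResourcePaths)

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        for name in ("input_dir", "feature_csv", "demographics_csv"):
            value = getattr(self, name)
            if value is not None:
                value = Path(value)
                setattr(self, name, value)
                if not value.exists():
                    raise FileNotFoundError(f"{name}: {value} does not exist")
        unknown = set(self.models) - set(MODEL_NAMES)
        if unknown:
            raise ValueError(f"unknown models: {sorted(unknown)}")
        if self.folds < 2 or self.repeats < 1:
            raise ValueError("folds must be >= 2 and repeats >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = {
            k: str(v) if isinstance(v, Path) else v
            for k, v in asdict(self).items()
            if k != "resources"
        }
        payload["resources"] = {
            k: str(v) for k, v in asdict(self.resources).items()
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_transcripts(config: PipelineConfig) -> tuple[list[Transcript], list[tuple[str, str]]]:
    """Read every .cha under input_dir; per-file failures are isolated."""
    assert config.input_dir is not None
    demographics = (
        read_demographics_csv(config.demographics_csv)
        if config.demographics_csv
        else None
    )
    transcripts, failures = [], []
    for path in sorted(config.input_dir.glob("*.cha")):
        try:
            transcripts.append(
                read_chat(path, participant=config.participant, demographics=demographics)
            )
        except Exception as exc:
            log.warning("skipping %s: %s", path.name, exc)
            failures.append((path.name, str(exc)))
    return transcripts, failures


def run_extract(config: PipelineConfig) -> pd.DataFrame:
    """Feature-extraction arm: one 17-feature row per readable transcript."""
    transcripts, read_failures = load_transcripts(config)
    extractor = FeatureExtractor(paths=config.resources)
    frame, failures = transcripts_to_table(transcripts, extractor, on_error="skip")
    for sid, exc in failures:
        log.warning("extraction failed for %s: %s", sid, exc)
    if frame.empty:
        raise RuntimeError(
            f"no subject could be extracted "
            f"({len(read_failures)} read failures, {len(failures)} extraction failures)"
        )
    config.output_dir.mkdir(parents=True, exist_ok=True)
    out = config.output_dir / "features.csv"
    frame.to_csv(out, index=False, float_format="%.15g")
    log.info("wrote %d feature rows to %s", len(frame), out)
    return frame


def run_relevance(config: PipelineConfig, frame: pd.DataFrame) -> dict:
    usable = frame.dropna(subset=["mmse"])
    table, spearman = relevance_report(
        usable[list(FEATURE_NAMES)],
        usable["mmse"].to_numpy(),
        usable["label"].to_numpy(),
        bins=config.bins,
        alpha=config.alpha,
    )
    config.output_dir.mkdir(parents=True, exist_ok=True)
    table.to_csv(config.output_dir / "relevance.csv", index=False)
    block = {
        "rho": spearman.rho,
        "p_value": spearman.p_value,
        "power": spearman.power,
        "n": int(len(usable)),
    }
    (config.output_dir / "spearman.json").write_text(json.dumps(block, indent=2))
    return {"table": table, "spearman": block}


def run_classify(
    config: PipelineConfig, frame: pd.DataFrame, feature_set: str = "all"
) -> CVSummary:
    columns = list(FEATURE_SETS[feature_set])
    specs = [ModelSpec(name) for name in config.models]
    summary = evaluate_models(
        frame[columns],
        frame["label"].to_numpy(),
        specs,
        k=config.folds,
        repeats=config.repeats,
        seed=config.seed,
    )
    config.output_dir.mkdir(parents=True, exist_ok=True)
    summary.table.to_csv(config.output_dir / f"cv_{feature_set}.csv")
    summary.trace.to_csv(config.output_dir / f"cv_{feature_set}_trace.csv", index=False)
    return summary


def run_all(config: PipelineConfig, frame: pd.DataFrame | None = None) -> dict:
    """Full flow; returns the artifact bundle as in-memory objects."""
    started = time.time()
    if frame is None:
        if config.feature_csv is not None:
            frame = read_feature_table(config.feature_csv)
        else:
            frame = run_extract(config)
    else:
        config.output_dir.mkdir(parents=True, exist_ok=True)
        frame.to_csv(config.output_dir / "features.csv", index=False,
                     float_format="%.15g")
    relevance = run_relevance(config, frame)
    cv_lexsyn = run_classify(config, frame, "lexsyn")
    cv_all = run_classify(config, frame, "all")
    manifest = {
        "package": "cookietalk",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_subjects": int(len(frame)),
        "n_features": len(FEATURE_NAMES),
        "models": list(config.models),
        "wall_time_s": round(time.time() - started, 3),
    }
    (config.output_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "features": frame,
        "relevance": relevance,
        "cv_lexsyn": cv_lexsyn,
        "cv_all": cv_all,
        "manifest": manifest,
    }
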