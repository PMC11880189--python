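"""File I/O, configuration and the end-to-end pipeline.

Images and label masks are TIFF / OME-TIFF read through ``tifffile``; tables
are plain CSV with stable headers so every artifact re-parses with the
package's own readers.  ``PipelineConfig`` mirrors the stage configs
(scene, extraction, training, Monte Carlo) and fails fast on unknown keys.
All stage randomness is derived from one global seed so any stage can be
rerun in isolation reproducibly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import model as model_mod
from . import patches as patches_mod
from . import scoring as scoring_mod
from . import synthetic as synthetic_mod

log = logging.getLogger("mnquant")


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


def read_image(path: str | Path, channel_index: int | None = None) -> np.ndarray:
    """Read a single nuclear channel from a TIFF / OME-TIFF file.

    2D files are returned as-is (dtype preserved).  For 3D files the channel
    axis is taken to be the smallest axis of length <= 8 (the layout of
    channels-first or channels-last OME exports); ``channel_index`` selects
    the channel and is required for multi-channel input.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        if channel_index not in (None, 0):
            raise IndexError(f"channel {channel_index} requested from a single-channel image")
        return arr
    if arr.ndim == 3:
        ch_axis = int(np.argmin(arr.shape))
        if arr.shape[ch_axis] > 8:
            raise ValueError(f"cannot identify a channel axis in shape {arr.shape}")
        if channel_index is None:
            raise ValueError(
                f"multi-channel image {path} ({arr.shape[ch_axis]} channels): "
                "channel_index is required"
            )
        if not (0 <= channel_index < arr.shape[ch_axis]):
            raise IndexError(
                f"channel {channel_index} out of range for {arr.shape[ch_axis]} channels"
            )
        return np.take(arr, channel_index, axis=ch_axis)
    raise ValueError(f"unsupported image dimensionality {arr.ndim} in {path}")


def read_mask(path: str | Path) -> np.ndarray:
    """Read an integer label mask, validating dtype and label sign."""
    arr = read_image(path)
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"label mask must be integer-typed, got {arr.dtype}")
    if arr.min() < 0:
        raise ValueError("label mask contains negative labels")
    return arr


def _to_float01(image: np.ndarray) -> np.ndarray:
    """Scale an intensity image to [0, 1] by its dtype range (or max)."""
    if np.issubdtype(image.dtype, np.integer):
        return image.astype(np.float32) / np.iinfo(image.dtype).max
    img = image.astype(np.float32)
    peak = img.max()
    return img / peak if peak > 1.0 else img


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_SECTIONS = {
    "scene": synthetic_mod.SceneConfig,
    "extraction": patches_mod.PatchExtractionConfig,
    "training": model_mod.TrainingConfig,
    "model": model_mod.ModelSpec,
    "monte_carlo": scoring_mod.MonteCarloConfig,
}
_TOP_LEVEL_KEYS = set(_SECTIONS) | {"seed", "log_level", "channel_index", "output_dir"}


@dataclasses.dataclass
class PipelineConfig:
    scene: synthetic_mod.SceneConfig
    extraction: patches_mod.PatchExtractionConfig
    training: model_mod.TrainingConfig
    model: model_mod.ModelSpec
    monte_carlo: scoring_mod.MonteCarloConfig
    seed: int = 0
    log_level: str = "INFO"
    channel_index: int | None = None
    output_dir: str = "mnquant_out"

    def stage_seed(self, stage: str) -> int:
        """Stage-specific seed derived from the global seed (stable hash)."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "little") % (2**31)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _build_section(cls, data: dict, name: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise KeyError(f"unknown keys in config section {name!r}: {sorted(unknown)}")
    for key in ("nucleus_radius_range", "mn_count_distribution", "mn_radius_fraction_range",
                "mn_annulus", "conv_channels", "fov_shape", "target_nuclei_per_fov"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return cls(**data)


def load_pipeline_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file and/or an override dict.

    Unknown keys anywhere are rejected.  The global ``seed`` is threaded into
    every section that accepts one (stage-derived), unless the section sets
    its own explicitly.
    """
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        for key, val in overrides.items():
            if isinstance(val, dict):
                data.setdefault(key, {}).update(val)
            else:
                data[key] = val
    unknown = set(data) - _TOP_LEVEL_KEYS
    if unknown:
        raise KeyError(f"unknown top-level config keys: {sorted(unknown)}")
    sections = {}
    for name, cls in _SECTIONS.items():
        sections[name] = _build_section(cls, dict(data.get(name, {})), name)
    cfg = PipelineConfig(
        **sections,
        seed=int(data.get("seed", 0)),
        log_level=str(data.get("log_level", "INFO")),
        channel_index=data.get("channel_index"),
        output_dir=str(data.get("output_dir", "mnquant_out")),
    )
    # thread the global seed into seeded sections unless explicitly set
    if "seed" not in data.get("scene", {}):
        cfg.scene = dataclasses.replace(cfg.scene, seed=cfg.stage_seed("scene"))
    if "seed" not in data.get("training", {}):
        cfg.training = dataclasses.replace(cfg.training, seed=cfg.stage_seed("training"))
    if "seed" not in data.get("monte_carlo", {}):
        cfg.monte_carlo = dataclasses.replace(cfg.monte_carlo, seed=cfg.stage_seed("monte_carlo"))
    return cfg


# ---------------------------------------------------------------------------
# pipeline stages on disk
# ---------------------------------------------------------------------------

def score_image(
    image: np.ndarray,
    mask: np.ndarray,
    trained: model_mod.TrainedModel,
    extraction: patches_mod.PatchExtractionConfig | None = None,
    image_id: str = "image",
) -> tuple[scoring_mod.CinScoreReport, pd.DataFrame]:
    """Image + mask -> per-nucleus counts and a per-image CIN report.

    Runs patch extraction, count prediction, the out-of-focus QC and the
    patch-overlap (IoU) audit; returns the report and the per-nucleus
    prediction table (columns ``patch_id, label, raw_count, count``).
    """
    extraction = extraction or patches_mod.PatchExtractionConfig(
        final_size=trained.input_size
    )
    image01 = _to_float01(np.asarray(image))
    patches, removed = patches_mod.extract_patches(image01, mask, extraction, image_id)
    if not patches:
        raise ValueError(f"no nuclei found in {image_id}")
    log.info("%s: %d nuclei kept, %d removed by area filter", image_id, len(patches), len(removed))
    records = model_mod.predict_counts(trained, patches)
    pct_oof = patches_mod.pct_out_of_focus(patches, extraction.blur_threshold)
    _, flagged = patches_mod.iou_audit([p.source_bbox for p in patches],
                                       extraction.iou_threshold)
    counts = [r.count for r in records]
    report = scoring_mod.make_report(image_id, counts, pct_out_of_focus=pct_oof,
                                     n_flagged_overlap_pairs=len(flagged))
    table = model_mod.predictions_frame(records)
    table.insert(1, "label", [p.label for p in patches])
    return report, table


def run_pipeline(config: PipelineConfig, model_dir: str | Path | None = None) -> dict:
    """End-to-end run: simulate -> extract -> (train) -> predict -> score.

    With ``model_dir`` given, the trained model is loaded from disk;
    otherwise a model is trained on freshly simulated scenes first.  Writes
    every artifact under ``config.output_dir`` and returns a manifest of
    paths.  Deterministic for a fixed global seed.
    """
    setup_logging(config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("pipeline start, config hash %s", config.config_hash())

    scene = synthetic_mod.generate_scene(config.scene)
    scene_manifest = synthetic_mod.write_scene(scene, out / "scene", force=True)

    if model_dir is not None:
        trained = model_mod.TrainedModel.load(model_dir)
    else:
        trained = train_on_scenes(config)
        trained.save(out / "model")

    report, table = score_image(scene.image, scene.mask, trained,
                                config.extraction, image_id="scene")
    table.to_csv(out / "predictions.csv", index=False)
    report_frame = scoring_mod.reports_frame([report])
    report_frame.to_csv(out / "report.csv", index=False)
    log.info("scene CIN score %.4f over %d nuclei (truth %.4f)",
             report.cin_score, report.n_nuclei, scene.true_cin_score)
    manifest = {
        "config_hash": config.config_hash(),
        "scene": scene_manifest["files"],
        "predictions": str(out / "predictions.csv"),
        "report": str(out / "report.csv"),
        "true_cin_score": scene.true_cin_score,
        "predicted_cin_score": report.cin_score,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def simulate_training_set(
    config: PipelineConfig, n_scenes: int = 8
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate scenes and extract labeled patches for training.

    Ground-truth per-nucleus counts come from the scene truth table joined on
    the mask label of each kept patch.  Returns (patches, labels) with
    patches as an (N, S, S) float array in [0, 1].
    """
    all_patches, all_labels = [], []
    for i in range(n_scenes):
        scene_cfg = dataclasses.replace(
            config.scene, seed=(config.stage_seed("trainset") + i) % (2**31)
        )
        scene = synthetic_mod.generate_scene(scene_cfg)
        patches, _ = patches_mod.extract_patches(
            scene.image, scene.mask, config.extraction, source_image_id=f"scene{i}"
        )
        truth = scene.truth.set_index("nucleus_label")["count"]
        for p in patches:
            all_patches.append(p.pixels)
            all_labels.append(int(truth.loc[p.label]))
    return np.stack(all_patches), np.asarray(all_labels)


def train_on_scenes(config: PipelineConfig, n_scenes: int = 8) -> model_mod.TrainedModel:
    """Simulate, balance, split and train per the standard recipe."""
    patches, labels = simulate_training_set(config, n_scenes)
    patches, labels = model_mod.balance_dataset(
        patches, labels, seed=config.stage_seed("balance")
    )
    train_idx, val_idx = model_mod.split_dataset(
        labels, val_fraction=0.10, seed=config.stage_seed("split")
    )
    trained, history = model_mod.train(
        patches[train_idx], labels[train_idx], patches[val_idx], labels[val_idx],
        model_spec=config.model, config=config.training,
    )
    log.info("training finished: best val MSE %.4f after %d epochs",
             history["val_loss"].min(), len(history))
    return trained
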