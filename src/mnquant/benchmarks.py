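"""Desk-scale benchmark: train the counting CNN on synthetic scenes and
measure hold-out classification metrics plus end-to-end scene-score recovery.

This is the package's standard self-evaluation protocol, sized to run on a
single CPU in roughly ten minutes:

1. Simulate training scenes and extract labeled patches at a reduced
   working resolution (96 px).
2. Balance the label distribution, hold out a stratified 20 % test split,
   and train the small CNN (the remaining 80 % is itself split 90/10 into
   train/validation for the plateau scheduler and early stopping).
3. Report weighted F1 and the multiclass Matthews correlation coefficient
   of rounded counts on the hold-out split.
4. Simulate evaluation scenes whose expected micronucleus rates lie on a
   grid spanning [0, 0.5], score each end-to-end (mask -> patches ->
   counts -> CIN score) and report the Pearson correlation between the
   ground-truth and predicted per-scene CIN scores.

All randomness is derived from the single ``seed`` argument via stable
named sub-seeds, so a benchmark run is exactly reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging

import numpy as np

from . import model as model_mod
from . import patches as patches_mod
from . import synthetic as synthetic_mod
from .io import score_image
from .scoring import compare_scores

log = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class BenchmarkConfig:
    """Problem sizes for the desk-scale benchmark.

    Defaults produce roughly 2,500 labeled patches before balancing.
    """

    n_train_scenes: int = 26
    n_eval_scenes: int = 12
    scene_size: int = 576
    n_nuclei: int = 100
    final_size: int = 96
    max_epochs: int = 30
    holdout_fraction: float = 0.20
    val_fraction: float = 0.10
    max_rate: float = 0.5


def derived_seed(seed: int, name: str) -> int:
    """Stable, order-independent sub-seed in [0, 2^31) for a named stage."""
    digest = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def build_training_set(
    seed: int, config: BenchmarkConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate training scenes and return (patches, labels) before balancing."""
    config = config or BenchmarkConfig()
    base = derived_seed(seed, "train-scenes")
    extraction = patches_mod.PatchExtractionConfig(final_size=config.final_size)
    all_patches, all_labels = [], []
    for i in range(config.n_train_scenes):
        scene_cfg = synthetic_mod.SceneConfig(
            width=config.scene_size,
            height=config.scene_size,
            n_nuclei=config.n_nuclei,
            seed=(base + i) % (2**31),
        )
        scene = synthetic_mod.generate_scene(scene_cfg)
        kept, _ = patches_mod.extract_patches(
            scene.image, scene.mask, extraction, source_image_id=f"train{i}"
        )
        truth = scene.truth.set_index("nucleus_label")["count"]
        for p in kept:
            all_patches.append(p.pixels)
            all_labels.append(int(truth.loc[p.label]))
    log.info("training set: %d patches from %d scenes",
             len(all_labels), config.n_train_scenes)
    return np.stack(all_patches), np.asarray(all_labels)


def train_benchmark_model(seed: int, config: BenchmarkConfig | None = None) -> dict:
    """Balance, split, train and evaluate on the hold-out patch split.

    Returns a dict with the trained model, the hold-out metrics
    (``f1_weighted``, ``mcc``, full ``evaluation``), the training history
    and the hold-out size ``n_holdout``.
    """
    config = config or BenchmarkConfig()
    patches, labels = build_training_set(seed, config)
    idx = model_mod.balance_indices(labels, seed=derived_seed(seed, "balance"))
    xb, yb = patches[idx], labels[idx]

    fit_idx, hold_idx = model_mod.split_dataset(
        yb, val_fraction=config.holdout_fraction, seed=derived_seed(seed, "holdout")
    )
    train_idx, val_idx = model_mod.split_dataset(
        yb[fit_idx], val_fraction=config.val_fraction, seed=derived_seed(seed, "val")
    )
    train_idx, val_idx = fit_idx[train_idx], fit_idx[val_idx]

    training = model_mod.TrainingConfig(
        max_epochs=config.max_epochs, seed=derived_seed(seed, "train")
    )
    trained, history = model_mod.train(
        xb[train_idx], yb[train_idx], xb[val_idx], yb[val_idx],
        model_spec=model_mod.ModelSpec(), config=training,
    )

    raw = trained.predict_raw(xb[hold_idx])
    pred = np.maximum(model_mod.round_half_away_from_zero(raw), 0).astype(int)
    evaluation = model_mod.evaluate_classification(
        yb[hold_idx], pred, raw_scores=raw
    )
    log.info("hold-out (%d patches): weighted F1 %.4f, MCC %.4f",
             hold_idx.size, evaluation["f1_weighted"], evaluation["mcc"])
    return {
        "trained": trained,
        "history": history,
        "f1_weighted": evaluation["f1_weighted"],
        "mcc": evaluation["mcc"],
        "evaluation": evaluation,
        "n_holdout": int(hold_idx.size),
        "n_balanced": int(yb.size),
        "holdout_true": yb[hold_idx],
        "holdout_pred": pred,
    }


def evaluate_scene_scores(
    trained: model_mod.TrainedModel,
    seed: int,
    config: BenchmarkConfig | None = None,
) -> dict:
    """Score held-out scenes spanning expected rates [0, max_rate] end-to-end.

    True scores are the realized ground-truth CIN scores of each simulated
    scene; predicted scores come from the full pipeline on image + mask.
    Returns rates, both score vectors and their comparison statistics.
    """
    config = config or BenchmarkConfig()
    base = derived_seed(seed, "eval-scenes")
    extraction = patches_mod.PatchExtractionConfig(final_size=config.final_size)
    rates = np.linspace(0.0, config.max_rate, config.n_eval_scenes)
    true_scores, predicted_scores = [], []
    for i, rate in enumerate(rates):
        scene_cfg = synthetic_mod.SceneConfig(
            width=config.scene_size,
            height=config.scene_size,
            n_nuclei=config.n_nuclei,
            mn_count_distribution=synthetic_mod.distribution_for_rate(float(rate)),
            seed=(base + i) % (2**31),
        )
        scene = synthetic_mod.generate_scene(scene_cfg)
        report, _ = score_image(
            scene.image, scene.mask, trained, extraction, image_id=f"eval{i}"
        )
        true_scores.append(scene.true_cin_score)
        predicted_scores.append(report.cin_score)
    comparison = compare_scores(true_scores, predicted_scores)
    log.info("scene scores over %d scenes: Pearson %.4f, RMSE %.4f",
             len(rates), comparison["pearson"], comparison["rmse"])
    return {
        "rates": rates,
        "true_scores": np.asarray(true_scores),
        "predicted_scores": np.asarray(predicted_scores),
        "comparison": comparison,
        "pearson": comparison["pearson"],
        "n_scenes": int(rates.size),
    }


def run_benchmark(seed: int, config: BenchmarkConfig | None = None) -> dict:
    """Full protocol: train, evaluate patches, evaluate scene scores."""
    config = config or BenchmarkConfig()
    result = train_benchmark_model(seed, config)
    result["scene_eval"] = evaluate_scene_scores(result["trained"], seed, config)
    result["pearson"] = result["scene_eval"]["pearson"]
    return result
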