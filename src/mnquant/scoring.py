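"""CIN score aggregation and comparison against reference counts.

The CIN score of an image is the ratio of the total number of micronuclei
and associated structures (NBUDs) to the total number of nuclei.  This
module computes per-image scores from per-nucleus counts, averages them
across replicate images per condition, reproduces the manual Monte Carlo
protocol (score a few random fields of view instead of the whole image),
and compares automated against reference score vectors with RMSE, R^2 and
Pearson correlation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as _stats


@dataclasses.dataclass(frozen=True)
class CinScoreReport:
    """Per-image aggregate of the pipeline output."""

    image_id: str
    n_nuclei: int
    total_mn: int
    cin_score: float
    pct_out_of_focus: float = 0.0
    n_flagged_overlap_pairs: int = 0

    def __post_init__(self):
        if self.n_nuclei <= 0:
            raise ValueError("n_nuclei must be positive")
        if abs(self.cin_score - self.total_mn / self.n_nuclei) > 1e-12:
            raise ValueError("cin_score must equal total_mn / n_nuclei")


def make_report(image_id: str, counts, pct_out_of_focus: float = 0.0,
                n_flagged_overlap_pairs: int = 0) -> CinScoreReport:
    counts = np.asarray(counts, dtype=np.int64)
    return CinScoreReport(
        image_id=image_id,
        n_nuclei=int(counts.size),
        total_mn=int(counts.sum()),
        cin_score=float(counts.sum() / counts.size),
        pct_out_of_focus=pct_out_of_focus,
        n_flagged_overlap_pairs=n_flagged_overlap_pairs,
    )


def cin_score(counts) -> float:
    """Total MN+NBUD count divided by the number of nuclei."""
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        raise ValueError("cin_score of an empty count vector is undefined")
    return float(counts.sum() / counts.size)


def reports_frame(reports: list[CinScoreReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [dataclasses.asdict(r) for r in reports],
        columns=["image_id", "n_nuclei", "total_mn", "cin_score",
                 "pct_out_of_focus", "n_flagged_overlap_pairs"],
    )


def aggregate_replicates(reports: list[CinScoreReport], grouping: dict[str, str]) -> pd.DataFrame:
    """Per-condition CIN scores across replicate images.

    ``grouping`` maps image_id -> condition label.  The primary estimate is
    the unweighted mean of per-image scores (replicates count equally, the
    convention of manual scoring); the pooled alternative — total MN over
    total nuclei across the group — is reported alongside for transparency.
    """
    missing = [r.image_id for r in reports if r.image_id not in grouping]
    if missing:
        raise KeyError(f"images without a condition label: {missing}")
    frame = reports_frame(reports)
    frame["condition"] = frame["image_id"].map(grouping)
    rows = []
    for condition, grp in frame.groupby("condition", sort=True):
        rows.append({
            "condition": condition,
            "n_images": len(grp),
            "mean_cin_score": grp["cin_score"].mean(),
            "pooled_cin_score": grp["total_mn"].sum() / grp["n_nuclei"].sum(),
        })
    return pd.DataFrame(rows)


@dataclasses.dataclass(frozen=True)
class MonteCarloConfig:
    """Random field-of-view (FOV) scoring protocol.

    The manual protocol draws ``n_fov`` random FOVs per image and scores
    about 800–1000 nuclei per FOV; at smaller scene sizes
    ``min_nuclei_per_fov`` controls when an FOV is resampled as too sparse.
    """

    n_fov: int = 3
    fov_shape: tuple[int, int] = (1024, 1024)
    target_nuclei_per_fov: tuple[int, int] = (800, 1000)
    min_nuclei_per_fov: int = 1
    max_resample: int = 200
    seed: int = 0

    def validate(self) -> None:
        if self.n_fov < 1:
            raise ValueError("n_fov must be >= 1")
        if min(self.fov_shape) < 1:
            raise ValueError("fov_shape must be positive")


def monte_carlo_estimate(
    nucleus_table: pd.DataFrame,
    image_shape: tuple[int, int],
    config: MonteCarloConfig,
) -> tuple[float, list[float]]:
    """Estimate the image CIN score from ``n_fov`` random fields of view.

    ``nucleus_table`` needs columns ``centroid_y``, ``centroid_x`` and
    ``count``.  FOV top-left corners are uniform over all valid positions;
    nuclei are assigned to an FOV by centroid (half-open window), so a
    nucleus is never counted twice within one FOV.  FOVs with fewer than
    ``min_nuclei_per_fov`` nuclei are redrawn up to ``max_resample`` times.
    Returns the mean of per-FOV scores and the per-FOV scores themselves.
    """
    config.validate()
    rows, cols = image_shape
    fh, fw = min(config.fov_shape[0], rows), min(config.fov_shape[1], cols)
    ys = nucleus_table["centroid_y"].to_numpy(float)
    xs = nucleus_table["centroid_x"].to_numpy(float)
    counts = nucleus_table["count"].to_numpy(float)
    rng = np.random.default_rng(config.seed)
    fov_scores: list[float] = []
    for _ in range(config.n_fov):
        for attempt in range(config.max_resample + 1):
            y0 = rng.uniform(0, rows - fh) if rows > fh else 0.0
            x0 = rng.uniform(0, cols - fw) if cols > fw else 0.0
            inside = (ys >= y0) & (ys < y0 + fh) & (xs >= x0) & (xs < x0 + fw)
            if inside.sum() >= config.min_nuclei_per_fov:
                fov_scores.append(float(counts[inside].sum() / inside.sum()))
                break
        else:
            achievable = len(ys) * (fh * fw) / (rows * cols)
            raise RuntimeError(
                f"no {fh}x{fw} FOV with >= {config.min_nuclei_per_fov} nuclei "
                f"after {config.max_resample} draws (expected ~{achievable:.1f} "
                "nuclei per FOV at this density)"
            )
    return float(np.mean(fov_scores)), fov_scores


def compare_scores(reference, predicted) -> dict:
    """RMSE, Pearson correlation and R^2 between two score vectors.

    R^2 is reported twice: ``r2`` is the coefficient of determination of the
    predictions about the identity line (1 - SS_res/SS_tot, can be negative),
    and ``pearson_squared`` is the square of the correlation; the two differ
    whenever predictions are biased.  Degenerate (zero-variance) inputs set
    ``degenerate=True`` instead of silently returning NaN correlations.
    """
    ref = np.asarray(reference, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if ref.shape != pred.shape or ref.ndim != 1 or ref.size < 2:
        raise ValueError("need two equal-length 1D vectors of length >= 2")
    out = {"rmse": float(np.sqrt(np.mean((ref - pred) ** 2))), "n": int(ref.size)}
    if np.std(ref) == 0 or np.std(pred) == 0:
        out.update(pearson=float("nan"), pearson_squared=float("nan"),
                   r2=float("nan"), degenerate=True)
        return out
    r = float(_stats.pearsonr(ref, pred).statistic)
    ss_res = float(np.sum((ref - pred) ** 2))
    ss_tot = float(np.sum((ref - ref.mean()) ** 2))
    out.update(pearson=r, pearson_squared=r * r, r2=1.0 - ss_res / ss_tot,
               degenerate=False)
    return out
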