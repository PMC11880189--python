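"""Seeded synthetic nuclear-stain scene generator.

Renders 2D fluorescence-like scenes of DAPI/Hoechst-stained nuclei with a
known number of micronuclei (MN) and nuclear buds (NBUDs) per nucleus, plus
the matching instance label mask and a ground-truth table.  The generator
emulates the manual scoring criteria used for real data:

* an MN is a small round chromatin body less than one third of the parent
  nucleus diameter, with staining intensity similar to the parent;
* an NBUD is the same structure still touching / budding from the nuclear
  boundary;
* apoptotic cells (many small fragments, no dominant body) and mitotic cells
  (two adjacent extra-bright lobes) carry a true count of 0.

The label mask contains nuclei only — MN pixels are never part of a mask
label, because in the real pipeline MN detection is the model's job, not the
segmenter's.  All randomness flows from a single ``numpy`` generator seeded
from ``SceneConfig.seed``, so scenes are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from skimage.draw import disk as _draw_disk

PHENOTYPE_NORMAL = "normal"
PHENOTYPE_APOPTOTIC = "apoptotic"
PHENOTYPE_MITOTIC = "mitotic"

TRUTH_COLUMNS = ["nucleus_label", "count", "phenotype", "centroid_y", "centroid_x"]
MN_COLUMNS = ["parent_label", "center_y", "center_x", "radius", "attached"]


class PlacementError(RuntimeError):
    """Raised when nuclei cannot be placed at the requested density."""


@dataclasses.dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic scene.

    Intensities are arbitrary fluorescence units on a [0, 1] scale (written
    to disk as 16-bit).  Lengths are pixels.  ``mn_count_distribution`` is a
    probability vector over per-nucleus CIN counts {0, 1, 2, 3}.
    """

    width: int = 512
    height: int = 512
    n_nuclei: int = 80
    nucleus_radius_range: tuple[float, float] = (9.0, 13.0)
    mn_count_distribution: tuple[float, ...] = (0.6, 0.3, 0.08, 0.02)
    attached_fraction: float = 0.2
    mn_radius_fraction_range: tuple[float, float] = (0.16, 0.30)
    min_mn_radius: float = 1.6
    # detached MN centers are drawn in this annulus (units of parent radius),
    # then pushed out so the MN clears the nucleus boundary by >= 1 px
    mn_annulus: tuple[float, float] = (1.05, 1.35)
    mn_intensity_jitter: float = 0.2
    nbud_max_overlap: float = 2.0
    intensity_mean: float = 0.55
    intensity_sd: float = 0.10
    background_level: float = 0.04
    noise_sd: float = 0.02
    blur_sigma: float = 1.0
    apoptotic_fraction: float = 0.02
    mitotic_fraction: float = 0.02
    min_separation: float | None = None
    max_placement_attempts: int = 500
    seed: int = 0

    def validate(self) -> None:
        p = np.asarray(self.mn_count_distribution, dtype=float)
        if p.size != 4:
            raise ValueError("mn_count_distribution must have 4 entries (counts 0..3)")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"mn_count_distribution must be non-negative and sum to 1, got {p.tolist()}"
            )
        if self.n_nuclei < 1:
            raise ValueError("n_nuclei must be >= 1")
        lo, hi = self.mn_radius_fraction_range
        if not (0 < lo <= hi <= 1 / 3):
            raise ValueError("mn_radius_fraction_range must lie in (0, 1/3]")
        rlo, rhi = self.nucleus_radius_range
        if not (0 < rlo <= rhi):
            raise ValueError("nucleus_radius_range must be positive and ordered")
        for name in ("attached_fraction", "apoptotic_fraction", "mitotic_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.apoptotic_fraction + self.mitotic_fraction > 1.0:
            raise ValueError("apoptotic_fraction + mitotic_fraction must be <= 1")
        if min(self.width, self.height) < 4 * rhi:
            raise ValueError("scene too small for the requested nucleus radii")

    @property
    def separation(self) -> float:
        if self.min_separation is not None:
            return float(self.min_separation)
        return 2.8 * self.nucleus_radius_range[1]


@dataclasses.dataclass
class SyntheticScene:
    """A rendered scene: intensity image, nuclear label mask and ground truth.

    ``truth`` has one row per nucleus (columns ``nucleus_label, count,
    phenotype, centroid_y, centroid_x``); ``mn_records`` one row per rendered
    MN/NBUD (``parent_label, center_y, center_x, radius, attached``).
    """

    image: np.ndarray
    mask: np.ndarray
    truth: pd.DataFrame
    mn_records: pd.DataFrame
    config: SceneConfig

    @property
    def true_cin_score(self) -> float:
        """Realized scene-wide CIN score: total MN+NBUD over total nuclei."""
        return float(self.truth["count"].sum() / len(self.truth))


def _place_centers(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Dart-throwing placement with a minimum pairwise separation."""
    r_hi = cfg.nucleus_radius_range[1]
    margin = math.ceil(r_hi) + 2
    if cfg.height - 2 * margin <= 0 or cfg.width - 2 * margin <= 0:
        raise PlacementError("image too small for nucleus radius plus margin")
    centers: list[tuple[float, float]] = []
    sep2 = cfg.separation**2
    attempts_left = cfg.max_placement_attempts * cfg.n_nuclei
    while len(centers) < cfg.n_nuclei:
        if attempts_left <= 0:
            raise PlacementError(
                f"placed only {len(centers)}/{cfg.n_nuclei} nuclei: "
                f"min_separation={cfg.separation:.1f} px is too dense for a "
                f"{cfg.height}x{cfg.width} scene"
            )
        attempts_left -= 1
        y = rng.uniform(margin, cfg.height - margin)
        x = rng.uniform(margin, cfg.width - margin)
        if all((y - cy) ** 2 + (x - cx) ** 2 >= sep2 for cy, cx in centers):
            centers.append((y, x))
    return np.asarray(centers)


def _paint(img: np.ndarray, cy: float, cx: float, radius: float, value: float) -> None:
    rr, cc = _draw_disk((cy, cx), radius, shape=img.shape)
    img[rr, cc] = np.maximum(img[rr, cc], value)


def _disk_coords(shape, cy, cx, radius):
    return _draw_disk((cy, cx), radius, shape=shape)


def generate_scene(config: SceneConfig) -> SyntheticScene:
    """Render one scene deterministically from ``config.seed``.

    Returns a :class:`SyntheticScene` whose mask labels are ``1..n_nuclei``.
    Detached MN are rejected if they would touch any nucleus footprint; after
    bounded retries an MN falls back to being rendered attached (as an NBUD)
    so the ground-truth count is always honored.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    shape = (config.height, config.width)
    centers = _place_centers(config, rng)
    n = config.n_nuclei

    radii = rng.uniform(*config.nucleus_radius_range, size=n)
    base = rng.normal(config.intensity_mean, config.intensity_sd, size=n)
    base = np.clip(base, 0.15, 1.0)

    # phenotype roll, then per-nucleus count
    roll = rng.random(n)
    phenotypes = np.where(
        roll < config.apoptotic_fraction,
        PHENOTYPE_APOPTOTIC,
        np.where(
            roll < config.apoptotic_fraction + config.mitotic_fraction,
            PHENOTYPE_MITOTIC,
            PHENOTYPE_NORMAL,
        ),
    )
    counts = rng.choice(4, size=n, p=np.asarray(config.mn_count_distribution, float))
    counts[phenotypes != PHENOTYPE_NORMAL] = 0

    img = np.full(shape, config.background_level, dtype=np.float64)
    mask = np.zeros(shape, dtype=np.uint16 if n < 65535 else np.uint32)

    truth_rows = []
    mn_rows = []
    # nucleus body footprint used for the detached-MN overlap veto; grown by
    # 1 px so blur halos of MN and nuclei stay visually separable
    occupied = np.zeros(shape, dtype=bool)
    for k in range(n):
        cy, cx = centers[k]
        r = radii[k]
        if phenotypes[k] == PHENOTYPE_MITOTIC:
            ang = rng.uniform(0, 2 * math.pi)
            off = 0.55 * r
            lobe_r = 0.75 * r
            bright = min(1.9 * base[k], 1.0)
            for s in (-1.0, 1.0):
                ly, lx = cy + s * off * math.sin(ang), cx + s * off * math.cos(ang)
                _paint(img, ly, lx, lobe_r, bright)
                rr, cc = _disk_coords(shape, ly, lx, lobe_r)
                mask[rr, cc] = k + 1
                orr, occ_ = _disk_coords(shape, ly, lx, lobe_r + 1)
                occupied[orr, occ_] = True
        elif phenotypes[k] == PHENOTYPE_APOPTOTIC:
            n_frag = rng.integers(5, 13)
            for _ in range(n_frag):
                ang = rng.uniform(0, 2 * math.pi)
                d = 0.8 * r * math.sqrt(rng.random())
                fy, fx = cy + d * math.sin(ang), cx + d * math.cos(ang)
                fr = rng.uniform(0.12, 0.22) * r
                _paint(img, fy, fx, fr, base[k] * rng.uniform(0.9, 1.3))
                rr, cc = _disk_coords(shape, fy, fx, fr)
                mask[rr, cc] = k + 1
                orr, occ_ = _disk_coords(shape, fy, fx, fr + 1)
                occupied[orr, occ_] = True
        else:
            _paint(img, cy, cx, r, base[k])
            rr, cc = _disk_coords(shape, cy, cx, r)
            mask[rr, cc] = k + 1
            orr, occ_ = _disk_coords(shape, cy, cx, r + 1)
            occupied[orr, occ_] = True
        truth_rows.append((k + 1, int(counts[k]), phenotypes[k], cy, cx))

    # MN/NBUD rendering in a second pass so the occupancy map is complete
    for k in range(n):
        if phenotypes[k] != PHENOTYPE_NORMAL:
            continue
        cy, cx = centers[k]
        r = radii[k]
        for _ in range(int(counts[k])):
            frac = rng.uniform(*config.mn_radius_fraction_range)
            mn_r = min(max(frac * r, config.min_mn_radius), r / 3)
            intensity = base[k] * (1.0 + rng.uniform(-1, 1) * config.mn_intensity_jitter)
            intensity = float(np.clip(intensity, 0.1, 1.0))
            attached = rng.random() < config.attached_fraction
            placed = False
            if not attached:
                for _try in range(60):
                    ang = rng.uniform(0, 2 * math.pi)
                    d = rng.uniform(*config.mn_annulus) * r
                    d = max(d, r + mn_r + 1.0)
                    my, mx = cy + d * math.sin(ang), cx + d * math.cos(ang)
                    if not (0 <= my < shape[0] and 0 <= mx < shape[1]):
                        continue
                    rr, cc = _disk_coords(shape, my, mx, mn_r + 1)
                    if rr.size and not occupied[rr, cc].any():
                        _paint(img, my, mx, mn_r, intensity)
                        mn_rows.append((k + 1, my, mx, mn_r, False))
                        placed = True
                        break
                if not placed:
                    attached = True  # crowded neighborhood: render as a bud
            if attached:
                ang = rng.uniform(0, 2 * math.pi)
                d = r + mn_r - rng.uniform(0.0, config.nbud_max_overlap)
                my, mx = cy + d * math.sin(ang), cx + d * math.cos(ang)
                _paint(img, my, mx, mn_r, intensity)
                mn_rows.append((k + 1, my, mx, mn_r, True))

    if config.blur_sigma > 0:
        img = ndi.gaussian_filter(img, config.blur_sigma)
    if config.noise_sd > 0:
        img = img + rng.normal(0.0, config.noise_sd, size=shape)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    mn_records = pd.DataFrame(mn_rows, columns=MN_COLUMNS)
    return SyntheticScene(image=img, mask=mask, truth=truth, mn_records=mn_records, config=config)


def distribution_for_rate(rate: float) -> tuple[float, float, float, float]:
    """A count distribution over {0..3} whose mean equals ``rate``.

    Convenience for sweeping scenes across CIN scores: probability mass is
    mostly on count 1 with small tails on 2 and 3, which matches the heavy
    skew of real per-nucleus counts.  Valid for ``rate`` in [0, ~1.16].
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    p1, p2, p3 = 0.74 * rate, 0.10 * rate, 0.02 * rate
    p0 = 1.0 - p1 - p2 - p3
    if p0 < 0:
        raise ValueError(f"rate {rate} too large for this parametrization")
    return (p0, p1, p2, p3)


def write_scene(scene: SyntheticScene, directory: str | Path, force: bool = False) -> dict:
    """Write image/mask TIFFs and truth CSVs; return a manifest dict.

    The image is scaled to uint16 (full range = intensity 1.0); the mask keeps
    its integer dtype so labels round-trip exactly.  Refuses to overwrite
    existing files unless ``force``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": directory / "image.tif",
        "mask": directory / "mask.tif",
        "truth": directory / "truth.csv",
        "mn_records": directory / "mn_records.csv",
        "manifest": directory / "manifest.json",
    }
    if not force:
        clashes = [str(p) for p in paths.values() if p.exists()]
        if clashes:
            raise FileExistsError(f"refusing to overwrite {clashes}; pass force=True")
    tifffile.imwrite(paths["image"], (scene.image * 65535.0 + 0.5).astype(np.uint16))
    tifffile.imwrite(paths["mask"], scene.mask)
    scene.truth.to_csv(paths["truth"], index=False)
    scene.mn_records.to_csv(paths["mn_records"], index=False)
    manifest = {
        "files": {k: str(v) for k, v in paths.items() if k != "manifest"},
        "config": dataclasses.asdict(scene.config),
        "n_nuclei": int(len(scene.truth)),
        "true_cin_score": scene.true_cin_score,
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    return manifest
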