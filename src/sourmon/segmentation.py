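"""Tile stitching, chamber grid bookkeeping and trainable pixel classification.

The chamber is imaged as a grid of stage tiles; tiles are placed on a common
canvas by translating calibrated stage coordinates into pixel space, with an
optional cross-correlation refinement of each placement.  The stitched image
is partitioned into a rectangular grid of analysis regions (47 x 15 by
default, matching the chamber geometry); uninformative regions (sensor
location, uneven chamber edges) are deselected through configurable
exclusion zones.  Pixels are classified into cell / background by a
regularized logistic model over handcrafted local features — the lightest
model that is genuinely trainable on a handful of labeled images.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from skimage.morphology import remove_small_holes, remove_small_objects

logger = logging.getLogger(__name__)

FEATURE_NAMES = (
    "intensity",
    "mean_s3",
    "mean_s9",
    "sd_s3",
    "sd_s9",
    "gradient",
    "log_s2",
)


@dataclass
class TileImage:
    """One stage tile: pixel data plus calibrated stage coordinates (µm)."""

    pixels: np.ndarray
    stage_x_um: float
    stage_y_um: float
    t_h: float = 0.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("tile intensities must be finite")


@dataclass
class StitchCalibration:
    """Stage-to-image mapping: µm per pixel and axis orientation."""

    um_per_px: float = 1.0
    y_flip: bool = False

    def to_px(self, x_um: float, y_um: float) -> tuple[float, float]:
        col = x_um / self.um_per_px
        row = (-y_um if self.y_flip else y_um) / self.um_per_px
        return row, col


def stitch(
    tiles: list[TileImage],
    calibration: StitchCalibration,
    refine: bool = False,
    search_radius_px: int = 5,
    return_offsets: bool = False,
):
    """Assemble stage tiles onto a common canvas by translation.

    Overlapping pixels are resolved by feathered averaging (weights taper
    toward each tile's edges).  With ``refine=True`` each tile placement is
    adjusted by registering it against the partially built canvas within
    ``search_radius_px`` (corrects stage jitter).  Gaps not covered by any
    tile are NaN and reported via a warning.
    """
    if not tiles:
        raise ValueError("no tiles to stitch")
    if not math.isfinite(calibration.um_per_px) or calibration.um_per_px <= 0:
        raise ValueError("calibration must be finite and positive")
    t0 = tiles[0].t_h
    if any(abs(t.t_h - t0) > 1e-9 for t in tiles):
        raise ValueError("all tiles must share the acquisition time")

    offsets = []
    for tile in tiles:
        row, col = calibration.to_px(tile.stage_x_um, tile.stage_y_um)
        offsets.append((int(round(row)), int(round(col))))
    min_r = min(r for r, _ in offsets)
    min_c = min(c for _, c in offsets)
    offsets = [(r - min_r, c - min_c) for r, c in offsets]

    pad = search_radius_px if refine else 0
    offsets = [(r + pad, c + pad) for r, c in offsets]
    h = max(r + t.pixels.shape[0] for (r, _), t in zip(offsets, tiles)) + pad
    w = max(c + t.pixels.shape[1] for (_, c), t in zip(offsets, tiles)) + pad
    acc = np.zeros((h, w))
    weight = np.zeros((h, w))

    def _feather(shape):
        ry = np.minimum(np.arange(shape[0]) + 1, np.arange(shape[0])[::-1] + 1)
        rx = np.minimum(np.arange(shape[1]) + 1, np.arange(shape[1])[::-1] + 1)
        return np.minimum.outer(ry, rx).astype(float)

    used_offsets = []
    for i, (tile, (r, c)) in enumerate(zip(tiles, offsets)):
        th, tw = tile.pixels.shape
        if refine and i > 0 and weight.max() > 0:
            r, c = _refine_offset(acc, weight, tile.pixels, r, c, search_radius_px)
        r = int(np.clip(r, 0, h - th))
        c = int(np.clip(c, 0, w - tw))
        fw = _feather(tile.pixels.shape)
        acc[r : r + th, c : c + tw] += tile.pixels * fw
        weight[r : r + th, c : c + tw] += fw
        used_offsets.append((r, c))

    out = np.full((h, w), np.nan)
    covered = weight > 0
    out[covered] = acc[covered] / weight[covered]
    # crop to the covered bounding box (removes any refinement padding)
    rows = np.flatnonzero(covered.any(axis=1))
    cols = np.flatnonzero(covered.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    out = out[r0:r1, c0:c1]
    used_offsets = [(r - r0, c - c0) for r, c in used_offsets]
    n_gap = int(np.isnan(out).sum())
    if n_gap:
        logger.warning("stitched canvas has %d uncovered gap pixels (NaN)", n_gap)
    if return_offsets:
        return out, used_offsets
    return out


def _refine_offset(acc, weight, tile, r, c, radius):
    """Refine one tile placement against the current canvas.

    Exhaustive integer search over the ±radius window, scoring each
    candidate by mean squared difference against the already-covered canvas
    pixels.  Exact for translation-only jitter; ties keep the nominal
    placement.
    """
    th, tw = tile.shape
    big_h, big_w = acc.shape
    best = (0.0, 0, 0)
    best_score = None
    for dr in range(-radius, radius + 1):
        for dc in range(-radius, radius + 1):
            r2, c2 = r + dr, c + dc
            rr0, cc0 = max(r2, 0), max(c2, 0)
            rr1, cc1 = min(r2 + th, big_h), min(c2 + tw, big_w)
            if rr1 <= rr0 or cc1 <= cc0:
                continue
            sub_w = weight[rr0:rr1, cc0:cc1]
            cov = sub_w > 0
            n_cov = int(cov.sum())
            if n_cov < 0.01 * tile.size:
                continue
            sub_ref = acc[rr0:rr1, cc0:cc1][cov] / sub_w[cov]
            sub_tile = tile[rr0 - r2 : rr1 - r2, cc0 - c2 : cc1 - c2][cov]
            score = float(np.mean((sub_ref - sub_tile) ** 2))
            # prefer strictly better scores; nominal placement wins ties
            if best_score is None or score < best_score - 1e-12 or (
                score < best_score + 1e-12 and (dr, dc) == (0, 0)
            ):
                best_score = score
                best = (score, dr, dc)
    if best_score is None:
        return r, c
    return r + best[1], c + best[2]


# ---------------------------------------------------------------------------
# analysis grid


@dataclass
class RegionGrid:
    """Rectangular partition of the stitched image into analysis regions.

    Row/column boundaries are integer edges covering the image exactly
    (remainder pixels are absorbed by edge regions).  ``retained`` flags
    regions kept for confluency averaging.
    """

    rows: int
    cols: int
    row_edges: np.ndarray
    col_edges: np.ndarray
    retained: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.retained is None:
            self.retained = np.ones(self.rows * self.cols, dtype=bool)
        self.retained = np.asarray(self.retained, dtype=bool)

    @property
    def n_regions(self) -> int:
        return self.rows * self.cols

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())

    @property
    def n_discarded(self) -> int:
        return self.n_regions - self.n_retained

    def region_slices(self, index: int) -> tuple[slice, slice]:
        r, c = divmod(index, self.cols)
        return (
            slice(int(self.row_edges[r]), int(self.row_edges[r + 1])),
            slice(int(self.col_edges[c]), int(self.col_edges[c + 1])),
        )

    def to_dict(self) -> dict:
        return {
            "rows": self.rows,
            "cols": self.cols,
            "row_edges": self.row_edges.tolist(),
            "col_edges": self.col_edges.tolist(),
            "retained": self.retained.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegionGrid":
        return cls(
            rows=d["rows"],
            cols=d["cols"],
            row_edges=np.asarray(d["row_edges"]),
            col_edges=np.asarray(d["col_edges"]),
            retained=np.asarray(d["retained"], dtype=bool),
        )


def build_grid(image_shape: tuple[int, int], rows: int = 47, cols: int = 15) -> RegionGrid:
    """Partition an image of ``image_shape`` into a rows x cols region grid."""
    h, w = image_shape[:2]
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    if rows * cols > h * w or rows > h or cols > w:
        raise ValueError(f"grid {rows}x{cols} exceeds image of shape {h}x{w}")
    row_edges = np.round(np.linspace(0, h, rows + 1)).astype(int)
    col_edges = np.round(np.linspace(0, w, cols + 1)).astype(int)
    return RegionGrid(rows=rows, cols=cols, row_edges=row_edges, col_edges=col_edges)


def deselect_regions(
    grid: RegionGrid,
    indices=None,
    border: int = 0,
    blocks=None,
) -> RegionGrid:
    """Return a copy of the grid with uninformative regions discarded.

    Deselection is data-driven: explicit region ``indices``, a ``border``
    ring of regions (uneven chamber edges), and/or rectangular ``blocks``
    of grid cells ``(row0, row1, col0, col1)`` (half-open; e.g. the oxygen
    sensor footprint).
    """
    retained = grid.retained.copy()
    if indices is not None:
        idx = np.asarray(list(indices), dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= grid.n_regions):
            raise ValueError("region index out of range")
        retained[idx] = False
    if border > 0:
        for i in range(grid.n_regions):
            r, c = divmod(i, grid.cols)
            if r < border or r >= grid.rows - border or c < border or c >= grid.cols - border:
                retained[i] = False
    if blocks:
        for r0, r1, c0, c1 in blocks:
            for r in range(r0, r1):
                for c in range(c0, c1):
                    if 0 <= r < grid.rows and 0 <= c < grid.cols:
                        retained[r * grid.cols + c] = False
    if not retained.any():
        raise ValueError("deselection left no retained regions")
    return RegionGrid(
        rows=grid.rows,
        cols=grid.cols,
        row_edges=grid.row_edges,
        col_edges=grid.col_edges,
        retained=retained,
    )


# ---------------------------------------------------------------------------
# pixel features and classifier


def extract_features(image: np.ndarray) -> np.ndarray:
    """Per-pixel feature stack for cell/background classification.

    Features: raw intensity; local mean and SD at two scales (3 and 9 px);
    gradient magnitude; Laplacian-of-Gaussian response at sigma 2 px (the
    halo-sensitive channel).  Returns an (H, W, 7) float array; a constant
    image yields exactly zero contrast features.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or not np.all(np.isfinite(img)):
        raise ValueError("image must be a finite 2-D array")
    means, sds = [], []
    for size in (3, 9):
        mean = ndimage.uniform_filter(img, size)
        sq = ndimage.uniform_filter(img * img, size)
        var = sq - mean * mean
        # clamp catastrophic-cancellation residue so flat patches give SD 0
        var[var < 1e-10 * (mean * mean + 1.0)] = 0.0
        means.append(mean)
        sds.append(np.sqrt(var))
    grad = np.hypot(ndimage.sobel(img, axis=1), ndimage.sobel(img, axis=0))
    # mean-centering removes the DC residue of the truncated LoG kernel
    log2 = ndimage.gaussian_laplace(img - img.mean(), sigma=2.0)
    return np.stack([img, means[0], means[1], sds[0], sds[1], grad, log2], axis=-1)


@dataclass
class TrainedPixelClassifier:
    """Regularized logistic pixel classifier over handcrafted features."""

    feature_names: tuple[str, ...]
    coef: np.ndarray
    intercept: float
    feat_mean: np.ndarray
    feat_sd: np.ndarray
    holdout_accuracy: float
    n_train_pixels: int
    seed: int
    min_object_area: int = 30
    max_hole_area: int = 100

    def decision(self, features: np.ndarray) -> np.ndarray:
        z = (features - self.feat_mean) / self.feat_sd
        return z @ self.coef + self.intercept

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "feat_mean": self.feat_mean.tolist(),
            "feat_sd": self.feat_sd.tolist(),
            "holdout_accuracy": self.holdout_accuracy,
            "n_train_pixels": self.n_train_pixels,
            "seed": self.seed,
            "min_object_area": self.min_object_area,
            "max_hole_area": self.max_hole_area,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedPixelClassifier":
        return cls(
            feature_names=tuple(d["feature_names"]),
            coef=np.asarray(d["coef"], dtype=float),
            intercept=float(d["intercept"]),
            feat_mean=np.asarray(d["feat_mean"], dtype=float),
            feat_sd=np.asarray(d["feat_sd"], dtype=float),
            holdout_accuracy=float(d["holdout_accuracy"]),
            n_train_pixels=int(d["n_train_pixels"]),
            seed=int(d["seed"]),
            min_object_area=int(d.get("min_object_area", 30)),
            max_hole_area=int(d.get("max_hole_area", 100)),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"schema": "sourmon.pixel_classifier.v1", **self.to_dict()}, fh)

    @classmethod
    def load(cls, path) -> "TrainedPixelClassifier":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def train_classifier(
    images,
    labels,
    seed: int = 0,
    max_pixels_per_class: int = 40000,
    holdout_frac: float = 0.25,
) -> TrainedPixelClassifier:
    """Train the pixel classifier on labeled images (ground-truth masks).

    Pixels are subsampled per class, features standardized, and a
    regularized logistic model fit; held-out pixel accuracy is reported.
    Deterministic for a given seed.
    """
    if isinstance(images, np.ndarray) and images.ndim == 2:
        images, labels = [images], [labels]
    feats_list, lab_list = [], []
    for img, lab in zip(images, labels):
        stack = extract_features(np.asarray(img, dtype=float))
        feats_list.append(stack.reshape(-1, stack.shape[-1]))
        lab_list.append(np.asarray(lab).astype(bool).ravel())
    X = np.concatenate(feats_list)
    y = np.concatenate(lab_list)
    if y.all() or not y.any():
        raise ValueError("training labels must contain both classes")

    rng = np.random.default_rng(seed)
    keep = []
    for cls_val in (False, True):
        idx = np.flatnonzero(y == cls_val)
        if len(idx) > max_pixels_per_class:
            idx = rng.choice(idx, size=max_pixels_per_class, replace=False)
        keep.append(idx)
    keep = np.concatenate(keep)
    X, y = X[keep], y[keep]

    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=holdout_frac, random_state=seed, stratify=y
    )
    mean = X_tr.mean(axis=0)
    sd = X_tr.std(axis=0)
    sd = np.where(sd > 1e-12, sd, 1.0)
    model = LogisticRegression(C=1.0, max_iter=300, random_state=seed)
    model.fit((X_tr - mean) / sd, y_tr)
    acc = float(model.score((X_te - mean) / sd, y_te))
    return TrainedPixelClassifier(
        feature_names=FEATURE_NAMES,
        coef=model.coef_.ravel(),
        intercept=float(model.intercept_[0]),
        feat_mean=mean,
        feat_sd=sd,
        holdout_accuracy=acc,
        n_train_pixels=len(y_tr),
        seed=seed,
    )


@dataclass
class SegMask:
    """Binary segmentation (1 = cell, 0 = background) with provenance."""

    mask: np.ndarray
    classifier_seed: int | None = None
    postprocessing: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)

    @property
    def confluency(self) -> float:
        return float(self.mask.mean())


def segment(image: np.ndarray, clf: TrainedPixelClassifier) -> SegMask:
    """Classify every pixel of ``image`` and post-process the binary mask.

    Decision-boundary ties (score exactly 0) go to background — the
    conservative choice for confluency.  Post-processing removes connected
    components below ``min_object_area`` and fills holes below
    ``max_hole_area``.
    """
    stack = extract_features(image)
    if stack.shape[-1] != len(clf.feature_names):
        raise ValueError(
            f"feature mismatch: classifier expects {clf.feature_names}, "
            f"got {stack.shape[-1]} features"
        )
    score = clf.decision(stack.reshape(-1, stack.shape[-1])).reshape(image.shape)
    mask = score > 0.0
    if clf.min_object_area > 0:
        mask = remove_small_objects(mask, max_size=clf.min_object_area - 1)
    if clf.max_hole_area > 0:
        mask = remove_small_holes(mask, max_size=clf.max_hole_area - 1)
    return SegMask(
        mask=mask,
        classifier_seed=clf.seed,
        postprocessing=f"min_object={clf.min_object_area},max_hole={clf.max_hole_area}",
    )
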