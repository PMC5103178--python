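"""Confluency, packing-corrected confluency (PCC) and cell density.

Raw confluency — the fraction of culture area covered by cells — understates
cell number once cells pack into contact and clusters, because projected
areas overlap.  The packing-corrected confluency multiplies the raw value by
a monotone packing factor (>= 1, identity for isolated cells) so that

    density [cells/cm^2] = PCC / mean_cell_footprint [cm^2].

The packing curve and footprint are calibrated on ground-truthed fixtures
(images with known cell counts) so that the density estimate is unbiased on
them; the monolayer assumption is tracked with a QC flag once raw
confluency exceeds a warning threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segmentation import RegionGrid, SegMask

#: Raw confluency above which the monolayer assumption becomes doubtful.
MONOLAYER_WARN_THRESHOLD = 0.85

UM2_PER_CM2 = 1e8


@dataclass
class ConfluencyRecord:
    """Per-region and culture-mean confluency at one timepoint."""

    t_h: float
    per_region: np.ndarray       # retained regions only, in grid order
    culture_mean: float
    region_indices: np.ndarray = field(default=None)


def region_confluency(mask: SegMask | np.ndarray, grid: RegionGrid, t_h: float = 0.0) -> ConfluencyRecord:
    """Cell-pixel fraction per region; culture mean over retained regions.

    Discarded regions are excluded from the culture mean (the mean is
    unweighted across retained regions).
    """
    arr = mask.mask if isinstance(mask, SegMask) else np.asarray(mask).astype(bool)
    if arr.shape[0] < grid.row_edges[-1] or arr.shape[1] < grid.col_edges[-1]:
        raise ValueError("mask smaller than the grid it should cover")
    values, indices = [], []
    for i in range(grid.n_regions):
        if not grid.retained[i]:
            continue
        sl = grid.region_slices(i)
        region = arr[sl]
        if region.size == 0:
            raise ValueError(f"region {i} contains zero pixels — grid invalid")
        values.append(region.mean())
        indices.append(i)
    per_region = np.asarray(values, dtype=float)
    return ConfluencyRecord(
        t_h=t_h,
        per_region=per_region,
        culture_mean=float(per_region.mean()),
        region_indices=np.asarray(indices),
    )


@dataclass
class PackingModel:
    """Calibrated footprint + monotone packing curve (confluency -> factor >= 1).

    ``knots`` are (confluency, packing_factor) pairs of a piecewise-linear
    monotone curve; the curve is 1 in the isolated-cell regime.
    """

    mean_cell_footprint_um2: float
    knots: tuple[tuple[float, float], ...]
    provenance: str = ""
    calibrated: bool = True

    def __post_init__(self) -> None:
        if self.mean_cell_footprint_um2 <= 0:
            raise ValueError("cell footprint must be positive")
        pf = [k[1] for k in self.knots]
        if any(p < 1.0 - 1e-9 for p in pf):
            raise ValueError("packing factor must be >= 1")
        if any(b < a - 1e-9 for a, b in zip(pf, pf[1:])):
            raise ValueError("packing curve must be monotone non-decreasing")

    def packing_factor(self, confluency):
        xs = np.array([k[0] for k in self.knots])
        ys = np.array([k[1] for k in self.knots])
        return np.interp(np.asarray(confluency, dtype=float), xs, ys)

    def to_dict(self) -> dict:
        return {
            "mean_cell_footprint_um2": self.mean_cell_footprint_um2,
            "knots": [list(k) for k in self.knots],
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PackingModel":
        return cls(
            mean_cell_footprint_um2=float(d["mean_cell_footprint_um2"]),
            knots=tuple(tuple(k) for k in d["knots"]),
            provenance=d.get("provenance", ""),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"schema": "sourmon.packing_model.v1", **self.to_dict()}, fh)

    @classmethod
    def load(cls, path) -> "PackingModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def identity_packing_model(footprint_um2: float) -> PackingModel:
    """Packing model with factor 1 everywhere (isolated cells)."""
    return PackingModel(
        mean_cell_footprint_um2=footprint_um2,
        knots=((0.0, 1.0), (1.0, 1.0)),
        provenance="identity",
    )


def packing_corrected_confluency(confluency, model: PackingModel):
    """PCC = confluency * packing_factor(confluency).

    Accepts a raw confluency fraction (or array) or a :class:`SegMask`.
    """
    if isinstance(confluency, SegMask):
        confluency = confluency.confluency
    if not model.calibrated:
        raise ValueError("packing model is not calibrated")
    c = np.asarray(confluency, dtype=float)
    pcc = c * model.packing_factor(c)
    return float(pcc) if np.ndim(confluency) == 0 else pcc


@dataclass
class DensityRecord:
    """Cell density (the X of the growth and mass-balance equations)."""

    t_h: float
    density_cells_cm2: float
    cell_count: float
    confluency: float
    pcc: float
    qc_monolayer_warn: bool


def density_from_pcc(
    pcc: float,
    model: PackingModel,
    chamber_area_cm2: float,
    t_h: float = 0.0,
    raw_confluency: float | None = None,
) -> DensityRecord:
    """Convert PCC to cell density (cells/cm^2) and chamber cell count.

    The monolayer QC flag is raised when the raw confluency exceeds
    0.85 — beyond that, cells pile up and area-based density
    underestimates the true count.
    """
    if not (0.0 <= pcc <= 2.0):
        raise ValueError("pcc must be a fraction (0..~1.6)")
    footprint_cm2 = model.mean_cell_footprint_um2 / UM2_PER_CM2
    density = pcc / footprint_cm2
    raw = pcc if raw_confluency is None else raw_confluency
    return DensityRecord(
        t_h=t_h,
        density_cells_cm2=float(density),
        cell_count=float(density * chamber_area_cm2),
        confluency=float(raw),
        pcc=float(pcc),
        qc_monolayer_warn=bool(raw > MONOLAYER_WARN_THRESHOLD),
    )


def density_series(
    confluencies: np.ndarray,
    times_h: np.ndarray,
    model: PackingModel,
    chamber_area_cm2: float,
) -> pd.DataFrame:
    """Vectorized confluency -> density table (t_h, confluency, pcc, density, count, qc)."""
    recs = []
    for t, c in zip(np.asarray(times_h, float), np.asarray(confluencies, float)):
        pcc = packing_corrected_confluency(c, model)
        recs.append(density_from_pcc(pcc, model, chamber_area_cm2, t_h=t, raw_confluency=c))
    return pd.DataFrame(
        {
            "t_h": [r.t_h for r in recs],
            "confluency": [r.confluency for r in recs],
            "pcc": [r.pcc for r in recs],
            "density_cells_cm2": [r.density_cells_cm2 for r in recs],
            "cell_count": [r.cell_count for r in recs],
            "qc_monolayer_warn": [r.qc_monolayer_warn for r in recs],
        }
    )


def calibrate_packing(
    fixture_confluencies,
    fixture_counts,
    fixture_area_cm2,
    n_knots: int = 5,
    identity_below: float = 0.30,
) -> PackingModel:
    """Fit footprint + packing curve from ground-truthed fixtures.

    Fixtures are (mask confluency, true cell count) pairs over a common
    imaged area.  The mean footprint is estimated in the identity regime
    (fixtures with confluency below ``identity_below``, where cells are
    isolated and the packing factor is 1); the packing curve then follows
    from pf(c) = footprint * count / (c * area), pooled into at most
    ``n_knots`` monotone piecewise-linear knots.  Deterministic for a fixed
    fixture set.

    Raises
    ------
    ValueError
        With fewer than 3 fixtures or a confluency span below 20%
        (extrapolation would be unsafe).
    """
    c = np.asarray(fixture_confluencies, dtype=float)
    n = np.asarray(fixture_counts, dtype=float)
    if c.size < 3:
        raise ValueError("calibration requires at least 3 fixtures")
    if c.max() - c.min() < 0.20:
        raise ValueError(
            f"fixtures span only {c.max() - c.min():.2f} confluency; "
            ">= 0.20 required for safe interpolation"
        )
    area_um2 = fixture_area_cm2 * UM2_PER_CM2

    low = c <= identity_below
    if not low.any():
        low = c <= np.quantile(c, 0.34)  # fall back to the sparsest third
    # pooled (count-weighted) footprint: total covered area over total cells
    footprint = float(np.sum(c[low] * area_um2) / np.sum(n[low]))

    pf_obs = footprint * n / (c * area_um2)
    order = np.argsort(c)
    c_sorted, pf_sorted = c[order], pf_obs[order]
    # isotonic pooling (PAVA) enforces monotonicity against fixture noise
    pf_iso = _pava(pf_sorted)
    pf_iso = np.maximum(pf_iso, 1.0)
    knot_x = np.linspace(c_sorted[0], c_sorted[-1], min(n_knots, len(c_sorted)))
    knot_y = np.interp(knot_x, c_sorted, pf_iso)
    knot_y = np.maximum.accumulate(np.maximum(knot_y, 1.0))
    knots = [(0.0, 1.0)] if knot_x[0] > 0 else []
    knots += list(zip(knot_x.tolist(), knot_y.tolist()))
    return PackingModel(
        mean_cell_footprint_um2=footprint,
        knots=tuple(knots),
        provenance=f"calibrated on {c.size} fixtures, confluency {c.min():.2f}-{c.max():.2f}",
    )


def _pava(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators for a non-decreasing fit (unit weights)."""
    y = np.asarray(y, dtype=float).copy()
    n = len(y)
    level = y.copy()
    weight = np.ones(n)
    blocks = [(i, i) for i in range(n)]
    values = list(level)
    wts = list(weight)
    i = 0
    while i < len(values) - 1:
        if values[i] > values[i + 1] + 1e-15:
            merged = (values[i] * wts[i] + values[i + 1] * wts[i + 1]) / (wts[i] + wts[i + 1])
            blocks[i] = (blocks[i][0], blocks[i + 1][1])
            values[i] = merged
            wts[i] = wts[i] + wts[i + 1]
            del blocks[i + 1], values[i + 1], wts[i + 1]
            if i > 0:
                i -= 1
        else:
            i += 1
    out = np.empty(n)
    for (a, b), v in zip(blocks, values):
        out[a : b + 1] = v
    return out
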