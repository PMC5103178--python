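"""File round-tripping: TIFF tiles, stage sheets, sensor CSVs, reports.

All tabular data is RFC-4180 CSV with a header row and SI units in the
column names; images are TIFF; models and reports are JSON; configuration
is YAML.  Every writer here has a paired reader with lossless field
recovery.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .segmentation import RegionGrid, TileImage


def write_tiles(out_dir, tiles, prefix: str = "tile") -> Path:
    """Write per-tile TIFFs plus the stage-position sheet.

    ``tiles`` is a list of dicts or :class:`TileImage` with pixel data and
    stage coordinates.  Returns the path of the stage sheet CSV
    (tile_id, x_um, y_um, t_h, filename).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, tile in enumerate(tiles):
        if isinstance(tile, TileImage):
            pixels, x, y, t = tile.pixels, tile.stage_x_um, tile.stage_y_um, tile.t_h
        else:
            pixels, x, y, t = tile["pixels"], tile["stage_x_um"], tile["stage_y_um"], tile["t_h"]
        fname = f"{prefix}_{i:04d}.tif"
        tifffile.imwrite(out_dir / fname, np.asarray(pixels, dtype=np.float32))
        rows.append({"tile_id": i, "x_um": x, "y_um": y, "t_h": t, "filename": fname})
    sheet = out_dir / f"{prefix}_stage_positions.csv"
    pd.DataFrame(rows).to_csv(sheet, index=False)
    return sheet


def read_tiles(stage_sheet) -> list[TileImage]:
    """Read tiles referenced by a stage-position sheet back into memory."""
    sheet_path = Path(stage_sheet)
    df = pd.read_csv(sheet_path)
    tiles = []
    for _, row in df.iterrows():
        pixels = tifffile.imread(sheet_path.parent / row["filename"])
        tiles.append(
            TileImage(
                pixels=pixels,
                stage_x_um=float(row["x_um"]),
                stage_y_um=float(row["y_um"]),
                t_h=float(row["t_h"]),
            )
        )
    return tiles


def write_mask(path, mask: np.ndarray) -> None:
    """Binary mask as 0/255 uint8 TIFF."""
    tifffile.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))


def read_mask(path) -> np.ndarray:
    return tifffile.imread(path) > 0


def write_do_csv(path, frame: pd.DataFrame) -> None:
    """Sensor trace CSV: time_h, channel, then phase_deg and/or conc_uM."""
    cols = [c for c in ("t_h", "channel", "phase_deg", "conc_uM") if c in frame.columns]
    frame[cols].to_csv(path, index=False)


def read_do_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "t_h" not in df or "channel" not in df:
        raise ValueError(f"{path}: sensor CSV needs t_h and channel columns")
    if "phase_deg" not in df and "conc_uM" not in df:
        raise ValueError(f"{path}: sensor CSV needs phase_deg or conc_uM")
    return df


def do_wide(df: pd.DataFrame, value: str = "conc_uM") -> pd.DataFrame:
    """Pivot a long sensor table to one column per channel."""
    wide = df.pivot_table(index="t_h", columns="channel", values=value).reset_index()
    wide.columns.name = None
    return wide


def write_grid(path, grid: RegionGrid) -> None:
    with open(path, "w") as fh:
        json.dump({"schema": "sourmon.region_grid.v1", **grid.to_dict()}, fh)


def read_grid(path) -> RegionGrid:
    with open(path) as fh:
        return RegionGrid.from_dict(json.load(fh))


def write_truth_csv(path, truth) -> None:
    pd.DataFrame(
        {
            "t_h": truth.times_h,
            "cell_count": truth.cell_count,
            "density_cells_cm2": truth.density,
            "confluency": truth.confluency,
            "packing_factor": truth.packing_factor,
            "sour_true_amol_cell_s": truth.sour_true,
        }
    ).to_csv(path, index=False)


def read_truth_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_report(path, report: dict) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
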