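"""Run configuration: schema-validated YAML, scenario presets, seeds.

A run configuration collects every tunable of the pipeline — culture and
sensor simulation parameters, tile geometry, region grid and deselection,
analysis thresholds, file paths and the master seed.  Unknown keys are
rejected so that typos fail loudly before any stage runs.  Presets encode
the three study scenarios: a CHO-like culture (no lag), an mESC-like
culture (72 h lag, clustered colonies) and a mitochondrial respiration
assay (oligomycin at 2.5 h, FCCP at 6 h, no net growth over the 9 h span).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace

import yaml

from .simulate import CultureSimConfig, RespiratoryProtocol, SensorSimConfig, TileGeometry


@dataclass(frozen=True)
class GridConfig:
    """Analysis-grid definition and data-driven deselection zones."""

    rows: int = 47
    cols: int = 15
    border: int = 0
    blocks: tuple = ()            # (row0, row1, col0, col1) half-open grid blocks
    indices: tuple = ()           # explicit region indices to discard


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and windows of the analysis stages."""

    mu_window_h: float = 10.0
    r2_threshold: float = 0.95
    plateau_density_threshold: float = 5e4   # cells/cm^2
    smooth_window: int = 5                   # samples (75 min at 15-min cadence)
    spike_k: float = 5.0
    min_shift_uM: float = 20.0
    min_slope_uM_per_h: float = 15.0
    monolayer_warn: float = 0.85


@dataclass
class RunConfig:
    """Top-level, schema-validated configuration of one pipeline run."""

    culture: CultureSimConfig = field(default_factory=CultureSimConfig)
    sensors: SensorSimConfig = field(default_factory=SensorSimConfig)
    geometry: TileGeometry = field(default_factory=TileGeometry)
    grid: GridConfig = field(default_factory=GridConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    protocol: RespiratoryProtocol | None = None
    duration_h: float = 40.0
    seed: int = 0
    preset: str = ""
    paths: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "culture": asdict(self.culture),
            "sensors": asdict(self.sensors),
            "geometry": asdict(self.geometry),
            "grid": asdict(self.grid),
            "analysis": asdict(self.analysis),
            "duration_h": self.duration_h,
            "seed": self.seed,
            "preset": self.preset,
            "paths": dict(self.paths),
        }
        if self.protocol is not None:
            d["protocol"] = {
                "segments": [list(s) for s in self.protocol.segments],
                "labels": list(self.protocol.labels),
            }
        # callables are not serializable; drop them (they are code-level hooks)
        if callable(d["culture"].get("true_sour_profile")):
            d["culture"]["true_sour_profile"] = None
        d["sensors"].pop("insitu_overgrowth_bias", None)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


_SECTION_TYPES = {
    "culture": CultureSimConfig,
    "sensors": SensorSimConfig,
    "geometry": TileGeometry,
    "grid": GridConfig,
    "analysis": AnalysisConfig,
}
_TOP_KEYS = set(_SECTION_TYPES) | {"protocol", "duration_h", "seed", "preset", "paths"}


def load_config(path=None, data: dict | None = None, preset: str = "", seed: int | None = None) -> RunConfig:
    """Build a :class:`RunConfig` from YAML and/or a preset, rejecting unknown keys."""
    if data is None:
        data = {}
        if path is not None:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")

    cfg = preset_config(preset or data.get("preset", ""))
    for name, cls in _SECTION_TYPES.items():
        if name in data and data[name] is not None:
            section = data[name]
            known = {f.name for f in fields(cls)}
            unknown = set(section) - known
            if unknown:
                raise ValueError(f"unknown keys in [{name}]: {sorted(unknown)}")
            coerced = {
                k: tuple(tuple(v) if isinstance(v, list) else v for v in val)
                if isinstance(val, list)
                else val
                for k, val in section.items()
            }
            setattr(cfg, name, replace(getattr(cfg, name), **coerced))
    if "protocol" in data and data["protocol"] is not None:
        p = data["protocol"]
        cfg.protocol = RespiratoryProtocol(
            segments=tuple(tuple(s) for s in p["segments"]),
            labels=tuple(p.get("labels", [f"segment{i}" for i in range(len(p["segments"]))])),
        )
    if "duration_h" in data:
        cfg.duration_h = float(data["duration_h"])
    if "seed" in data:
        cfg.seed = int(data["seed"])
    if seed is not None:
        cfg.seed = int(seed)
    if "paths" in data:
        cfg.paths = dict(data["paths"])
    return cfg


def preset_config(name: str = "") -> RunConfig:
    """Scenario presets encoding the study conditions.

    * ``cho_culture`` — seeding 3e4 cells/cm^2, no lag, µ_max 0.041 1/h,
      isolated cells, 40 h, constant true sOUR 20 amol/cell/s.
    * ``mesc_culture`` — seeding 5e4 cells/cm^2, 72 h lag, µ_max 0.035 1/h,
      clustered colonies, 144 h, constant true sOUR 10 amol/cell/s.
    * ``respiratory_assay`` — dense static-seeded culture (5e5 cells/cm^2,
      no growth), oligomycin x0.2 at 2.5 h, FCCP x3.0 at 6 h over 9 h.
    """
    if name in ("", "cho_culture"):
        return RunConfig(preset="cho_culture")
    if name == "mesc_culture":
        return RunConfig(
            culture=CultureSimConfig(
                seeding_density=5e4,
                lag_h=72.0,
                mu_max=0.035,
                saturation_confluency=0.9,
                cell_footprint_um2=(180.0, 40.0),
                colony_mode=True,
                true_sour_profile=10.0,
            ),
            duration_h=144.0,
            preset="mesc_culture",
        )
    if name == "respiratory_assay":
        return RunConfig(
            culture=CultureSimConfig(
                seeding_density=5e5,
                lag_h=0.0,
                mu_max=0.0,
                saturation_confluency=0.9,
                cell_footprint_um2=(180.0, 40.0),
                colony_mode=True,
                true_sour_profile=25.0,
            ),
            sensors=SensorSimConfig(bias_max_uM=60.0),
            protocol=RespiratoryProtocol(),
            duration_h=9.0,
            preset="respiratory_assay",
        )
    raise ValueError(f"unknown preset {name!r}; expected cho_culture|mesc_culture|respiratory_assay")
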