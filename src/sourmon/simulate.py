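"""Ground-truthed synthetic cultures: growth, phase-contrast-like tiles, DO traces.

This module generates every input the analysis consumes, with known ground
truth, so the whole pipeline is testable without any experimental data:

* a growth trajectory (lag → exponential → smooth saturation cap) for an
  adherent culture in a perfused chamber;
* stylized phase-contrast tiles (dark textured cell bodies with a bright
  halo rim on a noisy background) whose per-pixel labels are known exactly;
* inlet/outlet/in-situ dissolved-oxygen traces driven by the quasi-steady
  perfusion mass balance, with sensor lag, transport delay, Gaussian noise,
  simultaneous inlet+outlet spike artifacts and an in-situ overgrowth bias.

The mass balance is quasi-steady because the chamber residence time
(25 µL / 300 µL h^-1 = 5 min) is far below the growth timescale; the outlet
responds to uptake through a first-order sensor lag plus a pure transport
delay rather than a spatial transport model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from skimage.draw import ellipse as draw_ellipse
from skimage.morphology import dilation, disk

from .oxygen import DOCalibration, SENSOR_MAX_UM, concentration_to_phase

__all__ = [
    "CultureSimConfig",
    "SensorSimConfig",
    "RespiratoryProtocol",
    "GroundTruthCulture",
    "TileGeometry",
    "RenderedFrame",
    "RawDOTraces",
    "simulate_growth",
    "render_frame",
    "render_tiles",
    "simulate_do_series",
    "simulate_respiratory_assay",
    "phase_from_concentration",
    "default_sim_calibration",
]


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class CultureSimConfig:
    """Parameters of a simulated adherent culture.

    Defaults reflect a CHO-like perfusion culture: seeding at
    3e4 cells cm^-2, no lag, µ_max = 0.041 h^-1, flow 300 µL h^-1 through a
    ~25 µL chamber.  ``true_sour_profile`` maps time (h) to the true
    specific uptake rate in amol cell^-1 s^-1 (a constant may be given).
    """

    seeding_density: float = 3e4          # cells / cm^2
    lag_h: float = 0.0
    mu_max: float = 0.041                 # 1/h
    saturation_confluency: float = 0.85   # fraction in (0, 1]
    cell_footprint_um2: tuple[float, float] = (600.0, 90.0)  # mean, SD
    colony_mode: bool = False
    chamber_area_cm2: float = 0.8
    chamber_volume_uL: float = 25.0
    flow_rate_uL_h: float = 300.0
    true_sour_profile: float | Callable[[np.ndarray], np.ndarray] = 20.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        scalars = {
            "seeding_density": self.seeding_density,
            "lag_h": self.lag_h,
            "mu_max": self.mu_max,
            "saturation_confluency": self.saturation_confluency,
            "chamber_area_cm2": self.chamber_area_cm2,
            "chamber_volume_uL": self.chamber_volume_uL,
            "flow_rate_uL_h": self.flow_rate_uL_h,
        }
        for name, value in scalars.items():
            if not math.isfinite(value):
                raise ValueError(f"{name} must be finite, got {value!r}")
        if self.seeding_density <= 0:
            raise ValueError("seeding_density must be > 0")
        if self.mu_max < 0:
            raise ValueError("mu_max must be >= 0")
        if not (0.0 < self.saturation_confluency <= 1.0):
            raise ValueError("saturation_confluency must be in (0, 1]")
        if self.flow_rate_uL_h <= 0 or self.chamber_volume_uL <= 0:
            raise ValueError("flow rate and chamber volume must be > 0")
        if self.lag_h < 0:
            raise ValueError("lag_h must be >= 0")
        mean_fp, sd_fp = self.cell_footprint_um2
        if not (math.isfinite(mean_fp) and math.isfinite(sd_fp)) or mean_fp <= 0 or sd_fp < 0:
            raise ValueError("cell_footprint_um2 must be (positive mean, non-negative SD)")

    def sour_at(self, times_h: np.ndarray) -> np.ndarray:
        t = np.asarray(times_h, dtype=float)
        if callable(self.true_sour_profile):
            return np.asarray(self.true_sour_profile(t), dtype=float) * np.ones_like(t)
        return np.full_like(t, float(self.true_sour_profile))


@dataclass(frozen=True)
class SensorSimConfig:
    """Parameters of the simulated oxygen-sensing chain."""

    noise_sd_uM: float = 1.5
    spike_rate_per_h: float = 0.05
    spike_amplitude_uM: float = 25.0
    insitu_overgrowth_bias: Callable[[np.ndarray], np.ndarray] | None = None
    full_depletion_confluency: float = 0.8   # default linear-ramp bias endpoint
    bias_max_uM: float | None = None         # ramp ceiling; None = inlet setpoint
    sensor_lag_min: float = 3.0
    outlet_transport_delay_min: float = 5.0
    do_sample_interval_min: float = 15.0
    image_interval_min: float = 30.0
    inlet_setpoint_uM: float = 215.0

    def __post_init__(self) -> None:
        if self.noise_sd_uM < 0:
            raise ValueError("noise_sd_uM must be >= 0")
        if self.do_sample_interval_min <= 0 or self.image_interval_min <= 0:
            raise ValueError("sample intervals must be > 0")
        if not (0.0 <= self.inlet_setpoint_uM <= SENSOR_MAX_UM):
            raise ValueError(
                f"inlet_setpoint_uM must lie within the sensor range [0, {SENSOR_MAX_UM:.2f}] µM"
            )

    def bias_at(self, confluency: np.ndarray) -> np.ndarray:
        """In-situ depletion bias (µM) caused by cells overgrowing the sensor.

        Default: linear ramp from 0 at confluency 0 to full depletion of the
        inlet setpoint at ``full_depletion_confluency``.
        """
        c = np.asarray(confluency, dtype=float)
        if self.insitu_overgrowth_bias is not None:
            return np.asarray(self.insitu_overgrowth_bias(c), dtype=float)
        ceiling = self.inlet_setpoint_uM if self.bias_max_uM is None else self.bias_max_uM
        return ceiling * np.clip(c / self.full_depletion_confluency, 0.0, 1.0)


@dataclass(frozen=True)
class RespiratoryProtocol:
    """Medium-switch schedule for a respiration assay.

    ``segments`` is an ordered list of ``(start_h, sour_multiplier)``; each
    segment runs until the next start.  The default mirrors the standard
    mitochondrial assay: basal medium, ATP-synthase inhibition (oligomycin,
    uptake falls) at 2.5 h, then uncoupling (FCCP, uptake rises) at 6.0 h.
    """

    segments: tuple[tuple[float, float], ...] = ((0.0, 1.0), (2.5, 0.2), (6.0, 3.0))
    labels: tuple[str, ...] = ("basal", "oligomycin", "FCCP")

    def __post_init__(self) -> None:
        starts = [s for s, _ in self.segments]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("segment start times must be strictly increasing")
        if any(m <= 0 for _, m in self.segments):
            raise ValueError("sour multipliers must be > 0")
        if len(self.labels) != len(self.segments):
            raise ValueError("one label per segment required")

    def multiplier_at(self, times_h: np.ndarray) -> np.ndarray:
        t = np.asarray(times_h, dtype=float)
        starts = np.array([s for s, _ in self.segments])
        mults = np.array([m for _, m in self.segments])
        idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(mults) - 1)
        return mults[idx]

    def switch_events(self):
        """True switch times with the expected direction of the uptake change."""
        events = []
        for (t0, m0), (t1, m1), label in zip(
            self.segments, self.segments[1:], self.labels[1:]
        ):
            direction = "uptake_decrease" if m1 < m0 else "uptake_increase"
            events.append({"t_h": t1, "direction": direction, "label": label})
        return events


@dataclass
class GroundTruthCulture:
    """Per-timepoint ground truth of a simulated culture (the recovery oracle)."""

    times_h: np.ndarray
    cell_count: np.ndarray
    density: np.ndarray          # cells / cm^2
    confluency: np.ndarray       # fraction of area covered
    packing_factor: np.ndarray   # >= 1
    sour_true: np.ndarray        # amol / cell / s
    config: CultureSimConfig

    def interp_count(self, t_h: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(t_h, dtype=float), self.times_h, self.cell_count)

    def interp_confluency(self, t_h: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(t_h, dtype=float), self.times_h, self.confluency)

    def interp_sour(self, t_h: np.ndarray) -> np.ndarray:
        t = np.asarray(t_h, dtype=float)
        if callable(self.config.true_sour_profile):
            return self.config.sour_at(t)
        return np.interp(t, self.times_h, self.sour_true)


# ---------------------------------------------------------------------------
# growth


# Nominal monotone packing curves (confluency -> packing factor >= 1) used by
# the analytic truth; the renderer's realized packing is emergent and close.
_PACKING_KNOTS_ISOLATED = ((0.0, 1.0), (0.30, 1.0), (0.60, 1.10), (0.80, 1.25), (1.0, 1.45))
_PACKING_KNOTS_COLONY = ((0.0, 1.02), (0.30, 1.10), (0.60, 1.25), (0.80, 1.40), (1.0, 1.60))


def nominal_packing_factor(confluency, colony_mode: bool = False):
    knots = _PACKING_KNOTS_COLONY if colony_mode else _PACKING_KNOTS_ISOLATED
    xs = np.array([k[0] for k in knots])
    ys = np.array([k[1] for k in knots])
    return np.interp(np.asarray(confluency, dtype=float), xs, ys)


def _confluency_from_coverage(coverage, colony_mode: bool):
    """Solve c * pf(c) = coverage for c (pf monotone => unique root)."""
    cov = np.atleast_1d(np.asarray(coverage, dtype=float))
    out = np.empty_like(cov)
    for i, v in enumerate(cov):
        lo, hi = 0.0, 1.0
        if v <= 0:
            out[i] = 0.0
            continue
        if v >= 1.0 * nominal_packing_factor(1.0, colony_mode):
            out[i] = 1.0
            continue
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if mid * nominal_packing_factor(mid, colony_mode) < v:
                lo = mid
            else:
                hi = mid
        out[i] = 0.5 * (lo + hi)
    return out if np.ndim(coverage) else float(out[0])


def _softmin(a: np.ndarray, b: float, width: float) -> np.ndarray:
    """Smooth elementwise min with transition width ``width`` (same units)."""
    m = np.minimum(a, b)
    return m - width * np.log1p(np.exp(-np.abs(a - b) / width))


def simulate_growth(config: CultureSimConfig, times_h: Sequence[float]) -> GroundTruthCulture:
    """Ground-truth growth trajectory: lag, exponential, smooth saturation cap.

    Density stays at the seeding value for t <= lag_h, then grows
    exponentially at µ_max, smoothly capped so that confluency never exceeds
    ``saturation_confluency``.  Confluency follows from density through the
    mean cell footprint and the nominal packing curve
    (confluency * packing_factor = density * footprint).
    """
    t = np.asarray(times_h, dtype=float)
    if t.ndim != 1 or len(t) == 0:
        raise ValueError("times must be a non-empty 1-D sequence")
    if np.any(np.diff(t) < 0) or np.any(t < 0):
        raise ValueError("times must be sorted and non-negative")

    mean_fp_cm2 = config.cell_footprint_um2[0] * 1e-8
    te = np.maximum(t - config.lag_h, 0.0)
    x_exp = config.seeding_density * np.exp(config.mu_max * te)

    c_sat = config.saturation_confluency
    k_density = c_sat * nominal_packing_factor(c_sat, config.colony_mode) / mean_fp_cm2
    if k_density > config.seeding_density:
        density = _softmin(x_exp, k_density, width=0.05 * k_density)
        # keep the lag/seeding identity exact when far from saturation
        density = np.maximum(density, np.minimum(x_exp, config.seeding_density))
    else:
        density = np.full_like(x_exp, config.seeding_density)

    coverage = density * mean_fp_cm2
    confluency = _confluency_from_coverage(coverage, config.colony_mode)
    confluency = np.clip(confluency, 0.0, 1.0)
    packing = nominal_packing_factor(confluency, config.colony_mode)

    return GroundTruthCulture(
        times_h=t,
        cell_count=density * config.chamber_area_cm2,
        density=density,
        confluency=confluency,
        packing_factor=packing,
        sour_true=config.sour_at(t),
        config=config,
    )


# ---------------------------------------------------------------------------
# rendering


@dataclass(frozen=True)
class TileGeometry:
    """Tiling of the chamber image by the motorized stage."""

    tile_h: int = 192
    tile_w: int = 192
    n_rows: int = 2
    n_cols: int = 2
    overlap_frac: float = 0.10
    um_per_px: float = 1.0
    stage_y_flip: bool = False

    @property
    def step_h(self) -> int:
        return int(round(self.tile_h * (1.0 - self.overlap_frac)))

    @property
    def step_w(self) -> int:
        return int(round(self.tile_w * (1.0 - self.overlap_frac)))

    @property
    def canvas_shape(self) -> tuple[int, int]:
        return (
            self.tile_h + (self.n_rows - 1) * self.step_h,
            self.tile_w + (self.n_cols - 1) * self.step_w,
        )


@dataclass
class RenderedFrame:
    """One rendered timepoint: tiles + exact ground truth."""

    tiles: list          # list of TileImage-compatible dicts (pixels, stage_x_um, stage_y_um, t_h)
    mask: np.ndarray     # ground-truth cell-body mask on the full canvas (bool)
    image: np.ndarray    # full stitched-canvas rendering (float in [0,1])
    t_h: float
    realized_count: int
    realized_confluency: float
    realized_packing: float
    mean_cell_area_px: float
    geometry: TileGeometry


#: Hard ceiling on achievable rendered confluency (halo/packing geometry).
MAX_RENDER_CONFLUENCY = 0.92


def _sample_ellipse(rng, mean_area_px, sd_area_px):
    area = rng.normal(mean_area_px, sd_area_px)
    area = float(np.clip(area, 0.3 * mean_area_px, 2.5 * mean_area_px))
    aspect = rng.uniform(0.55, 0.95)
    a = math.sqrt(area / (math.pi * aspect))   # semi-major
    b = a * aspect
    theta = rng.uniform(0.0, math.pi)
    return a, b, theta, area


def _paint_cells(
    rng: np.random.Generator,
    shape: tuple[int, int],
    target_confluency: float,
    mean_area_px: float,
    sd_area_px: float,
    colony_mode: bool,
) -> tuple[np.ndarray, int, float, float]:
    """Place ellipses until the union covers ``target_confluency`` of the canvas.

    Isolated mode first attempts strictly non-overlapping placement and only
    falls back to minimal-overlap placement once the canvas jams; colony mode
    preferentially places new cells adjacent to existing ones.  Returns the
    boolean union mask, the number of cells placed, the summed single-cell
    area (px) and the realized union fraction.
    """
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    n_px = h * w
    total_cell_area = 0.0
    centers: list[tuple[float, float]] = []
    count = 0
    frac = 0.0
    mean_r = math.sqrt(mean_area_px / math.pi)
    max_cells = int(3 * target_confluency * n_px / mean_area_px) + 50

    while frac < target_confluency and count < max_cells:
        a, b, theta, _ = _sample_ellipse(rng, mean_area_px, sd_area_px)

        def _candidate():
            if colony_mode and centers and rng.uniform() < 0.7:
                cy, cx = centers[rng.integers(len(centers))]
                d = 2.0 * mean_r * rng.uniform(0.8, 1.3)
                ang = rng.uniform(0, 2 * math.pi)
                return cy + d * math.sin(ang), cx + d * math.cos(ang)
            return rng.uniform(0, h), rng.uniform(0, w)

        placed = None
        if not colony_mode:
            for _ in range(30):
                cy, cx = _candidate()
                rr, cc = draw_ellipse(cy, cx, a, b, shape=shape, rotation=theta)
                if rr.size and not mask[rr, cc].any():
                    placed = (rr, cc)
                    break
        if placed is None:
            # greedy fallback; colony mode aims for a contact-overlap fraction
            target_ov = 0.18 if colony_mode else 0.0
            best, best_gap = None, None
            for _ in range(8):
                cy, cx = _candidate()
                rr, cc = draw_ellipse(cy, cx, a, b, shape=shape, rotation=theta)
                if not rr.size:
                    continue
                ov = mask[rr, cc].sum() / rr.size
                gap = abs(ov - target_ov)
                if best is None or gap < best_gap:
                    best, best_gap = (rr, cc, cy, cx), gap
            if best is None:
                continue
            rr, cc, cy, cx = best
            placed = (rr, cc)
        else:
            # recover the center used for the accepted non-overlap placement
            cy, cx = float(np.mean(placed[0])), float(np.mean(placed[1]))

        rr, cc = placed
        new_px = int((~mask[rr, cc]).sum())
        new_frac = frac + new_px / n_px
        # accept only if it brings coverage closer to the target
        if abs(new_frac - target_confluency) > abs(frac - target_confluency):
            break
        mask[rr, cc] = True
        centers.append((cy, cx))
        total_cell_area += rr.size
        count += 1
        frac = new_frac

    return mask, count, total_cell_area, frac


def _render_appearance(rng: np.random.Generator, mask: np.ndarray) -> np.ndarray:
    """Stylized phase-contrast appearance: dark textured body, bright halo rim."""
    h, w = mask.shape
    img = 0.55 + rng.normal(0.0, 0.035, size=(h, w))
    halo = dilation(mask, disk(2)) & ~mask
    img[mask] = 0.33 + rng.normal(0.0, 0.05, size=int(mask.sum()))
    img[halo] = 0.82 + rng.normal(0.0, 0.04, size=int(halo.sum()))
    # mild optical blur
    from scipy.ndimage import gaussian_filter

    img = gaussian_filter(img, 0.6)
    img += rng.normal(0.0, 0.01, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def render_frame(
    target_confluency: float,
    geometry: TileGeometry,
    config: CultureSimConfig,
    rng: np.random.Generator,
    t_h: float = 0.0,
) -> RenderedFrame:
    """Render one timepoint of the culture as stage tiles + ground-truth mask.

    The full chamber canvas is rendered once and tiles are cut from it at the
    stage positions, so overlapping strips of neighboring tiles carry
    identical cell content by construction.  The realized mask confluency is
    within 2% absolute of the request.
    """
    if not (0.0 <= target_confluency <= 1.0):
        raise ValueError("requested confluency must lie in [0, 1]")
    if target_confluency > MAX_RENDER_CONFLUENCY:
        raise ValueError(
            f"requested confluency {target_confluency:.2f} exceeds the maximum "
            f"achievable {MAX_RENDER_CONFLUENCY:.2f} for this cell geometry"
        )
    shape = geometry.canvas_shape
    mean_area_px = config.cell_footprint_um2[0] / geometry.um_per_px**2
    sd_area_px = config.cell_footprint_um2[1] / geometry.um_per_px**2

    mask, count, total_area, frac = _paint_cells(
        rng, shape, target_confluency, mean_area_px, sd_area_px, config.colony_mode
    )
    image = _render_appearance(rng, mask)

    tiles = []
    for r in range(geometry.n_rows):
        for c in range(geometry.n_cols):
            y0, x0 = r * geometry.step_h, c * geometry.step_w
            pix = image[y0 : y0 + geometry.tile_h, x0 : x0 + geometry.tile_w].copy()
            stage_y = y0 * geometry.um_per_px
            if geometry.stage_y_flip:
                stage_y = -stage_y
            tiles.append(
                {
                    "pixels": pix,
                    "stage_x_um": x0 * geometry.um_per_px,
                    "stage_y_um": stage_y,
                    "t_h": t_h,
                }
            )
    packing = (total_area / mask.sum()) if mask.any() else 1.0
    return RenderedFrame(
        tiles=tiles,
        mask=mask,
        image=image,
        t_h=t_h,
        realized_count=count,
        realized_confluency=float(frac),
        realized_packing=float(max(packing, 1.0)),
        mean_cell_area_px=float(total_area / count) if count else float("nan"),
        geometry=geometry,
    )


def render_tiles(
    truth: GroundTruthCulture,
    index: int,
    geometry: TileGeometry,
    rng: np.random.Generator,
) -> RenderedFrame:
    """Render the culture at ``truth.times_h[index]`` (see :func:`render_frame`)."""
    return render_frame(
        float(truth.confluency[index]), geometry, truth.config, rng, t_h=float(truth.times_h[index])
    )


# ---------------------------------------------------------------------------
# sensors


def default_sim_calibration(channel: str = "", c_air_uM: float = 200.0) -> DOCalibration:
    """Calibration used by the simulator to emit phase-domain traces."""
    return DOCalibration(phi0_deg=55.0, phi_air_deg=22.0, c_air_uM=c_air_uM, channel=channel)


def phase_from_concentration(conc_uM, cal: DOCalibration):
    """Phase (degrees) for a given concentration — exact inverse of the
    tan-form Stern–Volmer conversion used by the analysis."""
    return concentration_to_phase(conc_uM, cal)


@dataclass
class RawDOTraces:
    """Simulated raw sensor traces with their generating events."""

    t_h: np.ndarray
    inlet_uM: np.ndarray
    outlet_uM: np.ndarray
    insitu_uM: np.ndarray
    spike_times_h: np.ndarray
    spike_amplitudes_uM: np.ndarray
    clip_events: int
    x_at_t: np.ndarray
    sour_at_t: np.ndarray

    def to_frame(self, cal: DOCalibration | None = None):
        import pandas as pd

        rows = []
        for channel, conc in (
            ("inlet", self.inlet_uM),
            ("outlet", self.outlet_uM),
            ("insitu", self.insitu_uM),
        ):
            df = pd.DataFrame({"t_h": self.t_h, "channel": channel, "conc_uM": conc})
            if cal is not None:
                df["phase_deg"] = concentration_to_phase(np.clip(conc, 0, SENSOR_MAX_UM), cal)
            rows.append(df)
        return pd.concat(rows, ignore_index=True)


def _first_order_lag(u: np.ndarray, dt_h: float, tau_min: float) -> np.ndarray:
    if tau_min <= 0:
        return u.copy()
    alpha = 1.0 - math.exp(-dt_h * 60.0 / tau_min)
    y = np.empty_like(u)
    y[0] = u[0]
    for i in range(1, len(u)):
        y[i] = y[i - 1] + alpha * (u[i] - y[i - 1])
    return y


def _delta_uM(sour_amol, x_cells, q_uL_h) -> np.ndarray:
    """Inlet-outlet differential (µM) implied by uptake at flow Q."""
    q_L_s = q_uL_h * 1e-6 / 3600.0
    our_mol_s = np.asarray(sour_amol) * np.asarray(x_cells) * 1e-18
    return our_mol_s / q_L_s * 1e6


def simulate_do_series(
    truth: GroundTruthCulture,
    sensors: SensorSimConfig,
    rng: np.random.Generator,
    t_end_h: float | None = None,
) -> RawDOTraces:
    """Simulate inlet/outlet/in-situ DO traces for a culture trajectory.

    Quasi-steady mass balance: outlet = inlet − sOUR·X/Q (clipped at 0 µM),
    then a pure transport delay and first-order sensor lag are applied to the
    outlet; per-channel Gaussian noise is added; spike artifacts hit inlet
    AND outlet with the same amplitude at the same timestamp; the in-situ
    trace is the (undelayed) quasi-steady outlet minus the overgrowth bias,
    clipped at 0.
    """
    t_end = float(truth.times_h[-1]) if t_end_h is None else float(t_end_h)
    dt_h = sensors.do_sample_interval_min / 60.0
    t = np.arange(0.0, t_end + 1e-9, dt_h)

    cfg = truth.config
    x = truth.interp_count(t)
    sour = truth.interp_sour(t)
    conf = truth.interp_confluency(t)

    inlet_true = np.full_like(t, sensors.inlet_setpoint_uM)
    delta = _delta_uM(sour, x, cfg.flow_rate_uL_h)
    outlet_qs = inlet_true - delta
    clip_events = int(np.sum(outlet_qs < 0))
    outlet_qs = np.clip(outlet_qs, 0.0, None)

    # transport delay: outlet sensor sees the chamber state delay minutes ago
    delay_h = sensors.outlet_transport_delay_min / 60.0
    outlet_delayed = np.interp(np.clip(t - delay_h, 0.0, None), t, outlet_qs)
    outlet_sens = _first_order_lag(outlet_delayed, dt_h, sensors.sensor_lag_min)
    inlet_sens = _first_order_lag(inlet_true, dt_h, sensors.sensor_lag_min)

    insitu_qs = np.clip(outlet_qs - sensors.bias_at(conf), 0.0, None)
    insitu_sens = _first_order_lag(insitu_qs, dt_h, sensors.sensor_lag_min)

    noise_rng, spike_rng = rng.spawn(2)
    if sensors.noise_sd_uM > 0:
        inlet_sens = inlet_sens + noise_rng.normal(0, sensors.noise_sd_uM, t.shape)
        outlet_sens = outlet_sens + noise_rng.normal(0, sensors.noise_sd_uM, t.shape)
        insitu_sens = insitu_sens + noise_rng.normal(0, sensors.noise_sd_uM, t.shape)
    else:
        inlet_sens, outlet_sens, insitu_sens = (
            inlet_sens.copy(),
            outlet_sens.copy(),
            insitu_sens.copy(),
        )

    n_spikes = spike_rng.poisson(sensors.spike_rate_per_h * t_end) if t_end > 0 else 0
    if n_spikes > 0:
        idx = np.sort(spike_rng.choice(len(t), size=min(n_spikes, len(t)), replace=False))
        amps = sensors.spike_amplitude_uM * spike_rng.choice([-1.0, 1.0], size=len(idx))
        inlet_sens[idx] += amps
        outlet_sens[idx] += amps
        spike_times, spike_amps = t[idx], amps
    else:
        spike_times, spike_amps = np.array([]), np.array([])

    insitu_sens = np.clip(insitu_sens, 0.0, None)
    return RawDOTraces(
        t_h=t,
        inlet_uM=inlet_sens,
        outlet_uM=outlet_sens,
        insitu_uM=insitu_sens,
        spike_times_h=spike_times,
        spike_amplitudes_uM=spike_amps,
        clip_events=clip_events,
        x_at_t=x,
        sour_at_t=sour,
    )


def simulate_respiratory_assay(
    protocol: RespiratoryProtocol,
    config: CultureSimConfig,
    sensors: SensorSimConfig,
    rng: np.random.Generator,
    t_end_h: float = 9.0,
):
    """Simulate a respiration assay: the true sOUR profile is multiplied per
    protocol segment and fed through :func:`simulate_do_series`.

    Returns ``(traces, events)`` where ``events`` is the list of true switch
    times with their expected uptake direction.
    """
    if protocol.segments[-1][0] >= t_end_h:
        raise ValueError("protocol segments must start within the simulated span")

    base_profile = config.true_sour_profile

    def modulated(t):
        t = np.asarray(t, dtype=float)
        if callable(base_profile):
            base = np.asarray(base_profile(t), dtype=float)
        else:
            base = np.full_like(t, float(base_profile))
        return base * protocol.multiplier_at(t)

    cfg = replace(config, true_sour_profile=modulated)
    dt_h = sensors.do_sample_interval_min / 60.0
    times = np.arange(0.0, t_end_h + 1e-9, dt_h)
    truth = simulate_growth(cfg, times)
    traces = simulate_do_series(truth, sensors, rng, t_end_h=t_end_h)
    return traces, protocol.switch_events()
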