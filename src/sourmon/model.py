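"""Model/Results interface tying the pipeline together.

:class:`PerfusedCultureModel` holds the observations of one perfused-culture
run — time-lapse images of the chamber and the three-channel dissolved-
oxygen record — together with a :class:`~sourmon.config.RunConfig`.  Its
:meth:`~PerfusedCultureModel.fit` executes the analysis chain

    segment -> confluency -> packing-corrected density -> despike ->
    mass-balance sOUR -> growth kinetics -> plateau sOUR -> events

and returns a :class:`PerfusedCultureResults` carrying the estimates
(µ_max, doubling time, lag, plateau sOUR), their replicate spread where
available, the full intermediate tables, QC diagnostics and a ``summary()``
report.  ``from_simulation`` builds a model from the synthetic-culture
generator with ground truth attached, which is how the pipeline is
validated end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kinetics as kin
from .config import RunConfig
from .density import PackingModel, calibrate_packing, density_series, region_confluency
from .kinetics import GrowthKinetics, RespiratoryEvent, attach_latencies, detect_events, sour_vs_density
from .oxygen import despike, sour_series
from .segmentation import (
    RegionGrid,
    StitchCalibration,
    TrainedPixelClassifier,
    build_grid,
    deselect_regions,
    segment,
    stitch,
    train_classifier,
)
from .simulate import (
    GroundTruthCulture,
    RawDOTraces,
    render_frame,
    simulate_do_series,
    simulate_growth,
    simulate_respiratory_assay,
)


@dataclass
class SimulatedRun:
    """A complete synthetic run: images, ground truth and sensor traces."""

    config: RunConfig
    times_img_h: np.ndarray
    images: list
    gt_masks: list
    gt_counts: np.ndarray              # realized cell counts on the imaged canvas
    gt_confluency: np.ndarray          # realized mask confluencies
    truth: GroundTruthCulture          # analytic trajectory (chamber scale)
    truth_realized: GroundTruthCulture # trajectory rescaled to realized counts
    traces: RawDOTraces
    canvas_area_cm2: float
    tiles_by_frame: list = field(default_factory=list)


def simulate_run(config: RunConfig, render_images: bool = True, keep_tiles: bool = False) -> SimulatedRun:
    """Generate a fully ground-truthed synthetic run from a configuration.

    Images are rendered at the imaging cadence; the DO traces are driven by
    the *realized* rendered cell counts (converted to chamber scale), so the
    image record and the oxygen record describe the same culture.  All
    randomness flows from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    rng_frames, rng_sensors = rng.spawn(2)

    dt_img = config.sensors.image_interval_min / 60.0
    times_img = np.arange(0.0, config.duration_h + 1e-9, dt_img)
    if config.protocol is not None:
        traces, _ = simulate_respiratory_assay(
            config.protocol, config.culture, config.sensors, rng_sensors, t_end_h=config.duration_h
        )
        truth = simulate_growth(config.culture, times_img)
        return SimulatedRun(
            config=config,
            times_img_h=times_img,
            images=[],
            gt_masks=[],
            gt_counts=truth.cell_count.copy(),
            gt_confluency=truth.confluency.copy(),
            truth=truth,
            truth_realized=truth,
            traces=traces,
            canvas_area_cm2=float("nan"),
        )

    truth = simulate_growth(config.culture, times_img)
    geometry = config.geometry
    h, w = geometry.canvas_shape
    canvas_area_cm2 = h * w * geometry.um_per_px**2 * 1e-8

    images, masks, counts, confs, tiles_by_frame = [], [], [], [], []
    if render_images:
        for i, t in enumerate(times_img):
            frame = render_frame(
                float(truth.confluency[i]), geometry, config.culture, rng_frames, t_h=float(t)
            )
            images.append(frame.image)
            masks.append(frame.mask)
            counts.append(frame.realized_count)
            confs.append(frame.realized_confluency)
            if keep_tiles:
                tiles_by_frame.append(frame.tiles)
        counts = np.asarray(counts, dtype=float)
        confs = np.asarray(confs, dtype=float)
        realized_density = counts / canvas_area_cm2
        truth_realized = GroundTruthCulture(
            times_h=times_img,
            cell_count=realized_density * config.culture.chamber_area_cm2,
            density=realized_density,
            confluency=confs,
            packing_factor=truth.packing_factor,
            sour_true=truth.sour_true,
            config=config.culture,
        )
    else:
        counts = truth.cell_count.copy()
        confs = truth.confluency.copy()
        truth_realized = truth

    traces = simulate_do_series(truth_realized, config.sensors, rng_sensors, t_end_h=config.duration_h)
    return SimulatedRun(
        config=config,
        times_img_h=times_img,
        images=images,
        gt_masks=masks,
        gt_counts=np.asarray(counts, dtype=float),
        gt_confluency=np.asarray(confs, dtype=float),
        truth=truth,
        truth_realized=truth_realized,
        traces=traces,
        canvas_area_cm2=canvas_area_cm2,
        tiles_by_frame=tiles_by_frame,
    )


class PerfusedCultureModel:
    """Joint image + dissolved-oxygen model of one perfused culture run.

    Parameters
    ----------
    images
        Stitched chamber images, one per imaging timepoint (may be empty for
        sensor-only runs such as respiration assays).
    times_img_h
        Imaging timestamps, hours.
    do
        Wide DO table with columns ``t_h, inlet_uM, outlet_uM, insitu_uM``.
    config
        Full run configuration.
    gt_masks, gt_counts
        Optional ground-truth masks / canvas cell counts (synthetic runs);
        used to train the pixel classifier and calibrate the packing model
        when none are supplied to :meth:`fit`.
    """

    def __init__(
        self,
        images,
        times_img_h,
        do: pd.DataFrame,
        config: RunConfig,
        gt_masks=None,
        gt_counts=None,
        canvas_area_cm2: float | None = None,
        truth: GroundTruthCulture | None = None,
    ):
        self.images = list(images)
        self.times_img_h = np.asarray(times_img_h, dtype=float)
        self.do = do
        self.config = config
        self.gt_masks = list(gt_masks) if gt_masks is not None else None
        self.gt_counts = np.asarray(gt_counts, dtype=float) if gt_counts is not None else None
        self.canvas_area_cm2 = canvas_area_cm2
        self.truth = truth

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_simulation(cls, config: RunConfig, render_images: bool = True) -> "PerfusedCultureModel":
        run = simulate_run(config, render_images=render_images)
        do = pd.DataFrame(
            {
                "t_h": run.traces.t_h,
                "inlet_uM": run.traces.inlet_uM,
                "outlet_uM": run.traces.outlet_uM,
                "insitu_uM": run.traces.insitu_uM,
            }
        )
        model = cls(
            images=run.images,
            times_img_h=run.times_img_h,
            do=do,
            config=config,
            gt_masks=run.gt_masks or None,
            gt_counts=run.gt_counts if run.images else None,
            canvas_area_cm2=run.canvas_area_cm2,
            truth=run.truth_realized,
        )
        model._sim = run
        return model

    @classmethod
    def from_files(cls, stage_sheets, sensor_csv, config: RunConfig, calibration=None) -> "PerfusedCultureModel":
        """Build from per-timepoint stage sheets (TIFF tiles) and a sensor CSV."""
        from .io import do_wide, read_do_csv, read_tiles
        from .oxygen import phase_to_do

        cal = StitchCalibration(um_per_px=config.geometry.um_per_px, y_flip=config.geometry.stage_y_flip)
        images, times = [], []
        for sheet in stage_sheets:
            tiles = read_tiles(sheet)
            images.append(stitch(tiles, cal))
            times.append(tiles[0].t_h)
        order = np.argsort(times)
        images = [images[i] for i in order]
        times = [times[i] for i in order]

        df = read_do_csv(sensor_csv)
        if "conc_uM" not in df:
            if calibration is None:
                raise ValueError("phase-only sensor CSV requires a DOCalibration")
            conc, _ = phase_to_do(df["phase_deg"].to_numpy(), calibration)
            df = df.assign(conc_uM=conc)
        wide = do_wide(df)
        wide = wide.rename(columns={"inlet": "inlet_uM", "outlet": "outlet_uM", "insitu": "insitu_uM"})
        h, w = images[0].shape
        return cls(
            images=images,
            times_img_h=np.asarray(times),
            do=wide,
            config=config,
            canvas_area_cm2=h * w * config.geometry.um_per_px**2 * 1e-8,
        )

    # -- fitting ------------------------------------------------------------

    def _grid(self, shape) -> RegionGrid:
        g = build_grid(shape, self.config.grid.rows, self.config.grid.cols)
        gc = self.config.grid
        if gc.border or gc.blocks or gc.indices:
            g = deselect_regions(g, indices=gc.indices or None, border=gc.border, blocks=gc.blocks)
        return g

    def _train_classifier(self, seed: int) -> TrainedPixelClassifier:
        if self.gt_masks is None:
            raise ValueError("no classifier supplied and no labeled frames available")
        idx = sorted({0, len(self.images) // 2, len(self.images) - 1})
        return train_classifier(
            [self.images[i] for i in idx], [self.gt_masks[i] for i in idx], seed=seed
        )

    def _calibrate_packing(self) -> PackingModel:
        """Calibrate the packing model on a dedicated ground-truthed fixture sweep.

        A fresh sweep of rendered frames spanning sparse to packed
        confluency (deterministic in the run seed) gives an unbiased
        footprint/packing curve regardless of how much of the arc the run
        itself covers.  Real-data runs must supply a calibrated model.
        """
        if self.gt_masks is None:
            raise ValueError("no packing model supplied and no ground-truthed frames available")
        rng = np.random.default_rng((self.config.seed, 101))
        geometry = self.config.geometry
        area_cm2 = (
            np.prod(geometry.canvas_shape) * geometry.um_per_px**2 * 1e-8
        )
        confs, counts = [], []
        for target in np.linspace(0.05, 0.8, 9):
            fr = render_frame(float(target), geometry, self.config.culture, rng)
            confs.append(fr.realized_confluency)
            counts.append(fr.realized_count)
        return calibrate_packing(confs, counts, area_cm2)

    def fit(
        self,
        classifier: TrainedPixelClassifier | None = None,
        packing_model: PackingModel | None = None,
        use_ground_truth_masks: bool = False,
    ) -> "PerfusedCultureResults":
        """Run the full analysis chain and return the results object."""
        cfg = self.config
        diagnostics: dict = {}

        masks: list[np.ndarray] = []
        if self.images:
            if use_ground_truth_masks:
                if self.gt_masks is None:
                    raise ValueError("no ground-truth masks on this model")
                masks = [np.asarray(m, dtype=bool) for m in self.gt_masks]
                clf = None
            else:
                clf = classifier or self._train_classifier(seed=cfg.seed)
                diagnostics["classifier_holdout_accuracy"] = clf.holdout_accuracy
                masks = [segment(img, clf).mask for img in self.images]

            grid = self._grid(self.images[0].shape)
            diagnostics["regions_total"] = grid.n_regions
            diagnostics["regions_retained"] = grid.n_retained
            confl = np.array(
                [region_confluency(m, grid, t_h=t).culture_mean for m, t in zip(masks, self.times_img_h)]
            )
            pm = packing_model or self._calibrate_packing()
            dens = density_series(confl, self.times_img_h, pm, cfg.culture.chamber_area_cm2)
            diagnostics["monolayer_warn_frames"] = int(dens.qc_monolayer_warn.sum())
        else:
            grid = None
            pm = packing_model
            clf = None
            # sensor-only run (e.g. respiration assay): density from config truth
            if self.truth is not None:
                dens = pd.DataFrame(
                    {
                        "t_h": self.truth.times_h,
                        "confluency": self.truth.confluency,
                        "pcc": self.truth.confluency * self.truth.packing_factor,
                        "density_cells_cm2": self.truth.density,
                        "cell_count": self.truth.cell_count,
                        "qc_monolayer_warn": False,
                    }
                )
            else:
                raise ValueError("a run without images needs a truth/density table")

        sour = sour_series(
            self.do,
            dens,
            q_uL_h=cfg.culture.flow_rate_uL_h,
            chamber_area_cm2=cfg.culture.chamber_area_cm2,
            smooth_window=cfg.analysis.smooth_window,
            spike_k=cfg.analysis.spike_k,
        )
        diagnostics["spike_flagged"] = int(sour.spike_flag.sum())
        diagnostics["negative_flagged"] = int(sour.negative_flag.sum())

        growth = kin.windowed_mu(
            dens.t_h.to_numpy(),
            dens.density_cells_cm2.to_numpy(),
            window_h=cfg.analysis.mu_window_h,
            r2_threshold=cfg.analysis.r2_threshold,
        )

        usable = sour[~sour.negative_flag]
        if len(usable):
            binned, plateau = sour_vs_density(
                sour, plateau_density_threshold=cfg.analysis.plateau_density_threshold
            )
        else:
            binned, plateau = pd.DataFrame(), float("nan")

        insitu_df = pd.DataFrame({"t_h": self.do["t_h"], "conc_uM": self.do["insitu_uM"]})
        spikes = despike(self.do["inlet_uM"], self.do["outlet_uM"], k=cfg.analysis.spike_k)
        insitu_df["spike_flag"] = spikes
        events = detect_events(
            insitu_df,
            min_shift_uM=cfg.analysis.min_shift_uM,
            min_slope_uM_per_h=cfg.analysis.min_slope_uM_per_h,
        )
        if cfg.protocol is not None:
            events = attach_latencies(events, cfg.protocol.switch_events())

        return PerfusedCultureResults(
            model=self,
            growth=growth,
            density=dens,
            sour=sour,
            sour_binned=binned,
            plateau_sour=plateau,
            events=events,
            packing_model=pm,
            classifier=clf,
            grid=grid,
            diagnostics=diagnostics,
        )


@dataclass
class PerfusedCultureResults:
    """Estimates, uncertainties and diagnostics of a fitted culture run."""

    model: PerfusedCultureModel
    growth: GrowthKinetics
    density: pd.DataFrame
    sour: pd.DataFrame
    sour_binned: pd.DataFrame
    plateau_sour: float
    events: list[RespiratoryEvent]
    packing_model: PackingModel | None
    classifier: TrainedPixelClassifier | None
    grid: RegionGrid | None
    diagnostics: dict

    @property
    def mu_max(self) -> float:
        return self.growth.mu_max

    @property
    def doubling_time_h(self) -> float:
        return self.growth.g_h

    @property
    def lag_h(self) -> float:
        return self.growth.lag_h

    def plateau_spread(self) -> kin.SummaryStats | None:
        """Replicate-style spread (population sigma) of plateau sOUR samples."""
        sel = (~self.sour.negative_flag) & (
            self.sour.density_cells_cm2 > self.model.config.analysis.plateau_density_threshold
        )
        vals = self.sour.loc[sel, "sour_amol_cell_s"]
        if vals.empty:
            return None
        return kin.stddev(vals)

    def to_report(self) -> dict:
        spread = self.plateau_spread()
        return {
            "schema": "sourmon.report.v1",
            "preset": self.model.config.preset,
            "seed": self.model.config.seed,
            "mu_max_per_h": self.mu_max,
            "doubling_time_h": self.doubling_time_h,
            "lag_h": self.lag_h,
            "plateau_sour_amol_cell_s": self.plateau_sour,
            "plateau_sour_sigma": spread.sigma if spread else None,
            "plateau_sour_n": spread.n if spread else 0,
            "final_density_cells_cm2": float(self.density.density_cells_cm2.iloc[-1]),
            "final_confluency": float(self.density.confluency.iloc[-1]),
            "events": [
                {
                    "t_detect_h": e.t_detect_h,
                    "direction": e.direction,
                    "magnitude_uM": e.magnitude_uM,
                    "latency_min": e.latency_min,
                }
                for e in self.events
            ],
            "qc": self.diagnostics,
        }

    def summary(self) -> str:
        """Human-readable summary table of the fitted run."""
        rep = self.to_report()
        lines = [
            "Perfused culture analysis",
            "=" * 54,
            f"{'preset':30s} {rep['preset'] or '-'}",
            f"{'imaging frames':30s} {len(self.model.images)}",
            f"{'DO samples':30s} {len(self.model.do)}",
            f"{'regions retained/total':30s} "
            f"{self.diagnostics.get('regions_retained', '-')}/{self.diagnostics.get('regions_total', '-')}",
            "-" * 54,
            f"{'mu_max [1/h]':30s} {rep['mu_max_per_h']:.4f}",
            f"{'doubling time g [h]':30s} {rep['doubling_time_h']:.2f}",
            f"{'lag [h]':30s} {rep['lag_h']:.2f}",
            f"{'plateau sOUR [amol/cell/s]':30s} {rep['plateau_sour_amol_cell_s']:.2f}"
            + (
                f"  (sigma {rep['plateau_sour_sigma']:.2f}, n {rep['plateau_sour_n']})"
                if rep["plateau_sour_sigma"] is not None
                else ""
            ),
            f"{'final density [cells/cm^2]':30s} {rep['final_density_cells_cm2']:.3g}",
            f"{'final confluency':30s} {rep['final_confluency']:.3f}",
            f"{'negative-flagged sOUR points':30s} {self.diagnostics.get('negative_flagged', 0)}",
            f"{'common-mode spikes flagged':30s} {self.diagnostics.get('spike_flagged', 0)}",
            "-" * 54,
        ]
        if self.events:
            lines.append("respiratory events:")
            for e in self.events:
                lat = f", latency {e.latency_min:.0f} min" if e.latency_min is not None else ""
                lines.append(
                    f"  t={e.t_detect_h:5.2f} h  {e.direction:16s} shift {e.magnitude_uM:6.1f} uM{lat}"
                )
        else:
            lines.append("respiratory events: none detected")
        return "\n".join(lines)

    # -- plotting -----------------------------------------------------------

    def plot_growth(self, ax=None):
        from .plotting import plot_growth

        return plot_growth(self, ax=ax)

    def plot_do(self, ax=None):
        from .plotting import plot_do

        return plot_do(self, ax=ax)

    def plot_sour_vs_density(self, ax=None):
        from .plotting import plot_sour_vs_density

        return plot_sour_vs_density(self, ax=ax)
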