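"""Optical dissolved-oxygen sensing and oxygen-uptake computation.

Phase-fluorimetric oxygen sensors report a luminescence phase shift that
decreases monotonically with oxygen concentration (dynamic quenching).  A
two-point calibration — a zero-oxygen (sulfite) point and an air-saturated
point — anchors a Stern–Volmer relation in tan-phase form,

    tan(phi0) / tan(phi) = 1 + Ksv * C,

from which concentration follows analytically.  Oxygen uptake of a perfused
culture is obtained from the inlet/outlet differential at flow rate Q,

    OUR  = Q * (O2_in - O2_out)          [mol / s]
    sOUR = OUR / X                       [amol / cell / s]

where X is the number of cells in the chamber.  The in-situ (chamber-floor)
channel is calibrated and cleaned identically but never enters the mass
balance: cell overgrowth on the sensor makes it unrepresentative of bulk
levels, so it feeds qualitative event detection only.

Unit conventions, fixed package-wide: concentrations in µM, flow rate in
µL/h at the interface (L/s internally), sOUR in amol cell^-1 s^-1;
1 mg/L O2 = 31.25 µM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Conversion factor for dissolved oxygen, µM per (mg/L).
UM_PER_MG_L = 31.25

#: Upper end of the sensor detection range (45 mg/L).
SENSOR_MAX_UM = 45.0 * UM_PER_MG_L

#: Duration of the stability window required for calibration points, minutes.
STABILITY_WINDOW_MIN = 3.0

#: Maximum allowed phase excursion (max - min) within the stability window,
#: degrees.  Corresponds to ±0.05° about the window midpoint.
STABILITY_BAND_DEG = 0.10

AMOL_PER_MOL = 1e18


@dataclass(frozen=True)
class DOCalibration:
    """Two-point Stern–Volmer calibration for one optical oxygen channel.

    Parameters
    ----------
    phi0_deg
        Luminescence phase at zero oxygen, degrees.  Must exceed
        ``phi_air_deg`` (quenching lowers the phase).
    phi_air_deg
        Phase at air saturation, degrees.
    c_air_uM
        Dissolved-oxygen concentration at air saturation, µM.
    channel
        Identifier of the calibrated channel (``inlet``/``outlet``/``insitu``).
    """

    phi0_deg: float
    phi_air_deg: float
    c_air_uM: float
    channel: str = ""
    calibrated_at: tuple[float, float] | None = None
    ksv: float = field(init=False)

    def __post_init__(self) -> None:
        if not (0.0 < self.phi_air_deg < self.phi0_deg < 90.0):
            raise ValueError(
                "non-physical calibration: require 0 < phi_air < phi0 < 90 deg, "
                f"got phi0={self.phi0_deg}, phi_air={self.phi_air_deg}"
            )
        if self.c_air_uM <= 0:
            raise ValueError("c_air_uM must be positive")
        ksv = (
            math.tan(math.radians(self.phi0_deg))
            / math.tan(math.radians(self.phi_air_deg))
            - 1.0
        ) / self.c_air_uM
        object.__setattr__(self, "ksv", ksv)

    def to_dict(self) -> dict:
        return {
            "phi0_deg": self.phi0_deg,
            "phi_air_deg": self.phi_air_deg,
            "c_air_uM": self.c_air_uM,
            "channel": self.channel,
            "ksv_per_uM": self.ksv,
        }


def check_stability(phase_deg: np.ndarray, times_min: np.ndarray) -> bool:
    """Apply the calibration-point stability rule to a phase stream.

    A calibration point may be recorded only once phase variations stay
    within ±0.05° over a trailing 3-minute window, i.e. the max-min spread
    of the trailing window must not exceed 0.1°.

    Parameters
    ----------
    phase_deg, times_min
        Phase samples and their timestamps (minutes, ascending).

    Returns
    -------
    bool
        True if the trailing 3-minute window satisfies the rule.

    Raises
    ------
    ValueError
        If the stream spans less than 3 minutes.
    """
    phase_deg = np.asarray(phase_deg, dtype=float)
    times_min = np.asarray(times_min, dtype=float)
    if phase_deg.shape != times_min.shape or phase_deg.ndim != 1:
        raise ValueError("phase and time arrays must be 1-D and congruent")
    span = times_min[-1] - times_min[0]
    if span < STABILITY_WINDOW_MIN:
        raise ValueError(
            f"stability window requires >= {STABILITY_WINDOW_MIN} min of data, got {span:.2f} min"
        )
    in_window = times_min >= times_min[-1] - STABILITY_WINDOW_MIN
    window = phase_deg[in_window]
    return float(window.max() - window.min()) <= STABILITY_BAND_DEG + 1e-12


def two_point_calibrate(
    phi0_stream: tuple[np.ndarray, np.ndarray],
    phi_air_stream: tuple[np.ndarray, np.ndarray],
    c_air_uM: float,
    channel: str = "",
) -> DOCalibration:
    """Build a :class:`DOCalibration` from zero-oxygen and air-saturated streams.

    Each stream is a ``(phase_deg, times_min)`` pair and must pass
    :func:`check_stability`; the calibration phase is the mean over the
    trailing stability window.
    """
    for name, (phase, times) in (
        ("zero-oxygen", phi0_stream),
        ("air-saturated", phi_air_stream),
    ):
        if not check_stability(phase, times):
            raise ValueError(f"{name} stream is not stable (±0.05° over 3 min)")

    def _window_mean(phase, times):
        phase = np.asarray(phase, dtype=float)
        times = np.asarray(times, dtype=float)
        sel = times >= times[-1] - STABILITY_WINDOW_MIN
        return float(phase[sel].mean())

    phi0 = _window_mean(*phi0_stream)
    phi_air = _window_mean(*phi_air_stream)
    if phi_air >= phi0:
        raise ValueError(
            f"air-saturated phase ({phi_air:.3f}°) must be below zero-oxygen "
            f"phase ({phi0:.3f}°)"
        )
    return DOCalibration(
        phi0_deg=phi0, phi_air_deg=phi_air, c_air_uM=c_air_uM, channel=channel
    )


def phase_to_do(phase_deg, cal: DOCalibration):
    """Convert phase readings (degrees) to dissolved oxygen (µM).

    Inverts the tan-form Stern–Volmer relation.  Output is clipped to the
    sensor range [0, 1406.25 µM]; non-finite input phases yield NaN rather
    than raising.

    Returns
    -------
    conc_uM : ndarray or float
    flags : ndarray of str, same shape ("" | "clipped" | "invalid")
    """
    phase = np.asarray(phase_deg, dtype=float)
    scalar = phase.ndim == 0
    phase = np.atleast_1d(phase)
    conc = np.full(phase.shape, np.nan)
    flags = np.full(phase.shape, "", dtype=object)
    valid = np.isfinite(phase) & (phase > 0.0) & (phase < 90.0)
    flags[~valid] = "invalid"
    tan0 = math.tan(math.radians(cal.phi0_deg))
    raw = (tan0 / np.tan(np.radians(phase[valid])) - 1.0) / cal.ksv
    clipped = np.clip(raw, 0.0, SENSOR_MAX_UM)
    conc[valid] = clipped
    out_of_range = np.zeros(phase.shape, dtype=bool)
    out_of_range[valid] = (raw < 0.0) | (raw > SENSOR_MAX_UM)
    flags[out_of_range & valid] = "clipped"
    if scalar:
        return float(conc[0]), str(flags[0])
    return conc, flags


def concentration_to_phase(conc_uM, cal: DOCalibration):
    """Exact inverse of :func:`phase_to_do`: concentration (µM) to phase (degrees).

    Used by the sensor simulator to exercise the phase→µM path round-trip.

    Raises
    ------
    ValueError
        If any concentration is negative or above the sensor range.
    """
    conc = np.asarray(conc_uM, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentration must be >= 0")
    if np.any(conc > SENSOR_MAX_UM):
        raise ValueError(
            f"concentration above sensor range ({SENSOR_MAX_UM:.2f} µM)"
        )
    tan0 = math.tan(math.radians(cal.phi0_deg))
    phase = np.degrees(np.arctan(tan0 / (1.0 + cal.ksv * conc)))
    if np.ndim(conc_uM) == 0:
        return float(phase)
    return phase


def despike(
    inlet: pd.Series,
    outlet: pd.Series,
    k: float = 5.0,
    window: int = 7,
) -> np.ndarray:
    """Flag common-mode spikes on the inlet/outlet pair.

    Spikes of electrical or optical origin hit both flow-through sensors at
    the same timestamp, so they cancel in the differential; they are flagged
    (BOTH channels deviate from their rolling median by more than ``k`` times
    the channel's MAD at the same timestamp) so that downstream smoothing can
    skip them, but the raw differential is retained.

    Parameters
    ----------
    inlet, outlet
        Concentration series (µM) sharing an index of common timestamps.
    k
        MAD multiplier threshold.
    window
        Rolling-median window length, samples (odd).

    Returns
    -------
    ndarray of bool
        True where a common-mode spike was flagged.
    """
    if len(inlet) != len(outlet):
        raise ValueError("inlet and outlet must share timestamps")

    def _deviation(series: pd.Series) -> tuple[np.ndarray, float]:
        med = series.rolling(window, center=True, min_periods=1).median()
        resid = (series - med).to_numpy()
        mad = float(np.median(np.abs(resid - np.median(resid))))
        return np.abs(resid), mad

    dev_in, mad_in = _deviation(pd.Series(np.asarray(inlet, dtype=float)))
    dev_out, mad_out = _deviation(pd.Series(np.asarray(outlet, dtype=float)))
    # Floor the MAD so that a noise-free trace with a handful of spikes does
    # not divide by zero and flag everything.
    floor = 1e-9
    return (dev_in > k * max(mad_in, floor)) & (dev_out > k * max(mad_out, floor))


def compute_our(q_uL_h: float, inlet_uM, outlet_uM):
    """Bulk oxygen uptake rate from the perfusion mass balance, mol/s.

    OUR = Q[L/s] * (O2_in - O2_out)[mol/L].  Negative values (outlet above
    inlet, i.e. noise exceeding the true differential) are returned as-is;
    sign handling is the caller's concern.
    """
    if q_uL_h <= 0:
        raise ValueError("flow rate must be positive")
    q_L_s = q_uL_h * 1e-6 / 3600.0
    delta_mol_L = (np.asarray(inlet_uM, dtype=float) - np.asarray(outlet_uM, dtype=float)) * 1e-6
    out = q_L_s * delta_mol_L
    if np.ndim(inlet_uM) == 0 and np.ndim(outlet_uM) == 0:
        return float(out)
    return out


def compute_sour(our_mol_s, x_cells):
    """Specific oxygen uptake rate, amol cell^-1 s^-1, with negative flags.

    Negative values are physically meaningless (instrument noise larger than
    the inlet-outlet differential, typical of early cultures); they are kept
    in the data with ``negative_flag=True`` so they can be excluded from
    plots while staying auditable.

    Returns
    -------
    sour : float or ndarray
    negative_flag : bool or ndarray of bool
    """
    x = np.asarray(x_cells, dtype=float)
    if np.any(x <= 0):
        raise ValueError("cell count X must be positive")
    sour = np.asarray(our_mol_s, dtype=float) / x * AMOL_PER_MOL
    neg = sour < 0
    if np.ndim(our_mol_s) == 0 and np.ndim(x_cells) == 0:
        return float(sour), bool(neg)
    return sour, neg


def align_series(do: pd.DataFrame, density: pd.DataFrame) -> pd.DataFrame:
    """Join a DO table onto a density table by linear interpolation in time.

    DO is sampled every 15 min, images every 30 min; density is interpolated
    onto the DO timestamps.  No extrapolation: DO rows outside the imaging
    span are dropped.

    Parameters
    ----------
    do
        Must carry a ``t_h`` column.
    density
        Must carry ``t_h`` and ``density_cells_cm2`` (and optionally
        ``cell_count``, ``confluency``) columns.

    Returns
    -------
    DataFrame
        The DO rows within the imaging span with interpolated density columns
        appended.
    """
    t_do = do["t_h"].to_numpy(dtype=float)
    t_img = density["t_h"].to_numpy(dtype=float)
    if t_do.min() > t_img.max() or t_do.max() < t_img.min():
        raise ValueError("DO and density series have disjoint time spans")
    keep = (t_do >= t_img[0]) & (t_do <= t_img[-1])
    joined = do.loc[keep].reset_index(drop=True).copy()
    for col in density.columns:
        if col == "t_h":
            continue
        joined[col] = np.interp(
            joined["t_h"].to_numpy(dtype=float), t_img, density[col].to_numpy(dtype=float)
        )
    return joined


def sour_series(
    do: pd.DataFrame,
    density: pd.DataFrame,
    q_uL_h: float,
    chamber_area_cm2: float,
    smooth_window: int = 5,
    spike_k: float = 5.0,
) -> pd.DataFrame:
    """End-to-end sOUR time series from calibrated DO and a density series.

    Steps: common-mode despike of inlet/outlet; centered rolling median of
    the raw OUR over ``smooth_window`` samples (75 min at the default 15-min
    cadence), excluding spike-flagged samples; alignment of density onto the
    DO timestamps; division by cell number.

    Returns a table with columns ``t_h, inlet_uM, outlet_uM, our_mol_s,
    sour_amol_cell_s, X_at_t, spike_flag, negative_flag``.
    """
    spikes = despike(do["inlet_uM"], do["outlet_uM"], k=spike_k)
    do = do.copy()
    do["spike_flag"] = spikes
    joined = align_series(do, density)

    our_raw = compute_our(q_uL_h, joined["inlet_uM"].to_numpy(), joined["outlet_uM"].to_numpy())
    # Rolling median with spike-flagged samples masked out.
    our_masked = pd.Series(np.where(joined["spike_flag"], np.nan, our_raw))
    our_smooth = (
        our_masked.rolling(smooth_window, center=True, min_periods=1).median().to_numpy()
    )
    # If every sample in a window was flagged, fall back to the raw value.
    our_smooth = np.where(np.isnan(our_smooth), our_raw, our_smooth)

    if "cell_count" in joined:
        x = joined["cell_count"].to_numpy(dtype=float)
    else:
        x = joined["density_cells_cm2"].to_numpy(dtype=float) * chamber_area_cm2
    sour, neg = compute_sour(our_smooth, x)
    out = joined[["t_h", "inlet_uM", "outlet_uM", "spike_flag"]].copy()
    out["our_mol_s"] = our_smooth
    out["sour_amol_cell_s"] = sour
    out["X_at_t"] = x
    out["negative_flag"] = neg
    if "density_cells_cm2" in joined:
        out["density_cells_cm2"] = joined["density_cells_cm2"]
    return out
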