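"""Figures: growth curve, DO triptych, sOUR vs density."""

from __future__ import annotations

import importlib.resources

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def literature_sour_table() -> pd.DataFrame:
    """Published sOUR ranges for common cell lines (reference annotation only)."""
    ref = importlib.resources.files("sourmon.data") / "reference_sour_literature.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def plot_growth(results, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    d = results.density
    ax.semilogy(d.t_h, d.density_cells_cm2, "o-", ms=3, label="estimated density")
    if results.model.truth is not None:
        t = results.model.truth
        ax.semilogy(t.times_h, t.density, "k--", lw=1, label="ground truth")
    ax.set_xlabel("time [h]")
    ax.set_ylabel("cell density [cells cm$^{-2}$]")
    ax.legend(fontsize=8)
    ax.set_title(
        f"$\\mu_{{max}}$ = {results.mu_max:.3f} h$^{{-1}}$, g = {results.doubling_time_h:.1f} h"
    )
    return ax


def plot_do(results, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    do = results.model.do
    for col, label in (("inlet_uM", "inlet"), ("outlet_uM", "outlet"), ("insitu_uM", "in situ")):
        if col in do:
            ax.plot(do.t_h, do[col], lw=0.8, label=label)
    for ev in results.events:
        ax.axvline(ev.t_detect_h, color="r", ls=":", lw=0.8)
    ax.set_xlabel("time [h]")
    ax.set_ylabel("dissolved O$_2$ [µM]")
    ax.legend(fontsize=8)
    return ax


def plot_sour_vs_density(results, ax=None, annotate_literature: str | None = None):
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    s = results.sour[~results.sour.negative_flag]
    ax.semilogx(s.density_cells_cm2, s.sour_amol_cell_s, ".", ms=3, alpha=0.5)
    if not results.sour_binned.empty:
        b = results.sour_binned
        ax.semilogx(b.density_mid, b.sour_median, "s-", color="C1", label="binned median")
    ax.axhline(results.plateau_sour, color="C2", ls="--", lw=1, label="plateau estimate")
    if annotate_literature:
        lit = literature_sour_table()
        rows = lit[lit.cell_type.str.lower() == annotate_literature.lower()]
        for _, r in rows.iterrows():
            ax.axhspan(r.sour_lo_amol_cell_s, r.sour_hi_amol_cell_s, color="gray", alpha=0.08)
    ax.set_xlabel("cell density [cells cm$^{-2}$]")
    ax.set_ylabel("sOUR [amol cell$^{-1}$ s$^{-1}$]")
    ax.legend(fontsize=8)
    return ax
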