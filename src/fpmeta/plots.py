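"""Plotting: pooled curves with bands, study spaghetti, weight profiles."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .basis import contrast_matrix
from .errors import ValidationError
from .pool import PooledCurve, weight_profiles


def plot_curve(curve: PooledCurve, path=None, hr_axis: bool = True, ax=None):
    """Pooled log hazard-ratio curve with pointwise confidence band."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 4))
    else:
        fig = ax.figure
    ax.fill_between(curve.grid, curve.ci_low, curve.ci_high, alpha=0.25,
                    color="tab:blue", linewidth=0)
    ax.plot(curve.grid, curve.estimate, color="tab:blue",
            label=f"{curve.method} ({curve.model.upper()})")
    ax.axhline(0.0, color="0.6", linewidth=0.8)
    ax.axvline(curve.x0, color="0.6", linewidth=0.8, linestyle=":")
    ax.set_xlabel("exposure")
    ax.set_ylabel(f"log hazard ratio vs {curve.x0:g}")
    ax.legend(frameon=False)
    if hr_axis:
        safe_log = lambda y: np.log(np.maximum(np.asarray(y, dtype=float), 1e-300))
        twin = ax.secondary_yaxis("right", functions=(np.exp, safe_log))
        twin.set_ylabel("hazard ratio")
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_spaghetti(fits, grid, x0, path=None, eb_curves=None, ax=None):
    """Study-specific fitted contrasts, optionally with shrunken overlays."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 4))
    else:
        fig = ax.figure
    colors = plt.cm.tab20(np.linspace(0, 1, max(len(fits), 2)))
    for fit, color in zip(fits, colors):
        A = contrast_matrix(grid, x0, fit.spec)
        ax.plot(grid, A @ fit.beta, color=color, alpha=0.8, linewidth=1,
                label=fit.study_id if len(fits) <= 10 else None)
    if eb_curves is not None:
        for curve, color in zip(eb_curves, colors):
            ax.plot(curve.grid, curve.estimate, color=color, linewidth=1.8,
                    linestyle="--")
    ax.axvline(x0, color="0.6", linewidth=0.8, linestyle=":")
    ax.set_xlabel("exposure")
    ax.set_ylabel(f"log hazard ratio vs {x0:g}")
    if len(fits) <= 10:
        ax.legend(frameon=False, fontsize=7)
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_weights(curve: PooledCurve, path=None, ax=None):
    """Percentage weight of each study against exposure (metacurve only)."""
    table = weight_profiles(curve)   # raises for non-metacurve input
    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 4))
    else:
        fig = ax.figure
    for sid, row in table.iterrows():
        ax.plot(table.columns, row.values, linewidth=1,
                label=sid if table.shape[0] <= 10 else None)
    ax.set_xlabel("exposure")
    ax.set_ylabel("meta-analysis weight (%)")
    if table.shape[0] <= 10:
        ax.legend(frameon=False, fontsize=7)
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_outputs(bundle, outdir) -> list[Path]:
    """Write the standard figure set (SVG and PNG) for an analysis bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if bundle.curve is None:
        raise ValidationError("bundle has no pooled curve to plot")
    written = []
    for ext in ("svg", "png"):
        p = outdir / f"curve.{ext}"
        plot_curve(bundle.curve, p)
        written.append(p)
        if bundle.fits:
            p = outdir / f"study_curves.{ext}"
            plot_spaghetti(bundle.fits, bundle.curve.grid, bundle.curve.x0, p)
            written.append(p)
        if bundle.curve.method == "metacurve":
            p = outdir / f"weights.{ext}"
            plot_weights(bundle.curve, p)
            written.append(p)
    return written
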