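"""Figure rendering: stacked resistance fractions, density time courses, LD."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = ["render_figures", "stacked_fractions", "density_timecourse", "ld_panel"]

_CLASS_COLOURS = {"f_S": "white", "f_C": "#3b6fb5", "f_R": "#e08214", "f_D": "#b2182b"}
_FRACTION_TOL = 1e-6


def _check_fractions(df: pd.DataFrame) -> None:
    sums = df[["f_S", "f_R", "f_C", "f_D"]].sum(axis=1)
    if not np.allclose(sums, 1.0, atol=_FRACTION_TOL):
        raise DomainError("genotype fractions must sum to 1 in every row")


def stacked_fractions(results: pd.DataFrame, path) -> Path:
    """Stacked bars of genotype fractions per treatment and day."""
    required = {"treatment", "day", "f_S", "f_R", "f_C", "f_D"}
    if not required.issubset(results.columns):
        raise DomainError(f"results table missing columns: {sorted(required - set(results.columns))}")
    _check_fractions(results)
    treatments = list(dict.fromkeys(results["treatment"]))
    fig, axes = plt.subplots(1, len(treatments), figsize=(2.2 * len(treatments) + 1, 3),
                             sharey=True, squeeze=False)
    for ax, tr in zip(axes[0], treatments):
        sub = results[results["treatment"] == tr].sort_values("day")
        bottom = np.zeros(len(sub))
        for col in ("f_S", "f_C", "f_R", "f_D"):
            ax.bar(sub["day"].astype(str), sub[col], bottom=bottom,
                   color=_CLASS_COLOURS[col], edgecolor="black", linewidth=0.5,
                   label=col)
            bottom = bottom + sub[col].to_numpy()
        ax.set_title(str(tr), fontsize=8)
        ax.set_xlabel("day")
    axes[0][0].set_ylabel("fraction")
    axes[0][-1].legend(fontsize=7, loc="upper right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def density_timecourse(traj_frame: pd.DataFrame, path) -> Path:
    """Log-scale densities of hosts and phage over time."""
    required = {"t", "S", "R", "C", "D", "V"}
    if not required.issubset(traj_frame.columns):
        raise DomainError(f"trajectory table missing columns: {sorted(required - set(traj_frame.columns))}")
    fig, ax = plt.subplots(figsize=(6, 3.5))
    for col, colour in (("S", "#3b6fb5"), ("R", "#2ca02c"), ("C", "#d62728"),
                        ("D", "#8c564b"), ("V", "black")):
        ax.plot(traj_frame["t"], np.maximum(traj_frame[col], 1e-2), label=col,
                color=colour, lw=1.2)
    ax.set_yscale("log")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("density (per ml)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def ld_panel(metrics: pd.DataFrame, path) -> Path:
    """Linkage disequilibrium against time."""
    if not {"t", "LD"}.issubset(metrics.columns):
        raise DomainError("metrics table must have 't' and 'LD' columns")
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.plot(metrics["t"], metrics["LD"], color="black", lw=1.2)
    ax.axhline(0.0, color="grey", lw=0.7, ls="--")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("LD = f_S f_D - f_R f_C")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def render_figures(results: pd.DataFrame, out_dir, prefix: str = "fig",
                   traj_frame: pd.DataFrame | None = None) -> list:
    """Render the standard panels for a results table; returns file paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = [stacked_fractions(results, out_dir / f"{prefix}_fractions.png")]
    if "LD" in results.columns and "t" in results.columns:
        paths.append(ld_panel(results, out_dir / f"{prefix}_ld.png"))
    if traj_frame is not None:
        paths.append(density_timecourse(traj_frame, out_dir / f"{prefix}_densities.png"))
    return paths
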