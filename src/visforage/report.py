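"""Descriptive artifacts: click maps, summary figures, result tables.

A click map is a 2D Gaussian kernel density of a participant's taps in the
canonical object frame, with contours enclosing the 10%, 25% and 50%
highest-density mass and the density mode marked.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import ndimage

from . import geometry
from .inference import PosteriorSummary, summaries_to_frame

HDR_LEVELS = (0.10, 0.25, 0.50)


@dataclass
class ClickMap:
    participant_id: int
    xy: np.ndarray  # canonical tap coordinates, (n, 2)
    grid_x: np.ndarray
    grid_y: np.ndarray
    density: np.ndarray  # (ny, nx), integrates to ~1 over the grid
    mode_xy: tuple[float, float]
    thresholds: dict[float, float]  # HDR level -> density threshold

    def region_mask(self, level: float) -> np.ndarray:
        return self.density >= self.thresholds[level]

    def region_area(self, level: float) -> float:
        dx = self.grid_x[1] - self.grid_x[0]
        dy = self.grid_y[1] - self.grid_y[0]
        return float(self.region_mask(level).sum() * dx * dy)

    def region_mass(self, level: float) -> float:
        dx = self.grid_x[1] - self.grid_x[0]
        dy = self.grid_y[1] - self.grid_y[0]
        return float(self.density[self.region_mask(level)].sum() * dx * dy)


def hdr_thresholds(density: np.ndarray, cell_area: float, levels=HDR_LEVELS) -> dict[float, float]:
    """Density cut-offs whose super-level sets enclose each mass level."""
    flat = np.sort(density.ravel())[::-1]
    cum = np.cumsum(flat) * cell_area
    total = cum[-1]
    out = {}
    for lev in levels:
        idx = int(np.searchsorted(cum, lev * total))
        idx = min(idx, flat.size - 1)
        out[lev] = float(flat[idx])
    return out


def click_map(
    canonical_xy,
    participant_id: int = 0,
    grid_size: int = 256,
    margin_sigmas: float = 3.0,
    levels=HDR_LEVELS,
    min_taps: int = 30,
) -> ClickMap:
    """Gaussian-KDE click map with highest-density-region thresholds.

    The grid covers the object's bounding box extended to the taps plus a
    ``margin_sigmas`` x tap-SD margin.  The density is a binned Gaussian KDE:
    taps are histogrammed onto the grid and convolved with a Gaussian kernel
    whose per-axis bandwidth follows Scott's plug-in rule (h = sd * n^(-1/6)),
    which keeps the cost independent of the number of taps.
    """
    xy = np.asarray(canonical_xy, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("canonical_xy must be an (n, 2) array")
    if xy.shape[0] < min_taps:
        raise ValueError(f"need >= {min_taps} taps for a click map, got {xy.shape[0]}")

    r = geometry.DEFAULT_RADIUS
    sd = xy.std(axis=0, ddof=1)
    lo = np.minimum(xy.min(axis=0), [-r, -r]) - margin_sigmas * sd
    hi = np.maximum(xy.max(axis=0), [r, r]) + margin_sigmas * sd
    gx = np.linspace(lo[0], hi[0], grid_size)
    gy = np.linspace(lo[1], hi[1], grid_size)
    dx, dy = gx[1] - gx[0], gy[1] - gy[0]

    ex = np.concatenate([gx - dx / 2, [gx[-1] + dx / 2]])
    ey = np.concatenate([gy - dy / 2, [gy[-1] + dy / 2]])
    hist, _, _ = np.histogram2d(xy[:, 0], xy[:, 1], bins=[ex, ey])
    h = sd * xy.shape[0] ** (-1.0 / 6.0)  # Scott's rule per axis
    dens = ndimage.gaussian_filter(hist, sigma=[h[0] / dx, h[1] / dy], truncate=5.0)
    dens = dens.T / (xy.shape[0] * dx * dy)  # (ny, nx), integrates to ~1
    cell = dx * dy
    thresholds = hdr_thresholds(dens, cell, levels)
    iy, ix = np.unravel_index(int(np.argmax(dens)), dens.shape)
    return ClickMap(
        participant_id=participant_id, xy=xy, grid_x=gx, grid_y=gy,
        density=dens, mode_xy=(float(gx[ix]), float(gy[iy])), thresholds=thresholds,
    )


def plot_click_map(cmap: ClickMap, ax=None, show_taps: bool = True):
    """Render one click map: taps, HDR contours, density mode, object outline."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    if show_taps:
        ax.plot(cmap.xy[:, 0], cmap.xy[:, 1], ".", color="gray", ms=2, alpha=0.3)
    ax.contour(
        cmap.grid_x, cmap.grid_y, cmap.density,
        levels=sorted(cmap.thresholds.values()), colors="k", linewidths=0.8,
    )
    ax.plot(*cmap.mode_xy, "o", color="white", mec="k", ms=6)
    r = geometry.DEFAULT_RADIUS
    th = np.linspace(0, np.pi, 100)
    ax.plot(r * np.cos(th), r * np.sin(th), "b-", lw=0.8)
    ax.plot([-r, r, r, -r, -r], [0, 0, -r, -r, 0], "b-", lw=0.8)
    ax.set_aspect("equal")
    ax.set_title(f"participant {cmap.participant_id}")
    return ax


def arcsine_mean(proportions) -> float:
    """Mean of proportions on the arcsine-square-root scale, back-transformed."""
    p = np.asarray(proportions, dtype=float)
    return float(np.sin(np.mean(np.arcsin(np.sqrt(p)))) ** 2)


def arcsine_sem(proportions) -> tuple[float, float]:
    """Back-transformed mean +/- SEM band on the arcsine-sqrt scale."""
    p = np.asarray(proportions, dtype=float)
    t = np.arcsin(np.sqrt(p))
    m, sem = t.mean(), t.std(ddof=1) / np.sqrt(t.size)
    return float(np.sin(m - sem) ** 2), float(np.sin(m + sem) ** 2)


def summarize_run(
    posteriors: dict[str, PosteriorSummary],
    switch_counts: pd.DataFrame | None,
    out_dir: str | Path,
    block_posteriors: dict[int, dict[str, PosteriorSummary]] | None = None,
) -> dict[str, Path]:
    """Write the run's result table and standard figures to ``out_dir``.

    Emits summary.csv (one row per estimand) and, where the inputs allow:
    a switching strip/forest figure with the 0.5 random-switching reference,
    a split-half preference scatter, and a block time-course figure.
    Missing inputs are reported by name.
    """
    if not posteriors:
        raise ValueError("missing input: posteriors (empty posterior store)")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    table = summaries_to_frame(posteriors)
    p = out_dir / "summary.csv"
    table.to_csv(p, index=False)
    written["summary"] = p

    part_switch = sorted(
        (k for k in posteriors if k.startswith("p_switch[")),
        key=lambda s: int(s.split("[")[1].rstrip("]")),
    )
    if part_switch and switch_counts is not None:
        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        props = (switch_counts["k_switch"] / switch_counts["m_opportunities"]).to_numpy()
        axes[0].plot(np.zeros_like(props), props, "*", color="tab:blue", alpha=0.7)
        m = arcsine_mean(props)
        lo, hi = arcsine_sem(props)
        axes[0].errorbar([0.15], [m], yerr=[[m - lo], [hi - m]], fmt="ko")
        axes[0].axhline(0.5, color="turquoise")
        axes[0].set_ylabel("proportion of part switches")
        axes[0].set_xticks([])
        for j, name in enumerate(part_switch):
            s = posteriors[name]
            axes[1].plot([s.hdi_low, s.hdi_high], [j, j], "-", color="tab:blue")
            axes[1].plot([s.mode], [j], "o", color="tab:blue", ms=3)
        axes[1].axvline(0.5, color="turquoise")
        axes[1].set_xlabel("switching probability")
        axes[1].set_ylabel("participant")
        fig.tight_layout()
        p = out_dir / "switching.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        written["switching"] = p

    p1 = sorted((k for k in posteriors if k.startswith("p_1st[")),
                key=lambda s: int(s.split("[")[1].rstrip("]")))
    p2 = sorted((k for k in posteriors if k.startswith("p_2nd[")),
                key=lambda s: int(s.split("[")[1].rstrip("]")))
    if p1 and p2:
        fig, ax = plt.subplots(figsize=(4.5, 4.5))
        for a_name, b_name in zip(p1, p2):
            sa, sb = posteriors[a_name], posteriors[b_name]
            ax.errorbar(
                [sa.mode], [sb.mode],
                xerr=[[sa.mode - sa.hdi_low], [sa.hdi_high - sa.mode]],
                yerr=[[sb.mode - sb.hdi_low], [sb.hdi_high - sb.mode]],
                fmt="o", color="tab:blue", ms=3, lw=0.8,
            )
        ax.plot([0, 1], [0, 1], "k--", lw=0.5)
        ax.set_xlabel("red-part preference, 1st half")
        ax.set_ylabel("red-part preference, 2nd half")
        fig.tight_layout()
        p = out_dir / "splithalf.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        written["splithalf"] = p

    if block_posteriors:
        fig, ax = plt.subplots(figsize=(6, 4))
        blocks = sorted(block_posteriors)
        pids = sorted(
            int(k.split("[")[1].rstrip("]"))
            for k in block_posteriors[blocks[0]]
        )
        for pid in pids:
            modes = [block_posteriors[b][f"p_red[{pid}]"].mode for b in blocks]
            los = [block_posteriors[b][f"p_red[{pid}]"].hdi_low for b in blocks]
            his = [block_posteriors[b][f"p_red[{pid}]"].hdi_high for b in blocks]
            ax.plot(blocks, modes, "-", lw=0.8, alpha=0.8)
            ax.fill_between(blocks, los, his, alpha=0.08)
        ax.axhline(0.5, color="k", lw=0.5, ls="--")
        ax.set_xlabel("block")
        ax.set_ylabel("red-part preference")
        fig.tight_layout()
        p = out_dir / "blocks.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        written["blocks"] = p

    return written
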