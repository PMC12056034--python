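"""Render the run's descriptive artifacts: click maps and summary figures.

Reads labeled.csv and the fitted summary/draws tables, rebuilds posterior
summaries, and writes per-participant click maps (canonical tap density with
10/25/50% highest-density contours) plus the switching, split-half and
blockwise figures into <run>/figures.
"""

import argparse
import sys
from pathlib import Path

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from visforage.inference import PosteriorSummary
from visforage.io import ensure_dir
from visforage.report import click_map, plot_click_map, summarize_run


def summaries_from_csv(path: Path) -> dict[str, PosteriorSummary]:
    df = pd.read_csv(path)
    out = {}
    for row in df.itertuples(index=False):
        out[row.parameter] = PosteriorSummary(
            name=row.parameter, draws=np.array([[row.mode]]), mode=row.mode,
            hdi_low=row.hdi_low, hdi_high=row.hdi_high, rhat=row.rhat, ess=row.ess,
        )
    return out


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--run", default="results/run")
    ap.add_argument("--max-maps", type=int, default=6)
    args = ap.parse_args()

    run = Path(args.run)
    figdir = ensure_dir(run / "figures")
    labeled = pd.read_csv(run / "labeled.csv")

    posteriors: dict[str, PosteriorSummary] = {}
    for name in ("switching_summary.csv", "preference_summary.csv", "splithalf_summary.csv"):
        p = run / name
        if p.exists():
            posteriors.update(summaries_from_csv(p))

    block_posteriors = None
    pb = run / "blockwise_summary.csv"
    if pb.exists():
        df = pd.read_csv(pb)
        block_posteriors = {}
        for b, grp in df.groupby("block"):
            block_posteriors[int(b)] = {
                row.parameter: PosteriorSummary(
                    name=row.parameter, draws=np.array([[row.mode]]), mode=row.mode,
                    hdi_low=row.hdi_low, hdi_high=row.hdi_high,
                )
                for row in grp.itertuples(index=False)
            }

    counts_path = run / "switch_counts_agg.csv"
    counts = pd.read_csv(counts_path) if counts_path.exists() else None
    written = summarize_run(posteriors, counts, figdir, block_posteriors)

    coll = labeled.loc[~labeled["is_error"]]
    pids = sorted(coll["participant_id"].unique())[: args.max_maps]
    fig, axes = plt.subplots(2, (len(pids) + 1) // 2, figsize=(3 * ((len(pids) + 1) // 2), 6))
    for ax, pid in zip(np.ravel(axes), pids):
        xy = coll.loc[coll["participant_id"] == pid, ["canon_x", "canon_y"]].to_numpy()
        cm = click_map(xy, participant_id=int(pid))
        plot_click_map(cm, ax=ax)
        ax.invert_yaxis()  # screen convention: half-disc (+y) plotted downward
    for ax in np.ravel(axes)[len(pids):]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(figdir / "clickmaps.png", dpi=150)
    plt.close(fig)
    written["clickmaps"] = figdir / "clickmaps.png"

    print("wrote:", ", ".join(str(p) for p in written.values()))


if __name__ == "__main__":
    main()
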