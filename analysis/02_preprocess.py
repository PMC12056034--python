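"""Preprocess the tap log: assign taps, label parts, build count tables.

Reads taps.csv / patches.csv from the run directory and writes labeled.csv,
switch_counts.csv (per trial), switch_counts_agg.csv (per participant),
pref_all.csv / pref_half.csv / pref_block.csv, itts.csv and endpeak.csv.
Prints the descriptives the study design targets: patch completion time,
median cruise inter-target time, and the end-peak factor.
"""

import argparse
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from visforage import preprocess
from visforage.io import ensure_dir, read_patches, read_taplog


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--run", default="results/run")
    args = ap.parse_args()

    run = ensure_dir(args.run)
    taplog = read_taplog(run / "taps.csv")
    patches = read_patches(run / "patches.csv")

    labeled = preprocess.label_taps(taplog, patches)
    labeled.to_csv(run / "labeled.csv", index=False)

    sw = preprocess.switch_counts_table(labeled)
    sw.to_csv(run / "switch_counts.csv", index=False)
    agg = preprocess.aggregate_switch_counts(sw)
    agg.to_csv(run / "switch_counts_agg.csv", index=False)

    for scope in ("all", "half", "block"):
        preprocess.preference_counts_table(labeled, scope=scope).to_csv(
            run / f"pref_{scope}.csv", index=False
        )

    itts = preprocess.itt_table(labeled)
    itts.to_csv(run / "itts.csv", index=False)
    ep = preprocess.end_peak_table(itts)
    ep.to_csv(run / "endpeak.csv", index=False)

    dur = ep.groupby("participant_id")["trial_duration_s"].mean()
    med_itt = itts.groupby(["participant_id", "trial_id"])["itt_ms"].median() \
                  .groupby("participant_id").mean()
    ep_part = ep.groupby("participant_id")["end_peak_factor"].mean()
    raw_switch = agg["k_switch"] / agg["m_opportunities"]
    print(f"patch completion time: M = {dur.mean():.2f} s (SD = {dur.std(ddof=1):.2f})")
    print(f"median ITT: M = {med_itt.mean():.2f} ms (SD = {med_itt.std(ddof=1):.2f})")
    print(f"end peak factor: M = {ep_part.mean():.2f} (SD = {ep_part.std(ddof=1):.2f})")
    print(f"raw switch proportion: M = {raw_switch.mean():.3f} "
          f"(range {raw_switch.min():.3f}-{raw_switch.max():.3f})")


if __name__ == "__main__":
    main()
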