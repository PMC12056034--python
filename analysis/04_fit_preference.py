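"""Estimate object-part preferences, their split-half reliability, and
their block-by-block time course.

Reads pref_all.csv / pref_half.csv / pref_block.csv; writes
preference_summary.csv, splithalf_summary.csv (with the correlation rho),
and blockwise_summary.csv.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from visforage.inference import (
    blockwise_preference,
    fit_preference_model,
    fit_splithalf_correlation,
    summaries_to_frame,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--run", default="results/run")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--chains", type=int, default=4)
    ap.add_argument("--draws", type=int, default=1000)
    args = ap.parse_args()

    run = Path(args.run)

    pref = pd.read_csv(run / "pref_all.csv").sort_values("participant_id")
    fit_pref = fit_preference_model(
        pref["k_red"], pref["n"], seed=args.seed,
        participant_ids=pref["participant_id"].tolist(),
    )
    summaries_to_frame(fit_pref).to_csv(run / "preference_summary.csv", index=False)
    n_red = sum(1 for s in fit_pref.values() if s.mode > 0.5)
    print(f"part preference: {n_red}/{len(fit_pref)} participants prefer the red part")

    half = pd.read_csv(run / "pref_half.csv")
    h1 = half[half["half"] == 1].sort_values("participant_id")
    h2 = half[half["half"] == 2].sort_values("participant_id")
    # With the symmetric attention chain, simulated preferences hover near 0.5
    # with little between-participant spread, so rho is weakly identified and
    # its chains mix slowly; report diagnostics instead of failing hard here.
    fit_sh = fit_splithalf_correlation(
        h1["k_red"], h1["n"], h2["k_red"], h2["n"],
        seed=args.seed + 1, chains=args.chains, warmup=args.draws, draws=args.draws,
        check=False,
    )
    summaries_to_frame(fit_sh).to_csv(run / "splithalf_summary.csv", index=False)
    rho = fit_sh["rho"]
    print(f"split-half correlation of preference (log-odds scale): "
          f"{rho.mode:.2f} [{rho.hdi_low:.2f}, {rho.hdi_high:.2f}] "
          f"(R-hat {rho.rhat:.3f}; weakly identified when preferences have "
          "little between-participant spread)")

    block = pd.read_csv(run / "pref_block.csv")
    fit_blocks = blockwise_preference(block, seed=args.seed + 2)
    rows = []
    for b, fits in fit_blocks.items():
        for s in fits.values():
            rows.append(dict(block=b, **s.as_row()))
    pd.DataFrame(rows).to_csv(run / "blockwise_summary.csv", index=False)
    print(f"blockwise preferences written for {len(fit_blocks)} blocks")


if __name__ == "__main__":
    main()
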