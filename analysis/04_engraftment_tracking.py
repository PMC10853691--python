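#!/usr/bin/env python
"""Quantify donor-taxon transfer into each recipient, FMT by FMT.

Reads the pipeline's engraftment table, prints the per-recipient
first-FMT summary in the form "X instances of engraftment out of Y
introduced taxa (Z%)", and compares the measured first-FMT engraftment
rates against the generator's recorded ground truth.
"""

import argparse
from pathlib import Path

import pandas as pd

from fmtgraft.simulate import GroundTruth

ROOT = Path(__file__).resolve().parents[1]


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--run", type=Path, default=ROOT / "results" / "run")
    parser.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    parser.add_argument("--out", type=Path,
                        default=ROOT / "results" / "engraftment_vs_truth.tsv")
    args = parser.parse_args()

    engraft = pd.read_csv(args.run / "engraftment.tsv", sep="\t")
    truth = GroundTruth.from_json(args.cohort / "truth.json")

    first = engraft[engraft.fmt_index == 1].set_index("recipient_id")
    rows = []
    for rid, row in first.iterrows():
        print(
            f"{rid}: {row.n_engrafted} instances of engraftment out of "
            f"{row.n_introduced} introduced taxa ({row.engraftment_pct:.0f}%); "
            f"{row.n_excluded}/{row.n_excludable} exclusions "
            f"({row.exclusion_pct:.0f}%)"
        )
        rows.append(
            {
                "recipient_id": rid,
                "measured_rate": row.n_engrafted / row.n_introduced,
                "latent_rate": truth.realized_pe(rid, 1),
                "n_introduced_measured": row.n_introduced,
                "n_introduced_latent": len(truth.introduced(rid, 1)),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(args.out, sep="\t", index=False)
    gap = (df.measured_rate - df.latent_rate).abs().max()
    print(f"\nmax |measured - latent| engraftment rate across recipients: {gap:.3f}")
    print("(detection at rarefied depth 1070 loses rare engrafted taxa, so the")
    print(" measured rate sits at or below the latent rate)")


if __name__ == "__main__":
    main()
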