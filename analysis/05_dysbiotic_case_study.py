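#!/usr/bin/env python
"""Track the dysbiotic recipient (R1) through its FMT course.

The generator pins three pathogen species — Paeniclostridium sordellii,
Clostridium perfringens, Photobacterium damselae — to ~87% of R1's
baseline community.  This driver reports R1's Shannon diversity before
and after treatment, the pathogen relative-abundance trajectories, and
the distance to each administered slurry.
"""

import argparse
from pathlib import Path

import pandas as pd

from fmtgraft.diversity import DistanceMatrix, alpha_diversity_table
from fmtgraft.profile_io import read_feature_table, read_lineages, read_metadata
from fmtgraft.pipeline import _pathogen_feature_ids
from fmtgraft.stats import welch_t
from fmtgraft.tracking import donor_similarity_series, taxon_trajectory

ROOT = Path(__file__).resolve().parents[1]


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--run", type=Path, default=ROOT / "results" / "run")
    parser.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    parser.add_argument("--recipient", default="R1")
    args = parser.parse_args()

    rarefied = read_feature_table(args.run / "rarefied.tsv")
    rarefied = rarefied.with_lineages(read_lineages(args.cohort / "lineages.tsv"))
    records = read_metadata(args.cohort / "metadata.tsv")
    dm = DistanceMatrix.read_tsv(args.run / "distance_unweighted_unifrac.tsv")

    rid = args.recipient
    alpha = alpha_diversity_table(rarefied)
    mine = {r.sample_id: r for r in records if r.animal_id == rid}
    pre = [alpha[s] for s, r in mine.items()
           if r.phase == "baseline" and s in alpha.index]
    post = [alpha[s] for s, r in mine.items()
            if r.phase == "post_fmt" and s in alpha.index]
    tt = welch_t(pre, post)
    print(f"{rid} Shannon (bits): baseline mean {sum(pre)/len(pre):.3f}, "
          f"post-FMT mean {sum(post)/len(post):.3f} "
          f"(Welch t={tt.t_statistic:.2f}, p={tt.p_value:.3g})")

    pathogen_ids = _pathogen_feature_ids(rarefied)
    traj = taxon_trajectory(rarefied, records, rid, pathogen_ids)
    traj.columns = [rarefied.lineages[f].split("s__")[-1] for f in traj.columns]
    out_traj = ROOT / "results" / f"{rid}_pathogen_trajectories.tsv"
    traj.to_csv(out_traj, sep="\t")
    baseline_load = traj.iloc[0].sum()
    final_load = traj.iloc[-1].sum()
    print(f"pathogen load: {100 * baseline_load:.2f}% at baseline -> "
          f"{100 * final_load:.2f}% after FMT #8 (table: {out_traj.name})")

    sim = donor_similarity_series(dm, records, rid)
    out_sim = ROOT / "results" / f"{rid}_donor_similarity.tsv"
    sim.rename("unweighted_unifrac").to_csv(out_sim, sep="\t", header=True)
    print("distance to administered slurry by FMT:")
    print("  " + ", ".join(f"#{k}: {v:.3f}" for k, v in sim.items()))


if __name__ == "__main__":
    main()
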