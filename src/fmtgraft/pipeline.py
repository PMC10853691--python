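"""Config-driven orchestration of the full analysis.

One call runs reconcile -> rarefy -> alpha/beta diversity -> group
statistics -> engraftment tracking -> donor screening, writing every
result as TSV plus a JSON manifest (input checksums, seed, versions)
that makes the run self-describing and exactly repeatable.
"""

from __future__ import annotations

import hashlib
import json
import sys
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diversity import (
    DistanceMatrix,
    METRICS,
    alpha_diversity_table,
    pairwise_distances,
    pcoa,
)
from .profile_io import (
    ValidationError,
    read_feature_table,
    read_lineages,
    read_metadata,
    read_newick,
    reconcile,
    write_feature_table,
)
from .rarefaction import RarefactionConfig, rarefy
from .screening import DEFAULT_THRESHOLD, default_pathogen_list, load_pathogen_list, screen_donor
from .simulate import PATHOGEN_SPECIES
from .stats import distance_from_baseline, permanova, permdisp, welch_t
from .tracking import (
    build_triplets,
    donor_similarity_series,
    engraftment_table,
    partition_taxa,
    taxon_trajectory,
)

__all__ = ["RunConfig", "StageError", "run_analysis", "summarize"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    """Inputs, settings, and output location for one pipeline run."""

    table: str
    metadata: str
    output_dir: str
    tree: str | None = None
    lineages: str | None = None
    pathogen_list: str | None = None  # YAML; None -> shipped default list
    rarefaction_depth: int = 1070
    metrics: tuple[str, ...] = METRICS
    n_permutations: int = 999
    screening_threshold: float = DEFAULT_THRESHOLD
    baseline_choice: str = "last"  # engraftment pre-FMT anchor
    series_metric: str = "unweighted_unifrac"  # distance-from-baseline metric
    shannon_base: float = 2.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if "metrics" in doc:
            doc["metrics"] = tuple(doc["metrics"])
        return cls(**doc)

    def validate(self) -> None:
        for name in ("table", "metadata", "tree", "lineages", "pathogen_list"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise StageError("config", f"missing input file for {name}: {p}")
        for m in self.metrics:
            if m not in METRICS:
                raise StageError("config", f"unknown metric {m!r}")
        needs_tree = any(m.endswith("unifrac") for m in self.metrics)
        if needs_tree and self.tree is None:
            raise StageError("config", "UniFrac metrics requested but no tree given")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_analysis(config: RunConfig) -> dict:
    """Run the full pipeline; returns the manifest dictionary.

    Emits under ``config.output_dir``: the rarefied table, one distance
    matrix and PCoA per metric, the Shannon table, PERMANOVA / PERMDISP /
    t-test results for the donor-vs-recipient baseline comparison, the
    engraftment and Venn-partition tables, pathogen trajectories for the
    dysbiotic recipient, per-animal distance-from-baseline series,
    donor-similarity series, screening reports, and ``manifest.json``.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        artifacts[name] = _sha256(path)

    # ---- load + reconcile
    try:
        table = read_feature_table(config.table)
        records = read_metadata(config.metadata)
        tree = read_newick(config.tree) if config.tree else None
        if config.lineages:
            table = table.with_lineages(read_lineages(config.lineages))
        bundle = reconcile(table, records, tree)
    except (ValidationError, OSError) as exc:
        raise StageError("load", str(exc)) from exc
    table, records, tree = bundle.table, bundle.records, bundle.tree

    # ---- rarefy
    try:
        rarefied, rare_report = rarefy(
            table, RarefactionConfig(depth=config.rarefaction_depth, seed=config.seed)
        )
    except ValidationError as exc:
        raise StageError("rarefy", str(exc)) from exc
    emit("rarefied.tsv", lambda p: write_feature_table(rarefied, p))
    kept = set(rarefied.sample_ids)
    records = tuple(r for r in records if r.sample_id in kept)

    # ---- alpha
    alpha = alpha_diversity_table(rarefied, log_base=config.shannon_base)
    emit("alpha_diversity.tsv", lambda p: alpha.to_csv(p, sep="\t", header=True))

    # ---- beta + ordination
    matrices: dict[str, DistanceMatrix] = {}
    for metric in config.metrics:
        try:
            dm = pairwise_distances(rarefied, metric, tree=tree)
        except ValidationError as exc:
            raise StageError(f"beta:{metric}", str(exc)) from exc
        matrices[metric] = dm
        emit(f"distance_{metric}.tsv", dm.write_tsv)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ord_res = pcoa(dm)
        coords = pd.DataFrame(
            ord_res.coordinates,
            index=list(dm.sample_ids),
            columns=[f"PC{i + 1}" for i in range(ord_res.coordinates.shape[1])],
        )
        emit(f"pcoa_{metric}.tsv", lambda p, c=coords: c.to_csv(p, sep="\t"))

    # ---- baseline group statistics (donor vs recipient)
    stat_metric = (
        "unweighted_unifrac" if "unweighted_unifrac" in matrices else config.metrics[0]
    )
    baseline_ids = [
        r.sample_id
        for r in records
        if r.phase == "baseline" and r.role in ("donor", "recipient")
    ]
    roles = {r.sample_id: r.role for r in records}
    stat_rows = []
    if len({roles[s] for s in baseline_ids}) == 2:
        dm_base = matrices[stat_metric].filter(baseline_ids)
        grouping = {s: roles[s] for s in baseline_ids}
        pn = permanova(dm_base, grouping, n_perm=config.n_permutations, seed=config.seed)
        pdp = permdisp(dm_base, grouping, n_perm=config.n_permutations, seed=config.seed)
        donors_a = alpha[[s for s in baseline_ids if roles[s] == "donor"]]
        recips_a = alpha[[s for s in baseline_ids if roles[s] == "recipient"]]
        tt = welch_t(donors_a, recips_a)
        disp = pdp.dispersions
        tt_disp = welch_t(
            disp[[s for s in baseline_ids if roles[s] == "donor"]],
            disp[[s for s in baseline_ids if roles[s] == "recipient"]],
        )
        stat_rows = [
            {"test": "permanova_baseline", "metric": stat_metric,
             "statistic": pn.statistic, "r_squared": pn.r_squared,
             "p_value": pn.p_value, "n_perm": pn.n_permutations, "seed": config.seed},
            {"test": "permdisp_baseline", "metric": stat_metric,
             "statistic": pdp.statistic, "r_squared": np.nan,
             "p_value": pdp.p_value, "n_perm": pdp.n_permutations, "seed": config.seed},
            {"test": "welch_t_shannon", "metric": f"shannon_base{config.shannon_base:g}",
             "statistic": tt.t_statistic, "r_squared": np.nan,
             "p_value": tt.p_value, "n_perm": 0, "seed": config.seed},
            {"test": "welch_t_dispersion", "metric": stat_metric,
             "statistic": tt_disp.t_statistic, "r_squared": np.nan,
             "p_value": tt_disp.p_value, "n_perm": 0, "seed": config.seed},
        ]
    stats_df = pd.DataFrame(
        stat_rows,
        columns=["test", "metric", "statistic", "r_squared", "p_value", "n_perm", "seed"],
    )
    emit("group_statistics.tsv", lambda p: stats_df.to_csv(p, sep="\t", index=False))

    # ---- engraftment tracking
    recipients = sorted({r.animal_id for r in records if r.role == "recipient"})
    engraft = engraftment_table(rarefied, records, baseline=config.baseline_choice)
    emit("engraftment.tsv", lambda p: engraft.to_csv(p, sep="\t", index=False))
    partitions = []
    for rid in recipients:
        trips = build_triplets(rarefied, records, rid, baseline=config.baseline_choice)
        if trips:
            part = partition_taxa(trips[0]).reset_index()
            part.insert(0, "recipient_id", rid)
            partitions.append(part)
    part_df = (
        pd.concat(partitions, ignore_index=True)
        if partitions
        else pd.DataFrame(columns=["recipient_id", "region", "n_taxa", "pct_of_union"])
    )
    emit("partition.tsv", lambda p: part_df.to_csv(p, sep="\t", index=False))

    # ---- longitudinal series
    series = distance_from_baseline(matrices[stat_metric], records)
    series_df = pd.DataFrame(series).rename_axis("timepoint")
    emit("distance_from_baseline.tsv", lambda p: series_df.to_csv(p, sep="\t"))
    sim_rows = {}
    for rid in recipients:
        try:
            sim_rows[rid] = donor_similarity_series(matrices[stat_metric], records, rid)
        except ValidationError:
            continue
    sim_df = pd.DataFrame(sim_rows).rename_axis("fmt_index")
    emit("donor_similarity.tsv", lambda p: sim_df.to_csv(p, sep="\t"))

    # ---- pathogen trajectories (dysbiotic taxa when present in the table)
    pathogen_ids = _pathogen_feature_ids(rarefied)
    traj_frames = []
    if pathogen_ids:
        for rid in recipients:
            try:
                tr = taxon_trajectory(rarefied, records, rid, pathogen_ids)
            except KeyError:
                continue
            tr = tr.reset_index()
            tr.insert(0, "animal_id", rid)
            traj_frames.append(tr)
    traj_df = (
        pd.concat(traj_frames, ignore_index=True) if traj_frames else pd.DataFrame()
    )
    emit("pathogen_trajectories.tsv", lambda p: traj_df.to_csv(p, sep="\t", index=False))

    # ---- donor screening
    plist = (
        load_pathogen_list(config.pathogen_list)
        if config.pathogen_list
        else default_pathogen_list()
    )
    screen_frames = []
    can_screen = rarefied.lineages is not None
    if can_screen:
        donor_baselines = [
            r.sample_id for r in records if r.role == "donor" and r.phase == "baseline"
        ]
        for sid in donor_baselines:
            rep = screen_donor(rarefied, sid, plist, threshold=config.screening_threshold)
            df = rep.to_frame().reset_index()
            df.insert(0, "sample_id", sid)
            df["overall"] = rep.verdict
            screen_frames.append(df)
    screen_df = (
        pd.concat(screen_frames, ignore_index=True) if screen_frames else pd.DataFrame()
    )
    emit("screening.tsv", lambda p: screen_df.to_csv(p, sep="\t", index=False))

    # ---- manifest
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "python": sys.version.split()[0],
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
        },
        "inputs": {
            name: _sha256(p)
            for name, p in (
                ("table", config.table),
                ("metadata", config.metadata),
                ("tree", config.tree),
                ("lineages", config.lineages),
            )
            if p
        },
        "rarefaction": {
            "depth": rare_report.depth,
            "dropped_samples": list(rare_report.dropped),
        },
        "reconcile": {
            "dropped_samples": list(bundle.dropped_samples),
            "dropped_features": list(bundle.dropped_features),
        },
        "artifacts": artifacts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _pathogen_feature_ids(table) -> list[str]:
    """Feature ids of the designated dysbiosis pathogens, if present."""
    if table.lineages is None:
        return []
    wanted = {name.lower() for name, _ in PATHOGEN_SPECIES}
    out = []
    for fid in table.feature_ids:
        lineage = table.lineages.get(fid, "")
        for part in lineage.split(";"):
            if part.strip().startswith("s__") and part.strip()[3:].lower() in wanted:
                out.append(fid)
    return out


def summarize(output_dir: str | Path) -> str:
    """Human-readable per-recipient engraftment/exclusion summary."""
    out = Path(output_dir)
    manifest_path = out / "manifest.json"
    if not manifest_path.exists():
        raise StageError("summarize", f"no manifest.json under {out}")
    engraft_path = out / "engraftment.tsv"
    if not engraft_path.exists():
        raise StageError("summarize", "bundle incomplete: missing engraftment.tsv")
    df = pd.read_csv(engraft_path, sep="\t")
    lines = []
    first = df[df["fmt_index"] == df.groupby("recipient_id")["fmt_index"].transform("min")]
    if first.empty:
        lines.append("No recipients with engraftment results.")
    for _, row in first.iterrows():
        if row["n_introduced"] > 0:
            lines.append(
                f"{row['recipient_id']}: {row['n_engrafted']} instances of engraftment "
                f"out of {row['n_introduced']} introduced taxa "
                f"({int(row['engraftment_pct'])}%) after FMT #{row['fmt_index']}"
            )
        else:
            lines.append(f"{row['recipient_id']}: no taxa introduced (rate undefined)")
        if row["n_excludable"] > 0:
            lines.append(
                f"{row['recipient_id']}: {row['n_excluded']} instances of exclusion "
                f"out of {row['n_excludable']} excludable taxa "
                f"({int(row['exclusion_pct'])}%)"
            )
    return "\n".join(lines)
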