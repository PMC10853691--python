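"""Synthetic FMT cohorts with known ground truth.

Generates everything the pipeline consumes — a rooted phylogeny, baseline
communities for donors/recipients/controls, pooled donor slurries, and
longitudinal post-FMT samples — under a simple generative model:

* Each animal carries a subset of the taxon pool (a shared "core" fraction
  plus independent peripheral carriage) with a heavy-tailed latent
  composition: log-normal perturbations of per-taxon base abundances,
  normalized to a simplex.  Base abundances encode phylum structure
  (two dominant phyla, ~20 in total).
* Sequenced samples are multinomial draws at stochastic depths around a
  few thousand reads; within-animal drift multiplies the latent
  composition by small log-normal factors per timepoint.
* Slurries are weighted mixtures of several donors' compositions.
* After each FMT, every slurry taxon absent from the recipient engrafts
  independently with probability ``engraftment_prob`` at an abundance
  inherited from the slurry; every recipient taxon absent from the slurry
  is removed with probability ``exclusion_prob``.  One recipient is
  dysbiotic: three designated pathogen species are pinned to target
  relative abundances at baseline and decay after the first FMT.

All draws are recorded in a :class:`GroundTruth` object so that the
tracking statistics can be validated against what actually happened.
Every stochastic stream is derived from a single master seed with named
substreams, so outputs are byte-identical for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from skbio import TreeNode

from .profile_io import (
    FeatureTable,
    SampleRecord,
    ValidationError,
    write_feature_table,
    write_metadata,
    write_newick,
)

__all__ = [
    "CohortParams",
    "GroundTruth",
    "CohortBundle",
    "PATHOGEN_SPECIES",
    "simulate_tree",
    "simulate_taxonomy",
    "simulate_baseline_communities",
    "simulate_slurry",
    "simulate_post_fmt_series",
    "simulate_cohort",
]

# The three species dominating the dysbiotic recipient's baseline, with
# their target relative abundances (50.00%, 20.37%, 16.92%).
PATHOGEN_SPECIES = (
    ("Paeniclostridium sordellii", 0.5000),
    ("Clostridium perfringens", 0.2037),
    ("Photobacterium damselae", 0.1692),
)

_PHYLA = (
    ("Firmicutes", 0.45),
    ("Proteobacteria", 0.38),
    ("Actinobacteria", 0.05),
    ("Candidatus Kryptonia", 0.04),
)
_N_MINOR_PHYLA = 16  # shares the remaining mass -> ~20 phyla in total


def _rng(seed: int, *names: str) -> np.random.Generator:
    """Named substream of the master seed."""
    key = tuple("/".join(names).encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


@dataclass(frozen=True)
class CohortParams:
    """Study-design and generative parameters for one synthetic cohort.

    Defaults mirror the study structure: 7 donors, 4 recipients (the
    first dysbiotic), 3 controls, 3 baseline samples per animal, 8 FMTs
    with one slurry and one post-FMT sample each, and multinomial depths
    around a few thousand reads.
    """

    n_taxa: int = 300
    n_donors: int = 7
    n_recipients: int = 4
    n_controls: int = 3
    n_baseline_per_animal: int = 3
    n_fmts: int = 8
    depth_mean: float = 5000.0
    depth_dispersion: float = 0.2  # log-normal sigma on sequencing depth
    concentration: float = 0.25  # evenness; latent log-sigma = 1/sqrt(c)
    donor_overlap: float = 0.3  # fraction of taxa in the shared core
    peripheral_carriage: float = 0.3  # per-animal carriage of non-core taxa
    engraftment_prob: float = 0.3
    exclusion_prob: float = 0.3
    drift_rate: float = 0.1  # per-timestep log-normal drift sigma
    engraft_scale: float = 1.0  # engrafted abundance = slurry prop * scale
    engraft_noise: float = 0.5  # log-normal sigma on engrafted abundance
    pathogen_decay: float = 0.02  # dysbiotic pathogen multiplier after FMT 1
    slurry_donors_min: int = 3
    slurry_donors_max: int = 6
    dysbiosis_spec: Mapping[str, float] | None = None  # None -> defaults; {} -> off
    seed: int = 0

    def __post_init__(self):
        for name in ("engraftment_prob", "exclusion_prob", "donor_overlap",
                     "peripheral_carriage"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_taxa", "n_donors", "n_recipients", "n_baseline_per_animal",
                     "n_fmts"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        if self.n_controls < 0:
            raise ValidationError("n_controls must be >= 0")
        if self.depth_mean < 1 or self.concentration <= 0:
            raise ValidationError("depth_mean and concentration must be positive")
        if self.dysbiosis_spec is not None:
            if sum(self.dysbiosis_spec.values()) > 1.0:
                raise ValidationError("dysbiosis target abundances sum above 1")

    @property
    def log_sigma(self) -> float:
        return 1.0 / np.sqrt(self.concentration)


@dataclass
class GroundTruth:
    """What the generator actually did, for parameter-recovery checks.

    ``per_recipient[rid]`` holds, for each FMT index, the latent
    introduced / engrafted / excludable / excluded taxon id lists, plus
    realized engraftment and exclusion fractions for FMT #1.
    """

    per_recipient: dict = field(default_factory=dict)
    slurry_weights: dict = field(default_factory=dict)  # fmt index -> {donor: w}
    dysbiotic_recipient: str | None = None
    params: dict = field(default_factory=dict)

    def introduced(self, rid: str, fmt: int = 1) -> frozenset[str]:
        return frozenset(self.per_recipient[rid][str(fmt)]["introduced"])

    def engrafted(self, rid: str, fmt: int = 1) -> frozenset[str]:
        return frozenset(self.per_recipient[rid][str(fmt)]["engrafted"])

    def excluded(self, rid: str, fmt: int = 1) -> frozenset[str]:
        return frozenset(self.per_recipient[rid][str(fmt)]["excluded"])

    def realized_pe(self, rid: str, fmt: int = 1) -> float:
        rec = self.per_recipient[rid][str(fmt)]
        return len(rec["engrafted"]) / max(len(rec["introduced"]), 1)

    def realized_px(self, rid: str, fmt: int = 1) -> float:
        rec = self.per_recipient[rid][str(fmt)]
        return len(rec["excluded"]) / max(len(rec["excludable"]), 1)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "per_recipient": self.per_recipient,
                    "slurry_weights": self.slurry_weights,
                    "dysbiotic_recipient": self.dysbiotic_recipient,
                    "params": self.params,
                },
                fh,
                indent=1,
                sort_keys=True,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(**doc)


@dataclass(frozen=True)
class CohortBundle:
    table: FeatureTable
    records: tuple[SampleRecord, ...]
    tree: TreeNode
    truth: GroundTruth
    params: CohortParams


# -- tree and taxonomy ---------------------------------------------------------


def simulate_tree(n_taxa: int, seed: int = 0, feature_ids: Sequence[str] | None = None) -> TreeNode:
    """Random rooted binary tree by successive random pair-joining.

    Branch lengths are exponential(1) draws, strictly positive.
    """
    if n_taxa < 2:
        raise ValidationError("a tree needs at least 2 taxa")
    if feature_ids is None:
        feature_ids = [f"OGU{i:05d}" for i in range(n_taxa)]
    if len(feature_ids) != n_taxa:
        raise ValidationError("feature_ids length must equal n_taxa")
    rng = _rng(seed, "tree")
    nodes = []
    for name in feature_ids:
        tip = TreeNode(name=name)
        nodes.append(tip)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        for child in (left, right):
            child.length = float(max(rng.exponential(1.0), 1e-6))
        parent = TreeNode(children=[left, right])
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


def simulate_taxonomy(n_taxa: int, seed: int = 0) -> tuple[list[str], dict[str, str]]:
    """Feature ids and ranked lineage strings with realistic phylum skew.

    Two phyla dominate and ~20 are present overall.  The first three taxa
    are the designated pathogen species with their real lineages.
    """
    rng = _rng(seed, "taxonomy")
    minor_mass = 1.0 - sum(w for _, w in _PHYLA)
    phyla = list(_PHYLA) + [
        (f"CandidatePhylum{i + 1:02d}", minor_mass / _N_MINOR_PHYLA)
        for i in range(_N_MINOR_PHYLA)
    ]
    names = [p for p, _ in phyla]
    weights = np.array([w for _, w in phyla])
    feature_ids = [f"OGU{i:05d}" for i in range(n_taxa)]
    lineages: dict[str, str] = {}
    fixed = {
        0: ("Firmicutes", "Peptostreptococcaceae", "Paeniclostridium",
            "Paeniclostridium sordellii"),
        1: ("Firmicutes", "Clostridiaceae", "Clostridium", "Clostridium perfringens"),
        2: ("Proteobacteria", "Vibrionaceae", "Photobacterium",
            "Photobacterium damselae"),
    }
    assignments = rng.choice(len(phyla), size=n_taxa, p=weights / weights.sum())
    for i, fid in enumerate(feature_ids):
        if i in fixed and n_taxa > 3:
            phylum, fam, genus, species = fixed[i]
        else:
            phylum = names[assignments[i]]
            fam = f"{phylum.replace(' ', '')}Family{(i % 7) + 1}"
            genus = f"Genus{i:05d}"
            species = f"{genus} synthetica"
        lineages[fid] = (
            f"k__Bacteria;p__{phylum};c__;o__;f__{fam};g__{genus};s__{species}"
        )
    return feature_ids, lineages


# -- latent communities --------------------------------------------------------


def _base_means(lineages: Mapping[str, str], feature_ids: Sequence[str]) -> np.ndarray:
    """Per-taxon base abundance encoding phylum mass split evenly within phylum."""
    phyla = {}
    get_phylum = lambda lin: next(
        (p[3:] for p in lin.split(";") if p.startswith("p__")), ""
    )
    for fid in feature_ids:
        phyla.setdefault(get_phylum(lineages[fid]), []).append(fid)
    mass = dict(_PHYLA)
    minor_mass = 1.0 - sum(mass.values())
    minor_phyla = [p for p in phyla if p not in mass]
    means = np.empty(len(feature_ids))
    index = {f: i for i, f in enumerate(feature_ids)}
    for phylum, members in phyla.items():
        w = mass.get(phylum, minor_mass / max(len(minor_phyla), 1))
        for fid in members:
            means[index[fid]] = w / len(members)
    return means


def _composition(rng, base_means, support, sigma) -> np.ndarray:
    x = np.zeros(len(base_means))
    x[support] = base_means[support] * np.exp(sigma * rng.standard_normal(support.sum()))
    return x / x.sum()


def _drift(rng, comp, rate) -> np.ndarray:
    if rate <= 0:
        return comp
    out = comp * np.exp(rate * rng.standard_normal(len(comp)) * (comp > 0))
    return out / out.sum()


def _draw_depth(rng, params: CohortParams) -> int:
    if params.depth_dispersion <= 0:
        return int(round(params.depth_mean))
    d = rng.lognormal(np.log(params.depth_mean), params.depth_dispersion)
    return max(int(round(d)), 100)


def _multinomial(rng, comp, depth) -> np.ndarray:
    return rng.multinomial(depth, comp)


def animal_ids(params: CohortParams) -> dict[str, list[str]]:
    return {
        "donor": [f"D{i + 1}" for i in range(params.n_donors)],
        "recipient": [f"R{i + 1}" for i in range(params.n_recipients)],
        "control": [f"C{i + 1}" for i in range(params.n_controls)],
    }


def _dysbiosis_targets(params: CohortParams, feature_ids) -> dict[str, float]:
    if params.dysbiosis_spec is not None:
        unknown = [t for t in params.dysbiosis_spec if t not in feature_ids]
        if unknown:
            raise ValidationError(f"dysbiosis taxa not in pool: {unknown}")
        return dict(params.dysbiosis_spec)
    if params.n_taxa <= 3:
        return {}
    return {feature_ids[i]: target for i, (_, target) in enumerate(PATHOGEN_SPECIES)}


def simulate_baseline_communities(
    params: CohortParams,
    feature_ids: Sequence[str] | None = None,
    lineages: Mapping[str, str] | None = None,
) -> tuple[FeatureTable, tuple[SampleRecord, ...], dict[str, np.ndarray]]:
    """Baseline samples for every animal, plus the latent compositions.

    Each animal's latent composition is a log-normal perturbation of the
    phylum-structured base abundances over its carried taxa; baseline
    samples are multinomial draws with per-timepoint drift.  The first
    recipient is dysbiotic: the designated pathogen taxa are pinned to
    their target relative abundances.
    """
    if feature_ids is None:
        feature_ids, lineages = simulate_taxonomy(params.n_taxa, params.seed)
    feature_ids = list(feature_ids)
    n = len(feature_ids)
    targets = _dysbiosis_targets(params, feature_ids)
    pathogen_idx = np.array(
        [feature_ids.index(t) for t in targets], dtype=np.intp
    )
    base = (
        _base_means(lineages, feature_ids)
        if lineages
        else np.full(n, 1.0 / n)
    )

    core_rng = _rng(params.seed, "core")
    n_core = int(round(params.donor_overlap * n))
    core = np.zeros(n, dtype=bool)
    if n_core:
        core[core_rng.choice(n, size=n_core, replace=False)] = True
    # donors never carry the designated pathogens (they are screened animals)
    ids = animal_ids(params)
    dysbiotic = ids["recipient"][0] if targets else None

    latents: dict[str, np.ndarray] = {}
    for role, animals in ids.items():
        for aid in animals:
            rng = _rng(params.seed, "animal", aid)
            support = core | (rng.random(n) < params.peripheral_carriage)
            if role == "donor" and len(pathogen_idx):
                support[pathogen_idx] = False
            if support.sum() < 2:
                support[rng.choice(n, size=2, replace=False)] = True
            comp = _composition(rng, base, support, params.log_sigma)
            if aid == dysbiotic and len(pathogen_idx):
                comp[pathogen_idx] = 0.0
                total_target = sum(targets.values())
                comp = comp / comp.sum() * (1.0 - total_target)
                comp[pathogen_idx] = [targets[feature_ids[i]] for i in pathogen_idx]
            latents[aid] = comp

    columns, records = [], []
    collection = 0
    for role, animals in ids.items():
        for aid in animals:
            rng = _rng(params.seed, "baseline", aid)
            comp = latents[aid]
            for t in range(params.n_baseline_per_animal):
                if t > 0:
                    comp = _drift(rng, comp, params.drift_rate)
                depth = _draw_depth(rng, params)
                columns.append(_multinomial(rng, comp, depth))
                records.append(
                    SampleRecord(
                        sample_id=f"{aid}_B{t}",
                        animal_id=aid,
                        role=role,
                        phase="baseline",
                        timepoint=t,
                        collection_index=collection,
                    )
                )
                collection += 1
            latents[aid] = comp  # post-drift state feeds the FMT phase
    table = FeatureTable(
        feature_ids=tuple(feature_ids),
        sample_ids=tuple(r.sample_id for r in records),
        counts=np.column_stack(columns),
        lineages=dict(lineages) if lineages else None,
    )
    return table, tuple(records), latents


def simulate_slurry(
    donor_profiles: Sequence[Mapping[str, float]],
    weights: Sequence[float],
    depth: int,
    seed: int = 0,
) -> tuple[dict[str, float], dict[str, int]]:
    """Pooled donor slurry: weighted mixture composition plus sampled counts.

    ``donor_profiles`` are relative-abundance maps; ``weights`` must lie
    on the simplex.  Returns the latent mixture composition and a
    multinomial draw of ``depth`` reads from it.
    """
    if len(donor_profiles) < 1:
        raise ValidationError("slurry needs at least one donor profile")
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(donor_profiles):
        raise ValidationError("weights length must match number of donor profiles")
    if abs(weights.sum() - 1.0) > 1e-9 or np.any(weights < 0):
        raise ValidationError("weights must be a simplex vector")
    mixture: dict[str, float] = {}
    for w, profile in zip(weights, donor_profiles):
        for fid, p in profile.items():
            if p > 0:
                mixture[fid] = mixture.get(fid, 0.0) + w * p
    total = sum(mixture.values())
    mixture = {f: v / total for f, v in mixture.items()}
    rng = _rng(seed, "slurry")
    fids = sorted(mixture)
    counts = rng.multinomial(depth, [mixture[f] for f in fids])
    return mixture, dict(zip(fids, (int(c) for c in counts)))


def _apply_fmt(rng, comp, slurry_comp, params: CohortParams):
    """One FMT on the latent composition; returns new state and event masks."""
    present = comp > 0
    s_present = slurry_comp > 0
    introduced = s_present & ~present
    engrafted = introduced & (rng.random(len(comp)) < params.engraftment_prob)
    excludable = present & ~s_present
    excluded = excludable & (rng.random(len(comp)) < params.exclusion_prob)
    new = comp.copy()
    noise = np.exp(params.engraft_noise * rng.standard_normal(int(engrafted.sum())))
    new[engrafted] = slurry_comp[engrafted] * params.engraft_scale * noise
    new[excluded] = 0.0
    new = new / new.sum()
    return new, introduced, engrafted, excludable, excluded


def simulate_post_fmt_series(
    recipient_comp: np.ndarray,
    slurry_comps: Sequence[np.ndarray],
    params: CohortParams,
    seed: int,
    feature_ids: Sequence[str],
    pathogen_idx: Sequence[int] = (),
) -> tuple[list[np.ndarray], dict]:
    """Post-FMT sample series for one recipient, with per-FMT ground truth.

    For each FMT the latent composition is updated (engraftment with
    probability ``engraftment_prob``, exclusion with ``exclusion_prob``,
    pathogen decay after FMT #1, drift), then sampled multinomially.
    Returns the sampled count vectors and a per-FMT event record.
    """
    if len(slurry_comps) != params.n_fmts:
        raise ValidationError("need one slurry per FMT")
    rng = _rng(seed, "post", "series")
    comp = np.asarray(recipient_comp, dtype=float).copy()
    pathogen_idx = np.asarray(list(pathogen_idx), dtype=np.intp)
    samples, truth = [], {}
    for k, slurry in enumerate(slurry_comps, start=1):
        comp, introduced, engrafted, excludable, excluded = _apply_fmt(
            rng, comp, np.asarray(slurry, dtype=float), params
        )
        if len(pathogen_idx) and k >= 1:
            decayed = comp[pathogen_idx] * params.pathogen_decay
            comp[pathogen_idx] = decayed
            comp = comp / comp.sum()
        comp = _drift(rng, comp, params.drift_rate)
        depth = _draw_depth(rng, params)
        samples.append(_multinomial(rng, comp, depth))
        truth[str(k)] = {
            "introduced": [feature_ids[i] for i in np.flatnonzero(introduced)],
            "engrafted": [feature_ids[i] for i in np.flatnonzero(engrafted)],
            "excludable": [feature_ids[i] for i in np.flatnonzero(excludable)],
            "excluded": [feature_ids[i] for i in np.flatnonzero(excluded)],
        }
    return samples, truth


def simulate_cohort(
    params: CohortParams | None = None,
    out_dir: str | Path | None = None,
    overwrite: bool = False,
    **kwargs,
) -> CohortBundle:
    """Generate a full cohort and optionally write it to disk.

    Writes ``table.tsv``, ``metadata.tsv``, ``tree.nwk``, ``lineages.tsv``
    and ``truth.json`` under ``out_dir``.  Byte-identical for a fixed
    seed; refuses to clobber existing files unless ``overwrite``.
    """
    if params is None:
        params = CohortParams(**kwargs)
    feature_ids, lineages = simulate_taxonomy(params.n_taxa, params.seed)
    tree = simulate_tree(params.n_taxa, params.seed, feature_ids=feature_ids)
    table, records, latents = simulate_baseline_communities(
        params, feature_ids=feature_ids, lineages=lineages
    )
    targets = _dysbiosis_targets(params, feature_ids)
    pathogen_idx = [feature_ids.index(t) for t in targets]
    ids = animal_ids(params)
    truth = GroundTruth(
        dysbiotic_recipient=ids["recipient"][0] if targets else None,
        params={
            "engraftment_prob": params.engraftment_prob,
            "exclusion_prob": params.exclusion_prob,
            "seed": params.seed,
        },
    )

    columns = list(table.counts.T)
    all_records = list(records)
    collection = len(all_records)
    index = {f: i for i, f in enumerate(feature_ids)}

    # slurries: 3-6 donors pooled per FMT with random simplex weights
    slurry_comps: list[np.ndarray] = []
    for k in range(1, params.n_fmts + 1):
        rng = _rng(params.seed, "slurry", str(k))
        k_donors = int(
            rng.integers(
                min(params.slurry_donors_min, params.n_donors),
                min(params.slurry_donors_max, params.n_donors) + 1,
            )
        )
        chosen = sorted(rng.choice(ids["donor"], size=k_donors, replace=False).tolist())
        weights = rng.dirichlet(np.ones(k_donors))
        profiles = [
            {feature_ids[i]: p for i, p in enumerate(latents[d]) if p > 0}
            for d in chosen
        ]
        mixture, counts = simulate_slurry(
            profiles, weights, _draw_depth(rng, params), seed=params.seed + 7919 * k
        )
        comp = np.zeros(len(feature_ids))
        for fid, p in mixture.items():
            comp[index[fid]] = p
        slurry_comps.append(comp)
        col = np.zeros(len(feature_ids), dtype=np.int64)
        for fid, c in counts.items():
            col[index[fid]] = c
        columns.append(col)
        all_records.append(
            SampleRecord(
                sample_id=f"SLURRY_F{k}",
                animal_id="SLURRY",
                role="slurry",
                phase="fmt_slurry",
                timepoint=k,
                collection_index=collection,
            )
        )
        collection += 1
        truth.slurry_weights[str(k)] = dict(zip(chosen, map(float, weights)))

    # recipients: engraftment/exclusion dynamics; controls: drift only
    for rid in ids["recipient"]:
        p_idx = pathogen_idx if rid == truth.dysbiotic_recipient else ()
        samples, rec_truth = simulate_post_fmt_series(
            latents[rid],
            slurry_comps,
            params,
            seed=params.seed + hash_stable(rid),
            feature_ids=feature_ids,
            pathogen_idx=p_idx,
        )
        truth.per_recipient[rid] = rec_truth
        for k, col in enumerate(samples, start=1):
            columns.append(col)
            all_records.append(
                SampleRecord(
                    sample_id=f"{rid}_P{k}",
                    animal_id=rid,
                    role="recipient",
                    phase="post_fmt",
                    timepoint=k,
                    collection_index=collection,
                )
            )
            collection += 1
    for cid in ids["control"]:
        rng = _rng(params.seed, "control", cid)
        comp = latents[cid]
        for k in range(1, params.n_fmts + 1):
            comp = _drift(rng, comp, params.drift_rate)
            depth = _draw_depth(rng, params)
            columns.append(_multinomial(rng, comp, depth))
            all_records.append(
                SampleRecord(
                    sample_id=f"{cid}_P{k}",
                    animal_id=cid,
                    role="control",
                    phase="post_fmt",
                    timepoint=k,
                    collection_index=collection,
                )
            )
            collection += 1

    full = FeatureTable(
        feature_ids=tuple(feature_ids),
        sample_ids=tuple(r.sample_id for r in all_records),
        counts=np.column_stack(columns),
        lineages=dict(lineages),
    )
    bundle = CohortBundle(
        table=full, records=tuple(all_records), tree=tree, truth=truth, params=params
    )
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir), overwrite)
    return bundle


def hash_stable(name: str) -> int:
    """Deterministic small integer from a name (process-independent)."""
    h = 0
    for ch in name.encode("utf-8"):
        h = (h * 131 + ch) % 1_000_003
    return h


def _write_bundle(bundle: CohortBundle, out_dir: Path, overwrite: bool) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    names = ("table.tsv", "metadata.tsv", "tree.nwk", "lineages.tsv", "truth.json")
    clashes = [n for n in names if (out_dir / n).exists()]
    if clashes and not overwrite:
        raise FileExistsError(f"refusing to overwrite {clashes} in {out_dir}")
    write_feature_table(bundle.table, out_dir / "table.tsv")
    write_metadata(bundle.records, out_dir / "metadata.tsv")
    write_newick(bundle.tree, out_dir / "tree.nwk")
    with open(out_dir / "lineages.tsv", "w") as fh:
        fh.write("#feature_id\tlineage\n")
        for fid in bundle.table.feature_ids:
            fh.write(f"{fid}\t{bundle.table.lineages[fid]}\n")
    bundle.truth.to_json(out_dir / "truth.json")
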