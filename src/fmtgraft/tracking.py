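"""Donor-taxon transfer tracking across an FMT course.

The central bookkeeping of the analysis: for each recipient and FMT, the
pre-FMT, donor-slurry, and post-FMT communities are reduced to presence
sets on the rarefied table, and taxa are classified by their membership
pattern.

Engraftment: a taxon absent in the recipient pre-FMT, present in the
administered donor slurry, and subsequently present in the recipient
post-FMT.  Exclusion: a taxon present pre-FMT, absent from the slurry,
and subsequently absent post-FMT.  Rates are reported over the taxa
eligible for each event (introduced and excludable taxa respectively).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diversity import DistanceMatrix
from .profile_io import FeatureTable, SampleRecord, ValidationError

__all__ = [
    "CommunityTriplet",
    "EngraftmentResult",
    "VENN_REGIONS",
    "presence_set",
    "partition_taxa",
    "engraftment_stats",
    "engraftment_table",
    "build_triplets",
    "taxon_trajectory",
    "donor_similarity_series",
    "round_half_away",
]

VENN_REGIONS = (
    "pre_only",
    "donor_only",
    "post_only",
    "pre_donor",
    "pre_post",
    "donor_post",
    "pre_donor_post",
)


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (so 30.5 -> 31)."""
    return int(np.floor(abs(x) + 0.5) * np.sign(x)) if x else 0


@dataclass(frozen=True)
class CommunityTriplet:
    """Presence sets of the three communities around one FMT."""

    pre_set: frozenset[str]
    donor_set: frozenset[str]
    post_set: frozenset[str]
    recipient_id: str = ""
    fmt_index: int = 1

    def __post_init__(self):
        object.__setattr__(self, "pre_set", frozenset(self.pre_set))
        object.__setattr__(self, "donor_set", frozenset(self.donor_set))
        object.__setattr__(self, "post_set", frozenset(self.post_set))


@dataclass(frozen=True)
class EngraftmentResult:
    """Engraftment and exclusion counts for one recipient-FMT triplet.

    ``engraftment_pct``/``exclusion_pct`` are integer percents (half away
    from zero) and are ``None`` when the denominator is zero.
    """

    recipient_id: str
    fmt_index: int
    n_introduced: int
    n_engrafted: int
    n_excludable: int
    n_excluded: int

    def __post_init__(self):
        if not (0 <= self.n_engrafted <= self.n_introduced):
            raise ValidationError("engrafted count outside [0, introduced]")
        if not (0 <= self.n_excluded <= self.n_excludable):
            raise ValidationError("excluded count outside [0, excludable]")

    @property
    def engraftment_pct(self) -> int | None:
        if self.n_introduced == 0:
            return None
        return round_half_away(100 * self.n_engrafted / self.n_introduced)

    @property
    def exclusion_pct(self) -> int | None:
        if self.n_excludable == 0:
            return None
        return round_half_away(100 * self.n_excluded / self.n_excludable)

    @property
    def engraftment_rate(self) -> float | None:
        return None if self.n_introduced == 0 else self.n_engrafted / self.n_introduced

    @property
    def exclusion_rate(self) -> float | None:
        return None if self.n_excludable == 0 else self.n_excluded / self.n_excludable


def presence_set(table: FeatureTable, sample_id: str) -> frozenset[str]:
    """Features with count >= 1 in the given sample."""
    col = table.sample_counts(sample_id)  # raises KeyError on unknown sample
    return frozenset(f for f, c in zip(table.feature_ids, col) if c >= 1)


def partition_taxa(triplet: CommunityTriplet) -> pd.DataFrame:
    """Counts and union-percentages for the 7 regions of the 3-set Venn diagram.

    Region counts sum to the size of the union of the three communities.
    """
    pre, donor, post = triplet.pre_set, triplet.donor_set, triplet.post_set
    union = pre | donor | post
    if not union:
        raise ValidationError("empty union of pre/donor/post communities")
    counts = {
        "pre_only": len(pre - donor - post),
        "donor_only": len(donor - pre - post),
        "post_only": len(post - pre - donor),
        "pre_donor": len((pre & donor) - post),
        "pre_post": len((pre & post) - donor),
        "donor_post": len((donor & post) - pre),
        "pre_donor_post": len(pre & donor & post),
    }
    df = pd.DataFrame(
        {
            "n_taxa": [counts[r] for r in VENN_REGIONS],
            "pct_of_union": [100 * counts[r] / len(union) for r in VENN_REGIONS],
        },
        index=list(VENN_REGIONS),
    )
    df.index.name = "region"
    return df


def engraftment_stats(triplet: CommunityTriplet) -> EngraftmentResult:
    """Engraftment and exclusion counts from the three presence sets.

    Introduced taxa: in the donor slurry but not the recipient pre-FMT.
    Engrafted: introduced taxa found post-FMT.  Excludable: pre-FMT taxa
    absent from the slurry.  Excluded: excludable taxa absent post-FMT.
    """
    introduced = triplet.donor_set - triplet.pre_set
    engrafted = introduced & triplet.post_set
    excludable = triplet.pre_set - triplet.donor_set
    excluded = excludable - triplet.post_set
    return EngraftmentResult(
        recipient_id=triplet.recipient_id,
        fmt_index=triplet.fmt_index,
        n_introduced=len(introduced),
        n_engrafted=len(engrafted),
        n_excludable=len(excludable),
        n_excluded=len(excluded),
    )


# -- study-design plumbing -----------------------------------------------------


def _samples_by(records: Sequence[SampleRecord], **match) -> list[SampleRecord]:
    out = [
        r
        for r in records
        if all(getattr(r, k) == v for k, v in match.items())
    ]
    return sorted(out, key=lambda r: (r.timepoint, r.collection_index))


def build_triplets(
    table: FeatureTable,
    records: Sequence[SampleRecord],
    recipient_id: str,
    baseline: str = "last",
    fmt_indices: Sequence[int] | None = None,
) -> list[CommunityTriplet]:
    """Assemble (pre, slurry, post) presence-set triplets for one recipient.

    The pre-FMT community is the recipient's last baseline sample before
    treatment (``baseline="first"`` or ``"union"`` are alternatives); the
    slurry for FMT *k* is the fmt_slurry-phase sample with timepoint *k*;
    the post community is the recipient's post_fmt sample with timepoint
    *k*.  Only samples present in the table are considered, so this is
    naturally run on the rarefied table.
    """
    in_table = set(table.sample_ids)
    recs = [r for r in records if r.sample_id in in_table]
    base = _samples_by(recs, animal_id=recipient_id, phase="baseline")
    if not base:
        raise ValidationError(f"recipient {recipient_id} has no baseline sample")
    if baseline == "last":
        pre = presence_set(table, base[-1].sample_id)
    elif baseline == "first":
        pre = presence_set(table, base[0].sample_id)
    elif baseline == "union":
        pre = frozenset().union(*(presence_set(table, b.sample_id) for b in base))
    else:
        raise ValueError("baseline must be 'last', 'first' or 'union'")

    posts = _samples_by(recs, animal_id=recipient_id, phase="post_fmt")
    slurries = {r.timepoint: r for r in _samples_by(recs, phase="fmt_slurry")}
    triplets = []
    for post_rec in posts:
        k = post_rec.timepoint
        if fmt_indices is not None and k not in fmt_indices:
            continue
        if k not in slurries:
            continue
        triplets.append(
            CommunityTriplet(
                pre_set=pre,
                donor_set=presence_set(table, slurries[k].sample_id),
                post_set=presence_set(table, post_rec.sample_id),
                recipient_id=recipient_id,
                fmt_index=k,
            )
        )
    return triplets


def engraftment_table(
    table: FeatureTable,
    records: Sequence[SampleRecord],
    baseline: str = "last",
) -> pd.DataFrame:
    """Engraftment/exclusion statistics for every recipient and FMT index."""
    recipients = sorted({r.animal_id for r in records if r.role == "recipient"})
    rows = []
    for rid in recipients:
        for trip in build_triplets(table, records, rid, baseline=baseline):
            res = engraftment_stats(trip)
            rows.append(
                {
                    "recipient_id": res.recipient_id,
                    "fmt_index": res.fmt_index,
                    "n_introduced": res.n_introduced,
                    "n_engrafted": res.n_engrafted,
                    "engraftment_pct": res.engraftment_pct,
                    "n_excludable": res.n_excludable,
                    "n_excluded": res.n_excluded,
                    "exclusion_pct": res.exclusion_pct,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "recipient_id",
            "fmt_index",
            "n_introduced",
            "n_engrafted",
            "engraftment_pct",
            "n_excludable",
            "n_excluded",
            "exclusion_pct",
        ],
    )


def taxon_trajectory(
    table: FeatureTable,
    records: Sequence[SampleRecord],
    animal_id: str,
    taxon_ids: Sequence[str],
) -> pd.DataFrame:
    """Relative abundance of chosen taxa across one animal's samples.

    Rows are the animal's samples ordered by phase (baseline first) and
    timepoint; columns are taxa.  An absent taxon has abundance 0.
    """
    unknown = [t for t in taxon_ids if t not in table.feature_ids]
    if unknown:
        raise KeyError(f"unknown taxa: {unknown}")
    in_table = set(table.sample_ids)
    recs = [
        r for r in records if r.animal_id == animal_id and r.sample_id in in_table
    ]
    if not recs:
        raise KeyError(f"no samples for animal {animal_id!r}")
    phase_order = {"baseline": 0, "fmt_slurry": 1, "post_fmt": 2}
    recs = sorted(recs, key=lambda r: (phase_order[r.phase], r.timepoint))
    idx = [table.feature_ids.index(t) for t in taxon_ids]
    rows = []
    for rec in recs:
        col = table.sample_counts(rec.sample_id)
        total = col.sum()
        rel = col[idx] / total if total > 0 else np.zeros(len(idx))
        rows.append(rel)
    df = pd.DataFrame(
        rows,
        columns=list(taxon_ids),
        index=pd.MultiIndex.from_tuples(
            [(r.phase, r.timepoint, r.sample_id) for r in recs],
            names=["phase", "timepoint", "sample_id"],
        ),
    )
    return df


def donor_similarity_series(
    dm: DistanceMatrix,
    records: Sequence[SampleRecord],
    recipient_id: str,
) -> pd.Series:
    """Distance of each post-FMT sample to its administered slurry.

    Indexed by FMT number; missing slurry samples produce NaN gaps.
    """
    in_dm = set(dm.sample_ids)
    recs = [r for r in records if r.sample_id in in_dm]
    posts = _samples_by(recs, animal_id=recipient_id, phase="post_fmt")
    if not posts:
        raise ValidationError(f"recipient {recipient_id} has no post-FMT samples in matrix")
    slurries = {r.timepoint: r for r in _samples_by(recs, phase="fmt_slurry")}
    values, index = [], []
    for post_rec in posts:
        k = post_rec.timepoint
        index.append(k)
        if k in slurries:
            values.append(dm[post_rec.sample_id, slurries[k].sample_id])
        else:
            values.append(np.nan)
    return pd.Series(values, index=index, name=recipient_id)
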