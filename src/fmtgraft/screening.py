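"""Metagenomic donor screening against a list of candidate bacterial pathogens.

Candidate donor profiles are screened for known or suspected
dolphin-relevant bacterial pathogens.  Entries match either an exact
species binomial (case-insensitive) or a whole genus; per-entry relative
abundance is summed over matched features and compared against a
configurable threshold.  A donor fails when any entry reaches the
threshold (>= rule).

The shipped default list covers the taxa flagged as known or suspected
pathogens in bottlenose dolphins: Erysipelothrix rhusopathiae, Brucella
ceti, Mycobacterium marinum/chelonae/abscessus, Nocardia asteroides/
farcinica/brasiliensis/cyriacigeorgica/levis, Staphylococcus aureus,
Streptococcus phocae/zooepidemicus/iniae as species entries, and
Salmonella, Mycoplasma, Bartonella, Clostridium, and Escherichia as
genus entries (E. coli and Clostridium are screened at genus level;
toxin-gene assays are culture/PCR territory, out of scope here).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .profile_io import FeatureTable, ValidationError

__all__ = [
    "PathogenEntry",
    "PathogenList",
    "ScreeningReport",
    "DEFAULT_THRESHOLD",
    "default_pathogen_list",
    "load_pathogen_list",
    "match_pathogens",
    "screen_donor",
]

DEFAULT_THRESHOLD = 0.01  # relative abundance; "significant" is a policy choice

_DEFAULT_ENTRIES: tuple[tuple[str, str], ...] = (
    ("Erysipelothrix rhusopathiae", "species"),
    ("Brucella ceti", "species"),
    ("Mycobacterium marinum", "species"),
    ("Mycobacterium chelonae", "species"),
    ("Mycobacterium abscessus", "species"),
    ("Nocardia asteroides", "species"),
    ("Nocardia farcinica", "species"),
    ("Nocardia brasiliensis", "species"),
    ("Nocardia cyriacigeorgica", "species"),
    ("Nocardia levis", "species"),
    ("Staphylococcus aureus", "species"),
    ("Streptococcus phocae", "species"),
    ("Streptococcus zooepidemicus", "species"),
    ("Streptococcus iniae", "species"),
    ("Salmonella", "genus"),
    ("Mycoplasma", "genus"),
    ("Bartonella", "genus"),
    ("Clostridium", "genus"),
    ("Escherichia", "genus"),
)


@dataclass(frozen=True)
class PathogenEntry:
    name: str
    match_level: str  # species | genus
    threshold: float | None = None  # overrides the screen-wide threshold

    def __post_init__(self):
        if not self.name.strip():
            raise ValidationError("empty pathogen name")
        if self.match_level not in ("species", "genus"):
            raise ValidationError(f"unknown match level {self.match_level!r}")


@dataclass(frozen=True)
class PathogenList:
    entries: tuple[PathogenEntry, ...]

    def __post_init__(self):
        keys = [(e.name.lower(), e.match_level) for e in self.entries]
        if len(set(keys)) != len(keys):
            raise ValidationError("duplicate pathogen entries")
        object.__setattr__(self, "entries", tuple(self.entries))


@dataclass(frozen=True)
class ScreeningReport:
    sample_id: str
    threshold: float
    abundances: pd.Series  # per-entry relative abundance
    flagged: tuple[str, ...]  # entries at/over their threshold

    @property
    def passed(self) -> bool:
        return not self.flagged

    @property
    def verdict(self) -> str:
        return "pass" if self.passed else "fail"

    def to_frame(self) -> pd.DataFrame:
        df = self.abundances.rename("relative_abundance").to_frame()
        df["verdict"] = ["fail" if e in self.flagged else "pass" for e in df.index]
        df.index.name = "pathogen"
        return df


def default_pathogen_list() -> PathogenList:
    return PathogenList(tuple(PathogenEntry(n, lvl) for n, lvl in _DEFAULT_ENTRIES))


def load_pathogen_list(path: str | Path) -> PathogenList:
    """Load a YAML pathogen list.

    Format: a top-level ``pathogens`` sequence of mappings with keys
    ``name``, ``match_level`` and optional ``threshold``.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "pathogens" not in doc:
        raise ValidationError("pathogen config must have a top-level 'pathogens' list")
    entries = []
    for item in doc["pathogens"]:
        entries.append(
            PathogenEntry(
                name=str(item["name"]),
                match_level=str(item.get("match_level", "species")),
                threshold=(
                    float(item["threshold"]) if item.get("threshold") is not None else None
                ),
            )
        )
    return PathogenList(tuple(entries))


def _species_name(lineage: str) -> str | None:
    for part in (p.strip() for p in lineage.split(";")):
        if part.startswith("s__") and part[3:].strip():
            return part[3:].strip()
    return None


def _genus_name(lineage: str) -> str | None:
    for part in (p.strip() for p in lineage.split(";")):
        if part.startswith("g__") and part[3:].strip():
            return part[3:].strip()
    return None


def match_pathogens(
    table: FeatureTable, plist: PathogenList | None = None
) -> dict[str, list[str]]:
    """Map each pathogen entry to the feature ids it matches.

    Species entries match the lineage's species binomial exactly
    (case-insensitive); genus entries match every species of the genus.
    Genus matching requires lineages on the table.
    """
    if plist is None:
        plist = default_pathogen_list()
    needs_genus = any(e.match_level == "genus" for e in plist.entries)
    if table.lineages is None:
        if needs_genus:
            raise ValidationError("genus-level screening requires lineages")
        lineages = {}
    else:
        lineages = table.lineages
    matches: dict[str, list[str]] = {e.name: [] for e in plist.entries}
    for fid in table.feature_ids:
        lineage = lineages.get(fid, "")
        species = _species_name(lineage)
        genus = _genus_name(lineage)
        if species is None and lineage == "":
            # a bare feature id may itself be a species binomial
            species = fid
        for entry in plist.entries:
            if entry.match_level == "species":
                if species is not None and species.lower() == entry.name.lower():
                    matches[entry.name].append(fid)
            else:
                target = genus
                if target is None and species is not None:
                    target = species.split()[0]
                if target is not None and target.lower() == entry.name.lower():
                    matches[entry.name].append(fid)
    return matches


def screen_donor(
    table: FeatureTable,
    sample_id: str,
    plist: PathogenList | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> ScreeningReport:
    """Screen one sample's profile against the pathogen list.

    Per-entry relative abundance is the summed proportion of the sample's
    reads over all matched features; the entry is flagged when it is at or
    above its threshold (per-entry override, else ``threshold``).
    """
    if not (0 <= threshold <= 1):
        raise ValueError("threshold must be a relative abundance in [0, 1]")
    if plist is None:
        plist = default_pathogen_list()
    rel = table.relative_abundance(sample_id)  # raises KeyError on unknown sample
    matches = match_pathogens(table, plist)
    abundances = {}
    flagged = []
    for entry in plist.entries:
        ab = sum(rel.get(f, 0.0) for f in matches[entry.name])
        abundances[entry.name] = ab
        cutoff = entry.threshold if entry.threshold is not None else threshold
        if ab >= cutoff:
            flagged.append(entry.name)
    return ScreeningReport(
        sample_id=sample_id,
        threshold=threshold,
        abundances=pd.Series(abundances, name=sample_id),
        flagged=tuple(flagged),
    )
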