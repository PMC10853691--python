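"""Permutation tests on distance matrices and longitudinal distance series.

PERMANOVA partitions the sum of squared dissimilarities among groups and
tests the pseudo-F statistic by permuting group labels; PERMDISP tests
homogeneity of group dispersions (distances to group centroids in PCoA
space, negative-eigenvalue axes dropped).  Both report permutation
p-values as (b + 1) / (m + 1) and support exhaustive enumeration on small
designs.  Welch's unequal-variance t-test is included for group
comparisons of scalar summaries (alpha diversity, dispersions).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .diversity import DistanceMatrix, pcoa
from .profile_io import SampleRecord, ValidationError

__all__ = [
    "PermTestResult",
    "TTestResult",
    "permanova",
    "permdisp",
    "welch_t",
    "distance_from_baseline",
]

_EXHAUSTIVE_LIMIT = 9  # N! enumeration cap


@dataclass(frozen=True)
class PermTestResult:
    method: str
    statistic: float
    p_value: float
    n_permutations: int
    seed: int | None
    r_squared: float | None = None
    dispersions: pd.Series | None = None  # PERMDISP only

    def __post_init__(self):
        if self.r_squared is not None and not (0 <= self.r_squared <= 1 + 1e-12):
            raise ValidationError("R^2 outside [0, 1]")


@dataclass(frozen=True)
class TTestResult:
    t_statistic: float
    p_value: float


def _resolve_grouping(dm: DistanceMatrix, grouping) -> np.ndarray:
    if isinstance(grouping, Mapping):
        missing = [s for s in dm.sample_ids if s not in grouping]
        if missing:
            raise ValidationError(f"samples without group label: {missing}")
        labels = [grouping[s] for s in dm.sample_ids]
    else:
        labels = list(grouping)
        if len(labels) != len(dm.sample_ids):
            raise ValidationError("grouping length does not match distance matrix")
    _, codes = np.unique(labels, return_inverse=True)
    n_groups = codes.max() + 1
    if n_groups < 2:
        raise ValidationError("PERMANOVA/PERMDISP require at least two groups")
    if np.bincount(codes).max() == len(codes):
        raise ValidationError("a single group spans all samples (degenerate)")
    return codes


def _permutation_indices(n: int, n_perm, rng: np.random.Generator | None):
    """Yield permutations of range(n): random draws or full enumeration."""
    if n_perm == "exhaustive":
        if n > _EXHAUSTIVE_LIMIT:
            raise ValidationError(
                f"exhaustive enumeration limited to {_EXHAUSTIVE_LIMIT} samples"
            )
        return np.array(list(itertools.permutations(range(n))), dtype=np.intp), True
    perms = np.empty((int(n_perm), n), dtype=np.intp)
    for i in range(int(n_perm)):
        perms[i] = rng.permutation(n)
    return perms, False


# -- PERMANOVA -----------------------------------------------------------------


def _permanova_f(d2: np.ndarray, codes: np.ndarray, n_groups: int):
    """Pseudo-F and R^2 for one labeling. d2 is the squared-distance matrix."""
    n = len(codes)
    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2 * idx.size)
    ss_between = ss_total - ss_within
    df_between = n_groups - 1
    df_within = n - n_groups
    if df_within <= 0:
        raise ValidationError("no residual degrees of freedom")
    f = (ss_between / df_between) / (ss_within / df_within)
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return f, r2


def _permuted_f_values(d2: np.ndarray, codes: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """Pseudo-F for every row of ``perms`` (permutations of sample indices)."""
    n = len(codes)
    n_groups = codes.max() + 1
    ss_total = d2.sum() / (2 * n)
    permuted_codes = codes[perms]  # (m, n)
    ss_within = np.zeros(perms.shape[0])
    for g in range(n_groups):
        mask = (permuted_codes == g).astype(float)
        n_g = int((codes == g).sum())
        ss_within += np.einsum("pi,ij,pj->p", mask, d2, mask) / (2 * n_g)
    ss_between = ss_total - ss_within
    df_b = n_groups - 1
    df_w = n - n_groups
    with np.errstate(divide="ignore", invalid="ignore"):
        return (ss_between / df_b) / (ss_within / df_w)


def permanova(
    dm: DistanceMatrix,
    grouping,
    n_perm: int | str = 999,
    seed: int | None = 0,
) -> PermTestResult:
    """Permutational multivariate analysis of variance on a distance matrix.

    ``grouping`` maps sample ids to group labels (or is a sequence aligned
    with ``dm.sample_ids``).  ``n_perm`` may be ``"exhaustive"`` to
    enumerate all labelings on small designs, in which case the p-value is
    the exact tail probability; otherwise p = (b + 1) / (m + 1) where b
    counts permuted pseudo-F values >= the observed one.
    """
    codes = _resolve_grouping(dm, grouping)
    n_groups = int(codes.max() + 1)
    d2 = dm.values**2
    f_obs, r2 = _permanova_f(d2, codes, n_groups)
    rng = np.random.default_rng(seed)
    perms, exhaustive = _permutation_indices(len(codes), n_perm, rng)
    f_perm = _permuted_f_values(d2, codes, perms)
    if exhaustive:
        p = float(np.mean(f_perm >= f_obs - 1e-12))
        m = perms.shape[0]
    else:
        b = int(np.sum(f_perm >= f_obs - 1e-12))
        m = perms.shape[0]
        p = (b + 1) / (m + 1)
    return PermTestResult(
        method="permanova",
        statistic=float(f_obs),
        p_value=p,
        n_permutations=m,
        seed=seed,
        r_squared=float(np.clip(r2, 0.0, 1.0)),
    )


# -- PERMDISP ------------------------------------------------------------------


def _dispersions(coords: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Distance of every sample to its own group centroid in PCoA space."""
    z = np.empty(len(codes))
    for g in range(codes.max() + 1):
        idx = np.flatnonzero(codes == g)
        centroid = coords[idx].mean(axis=0)
        z[idx] = np.linalg.norm(coords[idx] - centroid, axis=1)
    return z


def _anova_f(z: np.ndarray, codes: np.ndarray) -> float:
    groups = [z[codes == g] for g in range(codes.max() + 1)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant groups give F = 0/0
        f = scipy.stats.f_oneway(*groups).statistic
    return 0.0 if math.isnan(f) else float(f)


def permdisp(
    dm: DistanceMatrix,
    grouping,
    n_perm: int | str = 999,
    seed: int | None = 0,
) -> PermTestResult:
    """Test homogeneity of multivariate dispersions (Anderson's PERMDISP).

    Samples are embedded by PCoA (axes with negative eigenvalues are
    dropped), dispersion is each sample's Euclidean distance to its group
    centroid, and the one-way ANOVA F on dispersions is tested by
    permuting group labels, recomputing centroids each time.
    """
    codes = _resolve_grouping(dm, grouping)
    coords = pcoa(dm).coordinates
    z_obs = _dispersions(coords, codes)
    f_obs = _anova_f(z_obs, codes)
    rng = np.random.default_rng(seed)
    perms, exhaustive = _permutation_indices(len(codes), n_perm, rng)
    f_perm = np.empty(perms.shape[0])
    for i, perm in enumerate(perms):
        permuted = codes[perm]
        f_perm[i] = _anova_f(_dispersions(coords, permuted), permuted)
    if exhaustive:
        p = float(np.mean(f_perm >= f_obs - 1e-12))
        m = perms.shape[0]
    else:
        b = int(np.sum(f_perm >= f_obs - 1e-12))
        m = perms.shape[0]
        p = (b + 1) / (m + 1)
    return PermTestResult(
        method="permdisp",
        statistic=f_obs,
        p_value=p,
        n_permutations=m,
        seed=seed,
        dispersions=pd.Series(z_obs, index=list(dm.sample_ids), name="dispersion"),
    )


# -- t-test --------------------------------------------------------------------


def welch_t(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Two-sided Welch unequal-variance t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("Welch t-test needs at least two values per group")
    res = scipy.stats.ttest_ind(x, y, equal_var=False)
    return TTestResult(t_statistic=float(res.statistic), p_value=float(res.pvalue))


# -- longitudinal series -------------------------------------------------------


def distance_from_baseline(
    dm: DistanceMatrix,
    records: Sequence[SampleRecord],
    baseline: str = "last",
) -> dict[str, pd.Series]:
    """Per-animal series of dissimilarity to the animal's baseline community.

    For every animal with at least one baseline sample, returns the
    distance from each of its post-FMT-phase samples to the designated
    baseline sample, ordered by timepoint.  ``baseline`` chooses the
    anchor: ``"last"`` (default) or ``"first"`` baseline sample by
    timepoint, or ``"mean"`` for the average distance to all baseline
    samples.  Animals lacking a baseline are skipped with a warning.
    """
    if baseline not in ("last", "first", "mean"):
        raise ValueError("baseline must be 'last', 'first' or 'mean'")
    in_dm = set(dm.sample_ids)
    by_animal: dict[str, list[SampleRecord]] = {}
    for rec in records:
        if rec.role == "slurry" or rec.sample_id not in in_dm:
            continue
        by_animal.setdefault(rec.animal_id, []).append(rec)

    out: dict[str, pd.Series] = {}
    for animal, recs in by_animal.items():
        base = sorted(
            (r for r in recs if r.phase == "baseline"), key=lambda r: r.timepoint
        )
        post = sorted(
            (r for r in recs if r.phase == "post_fmt"), key=lambda r: r.timepoint
        )
        if not base:
            warnings.warn(f"animal {animal} has no baseline sample; skipped", stacklevel=2)
            continue
        if not post:
            continue
        if baseline == "mean":
            values = [
                float(np.mean([dm[p.sample_id, b.sample_id] for b in base]))
                for p in post
            ]
        else:
            anchor = base[-1] if baseline == "last" else base[0]
            values = [dm[p.sample_id, anchor.sample_id] for p in post]
        out[animal] = pd.Series(
            values, index=[p.timepoint for p in post], name=animal
        )
    return out
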