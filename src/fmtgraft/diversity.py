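"""Alpha diversity, beta-diversity metrics, and principal coordinate analysis.

Shannon diversity is computed per sample.  Pairwise dissimilarities support
Bray-Curtis and the two UniFrac variants (unweighted presence/absence and
weighted abundance, Lozupone & Knight); the UniFrac kernels are scikit-bio's.
PCoA follows Gower double-centering: negative eigenvalues are reported as-is
and their axes omitted from the coordinates, with no Cailliez/Lingoes
correction applied by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.spatial.distance
import scipy.stats
from skbio import TreeNode
from skbio.diversity import beta_diversity as _skbio_beta_diversity

from .profile_io import FeatureTable, ValidationError

__all__ = [
    "DistanceMatrix",
    "Ordination",
    "METRICS",
    "shannon",
    "alpha_diversity_table",
    "bray_curtis",
    "unweighted_unifrac",
    "weighted_unifrac",
    "pairwise_distances",
    "pcoa",
]

METRICS = ("bray_curtis", "unweighted_unifrac", "weighted_unifrac")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise sample dissimilarities with a metric label."""

    sample_ids: tuple[str, ...]
    values: np.ndarray
    metric: str

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise ValidationError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValidationError("distance matrix diagonal must be zero")
        if v.size and v.min() < 0:
            raise ValidationError("distances must be non-negative")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        i = self.sample_ids.index(a)
        j = self.sample_ids.index(b)
        return float(self.values[i, j])

    def filter(self, keep: list[str]) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in keep]
        return DistanceMatrix(tuple(keep), self.values[np.ix_(idx, idx)], self.metric)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.sample_ids)
        )

    def write_tsv(self, path) -> None:
        df = self.to_dataframe()
        df.index.name = self.metric
        df.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(tuple(str(c) for c in df.columns), df.to_numpy(float), df.index.name or "")


@dataclass(frozen=True)
class Ordination:
    """PCoA result: centered coordinates on positive-eigenvalue axes."""

    sample_ids: tuple[str, ...]
    coordinates: np.ndarray  # samples x axes
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    proportion_explained: np.ndarray
    negative_eigenvalues: np.ndarray  # reported, axes omitted


# -- alpha ---------------------------------------------------------------------


def shannon(counts, log_base: float = 2.0) -> float:
    """Shannon diversity H = -sum p_i log_base(p_i) over positive proportions."""
    x = np.asarray(counts, dtype=float)
    if x.size == 0 or x.sum() <= 0:
        raise ValidationError("Shannon diversity is undefined for an empty sample")
    if np.any(x < 0):
        raise ValidationError("negative counts")
    if log_base <= 1:
        raise ValueError("log_base must be > 1")
    return float(scipy.stats.entropy(x[x > 0]) / np.log(log_base))


def alpha_diversity_table(table: FeatureTable, log_base: float = 2.0) -> pd.Series:
    """Shannon index for every sample, as a Series indexed by sample id."""
    return pd.Series(
        {sid: shannon(table.sample_counts(sid), log_base) for sid in table.sample_ids},
        name=f"shannon_base{log_base:g}",
    )


# -- beta: scalar kernels ------------------------------------------------------


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity 1 - 2*sum(min)/(sum x + sum y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("count vectors must have equal length")
    if x.sum() == 0 and y.sum() == 0:
        raise ValidationError("Bray-Curtis undefined when both samples are empty")
    return float(scipy.spatial.distance.braycurtis(x, y))


def _tip_counts(members, feature_ids) -> np.ndarray:
    members = set(members)
    return np.array([1 if f in members else 0 for f in feature_ids])


def unweighted_unifrac(x, y, tree: TreeNode, feature_ids=None) -> float:
    """Unweighted UniFrac between two presence sets of tree tips.

    ``x`` and ``y`` may be sets of tip names or count vectors aligned to
    ``feature_ids``.  Fraction of observed branch length leading to tips
    found in exactly one of the two communities.
    """
    from skbio.diversity.beta import unweighted_unifrac as _uu

    if isinstance(x, (set, frozenset)):
        if feature_ids is None:
            feature_ids = sorted(set(x) | set(y))
        x = _tip_counts(x, feature_ids)
        y = _tip_counts(y, feature_ids)
    if feature_ids is None:
        raise ValueError("feature_ids required for count-vector input")
    x = np.asarray(x)
    y = np.asarray(y)
    if x.sum() == 0 or y.sum() == 0:
        raise ValidationError("UniFrac requires non-empty communities")
    return float(_uu(x, y, taxa=list(feature_ids), tree=tree))


def weighted_unifrac(
    x, y, tree: TreeNode, feature_ids, normalized: bool = False
) -> float:
    """Weighted UniFrac sum_b l_b |p_b(x) - p_b(y)| over branches.

    ``p_b(s)`` is the fraction of sample ``s``'s reads on tips below branch
    ``b``.  With ``normalized=True`` the sum is divided by
    ``sum_b l_b (p_b(x) + p_b(y))``, bounding the result in [0, 1].
    """
    from skbio.diversity.beta import weighted_unifrac as _wu

    x = np.asarray(x)
    y = np.asarray(y)
    if x.sum() == 0 or y.sum() == 0:
        raise ValidationError("UniFrac requires non-empty communities")
    return float(_wu(x, y, taxa=list(feature_ids), tree=tree, normalized=normalized))


# -- beta: full matrices -------------------------------------------------------


def pairwise_distances(
    table: FeatureTable,
    metric: str,
    tree: TreeNode | None = None,
    normalized: bool = False,
) -> DistanceMatrix:
    """Full symmetric dissimilarity matrix over the table's samples.

    Presence for the unweighted metric is count >= 1.  A tree is required
    for the UniFrac metrics and every feature must be one of its tips.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    data = table.counts.T  # samples x features
    ids = list(table.sample_ids)
    if metric == "bray_curtis":
        dm = _skbio_beta_diversity("braycurtis", data, ids=ids)
    else:
        if tree is None:
            raise ValidationError(f"metric {metric} requires a phylogenetic tree")
        kwargs = dict(taxa=list(table.feature_ids), tree=tree)
        if metric == "weighted_unifrac":
            kwargs["normalized"] = normalized
        dm = _skbio_beta_diversity(metric, data, ids=ids, **kwargs)
    label = metric if metric != "weighted_unifrac" or not normalized else (
        "weighted_unifrac_normalized"
    )
    return DistanceMatrix(tuple(ids), dm.data, label)


# -- ordination ----------------------------------------------------------------


def pcoa(dm: DistanceMatrix, n_axes: int | None = None, eig_tol: float = 1e-9) -> Ordination:
    """Principal coordinate analysis by Gower double-centering.

    B = -1/2 * J D^2 J with J the centering matrix; coordinates are
    eigenvectors scaled by sqrt(eigenvalue) for eigenvalues above
    ``eig_tol`` (relative to the largest).  Negative eigenvalues are
    reported but contribute no axes.
    """
    n = len(dm.sample_ids)
    if n < 2:
        raise ValidationError("PCoA requires at least two samples")
    d2 = dm.values**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = scipy.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    scale = max(abs(eigvals[0]), 1.0) if eigvals.size else 1.0
    pos = eigvals > eig_tol * scale
    neg = eigvals < -eig_tol * scale
    pos_vals = eigvals[pos]
    coords = eigvecs[:, pos] * np.sqrt(pos_vals)
    if n_axes is not None:
        if n_axes > pos_vals.size:
            warnings.warn(
                f"requested {n_axes} axes but only {pos_vals.size} positive "
                f"eigenvalues; truncating",
                stacklevel=2,
            )
        coords = coords[:, :n_axes]
        pos_vals_out = pos_vals[:n_axes]
    else:
        pos_vals_out = pos_vals
    total = pos_vals.sum() if pos_vals.size else 1.0
    return Ordination(
        sample_ids=dm.sample_ids,
        coordinates=coords,
        eigenvalues=pos_vals_out,
        proportion_explained=pos_vals_out / total,
        negative_eigenvalues=eigvals[neg],
    )
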