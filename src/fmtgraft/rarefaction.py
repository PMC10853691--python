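"""Rarefaction: per-sample subsampling without replacement to a fixed depth.

Each sample's count vector is reduced to exactly ``depth`` reads by a
multivariate hypergeometric draw (sampling reads without replacement), so
no feature's rarefied count can exceed its original count.  Samples whose
total is below the depth are dropped and reported.

Each sample gets its own RNG stream derived from ``(seed, sample_id)``,
so adding or removing a sample from a table never perturbs the draw for
any other sample.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .profile_io import FeatureTable, ValidationError

__all__ = ["RarefactionConfig", "RarefactionReport", "rarefy", "sample_rng"]

DEFAULT_DEPTH = 1070


@dataclass(frozen=True)
class RarefactionConfig:
    """Settings for one rarefaction pass.

    depth
        Target reads per sample (default 1070).
    seed
        Master seed; combined with each sample id to give per-sample streams.
    drop_below_depth
        Drop (and report) samples with fewer than ``depth`` total reads.
        When False, shallow samples are a hard error.
    """

    depth: int = DEFAULT_DEPTH
    seed: int = 0
    drop_below_depth: bool = True

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("rarefaction depth must be >= 1")


@dataclass(frozen=True)
class RarefactionReport:
    depth: int
    seed: int
    dropped: tuple[str, ...]  # samples with total < depth
    dropped_totals: tuple[int, ...]


def sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    """Deterministic per-sample generator keyed on (seed, sample_id)."""
    key = tuple(sample_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def rarefy(
    table: FeatureTable, config: RarefactionConfig | None = None, **kwargs
) -> tuple[FeatureTable, RarefactionReport]:
    """Subsample every sample to ``config.depth`` reads without replacement.

    Returns the rarefied table (retained samples only, each summing to
    exactly the depth) and a report listing dropped samples.  Deterministic
    for a fixed seed.
    """
    if config is None:
        config = RarefactionConfig(**kwargs)
    totals = table.sample_sums()
    deep_enough = totals >= config.depth
    if not deep_enough.any():
        raise ValidationError(
            f"all {table.n_samples} samples are below rarefaction depth {config.depth}"
        )
    if not config.drop_below_depth and not deep_enough.all():
        shallow = [s for s, ok in zip(table.sample_ids, deep_enough) if not ok]
        raise ValidationError(f"samples below depth {config.depth}: {shallow}")

    keep_ids = [s for s, ok in zip(table.sample_ids, deep_enough) if ok]
    cols = []
    for sid in keep_ids:
        col = table.sample_counts(sid)
        if col.sum() == config.depth:
            cols.append(col)
        else:
            rng = sample_rng(config.seed, sid)
            cols.append(rng.multivariate_hypergeometric(col, config.depth))
    rarefied = replace(
        table,
        sample_ids=tuple(keep_ids),
        counts=np.column_stack(cols).astype(np.int64),
    )
    dropped = [
        (s, int(t)) for s, t, ok in zip(table.sample_ids, totals, deep_enough) if not ok
    ]
    report = RarefactionReport(
        depth=config.depth,
        seed=config.seed,
        dropped=tuple(s for s, _ in dropped),
        dropped_totals=tuple(t for _, t in dropped),
    )
    return rarefied, report
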