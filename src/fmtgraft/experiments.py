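"""Calibration experiments run on synthetic data.

Two standing checks of the statistical machinery under known truth:

* type-I error of PERMANOVA under a true null (all samples drawn from one
  latent community, labels arbitrary) — the rejection rate at alpha
  should match alpha;
* recovery of the engraftment probability: the engraftment rate estimated
  by the presence-set statistics from sequenced profiles should match the
  generative ``p_e`` when enough taxa are introduced and sequencing is
  deep enough for reliable detection.

These functions are used by the analysis drivers, the test suite, and
the acceptance script; they are deterministic for a fixed seed.
"""

from __future__ import annotations

import numpy as np

from .diversity import pairwise_distances
from .profile_io import FeatureTable
from .simulate import (
    CohortParams,
    simulate_baseline_communities,
    simulate_post_fmt_series,
    simulate_taxonomy,
    _rng,
)
from .stats import permanova
from .tracking import CommunityTriplet, engraftment_stats

__all__ = [
    "permanova_type_i_error",
    "engraftment_recovery",
    "recovery_params",
]


def permanova_type_i_error(
    n_sims: int = 1000,
    n_per_group: int = 6,
    n_taxa: int = 200,
    depth: int = 2000,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of null datasets rejected by PERMANOVA at ``alpha``.

    Each simulated dataset draws ``2 * n_per_group`` samples multinomially
    from the same heavy-tailed latent composition and splits them into two
    arbitrary groups; Bray-Curtis distances are tested with ``n_perm``
    label permutations.  Under the null the rejection rate is ``alpha``.
    """
    master = _rng(seed, "type1")
    labels = ["g1"] * n_per_group + ["g2"] * n_per_group
    rejections = 0
    for _ in range(n_sims):
        comp = master.lognormal(0.0, 1.5, size=n_taxa)
        comp /= comp.sum()
        counts = master.multinomial(depth, comp, size=2 * n_per_group).T
        table = FeatureTable(
            feature_ids=tuple(f"t{i}" for i in range(n_taxa)),
            sample_ids=tuple(f"s{i}" for i in range(2 * n_per_group)),
            counts=counts,
        )
        dm = pairwise_distances(table, "bray_curtis")
        res = permanova(
            dm, labels, n_perm=n_perm, seed=int(master.integers(2**31))
        )
        if res.p_value <= alpha:
            rejections += 1
    return rejections / n_sims


def recovery_params(p_e: float, seed: int = 0) -> CohortParams:
    """Cohort settings for engraftment-probability recovery.

    A deep-sequencing, single-recipient design: 1500 taxa, three pooled
    donors, depth 50 000 with no depth noise, moderate compositional skew
    so the rarest carried taxa still yield several expected reads, no
    dysbiosis override, and no drift between transplant and sampling.
    With ~50% carriage this yields well over 500 introduced taxa.
    """
    return CohortParams(
        n_taxa=1500,
        n_donors=3,
        n_recipients=1,
        n_controls=0,
        n_fmts=1,
        depth_mean=50_000,
        depth_dispersion=0.0,
        concentration=2.0,
        donor_overlap=0.0,
        peripheral_carriage=0.5,
        engraftment_prob=p_e,
        exclusion_prob=0.3,
        drift_rate=0.0,
        engraft_noise=0.25,
        dysbiosis_spec={},
        seed=seed,
    )


def _one_recovery(p_e: float, seed: int):
    """Simulate pre/slurry/post for one recipient and estimate rates.

    Returns (estimated engraftment rate, n_introduced measured,
    ground-truth realized rate, classification agreement over the
    measured introduced set).
    """
    params = recovery_params(p_e, seed=seed)
    feature_ids, lineages = simulate_taxonomy(params.n_taxa, params.seed)
    table, records, latents = simulate_baseline_communities(
        params, feature_ids=feature_ids, lineages=lineages
    )
    rng = _rng(params.seed, "recovery")
    donors = [latents[f"D{i + 1}"] for i in range(params.n_donors)]
    weights = rng.dirichlet(np.ones(params.n_donors))
    slurry_comp = sum(w * d for w, d in zip(weights, donors))
    slurry_comp = slurry_comp / slurry_comp.sum()
    slurry_counts = rng.multinomial(int(params.depth_mean), slurry_comp)

    samples, truth = simulate_post_fmt_series(
        latents["R1"],
        [slurry_comp],
        params,
        seed=params.seed,
        feature_ids=feature_ids,
    )
    pre_counts = table.sample_counts(f"R1_B{params.n_baseline_per_animal - 1}")
    to_set = lambda col: frozenset(
        f for f, c in zip(feature_ids, col) if c >= 1
    )
    triplet = CommunityTriplet(
        pre_set=to_set(pre_counts),
        donor_set=to_set(slurry_counts),
        post_set=to_set(samples[0]),
        recipient_id="R1",
    )
    res = engraftment_stats(triplet)
    true_engrafted = frozenset(truth["1"]["engrafted"])
    measured_introduced = triplet.donor_set - triplet.pre_set
    measured_engrafted = measured_introduced & triplet.post_set
    disagree = len(
        (measured_engrafted ^ true_engrafted) & measured_introduced
    )
    agreement = 1.0 - disagree / max(len(measured_introduced), 1)
    realized = len(true_engrafted) / max(len(truth["1"]["introduced"]), 1)
    return res.engraftment_rate, res.n_introduced, realized, agreement


def engraftment_recovery(
    p_e: float = 0.3, n_sims: int = 1, seed: int = 0
) -> dict[str, float]:
    """Estimate the engraftment probability from simulated cohorts.

    Returns the mean estimated rate, the mean number of introduced taxa,
    the mean generative realized rate, and the mean classification
    agreement between measured and latent engraftment calls.
    """
    rates, ns, realized, agreements = [], [], [], []
    for i in range(n_sims):
        r, n, tr, ag = _one_recovery(p_e, seed=seed + i)
        rates.append(r)
        ns.append(n)
        realized.append(tr)
        agreements.append(ag)
    return {
        "p_e": p_e,
        "estimated_rate": float(np.mean(rates)),
        "mean_n_introduced": float(np.mean(ns)),
        "realized_rate": float(np.mean(realized)),
        "agreement": float(np.mean(agreements)),
        "n_sims": n_sims,
    }
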