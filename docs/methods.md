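# Methods

`fmtgraft` analyzes longitudinal fecal-microbiota-transplant (FMT) studies
from species-level shotgun taxonomic profiles. The package was built around
a dolphin FMT study design — healthy donor animals, a small number of
recipients (one clinically dysbiotic), untreated controls, pooled
multi-donor slurries, and repeated transplants with interleaved sampling —
but every component operates on generic feature tables, sample metadata,
and a phylogeny, and the synthetic cohort generator lets the entire
pipeline run and be validated with no external data.

## Inputs and reconciliation

The pipeline consumes a features-by-samples integer count table (TSV,
features as rows, first header cell `#OGU_ID`), per-sample metadata
(`sample_id`, `animal_id`, `role` in {donor, recipient, control, slurry},
`phase` in {baseline, fmt_slurry, post_fmt}, integer `timepoint`), an
optional two-column lineage file with semicolon-ranked strings
(`k__;p__;c__;o__;f__;g__;s__`), and a rooted Newick tree over the feature
ids with branch lengths on every non-root edge. Features here are OGUs
(operational genomic units — genome-resolved taxa from reference-based
shotgun classification, the shotgun analogue of OTUs/ASVs).

Reconciliation restricts the table to samples present in both table and
metadata and to features that are tips of the tree, reporting every
dropped id; identifier matching is exact, case-sensitive string equality
to avoid silent mis-joins. Rank collapsing sums counts within each label
at the requested rank, pools features lacking that rank under
`Unclassified`, and preserves per-sample totals exactly.

## Rarefaction

Each sample is subsampled **without replacement** to a fixed depth
(default 1070 reads) via a multivariate hypergeometric draw, so no
feature's rarefied count can exceed its raw count and retained column
sums equal the depth exactly. Samples below the depth are dropped and
reported. One draw is made per sample (no averaging over repeated
rarefactions). Each sample's RNG stream is derived from
`(seed, sample_id)` through a `SeedSequence` spawn key, so editing the
sample set never perturbs the draw for any other sample.

## Diversity

* **Shannon index** H = −Σ pᵢ·log pᵢ over positive proportions, log base
  2 by default (configurable); undefined (an error) on empty samples.
* **Bray–Curtis** 1 − 2·Σ min(xᵢ, yᵢ)/(Σx + Σy), via scipy.
* **Unweighted UniFrac**: fraction of observed branch length leading to
  tips present in exactly one of the two communities; **weighted
  UniFrac**: Σ_b l_b·|p_b(x) − p_b(y)| over branches, where p_b(s) is the
  fraction of sample s's reads below branch b, optionally normalized by
  Σ_b l_b·(p_b(x) + p_b(y)). Both are computed by scikit-bio's kernels;
  the test suite checks them against explicit per-branch enumeration on
  small trees, and against the Jaccard distance on star trees (to which
  unweighted UniFrac reduces).
* Presence for the unweighted metric is count ≥ 1 on the rarefied table,
  keeping the detection limit uniform across samples.
* **PCoA** uses Gower double-centering B = −½·J·D²·J and a symmetric
  eigendecomposition; coordinates are eigenvectors scaled by √λ for
  eigenvalues above 1e−9 (relative to the largest magnitude). Negative
  eigenvalues — expected for non-Euclidean dissimilarities like
  Bray–Curtis — are reported as-is and contribute no axes; no
  Cailliez/Lingoes correction is applied, favouring transparency over a
  corrected embedding. Proportion explained is taken over the positive
  eigenvalues.

## Permutation tests

**PERMANOVA** partitions the squared dissimilarities: SS_total =
Σ_{i<j} d²ᵢⱼ/N, SS_within = Σ_groups Σ_{i<j∈g} d²ᵢⱼ/n_g, pseudo-F =
(SS_between/(a−1))/(SS_within/(N−a)), R² = SS_between/SS_total. The
p-value permutes group labels: p = (b+1)/(m+1) with m = 999 by default,
where b counts permuted F values ≥ the observed (a tolerance of 1e−12
guards float ties). On designs of at most 9 samples `n_perm="exhaustive"`
enumerates every labeling and returns the exact tail probability.
Permuted F values are computed vectorized via group-indicator quadratic
forms, which keeps the 1000-dataset null calibration below a minute.

**PERMDISP** embeds the samples by the PCoA above (negative-eigenvalue
axes dropped — a deliberate simplification relative to implementations
that let those axes contribute negatively), computes each sample's
Euclidean distance to its group centroid, and tests the one-way ANOVA F
on those dispersions by permuting group labels with centroids recomputed
per permutation (Anderson's centroid variant). Group-size-degenerate
F values (0/0) are reported as 0.

**Welch's t** (unequal variances, two-sided) serves the scalar group
comparisons: Shannon values and dispersion vectors.

**Distance-from-baseline series**: for each animal, the dissimilarity of
every post-FMT-phase sample to the animal's designated baseline sample,
ordered by timepoint. The anchor is the last baseline sample before
treatment (temporally closest), configurable to the first sample or the
mean distance over all baseline samples. Animals lacking a baseline are
skipped with a warning.

## Engraftment and exclusion tracking

The communities around one FMT are reduced to presence sets on the
rarefied table: the recipient pre-FMT community (last baseline sample by
default; first or union-of-baselines configurable), the administered
donor slurry, and the recipient post-FMT sample for that transplant.
Then, per FMT:

* **introduced** = donor ∖ pre; **engrafted** = introduced ∩ post;
* **excludable** = pre ∖ donor; **excluded** = excludable ∖ post;
* rates are engrafted/introduced and excluded/excludable, with integer
  percents rounded half away from zero.

A rate with a zero denominator (e.g. the slurry introduces nothing) is
flagged as undefined (`None`), never silently NaN. The headline numbers
use the first post-FMT sample; the full per-FMT table for all eight
transplants is always emitted. The seven-region Venn partition of
pre/donor/post is reported with percentages of the union. Taxon
trajectories (per-taxon relative abundance through an animal's samples)
and donor-similarity series (distance of each post-FMT sample to its
administered slurry) complete the longitudinal picture.

Sensitivity note: presence is decided after rarefaction, so taxa whose
abundance sits near 1/depth blink in and out of detection; measured
engraftment rates therefore sit at or slightly below the latent transfer
probability at shallow depth. The calibration experiment (below)
quantifies this.

## Donor screening

Donor profiles are screened against a configurable list of candidate
bacterial pathogens relevant to bottlenose dolphins (shipped as YAML and
as a built-in default). Species entries match the lineage's species
binomial case-insensitively; genus entries match every species of the
genus. E. coli and Clostridium are screened at genus level — toxin-gene
detection is culture/PCR territory and out of scope for abundance-based
screening. Per-entry relative abundance is summed over matched features;
an entry at or above its threshold (boundary inclusive) flags the donor,
and any flagged entry fails the sample. The default threshold is 1%
relative abundance per entry: "significant abundance" has no published
operational cutoff, so this is a deliberately conservative, user-visible
policy default, overridable globally or per entry.

## Synthetic cohorts

The generator emulates the study structure: 7 donors, 4 recipients (the
first dysbiotic), 3 controls, 3 baseline samples per animal, and 8 FMTs,
each with one pooled slurry sample and one post-FMT sample per recipient
(controls are sampled on the same schedule), 106 samples in all.

* **Taxon pool**: default 300 OGUs across ~20 phyla, with two phyla
  (Firmicutes at 0.45 and Proteobacteria at 0.38 of base mass) dominating
  — communities where two phyla comprise >80% of reads, as reported for
  dolphin guts. Three designated pathogen species (*Paeniclostridium
  sordellii*, *Clostridium perfringens*, *Photobacterium damselae*) carry
  real lineages; all other lineages are synthetic placeholders.
* **Carriage**: a shared core (fraction `donor_overlap`, default 0.3, of
  the pool) carried by every animal, plus independent Bernoulli(0.3)
  peripheral carriage. Donors never carry the designated pathogens (they
  are screened animals), so simulated donors pass the default screen.
* **Latent compositions**: per-taxon base abundances (phylum mass split
  evenly within phylum) perturbed log-normally with σ = 1/√concentration
  (default concentration 0.25, σ = 2 — strongly uneven, dominance-prone
  communities; concentration → ∞ recovers the uniform limit).
* **Dysbiosis**: the first recipient's pathogens are pinned to relative
  abundances 0.5000/0.2037/0.1692 (87.29% total) with the rest of its
  community rescaled; after each FMT the pathogen abundances are
  multiplied by 0.02 per step, emulating clearance.
* **Sampling**: multinomial draws at log-normal depths (mean 5000 reads,
  σ = 0.2) — a few thousand reads per sample, comfortably above the 1070
  rarefaction depth. Within-animal drift multiplies the latent
  composition by exp(0.1·z) per timepoint.
* **Slurries**: each FMT pools 3–6 random donors with Dirichlet(1)
  weights; the latent slurry composition is the weighted average of
  donor compositions.
* **FMT dynamics**: each slurry taxon absent from the recipient engrafts
  independently with probability p_e (default 0.3) at the slurry's
  proportion times log-normal noise (σ = 0.5); each recipient taxon
  absent from the slurry is removed with probability p_x (default 0.3).
  There is no ecological interaction model — presence-level transfer
  with inherited abundance is exactly what the presence-set statistics
  can detect. Every draw is recorded as ground truth.
* All randomness flows from one master seed through named substreams
  (per animal, per timepoint, per purpose); outputs are byte-identical
  for a fixed seed.

### What the generator does and does not emulate

It reproduces the study's *design* (roles, phases, depths, slurry
pooling, dysbiosis, engraftment at presence level), not its data. Two
divergences matter when reading results. First, each synthetic animal
keeps a fixed taxon support, so baseline samples cluster very tightly by
animal (host identity explains ~85% of baseline variance versus ~40% in
the real data); role-level permutation tests on the synthetic baseline
inherit pseudo-replication and can flag "significant" role effects that
are artifacts of that clustering — the analysis drivers report the
host-identity PERMANOVA alongside for exactly this reason. Second, there
is no strain-level variation, no absolute-abundance signal, and no
transient colonization: passing tests demonstrate the correctness and
calibration of the statistics, not that real FMT data will behave this
way.

## Calibration experiments

* **PERMANOVA type-I error**: 1000 datasets of 12 samples drawn from a
  single log-normal community (depth 2000, 200 taxa), arbitrary 6/6
  labels, Bray–Curtis, 999 permutations. Rejection at α = 0.05 should
  occur at ~5%; the acceptance band is [0.035, 0.065].
* **Engraftment recovery**: a deep single-FMT design (1500 taxa, three
  pooled donors, depth 50 000 with no depth noise, moderate skew
  σ = 1/√2, 50% carriage, no dysbiosis, no drift) yields ~650 introduced
  taxa; the presence-set estimate of the engraftment rate should land
  within ±0.05 of p_e = 0.3 in one cohort and within ±0.02 of it averaged
  over 100 cohorts, with ≥99% per-taxon agreement between measured and
  latent engraftment calls. The design is sized so the rarest carried
  taxa still expect several reads, keeping detection failures — the main
  source of bias — near the 1% level.

## Numerical and design choices

* Weighted UniFrac defaults to the raw (unnormalized) form with a
  `normalized` flag; the Shannon base defaults to 2. Both choices follow
  common QIIME2-era defaults and are configurable because source
  analyses often leave them unstated.
* Percent rounding is half-away-from-zero to match how such results are
  conventionally printed.
* Permutation p-values use the (b+1)/(m+1) estimator, so the smallest
  attainable p is 1/(m+1); exhaustive enumeration instead returns the
  exact tail probability including the identity labeling.
* Problem sizes in the tests and the reproduction script (300-taxon
  cohorts, 1500-taxon recovery designs, 1000-dataset calibrations) were
  chosen so that every property being checked has comfortable
  statistical resolution while the full suite runs in well under a
  minute of compute; all of them are parameters, not constants.

## Known limitations

* Engraftment is presence-based; sub-species (strain/SNV) transfer and
  absolute abundances are out of scope.
* PERMANOVA/PERMDISP permute samples freely and do not model the
  repeated-measures structure of longitudinal designs; with few animals
  and several samples each, role-level tests are anticonservative.
* The printed study statistics computed from the deposited sequencing
  data (baseline R², PERMDISP F, per-animal Shannon values) are not
  reproducible without those data and the original processing seeds; the
  package reproduces the study's *procedures* and its printed worked
  examples, and validates the machinery on synthetic truth instead.
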