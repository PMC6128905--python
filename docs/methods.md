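# Methods

This note records the models behind `proxiscreen`, the defaults and why
they were chosen, the numerical conventions, and what the synthetic-data
generators do and do not emulate.

## Proximity-labeling quantification

The labeling arm starts from a peptide-level label-free quantification
table; upstream spectral processing (feature alignment, database search,
peptide FDR) is out of scope. A protein's expression value is the **sum**
of its peptides' intensities — the standard LFQ aggregate, which preserves
peptide-count weighting — and `n_peptides` counts distinct peptides, which
later enforces the ≥2-peptide confidence rule.

Four column normalizations are supported, each a per-sample size factor
rescaled so the factors' geometric mean is 1 (preserving the global
intensity scale):

| method        | size factor                                            |
|---------------|--------------------------------------------------------|
| `robust_mean` | 20%-trimmed mean of log intensities, re-exponentiated  |
| `carboxylase` | mean intensity of endogenously biotinylated carboxylases (pull-down efficiency) |
| `bira`        | mean intensity of the BirA* ligase (ligase expression) |
| `none`        | identity                                               |

`robust_mean` names a concept rather than a single estimator; the
20%-trimmed mean on logs was chosen as a conventional robust location
estimate. BirA normalization uses the mean over the annotated BirA
entries. Technical noise is summarized as the mean per-protein %CV
(100·sd/mean) across QC-pool injections, reported for all proteins and the
≥2-peptide subset, mirroring how such experiments report QC.

Zeros are retained through aggregation (absence after streptavidin capture
is informative, not missing-at-random) and replaced only at ratio/log time
by a pseudo-intensity of half the smallest nonzero value in the matrix;
the value used is recorded in run metadata.

## Interactome calling

For each bait, fold change is the ratio of bait to control replicate means
of normalized intensities; significance is a two-sample pooled-variance
Student's *t* test on log2 intensities (pooled variance because the design
is n = 3 per group; log2 because multiplicative noise is approximately
log-normal, making the test exact under the simulator). Degenerate
zero-variance rows get p = 1 when the means are equal and p = 0 otherwise,
which avoids NaN propagation and is conservative only in the null
direction. No multiple-testing correction is applied by default (the
membership rule is a raw p < 0.05 combined with a fold threshold);
Benjamini–Hochberg is available as an option.

The fold threshold is calibrated, not fixed: the supplied positive
controls (default ARAF, BRAF, RAF1, direct RAS effectors that must appear
in any credible RAS interactome) must each be significant; each control's
fold is the geometric mean of its per-bait folds ("least recovered"
describes a protein, not a single bait measurement); the minimum over
controls is the derived threshold, floored at 2.0. A single threshold is
shared across baits, producing one union set. Membership is
fold ≥ threshold ∧ p < α ∧ n_peptides ≥ 2; the Venn partition over the
three bait sets is computed exactly and always sums to the union size.

Z-scores are per protein over log2 intensities; clustering uses
correlation distance (1 − Pearson) with average linkage, leaf order taken
from the dendrogram. The distance metric is a package choice — the
original figures' software does not document one — and constant rows are
assigned maximal distance rather than NaN.

## Screen scoring

Counts are normalized to reads-per-million with a 0.5 pseudocount added to
counts but not to column totals, so the documented column-sum contract is
`1e6·(1 + n_guides·pc/total)`. The depletion metric is log2(T2/T1) within
a background — depletion negative, matching the waterfall sign
convention — with replicates averaged **after** per-replicate log-ratios so
replicate variance remains available for diagnostics. The direction of
"timepoint 1 to timepoint 2" and the read-fraction abundance scale are
conventions recorded in run metadata; pooling replicates before ratios is
available as an alternative only through manual composition of the
primitives. T0 is used for representation QC only (totals, zero-count
guides, Gini coefficient).

Enrichment scores subtract the vector-background metric in log2 space, so
any guide's vector score is identically 0. Gene collapse takes the mean of
the three largest guide scores (pos_score) and the three smallest
(neg_score) — per direction, the only reading under which a gene can be
"both" positively and negatively enriched. Sums use exactly rounded
`math.fsum`, so collapsed scores are independent of guide order; ties in
the top-k selection break lexicographically by guide id for determinism.
Genes with fewer than k guides collapse over all of them and are flagged.
Classification uses τ = 0.4 on the log2 scale by default, with optional
recalibration to |neg_score| of a benchmark gene per background. Top-1%
flags use the ⌈0.01·n⌉ most extreme genes per direction.

## Integration

Dual-hit calls compare each entity to a reference gene on the scales the
two assays natively report: labeling on fold change (linear), screen on
the log2 neg_score. An entity is a hit when both quantities reach half the
reference's, making the call invariant to any positive rescaling of either
column; both scale choices are recorded in output metadata. In the
end-to-end pipeline, candidates are restricted to the isoform's called
interactome members (the screen library targets interactome genes, so a
dual hit must be one), and isoforms where the reference fails its own
preconditions (no positive labeling or no negative screen score) yield no
calls and are recorded as skipped.

Differential labeling between knockout and vector conditions is the mean
log2 difference, weighting each knockout line equally, with a ±0.1 log2
rule for direction; whether the original ±0.1 was linear or log2 is not
documented, so log2 is the default and linear remains a user
transformation. The reference protein's own fold difference is reported as
the benchmark. Over-representation is the one-sided hypergeometric
(Fisher) tail toward enrichment with fold enrichment
(overlap/hits)/(set/background); two-sided is available. Percent viability
implements the plate formula exactly and reports out-of-range values
as-is.

## Synthetic data: what it emulates

`simulate_bioid` draws protein baselines log-normally (meanlog 15, sdlog
1.5 — heavy-tailed like LFQ intensities), applies per-bait fold effects,
multiplies by log-normal replicate noise of configurable CV (default 0.10,
in the 8–14% range typical of QC pools), and splits each protein's signal
over Dirichlet-weighted peptides (count 1 + Poisson(7), mean ≈ 8 peptides
per protein as in deep LFQ datasets). Reference proteins are planted:
carboxylases and BirA at boosted abundance with fold 1 (valid
normalizers), RAF-like positive controls at folds {4.0, 3.0, 2.5} in every
RAS bait, and a named KRAS-specific interactor at fold 4. Default design:
3 replicates per bait for control/KRAS/NRAS/HRAS, 2000 anonymous proteins
of which 100 per bait are true interactors with 75% of the union shared by
two or three baits, and 3 QC-pool injections whose values are the
all-sample mean times fresh technical noise.

`simulate_screen` models guide abundance as
`baseline · 2^(fitness·efficacy·generations)` renormalized within each
sample, with counts gamma-Poisson (negative binomial, dispersion 0.05, the
conventional pooled-screen noise level; dispersion 0 yields the rounded
deterministic expectation for exact limit tests). Efficacy is Beta(5, 2)
(most guides effective, a minority weak — the situation that motivates
best-3-of-5 collapse). Defaults: 500 target genes × 5 guides, 50 ribosomal
control genes, 100 non-targeting guides, four backgrounds × T0/T1/T2 × 3
replicates at 2×10⁶ reads, generations {0, 3, 8} (a 2–3 day doubling over
a three-week selection). The planted vulnerability has fitness −0.8 in
KRAS only; other target genes get small (|f| ≤ 0.2) background-independent
fitness effects that cancel in vector-referenced scores. Ribosomal
controls are essential everywhere but their realized per-generation cost
is −0.8 in RAS backgrounds and −0.6 in the vector background: essential-
gene dropout scales with proliferation, and vector cells in low serum
proliferate more slowly. This differential is what makes essential
controls come out negatively *enriched* relative to vector, as observed in
such screens.

Random streams are keyed per entity id, so enlarging a simulation never
perturbs existing draws; everything is deterministic given the seed.

What the generators do **not** emulate: missing-value structure of real MS
data (dropout is off by default; a configurable missingness rate exists
for stress tests), the ~30% single-peptide tail of real protein
identifications (configurable, but the default favors well-quantified
proteins), correlated protein abundances, guide-level off-target effects,
infection multiplicity, and sequencing depth imbalance (a jitter parameter
exists, default 0). Passing recovery tests therefore demonstrates
correctness of the scoring machinery under the stated noise models, not
performance on real data with those additional pathologies.

## Study problem sizes

The calibration/recovery studies run at 1,500–2,000 proteins, 100 spiked
interactors, and 500 genes × 5 guides × 4 backgrounds × 3 timepoints × 3
replicates — sizes chosen to match the original experimental scale while
keeping any study re-runnable in seconds on a single CPU.

## Numerical conventions and edge cases

- Geometric-mean rescaling of size factors; reference-based factors
  reproduce equal reference means across samples to 1e-9 relative.
- Empty count columns, missing timepoints, missing references, ambiguous
  many-to-many id maps, and reference proteins absent from a sample all
  raise errors naming the offending sample/entity.
- p-values from the hypergeometric tail are exact (scipy `hypergeom.sf`);
  the test suite cross-checks them against explicit tail summation to
  1e-12.

## Known limitations

- The calibrated threshold is only as good as the positive controls; a
  weakly labeled control drags the stringency to the 2-fold floor.
- Enrichment p-values across proteins are correlated after empirical
  normalization (shared size factors); per-protein calibration checks are
  therefore run on unnormalized data.
- Vector-referenced screen scores absorb composition effects
  (renormalization after strong dropout); with many essential genes the
  non-targeting null shifts slightly positive.
- The four-way gene classification at τ = 0.4 labels a nontrivial fraction
  of null genes "negative" under realistic noise, because best-3-of-5
  selection is biased; this mirrors the original analysis rather than
  correcting it.
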