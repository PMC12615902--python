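# Methods

## Scope and model

`semr` reconstructs a super-enhancer → master-regulator nomination
pipeline for a panel of cell lines: per-sample SE calling from H3K27ac
peaks, consolidation into a line-level presence matrix, ubiquity
classification, SE-to-gene association with Fisher enrichment,
regulon-based activity scoring per subtype contrast, and the final
intersection of "differentially active" with "ubiquitous-SE-
associated". Upstream read processing and peak calling are out of
scope: the pipeline consumes peak calls with ChIP and matched input
densities. Regulatory-network inference is likewise out of scope:
regulons (regulator, target, mode, likelihood) are inputs.

## Super-enhancer calling

Stitching merges consecutive same-chromosome peaks whose gap is at
most `d_stitch` (default 12,500 bp); peaks fully contained within
±`tss_window` (default 2,500 bp) of a TSS are removed first. Both
defaults follow the widely used ROSE conventions and are configurable.

Region signal is `S = max(0, Σ (chip − input) × length)` over
constituents. The floor at zero is a deliberate numerical choice:
negative areas destabilise both the ranking and the tangent geometry
of the cutoff.

The hockey-stick cutoff sorts signals ascending and minimises
`y_i − s·i` with `s = (y_n − y_1)/(n−1)`. Ties resolve to the largest
index, i.e. the fewest super-enhancers; this also pins the degenerate
cases (perfectly linear or all-equal signal vectors yield zero SEs).
The rank axis is the raw index 1..n — the argmin is invariant to
affine rescaling of either axis, so no normalisation to a unit square
is needed. Note that the first and last rank always have equal
residuals by construction, so the minimum is interior whenever the
curve dips below the chord.

A geometric remark that matters for recovery guarantees: the cutoff
lands exactly at the boundary between two planted signal classes only
when every rank-to-rank signal increment below the boundary stays
below `s`. Heavy-tailed typical-enhancer signal occasionally violates
this in its extreme order statistics (one top typical separated from
the next by more than `s`), in which case the cutoff admits a handful
of top typicals. Under the default study conditions this produces a
few extra line-specific/shared consensus regions but leaves ubiquity
classification intact; the exact-recovery checks use a
well-separated regime (tighter peak lengths and densities, fewer
typicals) where the boundary condition holds with large margin.

## Consolidation and ubiquity

Consensus regions are single-linkage merges of per-sample SE intervals
overlapping by ≥ 1 bp (abutting intervals do not merge; a chain A–B–C
merges even when A and C are disjoint). Replicates collapse to lines
by union: a line is present when at least one of its replicates
contributes, which makes row sums invariant to replicate count.
Reciprocal-overlap merging was considered and rejected as it leaves
the consensus dependent on merge order; single-linkage on merged
coordinates is order-independent and idempotent.

The ubiquity threshold is the smallest count strictly greater than a
fraction `f` of the panel: `k_min = floor(f·n) + 1` with `f = 2/3`
(17 lines → 12, 10 lines → 7). "At least" and "strictly more than"
two-thirds disagree only when `2n/3` is an integer; the strict rule is
used and the fraction is configurable. Categories partition presence
counts: 1 → line-specific, ≥ `k_min` → ubiquitous, else shared.

Line clustering uses distance `1 − Pearson r` between per-line
profiles of `log2(1 + mean signal)` over the `k` most variable
consensus regions (variance on the log scale; default k = 200), with
average linkage. A constant line profile makes the correlation
undefined and is reported as an error naming the line rather than
silently imputed.

## Gene association and Fisher enrichment

A gene is linked to a consensus SE when the distance between the SE
interval and the gene body is ≤ W (default 10 kb, overlap = 0). The
window is anchored on the gene body, not the TSS, as the more
inclusive reading of "±10 kb"; a TSS-only mode exists behind a flag.
The enrichment universe defaults to all annotated genes and is
configurable, since category gene sets are compared against an
externally defined set whose natural universe may differ.

The two-sided exact p sums hypergeometric probabilities of all
fixed-margin tables no more likely than the observed one (delegated to
`scipy.stats.fisher_exact`; the test suite re-derives it by exhaustive
enumeration in exact rational arithmetic). The odds ratio is the
sample `(ad)/(bc)` with Haldane–Anscombe +0.5 on all cells when any
cell is zero, and the 95% CI is the Wald interval
`exp(log OR ± 1.96·√(Σ 1/cell))` on the same (corrected) cells. The
conditional-MLE odds ratio was deliberately not used: the CI formula
above is the standard Woolf interval reported alongside Fisher tests.

## Regulon activity

Signatures are Welch t-statistics on `log2(1 + x)`, one subtype vs all
remaining samples, with an ε-stabilised denominator (ε = 1e−6 on the
squared standard error) so constant genes stay finite. Ranks use
average ties; quantile scores are `Φ⁻¹(r/(N+1))`.

The activity statistic is the two-tailed core of aREA:
`NES = Σ w_i m_i q_i / √(Σ w_i²)`, computed after dropping targets
absent from the signature universe. Its null over random target draws
is standard normal up to a finite-population factor
`√((N−k)/(N−1))·sd(q)` (≈ 0.97 at N = 1000, k = 50), which the null
calibration check makes visible. The full three-tail combination and
pleiotropy/shadow corrections of the original VIPER implementation are
intentionally not reproduced: downstream use consumes only the sign
and an |NES| > 2 rule, for which the two-tail statistic has the same
null and sign semantics. No multiple-testing correction is applied to
NES for the same reason.

Minimum regulon size after universe intersection is 10; below that the
analytic null degrades and the score is withheld (with a warning
record rather than a silent NaN). The permutation cross-check redraws
target quantiles without replacement (equivalent to gene-label
permutation) and standardises the observed score by the permutation
null; agreement with the analytic NES within 0.2 at 5000 permutations
is part of the acceptance checks.

Correlation-ranked enrichment (anchor-gene analysis) ranks all other
genes by Spearman correlation with the anchor and computes the
GSEA-style weighted Kolmogorov–Smirnov running-sum extremum with
weight |r|; p is a two-sided gene-label permutation estimate with +1
smoothing.

## Candidate intersection

A regulator enters the candidate table when |NES| is strictly greater
than the threshold (default 2) in some contrast and its own gene is
associated with at least one ubiquitous SE. Identity between regulator
ids and gene ids is assumed (shared symbol namespace); a two-column
mapping can bridge differing namespaces, and a zero-overlap namespace
is an error rather than an empty result. The alternative rule —
requiring any regulon member, rather than the regulator's own gene, to
carry the ubiquitous SE — was considered and not made the default, as
it dilutes the "regulator under its own ubiquitous element" logic the
intersection is meant to capture; the association table makes the
alternative trivial to compute.

## Synthetic data

The generator emulates a 10-line × 2-replicate H3K27ac panel (the
field's studies use panels of this order, e.g. 37 samples over 17
lines) with four planted region categories: ubiquitous SEs (all
lines), subtype-specific SEs (lines of one subtype; lines cycle
through Nor/Lum/HER2/TNBC), line-specific SEs (one line), and
single-peak typical enhancers (all lines). SEs are clusters of 4–8
constituent peaks of 500–2000 bp with intra-cluster gaps below the
stitching distance. Per-sample constituent ChIP densities are gamma
distributed around the category mean (SE 6.0, typical 0.6 — a 10×
separation — sd `noise_sd` = 0.3 units/bp); matched input densities
are gamma around 0.2 with sd 0.1. Planted regions are separated by at
least `d_stitch` + 20 kb so categories can never stitch or merge, and
each region carries one adjacent gene 4 kb downstream (within the
10 kb association window but outside the TSS-exclusion reach of any
constituent). Background genes live on a dedicated gene-only
chromosome. A planted-present SE fails to appear in a given replicate
with probability `dropout_rate` (default 0.05); typicals are never
dropped.

Expression is simulated on the log2 scale (baseline uniform 3–8,
additive Gaussian noise with sd `noise_sd`) and emitted as
`2^L − 1` so the pipeline's `log2(1+x)` transform recovers the
simulated values exactly. Each regulator owns a disjoint pool of 50
background-gene targets with modes ±1 (70% positive) and weights
uniform on (0.5, 1]. Active regulators shift each target by
`mode × sign × activity_effect` (default 3.0 log2 units) in the
designated subtype's samples, and their own gene by `sign × effect`.
Three active regulators anchor on ubiquitous-SE genes (the intended
candidates); decoys are one active regulator anchored on a
line-specific-SE gene plus two inactive regulators — together they
probe both arms of the intersection. All randomness flows from the
single config seed through named `numpy` generators (landscape and
expression draw from disjoint seed-sequence children, so either can be
regenerated independently).

What the generator does **not** emulate: read-level noise, fragment
models, GC and copy-number artifacts, correlated (batch) noise across
samples, continuous SE/typical signal gradation, overlapping genes, or
regulons with off-target overlap. Passing recovery tests therefore
show the pipeline's logic is correct under its stated model, not that
real panels yield these accuracy levels.

## Problem sizes and determinism

Default study conditions run the full pipeline in a few seconds:
~1180 planted regions over three 25 Mb chromosomes, 20 samples, 1600
genes, 6 regulators × 4 contrasts. The oracle checks use 200 random
cutoff instances (n up to 5000), 100 Fisher tables (margins ≤ 50),
1000 null signatures, and 50 permutation pairs at 5000 permutations.
Identical configuration and seed reproduce byte-identical outputs.

## Known limitations

* The tangent cutoff is sensitive to the extreme tail of the typical
  signal distribution (see the geometric remark above); on real data
  the SE count near the elbow should be treated as approximate.
* The two-tail aREA simplification can differ from three-tail VIPER
  for regulons with many near-zero modes.
* Wald CIs on the odds ratio are poor for very small cells even with
  the Haldane correction; the p-value, not the CI, should drive
  decisions there.
* Single-linkage consolidation can chain adjacent SEs into one
  consensus region in dense landscapes; the planted-region padding
  hides this failure mode in simulation, real data may not.
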