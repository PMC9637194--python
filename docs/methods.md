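# Methods

## Scope and data model

The package analyses per-sample CpG-level methylation count tables
(bedGraph-like TSV: chrom, start, end, ratio, methylated reads, total
reads), a sample sheet linking tumors to patients, subtypes, timepoints,
matched normals and PDOX models, a BED6 TSS annotation, and a gene ×
sample expression count matrix.  Coordinates are 0-based half-open; a
CpG/CpA site spans `[start, start+2)` (both strands pooled).  Chromosomes
are `chr`-prefixed and ordered naturally (chr2 < chr10).  Non-CpG (CpA)
sites live in separate per-sample files so the 6-column format stays fixed.

## Differential methylation calling

The DMC caller is a deliberately transparent substitute for credible-
difference callers: a two-sided Fisher exact test on the per-site 2×2
count table, Benjamini–Hochberg adjustment *within* each tumor-vs-normal
comparison (each comparison is an independent screen), and a minimum ratio
difference.  Defaults: coverage ≥ 5 reads in both samples (untested
otherwise — no imputation), |Δ| ≥ 0.2, q ≤ 0.05.  The 0.2 default sits
deliberately below the 0.3 driver-consistency filter so the stricter
downstream filter remains binding.  p-values are computed by exhaustive
enumeration over the hypergeometric support, vectorised over unique tables
(dedup + chunked pmf grids), which makes ~2.4 million tests on the default
synthetic cohort run in seconds; tests verify agreement with brute-force
enumeration and `scipy.stats.fisher_exact` to 1e-10.  Under a null
comparison (both samples drawn from identical ratios at 30×) the raw
p ≤ 0.05 fraction is ~0.015 (Fisher is conservative at these counts) and
the BH q ≤ 0.05 fraction is ~0.

## Trajectory classification

Per patient, sites tested at every timepoint yield a state sequence over
{Hyper, Hypo, NoChange} (primary first, then relapses; a patient lacking a
primary uses its earliest sample as timepoint 0, flagged downstream by the
booster procedure, which excludes such patients from support).  Categories:

* `ConsistentX` — all states X;
* `GainX` — a nonempty NoChange prefix then an all-X suffix;
* `LossX` — the mirror image;
* `Switch` — any other single-polarity mixture (more than one toggle,
  including gain-then-loss compounds) *and* sequences containing both
  polarities without adjacency;
* `ExcludedPolaritySwitch` — any adjacent Hyper↔Hypo flip (excluded from
  the seven categories as unreliable);
* all-NoChange sequences are not DMCs; sites missing any timepoint are
  `Uncovered`.

Gain/Loss are defined as single clean transitions (prefix/suffix form);
this is the reading consistent with alluvial-flow summaries of serial
relapse data.  The classifier is validated exhaustively against an
independent rule-table oracle on all 360 sequences of length 2–5.

## Cross-patient discovery

Shared sets use exact intersection across all patients of a subtype, with
UpSet-style exclusive-combination tallies (each site counted once, under
exactly the combination of patients that carry it).  Sites uncovered in a
patient are absent from that patient's set and therefore cannot be shared.
The consistency filter retains sites whose per-sample deltas are
direction-uniform with mean |Δ| strictly > 0.3 (a per-sample-strict variant
is available).  Drivers additionally require `ConsistentX` in every
patient; boosters require a NoChange primary and X at every relapse in
every patient; predictors require same-polarity DMC status in every
recurring primary and every recurrent sample, absence from every
non-recurrent reference primary (the procedure refuses to run without one),
and are ranked by mean |Δ| over recurring primaries with a top flag at
≥ 0.8 (inclusive).  Sites with partial coverage across relapse samples are
disqualified (strict reading).

## Regions, genes, PDOX preservation, expression

DMRs are maximal same-direction runs with start-to-start gaps ≤ 300 bp and
≥ 3 members (promoter-scale defaults; both CLI-exposed; region construction
parameters are not standardised in the field, so no count equivalence with
other callers is claimed).  Gene assignment associates a DMR with every
gene whose TSS lies within ±5 kb, strand-agnostically; strand is carried
for interpretation.  A candidate (site- or gene-level) is PDOX-preserved
only if *every* matched xenograft reproduces the mark with the same
polarity — the conservative reading; candidates without any matched model
are flagged `not_evaluated`, never silently kept as preserved.
Preservation percentages are `100·preserved/total` rounded half-up to one
decimal.

DEG calling normalises to counts-per-million on library size, tests each
gene with a two-sided Welch t-test on log2(CPM+1), BH-adjusts across genes,
and flags DEGs at q ≤ 0.05 and |log2FC| ≥ 1 (fold change ≥ 2, inclusive),
with log2FC computed on group-mean CPM.  This transparent two-group test
replaces negative-binomial count models; a pre-computed DEG table can be
substituted at the CLI.  Integration computes Pearson r between a candidate
gene's DMR mean methylation and its expression across all tumor + normal
samples (tumors-only via the `samples` argument); concordance requires
r < 0 (tightenable via `max_r`) plus polarity agreement (hyper→down,
hypo→up).  Genes with fewer than 3 paired samples or constant vectors are
flagged not-evaluated.

## Cohort metrics

The convergence series correlates each relapse with the nearest earlier
available sample (flagging non-adjacent fallbacks), over sites with ≥ 5
reads in both members; records with < 100 shared sites carry a warning
flag (a repository choice — the field reports no minimum).  PDOX fidelity
is the same Pearson r between a model and its source sample.  Top-variable
selection ranks complete-case sites by across-sample variance (ties broken
by position); the 1−r distance matrix is exported for external clustering
tools.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes; its
defaults are the study conditions of the test suite.

* **Cohort shape.** Two subtypes × five recurring patients with relapse
  counts {7,2,1,4,1} (RELA) and {3,2,1,2,3} (PFA), one non-recurrent
  primary per subtype, five normal replicates per tissue, one PDOX model
  per recurring patient (copied from the last relapse).  50,000 CpGs on 5
  chromosomes, mean coverage 50×, 2,000 CpA sites, 2,000 genes.
* **Baseline.** Bimodal Beta(1,10)/Beta(10,1) mixture (weights 0.55/0.45)
  shared between tissues up to a 2% flip fraction.
* **Tumor evolution.** Each patient has an attractor profile: the tissue
  baseline with a random 10% of background sites flipped to the opposite
  mode (chosen so per-sample DMC load is a few percent of sites, matching
  RRBS cohorts).  The primary mixes 30% toward the attractor; each relapse
  is `(1−c)·previous + c·attractor` with convergence rate c = 0.6, plus
  "in-transit" transient flips on 5%·(1−c)^t of background sites and
  N(0, 0.02) ratio jitter.  This yields a consecutive-relapse correlation
  series that rises monotonically (≈0.89 → 0.98 over four relapses).
* **Planted signal.** Clusters of 5 adjacent sites (30–120 bp gaps, hence
  mergeable into DMRs) for drivers (Δ = 0.5, all tumors), boosters
  (Δ = 0.5, relapses only), predictors (Δ = 0.8, recurring patients only);
  200 scattered switch sites shifted at a random nonempty proper subset of
  timepoints.  Planted baselines are drawn near the opposite mode so the
  design delta is exact; planted sites carry no jitter (binomial sampling
  is their only noise).  Because predictor sites are shifted in every
  recurring patient's primary and relapses, they satisfy the driver
  phenotype by construction; driver evaluation counts them as valid
  positives while driver recall is measured over planted drivers only.
* **Counts.** total ~ Poisson(coverage); methylated ~ Binomial(total,
  ratio); zero-coverage sites are absent from the sample's table.  PDOX
  ratios are the source sample's plus truncated N(0, 0.05).
* **Expression.** Negative-binomial counts (dispersion 20, library-size
  lognormal sd 0.15), baseline means lognormal(log 300, 0.75).  A fraction
  of genes (3% by default) has its TSS placed within 2 kb of a persistent
  (driver or predictor) planted cluster and mean
  `b·2^(slope·promoter methylation)` with slope −3 per unit methylation —
  chosen so the expected |log2FC| of driver-coupled genes (Δ = 0.5) is 1.5,
  comfortably above the DEG cutoff; a slope of −2 would park the expectation
  exactly on the cutoff and make recovery a coin flip.  Booster clusters are
  not expression-coupled: their marks are absent from primaries, so a
  tumor-wide DEG truth would be structurally diluted below the cutoff.
  CpA sites are globally reduced in tumors (scale 0.3).
* **Determinism.** Every draw flows from one `numpy` Generator seeded by
  the config; identical configs produce byte-identical outputs.

What the generator does *not* emulate: RRBS fragment-based coverage
structure (coverage is Poisson), sequence context, copy-number effects,
cellular heterogeneity within a sample, batch effects, and realistic
genome geometry.  Passing tests therefore demonstrate the correctness and
calibration of the procedures under the stated statistical model, not
performance on real RRBS libraries.

## Numerical choices and edge cases

Fisher two-sided ties use a 1+1e-7 relative tolerance (the classical
convention).  BH is `statsmodels.multipletests(fdr_bh)`.  t-tests with
zero within-group variance return p = 1 (no evidence) rather than NaN.
log2FC of a group with zero mean is ±inf and can still satisfy the DEG
bound.  Variance in top-variable selection uses ddof = 1 on complete-case
sites only.  Sites failing coverage anywhere are never imputed.  Planted
site fidelity at 50× follows exact binomial sampling: for design ratios
near 0.5 about 12–15% of (site, sample) pairs fall more than 0.1 from the
design value — the property tests check agreement with the binomial
prediction rather than a blanket bound, and the stricter 95%-within-0.1
bound for extreme design ratios.

## Problem sizes

The test suite exercises a 4,000-site, 10-patient tiny cohort throughout
and the full 50,000-site default cohort in the acceptance tests; the
acceptance script runs the default cohort end-to-end plus a 20-seed
convergence study at 4,000 sites — sizes chosen to keep a complete run in
the low minutes on a single core while leaving every statistical
conclusion unchanged at larger n.

## Known limitations

No beta-binomial dispersion modelling or smoothing in the DMC caller; BH
per comparison rather than pooled; no replicate-aware designs; DMR
construction is gap-based rather than model-based; expression integration
uses a two-group t-test rather than count models; no support for
methylation arrays, BAM/FASTQ input, or liftover.
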