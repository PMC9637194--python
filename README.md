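# epirelapse

Longitudinal DNA-methylation analysis of serially relapsing tumors.

Pediatric ependymomas and other recurrence-prone tumors are resected and
profiled repeatedly over years: a primary tumor, then a series of relapses,
each compared against matched normal brain tissue (cerebrum for
supratentorial RELA-fusion tumors, cerebellum for posterior-fossa group A).
With RRBS-style CpG count data per sample, the scientific questions are
longitudinal: which abnormal marks are present at diagnosis and *sustained*
through every relapse (potential **drivers**), which are *acquired* at
relapse and kept (potential **boosters**), and which primary-tumor marks
separate patients who will relapse from those who will not (potential
**predictors**)?  `epirelapse` implements this full desk analysis for
methylation-epigenomics researchers, together with a synthetic cohort
generator with planted ground truth so every stage is testable without
access to patient data.

## The method

For a tumor sample *t* and its matched normal *n*, each CpG covered by at
least 5 reads in both is tested with a two-sided Fisher exact test on the
2×2 table [(meth, unmeth)_t ; (meth, unmeth)_n], BH-adjusted per
comparison.  A site is a DMC (HyperDMC / HypoDMC) when q ≤ 0.05 and the
methylation-ratio difference Δ = r_t − r_n satisfies |Δ| ≥ 0.2.

Within a patient, the per-timepoint states (P, R1, R2, … each vs the same
normal) form a sequence over {Hyper, Hypo, NoChange}, classified into seven
dynamic categories — consistent Hyper/Hypo, gain Hyper/Hypo, loss
Hyper/Hypo, switch — with sequences containing a direct Hyper↔Hypo flip
between adjacent stages excluded (they are rare and unreliable).

Discovery then works across patients of a subtype:

* **drivers** — sites consistently Hyper (or Hypo) in *every* patient,
  restricted to mean |Δ| > 0.3 across all tumor samples;
* **boosters** — sites NoChange in every primary but Hyper/Hypo at *every*
  relapse of every patient;
* **predictors** — DMCs in every eventually-recurring patient's primary,
  absent from the non-recurrent reference primary, and present with the
  same polarity in every recurrent sample; ranked by mean |Δ| with the top
  flag at |Δ| ≥ 0.8.

Driver/booster DMCs are merged into DMRs (same-direction runs, gap ≤ 300
bp, ≥ 3 sites) and assigned to genes whose TSS lies within ±5 kb.  A
candidate is *preserved* when every matched patient-derived orthotopic
xenograft (PDOX) reproduces the mark with the same polarity — an in-vivo
filter for marks that survive engraftment.  Expression integration calls
DEGs (Welch t-test on log2(CPM+1), BH, q ≤ 0.05 and |log2FC| ≥ 1) and keeps
candidate genes whose DMR methylation anticorrelates with expression
(Pearson r < 0) with concordant polarity (hyper→down, hypo→up).  Cohort
metrics include the consecutive-relapse Pearson correlation series (the
methylome *converges* over serial relapses), PDOX global fidelity r, and
top-variable CpG selection.

## Worked example

Simulate a small cohort (two subtypes, two recurring patients each plus a
non-recurrent reference, planted driver/booster/predictor clusters, PDOX
models, methylation-coupled genes) and run every stage:

```bash
epirelapse simulate --config cohort.yaml --out cohort
# wrote cohort with 30 samples to cohort

epirelapse call-dmc --tumor cohort/methylation/RELA1-R1.cpg.bedgraph \
    --normal cohort/methylation/N-cerebrum-1.cpg.bedgraph -o dmc.tsv
# 694 DMCs over 4000 tested sites -> dmc.tsv

epirelapse run-all --meth-dir cohort/methylation --sample-sheet cohort/samples.csv \
    --annotation cohort/genes.bed --counts cohort/expression.tsv --out results
```

`results/summary.json` then reports, among other things:

```
RELA: n_drivers 45, n_boosters 43, n_predictors 34, n_degs 9, n_concordant_genes 4
convergence RELA1: [0.890, 0.947, 0.971]
pdox_fidelity PDOX-RELA1-R3: 0.983
```

Reading: 45 driver DMCs were consistent in both RELA patients with mean
|Δ| > 0.3 (the cohort plants 30 driver sites; planted predictor sites
legitimately satisfy the driver phenotype too, and with only two patients a
few background sites slip through — at five patients per subtype they
vanish).  RELA1's methylome correlation with the previous tumor rises from
0.890 (P vs R1) to 0.971 (R2 vs R3): convergence.  The PDOX model of
RELA1-R3 reproduces its source methylome at r = 0.983.  Per-stage TSVs
(DMC calls, trajectories and category fractions, UpSet tallies, DMRs,
candidates with PDOX flags, DEGs, integrated genes, convergence series)
are written alongside, and every subcommand can be re-run standalone on
those files.

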