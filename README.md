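# tribepas

Target identification for m⁶A reader proteins by HyperTRIBE editing analysis,
and alternative-polyadenylation analysis from Smart-seq2 3′ tags — as a
tested, reusable Python library with a thin CLI.

## What it does, and for whom

When an RNA-binding protein is fused to the hyperactive catalytic domain of
ADAR (HyperTRIBE), transcripts it binds acquire A-to-G editing marks that
RNA-seq can read out. Deciding which marks are real requires comparing
editing *proportions* — G/(A+G) at each candidate adenosine — between
fusion-expressing and free-ADAR control replicates, while respecting the
overdispersion of biological replicates. Separately, oligo-dT-primed
Smart-seq2 reads that run through the poly(A) tail reveal poly(A) sites
(PASs), but only after untemplated-tail detection and removal of oligo-dT
mispriming artifacts at genomically A/G-rich positions.

This package implements both computations for transcriptomicists working on
RNA-binding-protein target atlases and alternative polyadenylation
(the motivating system is the *Arabidopsis* YTH-domain readers ECT2/ECT3/ECT4):

- **`tribepas.editing`** — strand-aware pileup over annotated genes,
  candidate detection at every mismatch position, a beta-binomial
  likelihood-ratio test of differential editing with a common (shared across
  sites) dispersion, Benjamini–Hochberg adjustment, A-to-G/SNP filtering,
  gene-level target aggregation, and a triple-vs-single mutant-background
  comparison with scaled ADAR transgene abundance as a covariate.
- **`tribepas.polya`** — untemplated tail detection (≥9 terminal As or
  leading Ts, ≤6% internal mismatch), post-trim length/quality filters,
  PAS location at the 3′-most aligned base, and the downstream-purine
  (≥80% of 15 nt) mispriming filter.
- **`tribepas.pac`** — per-sample poly(A)-site clusters (PACs) by
  subtractive Gaussian kernel density against gene-body background,
  cluster-level artifact removal, 2-of-3 replicate consensus in *both*
  genotypes, interval merging, organelle/rDNA exclusion, gene assignment.
- **`tribepas.shifts`** — dominant-PAC shifts for multi-PAC genes,
  signed most-common-PAS distances (binned ±10/±100/±1000/>1000 nt),
  Fisher's exact enrichment across gene sets.
- **`tribepas.targets`** — permissive/stringent/non-target set algebra,
  protein-specificity classes, single-cell marker overlap, expression
  filtering (≥1 TPM in all samples, total ≥5 TPM) and fold-change
  classification.
- **`tribepas.simulate`** — generators for all of the above with ground
  truth: toy genomes with decoy purine stretches and organelle/rDNA
  analogue contigs, editing experiments with beta-binomial replicate noise
  and SNPs, and paired Smart-seq2 reads with tails, mispriming artifacts
  and gene-body background.

## The statistical model

At site *i*, sample *s*, the alt count is modelled as

  G_is ~ BetaBinomial(n_is, μ_is, ρ),  logit(μ_is) = β₀ + β₁·group_s (+ β₂·x_s)

with intra-class correlation ρ shared across all candidate sites (maximum
Cox–Reid-adjusted profile likelihood, the moderation used when only a
handful of replicates inform each site). The group effect is tested with a
likelihood-ratio statistic referred to F(1, m−k) — the small-sample
quasi-likelihood convention — and BH-adjusted across candidates. Default
discovery thresholds: p_adj < 0.01 and log₂FC > 1 against free-ADAR
controls; p_adj < 0.1 and |log₂FC| > 0.25 between mutant backgrounds, with
the z-scored per-sample ADAR abundance x_s as covariate. Fold changes use
pooled proportions with one pseudocount on each group's alt and ref totals.

## Worked example

Simulate a 5+5-replicate editing experiment (12 true sites at fusion
proportion 0.35 vs 0.004 in controls, one homozygous and one heterozygous
SNP) and call sites:

```
$ tribepas simulate --mode editing --config cfg.yaml --out sim
wrote editing simulation to sim
$ tribepas call-editing --bam-dir sim/bam --fasta sim/genome.fa \
    --bed sim/genes.bed --samples sim/samples.tsv --out sites.tsv
12 significant filtered sites
```

All 12 true sites are recovered and both SNPs are rejected. `sites.tsv`
reports each site 1-based with per-sample counts, e.g.

```
contig  pos   strand ref alt prop_alt_group prop_ref_group log2fc p_raw
chr1    630   -      A   G   0.284          0.0035         5.38   3.8e-06
chr1    2499  -      A   G   0.294          0.0            6.71   1.8e-06
```

— at chr1:630 the fusion libraries edit 28% of transcripts versus 0.35% in
controls (a log₂ fold change of 5.4), and `sites.genes.tsv` aggregates the
sites into per-gene target counts. The poly(A) arm works the same way
(`tribepas simulate --mode polya`, then `extract-polya`, `call-pacs`,
`compare-pas`); on a 10-gene toy run it reports e.g.

```
15 merged PACs (2 on excluded contigs)
```

with per-gene dominant-PAC shift calls and the signed distance-bin table of
most-common-PAS changes between genotypes.

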