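# Methods

This note documents the models, defaults and design choices behind
`tribepas`, and what the synthetic-data studies do and do not demonstrate.

## Differential editing model

Editing at a candidate site is the proportion of transcripts carrying the
A-to-G mark, estimated from strand-aware base counts G/(A+G). Biological
replicates of the same line/genotype are overdispersed relative to a
binomial, so per-sample alt counts are modelled beta-binomially with mean
following a logistic regression on group (fusion vs free-ADAR control, or
triple vs single mutant background) and, optionally, a per-sample covariate;
the intra-class correlation ρ is *shared across sites*.

Key choices, and why:

- **Common dispersion, Cox–Reid adjusted.** With 5 replicates per group a
  per-site ρ estimate is so noisy that the likelihood-ratio test becomes
  anti-conservative. A single ρ maximising the summed profile likelihood
  over all candidate sites — with the Cox–Reid −½ log det adjustment that
  removes the bias induced by profiling each site's mean parameters — is
  the standard moderation (cf. edgeR's dispersion machinery) and restores
  calibration. The estimator subsamples at most 2,000 evenly spaced sites
  and refines a log-spaced grid by golden-section search.
- **F(1, m−k) reference.** The LRT statistic is compared to an
  F distribution with 1 numerator and m−k denominator degrees of freedom
  (m = covered samples at the site, k = mean-model parameters), the
  small-sample quasi-likelihood convention, rather than χ²₁. At the
  simulated study conditions (5v5 replicates, coverage ~Poisson(100),
  ρ = 0.02, editing 1%) χ²₁ rejects ~8–9% of null sites at α = 0.05 while
  F(1,8) rejects ~4.5%; the F tail is slightly conservative, which is the
  right failure mode for a discovery pipeline. A consequence worth knowing:
  with only 3 replicates per group (df = 4) even very strong sites cannot
  reach extreme p-values — the replication level, not the effect, limits
  discovery.
- **Fold change.** log₂FC of pooled proportions with one pseudocount added
  to each group's alt and ref totals, so zero-alt groups yield finite,
  monotone fold changes.
- **Covariate.** "Scaled ADAR abundance" is the z-score of per-sample
  transgene expression within the comparison, entered additively on the
  logit scale. A constant covariate is dropped with a warning.
- **Thresholds** (all config-exposed): fusion-vs-control significance
  p_adj < 0.01 and log₂FC > 1; background comparison p_adj < 0.1 and
  |log₂FC| > 0.25, restricted to positions control-significant in at least
  one background. SNP heuristics: pooled control alt proportion ≥ 0.35, or
  alt ≥ 0.8 in every sample. Pileup: minimum base quality 20; positions
  must reach coverage 10 in at least one fusion sample (prevents
  single-read candidates from dominating the multiple-testing burden).

## Poly(A) pipeline

- **Tail detection.** The longest terminal run (3′ As or 5′ Ts) with
  length ≥ 9 and mismatch rate ≤ 6% of the span; the tail must terminate
  the read and may not end in a mismatch (the read's terminal base must
  match), which forbids degenerate tails padded by trailing non-A. Longest
  valid suffix wins; a 3′A call beats an equal-length 5′T call. 5′T reads
  are reverse-complemented downstream.
- **Read filters.** Keep iff trimmed length > 20 *and* trimmed mean Phred
  > 25 (strict inequalities, mean over the trimmed portion); reads without
  qualities are discarded with a warning.
- **PAS location.** The 3′-most aligned genomic base in gene orientation;
  terminal soft-clips/mismatches do not shift the call (default allowance
  2, config-exposed).
- **Mispriming filter.** A PAS is an artifact iff the 15-nt window
  immediately downstream in gene orientation is ≥ 80% purine (inclusive
  boundary: 12/15 purines is filtered). Windows truncated below 8 bases at
  contig ends are classified genuine with a warning. Filtered reads are
  kept in a companion track — they later veto whole clusters.
- **Cluster calling.** Per sample, PAS-end counts and gene-body-read
  3′-end counts are smoothed with a Gaussian kernel (σ = 15 nt); the
  background is scaled by the foreground/background read-count ratio
  (scale-free subtraction) and subtracted. Maximal runs of positive signal,
  trimmed to the span of supporting PAS reads and holding ≥ 2 genuine
  reads, become clusters. A cluster with more misprime-filtered than
  genuine reads is removed entirely (ties keep it).
- **Consensus and merging.** A per-sample cluster is retained iff clusters
  overlap it (≥ 1 bp, its own replicate counted) in at least two replicates
  of *each* genotype; retained clusters are coalesced with bedtools-merge
  semantics (touching intervals union; merging is idempotent) and
  per-sample support is re-aggregated from the PAS tracks. Clusters on
  organelle/rDNA-analogue contigs (or user intervals) are then excluded.
- **Gene assignment.** Annotated spans extended 200 nt past the 3′ end
  (PASs routinely fall downstream of annotation); multi-gene overlaps
  resolve to the gene with the nearer annotated 3′ end.
- **Shift statistics.** Read totals are summed over a genotype's
  replicates before picking dominants; exact ties are excluded
  ("tie"/"single-PAC" reasons are reported), never tie-broken — any
  tie-break would fabricate a result. Most-common-PAS distances are signed
  in gene orientation (negative = upstream) and binned
  ±10/±100/±1000/>1000 with d = 0 in the +10 bin; a ±40 nt per-nucleotide
  histogram is also returned. Fisher's exact test is two-sided with a 0.5
  (Haldane) odds-ratio correction at zero cells; empty margins are
  reported undefined.

## Synthetic data: what it emulates, and what it does not

The generators define the study conditions under which the pipeline's
guarantees are measured:

- **Toy genome.** 1–2 nuclear contigs of uniform-random sequence with
  non-overlapping genes on both strands (defaults: 800–1,500 nt genes,
  ~300 nt intergenic), plus one organelle-analogue and one rDNA-analogue
  contig each carrying a gene, so contig exclusion has real work to do.
  Each gene receives 1–2 true PASs in its last ~300 nt, ≥ 150 nt apart —
  chosen so that truly distinct clusters are resolvable at the default
  15-nt bandwidth. Poly(A) sites in plants carry U-rich downstream
  elements; the generator writes spaced pyrimidines into the 15 nt
  downstream of every true PAS, which both emulates that context and
  guarantees no true site sits in the mispriming filter's blind spot — the
  blind spot is exercised deliberately by decoy stretches (≥ 80% purine by
  construction, with a ≥ 10-A leading run for the primer to anneal to)
  written into gene bodies. In 10% of multi-PAS genes (configurable) the
  two most-used PASs swap usage between genotypes — the ground truth for
  shift detection.
- **Editing experiments.** Per-sample realised editing proportions are
  beta draws around the group mean with ρ = 0.02 (replicate
  overdispersion; ρ is not stated by upstream work, 0.02 is a typical
  replicate ICC for proportions), then reads covering a site are edited
  independently. SNPs are emitted at proportion 1 or 0.5 in *all* groups.
  An optional coupling mode scales each sample's mean proportion linearly
  with its ADAR abundance. The truth table records both the group-level
  parameter and the realised per-sample proportions: the pooled estimator
  G/(A+G) converges to the *realised* editing of the sequenced libraries;
  its deviation from the group parameter has an irreducible replicate
  floor of sd ≈ √(p(1−p)ρ/m) (~0.03 at p = 0.5 with m = 5), so accuracy
  statements are made against the realised truth and both numbers are
  reported.
- **Smart-seq2 experiments.** Tail lengths are floor-9 plus a negative
  binomial (the empirical tail-length distribution is not documented
  upstream; the floor is forced by the detector threshold), with internal
  non-A contamination capped at 6% of the span so every simulated tail is
  a valid detector call. Read 3′ ends jitter N(0, 5 nt) around the true
  PAS. Misprimed reads end at decoy positions with genomically templated
  A-runs; body reads carry no tail. Mates are proper pairs; the BAM stores
  the aligned trimmed span with the raw as-sequenced read in the `OS`/`OQ`
  tags, since alignment itself is out of scope.
- **Covariate study.** Per-line transgene abundances are fixed design
  constants (0.7–1.3 in the single background, two-fold higher in the
  triple), emulating systematically different transgene expression between
  backgrounds; editing tracks abundance linearly with no true background
  effect.

Not emulated: isoform structure and splicing, position-dependent error
profiles, quality-score realism beyond a constant offset, GC/coverage
biases, and genome repeat structure. Passing the recovery studies
therefore shows the statistics and filters behave as designed under the
assumed noise model — not that real libraries meet those assumptions.

## Numerical notes

- The beta-binomial mean fits use a damped Newton iteration vectorised
  across sites (per-site backtracking line search, Hessian clamped
  negative-definite, linear predictor clamped to ±18); degenerate all-zero
  or all-alt sites converge to boundary fits with finite likelihoods.
- BH adjustment is the standard monotone step-up; adjusted p-values
  preserve the raw-p ordering.
- Simulator outputs are deterministic functions of the seed; per-sample
  streams are spawned from a `SeedSequence`, so adding samples does not
  perturb earlier ones. FASTA/GFF3/BED outputs are byte-identical across
  runs; BAMs are identical at alignment-record level (the container header
  embeds the sort command's temporary path).
- Problem sizes in the acceptance studies: 10,000 reads for the trimming
  oracle, 2,000 null and 500 true sites for calibration/power, 2,000 sites
  for the covariate study, and a 200-gene, 3+3-replicate poly(A)
  experiment (~50–200 tailed reads per gene per sample) — sizes at which
  the measured fractions have sampling error well below the margins being
  asserted.

## Known limitations

- A true PAS immediately upstream of a naturally purine-rich stretch is
  removed by the mispriming filter — an inherent blind spot of the
  downstream-purine rule that real pipelines share; the generator places
  true PASs outside it (see above) so cluster-recovery metrics measure
  clustering rather than this documented loss.
- The common-dispersion model assumes one ρ describes all sites; strongly
  site-specific dispersion would be mis-calibrated at the extremes.
- With < 4 replicates per group the F reference makes genome-wide
  discovery at p_adj < 0.01 essentially impossible (by design — the
  dispersion is then barely identified).
- Gene assignment ignores overlapping/nested gene models beyond the
  nearer-3′-end tie-break, and the pileup drops strand-ambiguous positions
  rather than apportioning them.
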