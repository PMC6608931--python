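# Methods

This note documents the statistical procedures, the synthetic-cohort
model behind the test suite, and the numerical/design choices that were
genuinely open.

## Association cascade

Phenotypes are binary (resistant/susceptible) per insecticide, one
individual per family.  For each SNP, individuals with a missing
genotype call are dropped for that SNP only (complete-case per test; the
count is reported).  Two codings are used deliberately:

- **Carrier (dominant) coding** for the Fisher exact test and for
  sensitivity/specificity/AUC.  The sensitivity definition counts
  "samples with resistant phenotypes AND alternate alleles", which is a
  per-individual carrier property, so the 2×2 table is phenotype ×
  carrier status.  AUC here is the arithmetic mean of sensitivity and
  specificity — a ranking score in [0, 1], not a ROC integral.
- **Co-dominant coding** for the Cochran–Armitage trend test: the 3×2
  genotype (0/1/2) × phenotype table with scores w = (0, 1, 2).  The
  statistic is the score-test form
  T = Σ w_i (r_i − n_i r/N), Var(T) = p̄(1−p̄)(Σ w_i² n_i − (Σ w_i n_i)²/N),
  X² = T²/Var referred to χ²(1).  Monomorphic tables are flagged and
  given p = 1.  The tests validate this against a separately implemented
  textbook form and against the margin-conditioned permutation null
  (multivariate hypergeometric).

Cascade thresholds are inclusive, exactly as reported: Data Set 2 keeps
exonic in-gene SNPs with Fisher p ≤ 0.10 (flank and intron SNPs are
disregarded), sorted by descending AUC with ties broken by genomic
order; Data Set 3 keeps Data Set 2 SNPs with CATT p ≤ 0.05.  No
multiple-testing correction enters the cascade — the thresholds are
intentionally liberal screens — but a Benjamini–Hochberg column is
emitted for information.  Degenerate 2×2 margins (no carriers anywhere,
or one phenotype group empty of information) yield p = 1 with a flag
rather than an error.

Population/phenotype carrier frequencies are reported to two decimals,
the precision of the published per-population tables, and the
resistant-minus-susceptible difference is computed on the reported
(rounded) values.  Percentage summaries of synonymous/nonsynonymous
counts use standard half-up rounding at one decimal.  A site whose two
alternate alleles have different effects is classed "mixed", flagged,
and counted in neither pure class, so the pure counts partition the
remaining sites.

## Annotation model

Coordinates are 1-based inclusive on supercontigs at every interface
(BED files are 0-based half-open as usual).  A gene is an ordered set of
non-overlapping exons plus a strand; flank = within `flank_length`
(default 150 bp) of the gene span but outside it; intron = inside the
span but not in an exon.  Overlapping genes are legal and produce one
annotation row per (site, gene) pair; the first gene in panel order is
the reporting row.  Codon numbering runs 5'→3' in gene orientation over
the concatenated exons, after an optional per-gene frame offset
(default 0); minus-strand codons are reverse complements of the
supercontig sequence.  Translation uses the standard genetic code; stop
gains/losses are classed separately from nonsynonymous changes (a
`merge_stop` flag folds them in for two-class summaries).  A reference
allele that contradicts the CDS base is flagged on the annotation record
rather than raised, so one corrupt record cannot abort a run.  Trailing
partial codons and sites upstream of the frame offset get region labels
but no effect call.

## CNV stage

RPKM = reads / (amplicon kb × sample total in millions); per-sample
library size therefore cancels.  ZRPKM standardizes each amplicon across
samples; zero-variance amplicons are flagged and excluded from the SVD.
SVD denoising zeroes the k largest singular components and reconstructs;
k = 0 is the identity and k ≥ min(dims) is an error.  **k defaults to 2**
for panel-scale cohorts (~1220 amplicons × 125 samples): exome-scale
defaults do not transfer, and the fitted singular-value spectrum is
exposed (`singular_values_`, plus a scree TSV from the CLI) so the
choice can be revisited per cohort.  Denoising is run once on the full
cohort (batch structure is shared), then groups are compared.

Per gene: the gene signal is the mean over its amplicons per sample.
The Welch (unequal-variance) t-test compares denoised gene signals
between phenotype groups — the source work says only "t-test", and
Welch is the safer default under unequal group sizes (90/35, 106/19).
The group fold change is mean resistant gene-level RPKM over mean
susceptible gene-level RPKM; the quantity the original "fold change"
was computed on is not stated, so this interpretation is recorded here
and the group means are reported alongside.  Every gene receives exactly
one determination: duplicated iff the resistant mean signal is ≥ the
susceptible mean (exact ties — a probability-zero event on real data —
go to "duplicated" with a flag), else deleted.  The reported
"significant duplications" are genes determined duplicated with
t_p ≤ 0.05.

mRMR uses the MID (difference) form with mutual information on
tercile-discretized gene signals: the first pick maximizes MI(signal,
phenotype); later picks maximize relevance minus mean redundancy against
the selected set; zero-relevance (e.g. constant) features are appended
last in input order.  The variant is unstated in the source; MID with
tercile discretization is the standard deterministic choice.

qPCR: ΔΔCq = (Cq_target − Cq_ref)_sample − (Cq_target − Cq_ref)_control
on replicate means; fold change 2^(−ΔΔCq); amplified iff fold ≥ 1.5
(inclusive).

## DAPC and snpzip

Pruning drops cohort-monomorphic SNPs (including those fixed for the
alternate allele) and SNPs with more than 5% missing calls (strict
inequality: 6/125 = 4.8% stays, 7/125 = 5.6% goes); residual missing
dosages are mean-imputed so the decomposition sees a complete matrix,
and the imputed fraction is recorded.  The dosage matrix is centered and
unit-scaled (scaling is unstated in the source; unit scale keeps
common and rare SNPs comparable).  PCA retains n_pcs components; a
linear discriminant on the retained PCs gives one axis for two classes;
per-SNP loadings are the discriminant coefficients back-projected
through the PC rotation, on the standardized dosage scale.  The
retained-PC count comes from repeated stratified cross-validation on
held-out assignment success, ties to the fewest PCs.  snpzip splits
|loadings| into two groups by Ward clustering (the common default; the
method is not named in the source) and returns the higher-mean group in
descending |loading| order; all-equal loadings are unsplittable and
return an empty flagged set.  Phenotype is the grouping factor, with the
permethrin labels as the default.

A structural caveat the tests make explicit: a handful of *independent*
causal SNPs is near-invisible to this procedure, because their joint
direction carries no excess variance for PCA to rank highly.  The
procedure works when associated SNPs come in LD blocks — the situation a
selective sweep produces and the situation in the motivating study,
where the selected SNPs clustered on two supercontigs.  Recovery tests
therefore plant LD blocks.

## Synthetic cohort model

The generator emulates the study design, not its sequences:

- **Populations**: eight named populations, sizes following the field
  sampling design; the listed sizes total 124, so the smallest
  population takes one extra individual to reach the 125 sequenced.
  Individuals are unrelated (one per family); population structure
  beyond per-population allele frequencies is off by default.
- **Panel**: 122 genes, 3 exons × 260 bp with 50 bp introns, random
  strands, two genes per supercontig, 150 bp flanks, tiled by 200 bp
  amplicons at 100 bp step alternating between two primer pools
  (~10 amplicons/gene, ~1220 total — matching the ~1255 primer pairs of
  the real panel at desk scale).
- **Genotypes**: Hardy–Weinberg dosages per population; neutral allele
  frequencies uniform on [0.05, 0.5]; neutral SNPs placed
  exon/intron/flank at 63/18/19% (the study's observed split); 2%
  missing calls.  A causal spec may plant an LD block: the first site
  carries the effect, the others copy each haploid allele of the causal
  haplotype with probability 0.95 (r² ≈ 0.8), emulating sweep-linked
  SNP clusters.
- **Phenotypes**: logistic in causal dosage — the minimal monotone model
  consistent with the trend test's co-dominant alternative; the paper
  has no generative model.  The intercept is calibrated (by solving the
  Hardy–Weinberg expectation) so the expected marginal resistant
  fraction matches the study's 106/125 (permethrin) and 90/125
  (malathion) even when causal effects are planted; explicit intercepts
  override this.  The bottle-bioassay rule is available directly: a
  family is resistant iff ≤ 80% dead at the diagnostic time (30 min
  permethrin, 45 min malathion).
- **Depths**: negative binomial with mean = 60 reads/amplicon (the
  "50× or more" coverage regime) and dispersion 12, times lognormal
  per-amplicon efficiency (σ 0.30), per-sample library scale (σ 0.25),
  per-run *amplicon-specific* batch biases (σ 0.25, runs of 12 samples
  emulating chips) and a small per-run pool factor (σ 0.05).  The batch
  biases are amplicon-specific on purpose: a per-run scalar cancels
  under RPKM and leaves nothing for the SVD stage to remove; real
  panels' run-to-run variation is amplicon-level amplification
  efficiency, and in this regime the leading singular components are
  batch — which is the premise of the denoising step.  Duplication
  carriers get copy-ratio-scaled means on the duplicated gene's
  amplicons only, with carriers drawn from the resistant group at the
  configured fraction.
- **Reproducibility**: all generators draw from child streams of one
  `SeedSequence`, so a config plus a seed reproduces the cohort
  byte-for-byte, and `truth.json` records planted SNPs (with their LD
  partners), duplication carriers, and the true per-sample resistance
  probabilities.

What the generator does *not* model — read-level artifacts, PCR
duplicates, kinship, LD beyond planted blocks, genotype-calling error
structure — bounds what passing tests show: they validate the
statistical machinery under the stated model, not robustness to
upstream calling artifacts.

## Problem sizes used by the automated checks

The recovery checks run at study dimensions (125 samples, 122 genes,
~1220 amplicons): CNV sensitivity over 10 cohorts × 6 planted 1.5×
duplications with 40% resistant carriers, null false-positive rate over
10 null cohorts (~1220 gene tests), Data Set 3 recovery over 100 cohorts
with one OR-8 causal SNP among 200 neutral, and snpzip recall over 10
cohorts with two 5-SNP LD blocks among 500 SNPs.  The Fisher oracle
enumerates all 20,475 2×2 tables with N ≤ 24; the trend-test permutation
oracle uses 10⁵ margin-conditioned draws.  These sizes keep the full
suite to a few minutes while leaving Monte-Carlo error well inside the
asserted margins.

## Known limitations

- The AUC is the study's own mean-of-sensitivity-and-specificity score;
  it is not comparable to ROC-AUCs from other tools.
- The trend test relies on the χ²(1) asymptotic; at very small counts it
  diverges from the exact permutation null (the tests quantify this),
  which is acceptable at cohort scale (N ≈ 125) but would not be for
  tiny phenotype groups.
- With SVD denoising, a CNV shared by many samples and aligned with a
  dominant component can be partially absorbed when batch structure is
  weak; the scree report exists so an analyst can lower k in that
  situation.
- snpzip recall is seed-variable (roughly 0.65–1.0 across replicate
  streams at the default conditions): when cross-validation retains a
  single PC, one of two independent planted blocks can dominate the
  axis.  This mirrors the method, not an implementation defect.
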