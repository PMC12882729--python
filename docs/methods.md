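# Methods

This note documents the models behind gtpanel, the defaults and why they
were chosen, the numerical decisions, and the limits of what the synthetic
tests demonstrate.

## Data model

A *microhaplotype locus* is a short (≤ 150 bp) reference-anchored sequence
carrying one or more SNPs close enough to sit on one sequencing read, so
its alleles are phased haplotype strings ("ACT") rather than independent
SNP genotypes. Single-SNP loci degenerate to single bases. Genotypes are
unordered diploid pairs of haplotype-catalogue indices; a missing call is
a dedicated sentinel, never an allele index. All internal coordinates are
0-based half-open; 1-based coordinates exist only at the VCF and report
boundaries, and the conversion is applied exactly once at input.

## Locus filters

- **Depth / missingness.** A locus needs mean coverage ≥ 20× (exactly 20
  is kept; the exclusion is strictly-below). Individuals are dropped when
  their missing fraction over the depth-passing loci is ≥ 25%
  (strictly-below retains), before any downstream statistic is computed.
- **Hardy–Weinberg.** The classic chi-square goodness-of-fit test on
  genotype classes (all unordered pairs of segregating alleles; degrees of
  freedom = #classes − #alleles), per temporal collection, Bonferroni
  correction across loci within each collection. A locus is discarded only
  when the corrected test is significant in **every** collection: a
  deviation confined to some years is indistinguishable from drift and
  sampling, whereas a genotyping artifact (null allele, paralog collapse)
  deviates everywhere. An empty collection cannot reject (p = 1). No exact
  test is provided; at the sample sizes of a monitoring program (n ≈ 30)
  the chi-square approximation is the intended behaviour of the classic
  test.
- **Linkage disequilibrium.** One SNP per locus is chosen with a logged
  seed. r² is the squared Pearson correlation of diploid dosages (0/1/2)
  over individuals called at both loci — a composite, phase-free measure;
  genotype-likelihood-aware LD estimators need read-level input that a
  called genotype matrix no longer carries, a documented divergence.
  Significance is n·r² against χ²(1) with n = the number of individuals in
  the pairwise-complete set, Bonferroni over all pairs. From each
  significant pair the locus with higher missingness is removed (ties: the
  lexicographically larger id), cascading until no significant pair
  remains among retained loci. The chain depth/missingness → HWE → LD is
  idempotent.

## Assay preparation

The trimming flank of 33 bp decomposes as 25 bp for the primer plus 8 bp
for the probe. "Within the first or last 33 bp" is read as 0-based offsets
0..32 from the relevant end: a SNP at 1-based position 33 has only 32
bases before it, which cannot hold 25 + 8. The rule is greedy per end —
cut through the offending SNP, rescan the next 33 bp window — run 5′ to a
fixpoint, then 3′; the two passes commute (property-tested), so the order
is presentational. Equivalence with an independent cut-point-enumeration
oracle is exhaustively tested at a reduced flank. Templates longer than
150 bp (the read length) are removed; exactly 150 is kept.

Probes are 17 nt: the allele base with 8 nt of template on both sides;
any other retained SNP inside the window becomes the IUPAC code over its
alleles, so one probe matches reads carrying any neighbouring allele.

Primer design itself is delegated to an external thermodynamic designer
(18–25 bp primers, 100–150 bp products, ≤ 5 ranked pairs per locus);
gtpanel consumes candidate tables and owns the surrounding logic. The
specificity screen searches each primer as an exact full-length match on
both strands of every reference sequence — the "100% coverage and
identity" criterion of a short-word BLAST screen is exactly exact-match,
so no alignment heuristics are needed; ambiguous reference bases never
match. Matches inside the source locus interval (identified by
coordinates) never count. Candidates are consumed in rank order until one
is specific; a locus with no specific pair is discarded. The synthetic
stand-in candidate generator (template-prefix forward, suffix
reverse-complement) exists so the iteration logic is testable; it designs
nothing thermodynamically and says so in its docstring.

## Panel selection

- **F_ST.** Weir–Cockerham (1984) variance components a, b, c per allele,
  with collections as populations; multi-allelic loci sum components over
  alleles, multilocus values are ratios of sums. Populations with no
  called genotype at a locus are excluded for that locus; loci with fewer
  than two informative populations or overall monomorphic are flagged
  undefined (NaN), never silently 0. The implementation is vectorized with
  a broadcastable leading axis so permutation tests evaluate thousands of
  relabelled datasets per call; tests pin it to an independently coded
  loop transcription of the textbook formulas at 1e-12.
- **Subsets.** Top-n by θ (undefined excluded, ties by locus id) plus a
  seeded random complement drawn from the loci not already taken by that
  scheme's top block. The default schemes are the five 500-locus recipes
  (pure top-F_ST, pure random, and 350/250/150 mixes).
- **Diversity.** H_E is Nei's unbiased estimator (2n/(2n−1) correction);
  H_O the observed heterozygote fraction; F_IS = 1 − ΣH_O/ΣH_E over
  polymorphic loci only (monomorphic loci carry no inbreeding
  information); A_R is the exact hypergeometric rarefaction expectation —
  not resampling — at g gene copies, g defaulting to twice the smallest
  per-collection called-genotype count; loci with fewer copies are skipped
  with a warning. CIs are percentile bootstrap over loci (1,000 draws by
  default) for all four statistics; bootstrapping over individuals is the
  other defensible family and the choice is configurable.
- **Pairwise F_ST.** Multilocus θ per collection pair; significance by
  permuting individuals between the two collections, one-sided
  (θ* ≥ θ̂) with the +1/(n+1) correction — the differentiation-testing
  convention; 10,000 permutations and 1,000 bootstrap draws by default.
- **DAPC.** Allele-dosage table → within-collection imputation (mean by
  default; a regression-forest option mirrors heavier imputation schemes
  but costs ~100× more and changes centroids negligibly at 3%
  missingness) → PCA without scaling → LDA on the retained PCs → 2
  discriminant axes. The a-score (mean over groups of correct
  reassignment minus its label-permuted expectation, default 10
  permutations, grid 1..min(50, n−groups)) selects the PC count when
  requested; a fixed count is accepted for replicate studies where
  comparability across fits matters more than per-fit optimality.
- **Subset comparison.** Discriminant axes from independent fits are
  arbitrary up to rotation and reflection, so subset centroid sets are
  aligned to the complete dataset's by orthogonal Procrustes (no scaling —
  a subset that exaggerates temporal structure *should* pay for it in
  distance) before per-year Euclidean distances; `none` replicates raw
  comparison. Schemes are ranked by mean distance ascending.

A caveat the synthetic experiments expose: in the whitened discriminant
space, top-θ̂ selection inflates apparent temporal separation (selection on
realized drift plus sampling noise) and random selection deflates it by a
comparable amount, so which scheme lands closer to the complete dataset
depends on how the complete dataset's own separation compares — on clean
equal-information Wright–Fisher loci the mixed-vs-pure ordering is not
systematic, even though the inflation itself is (the acceptance script
reports the measured win rate). On real data, locus heterogeneity and the
gap between the complete dataset and the candidate pool can tip this
either way; the ranking machinery is agnostic.

## Read simulation and multiplex QC

The read simulator emits single-end 150 bp reads (Phred+33, constant Q30
unless configured): on-target reads are the forward primer plus the
amplicon carrying one of the individual's haplotypes, base-substitution
errors outside the primer (configurable), padded with an adapter-like
tail; interaction reads are the forward primer of pair i, random filler,
and a primer of pair j ≠ i in either orientation. Ordered pair (i, j)
occurs at a rate ∝ w_i·w_j for per-locus propensities w, so a designated
"hot" set dominates the chimera load, and the panel-wide interaction
fraction scales with the surviving pairwise mass — re-simulating a pruned
panel behaves like the next optimization round. Per-read truth labels are
recorded at generation time (an on-target read whose probe window is
destroyed by a simulated error is truth-labelled unknown, since no counter
could see it). Depths are negative-binomial (mean 50, dispersion 10 —
comfortably above the genotyping floor yet cheap to simulate); defaults
for ε (per-read misassignment, 0.01) and the depth floor (10 reads) are
explicit stand-ins for unspecified assay constants and are configurable.

Classification: a read leads with the forward primer of exactly one locus
(prefix collisions are rejected upfront); containing any probe of that
locus makes it on-target; otherwise containing any other pair's primer
(fwd/rev, either orientation, anywhere downstream) makes it an
interaction; otherwise unknown. Genotypes are called per locus from phased
haplotype read counts (all SNPs sit on one read) under a multinomial
model: expected allele-read proportions (1−ε)·w + ε/k with w = 1
(homozygote) or 0.5/0.5 (heterozygote); the argmax over unordered pairs is
the call, total depth < 10 is missing. The model is scale-consistent
(multiplying counts by a constant never changes the argmax). This
multinomial formulation is this package's own; published amplicon
genotypers describe their likelihood only in documentation, so equivalence
is not claimed.

Concordance gates individuals at ≥ 70% locus call rate in both datasets,
compares unordered genotypes per SNP and averages over SNPs.
Representation folds (over 10× / under 0.1× of the mean on-target count)
are explicit defaults for a criterion usually stated only as
"disproportional". Removal recommendations walk loci by interaction
involvement until 90% of interaction reads are covered, with the duo rule:
a locus whose interactions are > 50% with one single partner loses only
the duo member with lower temporal θ (no θ: the busier member); a
protected locus (sex marker) deflects removal onto its partner. SNPs below
0.9 accuracy are dropped; the locus survives if another SNP passes. The
stopping rule is exactly: interaction proportion < 1/3 AND accuracy >
0.95; unavailable accuracy (genotyping rate too low, as in a
chimera-dominated first round) never stops.

Sex assignment is a lookup of the two-SNP diplotype at the sex-linked
locus in a user-supplied mapping (the genotype→sex key is assay-specific
and ships as configuration, not code); missing calls or unmapped
diplotypes are UNRESOLVED.

## The synthetic-data generator

Defaults emulate a two-decade monitoring series of a short-lived (1–3 y)
riverine fish: twelve collections (1999–2018, the gaps of a real archive),
30 diploids per collection, one generation per calendar year, Ne = 500
with a two-year bottleneck at Ne = 50 (2013–2014), 675 candidate loci (a
with-primers pool; the pipeline simulates a larger raw set and lets
trimming and screening thin it), 2–4 haplotype alleles per locus
(60/25/15%), symmetric Dirichlet(1) initial frequencies, and 3% missing
calls. Drift is multinomial resampling of allele frequencies — not
individual-based — which reproduces exactly the moments the estimators
consume (conditional frequency-change variance p₀q₀(1−(1−1/(2Ne))^t),
Hardy–Weinberg genotypes at the sampled year) at a fraction of the cost.
What it does not emulate: selection, migration, overlapping generations,
physical linkage, batch/preservation effects, allele dropout correlated
with depth, or PCR duplicates. Passing tests therefore certify the
estimators and the decision logic, not robustness to those real-data
pathologies. Same seed → byte-identical output everywhere.

For the temporal-θ expectation used in testing: between two samples of one
lineage t generations apart, only the later sample accrues drift relative
to the earlier, so E[(p₁−p₂)²] = p₀q₀·F_t with F_t = 1−(1−1/(2Ne))^t, and
the among-sample variance component is half the total temporal variance:
E[θ̂] ≈ (F_t/2)/(1−F_t/4). F_t itself is the right target for a
frequency-change (temporal-method) estimator, not for the two-sample
variance-components estimator; the tests assert each quantity against its
own closed form.

## Problem sizes

Test and acceptance runs use deliberately scaled problems chosen to
exercise every code path with tight Monte-Carlo error: 10,000 random loci
for the trimming oracle, 1,000 random tables for the F_ST oracle, 20
replicates of 500 loci for drift recovery, 200 null datasets at 500
permutations for p-value uniformity, 10,000 count vectors for the caller,
50 replicate series for the subset ordering, and a 120-locus panel with 30
hot pairs for the optimization loop. The end-to-end study in the
acceptance script runs 800 raw loci, 24 samples per year and a 120-locus
multiplex.

## Known limitations

- The probe/primer table dialect is this package's documented eight-column
  layout (locus, ploidy, alleles, probes, fwd_primer, snp_offset,
  allele_correction, notes); a strict reader rejects other layouts rather
  than guessing column semantics.
- LD is tested on called genotypes (see above), not read likelihoods.
- The specificity screen is exact-match by design; near-matches with
  mismatches, which can still mis-prime, are out of scope along with all
  primer thermodynamics.
- Multi-SNP genotypes come from single-read phase; assays whose SNPs span
  reads would need a phasing model the caller does not have.
- DAPC centroid comparison across independently fitted models is only
  defined up to the chosen alignment; both aligned and raw modes ship
  because the convention is not standardized.
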