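# Methods

## Scope and data model

`clonekin` operates on diploid-style dosage calls at bi-allelic SNPs:
0 (hom-ref), 1 (het), 2 (hom-alt), −1 (missing), stored samples × loci with
1-based VCF coordinates. Triploid individuals are represented by the same
three states, exactly as a diploid variant caller would emit them; nothing
downstream is ploidy-aware except the heterozygosity classifier. Indels,
multi-allelic sites and half-calls are excluded at read time (half-calls
become missing). Allele frequencies are always plug-in estimates
(alt-allele count over called alleles); minor-allele frequency is folded in
count space so loci at *f* and 1−*f* get identical MAF.

## Identity-by-descent estimator

The relatedness stage is a method-of-moments estimator on identity-by-state
counts. For a pair, over loci called in both samples, the IBS class is
2 − |d₁ − d₂| for dosages d. Conditional probabilities under random mating:

| | IBD 0 | IBD 1 | IBD 2 |
|---|---|---|---|
| IBS 0 | 2p²q² | 0 | 0 |
| IBS 1 | 4p³q + 4pq³ | 2p²q + 2pq² | 0 |
| IBS 2 | p⁴ + q⁴ + 4p²q² | p³ + q³ + p²q + pq² | 1 |

Summing each over the pair's complete loci gives the triangular system
solved as a cascade (Ẑ₀ from IBS 0, then Ẑ₁, then Ẑ₂); the raw solution is
clamped to [0, 1] and renormalized to sum one, and π̂ = Ẑ₁/2 + Ẑ₂.
Numerical choices:

- **Plug-in frequencies, no small-sample bias corrections.** The
  corrections are O(1/n) and all decision thresholds here are ranges robust
  to them; the estimator is deterministic and auditable. This is a
  deliberate deviation from what fuller kinship programs do internally.
- **Clamp-then-renormalize** keeps π̂ ∈ [0, 1] in all cases and makes the
  constraint rule explicit; the raw pre-clamp solution is also returned and
  is tested against an independent direct linear solve to 1e−10.
- **Boundary loci** (frequency 0, 1 or undefined) are excluded from both
  the counts and the expectations, with a warning, so both sides of the
  moment system always use the same locus set.
- **Missing data**: pairwise-complete deletion per pair.
- A pair with zero complete loci is flagged undefined, never silently 0.

Thresholds: clone edges at π̂ > 0.85 (strictly; the margin below the
theoretical 1.0 absorbs genotyping error and somatic mutation), first-degree
edges at 0.43 ≤ π̂ ≤ 0.52 (closed band, as calibrated on known pedigrees).
Pairs strictly between 0.52 and 0.85 are reported in an audit table rather
than dropped. Band inclusivity is configurable on the network constructor.
One representative per clonal component is kept, seeded-random by default
(lexicographic mode for byte-stable outputs).

## Ploidy classification

Under HWE a trisomic genotype is heterozygous (through a diploid caller)
with probability 1 − p³ − q³ = 3pq, versus 2pq for a disomic genotype —
a 50% excess at every frequency, which makes per-sample observed
heterozygosity bimodal in a mixed collection. Classification is either:

- **valley-split** (default): exact 1-D two-means over the sorted het
  values (exhaustive over sorted splits, which contains the optimum);
  the split is *rejected* (no-split flag, everything called diploid with a
  warning) when the between-cluster gap is below 2× the pooled
  within-cluster standard deviation √(WSS/n). Real ploidy mixtures clear
  that bar by an order of magnitude; the guard prevents a pure-diploid
  collection from being split anyway, which bare two-means always does.
- **fixed thresholds**: diploid at het ≤ 0.335, triploid at het ≥ 0.345,
  ambiguous strictly between. Appropriate once a collection's bimodality
  has been characterised; the data-driven split is the default because
  fixed cutpoints do not transfer across collections.

Ambiguous samples are excluded from the first-degree stage with a warning.
There is no tetraploid class; values far above the triploid cluster only
warn. Real collections violate HWE, compressing the observed
triploid/diploid ratio below 1.5 (to ~1.3 in heavily related material), so
the package reports the observed ratio and never asserts the analytic one
on data.

## Filter cascade

Order as driven by the pipeline: bi-allelic + per-genotype min depth (8) at
read time → distance thinning (10 bp, greedy left-to-right per chromosome)
→ missingness (≤ 20% per locus, then per sample over surviving loci) →
mean-depth 90th-percentile cap → HWE exact test (p ≥ 10⁻⁴) → MAF
(> 0.05 for relatedness; > 0.01 for PCA). Notes:

- The HWE test is the exact conditional test on the heterozygote count
  given allele counts (enumeration over het counts of matching parity);
  two-sided by default, with a one-sided excess-heterozygosity option.
  Monomorphic loci return p = 1.
- The depth percentile uses linear interpolation (documented because
  survivor counts depend on it). Re-applying the percentile form
  re-estimates the cutoff on the survivors and trims again by construction;
  the absolute-cap form `filter_depth_cap` is the idempotent primitive.
  All other filters are idempotent as applied.
- LD pruning slides a window of 10 surviving SNPs advancing by 3 per
  chromosome; within a window, while any pair exceeds r² = 0.5
  (pairwise-complete Pearson on dosages; zero-variance pairs count as 0),
  the lower-MAF member is removed (tie: later position). Sweeps repeat
  until stable, so the no-violating-pair postcondition holds on exit.

## PCA and group tests

Missing dosages are mean-imputed per locus; columns are centered and scaled
by the population (divide-by-n) standard deviation, zero-variance columns
dropped. Decomposition is by SVD; explained fractions are eigenvalue shares
and component signs are normalized so the largest-magnitude loading is
positive. Group separation along a PC uses a two-sided Mann-Whitney U test:
exact enumeration when the combined n ≤ 12 with no ties, otherwise the
normal approximation with tie and continuity corrections. All p-values in
the structure stage are Bonferroni-multiplied by the experiment-wide
comparison count (25 for the 5 × 5 cross-marker PC correlation table and
the associated group tests). Dosage coding (0/1/2) is used throughout.

## The simulator

`simulate_collection` emulates the composition of a clonally propagated
gene bank; its defaults are the package's reference study conditions,
chosen once:

| parameter | default | why |
|---|---|---|
| n_loci | 5,000 | enough for π̂ s.e. ≈ 0.006; desk-scale runtimes |
| allele-frequency law | U(0.05, 0.5) | post-MAF-filter GBS frequency spectrum |
| founders | 176 | with the groups below, totals 349 accessions |
| clone groups | 31×2 + 3,3,3,4,4,4,5,5,5,6,15 | 42 groups, 119 clonal members, largest 15 |
| offspring | 30 | founder × founder Mendelian crosses |
| triploids | 66 (~19%) | unreduced ♀ gamete + haploid ♂ gamete, diploid-coded |
| error rate | 0.002/call | clone-vs-source discordance (error + somatic mutation) |
| missing rate | 0.05/call | typical reduced-representation dropout |

Mechanics: founders are Binomial(2, p) per locus (HWE, unlinked); offspring
draw one uniform allele per parent per locus; a triploid takes both alleles
of parent A plus one of parent B and collapses to dosage 1 unless all three
alleles agree (AAB and ABB both read as heterozygous — a diploid caller
sees both alleles regardless of ratio); clonal copies flip each call with
the error probability to a uniform other state; missingness is i.i.d.
Optional two-subpopulation structure draws a second founder frequency
vector by a Balding-Nichols Beta perturbation with an FST-like parameter.
Per-call error is applied to clonal copies only — founders, offspring and
triploids carry exact genotypes — so the error rate is interpretable as
clone-pair discordance, the quantity that matters for the 0.85 threshold.

What the simulator does **not** model, and hence what passing tests do not
show about real data: linkage (loci are unlinked, so the LD pruner is
exercised on duplicated/resampled columns instead), departure from HWE in
the founder pool (real collections are related, which compresses the
triploid/diploid het ratio and shifts π̂ calibrations), multi-generation
pedigrees, selfing, aneuploidy, reference-genome artefacts (the real
motivation for the depth cap), and sequence-level error structure (depth is
simulated as a Poisson floor-shifted count independent of the calls).
Positions are consecutive multiples of 1 kb on one chromosome, keeping the
10 bp thinning filter inert by default.

## Pipeline order and bookkeeping

Clone network on all filtered samples → one representative per clonal
component → heterozygosity/ploidy on the representatives → triploid and
ambiguous exclusion → IBD recomputed on the unique diploids → first-degree
network → PCA. Every sample ends in exactly one disposition
(unique-diploid / clone-duplicate / triploid-excluded / ambiguous-excluded /
filtered-out), "unique genotypes" = singletons + one per clonal group, and
percentages are always recomputed from counts. Reports echo the full
configuration and are byte-identical under a fixed seed.

## Known limitations

- The first-degree band [0.43, 0.52] was calibrated at ~15k SNPs on real
  pedigrees; at other SNP densities or error levels the π̂ sampling
  distribution widens and the closed band clips its tails (measured ~98–99%
  per-pair sensitivity at 5,000 loci with 0.2% clone error). The package
  reports band membership, not a guarantee of pedigree completeness, and
  surfaces between-band pairs in the audit table.
- Where triploids are derived from a narrow diploid base, the
  heterozygosity modes can merge; the valley-split guard will then refuse
  to split rather than fabricate classes.
- π̂ from diploid-coded triploid calls is not a calibrated quantity; the
  pipeline follows the curation order (clones first, ploidy exclusion
  second) without claiming the clone threshold is tuned for triploid pairs.
- No maximum-likelihood kinship, no IBD segments, no admixture modelling;
  PCA plus rank tests is the whole structure stage.

## Problem sizes used by the test suite

Property and recovery tests run on simulated collections of 40–350 samples
at 300–5,000 loci, 8–20 seeds per property — sizes at which every stage's
behaviour is already asymptotic enough for the decision thresholds being
tested, while the full suite stays comfortably within a coffee break.
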