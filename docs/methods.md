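# Methods

This note records the models implemented in `mutascope`, the parameter
choices that matter, and what the synthetic-data generators do and do not
emulate.

## Coordinate conventions

All internal coordinates are 0-based, half-open.  Variant tables and VCF
emission use 1-based positions (converted at the I/O boundary).  Deletions
are reported as half-open `[left, right)` breakpoint pairs on the construct,
always left-aligned: when the two junction flanks share sequence, all
`mh + 1` placements reconstruct the same molecule and the leftmost is
canonical.  The microhomology length `mh` is defined as the size of that
shared run — equivalently the maximal exact repeat carried by the two
flanks — and is placement-invariant.

## Genome model and the BIR track

The default `GenomeModel` has 16 nominal chromosomes totalling exactly
12.0 Mb, with the BIR track the terminal 120 kb of the chrIII right arm, so
`track_fraction = 0.01` exactly.  A repair track of roughly one percent of a
yeast-sized genome is the regime of interest; making the fraction exact
keeps the redistribution null's Binomial(n, f) oracle exact as well.  The
disomic configuration of a BIR strain (a second, donor copy of chrIII) is
constructible through the model's fields but deliberately left out of the
default, which describes the haploid reference coordinate space that
variants are called against.  Centromere positions are nominal (chrIII at
115 kb, others mid-chromosome); only the left/right arm split depends on
them, and they are ordinary parameters.

Reference sequence is synthesized i.i.d. at 40% GC, per chromosome from a
`(seed, chromosome-index)` stream, so any subset of chromosomes reproduces
identically.

## Variant pipeline

Filters follow the strand-resolved WGS analysis conventions:

* allele fraction < 0.35 removed; exactly 0.35 kept (the rule removes
  strictly lower values; `keep_af_at_threshold=False` flips this reading);
* allele fraction ≥ 0.85 called homozygous, otherwise heterozygous;
* a variant whose `(chrom, pos, alt)` occurs in ≥ 2 distinct samples is
  treated as pre-existing and removed from every sample.  "Distinct
  samples" means distinct `sample_id`s within the analysed cohort.  The
  filter is idempotent;
* allele fractions outside [0, 1] are rejected and reported, not silently
  dropped.

Strand class comes from the Watson-strand reference base: C→N variants mark
A3A lesions in the nascent-strand ssDNA (lagging-strand template), G→N
variants mark lesions in the D-loop bottom template strand.  Indels are
ingested but classed `other`; multi-allelic VCF records are split into
biallelic rows on read.  TCW annotation tests the Watson triplet (TCA/TCT)
for C→N and the Crick triplet for G→N (i.e. Watson TGA/AGA); variants
without two flanking bases of context are flagged undefined rather than
guessed.

## Redistribution null

`redistribute(n, genome, n_samplings, seed)` places `n` positions uniformly
at random over the concatenated genome per sampling and counts those inside
the track.  Sampling is with replacement at the position level: for ~100
mutations over 12 Mb the collision probability is negligible and the
per-sampling count is then exactly Binomial(n, f), which the test suite
verifies by chi-square at 100,000 samplings.  "Samplings" are independent
draws (deduplicating identical outcomes would be statistically
meaningless).  The empirical tail is `#{count ≥ k}/n_samplings`, with an
optional add-one form `(#+1)/(n+1)` as a nonzero Monte-Carlo p-value bound.
The KDE is Gaussian with Silverman bandwidth; an all-identical count vector
falls back to a fixed minimum bandwidth (0.3) and is flagged.

## Reporter construct and fixture engineering

The construct is `fwd_primer + left flank + DR·IR·spacer·IR·DR + right
flank + revcomp(rev_primer)`, default geometry 69/9/9 with 120-bp flanks
(405-bp amplicon).  The insertion duplicates one direct-repeat copy, so its
net inserted length is 2·69+9+9 = 156 and precise excision leaves a 9-bp
(DR-length) microhomology.  Four canonical fixtures are engineered:

| fixture | deletion | microhomology | frame | polarity |
|---|---|---|---|---|
| precise | 156 bp | 9 bp | in | DR-to-DR excision |
| typeI | 126 bp | 6 bp | in | left breakpoint inside the left IR arm, right microhomology outside |
| typeII | 171 bp | 6 bp | in | opposite polarity; also removes flanking reporter sequence |
| J1 | 125 nt | 5 bp | out | frequent out-of-frame class, invisible to phenotypic selection |

Frame status is `del_len mod 3 == 0` (126, 156 and 171 are divisible by 3;
125 is not).  Because the published reporter's base-level sequence is not a
machine-readable input, the generator engineers an equivalent context:
random arm/flank sequence with targeted base assignments that give each
fixture *exactly* its expected microhomology (copied runs plus boundary
bases forced unequal so the run cannot extend), for both insert
orientations.  Ori2 is the same construct with the insertion region
reverse-complemented; its fixtures are the mirror images of the Ori1 ones,
and a brute-force verification of every fixture's left-alignment and
microhomology runs at build time.  The engineering needs room for the
junction offsets — `ir_len ≥ 65`, `dr_len ≥ 7`, `flank_len ≥ 80` — and the
builder rejects geometries outside this family (including any arm shorter
than a fixture's microhomology).

## Junction caller

The filter cascade mirrors a deep-sequencing deletion analysis: DUST-style
low-complexity filtering, exact primer anchoring (either final-amplicon
primer, unchanged; reverse-orientation reads are reoriented; conflicting
orientations are rejected as ambiguous), removal of reads under 220 bp and
of reads consistent with the no-deletion amplicon (≤ 2 substitutions),
grouping of identical sequences, junction detection on the most common
groups (largest groups covering ≥ 90% of surviving reads, minimum support
5 — automation of a manually-verified step needs a threshold; the largest
group is always eligible so tiny pools still get a reference), and
assignment of the rest to detected junctions at a Hamming distance ≤ 2
(substitutions only — the "two errors" tolerance is read as excluding
indels; ties break toward the higher-support junction, then lexically).

The DUST score normalizes the triplet-redundancy sum `Σ c(c−1)/2 /
(window − 2)` over 64-bp windows so a homopolymer scores 1.0 and a window of
all-distinct trinucleotides 0.0; the read score is the max over windows.
**Direction of the threshold:** the protocol this emulates is printed as
removing reads with scores *lower* than 0.07, but under this normalization
ordinary amplicon reads score ≈ 0.02 and dimer repeats ≈ 0.5, so the
as-printed direction would discard every real read and keep the junk — the
printed sentence is evidently a transcription slip of the conventional
filter.  Both directions are implemented
(`dust_mode={"conventional","as-printed"}`); the default is conventional
(remove scores above the threshold), which is the only direction consistent
with the pipeline producing output at all.

Detection assumes one contiguous deletion and substitution-only errors, so
the deletion length is fixed by the read/construct length difference; the
junction position minimizes mismatches via prefix/suffix mismatch arrays
(O(L)), preferring the leftmost minimizer, then left-aligns on the
construct.  Reads that no single-deletion model explains within the
mismatch slack (default 2) — including double deletions — return no call
and are counted, so input reads are always conserved across
dust/primer/length/no-deletion/called/unassigned.  The test suite checks
the caller against an exhaustive breakpoint-pair oracle on 500 random
errorless junctions.

## Rates and statistics

* Reversion frequency: `(selective count × volume factor) / (viable count ×
  volume factor)`.  The upstream literature's exact rate formula is not
  restated here; medians and CIs of frequencies are what the comparisons
  operate on, and the estimator is pluggable.
* Median CI: exact binomial order statistics — the largest symmetric rank
  pair `(j, n+1−j)` with `P(j ≤ B ≤ n−j) ≥ 0.95`, `B ~ Binomial(n, ½)`
  (for n = 10: ranks 2 and 9).  Below 6 replicates the min–max range is
  reported instead, tagged `"range"`.
* Mann–Whitney U, two-sided: exact enumeration when both groups have ≤ 8
  observations and no cross-group ties, tie-corrected normal approximation
  otherwise; fully tied inputs return p = 1, flagged.  Fisher's exact test
  is two-sided by hypergeometric tail summation (cross-checked against full
  enumeration in the tests).  No multiple-testing correction is applied;
  raw p-values are reported.
* ddPCR: per channel λ = −ln(1 − positives/total); frequency =
  (λ_target/λ_reference) × dilution ratio.  Saturated channels are
  undefined and rejected.  As occupancy → 0 this reduces to the ratio of
  positive fractions.
* Fraction-shift prediction: `frac_A / (class_ratio × overall_ratio)` —
  the focal class's frequency falls `class_ratio`-fold while the
  denominator (total rate) rises `overall_ratio`-fold.  dU→mutation
  fraction: `100/ratio` percent, assuming every dU mutates when uracil
  glycosylase is absent (hence ratio < 1 is a model violation).

## Synthetic-data generators: what they emulate, and don't

The generators reproduce the *observable endpoints* of BIR mutagenesis, not
the mechanism: no resection-length variability, D-loop migration kinetics,
or fork mechanics.

* **Variant tables** (`LesionSimConfig`): per outcome, track lesion counts
  are Poisson — defaults `n_outcomes=62`, `nascent_rate=5.6`,
  `dbts_rate=0.66` mirror a 62-outcome Ung1-proficient cohort (345 C→N and
  41 G→N track mutations overall); positions are drawn without replacement
  from the track's TCW-compatible sites (Watson TCA/TCT for C lesions,
  TGA/AGA for D-BTS lesions).  With Ung1 active the mutation-type mixture
  is 45/45/10 transition/transversion/transversion per strand (reflecting
  roughly equal abasic-site and direct-miscoding outcomes); in ung1Δ mode
  lesions are pure C→T / G→A.  Heterozygous allele fractions are
  Beta(20, 20) (centred on 0.5, s.d. ≈ 0.08), homozygous Beta(60, 3),
  artifacts Uniform(0.05, 0.30) — the thresholds 0.35/0.85 are given by the
  analysis, the generative shapes are this package's choice of a realistic
  sequencing-noise model.  About 3% of true heterozygous lesions fall below
  the 0.35 cutoff and a handful of independent lesions collide at the same
  site across outcomes (and are then removed as "recurrent"); recovery
  tests therefore check count *ratios* to sampling error, not exact
  equality.  Shared pre-existing variants are injected identically into
  every outcome.
* **Read pools**: junction reads are exact fixture deletions of the
  amplicon with both primers present before errors; substitution errors are
  i.i.d. per base (no indels, keeping junction ground truth unambiguous —
  indel noise would be a config extension); half the reads are emitted
  reverse-complemented; contaminants are homopolymer/dimer repeats and
  short primer-bearing fragments.  PCR amplification bias, chimeras and
  quality decay along the read are *not* modelled, so passing tests
  demonstrate algorithmic correctness, not robustness to every real-library
  artifact.
* **Assay counts**: selective colonies are Binomial(cells, frequency) per
  culture, droplet positives Binomial with Poisson occupancy.  Fluctuation
  (jackpot) skew of mutant counts is not modelled, consistent with the
  frequency-based median/CI reporting used here (no Luria–Delbrück
  estimators).

## Problem sizes and numerical choices

The default test-and-acceptance workloads are the analysis-scale ones: the
null at the full 100,000 samplings (sub-second in vectorized chunks of
20,000 × 98 draws), parameter recovery on 50 simulated outcomes, oracle
equivalence on 500 random junctions, and CI coverage on 200 simulated
assays of 12 cultures.  Degenerate inputs are handled explicitly rather
than by exception where the quantity is well-defined: zero mutations give
an all-zero null, empty groups are flagged with n = 0, zero-variance KDEs
fall back to a fixed bandwidth, and all-tied rank tests return p = 1.

## Known limitations

* The junction caller models single contiguous deletions; inversions,
  duplications, double deletions and insertion-bearing junctions are
  deliberately out of scope (complex reads are counted, not called).
* Primer anchoring is exact-match by design; reads whose primer carries a
  sequencing error are lost at that stage (visible in the conservation
  accounting).
* The variant pipeline ingests caller output; alignment, base-quality
  recalibration and somatic calling are upstream concerns.
* The synthetic genome is i.i.d. sequence: real motif densities,
  replication timing and chromatin context are not represented, so absolute
  lesion densities are nominal even though strand logic, filters and
  statistics are exercised exactly.
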