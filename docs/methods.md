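# Methods

This note records the models, parameter choices and numerical decisions
behind each stage, and what the synthetic-data generators do and do not
emulate.

## Variant filtering from paired pileups

The filter is a deterministic threshold scheme for a diploid
ancestor/evolved strain pair, not a likelihood model. Allele frequency for
a base allele is supporting reads over the *unambiguous* depth (reads with
an `A/C/G/T` call); `N` and `*` reads are quality signals, tracked
separately and excluded from the denominator. Indel allele frequency uses
the total depth, since indel-bearing reads also report a base at the
anchor position.

Rules and guards (defaults in `FilterParams`):

| parameter | default | meaning |
|---|---|---|
| `min_af_evo_het` | 0.30 | rule A evolved-strain floor (heterozygote) |
| `max_af_anc` | 0.10 | rule A ancestor ceiling |
| `min_af_evo_hom` | 0.80 | rule B evolved floor (homozygote) |
| `max_af_anc_hom` | 0.80 (exclusive) | rule B ancestor ceiling |
| `min_depth_snp` | 5 | reads covering the site, each strain |
| `max_ambiguous` | 1 | `N` + `*` budget, per strain |
| `min_depth_indel` | 10 | raw coverage floor for indels, each strain |
| `min_indel_delta` | 0.30 | required allele-frequency difference |
| `top2_indel_fraction` | 0.80 | top-2 share when > 2 indel strings occur |

Design choices that the thresholds do not determine by themselves:

* The ambiguity budget is applied per strain (the stricter, symmetric
  reading), counting `N` and `*` jointly.
* Strand confirmation is demanded in the evolved strain only — the strain
  asserting the new allele.
* Zygosity labels reuse the filter constants (≤ 0.10 hom-ref, [0.30, 0.80)
  het, ≥ 0.80 hom-alt); frequencies in (0.10, 0.30) are labelled
  ambiguous, and an ambiguous endpoint does not veto a call whose rule
  passes.
* Every alt base with evolved support is evaluated independently; if both
  rules hold, rule B is recorded (homozygosity is the stronger claim).
* The `>2 indel strings` guard pools counts across the two strains and
  compares the top two against the pooled covering reads.

The whole-pileup scan is vectorized over the site table; a property test
checks it against the single-site scalar path.

## Feature annotation and mutation tables

CDS consequences are computed codon-locally: the affected codon is mutated
with all other positions at reference, matching single-substitution
notation like `P 320 S` (`syn` for synonymous, `*` for a created stop).
Frameshifting indels are annotated with the signed change in translated
protein length before the first stop (`-169aa` style). Intergenic variants
report the nearest flanking gene(s) as `LEFT/RIGHT`. Multi-row events
(adjacent substitutions) are kept as separate rows; no MNV merging.
Coordinates are 1-based inclusive in memory and in mutation tables;
BED-like files on disk are 0-based half-open and converted at the
boundary.

The five transcribed per-strain mutation tables ship as package data and
round-trip byte-for-byte through the parser/writer. Summaries report raw
row-derived counts; prose counts in the literature occasionally disagree
with naive row counting, and no forcing is applied.

## Neutral mutation statistics

`NeutralModel` exposes ploidy explicitly (default 2) instead of folding it
into L: the diploid cell presents 2L mutable bases per generation. With
μ = 6.44e-10 /bp/gen (the CAN1 fluctuation-assay estimate of Lang &
Murray, the most generous published rate for budding yeast) and haploid
L = 12,071,326 bp (the S288c nuclear genome; the mitochondrial genome is
excluded), 460 generations give λ ≈ 7.15.

Upper tails are exact Poisson survival probabilities via the regularized
incomplete gamma function; a term-by-term summation oracle agrees to
1e-10 over λ ≤ 30, observed ≤ 60. Indels are excluded from observed
counts by default (per-strain totals are SNP-only), with a flag to
include them.

Class partitions use expected = n·p with a Poisson tail on the observed
sub-count at λ = n·p. Note this Poisson treatment of a bounded binomial
sub-count is conservative in the upper tail; tails for specific published
sub-counts are reported as computed here and are not calibrated against
any externally printed p-values, which could not be reproduced from the
stated construction.

The genome-wide class probabilities come from `evoscan.genome`:
`coding_fraction` is the CDS-interval union (stop codons included) over
total genome length; `genome_nonsyn_probability` averages, over every
sense codon of every CDS (overlapping genes counted independently), the
fraction of the codon's 9 single-nucleotide mutants that change the
residue or create a stop. Stop codons are excluded from the average (they
encode no amino acid) but mutations *to* a stop count as non-synonymous.
Whether published genome-wide values include introns, dubious ORFs or the
mitochondrion is annotation-version dependent; reproducing them exactly
requires the matching reference FASTA and gene set.

## CNV segmentation

Pipeline: bin → log ratio → outlier smoothing → circular binary
segmentation (CBS) → sd-undo.

* Binning averages interval depth into fixed-width bins (1 kb default);
  the last bin per chromosome may be short; uncovered bins are missing and
  dropped before the ratio.
* The log2(evolved/ancestor) ratio uses a pseudocount (default 0.5) and is
  centered on the genome-wide mean of retained bins, removing global
  depth-of-sequencing differences.
* Outlier smoothing shrinks *isolated* single-bin outliers (> 4 noise SDs
  from the median of their ±3-bin neighborhood) to that median ± 4 SDs;
  runs of two or more adjacent outliers are untouched, since short real
  events look exactly like that.
* CBS: for each chromosome the circularized series is searched over all
  boundary pairs (i, j) whose two arcs have ≥ `min_width` (5) bins,
  maximizing the between-arc Welch t statistic (unequal variances). A
  split is accepted when its permutation p-value is < α = 0.01 under
  `nperm` = 10,000 within-segment permutations; accepted cut points are
  applied and the pieces are recursed. Permutation streams derive from
  (seed, test counter), so a run is bit-reproducible for a given seed.
* The permutation loop stops early once exceedances reach
  ceil(α·nperm) = 100, the exact point at which the completed-run p-value
  is guaranteed to be ≥ α. For speed the exceedance check is evaluated as
  a per-pair quadratic in the arc sums with precomputed coefficients
  (permutations preserve the series totals), in float32.
* Noise SD is estimated robustly as 1.4826·MAD(first differences)/√2 —
  insensitive to true copy-number steps. sd-undo then iteratively merges,
  least-significant-difference first, adjacent segments whose means differ
  by < 4 noise SDs.

Degenerate inputs: a constant series has zero statistic everywhere and
stays one segment; a noiseless step has zero within-arc variance, which a
small variance guard turns into an effectively infinite statistic, so
exact change points are recovered.

## Fitness, growth, qPCR

* Chemostat generations are counted from measured effluent turnover,
  g = V_effluent/(V_culture·ln 2); a nominal g = D·t/ln 2 fallback exists
  for runs without effluent records. Serial-transfer generations are
  transfers × log2(dilution factor) (≈ 6.6 per 100-fold daily dilution).
* `competition_coefficient` is an OLS fit (slope, SE, r²) of ln(test/ref)
  on generations; samples with a zero count on either side are dropped,
  and < 3 usable samples is an error, not a guess.
* Normalization divides replicate-mean s by the ancestor's replicate mean
  within an environment (ratio of means, matching bar-level
  normalization), mapping the ancestor to exactly 1; a near-zero ancestor
  mean raises an error. Replicate comparisons use a two-tailed Welch
  t-test — group sizes of ~3 give no basis for assuming equal variances.
* μ_max is the maximum sliding-window (default 5 points) OLS slope of
  ln(OD) vs time, after dropping non-positive ODs.
* ΔΔCt: ΔCt = Ct_target − Ct_control per record, ΔΔCt subtracts the
  calibrator's ΔCt, copy number = 2^(−ΔΔCt); replicate lists average ΔCt
  first and return (mean, SD).

## Synthetic data: what it emulates, and what it does not

Each generator draws from its own stream derived from (scenario seed,
CRC32 of the generator name), so outputs are bit-reproducible and adding a
generator never perturbs another's stream.

* **Genome**: random sequence with non-overlapping ORFs (ATG … stop, no
  internal stops) packed to a requested coding fraction (default 0.72,
  the gene-dense regime of a yeast-like genome).
* **Pileups**: per site, depth ~ Poisson(50); each read is ref, an error
  (rate 0.005, uniform over the three alt bases), `N` (0.001) or `*`
  (0.001); planted diploid variants draw alt support
  Binomial(depth, 0.5 or 1.0); strands split Bernoulli(0.5). Reads are
  site-independent — no read-length correlation, mapping artifacts,
  GC bias or quality structure. Passing filter tests therefore shows the
  thresholds behave as specified under the assumed sampling model, not
  that they are robust to alignment pathology.
* **Coverage**: bin values are means of per-base Poisson coverage
  (bin total ~ Poisson(depth·width), divided by width), emulating raw
  coverage averaged over 1-kb windows; planted segments scale the rate by
  2^shift. At depth 50 this gives a log2-ratio bin SD of ≈ 0.009.
* **Competition**: the expected test-strain fraction follows the logistic
  trajectory implied by a constant ln-ratio slope s; 50,000 cells are
  counted per sample (binomial). Default s = 0.28 with 8 samples over 20
  generations in a 400-mL chemostat at D = 0.17 h⁻¹.
* **Growth**: noise-free logistic OD with intrinsic rate μ (default
  0.40 h⁻¹, od0 = 0.05, K = 2.0, 24 h at 15-min sampling).
* **qPCR**: Ct_target = ct0 − log2(copy number) + N(0, σ), Ct_control =
  ct0; σ defaults to 0 so inversion is exact.

## Problem sizes used in the test suite

Recovery checks run at: 100-kb genomes with 20 planted heterozygous SNPs
(3 seeds) and 20 mutation-free seeds for the false-positive check; 120-bin
coverage tracks with a 50-bin +1.0 log2 event over 100 replicates; 200
simulated competition series per planted s ∈ {0.143, 0.280, 0.437}. These
sizes make the binomial/Poisson tails that drive sensitivity and
false-positive behavior essentially deterministic while keeping the suite
fast.

## Known limitations

* The filter has no base-quality or mapping-quality model; it assumes the
  pileup counts are trustworthy.
* CBS here uses the Welch two-sample t on bin values with an explicit MAD
  noise estimator; reference implementations differ in smoothing and SD
  details, so borderline splits may differ — equivalence is claimed only
  on clear signals.
* The Poisson partition of sub-counts ignores the binomial upper bound at
  n, making upper-tail p-values conservative.
* Chemostat generation accounting from effluent assumes well-mixed
  steady-state turnover; transient start-up deviations are not modelled.
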