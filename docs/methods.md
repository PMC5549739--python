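# Methods

## Model and procedure

The analysis asks whether risk-increasing alleles for a disease group are
systematically more frequent in one population than another. Two statistics
carry the inference:

- **Unweighted GRS.** Per individual, the sum of risk-allele dosages over a
  fixed panel of M quasi-independent variants. No effect-size weights are
  used: the question is about coordinated frequency shifts, and in settings
  where the selected phenotype is unknown (or effect sizes were estimated in
  other populations) weights would import bias without adding power. With
  complete hard calls the score is an integer in [0, 2M]; under
  Hardy–Weinberg equilibrium its group mean is 2Σf and its variance
  Σ2f(1−f), identities the test suite verifies.
- **Binomial sign test.** Each variant contributes only the sign of its
  frequency difference between the focal and reference group. Under neutral
  drift signs are independent fair coin flips, so the count n₊ of variants
  higher in the focal group is Binomial(n, ½) over the n informative
  (non-tied) variants. We report the exact one-sided tail P(X ≥ n₊); a
  two-sided variant doubles the smaller tail and caps at 1. Exact ties are
  excluded, following classical sign-test practice. The test needs only
  frequencies, never genotypes or effect sizes.

The directional one-sided default reflects the motivating hypothesis
(risk alleles enriched in the focal, African-ancestry-like, group); the flag
`alternative="two-sided"` serves agnostic scans.

## Pipeline conventions

- **Coordinates** are 1-based (VCF convention); exclusion regions are
  half-open [start, end) so adjacency is unambiguous. The default HLA/MHC
  exclusion is GRCh37 chr6:25,000,000–35,000,000 — a deliberately wide
  extended-MHC window, configurable.
- **Harmonization**: exact {risk, other} vs {REF, ALT} match wins, then the
  reverse-complement match (strand flip). Palindromic A/T and C/G pairs that
  match without flipping are accepted as plus-strand and flagged
  (`ambiguous_palindrome`), because reference cohorts such as 1000 Genomes
  are plus-strand by construction; dropping them silently would shrink the
  panel. Unresolved variants are excluded with a logged reason, never
  guessed. DS dosages take precedence over GT hard calls when both exist.
  Missing calls stay missing (NaN), never zero-filled — zero would bias
  scores downward.
- **Missing-data policy** for the GRS: default `rescale` multiplies each
  individual's sum by M_total/m_used, keeping individuals with different
  marker availability on one scale; `raw` reports the bare sum. `m_used` is
  always reported.
- **LD pruning** is greedy keep-first in genomic order (chromosome,
  position, rsID), threshold r² < 0.2, with an optional
  most-significant-first ranking. r² is the squared Pearson correlation of
  unphased dosage vectors over pairwise-complete samples (composite LD) —
  phase-free and standard for pruning. Monomorphic pairs are treated as
  unlinked. Cross-chromosome pairs are never pruned. A post-hoc assertion
  re-checks every kept pair after each run.
- **Welch's t-test** (two-sided) compares group means; quartiles use linear
  interpolation between order statistics so summary tables are reproducible
  bit-for-bit.
- The large-difference subset uses a strict |Δf| > 0.2 (configurable).

## The simulator

`signburden.simulate` emulates two populations diverging from a shared
ancestral frequency p under the Balding–Nichols model: each population's
frequency is Beta(p(1−F)/F, (1−p)(1−F)/F), with mean p and variance
F·p(1−p), F being F_ST. Genotypes are Binomial(2, f) per individual
(Hardy–Weinberg, unlinked loci). Selection is a fixed logit-scale shift δ of
the focal population's risk-allele frequency — the simplest directional
alternative to drift. Frequencies are clamped to [0.01, 0.99] (configurable)
so no simulated variant is monomorphic and silently dropped downstream.

Defaults are the study conditions the package targets: L = 147 variants,
300 individuals per population, F_ST = 0.15 (continental-scale divergence,
about the African–European value), ancestral frequencies uniform on
[0.05, 0.95]. LD blocks for exercising the pruner are made by copying a seed
variant's genotype column and, with probability 1 − fidelity per entry,
redrawing the genotype from Binomial(2, f) — this keeps the marginal
frequency of every block member exactly at the truth-table value while
giving within-block r² near the fidelity. A fixed seed yields byte-identical
output files.

What the simulator does **not** emulate: realistic site-frequency spectra,
linkage beyond the artificial blocks, admixture, genotyping/imputation
error, or ascertainment of GWAS hits toward common variants. Passing tests
therefore demonstrate the statistical machinery is correct and calibrated
under the stated null, not that any particular real dataset satisfies that
null.

## Calibration results the code computes

`analysis/03_calibration.py` and the acceptance tests measure, at L = 147
and n = 300 per population:

- **Type-I error**: neutral (δ = 0) rejection at α = 0.05 sits near 0.045
  across F_ST ∈ {0.05, 0.15} — slightly conservative, because the exact
  binomial critical value (n₊ ≥ 84 at n = 147, tail 0.049) is discrete.
- **Power**: rises steeply in δ; ≈ 0.95 at δ = 0.5 and ≈ 1.0 at δ = 1.0
  with 147 variants, and grows with panel size at fixed δ.

Calibration replicates run on the frequency scale (truth frequencies plus
binomial allele-count sampling), which is distributionally identical to
drawing full genotype matrices for the sign test and orders of magnitude
faster; the full-matrix route is exercised separately by the end-to-end
pipeline tests.

## Numerical and degenerate-input choices

- Zero-variance dosage vectors make r² undefined: a sentinel is returned and
  the pair treated as unlinked rather than raising mid-pipeline.
- A sample with no scored variant is excluded from the GRS with a warning
  (its rescaled score would be 0/0).
- Two constant, equal groups compare with t = 0, p = 1.
- sign test with zero informative variants returns p = 1 with a warning.
- Duplicate rsIDs with conflicting risk alleles are reported and the first
  occurrence kept — never silently merged.

## Known limitations

- **Pruning reference population.** r² is computed on all samples in the
  provided VCF by default. Pooling diverged populations induces
  stratification LD between physically unlinked loci (proportional to the
  product of their frequency differences), so the pruner can remove a few
  truly unlinked variants in strongly shifted simulations; prune within one
  population (subset the matrix first) when that matters. Published SNP
  lists that are already pruned should be run with pruning disabled.
- The sign test treats variants as independent; residual LD inflates the
  effective weight of correlated loci, which is exactly why pruning precedes
  it.
- Palindromic-SNP acceptance assumes plus-strand reporting on both sides; a
  strict pipeline on array data of unknown strand should drop flagged
  variants.
- X-chromosome variants are accepted but scored as diploid for all samples;
  no sex-aware dosage model is implemented.
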