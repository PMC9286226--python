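# Methods

## The record model and the lazy contract

A VCF data line is a tree flattened onto one string by layered separators
(tab; then `;`, `,`, `:`, `=`, `|`, `/`).  `vcfpipe.core` keeps each record
as its original tab-split column strings.  The seven fixed columns are
tokenized at construction (POS validated as a positive integer, ALT split
on commas); the INFO and per-sample columns are parsed only when first
accessed, and module-level counters expose exactly when that happens so the
contract is testable.  Mutation goes through setters that rewrite only the
affected column, which makes two properties structural rather than
incidental: an untouched record serializes to its source bytes, and an
edit changes only the token it names.

Missing values (`.`) map to a dedicated `MISSING` singleton — never 0 or
the empty string — and every comparison against it is false.  This gives
filtering a predictable semantics: `r.info.AF < 0.001` and
`r.info.AF >= 0.001` both reject a record without the tag, and the user
writes an explicit presence test when the distinction matters.  Type
coercion follows the header declaration (Integer/Float/Flag, with
`Number=A` values as lists); a token that contradicts its declared type
degrades to a string with a logged warning rather than an error, on the
principle that a VCF consumer should ignore what it does not understand.
Undeclared INFO keys are passed through as strings, with numeric-looking
tokens sniffed to numbers for JSON output and comparisons.

## The expression language

The filter DSL is a closed grammar — comparisons, boolean connectives,
arithmetic, Perl-style regex match, `.to_i/.to_f/.to_s` conversions, and a
single higher-order form `count(<sample predicate>)` — compiled by a
hand-written recursive-descent parser into a small AST.  There is
deliberately no function definition, iteration, attribute access or host
interoperation: an expression can read fields and nothing else, so
untrusted filter strings are safe to evaluate.  Field names resolve
case-insensitively against the header, `FILTER` is exposed both as the raw
string (for regex) and as a code list (for equality), and expressions over
`s.*` are quantified over samples with `any` (default) or `all`.
Templates interpolate `{expression}` slots in header/body/footer blocks;
`{{`/`}}` escape literal braces so JSON documents need no special casing.

## Normalization

Primitive decomposition aligns REF against each ALT globally with affine
gaps (match +1, mismatch −2, gap open −4, extend −1).  The scoring was
chosen so that same-length allele pairs resolve to mismatches, never to an
insertion/deletion pair — a spurious gap costs at least 8 against 4 for two
mismatches — and traceback preference (diagonal, then deletion, then
insertion) makes the output deterministic.  Mismatch runs split into SNPs
unless MNPs are requested; indels take the preceding reference base as
anchor (the following base in the leading-gap corner case).  Genotypes on
split records mark presence/absence of that primitive's source ALT,
`Number=A` INFO tags are sliced to the source allele, QUAL and FILTER are
copied verbatim, and a provenance tag records the original site.  The
loss-free property — applying one ALT's primitives to REF reproduces the
ALT string — is tested exhaustively on random allele pairs.

Left alignment iterates the classic two-phase rewrite: while all alleles
share a final base, drop it (prepending the preceding reference base
whenever an allele would empty), then trim shared leading bases down to a
single anchor.  The result is the unique 5′-most parsimonious
representation; it is validated against an oracle that enumerates *every*
placement yielding the same alternate haplotype, and by idempotence and
haplotype-conservation checks on repeat-rich references, where the failure
modes live.

## Statistics

All estimators operate on biallelic sites (decompose multi-allelics
first); haplotype statistics additionally require fully phased genotypes
and skip others with a counted warning rather than pseudo-phasing.

**Weir–Cockerham Fst.**  The two-population variance components a (among
populations), b (among individuals within populations) and c (within
individuals) are computed from diploid sample sizes, allele frequencies
and observed heterozygote proportions; θ̂ = a/(a+b+c) per site.  For
multi-locus summaries the package combines loci as Σa/Σ(a+b+c).  The
alternative — averaging per-site ratios — is strongly biased toward zero
(simulations here show ≈0.32 for a true F of 0.5 at 50 diploids per
population) because low-information sites contribute ratios near zero with
full weight; the ratio of sums weights each site by its information
content and recovers the simulated divergence within ±0.03 at
F ∈ {0.05, 0.2, 0.5} over 5,000 sites.

**pFst.**  A binomial likelihood-ratio test from allele counts derived
from GT: the null model fits one shared frequency, the alternative a
frequency per population, and 2(lnL₁ − lnL₀) is referred to χ²(1) with
0·ln 0 = 0 at boundary MLEs.  A genotype-likelihood-weighted variant is a
possible extension; counts were chosen because they are always derivable
and make the test exactly reproducible.  Calibration: at 50 diploids per
population and allele frequencies away from the boundary, the empirical
type-I error at nominal 0.05 is ≈0.045.

**Vst.**  (Vt − Vs)/Vt with Vt the variance of pooled copy numbers and Vs
the sample-size-weighted mean of within-population variances.  Both use
the population (1/n) denominator: with Bessel-corrected (n−1) variances,
pooling two *identical* populations doubles n without changing spread, so
Vt < Vs and the statistic goes negative instead of hitting its natural
boundary of 0.  With 1/n denominators Vst = 0 for identical populations
and 1 when within-population variance vanishes, exactly.

**π and eHH.**  Nucleotide diversity is Σ 2j(n−j)/(n(n−1)) over window
sites (j = derived-allele count among n haplotypes), reported absolutely
and per bp.  Window haplotype homozygosity is Σ C(c_h,2)/C(n,2) over
distinct haplotype strings: the probability two distinct sampled
haplotypes are identical over the window, 0 when all unique and 1 when all
identical.

**iHS.**  EHH decay curves run outward from the core site separately for
reference- and alternate-allele carriers; each curve is integrated by
trapezoid against physical distance (bp, not genetic distance), truncating
at the last site with EHH ≥ 0.05 — segments beyond the first
sub-threshold site are dropped.  The unstandardized score is
ln(iHH_ref/iHH_alt); standardization subtracts the mean and divides by the
(n−1) standard deviation within 2% derived-allele-frequency bins, setting
scores in degenerate bins (fewer than two scores, or zero spread) to
missing.

**ABBA–BABA.**  Hard pattern counting over four individuals: a site
contributes only when all four are homozygous, with the outgroup defining
the ancestral allele; ABBA and BABA are tallied and
D = (ABBA − BABA)/(ABBA + BABA).  Frequency-weighted variants were
rejected because a site where the first two individuals agree must match
neither pattern.

**Permutation p-values** use the add-one estimator
p = (1 + #{permuted ≥ observed})/(1 + n_perm), which cannot return zero,
with a seeded generator for reproducibility.

**Smoothing** tiles each contig with windows of configurable span and
step starting at position 1, averaging scores per window; empty windows
carry a missing mean (suppressible).  It is verified against a
re-scanning brute-force oracle.

## Synthetic data: what it emulates, and what it does not

The two-population generator draws, per site, an ancestral frequency
p ~ Uniform(0.1, 0.9), per-population frequencies from a Beta with mean p
and variance p(1−p)F (the Balding–Nichols model, whose F is directly
comparable to the Weir–Cockerham θ), and diploid genotypes binomially.
Defaults — 50 diploids per population, F = 0.2, 1,000 sites on a 1 Mb
contig — reflect a modest resequencing cohort with strong but realistic
structure.  Sites are independent: there is no linkage, no mutation-model
realism, no missingness and no genotyping error, so passing recovery tests
demonstrates estimator correctness under the model, not robustness to real
data pathologies.  The sweep generator plants a shared core haplotype
(spanning the central half of the panel, derived allele fixed among
carriers at the focal site) on otherwise independent backgrounds — enough
to exercise the eHH/iHS machinery directionally, but not a coalescent
simulation with recombination; tail behavior of iHS on real sweeps is out
of scope.  The copy-number generator uses Poisson counts around means 2
and 2+shift.  Denormalization right-shifts indels within their repeat
tracts and merges nearby SNP pairs into complex blocks, recording truth so
normalization can be scored exactly.  All generators are byte-deterministic
under their seeds.

## Numerical and interface choices

- AF and other recomputed floats are formatted to 6 significant digits for
  stable round trips.
- `streamsort` holds a min-heap and flushes records once the input has
  advanced `window` bp past them (default 10,000 bp); disorder beyond the
  window is a hard, named error because it cannot be repaired with the
  buffer at hand.
- BED (0-based half-open) to VCF (1-based inclusive) conversion lives in a
  single function; indel overlap uses the full REF span.
- Contigs keep first-appearance order; a contig reappearing after a block
  ends is an error rather than a silent re-sort.
- Gzip input is detected by magic bytes; output is always plain text.
- Exit codes: 0 success, 1 validation failure (reference check found
  mismatches), 2 usage error.  Each transforming subcommand appends one
  `##vcfpipe_<name>=<args>` header line as provenance; logs go to stderr
  only.

## Test-suite problem sizes

Round-trip fidelity runs on 10,000 generated records; Fst recovery on
5,000 sites per divergence level; LRT calibration on 2,000 null sites;
left-alignment on 500 random tract indels against the exhaustive oracle;
smoothing and BED annotation on 1,000 random fixture points each.  These
sizes put sampling noise well inside the asserted tolerances while keeping
the full suite around ten seconds.

## Known limitations

No tabix indexing or BCF; streaming text only.  Breakend and symbolic ALTs
pass through untouched.  The DSL has no user-defined lambdas beyond
`count`.  Statistics assume diploid genotypes; arbitrary ploidy parses but
is skipped by the estimators.  pFst ignores genotype likelihoods; iHS uses
physical distance.  Multi-allelic sites must be decomposed before any
statistic.
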