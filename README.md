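# vcfpipe

A pipeable toolkit for the VCF variant call format: a lazy, tree-structured
record model, a safe filtering/templating expression language, streaming
record transforms, variant normalization, and a suite of population-genetic
statistics — with deterministic synthetic-data generators for all of it.

## Who this is for

Anyone processing variant calls in shell pipelines or Python: filtering and
reshaping VCF streams, canonicalizing indel representations before
comparing call sets, or computing per-site and windowed population
statistics (differentiation, diversity, haplotype homozygosity, linkage,
introgression) directly from genotype files.

## The model

A VCF line projects a tree onto one string through layered separators: tabs
split columns, `;` splits INFO pairs, `:` per-sample fields, `=` keys from
values, `,` allele-indexed lists, and `|`/`/` genotype allele indices.
`vcfpipe` parses this tree *lazily*: fixed columns are tokenized up front,
but INFO and sample columns stay raw text until a query touches them — so a
filter on `r.pos` never parses a malformed INFO column, and untouched
records write back byte-identically.

The statistics core implements, per biallelic site or window:

- **Weir–Cockerham Fst** — variance components a, b, c with
  θ̂ = a/(a+b+c) per site and the ratio-of-sums Σa/Σ(a+b+c) across loci;
- **pFst** — a binomial likelihood-ratio test of allele-frequency equality,
  2(lnL₁ − lnL₀) referred to χ²(1);
- **Vst** — (Vt − Vs)/Vt over per-sample copy numbers;
- **π** — mean pairwise differences, Σ 2j(n−j)/(n(n−1)) over sites;
- **eHH** — window haplotype homozygosity Σ C(c_h,2)/C(n,2), 0 when all
  haplotypes are unique and 1 when all are identical;
- **iHS** — ln(iHH_ref/iHH_alt) from trapezoid-integrated EHH decay curves,
  standardized within derived-allele-frequency bins;
- **LD** (D, D′, r²), the four-taxon **ABBA–BABA D** statistic,
  label-permutation empirical p-values, and sliding-window smoothing.

Normalization decomposes complex REF/ALT pairs into primitives via global
pairwise alignment (match +1, mismatch −2, gap open −4, extend −1) and
left-aligns indels to their 5′-most equivalent placement.

## Worked example

Simulate a two-population cohort (50 diploids per population, 1,000 sites)
whose allele frequencies diverged under the Balding–Nichols model with
F = 0.2, then estimate per-site Fst and smooth it over windows:

```sh
vcfpipe simulate twopop --sites 1000 --samples 50 --fst 0.2 --seed 1 > two.vcf
vcfpipe wcfst \
    --target $(seq 0 49 | sed 's/^/T/' | paste -sd,) \
    --background $(seq 0 49 | sed 's/^/B/' | paste -sd,) \
    two.vcf | head -3
```

```
chr1	2057	wcFst	0.450967	a=0.143994	b=0.00530612	c=0.17
chr1	2747	wcFst	-0.00943603	a=-0.000614286	b=-0.00428571	c=0.07
chr1	5820	wcFst	0.074455	a=0.0181	b=-0.035	c=0.26
```

Each row is one site: the θ̂ estimate and its variance components.  The
among-population component `a` is positive where the two populations have
drifted apart (per-site estimates are noisy and may dip below zero at
near-monomorphic sites).  Pooling the components over all sites
(`Σa/Σ(a+b+c)`, via `vcfpipe.popgen.wc_fst_multilocus`) gives 0.1949 over
the 999 polymorphic sites — recovering the simulated F = 0.2.

Filtering and reshaping use the expression language (`r.` is the record,
`s.` each sample).  Recompute AC/AN/AF from the genotypes, keep sites
where the alternate allele is the major one, and project them to BED:

```sh
vcfpipe fixup < two.vcf |
vcfpipe filter --filter 'r.info.AF > 0.5' |
vcfpipe eval --eval '[r.chrom, r.pos - 1, r.pos]' > sites.bed
```

This writes 491 of the 1,000 sites, the first being
`chr1	2056	2057` (0-based half-open BED from the 1-based VCF position).
Sample-level predicates look like `count(s.gt != "./.") > 40` (more than
40 called genotypes) or `s.dp > 20` quantified over samples with
`--sfilter-mode any|all`.

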