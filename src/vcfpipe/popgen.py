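"""Population-genetic statistics over VCF genotypes and phased haplotypes.

Per-site statistics (allele frequency, observed heterozygosity, genotype
counts, Weir–Cockerham Fst, a binomial likelihood-ratio Fst analogue, and
Vst for copy number) work from diploid GT or copy-number fields and a
target/background split of the samples.  Haplotype statistics (nucleotide
diversity π, extended haplotype homozygosity, iHS, linkage disequilibrium)
work on a 0/1 matrix of phased haplotypes.  All statistics are restricted
to biallelic sites; decompose multi-allelics first (normalize module).

Estimator notes
---------------
``wc_fst`` implements the two-population Weir & Cockerham (1984) variance
components a (among populations), b (among individuals within populations)
and c (within individuals), with the per-site estimate θ̂ = a/(a+b+c).  For
multi-locus estimates use :func:`wc_fst_multilocus`, which combines loci as
Σa / Σ(a+b+c) — the ratio of summed components, which is close to unbiased,
whereas averaging per-site ratios is strongly biased toward 0 at noisy
sites.

``p_fst`` is a binomial likelihood-ratio test of allele-frequency equality:
the null fits one shared frequency, the alternative one per population, and
2·(lnL₁ − lnL₀) is referred to χ²(1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from scipy.stats import chi2

from .core import MISSING, VcfError, VcfHeader, VcfRecord, parse_gt, sample_value

log = logging.getLogger("vcfpipe")


@dataclass
class PopulationAssignment:
    """Disjoint target/background sample index sets (GPAT convention)."""

    target: list[int]
    background: list[int]

    def __post_init__(self):
        if not self.target or not self.background:
            raise VcfError("target and background must both be non-empty")
        if set(self.target) & set(self.background):
            raise VcfError("target and background overlap")

    @classmethod
    def from_names(cls, header: VcfHeader, target: Sequence[str],
                   background: Sequence[str]) -> "PopulationAssignment":
        return cls([header.sample_index(s) for s in target],
                   [header.sample_index(s) for s in background])


@dataclass
class SiteStatResult:
    """One statistic at one site (or window), with its named components."""

    chrom: str
    pos: int
    statistic: str
    value: float
    components: dict = field(default_factory=dict)
    n_used: int = 0


class SiteSkipped(VcfError):
    """Raised when a statistic is undefined at a site (with the reason)."""


# ---------------------------------------------------------------------------
# Genotype extraction helpers
# ---------------------------------------------------------------------------

def _diploid_calls(record: VcfRecord, indices: Iterable[int]) -> list[tuple[int, int]]:
    """Called diploid genotypes (pairs of 0/1 allele indices) for samples."""
    calls = []
    for i in indices:
        gt = record.samples[i].get("GT", ".")
        alleles, _ = parse_gt(gt)
        if len(alleles) == 2 and all(a is not None for a in alleles):
            calls.append((alleles[0], alleles[1]))
    return calls


def _require_biallelic(record: VcfRecord) -> None:
    if len(record.alt) != 1:
        raise SiteSkipped(
            f"multi-allelic site {record.chrom}:{record.pos}; decompose first")


# ---------------------------------------------------------------------------
# Basic per-site statistics
# ---------------------------------------------------------------------------

def site_stats(record: VcfRecord, indices: Optional[Sequence[int]] = None) -> SiteStatResult:
    """Af, oHet and genotype counts at a biallelic site.

    Af is the ALT-allele frequency among called alleles; oHet the fraction
    of heterozygotes among called genotypes; counts are
    (homRef, het, homAlt, missing).
    """
    _require_biallelic(record)
    if indices is None:
        indices = range(record.n_samples)
    calls = _diploid_calls(record, indices)
    n_missing = len(list(indices)) - len(calls)
    if not calls:
        raise SiteSkipped(f"all genotypes missing at {record.chrom}:{record.pos}")
    hom_ref = sum(1 for a, b in calls if a == 0 and b == 0)
    het = sum(1 for a, b in calls if a != b)
    hom_alt = sum(1 for a, b in calls if a == 1 and b == 1)
    af = sum(a + b for a, b in calls) / (2 * len(calls))
    return SiteStatResult(
        record.chrom, record.pos, "popStat", af,
        components={"Af": af, "oHet": het / len(calls),
                    "homRef": hom_ref, "het": het, "homAlt": hom_alt,
                    "missing": n_missing},
        n_used=len(calls))


def variant_class(record: VcfRecord) -> str:
    alts = record.alt
    if all(len(a) == len(record.ref) == 1 for a in alts):
        return "SNV"
    if any(len(a) != len(record.ref) for a in alts):
        return "INDEL"
    return "MNP"


def genotype_summary(records: Iterable[VcfRecord]) -> Iterator[dict]:
    """Per-record genotype count rows for biallelic SNVs and indels."""
    for rec in records:
        try:
            st = site_stats(rec)
        except SiteSkipped as e:
            log.warning("genotype_summary: %s", e)
            continue
        yield {"chrom": rec.chrom, "pos": rec.pos,
               "class": variant_class(rec), **st.components}


GENO_SUMMARY_FIELDS = ("RO", "QR", "AO", "QA")


def geno_quality_summarize(record: VcfRecord,
                           header: Optional[VcfHeader] = None) -> VcfRecord:
    """Summarize per-sample observation counts/qualities into INFO.

    Adds totals of RO and AO plus mean per-observation qualities QR/RO and
    QA/AO across called samples.  Records without the fields pass through.
    """
    keys = record.format_keys
    if not all(k in keys for k in ("RO", "QR", "AO", "QA")):
        log.warning("geno_quality_summarize: RO/QR/AO/QA absent at %s:%s",
                    record.chrom, record.pos)
        return record
    ro = qr = ao = qa = 0.0
    n = 0
    for i in range(record.n_samples):
        f = record.samples[i]
        try:
            ro_i, qr_i = float(f["RO"]), float(f["QR"])
            ao_i, qa_i = float(f["AO"]), float(f["QA"])
        except (KeyError, ValueError):
            continue
        ro += ro_i
        qr += qr_i
        ao += ao_i
        qa += qa_i
        n += 1
    if n == 0:
        return record
    record.set_info("RefObsTotal", int(ro))
    record.set_info("AltObsTotal", int(ao))
    record.set_info("RefObsMean", ro / n)
    record.set_info("AltObsMean", ao / n)
    if ro > 0:
        record.set_info("RefObsQualMean", qr / ro)
    if ao > 0:
        record.set_info("AltObsQualMean", qa / ao)
    if header is not None:
        for tag, desc in (("RefObsTotal", "Total reference observations"),
                          ("AltObsTotal", "Total alternate observations"),
                          ("RefObsMean", "Mean reference observations per sample"),
                          ("AltObsMean", "Mean alternate observations per sample"),
                          ("RefObsQualMean", "Mean per-observation reference quality"),
                          ("AltObsQualMean", "Mean per-observation alternate quality")):
            header.add_meta("INFO", ID=tag, Number="1", Type="Float", Description=desc)
    return record


# ---------------------------------------------------------------------------
# Weir & Cockerham Fst
# ---------------------------------------------------------------------------

def wc_components(n1: int, p1: float, h1: float,
                  n2: int, p2: float, h2: float) -> tuple[float, float, float]:
    """Weir & Cockerham (1984) variance components for two populations.

    n_i: diploid sample sizes; p_i: ALT allele frequencies; h_i: observed
    heterozygote proportions.  Returns (a, b, c): among-population,
    within-population-among-individual, and within-individual components.
    """
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (s2 - (1.0 / (nbar - 1))
                       * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2
                               - ((2 * nbar - 1) / (4 * nbar)) * hbar)
    c = hbar / 2
    return a, b, c


def _pop_freq_het(record: VcfRecord, indices: Sequence[int]) -> tuple[int, float, float]:
    calls = _diploid_calls(record, indices)
    if len(calls) < 2:
        raise SiteSkipped(
            f"fewer than 2 called genotypes in a population at "
            f"{record.chrom}:{record.pos}")
    n = len(calls)
    p = sum(a + b for a, b in calls) / (2 * n)
    h = sum(1 for a, b in calls if a != b) / n
    return n, p, h


def wc_fst(record: VcfRecord, assignment: PopulationAssignment) -> SiteStatResult:
    """Per-site Weir–Cockerham θ̂ = a/(a+b+c) for two populations."""
    _require_biallelic(record)
    n1, p1, h1 = _pop_freq_het(record, assignment.target)
    n2, p2, h2 = _pop_freq_het(record, assignment.background)
    a, b, c = wc_components(n1, p1, h1, n2, p2, h2)
    denom = a + b + c
    if denom == 0:
        raise SiteSkipped(
            f"monomorphic site {record.chrom}:{record.pos} (a+b+c = 0)")
    return SiteStatResult(record.chrom, record.pos, "wcFst", a / denom,
                          components={"a": a, "b": b, "c": c},
                          n_used=n1 + n2)


def wc_fst_multilocus(records: Iterable[VcfRecord],
                      assignment: PopulationAssignment) -> tuple[float, int]:
    """Multi-locus θ̂ = Σa / Σ(a+b+c) over all usable sites.

    Returns (estimate, number of sites used).  This ratio-of-sums
    combination is the Weir–Cockerham prescription for pooling loci.
    """
    num = den = 0.0
    used = 0
    for rec in records:
        try:
            res = wc_fst(rec, assignment)
        except SiteSkipped:
            continue
        num += res.components["a"]
        den += (res.components["a"] + res.components["b"] + res.components["c"])
        used += 1
    if den == 0:
        raise SiteSkipped("no polymorphic sites")
    return num / den, used


# ---------------------------------------------------------------------------
# pFst: binomial likelihood-ratio test
# ---------------------------------------------------------------------------

def _binom_ll(x: int, n: int, p: float) -> float:
    # 0*log(0) = 0 at the boundary MLEs
    ll = 0.0
    if x > 0:
        ll += x * math.log(p)
    if n - x > 0:
        ll += (n - x) * math.log(1 - p)
    return ll


def _alt_allele_counts(record: VcfRecord, indices: Sequence[int]) -> tuple[int, int]:
    calls = _diploid_calls(record, indices)
    x = sum(a + b for a, b in calls)
    return x, 2 * len(calls)


def p_fst(record: VcfRecord, assignment: PopulationAssignment) -> SiteStatResult:
    """Binomial LRT for an allele-frequency difference between populations.

    Statistic 2(lnL₁ − lnL₀) with per-population vs pooled frequency MLEs;
    p-value from χ² with 1 degree of freedom.
    """
    _require_biallelic(record)
    x1, n1 = _alt_allele_counts(record, assignment.target)
    x2, n2 = _alt_allele_counts(record, assignment.background)
    if n1 == 0 or n2 == 0:
        raise SiteSkipped(
            f"no called alleles in a population at {record.chrom}:{record.pos}")
    l1 = _binom_ll(x1, n1, x1 / n1) + _binom_ll(x2, n2, x2 / n2)
    l0 = _binom_ll(x1, n1, (x1 + x2) / (n1 + n2)) + _binom_ll(x2, n2, (x1 + x2) / (n1 + n2))
    stat = max(0.0, 2 * (l1 - l0))
    p = float(chi2.sf(stat, 1)) if stat > 0 else 1.0
    return SiteStatResult(record.chrom, record.pos, "pFst", p,
                          components={"lrt": stat, "p": p,
                                      "af_target": x1 / n1,
                                      "af_background": x2 / n2},
                          n_used=(n1 + n2) // 2)


# ---------------------------------------------------------------------------
# Vst for copy number
# ---------------------------------------------------------------------------

def _cn_values(record: VcfRecord, indices: Sequence[int], cn_field: str,
               header: Optional[VcfHeader]) -> list[float]:
    vals = []
    for i in indices:
        v = sample_value(record, i, cn_field, header)
        if v is MISSING:
            continue
        try:
            vals.append(float(v))
        except (TypeError, ValueError):
            continue
    return vals


def p_vst(record: VcfRecord, assignment: PopulationAssignment,
          cn_field: str = "CN", header: Optional[VcfHeader] = None) -> SiteStatResult:
    """Vst = (Vt − Vs)/Vt for per-sample copy-number values.

    Vt is the variance of the pooled values; Vs the sample-size-weighted
    mean of within-population variances.  Both use the population (1/n)
    denominator: with the Bessel-corrected estimator two *identical*
    populations would give Vst < 0 rather than the boundary value 0,
    because pooling doubles n but not the spread.
    """
    v1 = _cn_values(record, assignment.target, cn_field, header)
    v2 = _cn_values(record, assignment.background, cn_field, header)
    if len(v1) < 2 or len(v2) < 2:
        raise SiteSkipped(
            f"fewer than 2 copy-number values in a population at "
            f"{record.chrom}:{record.pos}")
    vt = float(np.var(v1 + v2))
    if vt == 0:
        raise SiteSkipped(f"zero total variance at {record.chrom}:{record.pos}")
    n1, n2 = len(v1), len(v2)
    vs = (n1 * float(np.var(v1)) + n2 * float(np.var(v2))) / (n1 + n2)
    return SiteStatResult(record.chrom, record.pos, "pVst", (vt - vs) / vt,
                          components={"Vt": vt, "Vs": vs}, n_used=n1 + n2)


# ---------------------------------------------------------------------------
# Haplotype matrix
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeMatrix:
    """Phased 0/1 haplotypes: rows = haplotypes (2 per diploid sample),
    columns = ordered biallelic sites with bp positions."""

    data: np.ndarray          # (n_haplotypes, n_sites) of 0/1
    positions: np.ndarray     # (n_sites,) strictly increasing bp
    chrom: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.data.ndim != 2:
            raise VcfError("haplotype matrix must be 2-D")
        if self.data.shape[1] != len(self.positions):
            raise VcfError("positions do not match matrix columns")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise VcfError("site positions must be strictly increasing")

    @property
    def n_haplotypes(self) -> int:
        return self.data.shape[0]

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    def window(self, start_bp: int, end_bp: int) -> "HaplotypeMatrix":
        """Sites with start_bp <= position <= end_bp (1-based inclusive)."""
        mask = (self.positions >= start_bp) & (self.positions <= end_bp)
        return HaplotypeMatrix(self.data[:, mask], self.positions[mask], self.chrom)

    @classmethod
    def from_records(cls, records: Iterable[VcfRecord],
                     indices: Optional[Sequence[int]] = None,
                     chrom: str = "") -> "HaplotypeMatrix":
        """Build from biallelic records where every sampled GT is phased;
        unphased or multi-allelic records are skipped with a counted
        warning."""
        cols = []
        positions = []
        skipped = 0
        for rec in records:
            if len(rec.alt) != 1:
                skipped += 1
                continue
            idx = range(rec.n_samples) if indices is None else indices
            col = []
            ok = True
            for i in idx:
                gt = rec.samples[i].get("GT", ".")
                alleles, phased = parse_gt(gt)
                if (len(alleles) != 2 or any(a is None for a in alleles)
                        or not all(phased)):
                    ok = False
                    break
                col.extend(alleles)
            if not ok:
                skipped += 1
                continue
            cols.append(col)
            positions.append(rec.pos)
            chrom = chrom or rec.chrom
        if skipped:
            log.warning("HaplotypeMatrix: skipped %d unphased/multi-allelic records",
                        skipped)
        if not cols:
            return cls(np.zeros((0, 0), dtype=np.int8), np.zeros(0, dtype=np.int64), chrom)
        return cls(np.array(cols, dtype=np.int8).T, np.array(positions), chrom)


# ---------------------------------------------------------------------------
# Diversity and haplotype homozygosity
# ---------------------------------------------------------------------------

def pi_window(hap: HaplotypeMatrix, span_bp: Optional[int] = None) -> tuple[float, float]:
    """Nucleotide diversity π: mean pairwise difference count over all
    haplotype pairs, Σ_sites 2j(n−j)/(n(n−1)).

    Returns (π, π per bp); per-bp is π divided by ``span_bp`` (defaults to
    the spanned positions).
    """
    n = hap.n_haplotypes
    if n < 2:
        raise VcfError("pi requires at least 2 haplotypes")
    j = hap.data.sum(axis=0).astype(float)
    pi = float(np.sum(2.0 * j * (n - j)) / (n * (n - 1)))
    if span_bp is None:
        span_bp = (int(hap.positions[-1] - hap.positions[0]) + 1
                   if hap.n_sites > 1 else 1)
    return pi, pi / span_bp


def haplotype_homozygosity(strings: Sequence[bytes]) -> float:
    """Probability two distinct sampled haplotypes are identical:
    Σ_h C(c_h, 2) / C(n, 2) over distinct haplotype strings."""
    n = len(strings)
    if n < 2:
        raise VcfError("eHH requires at least 2 haplotypes")
    counts: dict = {}
    for s in strings:
        counts[s] = counts.get(s, 0) + 1
    num = sum(c * (c - 1) // 2 for c in counts.values())
    return num / (n * (n - 1) // 2)


def ehh_window(hap: HaplotypeMatrix) -> float:
    """Extended haplotype homozygosity of a window: 0 when all haplotypes
    are unique, 1 when all are identical."""
    strings = [hap.data[i].tobytes() for i in range(hap.n_haplotypes)]
    return haplotype_homozygosity(strings)


# ---------------------------------------------------------------------------
# iHS
# ---------------------------------------------------------------------------

EHH_TRUNCATE = 0.05


def _ehh_decay(data: np.ndarray, positions: np.ndarray, core_idx: int,
               direction: int) -> tuple[list[float], list[int]]:
    """EHH values at successive sites moving outward from the core.

    EHH at distance d is the haplotype homozygosity over the span from the
    core to the site, for the given haplotype subset.  Starts at the core
    (EHH=1 by construction over a 1-site span shared by construction).
    """
    n = data.shape[0]
    idxs = [core_idx]
    i = core_idx
    limit = data.shape[1]
    values = [1.0]
    poss = [int(positions[core_idx])]
    while True:
        i += direction
        if i < 0 or i >= limit:
            break
        if direction > 0:
            span = data[:, core_idx:i + 1]
        else:
            span = data[:, i:core_idx + 1]
        strings = [span[k].tobytes() for k in range(n)]
        values.append(haplotype_homozygosity(strings))
        poss.append(int(positions[i]))
    return values, poss


def _ihh(values: list[float], poss: list[int]) -> float:
    """Trapezoidal integral of the EHH decay against bp distance, truncated
    at the last site with EHH >= the truncation threshold."""
    total = 0.0
    for k in range(1, len(values)):
        if values[k] < EHH_TRUNCATE:
            break
        total += 0.5 * (values[k - 1] + values[k]) * abs(poss[k] - poss[k - 1])
    return total


def ihs(hap: HaplotypeMatrix, core_site: int) -> SiteStatResult:
    """Unstandardized iHS at a core site: ln(iHH_ref / iHH_alt).

    EHH decay curves run outward in both directions separately for the
    haplotypes carrying the reference and the alternate core allele; iHH
    integrates each curve over physical distance.
    """
    col = hap.data[:, core_site]
    ref_rows = np.where(col == 0)[0]
    alt_rows = np.where(col == 1)[0]
    if len(ref_rows) < 2 or len(alt_rows) < 2:
        raise SiteSkipped("core allele class with fewer than 2 haplotypes")
    out = {}
    for name, rows in (("iHH_ref", ref_rows), ("iHH_alt", alt_rows)):
        sub = hap.data[rows]
        total = 0.0
        for direction in (+1, -1):
            vals, poss = _ehh_decay(sub, hap.positions, core_site, direction)
            total += _ihh(vals, poss)
        out[name] = total
    if out["iHH_ref"] <= 0 or out["iHH_alt"] <= 0:
        raise SiteSkipped("zero integrated EHH on one allele background")
    value = math.log(out["iHH_ref"] / out["iHH_alt"])
    return SiteStatResult(hap.chrom, int(hap.positions[core_site]), "iHS",
                          value, components=out, n_used=hap.n_haplotypes)


def normalize_ihs(scores: Sequence[tuple[float, float]],
                  bin_width: float = 0.02) -> list[float]:
    """Standardize (derived-allele frequency, iHS) pairs within frequency
    bins: each score becomes (x − bin mean)/bin sd (n−1 denominator).

    Bins with zero standard deviation or a single score yield NaN with a
    warning.
    """
    if not scores:
        return []
    freqs = np.array([f for f, _ in scores], dtype=float)
    vals = np.array([v for _, v in scores], dtype=float)
    bins = np.minimum((freqs / bin_width).astype(int),
                      int(1.0 / bin_width) - 1)
    out = np.full(len(vals), np.nan)
    for b in np.unique(bins):
        mask = bins == b
        group = vals[mask]
        if len(group) < 2:
            log.warning("normalize_ihs: bin %d has < 2 scores; set missing", b)
            continue
        sd = float(np.std(group, ddof=1))
        if sd == 0:
            log.warning("normalize_ihs: bin %d has zero sd; set missing", b)
            continue
        out[mask] = (group - float(np.mean(group))) / sd
    return out.tolist()


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------

def ld_pair(hap: HaplotypeMatrix, site_i: int, site_j: int) -> SiteStatResult:
    """D, D' and r² between two sites from phased haplotype counts."""
    a = hap.data[:, site_i].astype(float)
    b = hap.data[:, site_j].astype(float)
    pa, pb = float(a.mean()), float(b.mean())
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise VcfError("ld_pair requires both sites polymorphic")
    pab = float((a * b).mean())
    d = pab - pa * pb
    r2 = d * d / (pa * (1 - pa) * pb * (1 - pb))
    if d > 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    elif d < 0:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    else:
        dmax = 1.0
    dprime = d / dmax if dmax > 0 else 0.0
    return SiteStatResult(hap.chrom, int(hap.positions[site_i]), "LD", r2,
                          components={"D": d, "Dprime": dprime, "r2": r2},
                          n_used=hap.n_haplotypes)


# ---------------------------------------------------------------------------
# ABBA-BABA (D statistic)
# ---------------------------------------------------------------------------

@dataclass
class AbbaBabaResult:
    abba: int
    baba: int

    @property
    def d(self) -> float:
        if self.abba + self.baba == 0:
            raise VcfError("D undefined: no ABBA or BABA sites")
        return (self.abba - self.baba) / (self.abba + self.baba)


def _hom_allele(record: VcfRecord, index: int) -> Optional[int]:
    alleles, _ = parse_gt(record.samples[index].get("GT", "."))
    if alleles and all(a is not None for a in alleles) and len(set(alleles)) == 1:
        return alleles[0]
    return None


def abba_baba(records: Iterable[VcfRecord], p1: int, p2: int, p3: int,
              outgroup: int) -> AbbaBabaResult:
    """Count ABBA and BABA site patterns for four individuals.

    A site contributes only when all four individuals are homozygous and
    biallelic; the outgroup's allele defines the ancestral state A.
    ABBA: P1 ancestral, P2 derived, P3 derived.  BABA: P1 derived,
    P2 ancestral, P3 derived.  A site with P1 = P2 matches neither.
    """
    abba = baba = 0
    for rec in records:
        if len(rec.alt) != 1:
            continue
        calls = [_hom_allele(rec, i) for i in (p1, p2, p3, outgroup)]
        if any(c is None for c in calls):
            continue
        g1, g2, g3, anc = calls
        der = 1 - anc
        if g3 != der:
            continue
        if g1 == anc and g2 == der:
            abba += 1
        elif g1 == der and g2 == anc:
            baba += 1
    return AbbaBabaResult(abba, baba)


# ---------------------------------------------------------------------------
# Permutation p-values
# ---------------------------------------------------------------------------

def permute_empirical_p(records: Sequence[VcfRecord],
                        assignment: PopulationAssignment,
                        statistic, n_perm: int, seed: int) -> list[tuple[SiteStatResult, float]]:
    """Empirical p-values for a per-site statistic under label permutation.

    For each site, the target/background labels are permuted ``n_perm``
    times and p = (1 + #{permuted >= observed}) / (1 + n_perm) — the
    add-one estimator, which never returns 0.
    """
    if n_perm < 1:
        raise VcfError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    pool = np.array(list(assignment.target) + list(assignment.background))
    k = len(assignment.target)
    out = []
    for rec in records:
        try:
            obs = statistic(rec, assignment)
        except SiteSkipped:
            continue
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(pool)
            pa = PopulationAssignment(list(perm[:k]), list(perm[k:]))
            try:
                val = statistic(rec, pa).value
            except SiteSkipped:
                continue
            if val >= obs.value:
                exceed += 1
        out.append((obs, (1 + exceed) / (1 + n_perm)))
    return out


# ---------------------------------------------------------------------------
# Sliding-window smoothing
# ---------------------------------------------------------------------------

@dataclass
class WindowStat:
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    mean: Optional[float]
    n_variants: int


def smooth_windows(scored: Iterable[tuple[str, int, float]], window_bp: int,
                   step_bp: int, emit_empty: bool = True) -> Iterator[WindowStat]:
    """Average per-position scores over a sliding window.

    Windows start at 1, 1+step, ... per contig and span ``window_bp``;
    input must be position-sorted within each contig.  Empty windows carry
    a missing mean (suppress with ``emit_empty=False``).
    """
    from collections import deque

    buffer: deque = deque()
    chrom = None
    next_start = 1
    max_pos = 0
    prev_pos = -1

    def flush(limit: Optional[int]) -> Iterator[WindowStat]:
        nonlocal next_start
        while True:
            end = next_start + window_bp - 1
            if limit is not None and end >= limit:
                return
            if limit is None and next_start > max_pos:
                return
            while buffer and buffer[0][0] < next_start:
                buffer.popleft()
            vals = [v for p, v in buffer if next_start <= p <= end]
            if vals:
                yield WindowStat(chrom, next_start, end,
                                 sum(vals) / len(vals), len(vals))
            elif emit_empty:
                yield WindowStat(chrom, next_start, end, None, 0)
            next_start += step_bp

    for c, pos, score in scored:
        if c != chrom:
            if chrom is not None:
                yield from flush(None)
            chrom, next_start, max_pos, prev_pos = c, 1, 0, -1
            buffer.clear()
        if pos < prev_pos:
            raise VcfError(f"unsorted scores: {c}:{pos} after {c}:{prev_pos}")
        prev_pos = pos
        max_pos = max(max_pos, pos)
        yield from flush(pos)
        buffer.append((pos, score))
    if chrom is not None:
        yield from flush(None)
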