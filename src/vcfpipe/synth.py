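"""Deterministic generators for every input the toolkit consumes.

The generators emulate the data the statistics are designed for: a
two-population diploid cohort whose allele frequencies diverge under the
Balding–Nichols model (its F parameter is directly comparable to the
Weir–Cockerham θ the estimators should recover), phased haplotype panels
with an optional selective sweep (a long shared core haplotype) to exercise
eHH/iHS, per-sample integer copy-number fields for Vst, and denormalized
indel/MNP representations to exercise left-alignment and primitive
decomposition.  Every generator is byte-deterministic under its seed, and
each VCF comes with a plain-TSV truth table sufficient to score the
estimators without external data.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import VcfError, VcfRecord, read_vcf
from .normalize import apply_variant
from .transforms import ReferenceGenome

BASES = "ACGT"


@dataclass
class SimulationConfig:
    """Seeds and parameters shared by the generators."""

    seed: int = 0
    n_sites: int = 1000
    n_per_pop: int = 50          # diploid samples per population
    fst: float = 0.2             # Balding-Nichols divergence F
    p_min: float = 0.1           # ancestral frequency ~ Uniform(p_min, p_max)
    p_max: float = 0.9
    contig: str = "chr1"
    contig_length: int = 1_000_000
    window_bp: int = 10_000
    step_bp: int = 10_000


# ---------------------------------------------------------------------------
# Reference sequences
# ---------------------------------------------------------------------------

def simulate_reference(length: int, seed: int, repeat_tracts: bool = False,
                       contig: str = "chr1") -> str:
    """FASTA text for one random uppercase ACGT contig.

    With ``repeat_tracts``, dinucleotide repeats of at least 8 bp are
    planted roughly every 500 bp, giving indels room to slide for the
    left-alignment tests.
    """
    if length < 1:
        raise VcfError("length must be >= 1")
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(list(BASES), size=length))
    if repeat_tracts:
        pos = 0
        while pos + 20 < length:
            start = pos + int(rng.integers(0, 480)) + 10
            if start + 16 >= length:
                break
            a, b = rng.choice(list(BASES), size=2, replace=False)
            n_units = int(rng.integers(4, 8))  # 8-14 bp tracts
            tract = (a + b) * n_units
            seq[start:start + len(tract)] = list(tract)
            pos = start + len(tract) + 10
    body = "".join(seq)
    lines = [f">{contig}"]
    for i in range(0, len(body), 70):
        lines.append(body[i:i + 70])
    return "\n".join(lines) + "\n"


def reference_from_fasta_text(text: str) -> ReferenceGenome:
    contigs = {}
    name = None
    chunks: list[str] = []
    for line in text.splitlines():
        if line.startswith(">"):
            if name is not None:
                contigs[name] = "".join(chunks)
            name = line[1:].split()[0]
            chunks = []
        else:
            chunks.append(line.strip())
    if name is not None:
        contigs[name] = "".join(chunks)
    return ReferenceGenome(contigs)


# ---------------------------------------------------------------------------
# VCF text assembly
# ---------------------------------------------------------------------------

def _vcf_header_text(samples: list[str], contig: str, contig_length: int,
                     extra_meta: list[str] = ()) -> str:
    lines = ["##fileformat=VCFv4.2",
             f"##contig=<ID={contig},length={contig_length}>",
             '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">',
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    lines.extend(extra_meta)
    cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if samples:
        cols += ["FORMAT"] + samples
    lines.append("\t".join(cols))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Two-population genotypes under Balding-Nichols
# ---------------------------------------------------------------------------

def simulate_two_pop_vcf(config: SimulationConfig) -> tuple[str, str]:
    """Two-population diploid genotype VCF plus a truth TSV.

    Per site: ancestral frequency p ~ Uniform(p_min, p_max); each
    population's frequency ~ Beta with mean p and variance p(1−p)F
    (Balding–Nichols); genotypes Binomial(2, p_pop).  Truth columns:
    pos, p_ancestral, p_pop1, p_pop2, F.
    """
    if not (0.0 < config.fst < 1.0):
        raise VcfError("F must be in (0, 1)")
    if not (0.0 < config.p_min < config.p_max < 1.0):
        raise VcfError("ancestral frequency bounds must satisfy 0 < p_min < p_max < 1")
    rng = np.random.default_rng(config.seed)
    n = config.n_per_pop
    samples = [f"T{i}" for i in range(n)] + [f"B{i}" for i in range(n)]
    out = io.StringIO()
    out.write(_vcf_header_text(samples, config.contig, config.contig_length))
    truth = ["pos\tp_ancestral\tp_pop1\tp_pop2\tF"]
    positions = np.sort(rng.choice(
        np.arange(1, config.contig_length + 1), size=config.n_sites, replace=False))
    f = config.fst
    shape = (1.0 - f) / f
    for pos in positions:
        p = float(rng.uniform(config.p_min, config.p_max))
        p1 = float(rng.beta(p * shape, (1 - p) * shape))
        p2 = float(rng.beta(p * shape, (1 - p) * shape))
        g1 = rng.binomial(2, p1, n)
        g2 = rng.binomial(2, p2, n)
        ref, alt = rng.choice(list(BASES), size=2, replace=False)
        gts = ["0/1" if g == 1 else ("1/1" if g == 2 else "0/0")
               for g in np.concatenate([g1, g2])]
        out.write(f"{config.contig}\t{pos}\t.\t{ref}\t{alt}\t.\t.\tAA={ref}\tGT\t"
                  + "\t".join(gts) + "\n")
        truth.append(f"{pos}\t{p:.6f}\t{p1:.6f}\t{p2:.6f}\t{f}")
    return out.getvalue(), "\n".join(truth) + "\n"


# ---------------------------------------------------------------------------
# Phased haplotypes with an optional sweep
# ---------------------------------------------------------------------------

def simulate_sweep_haplotypes(n_haplotypes: int = 100, n_sites: int = 200,
                              sweep_fraction: float = 0.5,
                              region_bp: int = 200_000, seed: int = 0,
                              maf: float = 0.3,
                              contig: str = "chr1") -> tuple[str, np.ndarray, np.ndarray]:
    """Phased haplotype panel with a selective-sweep signature.

    Neutral background: each site's ALT allele drawn independently per
    haplotype with frequency ~ Uniform(maf, 1−maf).  A ``sweep_fraction``
    of haplotypes additionally share one identical core haplotype across
    the central half of the region and carry the derived allele at the
    focal (central) site, mimicking the long shared haplotype a recent
    sweep leaves.  Returns (VCF text, haplotype matrix, positions); the
    matrix rows pair consecutively into diploid samples with ``|``-phased
    genotypes.
    """
    if n_haplotypes % 2:
        raise VcfError("n_haplotypes must be even (diploid samples)")
    rng = np.random.default_rng(seed)
    positions = np.sort(rng.choice(np.arange(1, region_bp + 1),
                                   size=n_sites, replace=False))
    freqs = rng.uniform(maf, 1 - maf, size=n_sites)
    data = (rng.random((n_haplotypes, n_sites)) < freqs).astype(np.int8)
    n_sweep = int(round(sweep_fraction * n_haplotypes))
    focal = n_sites // 2
    if n_sweep > 0:
        core_lo, core_hi = n_sites // 4, 3 * n_sites // 4
        core = (rng.random(core_hi - core_lo) < freqs[core_lo:core_hi]).astype(np.int8)
        carriers = rng.choice(n_haplotypes, size=n_sweep, replace=False)
        data[np.ix_(carriers, np.arange(core_lo, core_hi))] = core
        data[carriers, focal] = 1
        non = np.setdiff1d(np.arange(n_haplotypes), carriers)
        data[non, focal] = 0
    out = io.StringIO()
    samples = [f"S{i}" for i in range(n_haplotypes // 2)]
    out.write(_vcf_header_text(samples, contig, region_bp))
    for s, pos in enumerate(positions):
        ref, alt = "A", "C"
        gts = [f"{data[2*i, s]}|{data[2*i+1, s]}" for i in range(len(samples))]
        out.write(f"{contig}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\tGT\t"
                  + "\t".join(gts) + "\n")
    return out.getvalue(), data, positions


# ---------------------------------------------------------------------------
# Copy-number fields for Vst
# ---------------------------------------------------------------------------

def simulate_cnv_vcf(n_sites: int = 50, n_per_pop: int = 30,
                     mean_shift: float = 1.0, seed: int = 0,
                     contig: str = "chr1",
                     contig_length: int = 1_000_000) -> str:
    """Two-population VCF with a per-sample integer CN FORMAT field.

    Copy numbers are Poisson around 2 for the background and around
    2 + ``mean_shift`` for the target population, clipped at 0.
    """
    rng = np.random.default_rng(seed)
    samples = [f"T{i}" for i in range(n_per_pop)] + [f"B{i}" for i in range(n_per_pop)]
    extra = ['##FORMAT=<ID=CN,Number=1,Type=Integer,Description="Copy number">',
             '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
             '##ALT=<ID=CNV,Description="Copy number variable region">']
    out = io.StringIO()
    out.write(_vcf_header_text(samples, contig, contig_length, extra))
    positions = np.sort(rng.choice(np.arange(1, contig_length + 1),
                                   size=n_sites, replace=False))
    for pos in positions:
        cn_t = rng.poisson(2.0 + mean_shift, n_per_pop)
        cn_b = rng.poisson(2.0, n_per_pop)
        cells = [f"./.:{cn}" for cn in np.concatenate([cn_t, cn_b])]
        out.write(f"{contig}\t{pos}\t.\tN\t<CNV>\t.\t.\tSVTYPE=CNV\tGT:CN\t"
                  + "\t".join(cells) + "\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# Denormalized representations
# ---------------------------------------------------------------------------

def _repeat_unit_at(seq: str, start0: int) -> Optional[tuple[str, int, int]]:
    """Dinucleotide repeat tract covering 0-based ``start0``:
    (unit, tract_start0, tract_end0 exclusive), or None."""
    for off in (0, -1):
        s = start0 + off
        if s < 0 or s + 2 > len(seq):
            continue
        unit = seq[s:s + 2]
        if unit[0] == unit[1]:
            continue
        lo = s
        while lo - 2 >= 0 and seq[lo - 2:lo] == unit:
            lo -= 2
        hi = s + 2
        while hi + 2 <= len(seq) and seq[hi:hi + 2] == unit:
            hi += 2
        if hi - lo >= 8:
            return unit, lo, hi
    return None


def make_tract_indels(reference: ReferenceGenome, contig: str, seed: int,
                      n_variants: int = 50) -> list[tuple[int, str, str]]:
    """Left-aligned deletions/insertions of one repeat unit inside the
    reference's repeat tracts: list of (pos, ref, alt), 1-based, anchored."""
    rng = np.random.default_rng(seed)
    seq = reference.contigs[contig]
    tracts = []
    i = 1
    while i + 2 <= len(seq):
        hit = _repeat_unit_at(seq, i)
        if hit and (not tracts or hit[1] > tracts[-1][2]):
            tracts.append(hit)
            i = hit[2] + 1
        else:
            i += 1
    variants = []
    for unit, lo, hi in tracts:
        if len(variants) >= n_variants:
            break
        if lo == 0:
            continue
        anchor = seq[lo - 1]
        pos = lo  # 1-based position of the anchor base
        if rng.random() < 0.5:
            variants.append((pos, anchor + unit, anchor))       # deletion
        else:
            variants.append((pos, anchor, anchor + unit))       # insertion
    return variants


def right_shift(reference: ReferenceGenome, contig: str, pos: int, ref: str,
                alt: str, rng) -> tuple[int, str, str]:
    """Re-express an indel at a random equivalent position further 3'.

    The applied haplotype is preserved exactly; used to manufacture
    denormalized fixtures whose left-aligned form is known.
    """
    seq = reference.contigs[contig]
    placements = [(pos, ref, alt)]
    p, r, a = pos, ref, alt
    while True:
        # shift one base right: drop shared leading anchor, append next base
        end = p - 1 + len(r)
        if end >= len(seq) or len(r) < 1 or len(a) < 1 or r[0] != a[0]:
            break
        nxt = seq[end]
        r2, a2 = r[1:] + nxt, a[1:] + nxt
        p2 = p + 1
        if apply_variant(seq, p2, r2, a2) != apply_variant(seq, pos, ref, alt):
            break
        p, r, a = p2, r2, a2
        placements.append((p, r, a))
    return placements[int(rng.integers(0, len(placements)))]


def denormalize_variants(vcf_text: str, reference: ReferenceGenome,
                         seed: int) -> tuple[str, list[dict]]:
    """Right-shift indels within their repeat tracts and merge adjacent SNP
    pairs into complex blocks; returns the altered VCF and a truth list
    mapping each altered record to its normalized original."""
    rng = np.random.default_rng(seed)
    header, records = read_vcf(io.StringIO(vcf_text))
    recs = list(records)
    truth = []
    out_lines = header.to_lines()
    i = 0
    new_records = []
    while i < len(recs):
        rec = recs[i]
        nxt = recs[i + 1] if i + 1 < len(recs) else None
        if (nxt is not None and len(rec.alt) == 1 and len(nxt.alt) == 1
                and len(rec.ref) == 1 == len(rec.alt[0])
                and len(nxt.ref) == 1 == len(nxt.alt[0])
                and rec.chrom == nxt.chrom and 1 <= nxt.pos - rec.pos <= 3
                and rng.random() < 0.5):
            # merge the SNP pair into one complex REF/ALT block
            seq = reference.contigs[rec.chrom]
            span_ref = seq[rec.pos - 1:nxt.pos - 1 + len(nxt.ref)]
            span_alt = (rec.alt[0] + seq[rec.pos:nxt.pos - 1] + nxt.alt[0])
            merged = VcfRecord.build(rec.chrom, rec.pos, span_ref, [span_alt])
            new_records.append(merged)
            truth.append({"kind": "merged_snps", "pos": merged.pos,
                          "ref": span_ref, "alt": span_alt,
                          "originals": [(rec.pos, rec.ref, rec.alt[0]),
                                        (nxt.pos, nxt.ref, nxt.alt[0])]})
            i += 2
            continue
        if len(rec.alt) == 1 and len(rec.ref) != len(rec.alt[0]):
            p, r, a = right_shift(reference, rec.chrom, rec.pos, rec.ref,
                                  rec.alt[0], rng)
            shifted = VcfRecord.build(rec.chrom, p, r, [a])
            new_records.append(shifted)
            truth.append({"kind": "shifted_indel", "pos": p, "ref": r, "alt": a,
                          "original": (rec.pos, rec.ref, rec.alt[0])})
        else:
            new_records.append(rec)
            truth.append({"kind": "unchanged", "pos": rec.pos,
                          "ref": rec.ref, "alt": rec.alt[0] if rec.alt else "."})
        i += 1
    out_lines.extend(r.to_line() for r in new_records)
    return "\n".join(out_lines) + "\n", truth
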