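"""Variant normalization: allelic-primitive decomposition and left-alignment.

A complex REF/ALT pair (e.g. ``ACGT`` -> ``TCGA``) bundles several atomic
events.  :func:`decompose_primitives` recovers them with a global pairwise
alignment of REF against each ALT and splits the record into one output per
primitive (SNP/MNP/INS/DEL).  :func:`left_align` shifts indels to their
5'-most equivalent placement against the reference, the canonical
representation: a deletion inside a repeat tract has many equivalent
placements, all yielding the same alternate haplotype, and callers disagree
on which they emit.

Alignment scoring: match +1, mismatch -2, gap open -4, gap extension -1
(a gap of length L costs 4 + (L-1)).  Mismatches are preferred over spurious
gaps for same-length alleles, and tie-breaking is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

from .core import MISSING, VcfError, VcfHeader, VcfRecord, format_gt, parse_gt
from .transforms import ReferenceGenome

log = logging.getLogger("vcfpipe")

MATCH = 1
MISMATCH = -2
GAP_OPEN = -4
GAP_EXTEND = -1

_NEG_INF = float("-inf")


@dataclass
class AlleleAlignment:
    """Global REF/ALT alignment as (op, length) runs.

    ops: ``=`` match, ``X`` mismatch, ``I`` insertion (ALT-only bases),
    ``D`` deletion (REF-only bases).  Consuming REF and ALT per the cigar
    reproduces both strings exactly.
    """

    cigar: list[tuple[str, int]]
    score: float


def align_alleles(ref: str, alt: str) -> AlleleAlignment:
    """Affine-gap Needleman-Wunsch over two allele strings.

    Deterministic tie-breaking: diagonal (match/mismatch) preferred over
    gaps; deletion preferred over insertion.
    """
    if not ref or not alt:
        raise VcfError("align_alleles requires non-empty alleles")
    n, m = len(ref), len(alt)
    # DP over three states: M (diagonal), D (gap in ALT), I (gap in REF)
    M = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    D = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    I = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        D[i][0] = GAP_OPEN + GAP_EXTEND * (i - 1)
    for j in range(1, m + 1):
        I[0][j] = GAP_OPEN + GAP_EXTEND * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = MATCH if ref[i - 1] == alt[j - 1] else MISMATCH
            M[i][j] = max(M[i - 1][j - 1], D[i - 1][j - 1], I[i - 1][j - 1]) + s
            D[i][j] = max(M[i - 1][j] + GAP_OPEN, D[i - 1][j] + GAP_EXTEND)
            I[i][j] = max(M[i][j - 1] + GAP_OPEN, I[i][j - 1] + GAP_EXTEND)
    # traceback: prefer M (diagonal), then D, then I at equal score
    mats = {"M": M, "D": D, "I": I}
    i, j = n, m
    state = max(("M", "D", "I"), key=lambda st: mats[st][i][j])
    best = mats[state][n][m]
    ops: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            s = MATCH if ref[i - 1] == alt[j - 1] else MISMATCH
            ops.append("=" if s == MATCH else "X")
            target = M[i][j] - s
            i, j = i - 1, j - 1
            state = next(st for st in ("M", "D", "I") if mats[st][i][j] == target)
        elif state == "D":
            ops.append("D")
            state = "M" if D[i][j] == M[i - 1][j] + GAP_OPEN else "D"
            i -= 1
        else:
            ops.append("I")
            state = "M" if I[i][j] == M[i][j - 1] + GAP_OPEN else "I"
            j -= 1
        if i == 0 and j == 0:
            break
    ops.reverse()
    cigar: list[tuple[str, int]] = []
    for op in ops:
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + 1)
        else:
            cigar.append((op, 1))
    return AlleleAlignment(cigar=cigar, score=best)


def cigar_consumes(cigar: list[tuple[str, int]]) -> tuple[int, int]:
    """(ref consumed, alt consumed) — sanity check for alignment validity."""
    r = sum(ln for op, ln in cigar if op in "=XD")
    a = sum(ln for op, ln in cigar if op in "=XI")
    return r, a


# ---------------------------------------------------------------------------
# Primitives
# ---------------------------------------------------------------------------

@dataclass
class PrimitiveAllele:
    """An atomic variant recovered from a complex REF/ALT pair."""

    kind: str  # SNP | MNP | INS | DEL
    pos: int   # 1-based
    ref: str
    alt: str
    source_alt_index: int = 0


def allele_primitives(ref: str, alt: str, pos: int, keep_mnps: bool = False,
                      alt_index: int = 0) -> list[PrimitiveAllele]:
    """Split one REF/ALT pair into primitives via pairwise alignment.

    Adjacent mismatch runs become individual SNPs unless ``keep_mnps``.
    Indels carry an anchor base: the preceding aligned REF base when one
    exists, otherwise the following one (leading-gap case).
    """
    aln = align_alleles(ref, alt)
    prims: list[PrimitiveAllele] = []
    ri = ai = 0  # offsets into ref/alt
    for op, ln in aln.cigar:
        if op == "=":
            ri += ln
            ai += ln
        elif op == "X":
            if keep_mnps and ln > 1:
                prims.append(PrimitiveAllele(
                    "MNP", pos + ri, ref[ri:ri + ln], alt[ai:ai + ln], alt_index))
            else:
                for k in range(ln):
                    prims.append(PrimitiveAllele(
                        "SNP", pos + ri + k, ref[ri + k], alt[ai + k], alt_index))
            ri += ln
            ai += ln
        elif op == "I":
            inserted = alt[ai:ai + ln]
            if ri > 0:
                anchor = ref[ri - 1]
                prims.append(PrimitiveAllele(
                    "INS", pos + ri - 1, anchor, anchor + inserted, alt_index))
            else:
                anchor = ref[ri]  # anchor on the following base
                prims.append(PrimitiveAllele(
                    "INS", pos + ri, anchor, inserted + anchor, alt_index))
            ai += ln
        elif op == "D":
            deleted = ref[ri:ri + ln]
            if ri > 0:
                anchor = ref[ri - 1]
                prims.append(PrimitiveAllele(
                    "DEL", pos + ri - 1, anchor + deleted, anchor, alt_index))
            else:
                anchor = ref[ri + ln]  # anchor on the following base
                prims.append(PrimitiveAllele(
                    "DEL", pos + ri, deleted + anchor, anchor, alt_index))
            ri += ln
    return prims


def reconstruct_alt(ref: str, pos: int, prims: list[PrimitiveAllele]) -> str:
    """Apply one ALT's primitives (in order) back onto REF — the loss-free
    check: the result must equal the original ALT string."""
    out = ref
    shift = 0  # length drift from applied indels
    for p in prims:
        off = p.pos - pos + shift
        if p.kind in ("SNP", "MNP"):
            out = out[:off] + p.alt + out[off + len(p.ref):]
        else:
            out = out[:off] + p.alt + out[off + len(p.ref):]
            shift += len(p.alt) - len(p.ref)
    return out


_SYMBOLIC = ("<", "[", "]")

DECOMPOSED_TAG = "DecomposedFrom"


def is_symbolic(alt: str) -> bool:
    return any(ch in alt for ch in _SYMBOLIC) or alt == "*"


def _slice_info(record: VcfRecord, header: Optional[VcfHeader],
                alt_index: int) -> dict:
    """Copy INFO, slicing Number=A tags down to the primitive's source ALT."""
    out: dict = {}
    for tag, raw in record.info.items():
        if raw is True:
            out[tag] = True
            continue
        entry = header.get_def("INFO", tag) if header else None
        if entry is not None and entry.get("Number") == "A":
            vals = raw.split(",")
            if alt_index < len(vals):
                out[tag] = vals[alt_index]
        else:
            out[tag] = raw
    return out


def decompose_primitives(record: VcfRecord, header: Optional[VcfHeader] = None,
                         keep_mnps: bool = False) -> list[VcfRecord]:
    """Split a record with complex alleles into primitive records.

    Sample genotypes are remapped per primitive: allele indices equal to the
    primitive's source ALT become 1, every other called allele 0, missing
    stays missing; phase separators are preserved.  QUAL and FILTER are
    copied verbatim.  Already-primitive records pass through unchanged;
    symbolic ALTs pass through with a warning.
    """
    alts = record.alt
    if not alts:
        return [record]
    if any(is_symbolic(a) for a in alts):
        log.warning("symbolic ALT at %s:%s; record passed through",
                    record.chrom, record.pos)
        return [record]
    per_alt = [allele_primitives(record.ref, a, record.pos, keep_mnps, i)
               for i, a in enumerate(alts)]
    if all(len(p) == 1 and p[0].ref == record.ref and p[0].alt == alts[i]
           and p[0].pos == record.pos
           for i, p in enumerate(per_alt)):
        return [record]
    if header is not None:
        header.add_meta("INFO", ID=DECOMPOSED_TAG, Number="1", Type="String",
                        Description="Original CHROM:POS:REF:ALT this primitive was split from")
    out: list[tuple[tuple, VcfRecord]] = []
    provenance = f"{record.chrom}:{record.pos}:{record.ref}:{','.join(alts)}"
    for alt_index, prims in enumerate(per_alt):
        info = _slice_info(record, header, alt_index)
        info[DECOMPOSED_TAG] = provenance
        for p in prims:
            sample_texts = []
            fmt = record.format_keys
            for i in range(record.n_samples):
                fields = dict(record.samples[i])
                if "GT" in fields:
                    indices, phased = parse_gt(fields["GT"])
                    mapped = [None if ix is None else (1 if ix == alt_index + 1 else 0)
                              for ix in indices]
                    fields["GT"] = format_gt(mapped, phased)
                sample_texts.append(":".join(fields.get(k, ".") for k in fmt))
            rec = VcfRecord.build(
                record.chrom, p.pos, p.ref, [p.alt],
                id=record._cols[2], qual=record._cols[5],
                filter=record._cols[6], info=info,
                format_keys=fmt or None, sample_texts=sample_texts or None)
            out.append(((p.pos, p.ref, p.alt, alt_index), rec))
    out.sort(key=lambda kv: kv[0])
    return [rec for _, rec in out]


def decompose_stream(records: Iterable[VcfRecord],
                     header: Optional[VcfHeader] = None,
                     keep_mnps: bool = False) -> Iterator[VcfRecord]:
    for rec in records:
        yield from decompose_primitives(rec, header, keep_mnps)


# ---------------------------------------------------------------------------
# Left alignment
# ---------------------------------------------------------------------------

def apply_variant(sequence: str, pos: int, ref: str, alt: str) -> str:
    """Apply one REF->ALT substitution at 1-based ``pos`` to a sequence."""
    return sequence[:pos - 1] + alt + sequence[pos - 1 + len(ref):]


def left_align(record: VcfRecord, reference: ReferenceGenome) -> VcfRecord:
    """Shift indel representations to their absolute leftmost (5') extent.

    Iteratively: while every allele ends in the same base, drop that base
    (extending left from the reference when an allele would empty); then
    trim shared leading bases down to a single anchor.  The applied
    haplotype is invariant and the result is idempotent.  SNP/MNP records
    (all alleles the same length) are returned unchanged.
    """
    alts = record.alt
    if not alts or any(is_symbolic(a) for a in alts):
        return record
    ref_allele = record.ref
    expected = reference.lookup(record.chrom, record.pos, len(ref_allele))
    if ref_allele.upper() != expected:
        raise VcfError(
            f"REF {ref_allele!r} at {record.chrom}:{record.pos} does not match "
            f"reference {expected!r}; run check first")
    if all(len(a) == len(ref_allele) for a in alts):
        return record
    alleles = [ref_allele] + list(alts)
    pos = record.pos
    contig = reference.contigs[record.chrom]
    while True:
        last = {a[-1] for a in alleles if a}
        if len(last) != 1 or any(not a for a in alleles):
            break
        if any(len(a) == 1 for a in alleles):
            if pos == 1:
                break
            pos -= 1
            base = contig[pos - 1]
            alleles = [base + a for a in alleles]
        alleles = [a[:-1] for a in alleles]
    # trim shared leading bases, keeping one anchor
    while all(len(a) > 1 for a in alleles) and len({a[0] for a in alleles}) == 1:
        alleles = [a[1:] for a in alleles]
        pos += 1
    if pos == record.pos and alleles[0] == ref_allele:
        return record
    new = record.copy()
    new.pos = pos
    new.ref = alleles[0]
    new.alt = alleles[1:]
    return new


def left_align_stream(records: Iterable[VcfRecord],
                      reference: ReferenceGenome) -> Iterator[VcfRecord]:
    for rec in records:
        yield left_align(rec, reference)
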