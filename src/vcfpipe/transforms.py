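"""Streaming per-record VCF transformations and annotations.

Every function here consumes and produces record streams, holding at most a
small buffer in memory, so the tools compose in shell pipelines over
arbitrarily large files.  Coordinate conventions: VCF positions are 1-based
inclusive; BED intervals are 0-based half-open.  The conversion lives in
exactly one place (:func:`bed_to_vcf_span`) because the off-by-one is the
classic failure mode.
"""

from __future__ import annotations

import heapq
import logging
import math
import random
from bisect import bisect_right
from collections import Counter
from dataclasses import dataclass
from typing import IO, Iterable, Iterator, Optional

from .core import MISSING, VcfError, VcfHeader, VcfRecord, parse_gt

log = logging.getLogger("vcfpipe")


# ---------------------------------------------------------------------------
# Reference genome and BED intervals
# ---------------------------------------------------------------------------

class ReferenceGenome:
    """Uppercase contig sequences with 1-based substring lookup."""

    def __init__(self, contigs: dict):
        self.contigs = {name: seq.upper() for name, seq in contigs.items()}

    @classmethod
    def from_fasta(cls, path: str) -> "ReferenceGenome":
        from Bio import SeqIO
        return cls({rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")})

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    def lookup(self, contig: str, start_1based: int, length: int) -> str:
        if contig not in self.contigs:
            raise VcfError(f"contig {contig!r} not in reference")
        seq = self.contigs[contig]
        end = start_1based - 1 + length
        if start_1based < 1 or end > len(seq):
            raise VcfError(
                f"lookup {contig}:{start_1based}+{length} beyond contig length {len(seq)}")
        return seq[start_1based - 1:end]


@dataclass(frozen=True)
class BedInterval:
    """0-based half-open interval with an annotation label."""

    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    label: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise VcfError(f"invalid BED interval {self.chrom}:{self.start}-{self.end}")


def bed_to_vcf_span(iv: BedInterval) -> tuple[int, int]:
    """0-based half-open [start, end) -> 1-based inclusive [start+1, end]."""
    return iv.start + 1, iv.end


def read_bed(stream: Iterable[str]) -> list[BedInterval]:
    out = []
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split("\t")
        if len(cols) < 3:
            raise VcfError(f"malformed BED line {lineno}: {line!r}")
        try:
            start, end = int(cols[1]), int(cols[2])
        except ValueError:
            raise VcfError(f"malformed BED line {lineno}: non-integer bounds in {line!r}")
        label = cols[3] if len(cols) > 3 else ""
        try:
            out.append(BedInterval(cols[0], start, end, label))
        except VcfError as e:
            raise VcfError(f"malformed BED line {lineno}: {e}")
    return out


# ---------------------------------------------------------------------------
# fixup: recompute AC/AN/AF/NS from genotypes
# ---------------------------------------------------------------------------

def fixup(record: VcfRecord, header: VcfHeader) -> VcfRecord:
    """Recompute AC, AN, AF and NS from the sample genotypes, overwriting
    any stale values.  Idempotent.  Records without GT pass through."""
    if "GT" not in record.format_keys:
        log.warning("fixup: no GT at %s:%s; record passed through",
                    record.chrom, record.pos)
        return record
    n_alt = len(record.alt)
    ac = [0] * n_alt
    an = 0
    ns = 0
    for i in range(record.n_samples):
        gt = record.samples[i].get("GT", ".")
        indices, _ = parse_gt(gt)
        called = [ix for ix in indices if ix is not None]
        if called:
            ns += 1
        an += len(called)
        for ix in called:
            if 1 <= ix <= n_alt:
                ac[ix - 1] += 1
    record.set_info("AC", ac)
    record.set_info("AN", an)
    record.set_info("NS", ns)
    if an > 0:
        record.set_info("AF", [c / an for c in ac])
    else:
        record.del_info("AF")
    header.add_meta("INFO", ID="AC", Number="A", Type="Integer",
                    Description="Alternate allele count in called genotypes")
    header.add_meta("INFO", ID="AN", Number="1", Type="Integer",
                    Description="Total number of called alleles")
    header.add_meta("INFO", ID="AF", Number="A", Type="Float",
                    Description="Alternate allele frequency AC/AN")
    header.add_meta("INFO", ID="NS", Number="1", Type="Integer",
                    Description="Number of samples with at least one called allele")
    return record


def fixup_stream(records: Iterable[VcfRecord], header: VcfHeader) -> Iterator[VcfRecord]:
    for rec in records:
        yield fixup(rec, header)


# ---------------------------------------------------------------------------
# uniq / streamsort / distance
# ---------------------------------------------------------------------------

def _sort_key(rec: VcfRecord):
    return (rec.pos, rec.ref, ",".join(rec.alt))


def _check_sorted(prev, rec, contig_seen):
    if prev is not None and rec.chrom == prev.chrom and rec.pos < prev.pos:
        raise VcfError(
            f"unsorted input: {rec.chrom}:{rec.pos} after {prev.chrom}:{prev.pos}")
    if rec.chrom != (prev.chrom if prev else None) and rec.chrom in contig_seen:
        raise VcfError(f"contig {rec.chrom} appears in two separate blocks")


def uniq(records: Iterable[VcfRecord]) -> Iterator[VcfRecord]:
    """Drop consecutive duplicates on (CHROM, POS, REF, ALT); input must be
    coordinate-sorted."""
    prev = None
    contigs: set = set()
    for rec in records:
        _check_sorted(prev, rec, contigs)
        if prev is not None and rec.chrom != prev.chrom:
            contigs.add(prev.chrom)
        key = (rec.chrom, rec.pos, rec.ref, ",".join(rec.alt))
        prev_key = (prev.chrom, prev.pos, prev.ref, ",".join(prev.alt)) if prev else None
        if key != prev_key:
            yield rec
        prev = rec


def streamsort(records: Iterable[VcfRecord], window_bp: int = 10_000) -> Iterator[VcfRecord]:
    """Sort records disordered by at most ``window_bp`` within each contig.

    A min-heap buffer holds records until the input position has advanced
    past their position + window; a backwards jump larger than the window is
    a hard error naming the record, because it cannot be repaired with the
    available buffer.
    """
    heap: list = []
    seq = 0
    current_chrom: Optional[str] = None
    max_seen = -1
    done_contigs: set = set()

    def flush_upto(bound: Optional[int]) -> Iterator[VcfRecord]:
        while heap and (bound is None or heap[0][0] <= bound):
            yield heapq.heappop(heap)[3]

    for rec in records:
        if rec.chrom != current_chrom:
            if rec.chrom in done_contigs:
                raise VcfError(f"contig {rec.chrom} appears in two separate blocks")
            yield from flush_upto(None)
            if current_chrom is not None:
                done_contigs.add(current_chrom)
            current_chrom = rec.chrom
            max_seen = -1
        if rec.pos < max_seen - window_bp:
            raise VcfError(
                f"record {rec.chrom}:{rec.pos} is out of order by more than "
                f"{window_bp} bp (saw position {max_seen} earlier)")
        max_seen = max(max_seen, rec.pos)
        key = _sort_key(rec)
        heapq.heappush(heap, (key[0], key[1:], seq, rec))
        seq += 1
        yield from flush_upto(max_seen - window_bp - 1)
    yield from flush_upto(None)


DISTANCE_TAG = "BasesToClosestVariant"


def distance_to_nearest(records: Iterable[VcfRecord],
                        header: Optional[VcfHeader] = None) -> Iterator[VcfRecord]:
    """Annotate each record with the distance (bp) to its nearest neighbour
    on the same contig; a contig's sole record carries no tag."""
    if header is not None:
        header.add_meta("INFO", ID=DISTANCE_TAG, Number="1", Type="Integer",
                        Description="Distance in bp to the nearest variant on the contig")
    prev: Optional[VcfRecord] = None
    prev_dist: Optional[int] = None
    contigs: set = set()
    for rec in records:
        _check_sorted(prev, rec, contigs)
        if prev is not None and rec.chrom == prev.chrom:
            gap = rec.pos - prev.pos
            d_prev = gap if prev_dist is None else min(prev_dist, gap)
            prev.set_info(DISTANCE_TAG, d_prev)
            yield prev
            prev, prev_dist = rec, gap
        else:
            if prev is not None:
                if prev_dist is not None:
                    prev.set_info(DISTANCE_TAG, prev_dist)
                yield prev
                contigs.add(prev.chrom)
            prev, prev_dist = rec, None
    if prev is not None:
        if prev_dist is not None:
            prev.set_info(DISTANCE_TAG, prev_dist)
        yield prev


# ---------------------------------------------------------------------------
# addinfo: supplement INFO from a second sorted stream
# ---------------------------------------------------------------------------

def addinfo(stream_a: Iterable[VcfRecord],
            stream_b: Iterable[VcfRecord]) -> Iterator[VcfRecord]:
    """Copy INFO tags present in B but absent in A at matching
    (CHROM, POS, REF, ALT) sites.  Existing A tags are never overwritten.
    Both streams must be coordinate-sorted with the same contig order."""
    b_iter = iter(stream_b)
    b_buffer: dict = {}
    b_next: Optional[VcfRecord] = None
    b_chrom: Optional[str] = None
    prev = None
    contigs: set = set()

    def pull_b_until(chrom: str, pos: int):
        nonlocal b_next, b_chrom
        while True:
            if b_next is None:
                b_next = next(b_iter, None)
                if b_next is None:
                    return
            if b_next.chrom != chrom:
                # buffer only matters within the current A contig
                if b_chrom == chrom:
                    return
                b_buffer.clear()
                b_chrom = b_next.chrom
                if b_next.chrom != chrom:
                    # advance B until its contig matches or stream ends
                    b_next = None
                    continue
            if b_next.pos > pos:
                return
            key = (b_next.chrom, b_next.pos, b_next.ref, ",".join(b_next.alt))
            b_buffer[key] = b_next
            b_chrom = b_next.chrom
            b_next = None

    for rec in stream_a:
        _check_sorted(prev, rec, contigs)
        if prev is not None and rec.chrom != prev.chrom:
            contigs.add(prev.chrom)
            b_buffer.clear()
        prev = rec
        pull_b_until(rec.chrom, rec.pos)
        key = (rec.chrom, rec.pos, rec.ref, ",".join(rec.alt))
        match = b_buffer.get(key)
        if match is not None:
            for tag, val in match.info.items():
                if tag not in rec.info:
                    rec.set_info(tag, True if val is True else val)
        yield rec


# ---------------------------------------------------------------------------
# annotate from BED
# ---------------------------------------------------------------------------

class _ContigIntervals:
    """Sorted interval list with bisect lookup of all overlaps."""

    def __init__(self, intervals: list[BedInterval]):
        self.ivs = sorted(intervals, key=lambda iv: (iv.start, iv.end))
        self.starts = [iv.start for iv in self.ivs]
        self.max_len = max((iv.end - iv.start for iv in self.ivs), default=0)

    def overlapping(self, start0: int, end0: int) -> list[BedInterval]:
        """All intervals intersecting 0-based half-open [start0, end0)."""
        lo = bisect_right(self.starts, start0 - self.max_len)
        hits = []
        for iv in self.ivs[lo:]:
            if iv.start >= end0:
                break
            if iv.end > start0:
                hits.append(iv)
        return hits


def annotate_bed(records: Iterable[VcfRecord], intervals: list[BedInterval],
                 tag: str, header: Optional[VcfHeader] = None) -> Iterator[VcfRecord]:
    """Tag records whose REF span intersects a BED interval.

    The REF span is [POS, POS+len(REF)-1] 1-based inclusive; a BED interval
    covers 1-based positions [start+1, end].  Multiple hits are comma-joined
    in interval order.
    """
    if header is not None:
        header.add_meta("INFO", ID=tag, Number=".", Type="String",
                        Description="BED interval annotation")
    by_contig: dict = {}
    for iv in intervals:
        by_contig.setdefault(iv.chrom, []).append(iv)
    index = {c: _ContigIntervals(ivs) for c, ivs in by_contig.items()}
    for rec in records:
        contig = index.get(rec.chrom)
        if contig is not None:
            start0 = rec.pos - 1               # REF span, back to 0-based
            end0 = rec.pos - 1 + len(rec.ref)  # half-open
            hits = contig.overlapping(start0, end0)
            if hits:
                rec.set_info(tag, ",".join(iv.label or "." for iv in hits))
        yield rec


# ---------------------------------------------------------------------------
# vcf -> TSV
# ---------------------------------------------------------------------------

def to_tsv(records: Iterable[VcfRecord], header: VcfHeader,
           per_sample: bool = False) -> Iterator[str]:
    """Flatten records into a tab-separated table.

    Columns: the fixed VCF columns, then the header-declared INFO tags in
    sorted order; with ``per_sample`` each record expands to one row per
    sample with the declared FORMAT tags appended.  Absent values are ``.``.
    """
    info_tags = sorted(e["ID"] for e in header.meta.get("INFO", []) if "ID" in e)
    fmt_tags = sorted(e["ID"] for e in header.meta.get("FORMAT", []) if "ID" in e)
    cols = ["CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER"] + info_tags
    if per_sample:
        cols += ["SAMPLE"] + fmt_tags
    yield "\t".join(cols)
    for rec in records:
        fixed = [rec.chrom, str(rec.pos), rec._cols[2], rec.ref,
                 rec._cols[4], rec._cols[5], rec._cols[6]]
        info = rec.info
        info_cells = []
        for tag in info_tags:
            v = info.get(tag)
            if v is None:
                info_cells.append(".")
            elif v is True:
                info_cells.append("1")
            else:
                info_cells.append(v)
        if not per_sample:
            yield "\t".join(fixed + info_cells)
        else:
            for i, name in enumerate(header.samples):
                fields = rec.samples[i] if i < rec.n_samples else {}
                cells = [fields.get(t, ".") for t in fmt_tags]
                yield "\t".join(fixed + info_cells + [name] + cells)


# ---------------------------------------------------------------------------
# entropy annotation
# ---------------------------------------------------------------------------

ENTROPY_TAG = "SequenceEntropy"


def shannon_entropy(seq: str) -> float:
    """Shannon entropy (bits) of the single-base composition."""
    if not seq:
        return 0.0
    counts = Counter(seq)
    n = len(seq)
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def entropy_annotate(records: Iterable[VcfRecord], reference: ReferenceGenome,
                     window_bp: int, header: Optional[VcfHeader] = None) -> Iterator[VcfRecord]:
    """Annotate each record with the entropy of the reference window
    centered on POS; windows clipped at contig ends with a warning."""
    if header is not None:
        header.add_meta("INFO", ID=ENTROPY_TAG, Number="1", Type="Float",
                        Description=f"Shannon entropy (bits) of the {window_bp} bp reference window")
    half = window_bp // 2
    for rec in records:
        contig_len = reference.length(rec.chrom)
        start = rec.pos - half
        end = start + window_bp - 1
        if start < 1 or end > contig_len:
            log.warning("entropy window at %s:%s truncated to contig bounds",
                        rec.chrom, rec.pos)
            start = max(1, start)
            end = min(contig_len, end)
        seq = reference.lookup(rec.chrom, start, end - start + 1)
        rec.set_info(ENTROPY_TAG, round(shannon_entropy(seq), 4))
        yield rec


# ---------------------------------------------------------------------------
# random sampling
# ---------------------------------------------------------------------------

def random_sample(records: Iterable[VcfRecord], rate: float,
                  seed: int) -> Iterator[VcfRecord]:
    """Keep each record independently with probability ``rate``;
    reproducible under a fixed seed."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"sampling rate must be in [0, 1], got {rate}")
    rng = random.Random(seed)
    for rec in records:
        if rng.random() < rate:
            yield rec


# ---------------------------------------------------------------------------
# reference integrity check
# ---------------------------------------------------------------------------

@dataclass
class RefMismatch:
    chrom: str
    pos: int
    ref_allele: str
    reference_seq: str
    kind: str  # "mismatch" | "unknown contig"


def check_reference(records: Iterable[VcfRecord],
                    reference: ReferenceGenome) -> list[RefMismatch]:
    """Compare each REF allele against the reference slice it claims to
    cover; returns the mismatch reports (empty list = clean file)."""
    out = []
    for rec in records:
        if rec.chrom not in reference:
            out.append(RefMismatch(rec.chrom, rec.pos, rec.ref, "", "unknown contig"))
            continue
        try:
            expected = reference.lookup(rec.chrom, rec.pos, len(rec.ref))
        except VcfError:
            out.append(RefMismatch(rec.chrom, rec.pos, rec.ref, "", "unknown contig"))
            continue
        if rec.ref.upper() != expected:
            out.append(RefMismatch(rec.chrom, rec.pos, rec.ref, expected, "mismatch"))
    return out
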