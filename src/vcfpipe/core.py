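"""Lazy, tree-structured VCF record and header model.

A VCF line projects a tree onto a single string through layered separators:
tab splits columns, semicolon splits INFO pairs, comma splits allele-indexed
values, colon splits per-sample fields, ``=`` splits key from value, and
``|``/``/`` split genotype allele indices.  This module parses that tree
*lazily*: fixed columns (CHROM..FILTER) are tokenized on construction, but
the INFO and per-sample columns stay as raw text until a caller actually
asks for them.  Untouched text is written back byte-identically, so a
parse→write round trip is the identity on any valid input.
"""

from __future__ import annotations

import gzip
import io
import json
import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Optional, Union

log = logging.getLogger("vcfpipe")


class VcfError(Exception):
    """Base class for VCF parsing/validation failures."""


class MalformedHeaderError(VcfError):
    pass


class MalformedRecordError(VcfError):
    pass


class ValidationError(VcfError):
    pass


class UnknownSampleError(VcfError):
    pass


class _Missing:
    """Singleton for the VCF missing value ``.``.

    Distinct from 0, "" and None; comparisons against it are always false,
    and it renders back as ``.``.
    """

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):
        return "MISSING"

    def __bool__(self):
        return False


MISSING = _Missing()

#: incremented whenever an INFO or sample column is actually parsed;
#: the laziness contract is asserted against these counters in tests.
PARSE_COUNTERS = {"info": 0, "samples": 0}


# ---------------------------------------------------------------------------
# FieldTree: the layered-separator projection
# ---------------------------------------------------------------------------

#: separators in nesting order, outermost first
SEPARATOR_ORDER = ("\t", ";", ",", ":", "=", "|", "/")


@dataclass
class FieldTree:
    """One node of the separator tree: either a scalar token or an ordered
    list of children joined by ``sep``.  Serialization with the recorded
    separators is the exact inverse of tokenization."""

    text: Optional[str] = None
    children: Optional[list["FieldTree"]] = None
    sep: Optional[str] = None

    @classmethod
    def tokenize(cls, text: str, seps: tuple[str, ...] = SEPARATOR_ORDER) -> "FieldTree":
        for i, sep in enumerate(seps):
            if sep in text:
                rest = seps[i + 1:]
                kids = [cls.tokenize(part, rest) for part in text.split(sep)]
                return cls(children=kids, sep=sep)
        return cls(text=text)

    def serialize(self) -> str:
        if self.children is None:
            return self.text if self.text is not None else ""
        return self.sep.join(c.serialize() for c in self.children)

    def is_scalar(self) -> bool:
        return self.children is None


# ---------------------------------------------------------------------------
# Header
# ---------------------------------------------------------------------------

_STRUCTURED_CATEGORIES = ("INFO", "FORMAT", "FILTER", "contig", "ALT")
_META_RE = re.compile(r"^##([^=]+)=(.*)$")

_FIXED_COLUMNS = ("#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO")


def _split_structured(body: str) -> dict:
    """Split ``ID=DP,Number=1,Type=Integer,Description="Total Depth"`` into
    an ordered dict, honouring quoted values containing commas."""
    out: dict = {}
    i, n = 0, len(body)
    while i < n:
        eq = body.find("=", i)
        if eq < 0:
            # bare token (rare, tolerated)
            out[body[i:].strip()] = True
            break
        key = body[i:eq].strip()
        j = eq + 1
        if j < n and body[j] == '"':
            k = body.find('"', j + 1)
            while k > 0 and body[k - 1] == "\\":
                k = body.find('"', k + 1)
            if k < 0:
                raise MalformedHeaderError(f"unterminated quote in meta line: {body!r}")
            out[key] = body[j + 1:k]
            i = k + 1
            if i < n and body[i] == ",":
                i += 1
        else:
            k = body.find(",", j)
            if k < 0:
                out[key] = body[j:]
                break
            out[key] = body[j:k]
            i = k + 1
    return out


@dataclass
class VcfHeader:
    """Parsed VCF header: structured meta entries plus ordered sample names.

    ``raw_lines`` keeps the original text so an unmodified header
    round-trips byte-identically.
    """

    fileformat: str = "VCFv4.2"
    meta: dict = field(default_factory=dict)  # category -> list of entry dicts
    samples: list = field(default_factory=list)
    raw_lines: list = field(default_factory=list)
    _extra_lines: list = field(default_factory=list)  # provenance lines added later

    def get_def(self, category: str, tag: str) -> Optional[dict]:
        """Look up a structured entry by ID, case-insensitively."""
        for entry in self.meta.get(category, []):
            if entry.get("ID", "").upper() == tag.upper():
                return entry
        return None

    def sample_index(self, name: str) -> int:
        low = name.lower()
        for i, s in enumerate(self.samples):
            if s.lower() == low:
                return i
        raise UnknownSampleError(f"unknown sample {name!r}; known: {self.samples}")

    def has_sample(self, name: str) -> bool:
        return any(s.lower() == name.lower() for s in self.samples)

    def add_meta(self, category: str, **fields) -> None:
        """Add a structured meta entry (e.g. an INFO declaration) if absent."""
        if self.get_def(category, fields.get("ID", "")) is not None:
            return
        self.meta.setdefault(category, []).append(dict(fields))
        parts = []
        for k, v in fields.items():
            if k == "Description":
                parts.append(f'{k}="{v}"')
            else:
                parts.append(f"{k}={v}")
        self._extra_lines.append(f"##{category}=<{','.join(parts)}>")

    def add_provenance(self, text: str) -> None:
        self._extra_lines.append(f"##{text}")

    def to_lines(self) -> list[str]:
        lines = list(self.raw_lines[:-1]) + list(self._extra_lines) + [self.raw_lines[-1]]
        return lines

    def __str__(self) -> str:
        return "\n".join(self.to_lines())


def parse_header(lines: Iterable[str]) -> VcfHeader:
    """Parse ``#``-prefixed header lines into a :class:`VcfHeader`.

    The first line must be ``##fileformat=...`` and the last the ``#CHROM``
    column line.  INFO/FORMAT/FILTER/contig/ALT entries are structured;
    every other meta line is preserved verbatim and exposed as key/value.
    """
    lines = [ln.rstrip("\n") for ln in lines]
    if not lines or not lines[0].startswith("##fileformat="):
        raise MalformedHeaderError("header must begin with ##fileformat=")
    header = VcfHeader(raw_lines=lines)
    header.fileformat = lines[0].split("=", 1)[1]
    chrom_line = None
    for ln in lines:
        if ln.startswith("##"):
            m = _META_RE.match(ln)
            if not m:
                header.meta.setdefault("other", []).append({"key": ln[2:], "value": ""})
                continue
            key, value = m.group(1), m.group(2)
            if value.startswith("<") and value.endswith(">"):
                entry = _split_structured(value[1:-1])
                cat = key if key in _STRUCTURED_CATEGORIES else "other"
                if cat == "other":
                    entry = {"key": key, **entry}
                header.meta.setdefault(cat, []).append(entry)
            else:
                header.meta.setdefault("other", []).append({"key": key, "value": value})
        elif ln.startswith("#CHROM"):
            chrom_line = ln
    if chrom_line is None:
        raise MalformedHeaderError("missing #CHROM column line")
    cols = chrom_line.split("\t")
    if tuple(cols[:8]) != _FIXED_COLUMNS:
        raise MalformedHeaderError(f"unexpected #CHROM columns: {cols[:8]}")
    samples = cols[9:] if len(cols) > 9 else []
    if len(set(samples)) != len(samples):
        dupes = sorted({s for s in samples if samples.count(s) > 1})
        raise ValidationError(f"duplicate sample name(s): {dupes}")
    header.samples = samples
    # ID uniqueness within structured categories
    for cat in _STRUCTURED_CATEGORIES:
        ids = [e.get("ID") for e in header.meta.get(cat, []) if "ID" in e]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate {cat} ID(s): {dupes}")
    return header


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

def parse_gt(gt: str):
    """Parse a GT string like ``0|1`` into (allele_indices, phased_flags).

    Missing allele calls become ``None``; ``phased`` holds one flag per
    separator so mixed-ploidy separators survive round trips.
    """
    indices: list = []
    phased: list = []
    token = ""
    for ch in gt:
        if ch in "|/":
            indices.append(None if token in (".", "") else int(token))
            phased.append(ch == "|")
            token = ""
        else:
            token += ch
    indices.append(None if token in (".", "") else int(token))
    return indices, phased


def format_gt(indices, phased) -> str:
    parts = ["." if i is None else str(i) for i in indices]
    out = parts[0]
    for sep_phased, part in zip(phased, parts[1:]):
        out += ("|" if sep_phased else "/") + part
    return out


@dataclass
class SampleCall:
    """A parsed genotype call plus the other FORMAT fields, raw."""

    allele_indices: list
    phased: list
    other_fields: dict

    @property
    def is_phased(self) -> bool:
        return bool(self.phased) and all(self.phased)

    @property
    def called(self) -> bool:
        return bool(self.allele_indices) and all(i is not None for i in self.allele_indices)

    def gt_string(self) -> str:
        return format_gt(self.allele_indices, self.phased)


class VcfRecord:
    """One VCF data line.

    Fixed columns are tokenized eagerly; INFO and sample columns stay raw
    until accessed.  All mutation goes through setters that rewrite only the
    affected column string, so unmodified bytes are preserved on output.
    """

    __slots__ = ("_cols", "_info_cache", "_sample_cache", "n_samples")

    def __init__(self, line: str, n_samples: Optional[int] = None):
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 8:
            raise MalformedRecordError(f"record has {len(cols)} < 8 columns: {line[:80]!r}")
        try:
            pos = int(cols[1])
        except ValueError:
            raise MalformedRecordError(f"non-integer POS {cols[1]!r}")
        if pos < 1:
            raise MalformedRecordError(f"POS must be >= 1, got {pos}")
        self._cols = cols
        self._info_cache: Optional[dict] = None
        self._sample_cache: Optional[list] = None
        self.n_samples = len(cols) - 9 if len(cols) > 9 else 0
        if n_samples is not None and self.n_samples != n_samples:
            raise ValidationError(
                f"record at {cols[0]}:{cols[1]} has {self.n_samples} sample columns, header declares {n_samples}"
            )

    # -- fixed fields ------------------------------------------------------

    @property
    def chrom(self) -> str:
        return self._cols[0]

    @chrom.setter
    def chrom(self, v: str):
        self._cols[0] = v

    @property
    def pos(self) -> int:
        return int(self._cols[1])

    @pos.setter
    def pos(self, v: int):
        self._cols[1] = str(v)

    @property
    def id(self):
        return MISSING if self._cols[2] == "." else self._cols[2]

    @property
    def ref(self) -> str:
        return self._cols[3]

    @ref.setter
    def ref(self, v: str):
        self._cols[3] = v

    @property
    def alt(self) -> list:
        if self._cols[4] == ".":
            return []
        return self._cols[4].split(",")

    @alt.setter
    def alt(self, alts):
        self._cols[4] = ",".join(alts) if alts else "."

    @property
    def qual(self):
        raw = self._cols[5]
        if raw == ".":
            return MISSING
        try:
            return float(raw)
        except ValueError:
            return raw

    @qual.setter
    def qual(self, v):
        self._cols[5] = "." if v is MISSING else format(v, "g")

    @property
    def filter_raw(self) -> str:
        return self._cols[6]

    @property
    def filter(self):
        if self._cols[6] == ".":
            return MISSING
        return self._cols[6].split(";")

    # -- INFO --------------------------------------------------------------

    @property
    def info_raw(self) -> str:
        return self._cols[7]

    @property
    def info(self) -> dict:
        """Lazy map INFO tag -> raw value text (``True`` for flags)."""
        if self._info_cache is None:
            PARSE_COUNTERS["info"] += 1
            cache: dict = {}
            raw = self._cols[7]
            if raw not in (".", ""):
                for item in raw.split(";"):
                    if "=" in item:
                        k, v = item.split("=", 1)
                        cache[k] = v
                    else:
                        cache[item] = True
            self._info_cache = cache
        return self._info_cache

    def set_info(self, tag: str, value) -> None:
        """Set/overwrite one INFO tag, rewriting only the INFO column."""
        info = dict(self.info)
        if value is True:
            info[tag] = True
        elif value is MISSING or value is None:
            info.pop(tag, None)
        elif isinstance(value, (list, tuple)):
            info[tag] = ",".join(_fmt_num(v) for v in value)
        else:
            info[tag] = _fmt_num(value)
        self._info_cache = info
        self._cols[7] = _serialize_info(info)

    def del_info(self, tag: str) -> None:
        info = dict(self.info)
        info.pop(tag, None)
        self._info_cache = info
        self._cols[7] = _serialize_info(info)

    # -- samples -----------------------------------------------------------

    @property
    def format_keys(self) -> list:
        if len(self._cols) <= 8:
            return []
        return self._cols[8].split(":")

    @property
    def samples(self) -> list:
        """Lazy list of per-sample dicts: FORMAT tag -> raw text."""
        if self._sample_cache is None:
            PARSE_COUNTERS["samples"] += 1
            keys = self.format_keys
            out = []
            for raw in self._cols[9:]:
                vals = raw.split(":")
                out.append(dict(zip(keys, vals)))
            self._sample_cache = out
        return self._sample_cache

    def sample_call(self, index: int) -> SampleCall:
        fields = dict(self.samples[index])
        gt = fields.pop("GT", None)
        if gt is None:
            return SampleCall([], [], fields)
        indices, phased = parse_gt(gt)
        return SampleCall(indices, phased, fields)

    def set_sample_field(self, index: int, tag: str, value: str) -> None:
        keys = self.format_keys
        if tag not in keys:
            self._cols[8] = ":".join(keys + [tag])
            keys = self.format_keys
        fields = dict(self.samples[index])
        fields[tag] = value
        self._sample_cache[index] = fields
        self._cols[9 + index] = ":".join(fields.get(k, ".") for k in keys)

    # -- serialization -----------------------------------------------------

    def to_line(self) -> str:
        return "\t".join(self._cols)

    def copy(self) -> "VcfRecord":
        return VcfRecord(self.to_line())

    def __repr__(self):
        return f"<VcfRecord {self.chrom}:{self.pos} {self.ref}>{self._cols[4]}>"

    @classmethod
    def build(cls, chrom, pos, ref, alts, id=".", qual=".", filter=".",
              info=".", format_keys=None, sample_texts=None) -> "VcfRecord":
        """Construct a record from parts (canonical separators)."""
        if isinstance(info, dict):
            info = _serialize_info(info) or "."
        cols = [str(chrom), str(pos), id, ref,
                ",".join(alts) if alts else ".", str(qual), filter, info]
        if format_keys:
            cols.append(":".join(format_keys))
            cols.extend(sample_texts or [])
        return cls("\t".join(cols))


def _fmt_num(v) -> str:
    if isinstance(v, float):
        return format(v, ".6g")
    return str(v)


def _serialize_info(info: dict) -> str:
    parts = []
    for k, v in info.items():
        parts.append(k if v is True else f"{k}={v}")
    return ";".join(parts) if parts else "."


def parse_record(line: str, header: Optional[VcfHeader] = None) -> VcfRecord:
    """Parse one data line; sample-column count validated against header."""
    return VcfRecord(line, None if header is None else len(header.samples))


def write_record(record: VcfRecord, header: Optional[VcfHeader] = None) -> str:
    """Serialize a record; unmodified records reproduce their source bytes."""
    if header is not None and record.n_samples != len(header.samples):
        raise ValidationError(
            f"record has {record.n_samples} samples, header declares {len(header.samples)}"
        )
    return record.to_line()


# ---------------------------------------------------------------------------
# Typed field access
# ---------------------------------------------------------------------------

_FIXED_FIELDS = {"chrom", "pos", "id", "ref", "alt", "qual", "filter"}


def _coerce(raw: str, vtype: str, number: str, tag: str):
    """Coerce raw INFO/FORMAT text per the header declaration.

    Failures degrade to the raw string with a logged warning rather than an
    error — flexibility over strictness.
    """
    if raw is True:
        return True
    if raw == "." or raw == "":
        return MISSING

    def one(tok: str):
        if tok == ".":
            return MISSING
        try:
            if vtype == "Integer":
                return int(tok)
            if vtype == "Float":
                return float(tok)
        except ValueError:
            log.warning("INFO/FORMAT tag %s declared %s but value %r is not; keeping string",
                        tag, vtype, tok)
            return tok
        return tok

    if number in ("1", "0"):
        return one(raw)
    if "," in raw or number in ("A", "R", "G", "."):
        vals = [one(t) for t in raw.split(",")]
        if number in ("A", "R", "G") or "," in raw:
            return vals
        return vals[0] if len(vals) == 1 else vals
    return one(raw)


def get_field(record: VcfRecord, path: str, header: VcfHeader):
    """Navigate the record tree by a dotted path, case-insensitively.

    Paths: a fixed field (``pos``, ``qual``...), ``info.<TAG>``, or
    ``<sample-name>.<FORMAT-TAG>``.  Values are typed per the header
    declaration; an absent tag yields MISSING (False for declared flags).
    """
    parts = path.split(".")
    head = parts[0].lower()
    if len(parts) == 1 and head in _FIXED_FIELDS:
        return getattr(record, head)
    if head == "info" and len(parts) == 2:
        return info_value(record, parts[1], header)
    if len(parts) == 2:
        if not header.has_sample(parts[0]):
            raise UnknownSampleError(f"unknown sample {parts[0]!r}; known: {header.samples}")
        idx = header.sample_index(parts[0])
        return sample_value(record, idx, parts[1], header)
    raise VcfError(f"cannot resolve field path {path!r}")


def _resolve_tag(record_keys, tag: str):
    if tag in record_keys:
        return tag
    up = tag.upper()
    for k in record_keys:
        if k.upper() == up:
            return k
    return None


def info_value(record: VcfRecord, tag: str, header: Optional[VcfHeader] = None):
    info = record.info
    key = _resolve_tag(info.keys(), tag)
    entry = header.get_def("INFO", tag) if header else None
    if key is None:
        if entry is not None and entry.get("Type") == "Flag":
            return False
        return MISSING
    raw = info[key]
    if entry is None:
        # undeclared tag: numeric-looking tokens still come back typed
        if raw is True:
            return True
        return _coerce(raw, _sniff_type(raw), ".", tag)
    return _coerce(raw, entry.get("Type", "String"), entry.get("Number", "."), tag)


def sample_value(record: VcfRecord, sample_index: int, tag: str,
                 header: Optional[VcfHeader] = None):
    fields = record.samples[sample_index]
    key = _resolve_tag(fields.keys(), tag)
    if key is None:
        return MISSING
    raw = fields[key]
    if key == "GT":
        return raw
    entry = header.get_def("FORMAT", tag) if header else None
    if entry is None:
        return _coerce(raw, _sniff_type(raw), ".", tag)
    return _coerce(raw, entry.get("Type", "String"), entry.get("Number", "."), tag)


_INT_RE = re.compile(r"-?\d+$")
_FLOAT_RE = re.compile(r"-?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def _sniff_type(raw: str) -> str:
    first = raw.split(",")[0]
    if _INT_RE.match(first):
        return "Integer"
    if _FLOAT_RE.match(first):
        return "Float"
    return "String"


# ---------------------------------------------------------------------------
# JSON projections
# ---------------------------------------------------------------------------

def _jsonable(v):
    if v is MISSING:
        return None
    if isinstance(v, list):
        return [_jsonable(x) for x in v]
    return v


def record_to_dict(record: VcfRecord, header: VcfHeader) -> dict:
    """Nested-object view of the record tree (fixed fields, info, samples)."""
    obj = {
        "chrom": record.chrom,
        "pos": record.pos,
        "id": _jsonable(record.id),
        "ref": record.ref,
        "alt": record.alt,
        "qual": _jsonable(record.qual),
        "filter": _jsonable(record.filter),
        "info": {k: _jsonable(info_value(record, k, header)) for k in record.info},
    }
    if header.samples and record.n_samples:
        obj["samples"] = {
            name: {
                tag: _jsonable(sample_value(record, i, tag, header))
                for tag in record.samples[i]
            }
            for i, name in enumerate(header.samples)
        }
    return obj


def record_to_json(record: VcfRecord, header: VcfHeader) -> str:
    return json.dumps(record_to_dict(record, header))


def meta_to_json(header: VcfHeader, category_filter: Optional[str] = None) -> str:
    """Emit structured header meta as a JSON document.

    With a category filter, emits the JSON array for that one category.
    """
    known = list(header.meta.keys())
    if category_filter is not None:
        if category_filter not in header.meta:
            raise VcfError(f"unknown meta category {category_filter!r}; known: {known}")
        return json.dumps(header.meta[category_filter])
    doc = dict(header.meta)
    doc["samples"] = header.samples
    doc["fileformat"] = header.fileformat
    return json.dumps(doc)


# ---------------------------------------------------------------------------
# Streaming I/O
# ---------------------------------------------------------------------------

def open_text(path: str) -> IO[str]:
    """Open plain or gzip text, detected by magic bytes."""
    f = open(path, "rb")
    magic = f.read(2)
    f.seek(0)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=f), encoding="utf-8")
    return io.TextIOWrapper(f, encoding="utf-8")


def read_vcf(source: Union[str, IO[str], Iterable[str]]):
    """Read a VCF stream: returns ``(header, record_iterator)``.

    ``source`` may be a path (plain or gzipped), an open text stream, or any
    iterable of lines.  Records are parsed lazily as the iterator advances.
    """
    if isinstance(source, str):
        stream: Iterable[str] = open_text(source)
    else:
        stream = source
    it = iter(stream)
    header_lines = []
    first_data: Optional[str] = None
    for line in it:
        if line.startswith("#"):
            header_lines.append(line)
        else:
            first_data = line
            break
    header = parse_header(header_lines)

    def records() -> Iterator[VcfRecord]:
        n = len(header.samples)
        if first_data is not None and first_data.strip():
            yield VcfRecord(first_data, n)
        for line in it:
            if line.strip():
                yield VcfRecord(line, n)

    return header, records()


def write_vcf(out: IO[str], header: VcfHeader, records: Iterable[VcfRecord]) -> None:
    for ln in header.to_lines():
        out.write(ln + "\n")
    for rec in records:
        out.write(rec.to_line() + "\n")
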