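"""Safe filtering and templating expression language over VCF records.

Expressions read record fields as ``r.qual``, ``r.info.DP``,
``r.<sample>.<tag>`` and, inside sample filters, ``s.<tag>`` for the sample
currently bound.  The language is a closed, side-effect-free subset:
comparisons, boolean connectives, arithmetic, Perl-style regex match
(``=~`` / ``!~``), explicit conversions ``.to_i .to_f .to_s``, and a single
higher-order form ``count(<sample predicate>)`` that evaluates its argument
once per sample.  No host-language code can be reached from an expression,
and evaluation touches only the fields the expression references — the lazy
record model never parses anything else.

Missing-value semantics: any comparison with a missing operand is false, so
``r.info.AF < 0.001`` and ``r.info.AF >= 0.001`` both reject a record
without the tag.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from .core import (MISSING, UnknownSampleError, VcfError, VcfHeader,
                   VcfRecord, info_value, sample_value)


class DslSyntaxError(VcfError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class DslEvalError(VcfError):
    pass


# ---------------------------------------------------------------------------
# Tokenizer
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<number>(\d+\.\d*|\.\d+|\d+)([eE][+-]?\d+)?)
  | (?P<string>'[^']*'|"[^"]*")
  | (?P<op>==|!=|<=|>=|=~|!~|<|>|\+|-|\*|/|\(|\)|\[|\]|,)
  | (?P<ident>[A-Za-z_]\w*(\.[A-Za-z_]\w*)*)
    """,
    re.VERBOSE,
)

_REGEX_RE = re.compile(r"/((?:[^/\\]|\\.)*)/")


def _tokenize(src: str) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    i, n = 0, len(src)
    while i < n:
        # a '/' directly after =~ or !~ opens a regex literal, not division
        if src[i] == "/" and tokens and tokens[-1][1] in ("=~", "!~"):
            m = _REGEX_RE.match(src, i)
            if not m:
                raise DslSyntaxError("unterminated regex literal", i)
            tokens.append(("regex", m.group(1), i))
            i = m.end()
            continue
        m = _TOKEN_RE.match(src, i)
        if not m:
            raise DslSyntaxError(f"unexpected character {src[i]!r}", i)
        kind = m.lastgroup
        text = m.group()
        if kind != "ws":
            if kind == "ident" and text in ("and", "or", "not", "true", "false", "count"):
                kind = text
            tokens.append((kind, text, i))
        i = m.end()
    tokens.append(("eof", "", n))
    return tokens


# ---------------------------------------------------------------------------
# AST and parser
# ---------------------------------------------------------------------------

_CONVERSIONS = ("to_i", "to_f", "to_s")


@dataclass
class FilterExpression:
    """A compiled expression: source text, AST, and the set of field paths
    it can possibly read (the lazy contract's upper bound)."""

    source: str
    ast: tuple
    referenced_paths: frozenset = field(default_factory=frozenset)

    @property
    def needs_sample(self) -> bool:
        return _needs_sample(self.ast)


class _Parser:
    def __init__(self, tokens):
        self.tokens = tokens
        self.i = 0

    def peek(self):
        return self.tokens[self.i]

    def next(self):
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect(self, kind):
        tok = self.next()
        if tok[0] != kind:
            raise DslSyntaxError(f"expected {kind}, got {tok[1]!r}", tok[2])
        return tok

    def parse(self):
        node = self.expr()
        tok = self.peek()
        if tok[0] != "eof":
            raise DslSyntaxError(f"trailing input {tok[1]!r}", tok[2])
        return node

    def expr(self):
        return self.or_expr()

    def or_expr(self):
        node = self.and_expr()
        while self.peek()[0] == "or":
            self.next()
            node = ("or", node, self.and_expr())
        return node

    def and_expr(self):
        node = self.not_expr()
        while self.peek()[0] == "and":
            self.next()
            node = ("and", node, self.not_expr())
        return node

    def not_expr(self):
        if self.peek()[0] == "not":
            self.next()
            return ("not", self.not_expr())
        return self.comparison()

    def comparison(self):
        node = self.additive()
        kind, text, pos = self.peek()
        if kind == "op" and text in ("==", "!=", "<", "<=", ">", ">=", "=~", "!~"):
            self.next()
            if text in ("=~", "!~"):
                rk, rt, rp = self.peek()
                if rk == "regex":
                    self.next()
                    rhs = ("regex", rt)
                else:
                    rhs = self.additive()
            else:
                rhs = self.additive()
            return ("cmp", text, node, rhs)
        return node

    def additive(self):
        node = self.mult()
        while self.peek()[0] == "op" and self.peek()[1] in ("+", "-"):
            op = self.next()[1]
            node = ("arith", op, node, self.mult())
        return node

    def mult(self):
        node = self.unary()
        while self.peek()[0] == "op" and self.peek()[1] in ("*", "/"):
            op = self.next()[1]
            node = ("arith", op, node, self.unary())
        return node

    def unary(self):
        if self.peek()[0] == "op" and self.peek()[1] == "-":
            self.next()
            return ("neg", self.unary())
        return self.primary()

    def primary(self):
        kind, text, pos = self.peek()
        if kind == "number":
            self.next()
            return ("num", float(text) if ("." in text or "e" in text or "E" in text) else int(text))
        if kind == "string":
            self.next()
            return ("str", text[1:-1])
        if kind == "true":
            self.next()
            return ("bool", True)
        if kind == "false":
            self.next()
            return ("bool", False)
        if kind == "count":
            self.next()
            self.expect_op("(")
            arg = self.expr()
            self.expect_op(")")
            return ("count", arg)
        if kind == "op" and text == "(":
            self.next()
            node = self.expr()
            self.expect_op(")")
            return node
        if kind == "op" and text == "[":
            self.next()
            items = [self.expr()]
            while self.peek()[0] == "op" and self.peek()[1] == ",":
                self.next()
                items.append(self.expr())
            self.expect_op("]")
            return ("list", items)
        if kind == "ident":
            self.next()
            return self.path_node(text, pos)
        raise DslSyntaxError(f"unexpected token {text!r}", pos)

    def expect_op(self, op):
        kind, text, pos = self.next()
        if kind != "op" or text != op:
            raise DslSyntaxError(f"expected {op!r}, got {text!r}", pos)

    def path_node(self, text, pos):
        parts = text.split(".")
        convs = []
        while parts and parts[-1] in _CONVERSIONS:
            convs.append(parts.pop())
        if not parts:
            raise DslSyntaxError(f"bare conversion {text!r}", pos)
        scope = parts[0].lower()
        if scope == "r":
            if len(parts) < 2:
                raise DslSyntaxError("record path needs a field, e.g. r.qual", pos)
            node = ("path", "r", tuple(parts[1:]))
        elif scope == "s":
            if len(parts) != 2:
                raise DslSyntaxError("sample path must be s.<tag>", pos)
            node = ("path", "s", tuple(parts[1:]))
        else:
            raise DslSyntaxError(
                f"unknown scope {parts[0]!r}: paths start with r. or s.", pos)
        for conv in reversed(convs):
            node = ("conv", conv, node)
        return node


def _walk_paths(node, out):
    if not isinstance(node, tuple):
        return
    if node[0] == "path":
        out.add(node[1] + "." + ".".join(node[2]))
        return
    for child in node[1:]:
        if isinstance(child, tuple):
            _walk_paths(child, out)
        elif isinstance(child, list):
            for c in child:
                _walk_paths(c, out)


def _needs_sample(node) -> bool:
    if not isinstance(node, tuple):
        return False
    if node[0] == "path" and node[1] == "s":
        return True
    if node[0] == "count":
        return False  # count binds its own samples
    for child in node[1:]:
        if isinstance(child, tuple) and _needs_sample(child):
            return True
        if isinstance(child, list) and any(_needs_sample(c) for c in child):
            return True
    return False


def compile(expr: str) -> FilterExpression:
    """Compile expression text to a :class:`FilterExpression`.  Pure."""
    ast = _Parser(_tokenize(expr)).parse()
    paths: set = set()
    _walk_paths(ast, paths)
    return FilterExpression(source=expr, ast=ast, referenced_paths=frozenset(paths))


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

class _FilterView:
    """FILTER exposed both ways: raw string for regex, code list for
    equality."""

    def __init__(self, raw: str, codes):
        self.raw = raw
        self.codes = codes if codes is not MISSING else []

    def __eq__(self, other):
        return other == self.raw or other in self.codes

    def __ne__(self, other):
        return not self.__eq__(other)

    def __str__(self):
        return self.raw


def _resolve_record_path(parts, record: VcfRecord, header: VcfHeader):
    head = parts[0].lower()
    if len(parts) == 1:
        if head == "filter":
            return _FilterView(record.filter_raw, record.filter)
        if head in ("chrom", "pos", "id", "ref", "qual"):
            return getattr(record, head)
        if head == "alt":
            alts = record.alt
            return alts[0] if len(alts) == 1 else alts
    if head == "info" and len(parts) == 2:
        return info_value(record, parts[1], header)
    if len(parts) == 2 and header.has_sample(parts[0]):
        return sample_value(record, header.sample_index(parts[0]), parts[1], header)
    if len(parts) == 2:
        raise UnknownSampleError(
            f"unknown sample {parts[0]!r} in path r.{'.'.join(parts)}")
    raise DslEvalError(f"cannot resolve r.{'.'.join(parts)}")


def _truthy(v) -> bool:
    if v is MISSING:
        return False
    return bool(v)


def _unwrap(v):
    # Number=A tags on biallelic records come back as 1-element lists;
    # scalar comparison semantics unwrap them
    if isinstance(v, list) and len(v) == 1:
        return v[0]
    return v


def _compare(op: str, left, right) -> bool:
    left, right = _unwrap(left), _unwrap(right)
    if left is MISSING or right is MISSING:
        return False
    if op in ("=~", "!~"):
        pattern = right
        hit = re.search(pattern, str(left)) is not None
        return hit if op == "=~" else not hit
    if op in ("==", "!="):
        eq = _loose_eq(left, right)
        return eq if op == "==" else not eq
    lnum, rnum = _as_num(left), _as_num(right)
    if lnum is not None and rnum is not None:
        left, right = lnum, rnum
    else:
        left, right = str(left), str(right)
    if op == "<":
        return left < right
    if op == "<=":
        return left <= right
    if op == ">":
        return left > right
    if op == ">=":
        return left >= right
    raise DslEvalError(f"unknown comparison {op}")


def _loose_eq(left, right) -> bool:
    if isinstance(left, _FilterView) or isinstance(right, _FilterView):
        return left == right
    lnum, rnum = _as_num(left), _as_num(right)
    if lnum is not None and rnum is not None:
        return lnum == rnum
    return str(left) == str(right)


def _as_num(v):
    if isinstance(v, bool):
        return None
    if isinstance(v, (int, float)):
        return v
    return None


def evaluate(expr: FilterExpression, record: VcfRecord,
             header: VcfHeader, sample_index: Optional[int] = None):
    """Evaluate a compiled expression against one record (and optionally one
    bound sample for ``s.*`` paths)."""
    return _eval(expr.ast, record, header, sample_index)


def _eval(node, record, header, sample_index):
    kind = node[0]
    if kind in ("num", "str", "bool", "regex"):
        return node[1]
    if kind == "path":
        scope, parts = node[1], node[2]
        if scope == "r":
            return _resolve_record_path(list(parts), record, header)
        if sample_index is None:
            raise DslEvalError(
                f"expression reads s.{parts[0]} but no sample is bound")
        if parts[0].lower() == "gt":
            return sample_value(record, sample_index, "GT", header)
        return sample_value(record, sample_index, parts[0], header)
    if kind == "conv":
        v = _eval(node[2], record, header, sample_index)
        if v is MISSING:
            return MISSING
        try:
            if node[1] == "to_i":
                return int(float(v))
            if node[1] == "to_f":
                return float(v)
            return str(v)
        except (TypeError, ValueError):
            return MISSING
    if kind == "neg":
        v = _eval(node[1], record, header, sample_index)
        if v is MISSING:
            return MISSING
        return -v
    if kind == "not":
        return not _truthy(_eval(node[1], record, header, sample_index))
    if kind == "and":
        return (_truthy(_eval(node[1], record, header, sample_index))
                and _truthy(_eval(node[2], record, header, sample_index)))
    if kind == "or":
        return (_truthy(_eval(node[1], record, header, sample_index))
                or _truthy(_eval(node[2], record, header, sample_index)))
    if kind == "cmp":
        left = _eval(node[2], record, header, sample_index)
        right = _eval(node[3], record, header, sample_index)
        return _compare(node[1], left, right)
    if kind == "arith":
        left = _eval(node[2], record, header, sample_index)
        right = _eval(node[3], record, header, sample_index)
        if left is MISSING or right is MISSING:
            return MISSING
        lnum, rnum = _as_num(left), _as_num(right)
        if node[1] == "+" and (lnum is None or rnum is None):
            return str(left) + str(right)
        if lnum is None or rnum is None:
            raise DslEvalError(
                f"arithmetic {node[1]} on non-numeric operands {left!r}, {right!r}")
        if node[1] == "+":
            return lnum + rnum
        if node[1] == "-":
            return lnum - rnum
        if node[1] == "*":
            return lnum * rnum
        if node[1] == "/":
            return lnum / rnum
    if kind == "count":
        total = 0
        for i in range(record.n_samples):
            if _truthy(_eval(node[1], record, header, i)):
                total += 1
        return total
    if kind == "list":
        return [_eval(item, record, header, sample_index) for item in node[1]]
    raise DslEvalError(f"unknown AST node {kind!r}")


# ---------------------------------------------------------------------------
# Streams
# ---------------------------------------------------------------------------

def record_passes(expr: FilterExpression, record: VcfRecord, header: VcfHeader,
                  sample_mode: str = "any") -> bool:
    if expr.needs_sample:
        if record.n_samples == 0:
            return False
        results = (_truthy(_eval(expr.ast, record, header, i))
                   for i in range(record.n_samples))
        return any(results) if sample_mode == "any" else all(results)
    return _truthy(_eval(expr.ast, record, header, None))


def filter_stream(records: Iterable[VcfRecord], keep: FilterExpression,
                  header: VcfHeader, sample_mode: str = "any") -> Iterator[VcfRecord]:
    """Yield records for which the expression is true.

    Expressions with ``s.*`` paths are quantified over samples with
    ``sample_mode`` (default ``any``).
    """
    if sample_mode not in ("any", "all"):
        raise ValueError(f"sample_mode must be any|all, got {sample_mode!r}")
    for rec in records:
        if record_passes(keep, rec, header, sample_mode):
            yield rec


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------

@dataclass
class OutputTemplate:
    """Header/body/footer text blocks with ``{expression}`` slots.

    Rendering n records produces the header once, the body once per record,
    and the footer once.
    """

    body_block: str
    header_block: str = ""
    footer_block: str = ""

    @classmethod
    def from_text(cls, text: str) -> "OutputTemplate":
        """Parse a template file: blocks separated by lines of ``%%``;
        one block = body, two = header+body, three = header+body+footer."""
        blocks = re.split(r"^%%\s*$", text, flags=re.MULTILINE)
        if len(blocks) == 1:
            return cls(body_block=blocks[0])
        if len(blocks) == 2:
            return cls(header_block=blocks[0], body_block=blocks[1])
        if len(blocks) == 3:
            return cls(header_block=blocks[0], body_block=blocks[1],
                       footer_block=blocks[2])
        raise VcfError("template may have at most three %%-separated blocks")


def _render_value(v) -> str:
    if v is MISSING or v is None:
        return "."
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float):
        return format(v, "g")
    if isinstance(v, list):
        return "\t".join(_render_value(x) for x in v)
    return str(v)


def render_block(block: str, record: Optional[VcfRecord],
                 header: VcfHeader) -> str:
    """Left-to-right scan: ``{{``/``}}`` are literal braces, ``{expr}`` is
    an interpolation slot (so JSON templates need no special casing)."""
    out = []
    i, n = 0, len(block)
    while i < n:
        ch = block[i]
        if ch == "{":
            if block.startswith("{{", i):
                out.append("{")
                i += 2
                continue
            end = block.find("}", i + 1)
            if end < 0:
                raise VcfError(f"unterminated template slot at offset {i}")
            expr = compile(block[i + 1:end])
            v = evaluate(expr, record, header) if record is not None else MISSING
            out.append(_render_value(v))
            i = end + 1
        elif ch == "}" and block.startswith("}}", i):
            out.append("}")
            i += 2
        else:
            out.append(ch)
            i += 1
    return "".join(out)


def eval_stream(records: Iterable[VcfRecord], body, header: VcfHeader,
                on_error: str = "skip") -> Iterator[str]:
    """Render one output line per record.

    ``body`` is either an :class:`OutputTemplate`, a compiled expression
    (its value — a list renders tab-separated), or expression text.
    Slot evaluation errors skip the line with a warning unless
    ``on_error='abort'``.
    """
    import logging
    log = logging.getLogger("vcfpipe")
    if isinstance(body, str):
        body = compile(body)
    if isinstance(body, OutputTemplate):
        if body.header_block:
            yield render_block(body.header_block, None, header).rstrip("\n")
        for rec in records:
            try:
                yield render_block(body.body_block, rec, header).rstrip("\n")
            except VcfError as e:
                if on_error == "abort":
                    raise
                log.warning("template evaluation failed at %s:%s: %s",
                            rec.chrom, rec.pos, e)
        if body.footer_block:
            yield render_block(body.footer_block, None, header).rstrip("\n")
        return
    for rec in records:
        try:
            yield _render_value(evaluate(body, rec, header))
        except VcfError as e:
            if on_error == "abort":
                raise
            log.warning("eval failed at %s:%s: %s", rec.chrom, rec.pos, e)


def json_lines(records: Iterable[VcfRecord], header: VcfHeader) -> Iterator[str]:
    from .core import record_to_json
    for rec in records:
        yield record_to_json(rec, header)
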