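"""Path-like port identifiers and selector expressions.

Ports of a circuit module are named by hierarchical, path-like identifiers
such as ``/med/L1[0]``: a sequence of levels, each either a name token
(``med``, ``L1``) or a nonnegative integer index.  A *selector* is an
expression denoting an ordered, duplicate-free set of identifiers.  The
grammar (EBNF shipped in docs/selector-grammar.md):

* ``/med/L1[0]``            one port; ``/med/L1/0`` is the same port
* ``/med/[L1,L2][0]``       bracketed lists multiply out (left-major)
* ``/med/L1[0:10]``         half-open integer range -> ten ports
* ``a,b``                   union (ordered concatenation, first-kept dedup)
* ``a+b``                   product: every identifier of ``a`` concatenated
                            with every identifier of ``b`` (left-major)
* ``a.+b``                  elementwise join: i-th with i-th (equal sizes)
* ``/med/L1/*``             wildcard: any (possibly empty) level suffix;
                            only valid as the final level, and only usable
                            against a concrete universe of ports

Name tokens are ``[A-Za-z_][A-Za-z0-9_]*``; a bare digit level is an integer
index, which is why ``/med/L1/0`` and ``/med/L1[0]`` denote the same
identifier.  Whitespace between tokens is ignored (``[0, 1]``).
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Iterable, Sequence, Union

from .errors import (
    CardinalityError,
    SelectorSyntaxError,
    WildcardError,
)

__all__ = [
    "PortIdentifier",
    "Selector",
    "parse_selector",
    "expand",
    "expand_against",
    "count_ports",
    "combine",
]

Level = Union[str, int]

#: sentinel level token used in match patterns; never a legal name token
WILD = "*"

_NAME_RE = re.compile(r"[A-Za-z_]\w*")


@dataclass(frozen=True)
class PortIdentifier:
    """One port name: an ordered sequence of name/index levels."""

    levels: tuple[Level, ...]

    def __post_init__(self):
        if not self.levels:
            raise ValueError("identifier needs at least one level")
        for lev in self.levels:
            if isinstance(lev, bool) or not isinstance(lev, (str, int)):
                raise TypeError(f"bad level {lev!r}")
            if isinstance(lev, int) and lev < 0:
                raise ValueError(f"negative index level {lev}")
            if isinstance(lev, str) and not _NAME_RE.fullmatch(lev):
                raise ValueError(f"bad name level {lev!r}")

    @classmethod
    def coerce(cls, obj) -> "PortIdentifier":
        if isinstance(obj, PortIdentifier):
            return obj
        if isinstance(obj, str):
            ids = Selector(obj).expand()
            if len(ids) != 1:
                raise ValueError(f"{obj!r} does not denote exactly one port")
            return ids[0]
        if isinstance(obj, (tuple, list)):
            return cls(tuple(obj))
        raise TypeError(f"cannot interpret {obj!r} as a port identifier")

    def __str__(self) -> str:
        return _render_levels(self.levels)

    def __repr__(self) -> str:
        return f"PortIdentifier({self})"


def _render_levels(levels: Sequence[Level]) -> str:
    out = []
    for lev in levels:
        if lev == WILD:
            out.append("/*")
        elif isinstance(lev, int):
            out.append(f"[{lev}]")
        else:
            out.append(f"/{lev}")
    return "".join(out)


# ---------------------------------------------------------------------------
# expression tree


@dataclass(frozen=True)
class _Empty:
    pass


@dataclass(frozen=True)
class _Path:
    # each group: tuple of alternative levels, in source order; a wildcard
    # group is exactly (WILD,)
    groups: tuple[tuple[Level, ...], ...]


@dataclass(frozen=True)
class _Union:
    parts: tuple


@dataclass(frozen=True)
class _Concat:
    left: object
    right: object


@dataclass(frozen=True)
class _Zip:
    left: object
    right: object


def _has_wild(node) -> bool:
    if isinstance(node, _Path):
        return any(g == (WILD,) for g in node.groups)
    if isinstance(node, _Union):
        return any(_has_wild(p) for p in node.parts)
    if isinstance(node, (_Concat, _Zip)):
        return _has_wild(node.left) or _has_wild(node.right)
    return False


def _validate(node) -> None:
    """Enforce wildcard placement rules on a freshly parsed tree."""
    if isinstance(node, _Path):
        for i, g in enumerate(node.groups):
            if WILD in g:
                if g != (WILD,):
                    raise SelectorSyntaxError("wildcard cannot be mixed into a list")
                if i != len(node.groups) - 1:
                    raise SelectorSyntaxError("wildcard only allowed as the final level")
    elif isinstance(node, _Union):
        for p in node.parts:
            _validate(p)
    elif isinstance(node, _Concat):
        if _has_wild(node.left):
            raise SelectorSyntaxError("wildcard only allowed as the final level")
        _validate(node.left)
        _validate(node.right)
    elif isinstance(node, _Zip):
        if _has_wild(node.left) or _has_wild(node.right):
            raise SelectorSyntaxError("wildcard not allowed in an elementwise join")
        _validate(node.left)
        _validate(node.right)


# ---------------------------------------------------------------------------
# tokenizer / recursive-descent parser

_TOKEN_RE = re.compile(
    r"""(?P<ws>\s+)
      | (?P<zip>\.\+)
      | (?P<op>[/\[\],:()+*])
      | (?P<name>[A-Za-z_]\w*)
      | (?P<int>\d+)
    """,
    re.VERBOSE,
)


def _tokenize(text: str) -> list[tuple[str, object, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise SelectorSyntaxError(f"unexpected character {text[pos]!r}", pos)
        if m.lastgroup == "ws":
            pass
        elif m.lastgroup == "zip":
            tokens.append(("op", ".+", pos))
        elif m.lastgroup == "op":
            tokens.append(("op", m.group(), pos))
        elif m.lastgroup == "name":
            tokens.append(("name", m.group(), pos))
        else:
            tokens.append(("int", int(m.group()), pos))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else ("eof", None, len(self.text))

    def next(self):
        tok = self.peek()
        self.i += 1
        return tok

    def expect_op(self, op: str):
        kind, val, pos = self.next()
        if kind != "op" or val != op:
            raise SelectorSyntaxError(f"expected {op!r}", pos)

    def parse(self):
        if not self.tokens:
            return _Empty()
        node = self.parse_union()
        kind, val, pos = self.peek()
        if kind != "eof":
            raise SelectorSyntaxError(f"unexpected {val!r}", pos)
        return node

    def parse_union(self):
        parts = [self.parse_expr()]
        while self.peek()[:2] == ("op", ","):
            self.next()
            parts.append(self.parse_expr())
        return parts[0] if len(parts) == 1 else _Union(tuple(parts))

    def parse_expr(self):
        node = self.parse_atom()
        while True:
            kind, val, _ = self.peek()
            if kind == "op" and val == "+":
                self.next()
                node = _Concat(node, self.parse_atom())
            elif kind == "op" and val == ".+":
                self.next()
                node = _Zip(node, self.parse_atom())
            else:
                return node

    def parse_atom(self):
        kind, val, pos = self.peek()
        if kind == "op" and val == "(":
            self.next()
            node = self.parse_union()
            self.expect_op(")")
            return node
        return self.parse_path()

    def parse_path(self):
        groups: list[tuple[Level, ...]] = []
        while True:
            kind, val, pos = self.peek()
            if kind == "op" and val == "/":
                self.next()
                kind, val, pos = self.peek()
                if kind in ("name", "int"):
                    self.next()
                    groups.append((val,))
                elif kind == "op" and val == "*":
                    self.next()
                    groups.append((WILD,))
                elif kind == "op" and val == "[":
                    groups.append(self.parse_bracket())
                else:
                    raise SelectorSyntaxError("expected level after '/'", pos)
            elif kind == "op" and val == "[":
                groups.append(self.parse_bracket())
            else:
                break
        if not groups:
            raise SelectorSyntaxError("expected a selector", pos)
        return _Path(tuple(groups))

    def parse_bracket(self) -> tuple[Level, ...]:
        self.expect_op("[")
        items: list[Level] = []
        while True:
            items.extend(self.parse_bracket_item())
            kind, val, pos = self.next()
            if kind == "op" and val == "]":
                break
            if not (kind == "op" and val == ","):
                raise SelectorSyntaxError("expected ',' or ']' in bracket", pos)
        if not items:
            raise SelectorSyntaxError("empty bracket")
        return tuple(items)

    def parse_bracket_item(self) -> list[Level]:
        kind, val, pos = self.next()
        if kind == "name":
            return [val]
        if kind == "int":
            k2, v2, _ = self.peek()
            if k2 == "op" and v2 == ":":
                self.next()
                k3, v3, p3 = self.next()
                if k3 != "int":
                    raise SelectorSyntaxError("expected integer range bound", p3)
                if v3 < val:
                    raise SelectorSyntaxError(f"decreasing range [{val}:{v3}]", pos)
                return list(range(val, v3))
            return [val]
        raise SelectorSyntaxError("expected name, integer, or range in bracket", pos)


# ---------------------------------------------------------------------------
# expansion

def _expand_node(node) -> list[tuple[Level, ...]]:
    """Expand to a list of level tuples; a trailing WILD marks a prefix pattern."""
    if isinstance(node, _Empty):
        return []
    if isinstance(node, _Path):
        return [tuple(combo) for combo in itertools.product(*node.groups)]
    if isinstance(node, _Union):
        out = []
        for p in node.parts:
            out.extend(_expand_node(p))
        return out
    if isinstance(node, _Concat):
        left = _expand_node(node.left)
        right = _expand_node(node.right)
        return [a + b for a in left for b in right]
    if isinstance(node, _Zip):
        left = _expand_node(node.left)
        right = _expand_node(node.right)
        if len(left) != len(right):
            raise CardinalityError(
                f"elementwise join of {len(left)} vs {len(right)} identifiers"
            )
        return [a + b for a, b in zip(left, right)]
    raise TypeError(node)


def _dedupe(seq):
    seen = set()
    out = []
    for item in seq:
        if item not in seen:
            seen.add(item)
            out.append(item)
    return out


def _matches(pattern: tuple[Level, ...], ident: PortIdentifier) -> bool:
    if pattern and pattern[-1] == WILD:
        prefix = pattern[:-1]
        return ident.levels[: len(prefix)] == prefix
    return ident.levels == pattern


# ---------------------------------------------------------------------------
# public class

class Selector:
    """An ordered, duplicate-free set of port identifiers.

    Construct from a selector string, or via :meth:`from_identifiers`.
    ``a + b`` is the *union* of two selectors (the operator used to pool
    port sets); ``a.product(b)`` concatenates identifier paths pairwise
    (the string-level ``+``); ``a.zip_join(b)`` is the elementwise ``.+``.
    """

    __slots__ = ("_node", "_text", "_patterns_cache")

    def __init__(self, text: str = "", *, _node=None):
        if _node is not None:
            self._node = _node
            self._text = text or None
        else:
            if isinstance(text, Selector):
                self._node = text._node
                self._text = text._text
            else:
                self._node = _Parser(text).parse()
                _validate(self._node)
                self._text = text
        self._patterns_cache = None

    # -- construction helpers ------------------------------------------------

    @classmethod
    def coerce(cls, obj) -> "Selector":
        if isinstance(obj, Selector):
            return obj
        if isinstance(obj, str):
            return cls(obj)
        if isinstance(obj, PortIdentifier):
            return cls.from_identifiers([obj])
        if isinstance(obj, Iterable):
            return cls.from_identifiers(obj)
        raise TypeError(f"cannot interpret {obj!r} as a selector")

    @classmethod
    def from_identifiers(cls, identifiers: Iterable) -> "Selector":
        ids = [PortIdentifier.coerce(i) for i in identifiers]
        if not ids:
            return cls("")
        node = _Union(tuple(_Path(tuple((lev,) for lev in i.levels)) for i in ids))
        if len(ids) == 1:
            node = node.parts[0]
        return cls(_node=node)

    # -- core queries --------------------------------------------------------

    def _patterns(self) -> list[tuple[Level, ...]]:
        if self._patterns_cache is None:
            self._patterns_cache = _dedupe(_expand_node(self._node))
        return self._patterns_cache

    @property
    def has_wildcard(self) -> bool:
        return _has_wild(self._node)

    def expand(self) -> tuple[PortIdentifier, ...]:
        """The ordered identifier set; error if the selector has a wildcard."""
        if self.has_wildcard:
            raise WildcardError(
                "selector contains a wildcard; resolve it against a universe "
                "with expand_against()"
            )
        return tuple(PortIdentifier(p) for p in self._patterns())

    @property
    def identifiers(self) -> tuple[PortIdentifier, ...]:
        return self.expand()

    def __len__(self) -> int:
        return len(self.expand())

    @property
    def count(self) -> int:
        return len(self)

    def expand_against(self, universe: Iterable) -> tuple[PortIdentifier, ...]:
        """Members of ``universe`` matched by this selector, in universe order."""
        universe = [PortIdentifier.coerce(u) for u in universe]
        pats = self._patterns()
        exact = {p for p in pats if not (p and p[-1] == WILD)}
        wild = [p for p in pats if p and p[-1] == WILD]
        out = []
        for u in universe:
            if u.levels in exact or any(_matches(p, u) for p in wild):
                out.append(u)
        return tuple(out)

    def __contains__(self, ident) -> bool:
        ident = PortIdentifier.coerce(ident)
        return any(_matches(p, ident) for p in self._patterns())

    # -- algebra -------------------------------------------------------------

    def __add__(self, other) -> "Selector":
        """Union: ordered concatenation of the two port sets (first-kept dedup)."""
        other = Selector.coerce(other)
        return Selector(_node=_Union((self._node, other._node)))

    union = __add__

    def product(self, other) -> "Selector":
        """Pair every identifier of self with every identifier of other (left-major)."""
        other = Selector.coerce(other)
        return Selector(_node=_Concat(self._node, other._node))

    def zip_join(self, other) -> "Selector":
        """Concatenate the i-th identifier of self with the i-th of other."""
        other = Selector.coerce(other)
        sel = Selector(_node=_Zip(self._node, other._node))
        sel._patterns()  # force cardinality check eagerly
        return sel

    # -- rendering / equality ------------------------------------------------

    def render(self) -> str:
        """Canonical bracketed form: union of fully expanded identifiers."""
        return ",".join(_render_levels(p) for p in self._patterns())

    def __str__(self) -> str:
        return self.render()

    def __repr__(self) -> str:
        return f"Selector({self.render()!r})"

    def __eq__(self, other) -> bool:
        if not isinstance(other, (Selector, str)):
            return NotImplemented
        other = Selector.coerce(other)
        return self._patterns() == other._patterns()

    def __hash__(self) -> int:
        return hash(tuple(self._patterns()))

    def __iter__(self):
        return iter(self.expand())


# ---------------------------------------------------------------------------
# functional interface

def parse_selector(text: str) -> Selector:
    """Parse selector text; raises :class:`SelectorSyntaxError` on bad input."""
    return Selector(text)


def expand(sel) -> tuple[PortIdentifier, ...]:
    """Ordered, duplicate-free identifier set of a wildcard-free selector."""
    return Selector.coerce(sel).expand()


def expand_against(sel, universe) -> tuple[PortIdentifier, ...]:
    """Subset of ``universe`` matched by ``sel``, in universe order."""
    return Selector.coerce(sel).expand_against(universe)


def count_ports(sel) -> int:
    """Number of ports denoted by a wildcard-free selector."""
    return len(Selector.coerce(sel))


def combine(a, b, operator: str) -> Selector:
    """Combine two selectors: ``union``, ``product``, or ``elementwise``."""
    a = Selector.coerce(a)
    b = Selector.coerce(b)
    if operator == "union":
        return a + b
    if operator == "product":
        return a.product(b)
    if operator == "elementwise":
        return a.zip_join(b)
    raise ValueError(f"unknown operator {operator!r}")
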