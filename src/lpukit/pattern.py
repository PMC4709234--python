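"""Inter-module connectivity patterns.

A :class:`Pattern` links the ports of two circuit modules (LPUs).  It holds
two attributed interfaces, labelled 0 and 1, plus a sparse directed set of
connections between them.  Directions are *pattern-relative*: a port through
which an LPU's output enters the pattern is a pattern ``in`` port, and a
port through which the pattern delivers data into an LPU's input is a
pattern ``out`` port.  This inverts the naive reading of the attribute
table — an LPU output port appears in the pattern with ``io='in'``.

Structural rules enforced on every mutation:

* connection endpoints lie on opposite interfaces;
* the source is a pattern ``in`` port and the destination a pattern ``out``
  port;
* both endpoints carry the same transmission kind (``gpot`` or ``spike``);
* every destination has in-degree <= 1 (fan-in is prohibited; multiplexing
  of several sources happens inside the receiving LPU); fan-out is free.

A single pattern is bidirectional: connections may run 0 -> 1 and 1 -> 0
within the same instance.  Connections are presence-only — synaptic models
live inside LPUs, not on pattern edges.  Only existing connections are
stored, so memory grows with the connection count, not with the product of
the interface sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import (
    AttributeConflictError,
    DirectionError,
    FanInError,
    InterfaceMismatchError,
    OverlapError,
    SameInterfaceError,
    TransmissionMismatchError,
    UnknownPortError,
)
from .selectors import PortIdentifier, Selector

__all__ = [
    "PortAttributes",
    "Pattern",
    "CompatibilityReport",
    "make_pattern",
]

IO_VALUES = ("in", "out")
TRANSMISSION_VALUES = ("gpot", "spike")


@dataclass
class PortAttributes:
    """Attributes of one port inside a pattern."""

    identifier: PortIdentifier
    interface: int  # 0 or 1
    io: str | None = None  # 'in' | 'out', pattern-relative
    transmission: str | None = None  # 'gpot' | 'spike'

    @property
    def is_set(self) -> bool:
        return self.io is not None and self.transmission is not None


@dataclass
class CompatibilityReport:
    """Outcome of matching one pattern interface against an LPU interface."""

    mismatches: list[str] = field(default_factory=list)

    @property
    def compatible(self) -> bool:
        return not self.mismatches

    def __bool__(self) -> bool:
        return self.compatible


def _normalize_lpu_interface(lpu_interface) -> dict[PortIdentifier, tuple[str, str]]:
    """Accept an LPUSpec, a mapping id->(io, transmission), or an iterable of
    (identifier, io, transmission) triples."""
    if hasattr(lpu_interface, "interface"):  # LPUSpec-like
        lpu_interface = [
            (d.identifier, d.io, d.transmission) for d in lpu_interface.interface
        ]
    if isinstance(lpu_interface, Mapping):
        return {
            PortIdentifier.coerce(k): (io, tr)
            for k, (io, tr) in lpu_interface.items()
        }
    out = {}
    for ident, io, tr in lpu_interface:
        out[PortIdentifier.coerce(ident)] = (io, tr)
    return out


class Pattern:
    """Two attributed port interfaces plus sparse directed connections."""

    def __init__(self, sel0, sel1):
        ids0 = Selector.coerce(sel0).expand()
        ids1 = Selector.coerce(sel1).expand()
        overlap = set(ids0) & set(ids1)
        if overlap:
            raise OverlapError(
                f"identifiers appear in both interfaces: "
                f"{', '.join(str(i) for i in sorted(map(str, overlap)))}"
            )
        self._ports: dict[PortIdentifier, PortAttributes] = {}
        for ident in ids0:
            self._ports[ident] = PortAttributes(ident, 0)
        for ident in ids1:
            self._ports[ident] = PortAttributes(ident, 1)
        # sparse store: destination -> source (enforces fan-in <= 1 by key
        # uniqueness); insertion-ordered
        self._src_of: dict[PortIdentifier, PortIdentifier] = {}

    # -- queries -------------------------------------------------------------

    @property
    def ports(self) -> tuple[PortAttributes, ...]:
        return tuple(self._ports.values())

    @property
    def identifiers(self) -> tuple[PortIdentifier, ...]:
        return tuple(self._ports)

    def port(self, identifier) -> PortAttributes:
        ident = PortIdentifier.coerce(identifier)
        try:
            return self._ports[ident]
        except KeyError:
            raise UnknownPortError(ident) from None

    def interface_ids(self, interface: int) -> tuple[PortIdentifier, ...]:
        return tuple(a.identifier for a in self._ports.values() if a.interface == interface)

    @property
    def connections(self) -> tuple[tuple[PortIdentifier, PortIdentifier], ...]:
        return tuple((src, dst) for dst, src in self._src_of.items())

    @property
    def n_connections(self) -> int:
        return len(self._src_of)

    @property
    def storage_size(self) -> int:
        """Number of stored connection entries (sparse-representation proxy)."""
        return len(self._src_of)

    def __len__(self) -> int:
        return len(self._ports)

    def source_of(self, dst) -> PortIdentifier | None:
        return self._src_of.get(PortIdentifier.coerce(dst))

    def targets_of(self, src) -> tuple[PortIdentifier, ...]:
        src = PortIdentifier.coerce(src)
        return tuple(d for d, s in self._src_of.items() if s == src)

    # -- mutation ------------------------------------------------------------

    def set_attributes(self, sel, interface: int, io: str, transmission: str) -> "Pattern":
        """Set io/transmission on the ports of ``sel``, which must all belong
        to interface ``interface``.  Idempotent; refuses changes that would
        break the invariants of existing connections."""
        if io not in IO_VALUES:
            raise ValueError(f"io must be one of {IO_VALUES}, got {io!r}")
        if transmission not in TRANSMISSION_VALUES:
            raise ValueError(
                f"transmission must be one of {TRANSMISSION_VALUES}, got {transmission!r}"
            )
        universe = tuple(self._ports)
        sel = Selector.coerce(sel)
        if sel.has_wildcard:
            idents = sel.expand_against(universe)
        else:
            idents = sel.expand()
        for ident in idents:
            attrs = self.port(ident)
            if attrs.interface != interface:
                raise InterfaceMismatchError(
                    f"port {ident} belongs to interface {attrs.interface}, "
                    f"not {interface}"
                )
            connected = ident in self._src_of or any(
                s == ident for s in self._src_of.values()
            )
            if connected and (attrs.io != io or attrs.transmission != transmission):
                raise AttributeConflictError(
                    f"port {ident} has existing connections; cannot change its "
                    f"attributes from ({attrs.io}, {attrs.transmission}) to "
                    f"({io}, {transmission})"
                )
            attrs.io = io
            attrs.transmission = transmission
        return self

    def __setitem__(self, sel, value):
        """``pat[sel] = (interface, io, transmission)`` convenience form."""
        interface, io, transmission = value
        self.set_attributes(sel, interface, io, transmission)

    def add_connection(self, src, dst) -> "Pattern":
        """Connect pattern-in port ``src`` to pattern-out port ``dst``."""
        src_attrs = self.port(src)
        dst_attrs = self.port(dst)
        src, dst = src_attrs.identifier, dst_attrs.identifier
        if not (src_attrs.is_set and dst_attrs.is_set):
            unset = src if not src_attrs.is_set else dst
            raise DirectionError(f"port {unset} has no io/transmission attributes yet")
        if src_attrs.interface == dst_attrs.interface:
            raise SameInterfaceError(
                f"{src} and {dst} both lie on interface {src_attrs.interface}"
            )
        if src_attrs.io != "in":
            raise DirectionError(
                f"source {src} is a pattern '{src_attrs.io}' port; sources must "
                "be pattern 'in' ports (they receive an LPU's output)"
            )
        if dst_attrs.io != "out":
            raise DirectionError(
                f"destination {dst} is a pattern '{dst_attrs.io}' port; "
                "destinations must be pattern 'out' ports"
            )
        if src_attrs.transmission != dst_attrs.transmission:
            raise TransmissionMismatchError(
                f"{src} is {src_attrs.transmission} but {dst} is "
                f"{dst_attrs.transmission}; connections require equal kinds"
            )
        if dst in self._src_of and self._src_of[dst] != src:
            raise FanInError(
                f"destination {dst} already receives from {self._src_of[dst]}; "
                "fan-in is prohibited"
            )
        self._src_of[dst] = src
        return self

    # -- compatibility -------------------------------------------------------

    def check_compatibility(self, interface: int, lpu_interface) -> CompatibilityReport:
        """Match one pattern interface against an LPU interface.

        Compatible iff every *connected* pattern port on this interface (a)
        exists in the LPU by identifier, (b) has the same transmission kind,
        and (c) pattern-in ports are LPU outputs / pattern-out ports are LPU
        inputs.  Unconnected pattern ports are ignored.
        """
        lpu = _normalize_lpu_interface(lpu_interface)
        report = CompatibilityReport()
        for attrs in self._ports.values():
            if attrs.interface != interface:
                continue
            connected = attrs.identifier in self._src_of or any(
                s == attrs.identifier for s in self._src_of.values()
            )
            if not connected:
                continue
            ident = attrs.identifier
            if ident not in lpu:
                report.mismatches.append(f"{ident}: missing from LPU interface")
                continue
            lpu_io, lpu_tr = lpu[ident]
            if lpu_tr != attrs.transmission:
                report.mismatches.append(
                    f"{ident}: transmission mismatch (pattern {attrs.transmission}, "
                    f"LPU {lpu_tr})"
                )
            expected_lpu_io = "out" if attrs.io == "in" else "in"
            if lpu_io != expected_lpu_io:
                report.mismatches.append(
                    f"{ident}: direction mismatch (pattern '{attrs.io}' port "
                    f"requires an LPU '{expected_lpu_io}' port, LPU has '{lpu_io}')"
                )
        return report

    def connected_ports(self, interface: int, direction: str) -> Selector:
        """Selector over ports of ``interface`` with pattern-relative
        ``direction`` that participate in at least one connection."""
        if direction not in IO_VALUES:
            raise ValueError(f"direction must be one of {IO_VALUES}")
        participating = set(self._src_of) | set(self._src_of.values())
        out = [
            a.identifier
            for a in self._ports.values()
            if a.interface == interface
            and a.io == direction
            and a.identifier in participating
        ]
        return Selector.from_identifiers(out)


def make_pattern(sel0, sel1) -> Pattern:
    """Create an empty pattern whose interfaces cover ``sel0`` and ``sel1``."""
    return Pattern(sel0, sel1)
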