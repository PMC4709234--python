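"""Identifier-addressed value buffers.

A :class:`PortDataMap` assigns each port of a defining selector a contiguous
0-based index into a value buffer and supports selector-addressed reads and
writes, in the role the original plays for GPU-resident arrays.  Here the
reference backend keeps plain host arrays: buffer residency is a backend
concern, not part of the contract.  Graded-potential (``gpot``) buffers hold
double-precision reals; ``spike`` buffers hold 32-bit integers restricted to
{0, 1}.  Index order equals the defining selector's documented expansion
order and is stable for the lifetime of the mapper.
"""

from __future__ import annotations

import numpy as np

from .errors import UnknownPortError, WildcardError
from .selectors import PortIdentifier, Selector

__all__ = ["PortDataMap", "build_mapper"]

_DTYPES = {"gpot": np.float64, "spike": np.int32}


class PortDataMap:
    """Ordered identifier -> contiguous-index mapping over a value buffer."""

    def __init__(self, sel, kind: str):
        if kind not in _DTYPES:
            raise ValueError(f"kind must be 'gpot' or 'spike', got {kind!r}")
        sel = Selector.coerce(sel)
        if sel.has_wildcard:
            raise WildcardError("cannot build a mapper from a wildcard selector")
        self.kind = kind
        self.order: tuple[PortIdentifier, ...] = sel.expand()
        self.index_of: dict[PortIdentifier, int] = {
            ident: i for i, ident in enumerate(self.order)
        }
        self.buffer = np.zeros(len(self.order), dtype=_DTYPES[kind])

    def __len__(self) -> int:
        return len(self.order)

    def __contains__(self, ident) -> bool:
        return PortIdentifier.coerce(ident) in self.index_of

    def indices(self, sel) -> np.ndarray:
        """Buffer indices for ``sel``'s ports, in the selector's expansion order."""
        sel = Selector.coerce(sel)
        if sel.has_wildcard:
            idents = sel.expand_against(self.order)
        else:
            idents = sel.expand()
        idx = np.empty(len(idents), dtype=np.intp)
        for i, ident in enumerate(idents):
            try:
                idx[i] = self.index_of[ident]
            except KeyError:
                raise UnknownPortError(ident) from None
        return idx

    def get_values(self, sel) -> np.ndarray:
        """Values of the selected ports, in the selector's expansion order."""
        return self.buffer[self.indices(sel)]

    def set_values(self, sel, values) -> "PortDataMap":
        """Write ``values`` to the selected ports; lengths must agree and
        spike values must be 0/1."""
        idx = self.indices(sel)
        values = np.asarray(values)
        if values.ndim == 0:
            values = np.broadcast_to(values, idx.shape)
        if values.shape != idx.shape:
            raise ValueError(
                f"selector denotes {idx.size} ports but got {values.size} values"
            )
        if self.kind == "spike" and not np.isin(values, (0, 1)).all():
            raise ValueError("spike values must be 0 or 1")
        self.buffer[idx] = values
        return self

    __getitem__ = get_values
    __setitem__ = set_values

    def to_table(self) -> str:
        """Tab-separated dump of the mapper layout (port, index, value)."""
        lines = ["Port\tIndex\tValue"]
        for ident, value in zip(self.order, self.buffer):
            lines.append(f"{ident}\t{self.index_of[ident]}\t{value:g}")
        return "\n".join(lines)


def build_mapper(sel, kind: str) -> PortDataMap:
    """Zero-initialized mapper whose index order is ``expand(sel)``."""
    return PortDataMap(sel, kind)
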