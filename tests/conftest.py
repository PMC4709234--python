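"""Shared fixtures: the worked pattern example and small helper builders."""

import pytest

from lpukit import Pattern


TABLE_CONNECTIONS = [
    ("/lam[0]", "/med[0]"),
    ("/lam[0]", "/med[1]"),
    ("/lam[1]", "/med[2]"),
    ("/med[3]", "/lam[3]"),
    ("/med[4]", "/lam[4]"),
    ("/med[4]", "/lam[5]"),
]

TABLE_ATTRIBUTES = [
    ("/lam[0]", 0, "in", "gpot"),
    ("/lam[1]", 0, "in", "gpot"),
    ("/lam[2]", 0, "out", "gpot"),
    ("/lam[3]", 0, "out", "spike"),
    ("/lam[4]", 0, "out", "spike"),
    ("/lam[5]", 0, "out", "spike"),
    ("/med[0]", 1, "out", "gpot"),
    ("/med[1]", 1, "out", "gpot"),
    ("/med[2]", 1, "out", "gpot"),
    ("/med[3]", 1, "in", "spike"),
    ("/med[4]", 1, "in", "spike"),
]


def build_table_pattern() -> Pattern:
    """The 11-port, 6-connection lam/med worked example."""
    pat = Pattern("/lam[0:6]", "/med[0:5]")
    for ident, label, io, kind in TABLE_ATTRIBUTES:
        pat.set_attributes(ident, label, io, kind)
    for src, dst in TABLE_CONNECTIONS:
        pat.add_connection(src, dst)
    return pat


@pytest.fixture
def table_pattern() -> Pattern:
    return build_table_pattern()


#: LPU-relative interfaces matching the worked pattern (pattern 'in' ports
#: are LPU outputs and vice versa)
LAM_LPU_INTERFACE = {
    "/lam[0]": ("out", "gpot"),
    "/lam[1]": ("out", "gpot"),
    "/lam[2]": ("in", "gpot"),
    "/lam[3]": ("in", "spike"),
    "/lam[4]": ("in", "spike"),
    "/lam[5]": ("in", "spike"),
}

MED_LPU_INTERFACE = {
    "/med[0]": ("in", "gpot"),
    "/med[1]": ("in", "gpot"),
    "/med[2]": ("in", "gpot"),
    "/med[3]": ("out", "spike"),
    "/med[4]": ("out", "spike"),
}
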