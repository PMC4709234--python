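"""Port selectors: parse, expand, match, and combine path-like port names.

Every port of a circuit module is named by a hierarchical identifier such
as /med/L1[0] (module "med", neuron class "L1", index 0).  Selectors denote
ordered sets of such identifiers.
"""

from lpukit import Selector, combine, count_ports, expand, expand_against

# Ranges are half-open: [0:10] selects exactly ten ports.
sel = Selector("/med/L1[0:10]")
print(f"{sel.render()!r:40s} -> {count_ports(sel)} ports")

# Bracketed lists multiply out left-major; /med/L1/0 equals /med/L1[0].
print("list expansion:", [str(i) for i in expand("/med/[L1,L2][0:2]")])
print("slash/bracket equivalence:", Selector("/med/L1/0") == Selector("/med/L1[0]"))

# String-level '+' concatenates paths (product); '.+' joins elementwise.
print("product:", combine("/med", "/L1[0]", "product").render())
print("elementwise:", Selector("/med/[L1,L2].+[0:2]").render())

# Python-level '+' pools port sets (union), as used to assemble interfaces.
interface = Selector("/a/in/gpot[0:2]") + Selector("/a/out/gpot[0:2]")
print("union of in+out:", interface.render(), "->", len(interface), "ports")

# Wildcards resolve only against a concrete universe of ports.
universe = expand("/med/L1[0:3],/med/L2[0]")
hits = expand_against("/med/L1/*", universe)
print("wildcard matches:", [str(i) for i in hits])
# The printed counts are the sizes of the denoted ordered port sets.
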