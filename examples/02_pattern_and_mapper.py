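"""The worked connectivity pattern between a 'lam' and a 'med' module.

A pattern holds two attributed interfaces (labels 0 and 1) plus sparse
directed connections.  Directions are pattern-relative: an LPU *output*
port enters the pattern as an 'in' port.  Fan-out is free; fan-in (two
sources onto one destination) is structurally rejected so that the
receiving module decides how to multiplex.
"""

from lpukit import Pattern, build_mapper
from lpukit.errors import FanInError

pat = Pattern("/lam[0:6]", "/med[0:5]")
pat["/lam[0:2]"] = (0, "in", "gpot")
pat["/lam[2]"] = (0, "out", "gpot")
pat["/lam[3:6]"] = (0, "out", "spike")
pat["/med[0:3]"] = (1, "out", "gpot")
pat["/med[3:5]"] = (1, "in", "spike")

for src, dst in [
    ("/lam[0]", "/med[0]"), ("/lam[0]", "/med[1]"), ("/lam[1]", "/med[2]"),
    ("/med[3]", "/lam[3]"), ("/med[4]", "/lam[4]"), ("/med[4]", "/lam[5]"),
]:
    pat.add_connection(src, dst)

print(f"pattern: {len(pat)} attributed ports, {pat.n_connections} connections")
print("fan-out of /lam[0]:", [str(i) for i in pat.targets_of("/lam[0]")])

try:
    pat.add_connection("/lam[1]", "/med[0]")
except FanInError as exc:
    print("fan-in rejected:", exc)

# Port mappers assign contiguous buffer indices per transmission kind.
gpot = build_mapper("/lam[0:3]", "gpot")
gpot["/lam[0:3]"] = (0.71, 0.83, 0.52)
spike = build_mapper("/lam[3:6]", "spike")
spike["/lam[3:6]"] = (1, 0, 1)
print("\ngraded-potential mapper:\n" + gpot.to_table())
print("\nspiking mapper (separate index space):\n" + spike.to_table())
# Each table row is (port identifier, buffer index, current value).
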