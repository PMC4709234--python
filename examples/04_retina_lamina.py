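"""The toy fly visual-system composition: retina -> lamina.

Builds a hexagonal retina of surrogate photoreceptors (6 per ommatidium),
a lamina of graded-potential neurons behind inhibitory conductance
synapses, links them feed-forward by a neighbor-shift stand-in for the
neural superposition wiring rule, and drives the retina with a drifting
grating.  At the full paper scale (15 rings) the array holds 721 ommatidia
and the pattern 4,326 connections; here we run 2 rings to stay instant.
"""

from lpukit.demo import build_fixture, equation_count, hex_array, run_demo

full = build_fixture(rings=15)
print(f"full scale: {len(full.array)} ommatidia, "
      f"{full.n_connections} feed-forward connections, "
      f"{full.n_lamina_neurons} lamina neurons")
eqs = equation_count(len(full.array), 6, 30_000, 15)
print(f"full photoreceptor cascade bookkeeping: {eqs:,} equations "
      f"(~{eqs / 1e9:.2f} billion; the surrogate replaces this cascade)")

record = run_demo(rings=2, duration=0.1, dt=1e-4, seed=0)
r1 = record.get("retina", "gpot", "/ret/r1/*")
l1 = record.get("lamina", "gpot", "/lam/L1/*")
print(f"\nran {record.steps} steps over {len(hex_array(2))} ommatidia")
print(f"R1 photoreceptors, final step: mean {r1[-1].mean():.2f} mV "
      f"(depolarized from -65 mV rest by light)")
print(f"L1 lamina neurons, final step: mean {l1[-1].mean():.2f} mV "
      f"(sign-inverted response through the inhibitory synapse)")
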