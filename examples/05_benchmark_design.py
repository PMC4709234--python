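"""Communication-benchmark designs: topologies and sweep grids.

These reproduce the experimental *design* of the transport benchmarks —
empty-compute modules in pair / all-to-all / decreasing-connection
topologies, and the parameter grids swept.  Timings are hardware-dependent
and carry no expected values.
"""

from lpukit.benchmarks import (
    benchmark_topology,
    lpu_sweep_grid,
    ports_sweep_grid,
    time_sync,
)
from lpukit.executor import edge_cut, partition_lpus

grid = ports_sweep_grid()
print(f"port sweep: {len(grid)} values from {grid[0]} to {grid[-1]}")
print(f"module sweep: up to {lpu_sweep_grid()[-1]} modules")

pair = benchmark_topology(2, 100, "pair")
print(f"pair topology, 100 ports each: {pair.compile_routes().route_count} routes")

a2a = benchmark_topology(4, 50, "all_to_all")
print(f"all-to-all, 4 modules: {len(a2a.compile_routes().routes)} ordered pairs")

chain = benchmark_topology(6, 20, "connectome_counts")
assignment = partition_lpus(chain, 2)
print(f"connectome-style chain on 2 workers: edge cut {edge_cut(chain, assignment)} "
      f"of {chain.compile_routes().route_count} routes")

timing = time_sync(pair, steps=50)
print(f"\npair sync timing (hardware-dependent, illustrative only): "
      f"{timing['mean_step_s'] * 1e6:.0f} us/step, "
      f"{timing['ports_per_s']:.0f} ports/s")
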