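"""Benchmark topology generators and random-plan synthesis.

These reproduce the *experimental design* of the communication benchmarks —
parameter grids and topologies of empty-hook modules — so the transport
layer can be exercised and timed.  The timings themselves are
hardware-dependent and carry no expected values.

Topologies:

* ``pair`` — two modules, each of whose output ports is wired once to the
  peer (2P directed routes for P ports each);
* ``all_to_all`` — every module's P output ports fan out to every other
  module (N*(N-1) ordered connected pairs);
* ``connectome_counts`` — a decreasing-connection sequence of up to 19
  modules emulating successive addition of brain modules, with a synthetic
  geometric-decay connection count per added module (the measured per-pair
  counts live in an external supplement and are not reproduced).

:func:`random_plan` builds small randomized emulations (random interfaces,
random wiring, seeded random-output hooks) for the transport-equivalence
and conservation property tests.
"""

from __future__ import annotations

import time

import numpy as np

from .executor import EmulationPlan
from .lpu import LPUSpec
from .pattern import Pattern

__all__ = [
    "benchmark_topology", "ports_sweep_grid", "lpu_sweep_grid",
    "random_plan", "time_sync",
]


def _empty_hook(rt, k, t, dt):
    pass


def _bench_lpu(plan: EmulationPlan, name: str, out_ports: int,
               in_selectors: list[str], out_sel: str) -> None:
    spec = LPUSpec.from_selectors(
        name,
        out_gpot=out_sel,
        in_gpot=",".join(in_selectors) if in_selectors else "",
    )
    plan.add_lpu(spec, hook=_empty_hook)


def _wire(plan: EmulationPlan, a: str, b: str, n_ab: int, n_ba: int,
          in_name_a: str, in_name_b: str, off_a: int = 0, off_b: int = 0) -> None:
    """Bidirectional pattern: first n_ab outputs of a -> inputs of b starting
    at off_b, and first n_ba outputs of b -> inputs of a starting at off_a.
    Offsets keep destination ranges disjoint across patterns (global fan-in
    prohibition); source reuse (fan-out) is free."""
    sel_a_out = f"/{a}/out[0:{n_ab}]" if n_ab else ""
    sel_b_in = f"/{b}/{in_name_b}[{off_b}:{off_b + n_ab}]" if n_ab else ""
    sel_b_out = f"/{b}/out[0:{n_ba}]" if n_ba else ""
    sel_a_in = f"/{a}/{in_name_a}[{off_a}:{off_a + n_ba}]" if n_ba else ""
    side0 = ",".join(s for s in (sel_a_out, sel_a_in) if s)
    side1 = ",".join(s for s in (sel_b_out, sel_b_in) if s)
    pat = Pattern(side0, side1)
    if n_ab:
        pat.set_attributes(sel_a_out, 0, "in", "gpot")
        pat.set_attributes(sel_b_in, 1, "out", "gpot")
    if n_ba:
        pat.set_attributes(sel_b_out, 1, "in", "gpot")
        pat.set_attributes(sel_a_in, 0, "out", "gpot")
    for i in range(n_ab):
        pat.add_connection(f"/{a}/out[{i}]", f"/{b}/{in_name_b}[{off_b + i}]")
    for i in range(n_ba):
        pat.add_connection(f"/{b}/out[{i}]", f"/{a}/{in_name_a}[{off_a + i}]")
    plan.connect(a, b, pat, 0, 1)


def benchmark_topology(
    num_lpus: int, ports_per_lpu: int, topology: str = "pair",
    dt: float = 1e-4, decay: float = 0.7, base_connections: int = 512,
) -> EmulationPlan:
    """An emulation plan of empty-hook modules in the named topology."""
    if num_lpus < 2:
        raise ValueError("num_lpus must be >= 2")
    if ports_per_lpu < 1:
        raise ValueError("ports_per_lpu must be >= 1")
    plan = EmulationPlan(dt=dt)
    names = [f"bm{i}" for i in range(num_lpus)]
    if topology == "pair":
        if num_lpus != 2:
            raise ValueError("pair topology requires exactly 2 LPUs")
        p = ports_per_lpu
        for name in names:
            _bench_lpu(plan, name, p, [f"/{name}/in[0:{p}]"], f"/{name}/out[0:{p}]")
        _wire(plan, names[0], names[1], p, p, "in", "in")
        return plan
    if topology == "all_to_all":
        p = ports_per_lpu
        for i, name in enumerate(names):
            ins = [f"/{name}/in{j}[0:{p}]" for j in range(num_lpus) if j != i]
            _bench_lpu(plan, name, p, ins, f"/{name}/out[0:{p}]")
        for i in range(num_lpus):
            for j in range(i + 1, num_lpus):
                a, b = names[i], names[j]
                pat = Pattern(
                    f"/{a}/out[0:{p}],/{a}/in{j}[0:{p}]",
                    f"/{b}/out[0:{p}],/{b}/in{i}[0:{p}]",
                )
                pat.set_attributes(f"/{a}/out[0:{p}]", 0, "in", "gpot")
                pat.set_attributes(f"/{a}/in{j}[0:{p}]", 0, "out", "gpot")
                pat.set_attributes(f"/{b}/out[0:{p}]", 1, "in", "gpot")
                pat.set_attributes(f"/{b}/in{i}[0:{p}]", 1, "out", "gpot")
                for k in range(p):
                    pat.add_connection(f"/{a}/out[{k}]", f"/{b}/in{i}[{k}]")
                    pat.add_connection(f"/{b}/out[{k}]", f"/{a}/in{j}[{k}]")
                plan.connect(a, b, pat, 0, 1)
        return plan
    if topology == "connectome_counts":
        if num_lpus > 19:
            raise ValueError("connectome_counts covers at most 19 LPUs")
        counts = [
            max(1, int(round(base_connections * decay**k)))
            for k in range(num_lpus - 1)
        ]
        # LPU k needs input room for its incoming patterns (from k-1 and k+1)
        in_size = [0] * num_lpus
        for k, c in enumerate(counts):
            in_size[k] += c
            in_size[k + 1] += c
        maxc = counts[0]
        for i, name in enumerate(names):
            _bench_lpu(
                plan, name, maxc,
                [f"/{name}/in[0:{in_size[i]}]"], f"/{name}/out[0:{maxc}]",
            )
        # LPU k+1 joins by connecting to LPU k with a decaying count; its
        # inputs from k occupy [0:c], while k's inputs from k+1 sit after
        # any range already fed by k-1
        for k, c in enumerate(counts):
            off_a = counts[k - 1] if k > 0 else 0
            _wire(plan, names[k], names[k + 1], c, c, "in", "in",
                  off_a=off_a, off_b=0)
        return plan
    raise ValueError(f"unknown topology {topology!r}")


def ports_sweep_grid() -> list[int]:
    """25 equally spaced output-port counts between 50 and 15,000."""
    return [int(round(v)) for v in np.linspace(50, 15_000, 25)]


def lpu_sweep_grid(max_lpus: int = 19, start: int = 2) -> list[int]:
    """Module counts for the growing-emulation sweep."""
    return list(range(start, max_lpus + 1))


def time_sync(plan: EmulationPlan, steps: int = 50, backend: str = "serial",
              workers: int = 1) -> dict:
    """Wall-clock timing of a run; hardware-dependent, for reporting only."""
    routes = plan.compile_routes()
    start = time.perf_counter()
    plan.run(steps=steps, backend=backend, workers=workers)
    elapsed = time.perf_counter() - start
    per_step = elapsed / max(steps, 1)
    return {
        "steps": steps,
        "routes": routes.route_count,
        "total_s": elapsed,
        "mean_step_s": per_step,
        "ports_per_s": routes.route_count / per_step if per_step > 0 else float("nan"),
    }


# ---------------------------------------------------------------------------
# randomized plans for property tests

def _random_output_hook(seed: int):
    rng = np.random.default_rng(seed)

    def hook(rt, k, t, dt):
        if len(rt.out_gpot_ports):
            rt.pm["gpot"][rt.out_gpot_ports] = rng.random(len(rt.out_gpot_ports))
        if len(rt.out_spike_ports):
            rt.pm["spike"][rt.out_spike_ports] = rng.integers(
                0, 2, len(rt.out_spike_ports)
            )

    return hook


def _echo_hook(rt, k, t, dt):
    n = min(len(rt.in_gpot_ports), len(rt.out_gpot_ports))
    if n:
        ins = rt.pm["gpot"][rt.in_gpot_ports]
        outs = list(rt.out_gpot_ports)[:n]
        rt.pm["gpot"].set_values(outs, ins[:n])


def random_plan(seed: int, max_lpus: int = 4, max_ports: int = 6,
                dt: float = 1e-3) -> EmulationPlan:
    """A small random emulation: random interfaces, random fan-in-free
    wiring, and per-LPU seeded random-output or echo hooks.  Rebuilding with
    the same seed yields an identical plan."""
    rng = np.random.default_rng(seed)
    n_lpus = int(rng.integers(2, max_lpus + 1))
    plan = EmulationPlan(dt=dt)
    names = [f"r{i}" for i in range(n_lpus)]
    for i, name in enumerate(names):
        ng_out = int(rng.integers(1, max_ports + 1))
        ns_out = int(rng.integers(0, max_ports + 1))
        ng_in = int(rng.integers(1, max_ports + 1))
        ns_in = int(rng.integers(0, max_ports + 1))
        spec = LPUSpec.from_selectors(
            name,
            out_gpot=f"/{name}/og[0:{ng_out}]",
            in_gpot=f"/{name}/ig[0:{ng_in}]",
            out_spike=f"/{name}/os[0:{ns_out}]" if ns_out else "",
            in_spike=f"/{name}/is[0:{ns_in}]" if ns_in else "",
        )
        hook = (
            _echo_hook if rng.random() < 0.3 else _random_output_hook(seed * 1000 + i)
        )
        plan.add_lpu(spec, hook=hook)
    # wire random ordered pairs without violating the global fan-in rule
    fed: set[tuple[str, str, str]] = set()
    used_pairs: set[tuple[str, str]] = set()
    n_pairs = int(rng.integers(1, n_lpus + 2))
    for _ in range(n_pairs):
        i, j = rng.choice(n_lpus, size=2, replace=False)
        a, b = names[int(i)], names[int(j)]
        if (a, b) in used_pairs:
            continue
        used_pairs.add((a, b))
        sides = {0: set(), 1: set()}
        conns = []
        for kind, out_name, in_name in (("gpot", "og", "ig"), ("spike", "os", "is")):
            outs = [
                d.identifier for d in plan.lpus[a].spec.interface
                if d.io == "out" and d.transmission == kind
            ]
            ins = [
                d.identifier for d in plan.lpus[b].spec.interface
                if d.io == "in" and d.transmission == kind
                and (b, kind, str(d.identifier)) not in fed
            ]
            if not outs or not ins:
                continue
            take = int(rng.integers(1, len(ins) + 1))
            chosen = [ins[int(x)] for x in rng.choice(len(ins), take, replace=False)]
            for dst in chosen:
                src = outs[int(rng.integers(0, len(outs)))]
                sides[0].add((src, kind, "in"))
                sides[1].add((dst, kind, "out"))
                conns.append((src, dst))
                fed.add((b, kind, str(dst)))
        if not conns:
            continue
        from .selectors import Selector

        pat = Pattern(
            Selector.from_identifiers(sorted({s for s, _, _ in sides[0]}, key=str)),
            Selector.from_identifiers(sorted({s for s, _, _ in sides[1]}, key=str)),
        )
        for label in (0, 1):
            for ident, kind, io in sides[label]:
                pat.set_attributes([ident], label, io, kind)
        for src, dst in conns:
            pat.add_connection(src, dst)
        plan.connect(a, b, pat, 0, 1)
    return plan
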