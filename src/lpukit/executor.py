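"""Control plane: register LPUs, bind patterns, compile routes, run.

An :class:`EmulationPlan` collects LPU runtimes and pattern bindings,
compiles them into a sparse :class:`RoutingTable` of (source buffer index,
destination buffer index) pairs per (source LPU, destination LPU, kind),
and executes the bulk-synchronous loop: every LPU steps once, then all
output-port data crosses its patterns to the destination input buffers
before any LPU begins the next step.  Information therefore crosses exactly
one pattern per step, and step-0 inputs are the zero-initialized buffers.

Two transports satisfy the barrier contract:

* ``serial`` — the in-process reference backend; LPUs step in registration
  order, which the barrier makes unobservable;
* ``process`` — LPUs are partitioned across worker processes (POSIX fork)
  that exchange buffers with the coordinator at each barrier.  Routing only
  copies values, so both transports produce bitwise-identical buffers.

The greedy partitioner assigns LPUs to workers by local-search edge-cut
reduction, standing in for heavyweight graph partitioners at desk scale.
"""

from __future__ import annotations

import multiprocessing
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DuplicateIdError,
    IncompatibilityError,
    RoutingError,
    ValidationError,
)
from .lpu import LPURuntime, LPUSpec, attach_mappers, validate_spec
from .pattern import Pattern
from .selectors import Selector

__all__ = [
    "EmulationPlan", "RoutingTable", "ExecutionRecord",
    "add_lpu", "connect", "compile_routes", "run",
    "partition_lpus", "edge_cut",
]


@dataclass(frozen=True)
class Binding:
    id0: str
    id1: str
    pattern: Pattern
    label0: int
    label1: int

    def owner_of_label(self, label: int) -> str:
        if label == self.label0:
            return self.id0
        if label == self.label1:
            return self.id1
        raise ValueError(f"binding has no interface label {label}")


class RoutingTable:
    """Per (source LPU, destination LPU, kind): parallel index arrays."""

    def __init__(self):
        self.routes: dict[tuple[str, str, str], tuple[np.ndarray, np.ndarray]] = {}

    @property
    def route_count(self) -> int:
        return sum(len(si) for si, _ in self.routes.values())

    def items(self):
        return self.routes.items()


@dataclass
class ExecutionRecord:
    """Post-barrier buffer snapshots: ``buffers[(lpu, kind)][t]`` is the
    buffer state after step ``t``'s exchange (i.e. the inputs step ``t+1``
    will see, and the outputs step ``t`` produced)."""

    steps: int
    dt: float
    buffers: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    orders: dict[tuple[str, str], tuple] = field(default_factory=dict)

    def get(self, lpu_id: str, kind: str, sel=None) -> np.ndarray:
        data = self.buffers[(lpu_id, kind)]
        if sel is None:
            return data
        order = self.orders[(lpu_id, kind)]
        sel = Selector.coerce(sel)
        idents = (
            sel.expand_against(order) if sel.has_wildcard else sel.expand()
        )
        index = {ident: i for i, ident in enumerate(order)}
        cols = [index[i] for i in idents]
        return data[:, cols]


class EmulationPlan:
    """LPU set + pattern bindings + compiled routes + clock."""

    def __init__(self, dt: float = 1e-4):
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.dt = dt
        self.lpus: dict[str, LPURuntime] = {}
        self.bindings: list[Binding] = []
        self._routes: RoutingTable | None = None

    # -- construction --------------------------------------------------------

    def add_lpu(self, spec: LPUSpec, hook=None, **runtime_kwargs) -> "EmulationPlan":
        if spec.id in self.lpus:
            raise DuplicateIdError(f"LPU id {spec.id!r} already registered")
        report = validate_spec(spec)
        if not report.ok:
            raise ValidationError(report)
        self.lpus[spec.id] = attach_mappers(spec, hook, **runtime_kwargs)
        self._routes = None
        return self

    def connect(
        self, id0: str, id1: str, pattern: Pattern, label0: int = 0, label1: int = 1
    ) -> "EmulationPlan":
        for lpu_id in (id0, id1):
            if lpu_id not in self.lpus:
                raise KeyError(f"LPU {lpu_id!r} is not registered")
        rep0 = pattern.check_compatibility(label0, self.lpus[id0].spec)
        rep1 = pattern.check_compatibility(label1, self.lpus[id1].spec)
        if not (rep0.compatible and rep1.compatible):
            raise IncompatibilityError(rep0, rep1)
        for b in self.bindings:
            if (b.id0, b.id1, b.label0, b.label1) == (id0, id1, label0, label1):
                raise DuplicateIdError(
                    f"a pattern is already bound for ({id0!r}, {id1!r}) with "
                    f"labels ({label0}, {label1})"
                )
        self.bindings.append(Binding(id0, id1, pattern, label0, label1))
        self._routes = None
        return self

    # -- routing -------------------------------------------------------------

    def compile_routes(self) -> RoutingTable:
        if self._routes is not None:
            return self._routes
        table = RoutingTable()
        raw: dict[tuple[str, str, str], list[tuple[int, int]]] = {}
        used_dst: set[tuple[str, str, int]] = set()
        for b in self.bindings:
            for src_ident, dst_ident in b.pattern.connections:
                src_attrs = b.pattern.port(src_ident)
                dst_attrs = b.pattern.port(dst_ident)
                kind = src_attrs.transmission
                src_lpu = b.owner_of_label(src_attrs.interface)
                dst_lpu = b.owner_of_label(dst_attrs.interface)
                si = int(self.lpus[src_lpu].pm[kind].indices([src_ident])[0])
                di = int(self.lpus[dst_lpu].pm[kind].indices([dst_ident])[0])
                dst_key = (dst_lpu, kind, di)
                if dst_key in used_dst:
                    raise RoutingError(
                        f"input {dst_ident} of LPU {dst_lpu!r} is fed by more "
                        "than one pattern connection (global fan-in prohibition)"
                    )
                used_dst.add(dst_key)
                raw.setdefault((src_lpu, dst_lpu, kind), []).append((si, di))
        for key, pairs in raw.items():
            si = np.array([p[0] for p in pairs], dtype=np.intp)
            di = np.array([p[1] for p in pairs], dtype=np.intp)
            table.routes[key] = (si, di)
        self._routes = table
        return table

    # -- execution -----------------------------------------------------------

    def run(
        self,
        steps: int | None = None,
        duration: float | None = None,
        backend: str = "serial",
        workers: int = 1,
        record: bool = False,
        assignment: dict[str, int] | None = None,
    ) -> ExecutionRecord:
        if steps is None:
            if duration is None:
                raise ValueError("give either steps or duration")
            steps = int(duration / self.dt)
        routes = self.compile_routes()
        if backend == "serial":
            return _run_serial(self, routes, steps, record)
        if backend == "process":
            return _run_process(self, routes, steps, workers, record, assignment)
        raise ValueError(f"unknown backend {backend!r}")

    def partition(self, workers: int) -> dict[str, int]:
        return partition_lpus(self, workers)


# -- functional interface ----------------------------------------------------

def add_lpu(plan: EmulationPlan, spec: LPUSpec, hook=None, **kw) -> EmulationPlan:
    return plan.add_lpu(spec, hook, **kw)


def connect(plan, id0, id1, pattern, label0=0, label1=1) -> EmulationPlan:
    return plan.connect(id0, id1, pattern, label0, label1)


def compile_routes(plan: EmulationPlan) -> RoutingTable:
    return plan.compile_routes()


def run(plan: EmulationPlan, steps=None, **kw) -> ExecutionRecord:
    return plan.run(steps=steps, **kw)


# -- serial backend ----------------------------------------------------------

def _new_record(plan: EmulationPlan, steps: int) -> ExecutionRecord:
    rec = ExecutionRecord(steps=steps, dt=plan.dt)
    for lpu_id, rt in plan.lpus.items():
        for kind in ("gpot", "spike"):
            pm = rt.pm[kind]
            rec.buffers[(lpu_id, kind)] = np.zeros(
                (steps, len(pm)), dtype=pm.buffer.dtype
            )
            rec.orders[(lpu_id, kind)] = pm.order
    return rec


def _run_serial(plan, routes, steps, record) -> ExecutionRecord:
    rec = _new_record(plan, steps) if record else ExecutionRecord(steps, plan.dt)
    lpus = plan.lpus
    for t in range(steps):
        for rt in lpus.values():
            rt.step(t, plan.dt)
        # barrier: read all sources first, then write all destinations, so a
        # self-connection cannot observe a partially synced buffer
        moves = [
            (dst, kind, di, lpus[src].pm[kind].buffer[si].copy())
            for (src, dst, kind), (si, di) in routes.items()
        ]
        for dst, kind, di, vals in moves:
            lpus[dst].pm[kind].buffer[di] = vals
        if record:
            for lpu_id, rt in lpus.items():
                for kind in ("gpot", "spike"):
                    rec.buffers[(lpu_id, kind)][t] = rt.pm[kind].buffer
    return rec


# -- process backend ---------------------------------------------------------

def _worker_loop(conn, runtimes: dict[str, LPURuntime], steps: int, dt: float):
    try:
        for t in range(steps):
            for lpu_id, kind, di, vals in conn.recv():
                runtimes[lpu_id].pm[kind].buffer[di] = vals
            for rt in runtimes.values():
                rt.step(t, dt)
            conn.send(
                {
                    (lpu_id, kind): rt.pm[kind].buffer.copy()
                    for lpu_id, rt in runtimes.items()
                    for kind in ("gpot", "spike")
                }
            )
    except (EOFError, BrokenPipeError):
        pass
    finally:
        conn.close()


def _run_process(plan, routes, steps, workers, record, assignment) -> ExecutionRecord:
    if assignment is None:
        assignment = partition_lpus(plan, workers)
    groups: dict[int, list[str]] = {}
    for lpu_id, w in assignment.items():
        groups.setdefault(w, []).append(lpu_id)
    ctx = multiprocessing.get_context("fork")
    procs, conns, owner = [], {}, {}
    for w, ids in groups.items():
        parent_conn, child_conn = ctx.Pipe()
        p = ctx.Process(
            target=_worker_loop,
            args=(child_conn, {i: plan.lpus[i] for i in ids}, steps, plan.dt),
        )
        p.start()
        child_conn.close()
        procs.append(p)
        conns[w] = parent_conn
        for i in ids:
            owner[i] = w
    rec = _new_record(plan, steps) if record else ExecutionRecord(steps, plan.dt)
    try:
        staged: dict[int, list] = {w: [] for w in groups}
        for t in range(steps):
            for w, conn in conns.items():
                conn.send(staged[w])
            outbufs: dict[tuple[str, str], np.ndarray] = {}
            for conn in conns.values():
                outbufs.update(conn.recv())
            staged = {w: [] for w in groups}
            for (src, dst, kind), (si, di) in routes.items():
                vals = outbufs[(src, kind)][si]
                staged[owner[dst]].append((dst, kind, di, vals))
                # mirror the sync into the coordinator's snapshot copy
                outbufs[(dst, kind)][di] = vals
            if record:
                for key, buf in outbufs.items():
                    rec.buffers[key][t] = buf
        for conn in conns.values():
            conn.close()
    finally:
        for p in procs:
            p.join(timeout=30)
            if p.is_alive():
                p.terminate()
    return rec


# -- partitioning ------------------------------------------------------------

def _pair_weights(plan: EmulationPlan) -> dict[tuple[str, str], int]:
    weights: dict[tuple[str, str], int] = {}
    for b in plan.bindings:
        if b.id0 == b.id1:
            continue
        key = tuple(sorted((b.id0, b.id1)))
        weights[key] = weights.get(key, 0) + b.pattern.n_connections
    return weights


def edge_cut(plan: EmulationPlan, assignment: dict[str, int]) -> int:
    """Total connections crossing worker boundaries under ``assignment``."""
    return sum(
        w
        for (a, b), w in _pair_weights(plan).items()
        if assignment[a] != assignment[b]
    )


def partition_lpus(plan: EmulationPlan, workers: int) -> dict[str, int]:
    """Greedy local search reducing the edge cut under a balance constraint
    (at most ceil(n/workers) LPUs per worker), starting from a round-robin
    assignment in registration order.  Alternates single-move and pairwise
    swap passes, Kernighan-Lin style."""
    if workers < 1:
        raise ValueError("workers must be >= 1")
    ids = list(plan.lpus)
    assignment = {lpu_id: i % workers for i, lpu_id in enumerate(ids)}
    if workers == 1 or len(ids) <= 1:
        return assignment
    capacity = -(-len(ids) // workers)
    load = {w: 0 for w in range(workers)}
    for w in assignment.values():
        load[w] += 1
    weights = _pair_weights(plan)
    neighbors: dict[str, list[tuple[str, int]]] = {i: [] for i in ids}
    for (a, b), w in weights.items():
        neighbors[a].append((b, w))
        neighbors[b].append((a, w))

    def external_weight(lpu_id: str, worker: int, skip: str | None = None) -> int:
        return sum(
            w8
            for other, w8 in neighbors[lpu_id]
            if other != skip and assignment[other] != worker
        )

    for _ in range(20):
        improved = False
        for lpu_id in ids:  # single moves within capacity
            here = assignment[lpu_id]
            best, best_cost = here, external_weight(lpu_id, here)
            for w in range(workers):
                if w == here or load[w] >= capacity:
                    continue
                cost = external_weight(lpu_id, w)
                if cost < best_cost:
                    best, best_cost = w, cost
            if best != here:
                assignment[lpu_id] = best
                load[here] -= 1
                load[best] += 1
                improved = True
        for i, a in enumerate(ids):  # capacity-neutral swaps
            for b in ids[i + 1:]:
                wa, wb = assignment[a], assignment[b]
                if wa == wb:
                    continue
                # the (a, b) edge stays cut either way; compare the rest
                before = external_weight(a, wa, skip=b) + external_weight(b, wb, skip=a)
                after = external_weight(a, wb, skip=b) + external_weight(b, wa, skip=a)
                if after < before:
                    assignment[a], assignment[b] = wb, wa
                    improved = True
        if not improved:
            break
    return assignment
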