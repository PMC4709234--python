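"""Interpreter for declarative component graphs.

The engine executes an :class:`~lpukit.lpu.LPUSpec`'s internal component
graph one emulation step at a time, as the step hook of the owning runtime.
Update semantics are synchronous within the module: every component reads
the outputs its neighbors produced on the *previous* step, so evaluation
order is unobservable and the step is a pure function of (state, inputs).

Drive routing per component kind:

* neuron-kind components sum the ``current`` outputs of their predecessors,
  plus any bound input-port values and external stimulus;
* synapse-kind components read one presynaptic value from their single
  predecessor (spike flag or graded potential per the registry entry) or
  from a bound input port, and see the previous membrane potential of
  their single successor as ``v_post``.

Output ports deliver the bound component's graded value (``gpot`` ports)
or spike flag (``spike`` ports).  Stimulus is a mapping from component id
to either a per-step callable ``f(step_index) -> value`` or an indexable
sequence of per-step values.
"""

from __future__ import annotations

import numpy as np

from .models import default_registry

__all__ = ["CircuitEngine"]


class CircuitEngine:
    """Step hook interpreting a component graph via the model registry."""

    def __init__(self, spec, registry=None, stimulus=None, seed: int | None = None):
        self.spec = spec
        registry = registry or default_registry()
        self.stimulus = stimulus or {}
        g = spec.components
        self.order = list(g.nodes)  # insertion order: deterministic
        self.entries = {}
        self.params = {}
        self.state = {}
        self.rngs = {}
        self.preds = {}
        self.post_neuron = {}
        for idx, node in enumerate(self.order):
            attrs = g.nodes[node]
            if "model" not in attrs:
                raise ValueError(f"component {node!r} has no model attribute")
            entry = registry.get(attrs["model"])
            params = dict(entry.defaults)
            params.update(
                {
                    k: v
                    for k, v in attrs.items()
                    if k != "model" and isinstance(v, (int, float)) and not isinstance(v, bool)
                }
            )
            self.entries[node] = entry
            self.params[node] = params
            rng = np.random.default_rng(
                None if seed is None else [int(seed) % (2**31), idx]
            )
            self.rngs[node] = rng
            self.state[node] = entry.make_state(params, rng)
            self.preds[node] = list(g.predecessors(node))
            if entry.kind == "synapse":
                succs = list(g.successors(node))
                if len(self.preds[node]) > 1:
                    raise ValueError(
                        f"synapse {node!r} has {len(self.preds[node])} "
                        "presynaptic components; at most one is allowed"
                    )
                self.post_neuron[node] = succs[0] if succs else None
        # bindings grouped by direction for fast per-step access
        iface = spec.interface_map
        self.in_bindings = []  # (kind, identifier, component)
        self.out_bindings = []
        for ident, comp in spec.port_bindings.items():
            io, kind = iface[ident]
            (self.in_bindings if io == "in" else self.out_bindings).append(
                (kind, ident, comp)
            )
        self._port_idx_cache = None
        # seed component outputs with initial potentials so step-0 neighbors
        # see resting values rather than zeros
        self.out = {
            node: {
                "gpot": float(getattr(self.state[node], "v", 0.0)),
                "spike": 0,
                "current": 0.0,
            }
            for node in self.order
        }

    def _port_indices(self, runtime):
        if self._port_idx_cache is None:
            self._port_idx_cache = (
                [
                    (kind, int(runtime.pm[kind].indices([ident])[0]), comp)
                    for kind, ident, comp in self.in_bindings
                ],
                [
                    (kind, int(runtime.pm[kind].indices([ident])[0]), comp)
                    for kind, ident, comp in self.out_bindings
                ],
            )
        return self._port_idx_cache

    def _stimulus_value(self, node, step_index) -> float:
        stim = self.stimulus.get(node)
        if stim is None:
            return 0.0
        if callable(stim):
            return float(stim(step_index))
        return float(stim[step_index])

    def __call__(self, runtime, step_index, t, dt):
        in_idx, out_idx = self._port_indices(runtime)
        port_drive: dict[str, float] = {}
        for kind, idx, comp in in_idx:
            port_drive[comp] = port_drive.get(comp, 0.0) + float(
                runtime.pm[kind].buffer[idx]
            )
        prev = self.out
        new_out = {}
        for node in self.order:
            entry = self.entries[node]
            if entry.kind == "synapse":
                if self.preds[node]:
                    src = self.preds[node][0]
                    drive = prev[src]["spike" if entry.presyn == "spike" else "gpot"]
                else:
                    drive = port_drive.get(node, 0.0)
                post = self.post_neuron.get(node)
                v_post = prev[post]["gpot"] if post is not None else 0.0
            else:
                drive = sum(prev[p]["current"] for p in self.preds[node])
                drive += port_drive.get(node, 0.0)
                drive += self._stimulus_value(node, step_index)
                v_post = 0.0
            self.state[node], new_out[node] = entry.step(
                self.state[node], drive, self.params[node], dt,
                self.rngs[node], v_post,
            )
        self.out = new_out
        for kind, idx, comp in out_idx:
            runtime.pm[kind].buffer[idx] = new_out[comp][
                "gpot" if kind == "gpot" else "spike"
            ]
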