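# Methods

## The programming model

`lpukit` emulates networks of circuit modules called LPUs (local processing
units — the functional units of small brains, e.g. the neuropils of the
fly). The model enforces a strict separation between what a module
computes and how it communicates:

* **Interface.** Each module exposes communication ports only. A port has
  exactly one direction (`in`/`out`, module-relative) and one transmission
  kind: `spike` (boolean per step) or `gpot` (graded potential, a real per
  step). Ports are named by hierarchical path-like identifiers and
  addressed by selectors (grammar in `selector-grammar.md`).
* **Pattern.** Connections between two modules live in a `Pattern`: two
  attributed interfaces (labels 0/1) plus a sparse directed connection
  set. Pattern port directions are *pattern-relative* — a module's output
  port is a pattern `in` port, because the module's output flows *into*
  the pattern. This is easy to misread and is asserted throughout the
  test suite. Endpoints must lie on opposite interfaces and carry equal
  transmission kinds. Every destination has in-degree ≤ 1: multiplexing
  of several sources is the receiving module's business, so fan-in is
  structurally rejected while fan-out is free. Connections are
  presence-only; synapse models belong inside modules, never on pattern
  edges. One pattern may carry traffic in both directions.
* **Execution.** An `EmulationPlan` validates every pattern/module binding
  (identifier, kind, and direction compatibility), compiles all patterns
  into a routing table of (source buffer index → destination buffer index)
  pairs per (source module, destination module, kind), and runs a
  bulk-synchronous loop: all modules step once, then all output-port data
  crosses its patterns at a barrier before any module starts the next
  step. Consequences asserted by tests: information crosses exactly one
  pattern per step (a chain of L patterns has latency L), step-0 inputs
  are the zero-initialized buffers, and unconnected inputs read zero
  forever. Self-connections (a module wired to itself over disjoint port
  subsets) are delivered with the same one-step latency.

Port buffers are host `numpy` arrays behind the `PortDataMap` contract
(`gpot` as float64, `spike` as int32 restricted to {0, 1}); buffer
residency is a backend concern, not part of the semantics. Index order
equals the defining selector's expansion order — for a module, the
interface declaration order — and is stable for a run.

## Transports

Two backends satisfy the barrier contract and are required (and tested,
over randomized plans) to produce **bitwise identical** buffers:

* `serial`: in-process; modules step in registration order, which the
  barrier makes unobservable.
* `process`: modules are partitioned across POSIX-fork worker processes;
  a coordinator exchanges buffers with workers at each barrier
  (hub-and-spoke). Routing only copies IEEE-754 values, so equality is
  exact. The fork start method means hooks need not be picklable;
  the backend is POSIX-only.

Worker assignment uses a greedy Kernighan–Lin-style local search (single
moves within a ceil(n/workers) balance cap, then capacity-neutral swaps,
≤ 20 passes) that reduces the inter-worker connection count from a
round-robin start. It stands in for heavyweight graph partitioners at
desk scale; it is a heuristic and only guaranteed not to be worse than
round-robin.

## Compute plane

Models are pure step functions `(state, input, params, dt) → (state',
output)` registered by name; declarative circuits (GEXF property graphs)
instantiate them through the registry, and plugins are added with
`register_model`. Built-ins (potentials in mV, `dt` in seconds at the API
boundary):

| model | state | key defaults |
|---|---|---|
| `LeakyIAF` | V | τ = 20 ms, R = 1 mV/µA, V_rest = V_reset = −65, V_th = −55 |
| `MorrisLecar` | V, n ∈ [0,1] | classic excitable set: C = 20 µF/cm², g_L/g_Ca/g_K = 2/4.4/8 mS/cm², φ = 0.04 /ms |
| `HodgkinHuxley` | V, m, h, n | canonical squid-axon rates, g_Na/g_K/g_L = 120/36/0.3, E_L = −54.387 |
| `AlphaSynapse` | x, g | τ = 5 ms, kernel ∝ t·e^(−t/τ) |
| `ConductanceSynapse` | g ≥ 0 | σ((V_pre+50)/5) activation, τ = 5 ms, E_rev = −80 (inhibitory below rest) |
| `PhotoreceptorSurrogate` | V | gain = 10 mV per log-intensity unit, τ = 20 ms, optional Poisson shot noise |

Only the model *names* are fixed by the platform contract; the equations
are the canonical textbook formulations, chosen here with standard
parameterizations (Rinzel–Ermentrout for Morris–Lecar, the modern-units
squid axon for Hodgkin–Huxley). Morris–Lecar runs in its graded-output
configuration: the emitted value is the membrane potential with no
thresholding, matching its use for non-spiking neurons.

Numerical choices: explicit Euler at the emulation `dt`, with optional
internal sub-stepping (`substeps`) since a module may compute at finer
resolution as long as outputs are final at the end of its step. Gating and
recovery variables are clamped to [0, 1] (the continuous dynamics keep the
invariant; the clamp guards Euler overshoot). The Hodgkin–Huxley step
enforces a documented stability bound of 0.05 ms per internal step and
refuses coarser steps rather than silently diverging. The alpha synapse
uses the exact exponential update of its linear kinetics, so its discrete
impulse response is exactly (m·dt/τ)e^(−m·dt/τ) and peaks within one `dt`
of τ. Spike semantics: at most one spike per module step per neuron
(upward crossing of 0 mV for Hodgkin–Huxley; threshold-and-reset for the
leaky integrator).

Analytic anchors tested: the leaky integrator's interspike interval
matches τ·ln(RI/(RI − V_th + V_rest)) within 1% at dt = 10 µs; the
Morris–Lecar resting equilibrium (found by root-finding the voltage
nullcline with n on its steady-state curve) is stationary under
integration; halving `dt` halves the trajectory error (first order).

The declarative-circuit interpreter updates all components synchronously:
every component reads neighbor outputs from the *previous* step, making
the step order unobservable and each step a pure function of (state,
inputs, seed). Per-component RNG streams are derived from (seed, node
index) so results are independent of process layout. A neuron-kind
component sums its presynaptic current contributions plus bound input
ports and stimulus; a synapse-kind component reads one presynaptic value
(spike or graded per its registry entry) and the previous potential of its
single target.

## The retina/lamina composition

The demo fixture emulates the fly's early visual system at toy fidelity:

* **Retina**: a centered hexagonal array of ommatidia (count
  1 + 3·r·(r+1); r = 15 gives the full-scale 721) with six surrogate
  photoreceptors each, every one exposing a `gpot` output port.
* **Lamina**: one retinotopic cartridge per ommatidium; each of its six
  input ports drives an inhibitory conductance synapse onto one of the
  cartridge's Morris–Lecar neurons (L1, L2 exposed as outputs).
* **Wiring**: one feed-forward connection per photoreceptor —
  721 × 6 = 4,326 at full scale. The anatomical neural-superposition rule
  (photoreceptors of neighboring ommatidia viewing the same point converge
  on one cartridge) is replaced by a deterministic stand-in: for
  photoreceptor position p, a lattice translation along the p-th hex
  direction, completed to a bijection by assigning boundary leftovers in
  index order. It preserves the structural properties that matter here
  (a permutation per position; interior elements map to true neighbors)
  and none of the anatomy.

The surrogate photoreceptor (log-intensity transduction → first-order
low-pass, optional shot noise) replaces a stochastic microvilli cascade of
30,000 microvilli × 15 equations per photoreceptor; the fixture keeps that
arithmetic as explicit bookkeeping (721 × 6 × 30,000 × 15 ≈ 1.95 × 10⁹
equations) without claiming any biophysical fidelity. What the passing
demo tests show is therefore *architectural*: compatibility checking,
routing, latency, and the sign inversion of the lamina response under an
inhibitory synapse — not a validated model of fly vision. Video input is
sampled at hex centers by nearest pixel, frames spread uniformly over the
run.

Default demo problem sizes: rings = 2 (19 ommatidia), 0.1 s at dt = 0.1 ms.
The full-scale fixture (r = 15) is built in well under a second for the
counting checks; the interpreter demo is run at reduced rings, a package
default chosen to keep the example instant on a laptop.

## Benchmark harness

The communication benchmarks reproduce the *experimental design* only:
empty-compute modules in `pair`, `all_to_all`, and `connectome_counts`
topologies, a 25-point port sweep over [50, 15,000], and module sweeps up
to 19. The decreasing per-module connection counts of the real
19-module composition live in an external supplement, so
`connectome_counts` substitutes a geometric decay (512·0.7^k, floor 1),
labelled synthetic. Timings are hardware-dependent and are reported with
an explicit banner; no expected values are attached to them.

## Known limitations

* Inter-module connections are static for the lifetime of a run; no
  dynamic rewiring.
* Spike transport is dense per-step 0/1 sampling; no event/timestamped
  representation, and every port is sampled at every step.
* The process backend is fork-based (POSIX only) and exchanges full
  buffers through the coordinator; it demonstrates the barrier contract,
  not transport performance.
* The surrogate photoreceptor and the superposition stand-in are
  structural placeholders, as described above.
* GEXF attribute vocabulary (`model`, `port`, `io`, `transmission`, flat
  numeric params) is self-defined and versioned with this package; no
  external schema is implemented.
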