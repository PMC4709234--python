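"""Toy fly early-visual-system composition: retina and lamina modules.

The retina module is a centered hexagonal array of ommatidia (facet units
of the compound eye), each containing six photoreceptors modeled by the
surrogate photoreceptor of the compute plane.  The lamina module holds one
retinotopic cartridge per ommatidium, each with graded-potential
(Morris-Lecar) neurons driven through inhibitory conductance synapses.
The two modules are linked by one feed-forward pattern connection per
photoreceptor output port, wired by a deterministic neighbor-shift
permutation per photoreceptor position that stands in for the anatomical
neural-superposition rule (photoreceptors of neighboring ommatidia viewing
the same point converge onto one cartridge).

At the default ring radius of 15 the array holds 1 + 3*15*16 = 721
ommatidia, 721 x 6 = 4,326 photoreceptors and feed-forward connections,
and a 4,326-neuron lamina.  :func:`equation_count` keeps the bookkeeping
for the full stochastic photoreceptor cascade the surrogate replaces
(30,000 microvilli per photoreceptor at 15 equations each puts the full
retina near 1.95 billion equations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .executor import EmulationPlan, ExecutionRecord
from .lpu import LPUSpec, PortDecl
from .pattern import Pattern
from .selectors import PortIdentifier

__all__ = [
    "HexArray", "RetinaLaminaFixture",
    "hex_array", "build_fixture", "equation_count", "run_demo",
    "PHOTORECEPTORS_PER_OMMATIDIUM",
]

PHOTORECEPTORS_PER_OMMATIDIUM = 6

#: axial-coordinate steps for the six hex directions, in the order used to
#: walk each ring (and to shift each photoreceptor position's wiring)
_HEX_DIRECTIONS = [(1, 0), (1, -1), (0, -1), (-1, 0), (-1, 1), (0, 1)]


@dataclass(frozen=True)
class HexArray:
    """Centered hexagonal lattice: center plus ``rings`` concentric rings."""

    rings: int
    elements: tuple[tuple[int, int], ...]  # axial (q, r) coordinates

    def __len__(self) -> int:
        return len(self.elements)

    def centers_xy(self) -> np.ndarray:
        """Cartesian centers (pointy-top axial layout), unit spacing."""
        q = np.array([c[0] for c in self.elements], dtype=float)
        r = np.array([c[1] for c in self.elements], dtype=float)
        return np.stack([q + r / 2.0, r * np.sqrt(3.0) / 2.0], axis=1)


def hex_array(rings: int) -> HexArray:
    """Centered hexagonal array; element count is 1 + 3*rings*(rings+1)."""
    if rings < 0:
        raise ValueError("rings must be nonnegative")
    elements = [(0, 0)]
    for k in range(1, rings + 1):
        # start k steps along direction 4 and walk the ring
        q, r = k * _HEX_DIRECTIONS[4][0], k * _HEX_DIRECTIONS[4][1]
        for d in range(6):
            dq, dr = _HEX_DIRECTIONS[d]
            for _ in range(k):
                elements.append((q, r))
                q, r = q + dq, r + dr
    return HexArray(rings, tuple(elements))


def _shift_permutation(array: HexArray, offset: tuple[int, int]) -> list[int]:
    """Bijection on element indices: translate by ``offset`` where the
    translated coordinate exists in the array; leftover sources take the
    leftover targets in index order.  Stands in for neural superposition."""
    index = {c: i for i, c in enumerate(array.elements)}
    n = len(array)
    perm = [-1] * n
    taken = set()
    for i, (q, r) in enumerate(array.elements):
        j = index.get((q + offset[0], r + offset[1]))
        if j is not None:
            perm[i] = j
            taken.add(j)
    free = iter(j for j in range(n) if j not in taken)
    for i in range(n):
        if perm[i] < 0:
            perm[i] = next(free)
    return perm


@dataclass
class RetinaLaminaFixture:
    retina: LPUSpec
    lamina: LPUSpec
    pattern: Pattern
    array: HexArray
    bookkeeping: dict = field(default_factory=dict)

    @property
    def n_connections(self) -> int:
        return self.pattern.n_connections

    @property
    def n_lamina_neurons(self) -> int:
        return sum(
            1
            for _, a in self.lamina.components.nodes(data=True)
            if a.get("model") == "MorrisLecar"
        )


def build_fixture(
    rings: int = 15,
    neurons_per_cartridge: int = 6,
    photoreceptor_params: dict | None = None,
) -> RetinaLaminaFixture:
    """Retina + lamina specs and the feed-forward pattern linking them."""
    if neurons_per_cartridge < 1:
        raise ValueError("neurons_per_cartridge must be >= 1")
    array = hex_array(rings)
    n = len(array)
    npr = PHOTORECEPTORS_PER_OMMATIDIUM
    pr_params = photoreceptor_params or {}

    retina_comp = nx.DiGraph()
    retina_iface: list[PortDecl] = []
    retina_bind: dict[PortIdentifier, str] = {}
    for p in range(1, npr + 1):
        for o in range(n):
            node = f"pr{p}_{o}"
            retina_comp.add_node(node, model="PhotoreceptorSurrogate", **pr_params)
            ident = PortIdentifier(("ret", f"r{p}", o))
            retina_iface.append(PortDecl(ident, "out", "gpot"))
            retina_bind[ident] = node
    retina = LPUSpec(
        id="retina",
        interface=tuple(retina_iface),
        components=retina_comp,
        port_bindings=retina_bind,
    )

    lamina_comp = nx.DiGraph()
    lamina_iface: list[PortDecl] = []
    lamina_bind: dict[PortIdentifier, str] = {}
    for o in range(n):
        for m in range(1, neurons_per_cartridge + 1):
            lamina_comp.add_node(f"L{m}_{o}", model="MorrisLecar")
    for p in range(1, npr + 1):
        for o in range(n):
            syn = f"syn{p}_{o}"
            target = f"L{(p - 1) % neurons_per_cartridge + 1}_{o}"
            lamina_comp.add_node(syn, model="ConductanceSynapse")
            lamina_comp.add_edge(syn, target)
            ident = PortIdentifier(("lam", f"r{p}", o))
            lamina_iface.append(PortDecl(ident, "in", "gpot"))
            lamina_bind[ident] = syn
    for m in range(1, min(2, neurons_per_cartridge) + 1):
        for o in range(n):
            ident = PortIdentifier(("lam", f"L{m}", o))
            lamina_iface.append(PortDecl(ident, "out", "gpot"))
            lamina_bind[ident] = f"L{m}_{o}"
    lamina = LPUSpec(
        id="lamina",
        interface=tuple(lamina_iface),
        components=lamina_comp,
        port_bindings=lamina_bind,
    )

    pattern = Pattern(retina.ports(), lamina.ports(io="in"))
    pattern.set_attributes(retina.ports(), 0, "in", "gpot")
    pattern.set_attributes(lamina.ports(io="in"), 1, "out", "gpot")
    for p in range(1, npr + 1):
        perm = _shift_permutation(array, _HEX_DIRECTIONS[p - 1])
        for o in range(n):
            pattern.add_connection(
                PortIdentifier(("ret", f"r{p}", o)),
                PortIdentifier(("lam", f"r{p}", perm[o])),
            )

    bookkeeping = {
        "ommatidia": n,
        "photoreceptors_per_ommatidium": npr,
        "microvilli_per_photoreceptor": 30_000,
        "equations_per_microvillus": 15,
    }
    return RetinaLaminaFixture(retina, lamina, pattern, array, bookkeeping)


def equation_count(
    ommatidia: int,
    photoreceptors: int,
    microvilli: int,
    eqs_per_microvillus: int,
) -> int:
    """Equation-count bookkeeping for the full microvilli cascade the
    surrogate photoreceptor replaces: plain product of the four factors."""
    for v in (ommatidia, photoreceptors, microvilli, eqs_per_microvillus):
        if v < 0:
            raise ValueError("all factors must be nonnegative")
    return ommatidia * photoreceptors * microvilli * eqs_per_microvillus


# ---------------------------------------------------------------------------
# end-to-end demo

def default_video(
    steps: int, height: int = 32, width: int = 32, frames: int = 16
) -> np.ndarray:
    """A drifting luminance grating as a stand-in natural scene."""
    t = np.linspace(0.0, 2.0 * np.pi, frames, endpoint=False)
    x = np.linspace(0.0, 4.0 * np.pi, width)
    grid = 1.0 + np.sin(x[None, None, :] - t[:, None, None])
    return np.broadcast_to(grid, (frames, height, width)).copy()


def _sample_stimulus(video: np.ndarray, array: HexArray, steps: int) -> np.ndarray:
    """Per-(ommatidium, step) intensity: nearest pixel at each hex center,
    frames spread uniformly over the run."""
    frames, height, width = video.shape
    xy = array.centers_xy()
    span = xy.max(axis=0) - xy.min(axis=0)
    span[span == 0] = 1.0
    unit = (xy - xy.min(axis=0)) / span
    cols = np.clip(np.rint(unit[:, 0] * (width - 1)).astype(int), 0, width - 1)
    rows = np.clip(np.rint(unit[:, 1] * (height - 1)).astype(int), 0, height - 1)
    frame_of = np.minimum((np.arange(steps) * frames) // max(steps, 1), frames - 1)
    return video[frame_of][:, rows, cols].T  # (ommatidia, steps)


def run_demo(
    video: np.ndarray | None = None,
    rings: int = 2,
    duration: float = 0.1,
    dt: float = 1e-4,
    neurons_per_cartridge: int = 6,
    seed: int | None = None,
    out=None,
) -> ExecutionRecord:
    """Build the fixture, drive the retina with a video, run, and record.

    ``video`` is a (frames, height, width) intensity array covering the hex
    footprint; by default a drifting grating.  Recordings cover every port
    buffer; write them with ``out`` (HDF5 or CSV path).
    """
    steps = int(duration / dt)
    fixture = build_fixture(rings, neurons_per_cartridge)
    if video is None:
        video = default_video(steps)
    video = np.asarray(video, dtype=float)
    intensity = _sample_stimulus(video, fixture.array, steps)

    stimulus = {}
    for p in range(1, PHOTORECEPTORS_PER_OMMATIDIUM + 1):
        for o in range(len(fixture.array)):
            stimulus[f"pr{p}_{o}"] = intensity[o]

    plan = EmulationPlan(dt=dt)
    plan.add_lpu(fixture.retina, stimulus=stimulus, seed=seed)
    plan.add_lpu(fixture.lamina, seed=seed)
    plan.connect("retina", "lamina", fixture.pattern, 0, 1)
    record = plan.run(steps=steps, record=True)
    if out is not None:
        from .circuit_io import write_record

        write_record(record, out)
    return record
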