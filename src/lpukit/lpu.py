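"""The module (LPU) contract: identity, typed port interface, step hook.

An :class:`LPUSpec` describes a circuit module declaratively: a unique id,
an interface of typed ports (each exactly one io direction and one
transmission kind, LPU-relative), an optional internal component graph of
model-typed nodes, and port bindings tying interface ports to components.
:func:`attach_mappers` turns a valid spec into an :class:`LPURuntime`
holding one graded-potential and one spike :class:`~lpukit.portmap.PortDataMap`
over the interface plus the per-step behavior.

Two execution paths are first-class: a custom hook (any callable
``hook(runtime, step_index, t_seconds, dt)``) and the interpreter path,
where the component graph is executed by the built-in circuit engine.  A
hook may sub-step internally at finer resolution; its outputs must be final
when it returns.  Output ports a hook does not write retain their previous
value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from .errors import LPUStepError, ValidationError
from .portmap import PortDataMap
from .selectors import PortIdentifier, Selector

__all__ = [
    "PortDecl", "LPUSpec", "ValidationReport", "LPURuntime",
    "validate_spec", "attach_mappers", "setup_logging",
]


@dataclass(frozen=True)
class PortDecl:
    """One interface port, LPU-relative: ``io='in'`` receives, ``'out'`` emits."""

    identifier: PortIdentifier
    io: str
    transmission: str


@dataclass
class LPUSpec:
    """Declarative description of one LPU."""

    id: str
    interface: tuple[PortDecl, ...] = ()
    components: nx.DiGraph = field(default_factory=nx.DiGraph)
    port_bindings: dict[PortIdentifier, str] = field(default_factory=dict)

    @classmethod
    def from_selectors(
        cls, id: str, *, in_gpot="", out_gpot="", in_spike="", out_spike="",
        components=None, port_bindings=None,
    ) -> "LPUSpec":
        decls = []
        for sel, io, tr in (
            (in_gpot, "in", "gpot"), (out_gpot, "out", "gpot"),
            (in_spike, "in", "spike"), (out_spike, "out", "spike"),
        ):
            for ident in Selector.coerce(sel).expand():
                decls.append(PortDecl(ident, io, tr))
        return cls(
            id=id,
            interface=tuple(decls),
            components=components if components is not None else nx.DiGraph(),
            port_bindings={
                PortIdentifier.coerce(k): v for k, v in (port_bindings or {}).items()
            },
        )

    def ports(self, io: str | None = None, transmission: str | None = None) -> Selector:
        """Selector over interface ports filtered by direction and/or kind."""
        out = [
            d.identifier
            for d in self.interface
            if (io is None or d.io == io)
            and (transmission is None or d.transmission == transmission)
        ]
        return Selector.from_identifiers(out)

    @property
    def interface_map(self) -> dict[PortIdentifier, tuple[str, str]]:
        return {d.identifier: (d.io, d.transmission) for d in self.interface}


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:
        return self.ok


def validate_spec(spec: LPUSpec) -> ValidationReport:
    """Pure structural check; an empty interface is valid (components that do
    not talk to other LPUs simply are not exposed)."""
    report = ValidationReport()
    if not spec.id or not isinstance(spec.id, str):
        report.violations.append("LPU id must be a nonempty string")
    seen: dict[PortIdentifier, PortDecl] = {}
    for decl in spec.interface:
        if decl.io not in ("in", "out"):
            report.violations.append(
                f"port {decl.identifier}: io must be 'in' or 'out', got {decl.io!r}"
            )
        if decl.transmission not in ("gpot", "spike"):
            report.violations.append(
                f"port {decl.identifier}: transmission must be 'gpot' or "
                f"'spike', got {decl.transmission!r}"
            )
        if decl.identifier in seen:
            other = seen[decl.identifier]
            report.violations.append(
                f"port {decl.identifier} declared more than once "
                f"(({other.io},{other.transmission}) and "
                f"({decl.io},{decl.transmission})); io and transmission must "
                "each take exactly one value per port"
            )
        seen[decl.identifier] = decl
    for ident, comp in spec.port_bindings.items():
        if ident not in seen:
            report.violations.append(
                f"binding for {ident}: identifier not in the interface"
            )
        if comp not in spec.components:
            report.violations.append(
                f"binding for {ident}: component {comp!r} does not exist"
            )
    if len(spec.components) and spec.interface:
        unbound = [str(i) for i in seen if i not in spec.port_bindings]
        if unbound:
            report.violations.append(
                "unbound interface ports (component graph present): "
                + ", ".join(unbound)
            )
    return report


class LPURuntime:
    """A live LPU: spec + zeroed port mappers + step hook + logger."""

    def __init__(self, spec: LPUSpec, hook=None, logger: logging.Logger | None = None):
        self.spec = spec
        self.pm = {
            "gpot": PortDataMap(spec.ports(transmission="gpot"), "gpot"),
            "spike": PortDataMap(spec.ports(transmission="spike"), "spike"),
        }
        self.in_gpot_ports = spec.ports(io="in", transmission="gpot")
        self.out_gpot_ports = spec.ports(io="out", transmission="gpot")
        self.in_spike_ports = spec.ports(io="in", transmission="spike")
        self.out_spike_ports = spec.ports(io="out", transmission="spike")
        self.hook = hook if hook is not None else (lambda rt, k, t, dt: None)
        self.logger = logger or logging.getLogger(f"lpukit.lpu.{spec.id}")

    @property
    def id(self) -> str:
        return self.spec.id

    def log_info(self, msg: str) -> None:
        self.logger.info("[%s] %s", self.id, msg)

    def step(self, step_index: int, dt: float) -> None:
        """Run one emulation step; hook failures are wrapped with identity."""
        try:
            self.hook(self, step_index, step_index * dt, dt)
        except Exception as exc:  # noqa: BLE001 - wrapped and re-raised
            raise LPUStepError(self.id, step_index, exc) from exc


def attach_mappers(
    spec: LPUSpec,
    hook=None,
    *,
    registry=None,
    stimulus=None,
    seed: int | None = None,
    logger: logging.Logger | None = None,
) -> LPURuntime:
    """Validate ``spec`` and build its runtime.

    If no hook is given and the spec has a component graph, the built-in
    circuit engine interprets it; otherwise the hook is a no-op (outputs
    stay at their zero initialization until written).
    """
    report = validate_spec(spec)
    if not report.ok:
        raise ValidationError(report)
    if hook is None and len(spec.components):
        from .circuit import CircuitEngine

        hook = CircuitEngine(spec, registry=registry, stimulus=stimulus, seed=seed)
    return LPURuntime(spec, hook=hook, logger=logger)


def setup_logging(file_name: str | None = None, screen: bool = False,
                  level: int = logging.INFO) -> logging.Logger:
    """Route per-LPU tagged messages to a shared log file and/or the console."""
    logger = logging.getLogger("lpukit")
    logger.setLevel(level)
    fmt = logging.Formatter("%(asctime)s %(name)s %(message)s")
    if file_name:
        fh = logging.FileHandler(file_name)
        fh.setFormatter(fmt)
        logger.addHandler(fh)
    if screen:
        sh = logging.StreamHandler()
        sh.setFormatter(fmt)
        logger.addHandler(sh)
    return logger
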