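"""Point-neuron and synapse models of the compute plane.

Five named models plus a surrogate photoreceptor, each a pure step function
``(state, input, params, dt) -> (state', output)`` advanced by explicit
Euler at the emulation time step (the alpha synapse uses the exact
exponential update of its linear kinetics).  Potentials are in mV, time
constants carry their unit in the tables below, and ``dt`` is always in
seconds at the API boundary.

* Leaky integrate-and-fire: tau dV/dt = -(V - V_rest) + R*I; spike and
  reset on threshold crossing.  For constant suprathreshold I and
  V_reset = V_rest the interspike interval has the closed form
  T = tau * ln(R*I / (R*I - (V_thresh - V_rest))).
* Morris-Lecar (graded-output configuration): the canonical two-variable
  calcium/potassium model; the graded output is the membrane potential and
  no thresholding is applied, matching its use for non-spiking neurons.
* Hodgkin-Huxley: the canonical four-variable squid-axon model with
  standard rate functions; the spike flag marks upward crossings of 0 mV.
* Alpha synapse: impulse response proportional to t*exp(-t/tau), peaking at
  t = tau (current-based).
* Conductance synapse: first-order conductance kinetics driven by a
  sigmoidal function of the presynaptic potential; postsynaptic current
  g*(E_rev - V_post), inhibitory when E_rev lies below rest (the
  histamine-like configuration used in the lamina demo).
* Photoreceptor surrogate: log-intensity transduction followed by a
  first-order low-pass filter, with optional Poisson shot noise.  It stands
  in for the full stochastic microvilli cascade, whose equation count is
  tracked separately by the demo fixture's bookkeeping.

Models register in a :class:`ModelRegistry` so declarative circuit
documents can instantiate them by name; additional models plug in via
:func:`register_model`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, NamedTuple

from .errors import DuplicateIdError

__all__ = [
    "LIFState", "MLState", "HHState", "AlphaState", "CondState", "PRState",
    "lif_step", "morris_lecar_step", "hodgkin_huxley_step",
    "alpha_synapse_step", "conductance_synapse_step", "photoreceptor_step",
    "morris_lecar_equilibrium", "hh_steady_gates",
    "ModelEntry", "ModelRegistry", "register_model", "default_registry",
    "LIF_DEFAULTS", "ML_DEFAULTS", "HH_DEFAULTS", "ALPHA_DEFAULTS",
    "COND_DEFAULTS", "PR_DEFAULTS",
]


def _check_dt(dt: float) -> None:
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")


# ---------------------------------------------------------------------------
# Leaky integrate-and-fire

class LIFState(NamedTuple):
    v: float  # membrane potential, mV


#: tau [s], r [mV per unit input current], potentials [mV]
LIF_DEFAULTS = {
    "v_rest": -65.0,
    "v_reset": -65.0,
    "v_thresh": -55.0,
    "tau": 0.02,
    "r": 1.0,
}


def lif_step(state: LIFState, i_ext: float, params: dict, dt: float):
    """One explicit-Euler step; returns (state, spike_flag)."""
    _check_dt(dt)
    p = {**LIF_DEFAULTS, **params}
    v = state.v + dt * (-(state.v - p["v_rest"]) + p["r"] * i_ext) / p["tau"]
    if v >= p["v_thresh"]:
        return LIFState(p["v_reset"]), 1
    return LIFState(v), 0


def lif_isi_closed_form(i_ext: float, params: dict | None = None) -> float:
    """Interspike interval [s] for constant suprathreshold current when
    V_reset = V_rest.  Raises for subthreshold drive."""
    p = {**LIF_DEFAULTS, **(params or {})}
    drive = p["r"] * i_ext
    gap = p["v_thresh"] - p["v_rest"]
    if drive <= gap:
        raise ValueError("current is not suprathreshold")
    return p["tau"] * math.log(drive / (drive - gap))


# ---------------------------------------------------------------------------
# Morris-Lecar (graded-output configuration)

class MLState(NamedTuple):
    v: float  # membrane potential, mV
    n: float  # K+ recovery variable, dimensionless in [0, 1]


#: capacitance [uF/cm^2], conductances [mS/cm^2], potentials [mV],
#: phi [1/ms]; the classic excitable parameterization
ML_DEFAULTS = {
    "c": 20.0,
    "g_l": 2.0, "e_l": -60.0,
    "g_ca": 4.4, "e_ca": 120.0,
    "g_k": 8.0, "e_k": -84.0,
    "v1": -1.2, "v2": 18.0,
    "v3": 2.0, "v4": 30.0,
    "phi": 0.04,
}


def _ml_m_inf(v, p):
    return 0.5 * (1.0 + math.tanh((v - p["v1"]) / p["v2"]))


def _ml_n_inf(v, p):
    return 0.5 * (1.0 + math.tanh((v - p["v3"]) / p["v4"]))


def _ml_tau_n(v, p):  # ms
    return 1.0 / math.cosh((v - p["v3"]) / (2.0 * p["v4"]))


def _ml_ionic(v, n, p):
    return (
        -p["g_l"] * (v - p["e_l"])
        - p["g_ca"] * _ml_m_inf(v, p) * (v - p["e_ca"])
        - p["g_k"] * n * (v - p["e_k"])
    )


def morris_lecar_step(state: MLState, i_ext: float, params: dict, dt: float):
    """One explicit-Euler step; returns (state, graded_output=V)."""
    _check_dt(dt)
    p = {**ML_DEFAULTS, **params}
    dt_ms = dt * 1e3
    v, n = state
    dv = (i_ext + _ml_ionic(v, n, p)) / p["c"]
    dn = p["phi"] * (_ml_n_inf(v, p) - n) / _ml_tau_n(v, p)
    v_new = v + dt_ms * dv
    n_new = min(1.0, max(0.0, n + dt_ms * dn))
    return MLState(v_new, n_new), v_new


def morris_lecar_equilibrium(
    params: dict | None = None, i_ext: float = 0.0,
    bracket: tuple[float, float] = (-90.0, 40.0),
) -> MLState:
    """Resting equilibrium (V*, n*) with n* on its steady-state curve,
    found by root-finding on the voltage nullcline."""
    from scipy.optimize import brentq

    p = {**ML_DEFAULTS, **(params or {})}

    def f(v):
        return i_ext + _ml_ionic(v, _ml_n_inf(v, p), p)

    lo, hi = bracket
    grid = [lo + (hi - lo) * k / 400 for k in range(401)]
    for a, b in zip(grid[:-1], grid[1:]):
        if f(a) == 0.0:
            return MLState(a, _ml_n_inf(a, p))
        if f(a) * f(b) < 0:
            v_star = brentq(f, a, b, xtol=1e-12)
            return MLState(v_star, _ml_n_inf(v_star, p))
    raise ValueError("no equilibrium found in bracket")


# ---------------------------------------------------------------------------
# Hodgkin-Huxley

class HHState(NamedTuple):
    v: float
    m: float
    h: float
    n: float


#: capacitance [uF/cm^2], conductances [mS/cm^2], potentials [mV]
HH_DEFAULTS = {
    "c": 1.0,
    "g_na": 120.0, "e_na": 50.0,
    "g_k": 36.0, "e_k": -77.0,
    "g_l": 0.3, "e_l": -54.387,
    "v_init": -65.0,
    "max_dt_ms": 0.05,  # documented explicit-Euler stability bound
    "substeps": 1,
}


def _vtrap(x, y):
    """x / (1 - exp(-x/y)) with the removable singularity handled."""
    if abs(x / y) < 1e-6:
        return y * (1.0 + x / (2.0 * y))
    return x / (1.0 - math.exp(-x / y))


def _hh_rates(v):
    a_m = 0.1 * _vtrap(v + 40.0, 10.0)
    b_m = 4.0 * math.exp(-(v + 65.0) / 18.0)
    a_h = 0.07 * math.exp(-(v + 65.0) / 20.0)
    b_h = 1.0 / (1.0 + math.exp(-(v + 35.0) / 10.0))
    a_n = 0.01 * _vtrap(v + 55.0, 10.0)
    b_n = 0.125 * math.exp(-(v + 65.0) / 80.0)
    return a_m, b_m, a_h, b_h, a_n, b_n


def hh_steady_gates(v: float) -> tuple[float, float, float]:
    """(m_inf, h_inf, n_inf) at a clamped potential."""
    a_m, b_m, a_h, b_h, a_n, b_n = _hh_rates(v)
    return a_m / (a_m + b_m), a_h / (a_h + b_h), a_n / (a_n + b_n)


def hh_rest_state(params: dict | None = None) -> HHState:
    p = {**HH_DEFAULTS, **(params or {})}
    v = p["v_init"]
    return HHState(v, *hh_steady_gates(v))


def hodgkin_huxley_step(state: HHState, i_ext: float, params: dict, dt: float):
    """One step (optionally internally sub-stepped); returns (state, spike).

    The explicit-Euler scheme is only stable for internal steps below
    ``max_dt_ms``; coarser emulation steps must raise ``substeps``.
    """
    _check_dt(dt)
    p = {**HH_DEFAULTS, **params}
    sub = int(p["substeps"])
    dt_ms = dt * 1e3 / sub
    if dt_ms > p["max_dt_ms"]:
        raise ValueError(
            f"internal step {dt_ms:g} ms exceeds the stability bound "
            f"{p['max_dt_ms']:g} ms; increase 'substeps'"
        )
    v, m, h, n = state
    v_prev = v
    for _ in range(sub):
        a_m, b_m, a_h, b_h, a_n, b_n = _hh_rates(v)
        i_ion = (
            -p["g_na"] * m**3 * h * (v - p["e_na"])
            - p["g_k"] * n**4 * (v - p["e_k"])
            - p["g_l"] * (v - p["e_l"])
        )
        v = v + dt_ms * (i_ext + i_ion) / p["c"]
        m = min(1.0, max(0.0, m + dt_ms * (a_m * (1.0 - m) - b_m * m)))
        h = min(1.0, max(0.0, h + dt_ms * (a_h * (1.0 - h) - b_h * h)))
        n = min(1.0, max(0.0, n + dt_ms * (a_n * (1.0 - n) - b_n * n)))
    spike = 1 if (v_prev < 0.0 <= v) else 0
    return HHState(v, m, h, n), spike


# ---------------------------------------------------------------------------
# Synapses

class AlphaState(NamedTuple):
    x: float  # activation trace (impulse accumulator)
    g: float  # normalized conductance


#: tau [s]; g_max scales the emitted current
ALPHA_DEFAULTS = {"tau": 0.005, "g_max": 1.0}


def alpha_synapse_step(state: AlphaState, spike_in: float, params: dict, dt: float):
    """Exact exponential update of the two-stage alpha kinetics; returns
    (state, current).  A unit spike at step k yields the discrete kernel
    g_m = (m*dt/tau) * exp(-m*dt/tau), m steps later — peak within one dt
    of t = tau."""
    _check_dt(dt)
    p = {**ALPHA_DEFAULTS, **params}
    decay = math.exp(-dt / p["tau"])
    g = decay * (state.g + dt * state.x / p["tau"])
    x = decay * state.x + float(spike_in)
    return AlphaState(x, g), p["g_max"] * g


class CondState(NamedTuple):
    g: float  # conductance, nonnegative


#: tau [s], potentials [mV]; e_rev below rest -> inhibitory
COND_DEFAULTS = {
    "g_max": 1.0,
    "v_half": -50.0,
    "slope": 5.0,
    "tau": 0.005,
    "e_rev": -80.0,
}


def conductance_synapse_step(
    state: CondState, v_pre: float, params: dict, dt: float, v_post: float
):
    """Graded conductance kinetics; returns (state, current g*(E_rev - V_post))."""
    _check_dt(dt)
    p = {**COND_DEFAULTS, **params}
    g_inf = p["g_max"] / (1.0 + math.exp(-(v_pre - p["v_half"]) / p["slope"]))
    g = state.g + dt * (g_inf - state.g) / p["tau"]
    g = max(0.0, g)
    return CondState(g), g * (p["e_rev"] - v_post)


# ---------------------------------------------------------------------------
# Photoreceptor surrogate

class PRState(NamedTuple):
    v: float


#: gain [mV per log-intensity unit], tau [s]; noise_rate [events per unit
#: intensity per s] > 0 enables Poisson shot noise scaled by noise_gain [mV]
PR_DEFAULTS = {
    "v_rest": -65.0,
    "gain": 10.0,
    "tau": 0.02,
    "noise_rate": 0.0,
    "noise_gain": 0.1,
}


def photoreceptor_step(
    state: PRState, intensity: float, params: dict, dt: float, rng=None
):
    """Log transduction + first-order low-pass; returns (state, V)."""
    _check_dt(dt)
    p = {**PR_DEFAULTS, **params}
    intensity = max(0.0, float(intensity))
    target = p["v_rest"] + p["gain"] * math.log1p(intensity)
    if p["noise_rate"] > 0.0 and rng is not None:
        lam = p["noise_rate"] * intensity * dt
        target += p["noise_gain"] * (float(rng.poisson(lam)) - lam)
    v = state.v + dt * (target - state.v) / p["tau"]
    return PRState(v), v


# ---------------------------------------------------------------------------
# Registry

@dataclass(frozen=True)
class ModelEntry:
    """Registry record binding a model name to its factory and step adapter.

    ``kind`` distinguishes drive semantics: a ``neuron`` sums the current
    contributions of its presynaptic components (plus bound input-port
    values and stimulus), a ``synapse`` reads a single presynaptic value —
    the source's spike flag when ``presyn='spike'``, its graded potential
    when ``presyn='gpot'``.  The adapter signature is
    ``step(state, drive, params, dt, rng, v_post) -> (state, out)`` with
    ``out = {'gpot': float, 'spike': int, 'current': float}``.
    """

    name: str
    kind: str  # 'neuron' | 'synapse'
    make_state: Callable
    step: Callable
    schema: dict
    defaults: dict
    presyn: str = "spike"


class ModelRegistry:
    def __init__(self):
        self._entries: dict[str, ModelEntry] = {}

    def register(self, entry: ModelEntry) -> None:
        if entry.name in self._entries:
            raise DuplicateIdError(f"model {entry.name!r} already registered")
        bad = set(entry.defaults) - set(entry.schema)
        if bad:
            raise ValueError(f"defaults outside schema for {entry.name!r}: {bad}")
        self._entries[entry.name] = entry

    def get(self, name: str) -> ModelEntry:
        try:
            return self._entries[name]
        except KeyError:
            raise KeyError(f"unknown model {name!r}") from None

    def __contains__(self, name) -> bool:
        return name in self._entries

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self._entries)

    def copy(self) -> "ModelRegistry":
        reg = ModelRegistry()
        reg._entries = dict(self._entries)
        return reg


def register_model(
    registry: ModelRegistry,
    name: str,
    factory: Callable,
    step: Callable,
    schema: dict | None = None,
    defaults: dict | None = None,
    kind: str = "neuron",
    presyn: str = "spike",
) -> ModelRegistry:
    """Add a plugin model constructible from declarative attribute maps."""
    defaults = dict(defaults or {})
    schema = dict(schema if schema is not None else {k: "number" for k in defaults})
    registry.register(
        ModelEntry(name, kind, factory, step, schema, defaults, presyn)
    )
    return registry


def _out(gpot=0.0, spike=0, current=0.0):
    return {"gpot": gpot, "spike": spike, "current": current}


def _lif_adapter(state, drive, params, dt, rng, v_post):
    state, spike = lif_step(state, drive, params, dt)
    return state, _out(gpot=state.v, spike=spike)


def _ml_adapter(state, drive, params, dt, rng, v_post):
    state, v = morris_lecar_step(state, drive, params, dt)
    return state, _out(gpot=v)


def _hh_adapter(state, drive, params, dt, rng, v_post):
    state, spike = hodgkin_huxley_step(state, drive, params, dt)
    return state, _out(gpot=state.v, spike=spike)


def _alpha_adapter(state, drive, params, dt, rng, v_post):
    state, i = alpha_synapse_step(state, drive, params, dt)
    return state, _out(gpot=i, current=i)


def _cond_adapter(state, drive, params, dt, rng, v_post):
    state, i = conductance_synapse_step(state, drive, params, dt, v_post)
    return state, _out(gpot=i, current=i)


def _pr_adapter(state, drive, params, dt, rng, v_post):
    state, v = photoreceptor_step(state, drive, params, dt, rng)
    return state, _out(gpot=v)


_BUILTIN = ModelRegistry()
register_model(
    _BUILTIN, "LeakyIAF",
    lambda p, rng: LIFState(p.get("v_init", p.get("v_rest", LIF_DEFAULTS["v_rest"]))),
    _lif_adapter,
    schema={**{k: "number" for k in LIF_DEFAULTS}, "v_init": "number"},
    defaults=LIF_DEFAULTS, kind="neuron",
)
register_model(
    _BUILTIN, "MorrisLecar",
    lambda p, rng: MLState(p.get("v_init", -60.0), p.get("n_init", 0.0)),
    _ml_adapter,
    schema={**{k: "number" for k in ML_DEFAULTS}, "v_init": "number", "n_init": "number"},
    defaults=ML_DEFAULTS, kind="neuron",
)
register_model(
    _BUILTIN, "HodgkinHuxley",
    lambda p, rng: hh_rest_state(p),
    _hh_adapter,
    schema={**{k: "number" for k in HH_DEFAULTS}},
    defaults=HH_DEFAULTS, kind="neuron",
)
register_model(
    _BUILTIN, "AlphaSynapse",
    lambda p, rng: AlphaState(0.0, 0.0),
    _alpha_adapter,
    schema={k: "number" for k in ALPHA_DEFAULTS},
    defaults=ALPHA_DEFAULTS, kind="synapse", presyn="spike",
)
register_model(
    _BUILTIN, "ConductanceSynapse",
    lambda p, rng: CondState(0.0),
    _cond_adapter,
    schema={k: "number" for k in COND_DEFAULTS},
    defaults=COND_DEFAULTS, kind="synapse", presyn="gpot",
)
register_model(
    _BUILTIN, "PhotoreceptorSurrogate",
    lambda p, rng: PRState(p.get("v_init", p.get("v_rest", PR_DEFAULTS["v_rest"]))),
    _pr_adapter,
    schema={**{k: "number" for k in PR_DEFAULTS}, "v_init": "number"},
    defaults=PR_DEFAULTS, kind="neuron",
)


def default_registry() -> ModelRegistry:
    """A fresh copy of the built-in registry (five named models plus the
    photoreceptor surrogate); safe to extend per emulation."""
    return _BUILTIN.copy()
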