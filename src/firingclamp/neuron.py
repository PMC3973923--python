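"""Single-compartment conductance-based neuron simulator.

The cell is a Hodgkin-Huxley-type point neuron with a transient sodium
current (m^3 h), a delayed-rectifier potassium current (n^4) and a slow
potassium adaptation current (gate w, tau ~ 100 ms), on top of an Ohmic
leak.  Kinetics follow the Wang-Buzsaki hippocampal formulation, with
conductances scaled to a small dissociated cell (input conductance
1.5 nS, rest near -77 mV).

Units are fixed package-wide: mV, ms, nS, pA, pF (nS*mV = pA and
pF*mV/ms = pA, so the membrane equation closes without conversion
factors).

Integration is fixed-step: exponential (Rush-Larsen) updates for the
gating variables and forward Euler for the voltage, at dt = 0.03 ms by
default -- one step of the discrete control loop the clamp protocol is
defined on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "NeuronParams",
    "MembraneState",
    "VoltageTrace",
    "DEFAULT_DT_MS",
    "init_steady_state",
    "step",
    "run",
    "NumericalError",
]

#: Default control-loop step (ms); mirrors a 30 us real-time clamp cycle.
DEFAULT_DT_MS = 0.03

#: Hard stability bound for the gating integration (ms).
MAX_DT_MS = 0.05


class NumericalError(RuntimeError):
    """Integration produced a non-finite state or failed to converge."""


@dataclass(frozen=True)
class NeuronParams:
    """Passive and active membrane parameters.

    Attributes
    ----------
    C_m_pF : membrane capacitance (pF).
    G_leak_nS : resting input conductance G_0 (nS).
    V_rest_mV : leak reversal / resting potential V_0 (mV).
    gbar_Na_nS, gbar_K_nS, gbar_AHP_nS : maximal conductances (nS).
    E_Na_mV, E_K_mV : channel reversal potentials (mV).
    """

    C_m_pF: float = 15.0
    G_leak_nS: float = 1.5
    V_rest_mV: float = -77.0
    gbar_Na_nS: float = 1200.0
    gbar_K_nS: float = 400.0
    gbar_AHP_nS: float = 5.0
    E_Na_mV: float = 55.0
    E_K_mV: float = -90.0

    def __post_init__(self) -> None:
        if not self.C_m_pF > 0:
            raise ValueError("C_m_pF must be positive")
        if not self.G_leak_nS > 0:
            raise ValueError("G_leak_nS must be positive")
        if not (self.E_Na_mV > self.V_rest_mV > self.E_K_mV):
            raise ValueError("require E_Na > V_rest > E_K")
        for name in ("gbar_Na_nS", "gbar_K_nS", "gbar_AHP_nS"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class MembraneState:
    """Instantaneous state: voltage plus the four gating variables."""

    V_mV: float
    m: float
    h: float
    n: float
    w: float

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.V_mV, self.m, self.h, self.n, self.w)


@dataclass
class VoltageTrace:
    """Uniformly sampled membrane voltage and injected current.

    ``V_mV[k]`` is the voltage at time ``t0_ms + k*dt_ms``; ``Iinj_pA[k]``
    is the current injected during the step starting there.
    """

    dt_ms: float
    V_mV: np.ndarray
    Iinj_pA: np.ndarray
    t0_ms: float = 0.0

    def __post_init__(self) -> None:
        self.V_mV = np.asarray(self.V_mV, dtype=float)
        self.Iinj_pA = np.asarray(self.Iinj_pA, dtype=float)
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be positive")
        if self.V_mV.shape != self.Iinj_pA.shape:
            raise ValueError("V_mV and Iinj_pA must have equal length")

    @property
    def t_ms(self) -> np.ndarray:
        return self.t0_ms + self.dt_ms * np.arange(len(self.V_mV))

    def __len__(self) -> int:
        return len(self.V_mV)


# ---------------------------------------------------------------------------
# Channel kinetics (Wang-Buzsaki; rates in 1/ms, V in mV)
# ---------------------------------------------------------------------------

_PHI = 5.0  # temperature factor on h and n kinetics

# Uniform depolarizing shift of the spike-generating kinetics relative to
# the canonical formulation, placing spike threshold near -60 mV so the
# brief positive probe pulse is reliably suprathreshold from the -75 mV
# reset of a cell resting at -77 mV.
_V_SHIFT = 10.0


def _vtrap(x: float, y: float) -> float:
    """x / (1 - exp(-x/y)) with the removable singularity at x = 0."""
    if abs(x / y) < 1e-6:
        return y * (1.0 + x / (2.0 * y))
    return x / (1.0 - math.exp(-x / y))


def _alpha_m(V: float) -> float:
    V += _V_SHIFT
    return 0.1 * _vtrap(V + 35.0, 10.0)


def _beta_m(V: float) -> float:
    return 4.0 * math.exp(-(V + _V_SHIFT + 60.0) / 18.0)


def _alpha_h(V: float) -> float:
    return _PHI * 0.07 * math.exp(-(V + _V_SHIFT + 58.0) / 20.0)


def _beta_h(V: float) -> float:
    return _PHI * 1.0 / (1.0 + math.exp(-(V + _V_SHIFT + 28.0) / 10.0))


def _alpha_n(V: float) -> float:
    V += _V_SHIFT
    return _PHI * 0.01 * _vtrap(V + 34.0, 10.0)


def _beta_n(V: float) -> float:
    return _PHI * 0.125 * math.exp(-(V + _V_SHIFT + 44.0) / 80.0)


_TAU_W_MS = 100.0


def _w_inf(V: float) -> float:
    return 1.0 / (1.0 + math.exp(-(V + 35.0) / 10.0))


def gate_steady_state(V: float) -> tuple[float, float, float, float]:
    """Voltage-clamped fixed point (m_inf, h_inf, n_inf, w_inf) at V."""
    am, bm = _alpha_m(V), _beta_m(V)
    ah, bh = _alpha_h(V), _beta_h(V)
    an, bn = _alpha_n(V), _beta_n(V)
    return am / (am + bm), ah / (ah + bh), an / (an + bn), _w_inf(V)


def _step_raw(
    V: float,
    m: float,
    h: float,
    n: float,
    w: float,
    I_inj: float,
    dt: float,
    p: NeuronParams,
) -> tuple[float, float, float, float, float]:
    """One integration step on plain floats (hot path)."""
    # Rush-Larsen exponential update of the gates at the pre-step voltage.
    am, bm = _alpha_m(V), _beta_m(V)
    s = am + bm
    m += (am / s - m) * (1.0 - math.exp(-dt * s))
    ah, bh = _alpha_h(V), _beta_h(V)
    s = ah + bh
    h += (ah / s - h) * (1.0 - math.exp(-dt * s))
    an, bn = _alpha_n(V), _beta_n(V)
    s = an + bn
    n += (an / s - n) * (1.0 - math.exp(-dt * s))
    w += (_w_inf(V) - w) * (1.0 - math.exp(-dt / _TAU_W_MS))

    I_ion = (
        p.G_leak_nS * (V - p.V_rest_mV)
        + p.gbar_Na_nS * m * m * m * h * (V - p.E_Na_mV)
        + (p.gbar_K_nS * n * n * n * n + p.gbar_AHP_nS * w) * (V - p.E_K_mV)
    )
    V += dt * (I_inj - I_ion) / p.C_m_pF
    return V, m, h, n, w


def _derivatives(
    V: float, m: float, h: float, n: float, w: float, I_inj: float, p: NeuronParams
) -> tuple[float, float, float, float, float]:
    I_ion = (
        p.G_leak_nS * (V - p.V_rest_mV)
        + p.gbar_Na_nS * m**3 * h * (V - p.E_Na_mV)
        + (p.gbar_K_nS * n**4 + p.gbar_AHP_nS * w) * (V - p.E_K_mV)
    )
    dV = (I_inj - I_ion) / p.C_m_pF
    dm = _alpha_m(V) * (1 - m) - _beta_m(V) * m
    dh = _alpha_h(V) * (1 - h) - _beta_h(V) * h
    dn = _alpha_n(V) * (1 - n) - _beta_n(V) * n
    dw = (_w_inf(V) - w) / _TAU_W_MS
    return dV, dm, dh, dn, dw


def _check_finite(state: tuple[float, ...], t: float) -> None:
    names = ("V", "m", "h", "n", "w")
    for name, x in zip(names, state):
        if not math.isfinite(x):
            raise NumericalError(f"non-finite state variable {name!r} at t = {t:g} ms")


def init_steady_state(
    params: NeuronParams,
    *,
    settle_ms: float = 2000.0,
    dt_ms: float = 0.01,
    tol: float = 1e-6,
) -> MembraneState:
    """Relax the model to its resting fixed point at zero injected current.

    Integrates from (V_rest, gate steady states) for up to ``settle_ms``
    and verifies that the residual derivative norm is below ``tol``
    (per-ms units).  Raises :class:`NumericalError` if no stable rest is
    reached, e.g. for pacemaking parameter sets.
    """
    V = params.V_rest_mV
    m, h, n, w = gate_steady_state(V)
    state = (V, m, h, n, w)
    n_steps = int(round(settle_ms / dt_ms))
    check_every = max(1, int(round(1.0 / dt_ms)))
    for k in range(n_steps):
        state = _step_raw(*state, 0.0, dt_ms, params)
        if (k + 1) % check_every == 0:
            _check_finite(state, (k + 1) * dt_ms)
            dnorm = max(abs(d) for d in _derivatives(*state, 0.0, params))
            if dnorm < tol:
                return MembraneState(*state)
    dnorm = max(abs(d) for d in _derivatives(*state, 0.0, params))
    if dnorm < tol:
        return MembraneState(*state)
    raise NumericalError(
        f"no resting fixed point found within {settle_ms:g} ms "
        f"(residual derivative norm {dnorm:.3g}/ms)"
    )


def step(
    state: MembraneState, I_inj_pA: float, dt_ms: float, params: NeuronParams
) -> MembraneState:
    """Advance the membrane equation by one step of size ``dt_ms``.

    C_m dV/dt = -G_leak (V - V_rest) - I_Na - I_K - I_AHP + I_inj, with
    exponential gate updates.  Gates stay in [0, 1] by construction.
    """
    if dt_ms > MAX_DT_MS:
        raise ValueError(f"dt_ms = {dt_ms} exceeds stability bound {MAX_DT_MS} ms")
    out = _step_raw(*state.as_tuple(), I_inj_pA, dt_ms, params)
    _check_finite(out, float("nan"))
    return MembraneState(*out)


def run(
    params: NeuronParams,
    controller: Callable[[float, float], float],
    duration_ms: float,
    dt_ms: float = DEFAULT_DT_MS,
    *,
    initial_state: MembraneState | None = None,
    t0_ms: float = 0.0,
) -> VoltageTrace:
    """Closed-loop simulation against a causal current source.

    ``controller(t, V)`` is called once per control step, in order, with
    the voltage at the start of the step; it returns the current (pA)
    injected during that step and never sees future samples.
    """
    if dt_ms > MAX_DT_MS:
        raise ValueError(f"dt_ms = {dt_ms} exceeds stability bound {MAX_DT_MS} ms")
    n_steps = int(round(duration_ms / dt_ms))
    if initial_state is None:
        initial_state = init_steady_state(params)
    state = initial_state.as_tuple()
    V_out = np.empty(n_steps)
    I_out = np.empty(n_steps)
    check_every = max(1, int(round(1.0 / dt_ms)))
    for k in range(n_steps):
        t = t0_ms + k * dt_ms
        V = state[0]
        I = controller(t, V)
        V_out[k] = V
        I_out[k] = I
        state = _step_raw(*state, I, dt_ms, params)
        if (k + 1) % check_every == 0:
            _check_finite(state, t + dt_ms)
    _check_finite(state, t0_ms + n_steps * dt_ms)
    return VoltageTrace(dt_ms=dt_ms, V_mV=V_out, Iinj_pA=I_out, t0_ms=t0_ms)
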