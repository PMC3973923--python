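"""Ground-truth synaptic input scenarios.

Generators for the conditions the estimator is validated against:
sinusoidal conductance oscillations in the gamma (default 40 Hz) and
theta (default 6 Hz) bands, Poisson trains of mono-exponential synaptic
events (instantaneous rise), agonist-application steps with exponential
edges, additive Gaussian conductance noise (clipped at zero), and a slow
drift of the inhibitory reversal potential.  All randomness flows from
the scenario seed, so a (spec, seed) pair reproduces traces bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .estimation import ReversalSpec, compose
from .protocol import ControlSignals

__all__ = ["Component", "ScenarioSpec", "generate", "to_control_signals",
           "cycle_average", "gamma_theta_scenario", "glutamate_scenario",
           "gaba_scenario", "combined_scenario"]

_KINDS = ("sinusoid", "event_train", "agonist_step")


@dataclass(frozen=True)
class Component:
    """One additive contribution to G_E or G_I.

    kind "sinusoid": baseline + amplitude * sin(2 pi f t + phase),
    clipped at zero.  kind "event_train": Poisson events at rate_Hz,
    each an instantaneous-rise, mono-exponential-decay transient of the
    given amplitude and decay_tau_ms.  kind "agonist_step": amplitude
    between onset and offset with mono-exponential edges (decay_tau_ms).
    """

    target: str  # "E" | "I"
    kind: str
    amplitude_nS: float
    baseline_nS: float = 0.0
    frequency_Hz: float | None = None
    phase_rad: float = 0.0
    rate_Hz: float | None = None
    decay_tau_ms: float | None = None
    onset_ms: float = 0.0
    offset_ms: float | None = None

    def __post_init__(self) -> None:
        if self.target not in ("E", "I"):
            raise ValueError("target must be 'E' or 'I'")
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}")
        if self.amplitude_nS < 0 or self.baseline_nS < 0:
            raise ValueError("amplitudes must be non-negative")


@dataclass(frozen=True)
class ScenarioSpec:
    """A synaptic input scenario: components + noise + optional V_I drift.

    ``vi_drift_mV`` = (V_start, V_end, t_start_ms, t_end_ms) ramps the
    inhibitory reversal linearly between the two times (mimicking the
    activity-dependent shift seen under sustained GABA application);
    outside the ramp it is held at the endpoint values.
    """

    components: tuple[Component, ...]
    noise_sigma_nS: float = 0.0
    seed: int = 0
    vi_drift_mV: tuple[float, float, float, float] | None = None

    @property
    def kind(self) -> str:
        kinds = {c.kind for c in self.components}
        return kinds.pop() if len(kinds) == 1 else "composite"

    # -- convenience constructors -------------------------------------
    @staticmethod
    def sinusoid(
        target: str = "E",
        frequency_Hz: float = 40.0,
        amplitude_nS: float = 0.25,
        baseline_nS: float = 0.4,
        phase_rad: float = 0.0,
        **kw,
    ) -> "ScenarioSpec":
        return ScenarioSpec(
            (
                Component(
                    target=target,
                    kind="sinusoid",
                    amplitude_nS=amplitude_nS,
                    baseline_nS=baseline_nS,
                    frequency_Hz=frequency_Hz,
                    phase_rad=phase_rad,
                ),
            ),
            **kw,
        )

    @staticmethod
    def event_train(
        target: str = "I",
        rate_Hz: float = 10.0,
        amplitude_nS: float = 1.5,
        decay_tau_ms: float = 20.0,
        **kw,
    ) -> "ScenarioSpec":
        return ScenarioSpec(
            (
                Component(
                    target=target,
                    kind="event_train",
                    amplitude_nS=amplitude_nS,
                    rate_Hz=rate_Hz,
                    decay_tau_ms=decay_tau_ms,
                ),
            ),
            **kw,
        )

    @staticmethod
    def agonist_step(
        target: str = "I",
        amplitude_nS: float = 2.0,
        onset_ms: float = 500.0,
        offset_ms: float | None = 1500.0,
        decay_tau_ms: float = 200.0,
        **kw,
    ) -> "ScenarioSpec":
        return ScenarioSpec(
            (
                Component(
                    target=target,
                    kind="agonist_step",
                    amplitude_nS=amplitude_nS,
                    onset_ms=onset_ms,
                    offset_ms=offset_ms,
                    decay_tau_ms=decay_tau_ms,
                ),
            ),
            **kw,
        )


def _component_trace(
    c: Component, t: np.ndarray, dt: float, rng: np.random.Generator
) -> np.ndarray:
    if c.kind == "sinusoid":
        if c.frequency_Hz is None:
            raise ValueError("sinusoid component needs frequency_Hz")
        f_per_ms = c.frequency_Hz / 1000.0
        return np.clip(
            c.baseline_nS
            + c.amplitude_nS * np.sin(2 * np.pi * f_per_ms * t + c.phase_rad),
            0.0,
            None,
        )
    if c.kind == "event_train":
        if c.rate_Hz is None or c.decay_tau_ms is None:
            raise ValueError("event_train needs rate_Hz and decay_tau_ms")
        duration = t[-1] + dt - t[0] if len(t) else 0.0
        n_events = rng.poisson(c.rate_Hz * duration / 1000.0)
        impulses = np.zeros_like(t)
        if n_events:
            times = rng.uniform(t[0], t[0] + duration, size=n_events)
            idx = np.floor((times - t[0]) / dt).astype(int)
            np.add.at(impulses, np.clip(idx, 0, len(t) - 1), c.amplitude_nS)
        decay = np.exp(-dt / c.decay_tau_ms)
        return c.baseline_nS + lfilter([1.0], [1.0, -decay], impulses)
    if c.kind == "agonist_step":
        if c.decay_tau_ms is None:
            raise ValueError("agonist_step needs decay_tau_ms")
        g = np.zeros_like(t)
        on = t >= c.onset_ms
        g[on] = c.amplitude_nS * (1.0 - np.exp(-(t[on] - c.onset_ms) / c.decay_tau_ms))
        if c.offset_ms is not None:
            off = t >= c.offset_ms
            level = c.amplitude_nS * (
                1.0 - np.exp(-(c.offset_ms - c.onset_ms) / c.decay_tau_ms)
            )
            g[off] = level * np.exp(-(t[off] - c.offset_ms) / c.decay_tau_ms)
        return c.baseline_nS + g
    raise ValueError(f"unknown component kind {c.kind!r}")


def generate(
    spec: ScenarioSpec, duration_ms: float, dt_ms: float = 0.03
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Realize (G_E(t), G_I(t), V_I(t) or None) on the control grid.

    Conductances are sums of the spec's components plus additive
    Gaussian noise of ``noise_sigma_nS``, clipped at zero.
    """
    n = int(round(duration_ms / dt_ms))
    t = np.arange(n) * dt_ms
    rng = np.random.default_rng(spec.seed)
    G_E = np.zeros(n)
    G_I = np.zeros(n)
    for c in spec.components:
        tr = _component_trace(c, t, dt_ms, rng)
        if c.target == "E":
            G_E += tr
        else:
            G_I += tr
    if spec.noise_sigma_nS > 0:
        G_E = G_E + rng.normal(0.0, spec.noise_sigma_nS, size=n)
        G_I = G_I + rng.normal(0.0, spec.noise_sigma_nS, size=n)
    G_E = np.clip(G_E, 0.0, None)
    G_I = np.clip(G_I, 0.0, None)
    V_I = None
    if spec.vi_drift_mV is not None:
        v0, v1, t0, t1 = spec.vi_drift_mV
        V_I = np.interp(t, [t0, t1], [v0, v1])
    return G_E, G_I, V_I


def to_control_signals(
    G_E: np.ndarray,
    G_I: np.ndarray,
    rev: ReversalSpec,
    dt_ms: float = 0.03,
    *,
    V_I_mV: np.ndarray | None = None,
) -> ControlSignals:
    """Compose (G_E, G_I) pointwise into dynamic-clamp control signals."""
    G_E = np.asarray(G_E, dtype=float)
    G_I = np.asarray(G_I, dtype=float)
    if G_E.shape != G_I.shape:
        raise ValueError("G_E and G_I must be aligned")
    I, G = compose(G_E, G_I, rev, V_I_mV=V_I_mV)
    return ControlSignals(
        dt_ms=dt_ms, I_pA=I, G_nS=G, V_rev_for_G_mV=rev.V_0_mV, V_I_mV=V_I_mV
    )


def cycle_average(x: np.ndarray, markers, dt_ms: float) -> np.ndarray:
    """Mean of a control-grid series over each cycle window.

    The per-cycle average is what the probe-spike estimator can at best
    resolve; estimator error should be measured against this, not the
    raw waveform.
    """
    out = np.empty(len(markers))
    for i in range(len(markers)):
        k0 = int(round(markers.t_start_ms[i] / dt_ms))
        k1 = int(round(markers.t_cycle_end_ms[i] / dt_ms))
        out[i] = float(np.mean(x[k0:k1]))
    return out


# ---------------------------------------------------------------------------
# Canonical validation scenarios
# ---------------------------------------------------------------------------

def gamma_theta_scenario(seed: int = 0, noise_sigma_nS: float = 0.0) -> ScenarioSpec:
    """Gamma-band excitation plus theta-band inhibition.

    G_E oscillates at 40 Hz (0.4 +/- 0.25 nS) and G_I at 6 Hz
    (1.5 +/- 1.2 nS); the modest excitatory amplitude keeps the total
    synaptic current inside the subthreshold operating range of the
    default model cell between probe spikes.
    """
    return ScenarioSpec(
        (
            Component(target="E", kind="sinusoid", amplitude_nS=0.25,
                      baseline_nS=0.4, frequency_Hz=40.0),
            Component(target="I", kind="sinusoid", amplitude_nS=1.2,
                      baseline_nS=1.5, frequency_Hz=6.0),
        ),
        noise_sigma_nS=noise_sigma_nS,
        seed=seed,
    )


def glutamate_scenario(seed: int = 0, amplitude_nS: float = 0.8) -> ScenarioSpec:
    """Pure-excitatory agonist application (bath glutamate analogue)."""
    return ScenarioSpec.agonist_step(
        target="E", amplitude_nS=amplitude_nS, onset_ms=400.0,
        offset_ms=1400.0, decay_tau_ms=150.0, seed=seed,
    )


def gaba_scenario(seed: int = 0, amplitude_nS: float = 2.0) -> ScenarioSpec:
    """Pure-inhibitory agonist application (bath GABA analogue)."""
    return ScenarioSpec.agonist_step(
        target="I", amplitude_nS=amplitude_nS, onset_ms=400.0,
        offset_ms=1400.0, decay_tau_ms=150.0, seed=seed,
    )


def combined_scenario(seed: int = 0) -> ScenarioSpec:
    """Overlapping agonists: sustained inhibition with an excitatory
    episode inside the GABA window.

    The shunt from the inhibitory background keeps the unclamped
    membrane of the default model cell subthreshold throughout, so the
    reconstructed voltage can be compared against a direct free-running
    simulation.
    """
    return ScenarioSpec(
        (
            Component(target="I", kind="agonist_step", amplitude_nS=2.0,
                      baseline_nS=0.8, onset_ms=400.0, offset_ms=1600.0,
                      decay_tau_ms=150.0),
            Component(target="E", kind="agonist_step", amplitude_nS=0.15,
                      onset_ms=700.0, offset_ms=1300.0, decay_tau_ms=150.0),
        ),
        seed=seed,
    )
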