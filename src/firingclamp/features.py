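"""Probe-spike feature extraction.

Two characteristics are measured per meander cycle:

* ``V_pulse`` — the positive-pulse response, mainly reduced by the
  shunting effect of the total synaptic conductance.  Three operational
  readings are supported: ``"peak"`` (default) takes the probe-spike
  peak, the maximum voltage between pulse onset and the end of the
  negative phase, which is insensitive to spike-timing jitter;
  ``"difference"`` takes pulse-end minus pulse-start voltage;
  ``"absolute"`` takes the raw pulse-end voltage.  Because calibration
  and estimation share one definition, any reading yields a consistent
  estimator -- they differ in how much cycle-to-cycle spike-timing
  variability leaks into the feature.
* ``V_subthr`` — the mean membrane potential over the zero-current
  segment of the cycle (after the imposed reset), mainly sensitive to
  the total synaptic current.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .neuron import VoltageTrace
from .protocol import CycleMarkers

__all__ = ["FeatureConfig", "ProbeFeatureSeries", "extract_features"]

QC_OK = "ok"
QC_NO_SPIKE = "no_spike"
QC_EMPTY_WINDOW = "empty_window"
QC_SPIKE_CONTAMINATED = "spike_contaminated"


@dataclass(frozen=True)
class FeatureConfig:
    """Extraction parameters.

    settle_ms
        Margin after the negative pulse before the V_subthr averaging
        window opens (lets the reset transient decay).
    spike_threshold_mV
        Samples above this level inside the averaging window are
        treated as spontaneous-spike contamination and excluded.
    max_excluded_frac
        Cycles with more than this fraction of window samples excluded
        are flagged rather than averaged.
    pulse_mode
        "peak" (probe-spike peak voltage), "difference" (pulse end
        minus pulse start) or "absolute" (voltage at pulse end).
    """

    settle_ms: float = 0.5
    spike_threshold_mV: float = -50.0
    max_excluded_frac: float = 0.3
    pulse_mode: str = "peak"

    def __post_init__(self) -> None:
        if self.pulse_mode not in ("peak", "difference", "absolute"):
            raise ValueError(
                "pulse_mode must be 'peak', 'difference' or 'absolute'"
            )


@dataclass
class ProbeFeatureSeries:
    """Per-cycle (t_center, V_subthr, V_pulse) measurements with QC."""

    cycle: np.ndarray
    t_center_ms: np.ndarray
    V_subthr_mV: np.ndarray
    V_pulse_mV: np.ndarray
    qc: np.ndarray  # str flags; "ok" for usable cycles

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t_center_ms) <= 0):
            raise ValueError("cycle times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.cycle)

    @property
    def ok(self) -> np.ndarray:
        return self.qc == QC_OK

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": self.cycle,
                "t_ms": self.t_center_ms,
                "Vsubthr_mV": self.V_subthr_mV,
                "Vpulse_mV": self.V_pulse_mV,
                "qc": self.qc,
            }
        )


def extract_features(
    trace: VoltageTrace,
    markers: CycleMarkers,
    cfg: FeatureConfig | None = None,
) -> ProbeFeatureSeries:
    """Measure (V_subthr, V_pulse) for every meander cycle.

    ``V_pulse_i = V(t_pulse_end_i) - V(t_start_i)`` (or the absolute
    end voltage, per config); ``V_subthr_i`` is the mean of V over
    ``[t_neg_end_i + settle, t_cycle_end_i)`` with spike-contaminated
    samples excluded.  Cycles without a probe spike, with an empty
    averaging window, or with excessive contamination keep their row
    but carry a non-"ok" QC flag and NaN features where undefined.
    """
    if cfg is None:
        cfg = FeatureConfig()
    dt = trace.dt_ms
    V = trace.V_mV
    n = len(markers)
    t_center = np.empty(n)
    v_sub = np.full(n, np.nan)
    v_pul = np.full(n, np.nan)
    qc = np.full(n, QC_OK, dtype=object)

    def sample(t_ms: float) -> int:
        return int(round((t_ms - trace.t0_ms) / dt))

    for i in range(n):
        k_start = sample(markers.t_start_ms[i])
        k_pulse = sample(markers.t_pulse_end_ms[i])
        k_lo = sample(markers.t_neg_end_ms[i] + cfg.settle_ms)
        k_hi = min(sample(markers.t_cycle_end_ms[i]), len(V))
        t_center[i] = 0.5 * (
            markers.t_neg_end_ms[i] + cfg.settle_ms + markers.t_cycle_end_ms[i]
        )
        if cfg.pulse_mode == "peak":
            k_neg = max(sample(markers.t_neg_end_ms[i]), k_pulse + 1)
            v_pul[i] = float(np.max(V[k_start : min(k_neg, len(V))]))
        elif cfg.pulse_mode == "difference":
            v_pul[i] = V[k_pulse] - V[k_start]
        else:
            v_pul[i] = V[k_pulse]
        if not markers.spike_ok[i]:
            qc[i] = QC_NO_SPIKE
            continue
        if k_lo >= k_hi:
            qc[i] = QC_EMPTY_WINDOW
            continue
        window = V[k_lo:k_hi]
        keep = window <= cfg.spike_threshold_mV
        if np.mean(~keep) > cfg.max_excluded_frac:
            qc[i] = QC_SPIKE_CONTAMINATED
            continue
        v_sub[i] = float(np.mean(window[keep]))

    return ProbeFeatureSeries(
        cycle=markers.index.copy(),
        t_center_ms=t_center,
        V_subthr_mV=v_sub,
        V_pulse_mV=v_pul,
        qc=qc.astype(str),
    )
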