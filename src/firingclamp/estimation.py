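"""Per-cycle inverse problem and E/I decomposition.

Given the fitted calibration surfaces, each measured pair
(V_subthr_i, V_pulse_i) is inverted to the control signals (I_i, G_i):
for bilinear surfaces the 2x2 system reduces in closed form to a single
quadratic in G.  The control signals are then decomposed into excitatory
and inhibitory conductances with known reversal potentials,

    G_E = (I - G (V_I - V_0)) / (V_E - V_I),   G_I = G - G_E,

supporting a per-cycle (time-varying) inhibitory reversal V_I.  The
expected unclamped membrane voltage is reconstructed as the
conductance-weighted mean of the reversal potentials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import CalibrationSurface
from .features import ProbeFeatureSeries, extract_features, FeatureConfig
from .neuron import VoltageTrace
from .protocol import CycleMarkers

__all__ = [
    "ReversalSpec",
    "EstimateSeries",
    "invert_features",
    "align_subthr_epoch",
    "DEFAULT_EPOCH_WEIGHT",
    "decompose",
    "compose",
    "reconstruct_voltage",
    "estimate_pipeline",
]

STATUS_OK = "ok"
STATUS_FAILED = "failed"
STATUS_BAD_FEATURE = "bad_feature"


@dataclass(frozen=True)
class ReversalSpec:
    """Reversal potentials for the two-conductance decomposition.

    V_E_mV and V_I_mV are the excitatory and inhibitory synaptic
    reversals; V_0_mV is the resting potential from which the current
    control signal is measured.  V_I may be overridden per cycle.
    """

    V_E_mV: float = 0.0
    V_I_mV: float = -74.0
    V_0_mV: float = -77.0

    def __post_init__(self) -> None:
        if abs(self.V_E_mV - self.V_I_mV) < 1.0:
            raise ValueError(
                "|V_E - V_I| < 1 mV: decomposition is ill-conditioned"
            )


@dataclass
class EstimateSeries:
    """Per-cycle (I, G, G_E, G_I) estimates with solver status.

    ``G = G_E + G_I`` holds exactly by construction.  Negative
    conductance estimates are reported as-is; clipping is left to
    display code so that estimation error stays visible.
    """

    t_ms: np.ndarray
    I_pA: np.ndarray
    G_nS: np.ndarray
    G_E_nS: np.ndarray
    G_I_nS: np.ndarray
    status: np.ndarray
    rev: ReversalSpec | None = None

    def __len__(self) -> int:
        return len(self.t_ms)

    @property
    def ok(self) -> np.ndarray:
        return self.status == STATUS_OK

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_ms": self.t_ms,
                "I_pA": self.I_pA,
                "G_nS": self.G_nS,
                "GE_nS": self.G_E_nS,
                "GI_nS": self.G_I_nS,
                "status": self.status,
            }
        )


# ---------------------------------------------------------------------------
# Inversion
# ---------------------------------------------------------------------------

_RESIDUAL_TOL_MV = 1e-6
#: Roots farther outside the fit domain than this fraction of its width
#: are considered spurious.
_DOMAIN_MARGIN = 0.5


def _solve_I(
    surface: CalibrationSurface, G: float, V_subthr: float, V_pulse: float
) -> float:
    """Back-substitute I given G, using the better-conditioned equation."""
    s, p = surface.subthr, surface.pulse
    den_s = s.a_IG * G + s.a_I
    den_p = p.a_IG * G + p.a_I
    if abs(den_s) >= abs(den_p):
        return (V_subthr - s.a_0 - s.a_G * G) / den_s
    return (V_pulse - p.a_0 - p.a_G * G) / den_p


def invert_features(
    surface: CalibrationSurface,
    V_subthr_mV: float,
    V_pulse_mV: float,
    *,
    previous: tuple[float, float] | None = None,
) -> tuple[float, float, str]:
    """Solve (V_subthr, V_pulse) -> (I, G) on a bilinear surface pair.

    Eliminating I reduces the system to one quadratic in G.  Root
    selection: prefer a root inside the calibration domain; with two
    admissible roots take the one closer to ``previous`` (temporal
    continuity) or, lacking that, to the domain center.  Returns
    (I_pA, G_nS, status); on failure the values are NaN.
    """
    if surface.form != "bilinear4":
        return _invert_iterative(surface, V_subthr_mV, V_pulse_mV, previous)
    s, p = surface.subthr, surface.pulse
    a, b, c, d = s.a_IG, s.a_I, s.a_G, s.a_0
    e, f, g, h = p.a_IG, p.a_I, p.a_G, p.a_0
    ys = V_subthr_mV - d
    yp = V_pulse_mV - h
    # (e G + f)(ys - c G) = (yp - g G)(a G + b)  ->  A G^2 + B G + C = 0
    A = -e * c + g * a
    B = e * ys - f * c + g * b - a * yp
    C = f * ys - b * yp
    roots: list[float] = []
    if abs(A) < 1e-14 * max(1.0, abs(B), abs(C)):
        if B != 0.0:
            roots = [-C / B]
    else:
        disc = B * B - 4.0 * A * C
        if disc >= 0.0:
            sq = math.sqrt(disc)
            if B == 0.0:
                roots = [sq / (2.0 * A), -sq / (2.0 * A)]
            else:
                # numerically stable pair
                q = -0.5 * (B + math.copysign(sq, B))
                roots = [q / A, (C / q) if q != 0.0 else 0.0]

    g_lo, g_hi = surface.G_domain_nS
    width = g_hi - g_lo
    admissible = [
        r for r in roots if g_lo - _DOMAIN_MARGIN * width <= r <= g_hi + _DOMAIN_MARGIN * width
    ]
    if not admissible:
        return float("nan"), float("nan"), STATUS_FAILED
    inside = [r for r in admissible if g_lo <= r <= g_hi]
    pool = inside if inside else admissible
    if len(pool) == 1:
        G = pool[0]
    else:
        if previous is not None and math.isfinite(previous[1]):
            target = previous[1]
        else:
            target = surface.domain_center()[1]
        G = min(pool, key=lambda r: abs(r - target))
    I = _solve_I(surface, G, V_subthr_mV, V_pulse_mV)
    r1 = abs(s(I, G) - V_subthr_mV)
    r2 = abs(p(I, G) - V_pulse_mV)
    if not (math.isfinite(I) and r1 < _RESIDUAL_TOL_MV and r2 < _RESIDUAL_TOL_MV):
        return float("nan"), float("nan"), STATUS_FAILED
    return float(I), float(G), STATUS_OK


def _invert_iterative(
    surface: CalibrationSurface,
    V_subthr: float,
    V_pulse: float,
    previous: tuple[float, float] | None,
) -> tuple[float, float, str]:
    """Newton solve for non-bilinear (quadratic6) surfaces."""
    from scipy.optimize import fsolve

    s, p = surface.subthr, surface.pulse
    if previous is not None and all(math.isfinite(v) for v in previous):
        x0 = list(previous)
    else:
        x0 = list(surface.domain_center())

    def fun(x):
        return [s(x[0], x[1]) - V_subthr, p(x[0], x[1]) - V_pulse]

    sol, info, ier, _ = fsolve(fun, x0, full_output=True)
    I, G = float(sol[0]), float(sol[1])
    res = max(abs(v) for v in fun((I, G)))
    g_lo, g_hi = surface.G_domain_nS
    width = g_hi - g_lo
    if ier != 1 or res > _RESIDUAL_TOL_MV or not (
        g_lo - _DOMAIN_MARGIN * width <= G <= g_hi + _DOMAIN_MARGIN * width
    ):
        return float("nan"), float("nan"), STATUS_FAILED
    return I, G, STATUS_OK


# ---------------------------------------------------------------------------
# E/I decomposition and composition
# ---------------------------------------------------------------------------

def decompose(
    I_pA,
    G_nS,
    rev: ReversalSpec,
    *,
    V_I_mV=None,
):
    """Map control signals to (G_E, G_I) with known reversal potentials.

    ``V_I_mV`` optionally overrides the spec's inhibitory reversal,
    scalar or element-wise (time-varying V_I).
    """
    I = np.asarray(I_pA, dtype=float)
    G = np.asarray(G_nS, dtype=float)
    VI = rev.V_I_mV if V_I_mV is None else np.asarray(V_I_mV, dtype=float)
    if np.any(np.abs(rev.V_E_mV - VI) < 1.0):
        raise ValueError("|V_E - V_I| < 1 mV: decomposition is ill-conditioned")
    G_E = (I - G * (VI - rev.V_0_mV)) / (rev.V_E_mV - VI)
    G_I = G - G_E
    if np.ndim(G_E) == 0:
        return float(G_E), float(G_I)
    return G_E, G_I


def compose(G_E_nS, G_I_nS, rev: ReversalSpec, *, V_I_mV=None):
    """Forward control-signal equations: G = G_E + G_I and
    I = G_E (V_E - V_0) + G_I (V_I - V_0)."""
    G_E = np.asarray(G_E_nS, dtype=float)
    G_I = np.asarray(G_I_nS, dtype=float)
    if np.any(G_E < 0) or np.any(G_I < 0):
        import warnings

        warnings.warn("negative conductance passed to compose", stacklevel=2)
    VI = rev.V_I_mV if V_I_mV is None else np.asarray(V_I_mV, dtype=float)
    I = G_E * (rev.V_E_mV - rev.V_0_mV) + G_I * (VI - rev.V_0_mV)
    G = G_E + G_I
    if np.ndim(I) == 0:
        return float(I), float(G)
    return I, G


def reconstruct_voltage(G_0_nS, rev: ReversalSpec, G_E_nS, G_I_nS, *, V_I_mV=None):
    """Conductance-weighted steady-state voltage
    (G_0 V_0 + G_E V_E + G_I V_I) / (G_0 + G_E + G_I)."""
    G_E = np.asarray(G_E_nS, dtype=float)
    G_I = np.asarray(G_I_nS, dtype=float)
    VI = rev.V_I_mV if V_I_mV is None else np.asarray(V_I_mV, dtype=float)
    denom = G_0_nS + G_E + G_I
    if np.any(denom <= 0):
        raise ValueError("total conductance must be positive")
    V = (G_0_nS * rev.V_0_mV + G_E * rev.V_E_mV + G_I * VI) / denom
    return float(V) if np.ndim(V) == 0 else V


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

#: Default blend weight aligning the subthreshold feature to the probe
#: spike's intra-cycle epoch (see estimate_pipeline).
DEFAULT_EPOCH_WEIGHT = 0.4


def align_subthr_epoch(
    features: ProbeFeatureSeries, weight: float = DEFAULT_EPOCH_WEIGHT
) -> ProbeFeatureSeries:
    """Refer both probe features to a common intra-cycle epoch.

    V_pulse senses the synaptic state at the probe spike (~1 ms into the
    cycle) while V_subthr senses the late zero-current window (~4 ms).
    For inputs changing on a per-cycle time scale (gamma band) the
    mismatch leaks a quadrature copy of fast excitation into the
    conductance channel.  Blending ``weight`` of the previous cycle's
    V_subthr into the current one shifts its effective epoch earlier,
    toward the spike; weight 0 disables the correction.
    """
    if not 0.0 <= weight < 1.0:
        raise ValueError("epoch weight must be in [0, 1)")
    vs = features.V_subthr_mV.copy()
    vs[1:] = weight * features.V_subthr_mV[:-1] + (1 - weight) * features.V_subthr_mV[1:]
    return ProbeFeatureSeries(
        cycle=features.cycle.copy(),
        t_center_ms=features.t_center_ms.copy(),
        V_subthr_mV=vs,
        V_pulse_mV=features.V_pulse_mV.copy(),
        qc=features.qc.copy(),
    )


def estimate_pipeline(
    trace: VoltageTrace,
    markers: CycleMarkers,
    surface: CalibrationSurface,
    rev: ReversalSpec,
    *,
    feature_cfg: FeatureConfig | None = None,
    features: ProbeFeatureSeries | None = None,
    V_I_per_cycle: np.ndarray | None = None,
    epoch_weight: float = DEFAULT_EPOCH_WEIGHT,
) -> EstimateSeries:
    """Features -> inversion -> E/I decomposition, one row per cycle.

    Failed cycles (QC-flagged features or inversion failure) are carried
    through with NaN values and a non-"ok" status, never dropped.
    ``V_I_per_cycle`` supplies a time-varying inhibitory reversal
    aligned to cycle order.  ``epoch_weight`` applies
    :func:`align_subthr_epoch` before inversion (0 disables).
    """
    if features is None:
        features = extract_features(trace, markers, feature_cfg)
    if epoch_weight:
        features = align_subthr_epoch(features, epoch_weight)
    n = len(features)
    if V_I_per_cycle is not None and len(V_I_per_cycle) != n:
        raise ValueError("V_I_per_cycle must have one entry per cycle")
    I_out = np.full(n, np.nan)
    G_out = np.full(n, np.nan)
    GE_out = np.full(n, np.nan)
    GI_out = np.full(n, np.nan)
    status = np.full(n, STATUS_OK, dtype=object)
    prev: tuple[float, float] | None = None
    for i in range(n):
        if features.qc[i] != "ok" or not (
            math.isfinite(features.V_subthr_mV[i])
            and math.isfinite(features.V_pulse_mV[i])
        ):
            status[i] = STATUS_BAD_FEATURE
            continue
        I, G, st = invert_features(
            surface,
            features.V_subthr_mV[i],
            features.V_pulse_mV[i],
            previous=prev,
        )
        status[i] = st
        if st != STATUS_OK:
            continue
        I_out[i], G_out[i] = I, G
        prev = (I, G)
        VI = None if V_I_per_cycle is None else float(V_I_per_cycle[i])
        GE_out[i], GI_out[i] = decompose(I, G, rev, V_I_mV=VI)
    return EstimateSeries(
        t_ms=features.t_center_ms.copy(),
        I_pA=I_out,
        G_nS=G_out,
        G_E_nS=GE_out,
        G_I_nS=GI_out,
        status=status.astype(str),
        rev=rev,
    )
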