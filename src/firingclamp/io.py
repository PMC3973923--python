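"""File interfaces: columnar CSV for time series and tables, JSON for
calibration surfaces, YAML for run configuration.

Column names carry units and are part of the contract:

* trace:     ``t_ms,V_mV,Iinj_pA``  (optional HDF5 with the same names)
* controls:  ``t_ms,I_pA,G_nS`` (+ optional ``VI_mV``)
* features:  ``cycle,t_ms,Vsubthr_mV,Vpulse_mV,qc``
* estimates: ``t_ms,I_pA,G_nS,GE_nS,GI_nS,status``
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .calibration import CalibrationSurface, surface_from_json, surface_to_json
from .estimation import EstimateSeries, ReversalSpec
from .features import ProbeFeatureSeries
from .neuron import NeuronParams, VoltageTrace
from .protocol import ControlSignals, MeanderConfig

__all__ = [
    "read_trace",
    "write_trace",
    "read_controls",
    "write_controls",
    "read_features",
    "write_features",
    "read_estimates",
    "write_estimates",
    "read_surface",
    "write_surface",
    "load_config",
    "RunConfig",
    "ConfigError",
]


class ConfigError(ValueError):
    """Malformed configuration or file header."""


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...], path: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ConfigError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )


def _infer_dt(t: np.ndarray, path: str) -> float:
    if len(t) < 2:
        raise ConfigError(f"{path}: need at least two samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=0, atol=1e-9 + 1e-6 * dt[0]):
        raise ConfigError(f"{path}: time column is not uniformly sampled")
    return float(dt[0])


# -- voltage traces ---------------------------------------------------------

def write_trace(path: str, trace: VoltageTrace) -> None:
    if str(path).endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("t_ms", data=trace.t_ms)
            f.create_dataset("V_mV", data=trace.V_mV)
            f.create_dataset("Iinj_pA", data=trace.Iinj_pA)
        return
    pd.DataFrame(
        {"t_ms": trace.t_ms, "V_mV": trace.V_mV, "Iinj_pA": trace.Iinj_pA}
    ).to_csv(path, index=False, float_format="%.17g")


def read_trace(path: str) -> VoltageTrace:
    if str(path).endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "r") as f:
            for name in ("t_ms", "V_mV", "Iinj_pA"):
                if name not in f:
                    raise ConfigError(f"{path}: missing dataset {name!r}")
            t = f["t_ms"][:]
            V = f["V_mV"][:]
            I = f["Iinj_pA"][:]
    else:
        df = pd.read_csv(path, float_precision="round_trip")
        _require_columns(df, ("t_ms", "V_mV", "Iinj_pA"), str(path))
        t = df["t_ms"].to_numpy()
        V = df["V_mV"].to_numpy()
        I = df["Iinj_pA"].to_numpy()
    dt = _infer_dt(t, str(path))
    return VoltageTrace(dt_ms=dt, V_mV=V, Iinj_pA=I, t0_ms=float(t[0]))


# -- control signals --------------------------------------------------------

def write_controls(path: str, signals: ControlSignals) -> None:
    t = np.arange(len(signals)) * signals.dt_ms
    data = {"t_ms": t, "I_pA": signals.I_pA, "G_nS": signals.G_nS}
    if signals.V_I_mV is not None:
        data["VI_mV"] = signals.V_I_mV
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def read_controls(path: str) -> ControlSignals:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ("t_ms", "I_pA", "G_nS"), str(path))
    dt = _infer_dt(df["t_ms"].to_numpy(), str(path))
    return ControlSignals(
        dt_ms=dt,
        I_pA=df["I_pA"].to_numpy(),
        G_nS=df["G_nS"].to_numpy(),
        V_I_mV=df["VI_mV"].to_numpy() if "VI_mV" in df.columns else None,
    )


# -- feature tables ---------------------------------------------------------

def write_features(path: str, feats: ProbeFeatureSeries) -> None:
    feats.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_features(path: str) -> ProbeFeatureSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(
        df, ("cycle", "t_ms", "Vsubthr_mV", "Vpulse_mV", "qc"), str(path)
    )
    return ProbeFeatureSeries(
        cycle=df["cycle"].to_numpy(),
        t_center_ms=df["t_ms"].to_numpy(dtype=float),
        V_subthr_mV=df["Vsubthr_mV"].to_numpy(dtype=float),
        V_pulse_mV=df["Vpulse_mV"].to_numpy(dtype=float),
        qc=df["qc"].to_numpy(dtype=str),
    )


# -- estimate tables --------------------------------------------------------

def write_estimates(path: str, est: EstimateSeries) -> None:
    est.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_estimates(path: str) -> EstimateSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(
        df, ("t_ms", "I_pA", "G_nS", "GE_nS", "GI_nS", "status"), str(path)
    )
    return EstimateSeries(
        t_ms=df["t_ms"].to_numpy(dtype=float),
        I_pA=df["I_pA"].to_numpy(dtype=float),
        G_nS=df["G_nS"].to_numpy(dtype=float),
        G_E_nS=df["GE_nS"].to_numpy(dtype=float),
        G_I_nS=df["GI_nS"].to_numpy(dtype=float),
        status=df["status"].to_numpy(dtype=str),
    )


# -- calibration surfaces ---------------------------------------------------

def write_surface(path: str, surface: CalibrationSurface) -> None:
    with open(path, "w") as f:
        f.write(surface_to_json(surface))


def read_surface(path: str) -> CalibrationSurface:
    with open(path) as f:
        return surface_from_json(f.read())


# -- run configuration ------------------------------------------------------

@dataclass
class RunConfig:
    """Top-level run configuration (YAML)."""

    neuron: NeuronParams = field(default_factory=NeuronParams)
    protocol: MeanderConfig = field(default_factory=MeanderConfig)
    reversals: ReversalSpec = field(default_factory=ReversalSpec)
    seed: int = 0
    outdir: str = "."


def _build(cls, block: dict, name: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in config block {name!r}; "
            f"allowed: {sorted(allowed)}"
        )
    try:
        return cls(**block)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"invalid config block {name!r}: {e}") from e


def load_config(path: str) -> RunConfig:
    """Load a YAML run configuration; unknown keys are rejected."""
    import yaml

    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    known = {"neuron", "protocol", "reversals", "seed", "outdir"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(
            f"{path}: unknown top-level key(s) {sorted(unknown)}; "
            f"allowed: {sorted(known)}"
        )
    return RunConfig(
        neuron=_build(NeuronParams, raw.get("neuron", {}) or {}, "neuron"),
        protocol=_build(MeanderConfig, raw.get("protocol", {}) or {}, "protocol"),
        reversals=_build(ReversalSpec, raw.get("reversals", {}) or {}, "reversals"),
        seed=int(raw.get("seed", 0)),
        outdir=str(raw.get("outdir", ".")),
    )
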