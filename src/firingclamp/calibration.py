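"""Calibration of the probe-feature response surfaces.

During calibration, slow sinusoidal current ``I(t)`` and conductance
``G(t)`` are injected through the dynamic clamp on top of the meander,
and the per-cycle features (V_subthr, V_pulse) are regressed on the
per-cycle means of (I, G) by ordinary least squares.  Each surface is a
"quadratic polynomial" in the bilinear sense

    V(I, G) = a_IG * I * G + a_I * I + a_G * G + a_0,

matching the worked-example surfaces
V_subthr = 0.002 I G + 0.079 I + 0.8 G - 76.8 and
V_pulse  = -0.0039 I G + 0.0477 I - 0.49 G - 34.9
(voltage in mV, current in pA, conductance in nS); the full six-term
quadratic (adding I^2 and G^2) is available as ``form="quadratic6"``.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import ProbeFeatureSeries
from .protocol import ControlSignals, CycleMarkers

__all__ = [
    "SurfaceCoeffs",
    "CalibrationSurface",
    "CalibrationModel",
    "CalibrationResult",
    "make_calibration_signals",
    "cycle_average_controls",
    "fit_surfaces",
    "evaluate_surface",
    "FIG1_SURFACE",
]

_TERMS = {
    "bilinear4": ("a_IG", "a_I", "a_G", "a_0"),
    "quadratic6": ("a_IG", "a_I", "a_G", "a_0", "a_II", "a_GG"),
}


def _design(I: np.ndarray, G: np.ndarray, form: str) -> np.ndarray:
    cols = [I * G, I, G, np.ones_like(I)]
    if form == "quadratic6":
        cols += [I * I, G * G]
    elif form != "bilinear4":
        raise ValueError(f"unknown surface form {form!r}")
    return np.column_stack(cols)


@dataclass(frozen=True)
class SurfaceCoeffs:
    """Polynomial coefficients of one feature surface (mV, pA, nS units)."""

    a_IG: float
    a_I: float
    a_G: float
    a_0: float
    a_II: float = 0.0
    a_GG: float = 0.0

    def __call__(self, I_pA, G_nS):
        I = np.asarray(I_pA, dtype=float)
        G = np.asarray(G_nS, dtype=float)
        out = (
            self.a_IG * I * G
            + self.a_I * I
            + self.a_G * G
            + self.a_0
            + self.a_II * I * I
            + self.a_GG * G * G
        )
        return float(out) if out.ndim == 0 else out

    def to_dict(self) -> dict[str, float]:
        return {
            "a_IG_mV_per_pA_nS": self.a_IG,
            "a_I_mV_per_pA": self.a_I,
            "a_G_mV_per_nS": self.a_G,
            "a_0_mV": self.a_0,
            "a_II_mV_per_pA2": self.a_II,
            "a_GG_mV_per_nS2": self.a_GG,
        }


@dataclass(frozen=True)
class CalibrationSurface:
    """Fitted (I, G) -> feature surfaces plus fit diagnostics.

    ``subthr`` and ``pulse`` map injected current (pA) and conductance
    (nS) to the respective probe-spike feature (mV).  The fit domain is
    the bounding box of the calibration points; evaluating outside it is
    allowed but flagged by :func:`evaluate_surface`.
    """

    subthr: SurfaceCoeffs
    pulse: SurfaceCoeffs
    form: str = "bilinear4"
    I_domain_pA: tuple[float, float] = (-10.0, 65.0)
    G_domain_nS: tuple[float, float] = (0.0, 2.8)
    residual_rms_mV: tuple[float, float] = (float("nan"), float("nan"))
    n_points: int = 0

    def __post_init__(self) -> None:
        if not (
            self.I_domain_pA[1] > self.I_domain_pA[0]
            and self.G_domain_nS[1] > self.G_domain_nS[0]
        ):
            raise ValueError("fit domain must be non-degenerate")

    def in_domain(self, I_pA: float, G_nS: float) -> bool:
        return (
            self.I_domain_pA[0] <= I_pA <= self.I_domain_pA[1]
            and self.G_domain_nS[0] <= G_nS <= self.G_domain_nS[1]
        )

    def domain_center(self) -> tuple[float, float]:
        return (
            0.5 * (self.I_domain_pA[0] + self.I_domain_pA[1]),
            0.5 * (self.G_domain_nS[0] + self.G_domain_nS[1]),
        )


#: Worked-example surfaces (perforated-patch cell, Fig.-style legend values).
FIG1_SURFACE = CalibrationSurface(
    subthr=SurfaceCoeffs(a_IG=0.002, a_I=0.079, a_G=0.8, a_0=-76.8),
    pulse=SurfaceCoeffs(a_IG=-0.0039, a_I=0.0477, a_G=-0.49, a_0=-34.9),
)


def evaluate_surface(
    surface: CalibrationSurface, I_pA: float, G_nS: float
) -> tuple[float, float]:
    """Evaluate both feature surfaces at (I, G); warns on extrapolation."""
    if not surface.in_domain(I_pA, G_nS):
        warnings.warn(
            f"evaluating calibration surface outside its fit domain "
            f"(I={I_pA:g} pA, G={G_nS:g} nS)",
            stacklevel=2,
        )
    return surface.subthr(I_pA, G_nS), surface.pulse(I_pA, G_nS)


# ---------------------------------------------------------------------------
# Calibration stimulus
# ---------------------------------------------------------------------------

def _commensurate(a: float, b: float, max_term: int = 64) -> bool:
    """True if a/b is (close to) a rational with small numerator AND
    denominator; such period pairs retrace after few cycles."""
    from fractions import Fraction

    frac = Fraction(a / b).limit_denominator(max_term)
    return frac.numerator <= max_term and math.isclose(
        a / b, float(frac), rel_tol=1e-9
    )


def make_calibration_signals(
    periods_ms: tuple[float, float] = (40.0, 70.0),
    I_range_pA: tuple[float, float] = (-10.0, 65.0),
    G_range_nS: tuple[float, float] = (0.0, 2.8),
    duration_ms: float = 2000.0,
    dt_ms: float = 0.03,
    *,
    probe_period_ms: float = 5.0,
    phases_rad: tuple[float, float] = (0.0, math.pi / 3),
) -> ControlSignals:
    """Slow sinusoidal (I, G) calibration stimulus.

    The sinusoids span the stated ranges; G is clipped at zero.  Periods
    that are commensurate with each other or with the probe period make
    the per-cycle (I, G) points retrace a closed Lissajous figure and
    cover the plane sparsely; such choices trigger a warning.
    """
    if not (I_range_pA[1] > I_range_pA[0] and G_range_nS[1] >= G_range_nS[0]):
        raise ValueError("degenerate calibration range")
    TI, TG = periods_ms
    if _commensurate(TI, TG):
        warnings.warn(
            f"calibration periods {TI} and {TG} ms are commensurate; "
            "the (I, G) points will retrace a closed curve",
            stacklevel=2,
        )
    for T in (TI, TG):
        if _commensurate(T, probe_period_ms):
            warnings.warn(
                f"calibration period {T} ms is commensurate with the "
                f"{probe_period_ms} ms probe period; per-cycle means will "
                "take few distinct values",
                stacklevel=2,
            )
    n = int(round(duration_ms / dt_ms))
    t = np.arange(n) * dt_ms
    I_mid = 0.5 * (I_range_pA[0] + I_range_pA[1])
    I_amp = 0.5 * (I_range_pA[1] - I_range_pA[0])
    G_mid = 0.5 * (G_range_nS[0] + G_range_nS[1])
    G_amp = 0.5 * (G_range_nS[1] - G_range_nS[0])
    I = I_mid + I_amp * np.sin(2 * np.pi * t / TI + phases_rad[0])
    G = np.clip(G_mid + G_amp * np.sin(2 * np.pi * t / TG + phases_rad[1]), 0.0, None)
    return ControlSignals(dt_ms=dt_ms, I_pA=I, G_nS=G)


def cycle_average_controls(
    inputs: ControlSignals, markers: CycleMarkers
) -> pd.DataFrame:
    """Mean of I and G over each cycle window [t_start, t_cycle_end)."""
    dt = inputs.dt_ms
    n = len(inputs)
    rows = []
    for i in range(len(markers)):
        k0 = int(round(markers.t_start_ms[i] / dt))
        k1 = int(round(markers.t_cycle_end_ms[i] / dt))
        if k1 > n:
            raise ValueError("control signals do not cover all cycles")
        row = {
            "cycle": int(markers.index[i]),
            "I_pA": float(np.mean(inputs.I_pA[k0:k1])),
            "G_nS": float(np.mean(inputs.G_nS[k0:k1])),
        }
        if inputs.V_I_mV is not None:
            row["V_I_mV"] = float(np.mean(inputs.V_I_mV[k0:k1]))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Surface fitting (Model / Results)
# ---------------------------------------------------------------------------

class CalibrationModel:
    """OLS regression of probe features on per-cycle control signals.

    Parameters
    ----------
    features : ProbeFeatureSeries
        Per-cycle measurements; only unflagged ("ok") cycles enter the fit.
    controls : DataFrame
        Per-cycle mean (I_pA, G_nS), as from :func:`cycle_average_controls`.
    """

    def __init__(self, features: ProbeFeatureSeries, controls: pd.DataFrame):
        merged = features.to_frame().merge(controls, on="cycle")
        merged = merged[merged["qc"] == "ok"].reset_index(drop=True)
        self.data = merged
        self.I = merged["I_pA"].to_numpy()
        self.G = merged["G_nS"].to_numpy()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CalibrationModel":
        """Build from a table with columns Vsubthr_mV, Vpulse_mV, I_pA, G_nS."""
        need = {"Vsubthr_mV", "Vpulse_mV", "I_pA", "G_nS"}
        missing = need - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        df = df.copy()
        if "cycle" not in df:
            df["cycle"] = np.arange(len(df))
        if "qc" not in df:
            df["qc"] = "ok"
        if "t_ms" not in df:
            df["t_ms"] = df["cycle"].astype(float)
        feats = ProbeFeatureSeries(
            cycle=df["cycle"].to_numpy(),
            t_center_ms=df["t_ms"].to_numpy(dtype=float),
            V_subthr_mV=df["Vsubthr_mV"].to_numpy(dtype=float),
            V_pulse_mV=df["Vpulse_mV"].to_numpy(dtype=float),
            qc=df["qc"].to_numpy(dtype=str),
        )
        controls = df[["cycle", "I_pA", "G_nS"]]
        return cls(feats, controls)

    def fit(self, form: str = "bilinear4") -> "CalibrationResult":
        terms = _TERMS.get(form)
        if terms is None:
            raise ValueError(f"unknown surface form {form!r}")
        n_coef = len(terms)
        if len(self.data) < n_coef:
            raise ValueError(
                f"{len(self.data)} usable calibration points < {n_coef} coefficients"
            )
        if len(self.data) < 10 * n_coef:
            warnings.warn(
                f"only {len(self.data)} calibration points for {n_coef} "
                "coefficients; >= 10x is recommended",
                stacklevel=2,
            )
        X = _design(self.I, self.G, form)
        rank = np.linalg.matrix_rank(X)
        if rank < n_coef:
            raise np.linalg.LinAlgError(
                f"rank-deficient calibration design (rank {rank} < {n_coef}); "
                "the (I, G) points are degenerate (e.g. collinear)"
            )
        params = {}
        bse = {}
        rms = []
        resid = {}
        for name, col in (("subthr", "Vsubthr_mV"), ("pulse", "Vpulse_mV")):
            y = self.data[col].to_numpy(dtype=float)
            beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ beta
            dof = max(len(y) - n_coef, 1)
            sigma2 = float(r @ r) / dof
            XtX_inv = np.linalg.pinv(X.T @ X)
            params[name] = beta
            bse[name] = np.sqrt(np.maximum(sigma2 * np.diag(XtX_inv), 0.0))
            rms.append(float(np.sqrt(np.mean(r**2))))
            resid[name] = r
        surface = CalibrationSurface(
            subthr=SurfaceCoeffs(**dict(zip(terms, params["subthr"]))),
            pulse=SurfaceCoeffs(**dict(zip(terms, params["pulse"]))),
            form=form,
            I_domain_pA=(float(self.I.min()), float(self.I.max())),
            G_domain_nS=(float(self.G.min()), float(self.G.max())),
            residual_rms_mV=(rms[0], rms[1]),
            n_points=len(self.data),
        )
        return CalibrationResult(
            model=self,
            surface=surface,
            term_names=terms,
            params=params,
            bse=bse,
            resid=resid,
        )


@dataclass
class CalibrationResult:
    """Fitted calibration surfaces with OLS uncertainties."""

    model: CalibrationModel
    surface: CalibrationSurface
    term_names: tuple[str, ...]
    params: dict[str, np.ndarray]
    bse: dict[str, np.ndarray]
    resid: dict[str, np.ndarray]

    def summary(self) -> str:
        lines = [
            "Calibration surface fit (OLS)",
            f"  form: {self.surface.form}   n points: {self.surface.n_points}",
            f"  I domain: [{self.surface.I_domain_pA[0]:.3g}, "
            f"{self.surface.I_domain_pA[1]:.3g}] pA   "
            f"G domain: [{self.surface.G_domain_nS[0]:.3g}, "
            f"{self.surface.G_domain_nS[1]:.3g}] nS",
        ]
        for j, name in enumerate(("subthr", "pulse")):
            lines.append(
                f"  V_{name}: residual RMS = "
                f"{self.surface.residual_rms_mV[j]:.4g} mV"
            )
            for k, term in enumerate(self.term_names):
                lines.append(
                    f"    {term:6s} = {self.params[name][k]: .6g} "
                    f"(SE {self.bse[name][k]:.2g})"
                )
        return "\n".join(lines)


def fit_surfaces(
    features: ProbeFeatureSeries,
    controls: pd.DataFrame,
    form: str = "bilinear4",
) -> CalibrationSurface:
    """Functional wrapper: fit both surfaces, return the surface object."""
    return CalibrationModel(features, controls).fit(form=form).surface


# ---------------------------------------------------------------------------
# Surface (de)serialization
# ---------------------------------------------------------------------------

def surface_to_json(surface: CalibrationSurface) -> str:
    obj = {
        "units": {"V": "mV", "I": "pA", "G": "nS"},
        "form": surface.form,
        "subthr": surface.subthr.to_dict(),
        "pulse": surface.pulse.to_dict(),
        "I_domain_pA": list(surface.I_domain_pA),
        "G_domain_nS": list(surface.G_domain_nS),
        "residual_rms_mV": list(surface.residual_rms_mV),
        "n_points": surface.n_points,
    }
    return json.dumps(obj, indent=2)


def surface_from_json(text: str) -> CalibrationSurface:
    obj = json.loads(text)
    def coeffs(d: dict[str, float]) -> SurfaceCoeffs:
        return SurfaceCoeffs(
            a_IG=d["a_IG_mV_per_pA_nS"],
            a_I=d["a_I_mV_per_pA"],
            a_G=d["a_G_mV_per_nS"],
            a_0=d["a_0_mV"],
            a_II=d.get("a_II_mV_per_pA2", 0.0),
            a_GG=d.get("a_GG_mV_per_nS2", 0.0),
        )
    try:
        return CalibrationSurface(
            subthr=coeffs(obj["subthr"]),
            pulse=coeffs(obj["pulse"]),
            form=obj.get("form", "bilinear4"),
            I_domain_pA=tuple(obj["I_domain_pA"]),
            G_domain_nS=tuple(obj["G_domain_nS"]),
            residual_rms_mV=tuple(obj.get("residual_rms_mV", (np.nan, np.nan))),
            n_points=int(obj.get("n_points", 0)),
        )
    except KeyError as e:
        raise ValueError(f"surface JSON missing field {e.args[0]!r}") from e
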