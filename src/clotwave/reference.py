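"""Thrombin-generation route: reference-curve construction and inversion.

For each sample, the measured thrombin curve drives forward simulations of
the polymerization model over a grid of candidate fibrinogen inputs.  The
resulting map from fibrinogen to simulated maximum attenuance increase is
the sample's *reference curve*; the fibrinogen estimate is obtained by
projecting the measured maximum turbidity increase onto that curve with a
monotone (PCHIP) interpolant.  Samples whose thrombin or turbidity signal
is atypically low are flagged and excluded from estimation rather than
forced through the inversion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from clotwave.kinetics import (
    EnzymeInput,
    KineticParameters,
    ModelError,
    simulate,
)
from clotwave.waveform import (
    SampleRecord,
    Waveform,
    WaveformError,
    attenuance_from_transparency,
    max_attenuance_increase,
)

DEFAULT_FIB_GRID = np.arange(0.5, 12.0 + 1e-9, 0.5)
DEFAULT_TG_GRID = np.arange(0.0, 900.0 + 1e-9, 30.0)

#: QC thresholds: minimum peak thrombin (nM) and minimum turbidity
#: increase (attenuance) for a sample to be considered typical.
THETA_PEAK_NM = 10.0
THETA_DELTA_A = 0.02


@dataclass(frozen=True)
class ReferenceCurve:
    """Monotone map fibrinogen (g/L) -> simulated max attenuance increase."""

    fib_grid: np.ndarray
    max_dA: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        f = np.asarray(self.fib_grid, dtype=float)
        a = np.asarray(self.max_dA, dtype=float)
        object.__setattr__(self, "fib_grid", f)
        object.__setattr__(self, "max_dA", a)
        if f.size != a.size or f.size < 4:
            raise ModelError("reference curve needs >= 4 matched points")
        if not np.all(np.diff(f) > 0):
            raise ModelError("fibrinogen grid must be strictly increasing")
        d = np.diff(a)
        if not np.all(d > 0):
            i = int(np.argmin(d))
            raise ModelError(
                "simulated max attenuance not strictly increasing between "
                f"{f[i]:.2f} and {f[i + 1]:.2f} g/L")


@dataclass(frozen=True)
class TGEstimate:
    """Outcome of the TG-route inference for one sample.

    ``fibrinogen`` is populated only when ``qc == "ok"``; otherwise the
    flag explains why no estimate was produced.  Diagnostics carry the
    peak thrombin (nM) and the measured maximum attenuance increase.
    """

    fibrinogen: Optional[float]
    qc: str
    peak_thrombin_nM: float
    measured_dA: float

    def __post_init__(self) -> None:
        if (self.qc == "ok") != (self.fibrinogen is not None):
            raise ModelError("fibrinogen present iff qc == 'ok'")


def build_reference_curve(thrombin: Waveform,
                          params: Optional[KineticParameters] = None,
                          fib_grid: Optional[Sequence[float]] = None,
                          t_grid: Optional[Sequence[float]] = None,
                          ) -> ReferenceCurve:
    """Simulate the polymer model over a fibrinogen grid.

    One forward simulation per grid point, all driven by the same thrombin
    curve; construction fails if the resulting maximum attenuance increase
    is not strictly increasing in fibrinogen.
    """
    if thrombin.kind != "thrombin":
        raise WaveformError("reference curve needs a thrombin waveform")
    p = params if params is not None else KineticParameters()
    grid = (np.asarray(fib_grid, dtype=float) if fib_grid is not None
            else DEFAULT_FIB_GRID.copy())
    if grid.size < 4:
        raise ModelError("fibrinogen grid needs >= 4 points")
    tg = (np.asarray(t_grid, dtype=float) if t_grid is not None
          else DEFAULT_TG_GRID.copy())
    enzyme = EnzymeInput(mode="TG_driven", curve=thrombin)
    max_da = np.empty_like(grid)
    for i, fib in enumerate(grid):
        res = simulate(float(fib), enzyme, p, tg, assay="TG")
        max_da[i] = max_attenuance_increase(res.attenuance)
    prov = f"params={p.digest()};thrombin={thrombin.sample_id or 'anon'}"
    return ReferenceCurve(fib_grid=grid, max_dA=max_da, provenance=prov)


def invert(ref: ReferenceCurve, measured_dA: float) -> float:
    """Project a measured max attenuance increase onto the reference curve.

    Monotone shape-preserving (PCHIP) interpolation of fibrinogen as a
    function of max attenuance increase.  Values outside the simulated
    range raise ``OutOfRangeError``: the model is not extrapolated beyond
    its validated grid.
    """
    lo, hi = float(ref.max_dA[0]), float(ref.max_dA[-1])
    if not (lo <= measured_dA <= hi):
        raise OutOfRangeError(
            f"measured attenuance increase {measured_dA:.4f} outside the "
            f"simulated range [{lo:.4f}, {hi:.4f}]")
    interp = PchipInterpolator(ref.max_dA, ref.fib_grid)
    return float(interp(measured_dA))


class OutOfRangeError(ModelError):
    """Measured turbidity increase lies outside the reference curve."""


def qc_atypical(tg: Waveform, turbidity: Waveform,
                theta_peak_nM: float = THETA_PEAK_NM,
                theta_dA: float = THETA_DELTA_A) -> str:
    """Flag atypical or very low thrombin-generation / turbidity curves.

    Returns ``"atypical_low_tg"`` when the peak thrombin is below
    ``theta_peak_nM``, ``"atypical_low_turbidity"`` when the maximum
    attenuance increase is below ``theta_dA``, else ``"ok"``.  The
    turbidity input may be transparency (converted internally) or
    attenuance.
    """
    if tg is None or turbidity is None:
        raise WaveformError("both thrombin and turbidity waveforms required")
    if tg.kind != "thrombin":
        raise WaveformError("tg waveform must be a thrombin curve")
    if float(np.max(tg.values)) < theta_peak_nM:
        return "atypical_low_tg"
    if _measured_dA(turbidity) < theta_dA:
        return "atypical_low_turbidity"
    return "ok"


def _measured_dA(turbidity: Waveform) -> float:
    if turbidity.kind == "transparency":
        turbidity = attenuance_from_transparency(turbidity)
    elif turbidity.kind != "attenuance":
        raise WaveformError("turbidity waveform must be transparency or "
                            "attenuance")
    return max_attenuance_increase(turbidity)


def infer_fibrinogen_tg(rec: SampleRecord,
                        params: Optional[KineticParameters] = None,
                        fib_grid: Optional[Sequence[float]] = None,
                        t_grid: Optional[Sequence[float]] = None,
                        theta_peak_nM: float = THETA_PEAK_NM,
                        theta_dA: float = THETA_DELTA_A) -> TGEstimate:
    """Full TG-route inference for one sample.

    QC first; if the curves are typical, a reference curve is built from
    the sample's own thrombin input and the measured maximum turbidity
    increase is inverted.  QC failures and out-of-range measurements
    return a flagged estimate with no fibrinogen value — they never raise.
    """
    thrombin = rec.waveforms.get("tg_thrombin")
    turbidity = rec.waveforms.get("tg_turbidity")
    if thrombin is None or turbidity is None:
        raise WaveformError(
            f"sample {rec.sample_id!r} lacks TG thrombin and/or turbidity "
            "waveforms")
    peak = float(np.max(thrombin.values))
    measured = _measured_dA(turbidity)
    qc = qc_atypical(thrombin, turbidity, theta_peak_nM, theta_dA)
    if qc != "ok":
        return TGEstimate(fibrinogen=None, qc=qc, peak_thrombin_nM=peak,
                          measured_dA=measured)
    ref = build_reference_curve(thrombin, params, fib_grid, t_grid)
    try:
        fib = invert(ref, measured)
    except OutOfRangeError:
        return TGEstimate(fibrinogen=None, qc="out_of_range",
                          peak_thrombin_nM=peak, measured_dA=measured)
    return TGEstimate(fibrinogen=fib, qc="ok", peak_thrombin_nM=peak,
                      measured_dA=measured)
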