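"""Waveform container and clot-waveform feature extraction.

A :class:`Waveform` holds a sampled optical or enzymatic time series from a
clotting assay: transmitted light ("transparency", mA), attenuance
(dimensionless optical density), or thrombin concentration (nM).  The module
provides resampling to a uniform grid, smoothed (Savitzky-Golay) derivatives,
the transparency/attenuance conversion, and extraction of the four waveform
features used by the fibrinogen estimators: minimum transparency, maximum
absolute transparency gradient, and the extrema of the second derivative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.signal import savgol_filter

VALID_KINDS = ("transparency", "attenuance", "thrombin", "fluorescence",
               "derivative")
VALID_ASSAYS = ("TG", "PT", "RT", "none")


class WaveformError(ValueError):
    """Invalid waveform input."""


@dataclass(frozen=True)
class Waveform:
    """A sampled assay time series.

    Parameters
    ----------
    times : array of float
        Sample times in seconds, strictly increasing, first time >= 0.
    values : array of float
        Signal values; units depend on ``kind`` (mA for transparency,
        dimensionless for attenuance, nM for thrombin).
    kind : str
        One of ``transparency``, ``attenuance``, ``thrombin``,
        ``fluorescence``.
    assay : str
        One of ``TG``, ``PT``, ``RT``, ``none``.
    sample_id : str
        Opaque sample label.
    """

    times: np.ndarray
    values: np.ndarray
    kind: str = "transparency"
    assay: str = "none"
    sample_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size:
            raise WaveformError("times and values must be 1-D and equal length")
        if t.size == 0:
            raise WaveformError("empty waveform")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise WaveformError("non-finite entries in waveform")
        if t[0] < 0:
            raise WaveformError("times must start at t >= 0")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise WaveformError("times must be strictly increasing")
        if self.kind not in VALID_KINDS:
            raise WaveformError(f"unknown kind {self.kind!r}")
        if self.assay not in VALID_ASSAYS:
            raise WaveformError(f"unknown assay {self.assay!r}")
        if self.kind in ("transparency", "attenuance") and np.any(v < 0):
            raise WaveformError(f"{self.kind} values must be >= 0")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def dt(self) -> Optional[float]:
        """Sampling interval if the grid is uniform, else ``None``."""
        if len(self) < 2:
            return None
        d = np.diff(self.times)
        if np.allclose(d, d[0], rtol=1e-8, atol=1e-12):
            return float(d[0])
        return None

    def with_values(self, values: np.ndarray, kind: Optional[str] = None) -> "Waveform":
        return replace(self, values=np.asarray(values, dtype=float),
                       kind=kind if kind is not None else self.kind)


@dataclass(frozen=True)
class FeatureVector:
    """The four estimator input features of a transparency waveform.

    ``t_min``: minimum transparency (mA); ``g_max``: maximum absolute
    transparency gradient (mA/s); ``d2_max`` / ``d2_min``: extrema of the
    second derivative (mA/s^2).
    """

    t_min: float
    g_max: float
    d2_max: float
    d2_min: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise WaveformError("non-finite feature")
        if self.g_max < 0:
            raise WaveformError("g_max must be >= 0")
        if self.d2_max < self.d2_min:
            raise WaveformError("d2_max must be >= d2_min")

    def as_array(self) -> np.ndarray:
        return np.array([self.t_min, self.g_max, self.d2_max, self.d2_min],
                        dtype=float)

FEATURE_NAMES = ("t_min", "g_max", "d2_max", "d2_min")


@dataclass
class SampleRecord:
    """One plasma sample: waveforms plus clinical metadata.

    ``waveforms`` is keyed by ``"tg_thrombin"``, ``"tg_turbidity"``,
    ``"pt"``, ``"rt"``.  Metadata fields are optional (``None`` if the
    assay was not run): reference fibrinogen (g/L, Clauss or synthetic
    truth), INR, anti-Xa (U/mL) and D-dimer (mg/L).
    """

    sample_id: str
    fibrinogen_ref: Optional[float] = None
    inr: Optional[float] = None
    anti_xa: Optional[float] = None
    d_dimer: Optional[float] = None
    waveforms: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("fibrinogen_ref", "inr", "anti_xa", "d_dimer"):
            v = getattr(self, name)
            if v is not None:
                v = float(v)
                if not math.isfinite(v) or v < 0:
                    raise WaveformError(f"{name} must be finite and >= 0")
                setattr(self, name, v)


@dataclass(frozen=True)
class StrataLabels:
    """Clinical strata derived from sample metadata."""

    inr_stratum: str          # regular | intermediate | high | unknown
    antixa_positive: bool
    ddimer_elevated: bool
    challenging: bool


def resample_uniform(wf: Waveform, dt: float, t_end: float) -> Waveform:
    """Resample a waveform onto the uniform grid t = 0, dt, ..., t_end.

    Linear interpolation between samples; the tail may be extrapolated by
    at most one step (hold last value).  Points before ``wf.times[0]`` hold
    the first value (relevant when the recording starts slightly after 0).
    """
    if len(wf) < 2:
        raise WaveformError("resampling needs at least 2 points")
    if dt <= 0 or t_end <= 0:
        raise WaveformError("dt and t_end must be positive")
    if t_end > wf.times[-1] + dt + 1e-9:
        raise WaveformError(
            f"t_end={t_end} exceeds waveform end {wf.times[-1]} by more "
            "than one step; tail extrapolation is limited to one step")
    n = int(round(t_end / dt))
    grid = np.arange(n + 1) * dt
    vals = np.interp(grid, wf.times, wf.values)  # np.interp clamps ends
    return replace(wf, times=grid, values=vals)


def derivative(wf: Waveform, order: int, window: int = 5,
               polyorder: int = 2) -> Waveform:
    """Smoothed local-polynomial derivative of a uniformly sampled waveform.

    Savitzky-Golay filtering of the requested order; exact on polynomials
    of degree <= ``polyorder``.  Units of the result are the input units
    divided by s**order.
    """
    if order not in (1, 2):
        raise WaveformError("order must be 1 or 2")
    dt = wf.dt
    if dt is None:
        raise WaveformError("non-uniform grid: resample_uniform first")
    if window % 2 == 0:
        raise WaveformError("window must be odd")
    if window > len(wf):
        raise WaveformError("window exceeds waveform length")
    if polyorder >= window:
        raise WaveformError("polyorder must be < window")
    if polyorder < order:
        raise WaveformError("polyorder must be >= derivative order")
    d = savgol_filter(wf.values, window_length=window, polyorder=polyorder,
                      deriv=order, delta=dt, mode="interp")
    return replace(wf, values=d, kind="derivative")


def extract_features(wf: Waveform, window: int = 5,
                     polyorder: int = 2) -> FeatureVector:
    """Extract the four estimator features from a transparency waveform.

    The waveform must be uniformly sampled transparency.  Features are the
    minimum transparency, the maximum absolute value of the smoothed first
    derivative, and the maximum and minimum of the smoothed second
    derivative.
    """
    if wf.kind != "transparency":
        raise WaveformError("features are defined on transparency waveforms")
    if wf.dt is None:
        raise WaveformError("non-uniform grid: resample_uniform first")
    if len(wf) < window:
        raise WaveformError("waveform shorter than smoothing window")
    d1 = derivative(wf, 1, window=window, polyorder=polyorder).values
    d2 = derivative(wf, 2, window=window, polyorder=polyorder).values
    return FeatureVector(
        t_min=float(np.min(wf.values)),
        g_max=float(np.max(np.abs(d1))),
        d2_max=float(np.max(d2)),
        d2_min=float(np.min(d2)),
    )


def attenuance_from_transparency(wf: Waveform,
                                 t_ref: Optional[float] = None) -> Waveform:
    """Convert transmitted light T(t) to attenuance A(t) = log10(T_ref/T).

    The default reference is the well's own baseline T(0), so A(0) = 0 and
    the maximum of A is the maximum turbidity increase over baseline.
    """
    if wf.kind != "transparency":
        raise WaveformError("input must be a transparency waveform")
    if np.any(wf.values <= 0):
        raise WaveformError("transparency must be > 0 to form attenuance")
    ref = float(wf.values[0]) if t_ref is None else float(t_ref)
    if ref <= 0:
        raise WaveformError("reference transparency must be > 0")
    a = np.log10(ref / wf.values)
    # clip the tiny negative excursions produced by noise above baseline
    return wf.with_values(np.maximum(a, 0.0), kind="attenuance")


def transparency_from_attenuance(wf: Waveform, t_ref: float) -> Waveform:
    """Inverse of :func:`attenuance_from_transparency`: T = T_ref 10**(-A)."""
    if wf.kind != "attenuance":
        raise WaveformError("input must be an attenuance waveform")
    if t_ref <= 0:
        raise WaveformError("reference transparency must be > 0")
    return wf.with_values(t_ref * 10.0 ** (-wf.values), kind="transparency")


def max_attenuance_increase(wf: Waveform) -> float:
    """Maximum attenuance increase over baseline, max_t A(t) - A(0)."""
    if wf.kind != "attenuance":
        raise WaveformError("input must be an attenuance waveform")
    return float(np.max(wf.values) - wf.values[0])


def classify_sample(rec: SampleRecord) -> StrataLabels:
    """Derive the clinical strata used to stratify estimator performance.

    INR strata (closed intervals as printed on the clinical ranges, after
    rounding to one decimal): regular 0.9-1.1, intermediate 1.2-1.5,
    high > 1.5.  Anti-Xa positive strictly above 0.10 U/mL; D-dimer
    elevated strictly above 0.5 mg/L.  A sample is "challenging" if its
    INR exceeds 1.1, anti-Xa is positive, or D-dimer is elevated.
    """
    if rec.inr is None:
        inr_stratum = "unknown"
    else:
        # half-up rounding to one decimal (avoids banker's rounding
        # pushing 1.15 down into the regular band)
        r = math.floor(rec.inr * 10.0 + 0.5) / 10.0
        if r <= 1.1:
            inr_stratum = "regular"
        elif r <= 1.5:
            inr_stratum = "intermediate"
        else:
            inr_stratum = "high"
    antixa_positive = rec.anti_xa is not None and rec.anti_xa > 0.10
    ddimer_elevated = rec.d_dimer is not None and rec.d_dimer > 0.5
    challenging = (inr_stratum in ("intermediate", "high")
                   or antixa_positive or ddimer_elevated)
    return StrataLabels(inr_stratum, antixa_positive, ddimer_elevated,
                        challenging)
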