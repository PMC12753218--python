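"""Synthetic cohort emulating the clinical sample mix.

Generates seeded, reproducible plasma-sample records — thrombin-generation
curves, PT and RT transparency waveforms (forward-simulated through the
polymerization model plus instrument-like noise) and clinical metadata —
with the composition of the study population: 44 samples, fibrinogen
1.1-16.6 g/L (log-uniform, matching the clinically skewed range), 24/44
with a prolonged PT (vitamin-K-antagonist-like, INR 2-3), 14/44 with
measurable anti-Xa (0.1-1.37 U/mL) and 4/44 with elevated D-dimer.

Challenge effect models (config-exposed stand-ins, used to exercise QC and
robustness):

* anti-Xa scales the thrombin-curve amplitude geometrically from 1 at
  0 U/mL down to 0.02 at 1.4 U/mL, emulating heparin-suppressed thrombin
  generation (high anti-Xa samples fall below the QC peak threshold);
* a prolonged PT multiplies the tissue-factor burst rise time by the INR;
* D-dimer affects metadata only, not waveforms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from clotwave.kinetics import EnzymeInput, KineticParameters, simulate
from clotwave.reference import DEFAULT_TG_GRID
from clotwave.waveform import (
    SampleRecord,
    Waveform,
    WaveformError,
    transparency_from_attenuance,
)

#: baseline PT thrombin burst: amplitude (uM) and rise time (s)
PT_BURST_AMPLITUDE_UM = 0.15
PT_BURST_RISE_S = 5.0
#: baseline RT batroxobin level (uM)
RT_BATROXOBIN_UM = 0.05
#: anti-Xa level at which thrombin amplitude reaches its floor
ANTIXA_FULL_SUPPRESSION = 1.4
ANTIXA_FLOOR = 0.02


@dataclass(frozen=True)
class TGCurveParams:
    """Parametric thrombin-generation curve.

    Zero during the lag phase, then a gamma-shaped rise peaking at
    ``t_peak`` followed by exponential decay at rate ``decay``.
    """

    lag: float = 60.0       # s
    peak: float = 150.0     # nM
    t_peak: float = 300.0   # s
    decay: float = 0.01     # 1/s

    def __post_init__(self) -> None:
        if min(self.lag, self.peak, self.t_peak, self.decay) < 0:
            raise WaveformError("TG curve parameters must be >= 0")
        if self.t_peak <= self.lag:
            raise WaveformError("t_peak must exceed lag")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort composition and acquisition settings."""

    n: int = 44
    fib_range: tuple = (1.1, 16.6)          # g/L
    frac_prolonged_pt: float = 24 / 44
    frac_antixa: float = 14 / 44
    frac_ddimer: float = 4 / 44
    noise_sd_frac: float = 0.01             # of signal amplitude
    t0_light: float = 4000.0                # mA baseline transparency
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 8:
            raise WaveformError("cohort needs n >= 8")
        for f in (self.frac_prolonged_pt, self.frac_antixa,
                  self.frac_ddimer):
            if not 0 <= f <= 1:
                raise WaveformError("fractions must lie in [0, 1]")
        lo, hi = self.fib_range
        if not (0 < lo < hi):
            raise WaveformError("fib_range must be positive and increasing")


def synth_thrombin_curve(p: TGCurveParams,
                         t_grid: Optional[Sequence[float]] = None,
                         sample_id: str = "") -> Waveform:
    """Evaluate the parametric thrombin curve on a sampling grid.

    Default grid is 0..3600 s every 30 s, the acquisition schedule of a
    one-hour thrombin-generation run.
    """
    t = (np.asarray(t_grid, dtype=float) if t_grid is not None
         else np.arange(0.0, 3600.0 + 1e-9, 30.0))
    s = t - p.lag
    sp = p.t_peak - p.lag
    a = p.decay * sp
    vals = np.zeros_like(t)
    pos = s > 0
    if p.peak > 0 and a > 0:
        vals[pos] = p.peak * (s[pos] / sp) ** a * np.exp(-p.decay
                                                         * (s[pos] - sp))
    elif p.peak > 0:
        # degenerate decay = 0: plateau after a linear-ramp surrogate
        vals[pos] = p.peak * np.minimum(s[pos] / sp, 1.0)
    return Waveform(times=t, values=vals, kind="thrombin", assay="TG",
                    sample_id=sample_id)


def antixa_thrombin_factor(anti_xa: float) -> float:
    """Thrombin-amplitude suppression factor for a given anti-Xa level.

    Geometric interpolation from 1 at 0 U/mL to 0.02 at 1.4 U/mL,
    saturating beyond.
    """
    if anti_xa <= 0:
        return 1.0
    frac = min(anti_xa / ANTIXA_FULL_SUPPRESSION, 1.0)
    return float(ANTIXA_FLOOR ** frac)


def _add_noise_and_clip(values: np.ndarray, sd_frac: float,
                        t0_light: float, rng: np.random.Generator):
    amp = float(values.max() - values.min())
    if sd_frac > 0 and amp > 0:
        values = values + rng.normal(0.0, sd_frac * amp, size=values.shape)
    return np.clip(values, 0.0, t0_light)


def synth_sample(fib: float, assays: Sequence[str],
                 cfg: Optional[CohortConfig] = None,
                 rng: Optional[np.random.Generator] = None,
                 params: Optional[KineticParameters] = None,
                 sample_id: str = "S",
                 prolonged_pt: bool = False,
                 anti_xa: float = 0.0,
                 d_dimer: float = 0.0,
                 inr: Optional[float] = None) -> SampleRecord:
    """Generate one synthetic sample with the requested assay waveforms.

    Waveforms are produced by forward simulation of the polymerization
    model with assay-appropriate enzyme inputs, converted to transmitted
    light T = t0_light * 10**(-A), perturbed with additive Gaussian noise
    (SD = ``noise_sd_frac`` of the signal amplitude) and clipped to
    [0, t0_light].  PT/RT waveforms live on the t = 0..60 s grid; the TG
    turbidity curve is sampled every 30 s.
    """
    if fib <= 0:
        raise WaveformError("fibrinogen must be > 0")
    for a in assays:
        if a not in ("TG", "PT", "RT"):
            raise WaveformError(f"unknown assay {a!r}")
    cfg = cfg if cfg is not None else CohortConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    p = params if params is not None else KineticParameters()
    if inr is None:
        inr = float(rng.uniform(2.0, 3.0)) if prolonged_pt \
            else float(rng.uniform(0.9, 1.1))

    waveforms = {}
    if "TG" in assays:
        tgp = TGCurveParams(
            lag=float(rng.uniform(30.0, 90.0)),
            peak=float(150.0 * rng.lognormal(0.0, 0.2)
                       * antixa_thrombin_factor(anti_xa)),
            t_peak=float(rng.uniform(240.0, 420.0)),
            decay=float(rng.uniform(0.008, 0.012)),
        )
        thrombin = synth_thrombin_curve(tgp, sample_id=sample_id)
        res = simulate(fib, EnzymeInput(mode="TG_driven", curve=thrombin),
                       p, DEFAULT_TG_GRID, assay="TG")
        turb = transparency_from_attenuance(res.attenuance, cfg.t0_light)
        vals = _add_noise_and_clip(turb.values, cfg.noise_sd_frac,
                                   cfg.t0_light, rng)
        waveforms["tg_thrombin"] = thrombin
        waveforms["tg_turbidity"] = replace(turb, values=vals,
                                            sample_id=sample_id)
    if "PT" in assays:
        enz = EnzymeInput(
            mode="PT_burst",
            amplitude=float(PT_BURST_AMPLITUDE_UM
                            * rng.lognormal(0.0, 0.1)),
            rise_time=PT_BURST_RISE_S * (inr if prolonged_pt else 1.0),
        )
        res = simulate(fib, enz, p, np.arange(61.0), assay="PT")
        turb = transparency_from_attenuance(res.attenuance, cfg.t0_light)
        vals = _add_noise_and_clip(turb.values, cfg.noise_sd_frac,
                                   cfg.t0_light, rng)
        waveforms["pt"] = replace(turb, values=vals, sample_id=sample_id)
    if "RT" in assays:
        enz = EnzymeInput(mode="RT_constant",
                          level=float(RT_BATROXOBIN_UM
                                      * rng.lognormal(0.0, 0.1)))
        res = simulate(fib, enz, p, np.arange(61.0), assay="RT")
        turb = transparency_from_attenuance(res.attenuance, cfg.t0_light)
        vals = _add_noise_and_clip(turb.values, cfg.noise_sd_frac,
                                   cfg.t0_light, rng)
        waveforms["rt"] = replace(turb, values=vals, sample_id=sample_id)

    return SampleRecord(sample_id=sample_id, fibrinogen_ref=float(fib),
                        inr=inr, anti_xa=float(anti_xa),
                        d_dimer=float(d_dimer), waveforms=waveforms)


def synth_cohort(cfg: Optional[CohortConfig] = None,
                 assays: Sequence[str] = ("TG", "PT", "RT"),
                 params: Optional[KineticParameters] = None) -> list:
    """Generate the full synthetic cohort (pure function of the config).

    Fibrinogen truths are log-uniform over ``cfg.fib_range``; challenge
    flags are assigned by seeded sampling without replacement so the
    configured fractions are met exactly (after rounding to counts).
    """
    cfg = cfg if cfg is not None else CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    lo, hi = cfg.fib_range
    fibs = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))

    n_pt = int(round(cfg.frac_prolonged_pt * n))
    n_xa = int(round(cfg.frac_antixa * n))
    n_dd = int(round(cfg.frac_ddimer * n))
    pt_idx = set(rng.choice(n, size=n_pt, replace=False).tolist())
    xa_idx = set(rng.choice(n, size=n_xa, replace=False).tolist())
    dd_idx = set(rng.choice(n, size=n_dd, replace=False).tolist())

    records = []
    for i in range(n):
        anti_xa = float(rng.uniform(0.1, 1.37)) if i in xa_idx else 0.0
        d_dimer = float(rng.uniform(0.6, 5.0)) if i in dd_idx \
            else float(rng.uniform(0.1, 0.4))
        rec = synth_sample(float(fibs[i]), assays, cfg=cfg, rng=rng,
                           params=params, sample_id=f"S{i + 1:02d}",
                           prolonged_pt=(i in pt_idx), anti_xa=anti_xa,
                           d_dimer=d_dimer)
        records.append(rec)
    return records
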