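"""Shared fixtures: model parameters, synthetic curves and cohorts.

The expensive objects (the default reference curve, the full 44-sample
cohort) are session-scoped so the whole suite pays for each forward
simulation campaign once.
"""

import numpy as np
import pytest

from clotwave import (
    CohortConfig,
    KineticParameters,
    TGCurveParams,
    Waveform,
    build_reference_curve,
    synth_cohort,
    synth_thrombin_curve,
)


@pytest.fixture(scope="session")
def params():
    return KineticParameters()


@pytest.fixture(scope="session")
def thrombin_curve():
    """Deterministic healthy-sample thrombin-generation curve."""
    return synth_thrombin_curve(TGCurveParams(), sample_id="fixture")


@pytest.fixture(scope="session")
def reference_curve_default(thrombin_curve, params):
    """Reference curve on the default 0.5-12 g/L, 0.5 g/L grid."""
    return build_reference_curve(thrombin_curve, params)


@pytest.fixture(scope="session")
def full_cohort(params):
    """The default-composition 44-sample synthetic cohort, all assays."""
    return synth_cohort(CohortConfig(seed=20260924), params=params)


def sigmoid_transparency(amplitude, t50=20.0, slope=0.25, t0=4000.0,
                         sample_id="toy"):
    """Toy clot-like transparency curve (no ODE model involved)."""
    t = np.arange(61.0)
    drop = amplitude / (1.0 + np.exp(-slope * (t - t50)))
    return Waveform(times=t, values=t0 - drop, kind="transparency",
                    assay="PT", sample_id=sample_id)


@pytest.fixture
def toy_waveforms():
    """A spread of toy transparency curves with distinct shapes."""
    rng = np.random.default_rng(7)
    wfs = []
    for i in range(12):
        wfs.append(sigmoid_transparency(
            amplitude=400.0 + 250.0 * i + rng.uniform(0, 50),
            t50=12.0 + rng.uniform(0, 12),
            slope=0.2 + 0.03 * (i % 4),
            sample_id=f"T{i:02d}"))
    return wfs
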