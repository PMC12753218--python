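"""Mechanistic fibrin polymerization model with turbidimetric output.

The model couples an enzymatic block to a polymer block, 144 states in
total under the default configuration:

* 12 enzymatic states — fibrinogen, enzyme-fibrinogen complex, fibrin I
  (desA monomer), fibrinopeptide A, enzyme-fibrin-I complex, fibrin II
  (desAB monomer), fibrinopeptide B, factor XIII, enzyme-FXIII complex,
  activated FXIII, free enzyme and inhibited enzyme;
* 132 polymer states — a monomer-addition oligomer ladder O_j
  (j = 2..121, the longest species acting as the mature protofibril) and
  laterally aggregated fiber bundles B_k of k protofibrils (k = 2..13).

The driving enzyme is either thrombin (clamped to a measured or synthetic
thrombin-generation curve, or a tissue-factor-triggered burst emulating a
PT assay) or batroxobin (constant level, Reptilase assay).  Batroxobin
cleaves only fibrinopeptide A, so in RT mode the FpB release rate is
forced to zero and polymerization proceeds through desA fibrin I at a
reduced efficiency.

Light attenuance is computed from the fiber bundle distribution with the
thin-rod (Carr-Hermans) relation: turbidity proportional to fiber mass
concentration times mass/length ratio, tau = C(lambda) * sum_k c_k * mu_k
with mu_k = k * mu_pf, so thicker fibers scatter more per unit mass.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.sparse import lil_matrix

from clotwave.waveform import Waveform

AVOGADRO = 6.02214076e23
FIBRINOGEN_MW = 340_000.0  # g/mol

_ENZYMATIC_SPECIES = (
    "fibrinogen", "enzyme_fibrinogen", "fibrin_I", "FpA",
    "enzyme_fibrin_I", "fibrin_II", "FpB", "FXIII", "enzyme_FXIII",
    "FXIIIa", "enzyme_free", "enzyme_inhibited",
)
# enzymatic block index constants
FGN, E_FGN, FIB1, FPA, E_FIB1, FIB2, FPB, FX13, E_FX13, FX13A, E_FREE, E_INH \
    = range(12)


class ModelError(RuntimeError):
    """Model configuration or integration failure."""


@dataclass(frozen=True)
class KineticParameters:
    """Rate and optical constants of the polymerization model.

    Units: second-order rates in 1/(uM*s), first-order in 1/s, mu_pf in
    Da/cm, dndc in mL/g, wavelength in nm, path_length in cm.  The default
    constants are literature-plausible values for thrombin acting on
    fibrinogen (FpA release fast, FpB release an order of magnitude
    slower, slow FXIII activation) and for protofibril growth and lateral
    aggregation; they are adjustable parameters of the model, not claims
    about any particular reagent lot.
    """

    # enzyme-fibrinogen (FpA release -> fibrin I)
    k_on_F: float = 10.0
    k_off_F: float = 50.0
    k_cat_A: float = 84.0
    # enzyme-fibrin-I (FpB release -> fibrin II)
    k_on_I: float = 10.0
    k_off_I: float = 70.0
    k_cat_B: float = 7.4
    # enzyme-FXIII activation
    k_on_X: float = 1.0
    k_off_X: float = 9.9
    k_cat_X: float = 0.1
    # enzyme inhibition (plasma inhibitors; irrelevant under clamping)
    k_inh: float = 0.005
    # polymerization: oligomer initiation is much slower than monomer
    # addition, so nuclei grow to full protofibril length instead of the
    # monomer pool exhausting itself in dimers
    k_nuc: float = 5e-3          # oligomer nucleation, 1/(uM*s)
    k_poly: float = 150.0         # monomer addition, 1/(uM*s)
    k_lat: float = 50.0          # protofibril lateral aggregation, 1/(uM*s)
    fibrin_I_efficiency: float = 0.1   # desA monomer relative polymerizability
    L_max: int = 121             # protofibril length, monomers
    K_max: int = 13              # maximum fiber thickness, protofibrils
    # optics (Carr-Hermans thin-rod relation)
    mu_pf: float = 1.5e11        # protofibril mass/length, Da/cm
    n_s: float = 1.33            # solvent refractive index
    dndc: float = 0.18           # refractive increment, mL/g
    wavelength: float = 450.0    # nm
    path_length: float = 0.5     # optical path, cm
    C_geom: float = 1.0          # lumped geometric prefactor
    oligomer_scatter: float = 0.0  # weight of sub-protofibril oligomers
    # initial plasma FXIII
    fxiii_0: float = 0.07        # uM

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if name in ("L_max", "K_max"):
                continue
            if v < 0:
                raise ModelError(f"parameter {name} must be >= 0")
        if self.L_max < 2 or self.K_max < 2:
            raise ModelError("L_max and K_max must be >= 2")
        if self.wavelength <= 0:
            raise ModelError("wavelength must be > 0")

    def optical_prefactor(self) -> float:
        """Carr-Hermans thin-rod prefactor C(lambda), cm^2*mol/g^2.

        tau [1/cm] = C * c [g/cm^3] * mu [Da/cm];
        C = C_geom * (88/15) pi^3 n_s^2 (dn/dc)^2 / (N_A lambda^3).
        """
        lam_cm = self.wavelength * 1e-7
        return (self.C_geom * (88.0 / 15.0) * np.pi ** 3 * self.n_s ** 2
                * self.dndc ** 2 / (AVOGADRO * lam_cm ** 3))

    def digest(self) -> str:
        """Short provenance hash of the parameter set."""
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass(frozen=True)
class ModelStateSpace:
    """Named ordering of the model's concentration vector."""

    enzymatic_species: tuple
    polymer_species: tuple
    index: dict = field(repr=False)

    @property
    def n_states(self) -> int:
        return len(self.enzymatic_species) + len(self.polymer_species)

    def names(self) -> tuple:
        return self.enzymatic_species + self.polymer_species


def build_state_space(params: Optional[KineticParameters] = None) -> ModelStateSpace:
    """Construct the ordered state space of the model.

    With the default configuration (oligomer ladder j = 2..121, bundles
    k = 2..13) this yields 12 enzymatic + 132 polymer = 144 states.
    """
    p = params if params is not None else KineticParameters()
    oligomers = tuple(f"O_{j}" for j in range(2, p.L_max + 1))
    bundles = tuple(f"B_{k}" for k in range(2, p.K_max + 1))
    polymer = oligomers + bundles
    names = _ENZYMATIC_SPECIES + polymer
    if len(set(names)) != len(names):
        raise ModelError("species names must be unique")
    index = {name: i for i, name in enumerate(names)}
    return ModelStateSpace(_ENZYMATIC_SPECIES, polymer, index)


@dataclass(frozen=True)
class EnzymeInput:
    """Driving enzyme exposure for a simulation.

    Modes:

    * ``TG_driven`` — free thrombin clamped to a measured/synthetic
      thrombin curve (``curve``, nM vs s; linear interpolation, zero
      outside the recorded range).
    * ``PT_burst`` — tissue-factor-like burst, E(t) = amplitude *
      (1 - exp(-t / rise_time)) in uM.
    * ``RT_constant`` — constant batroxobin ``level`` in uM; FpB release
      is suppressed (batroxobin cleaves FpA only).
    """

    mode: str
    curve: Optional[Waveform] = None
    level: float = 0.0
    amplitude: float = 0.0
    rise_time: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("TG_driven", "RT_constant", "PT_burst"):
            raise ModelError(f"unknown enzyme mode {self.mode!r}")
        if self.mode == "TG_driven":
            if self.curve is None or self.curve.kind != "thrombin":
                raise ModelError("TG_driven requires a thrombin waveform")
        if self.mode == "RT_constant" and self.level < 0:
            raise ModelError("batroxobin level must be >= 0")
        if self.mode == "PT_burst" and (self.amplitude < 0
                                        or self.rise_time <= 0):
            raise ModelError("burst amplitude >= 0 and rise_time > 0 required")

    def concentration(self, t) -> np.ndarray:
        """Free enzyme concentration (uM) at time(s) t."""
        t = np.asarray(t, dtype=float)
        if self.mode == "TG_driven":
            # curve is in nM
            return np.interp(t, self.curve.times, self.curve.values,
                             left=0.0, right=0.0) * 1e-3
        if self.mode == "RT_constant":
            return np.full_like(t, self.level, dtype=float)
        return self.amplitude * (1.0 - np.exp(-t / self.rise_time))


def _unpack(y: np.ndarray, p: KineticParameters):
    n_olig = p.L_max - 1
    olig = y[12:12 + n_olig]
    bund = y[12 + n_olig:12 + n_olig + (p.K_max - 1)]
    return olig, bund


def rhs(t: float, y: np.ndarray, enzyme: EnzymeInput,
        params: KineticParameters) -> np.ndarray:
    """Mass-action time derivative of the model state.

    The free enzyme is clamped to ``enzyme.concentration(t)``; its own
    state (and the inhibited-enzyme state) carries zero derivative so the
    count of the state vector is preserved.
    """
    p = params
    y = np.asarray(y, dtype=float)
    dy = np.zeros_like(y)
    E = float(enzyme.concentration(t))
    # negative excursions from the solver are treated as zero in rates
    yc = np.maximum(y, 0.0)

    k_cat_B = 0.0 if enzyme.mode == "RT_constant" else p.k_cat_B

    v1f = p.k_on_F * E * yc[FGN]
    v1r = p.k_off_F * yc[E_FGN]
    v1c = p.k_cat_A * yc[E_FGN]
    v2f = p.k_on_I * E * yc[FIB1]
    v2r = p.k_off_I * yc[E_FIB1]
    v2c = k_cat_B * yc[E_FIB1]
    v3f = p.k_on_X * E * yc[FX13]
    v3r = p.k_off_X * yc[E_FX13]
    v3c = p.k_cat_X * yc[E_FX13]

    dy[FGN] = -v1f + v1r
    dy[E_FGN] = v1f - v1r - v1c
    dy[FIB1] = v1c - v2f + v2r
    dy[FPA] = v1c
    dy[E_FIB1] = v2f - v2r - v2c
    dy[FIB2] = v2c
    dy[FPB] = v2c
    dy[FX13] = -v3f + v3r
    dy[E_FX13] = v3f - v3r - v3c
    dy[FX13A] = v3c
    # enzyme states clamped externally
    dy[E_FREE] = 0.0
    dy[E_INH] = 0.0

    # --- polymer ladder -------------------------------------------------
    n_olig = p.L_max - 1            # species O_2 .. O_Lmax
    olig = yc[12:12 + n_olig]
    bund = yc[12 + n_olig:12 + n_olig + (p.K_max - 1)]
    w = p.fibrin_I_efficiency
    m_eff = w * yc[FIB1] + yc[FIB2]

    d_olig = np.zeros(n_olig)
    nuc = p.k_nuc * m_eff * m_eff
    elong = p.k_poly * m_eff * olig[:-1]   # O_2..O_{Lmax-1} + M -> next
    d_olig[0] = nuc - elong[0]
    d_olig[1:-1] = elong[:-1] - elong[1:]
    d_olig[-1] = elong[-1]
    monomer_cons = 2.0 * nuc + elong.sum()
    if m_eff > 0.0:
        frac_I = w * yc[FIB1] / m_eff
    else:
        frac_I = 0.0
    dy[FIB1] -= monomer_cons * frac_I
    dy[FIB2] -= monomer_cons * (1.0 - frac_I)

    # --- lateral aggregation -------------------------------------------
    P = olig[-1]
    d_bund = np.zeros(p.K_max - 1)
    bnuc = p.k_lat * P * P
    blat = p.k_lat * P * bund[:-1]         # B_2..B_{Kmax-1} + P -> next
    d_bund[0] = bnuc - blat[0]
    d_bund[1:-1] = blat[:-1] - blat[1:]
    d_bund[-1] = blat[-1]
    d_olig[-1] -= 2.0 * bnuc + blat.sum()

    dy[12:12 + n_olig] = d_olig
    dy[12 + n_olig:12 + n_olig + (p.K_max - 1)] = d_bund
    if not np.all(np.isfinite(dy)):
        raise ModelError(f"non-finite derivative at t={t}")
    return dy


def _jac_sparsity(p: KineticParameters):
    """Structural Jacobian sparsity for the stiff solver."""
    n_olig = p.L_max - 1
    n = 12 + n_olig + (p.K_max - 1)
    S = lil_matrix((n, n), dtype=np.int8)
    enz = [FGN, E_FGN, FIB1, E_FIB1, FIB2, FX13, E_FX13]
    for i in enz:
        for j in enz:
            S[i, j] = 1
    for i in (FPA, FPB, FX13A):
        for j in enz:
            S[i, j] = 1
    o0 = 12
    b0 = 12 + n_olig
    # monomer rows couple to the whole ladder; ladder rows to monomers
    for i in (FIB1, FIB2):
        S[i, FIB1] = S[i, FIB2] = 1
        for j in range(o0, o0 + n_olig):
            S[i, j] = 1
    for r in range(n_olig):
        i = o0 + r
        S[i, FIB1] = S[i, FIB2] = 1
        S[i, i] = 1
        if r > 0:
            S[i, i - 1] = 1
    # protofibril row couples to bundles; bundle rows to protofibril
    iP = o0 + n_olig - 1
    for j in range(b0, b0 + p.K_max - 1):
        S[iP, j] = 1
        S[j, iP] = 1
    for r in range(p.K_max - 1):
        i = b0 + r
        S[i, i] = 1
        if r > 0:
            S[i, i - 1] = 1
    return S.tocsr()


def fibrinogen_to_uM(fibrinogen_g_per_L: float) -> float:
    """Convert fibrinogen g/L to uM via the 340 kDa molar mass."""
    return fibrinogen_g_per_L / FIBRINOGEN_MW * 1e6


def initial_state(fibrinogen_g_per_L: float,
                  params: KineticParameters) -> np.ndarray:
    space_n = 12 + (params.L_max - 1) + (params.K_max - 1)
    y0 = np.zeros(space_n)
    y0[FGN] = fibrinogen_to_uM(fibrinogen_g_per_L)
    y0[FX13] = params.fxiii_0
    return y0


def fiber_attenuance(y: np.ndarray, params: KineticParameters) -> float:
    """Attenuance of the fiber population in a model state.

    Thin-rod scattering: each bundle class k contributes its mass
    concentration times its mass/length ratio mu_k = k * mu_pf.  Oligomers
    below protofibril maturity contribute with weight
    ``params.oligomer_scatter`` (default 0: only bundles scatter
    appreciably).  Returns decadic attenuance over the configured path.
    """
    p = params
    olig, bund = _unpack(np.asarray(y, dtype=float), p)
    ks = np.arange(2, p.K_max + 1, dtype=float)
    # bundle mass concentration in g/cm^3: c[uM] * 1e-9 mol/cm^3/uM * k*L*MW
    mass_c = np.maximum(bund, 0.0) * 1e-9 * ks * p.L_max * FIBRINOGEN_MW
    tau = p.optical_prefactor() * float(np.sum(mass_c * ks * p.mu_pf))
    if p.oligomer_scatter > 0.0:
        js = np.arange(2, p.L_max + 1, dtype=float)
        mass_o = np.maximum(olig, 0.0) * 1e-9 * js * FIBRINOGEN_MW
        tau += (p.oligomer_scatter * p.optical_prefactor()
                * float(np.sum(mass_o * p.mu_pf * js / p.L_max)))
    return tau * p.path_length / np.log(10.0)


def mass_balance(y: np.ndarray, params: KineticParameters) -> float:
    """Fibrinogen-equivalent content of a state, in uM of monomer units.

    Sums fibrinogen, its enzyme complexes, fibrin monomers, j monomers per
    oligomer O_j and L_max*k monomers per bundle B_k.  Conserved along any
    trajectory of :func:`rhs`.
    """
    p = params
    y = np.asarray(y, dtype=float)
    olig, bund = _unpack(y, p)
    js = np.arange(2, p.L_max + 1, dtype=float)
    ks = np.arange(2, p.K_max + 1, dtype=float)
    return float(y[FGN] + y[E_FGN] + y[FIB1] + y[E_FIB1] + y[FIB2]
                 + np.dot(js, olig) + p.L_max * np.dot(ks, bund))


@dataclass
class SimulationResult:
    """Trajectory of a forward simulation."""

    times: np.ndarray            # s
    states: np.ndarray           # (n_times, n_states), uM
    attenuance: Waveform
    space: ModelStateSpace
    params: KineticParameters

    def species(self, name: str) -> np.ndarray:
        return self.states[:, self.space.index[name]]


def simulate(fibrinogen_g_per_L: float, enzyme: EnzymeInput,
             params: Optional[KineticParameters] = None,
             t_grid: Optional[Sequence[float]] = None,
             rtol: float = 1e-6, atol: float = 1e-9,
             assay: str = "none") -> SimulationResult:
    """Integrate the polymerization model and compute attenuance.

    Parameters
    ----------
    fibrinogen_g_per_L : float
        Initial fibrinogen concentration (g/L, converted internally to uM).
    enzyme : EnzymeInput
        Driving enzyme exposure.
    t_grid : sequence of float
        Output times in seconds (default 0..60 s step 1).
    rtol, atol : float
        Solver tolerances (stiff BDF method).
    """
    if fibrinogen_g_per_L < 0:
        raise ModelError("fibrinogen must be >= 0")
    p = params if params is not None else KineticParameters()
    t = (np.asarray(t_grid, dtype=float) if t_grid is not None
         else np.arange(61.0))
    if t.ndim != 1 or t.size < 2 or not np.all(np.diff(t) > 0):
        raise ModelError("t_grid must be increasing with >= 2 points")
    y0 = initial_state(fibrinogen_g_per_L, p)
    space = build_state_space(p)

    sol = solve_ivp(rhs, (t[0], t[-1]), y0, method="BDF", t_eval=t,
                    args=(enzyme, p), rtol=rtol, atol=atol,
                    jac_sparsity=_jac_sparsity(p))
    if not sol.success:
        t_last = sol.t[-1] if sol.t.size else t[0]
        raise ModelError(f"stiff integration failed at t={t_last:.3f}s: "
                         f"{sol.message}")
    states = sol.y.T.copy()
    if states.min() < -1e-6:
        raise ModelError("negative concentrations beyond solver tolerance")
    # clip excursions within -atol..0; larger (still tolerated) negatives
    # are left untouched so mass-balance audits see the raw solution
    states[(states < 0) & (states > -atol)] = 0.0
    states[:, E_FREE] = enzyme.concentration(t)
    att = np.array([fiber_attenuance(s, p) for s in states])
    wf = Waveform(times=t, values=np.maximum(att, 0.0), kind="attenuance",
                  assay=assay)
    return SimulationResult(times=t, states=states, attenuance=wf,
                            space=space, params=p)
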