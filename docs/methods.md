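# Methods

## The polymerization model

The forward model is a mass-action ODE system for fibrin assembly under a
prescribed enzyme exposure, with 144 states in the default configuration.

**Enzymatic block (12 states).** Fibrinogen binds the driving enzyme E
(thrombin or batroxobin) reversibly; catalysis releases fibrinopeptide A
and yields fibrin I (desA monomer). A second complex releases
fibrinopeptide B (fibrin II, desAB). E also activates factor XIII through
its own complex, and a first-order inhibition channel drains free enzyme.
States: Fgn, E·Fgn, fibrin I, FpA, E·fibrin I, fibrin II, FpB, FXIII,
E·FXIII, FXIIIa, free E, inhibited E.

**Polymer block (132 states).** Monomers nucleate into dimers
(rate k_nuc·M²) and elongate along an oligomer ladder O_j + M → O_{j+1}
(rate k_poly·M·O_j) up to j = L_max = 121; O_121 is the mature
protofibril. Protofibrils aggregate laterally: P + P → B_2 and
B_k + P → B_{k+1} up to K_max = 13. The ladder (120 species) plus the
bundles (12 species) give 132 polymer states. The effective monomer pool
is M = [fibrin II] + w·[fibrin I] with w = 0.1: desA monomers polymerize,
but at reduced efficiency, which is what lets the Reptilase mode (FpB
release forced to zero, batroxobin cleaves FpA only) clot at all.
Monomer consumption is split between fibrin I and II in proportion to
their weighted contributions, so fibrinogen-equivalent mass
(Fgn + complexes + monomers + Σ j·O_j + L_max·Σ k·B_k) is conserved
exactly by construction; the integrated drift is a direct audit of solver
accuracy.

**Enzyme modes.** The free-enzyme state is *clamped* to a prescribed
exposure — the measured/synthetic thrombin curve (linear interpolation,
zero outside the record) for the TG route, a tissue-factor-like burst
amplitude·(1 − e^(−t/rise)) for PT, a constant batroxobin level for RT —
and carries zero derivative, so complex formation does not deplete it.
This mirrors using the thrombin measurement as an input rather than
modeling the upstream cascade.

**Optics.** Attenuance uses the thin-rod (Carr–Hermans) limit: turbidity
τ = C_geom·(88/15)π³ n_s²(dn/dc)²/(N_A λ³) · Σ_k c_k·m_k·μ_k, where c_k
is the bundle particle concentration, m_k its mass and μ_k = k·μ_pf its
mass/length ratio. Sub-protofibril oligomers carry a configurable
scattering weight, 0 by default (thin single strands scatter negligibly
compared with bundles). Decadic attenuance over a 0.5 cm path is
reported, so a doubled fiber thickness doubles the signal per unit mass.

**Rate constants.** Enzymatic constants follow thrombin kinetics
(FpA release kcat ≈ 84 s⁻¹ with a ~13 µM Michaelis constant, FpB an
order of magnitude slower, slow FXIII activation). The polymer constants
are effective values chosen so the model clots on assay timescales over
the clinically relevant range: mean oligomer length at exhaustion scales
as √(k_poly/2k_nuc)·√(M_tot/M_eff), so k_poly/k_nuc ≈ 3·10⁴ is required
for PT-like pools (M_tot = M_eff) to reach the 121-monomer protofibril
cap, while the conversion half-time √(2M_tot/(k_poly·k_nuc·M_eff³))
must stay under ~30 s for the weakest pool (RT at 1.1 g/L,
M_eff ≈ 0.3 µM). Defaults k_poly = 150 µM⁻¹s⁻¹, k_nuc = 5·10⁻³ µM⁻¹s⁻¹
satisfy both. All constants live in `KineticParameters` (YAML-loadable);
they are model parameters, not measured claims.

**Numerics.** Stiff BDF integration (scipy `solve_ivp`), rtol 1e-6 /
atol 1e-9, with a structural Jacobian sparsity pattern (the ladder is
nearly bidiagonal; monomer rows are dense) so finite-difference Jacobians
need only a few rhs evaluations. Negative excursions within −atol are
clipped to zero; anything below −1e-6 µM aborts with a diagnostic.
Fibrinogen converts to µM via the 340 kDa molar mass. Halving the
tolerances moves the final attenuance by well under 0.1%.

## The TG reference-curve route

For each sample, the model is run once per point of a fibrinogen grid
(default 0.5–12 g/L, step 0.5) under the sample's own thrombin curve,
storing the maximum attenuance increase ΔA_max. Construction fails unless
ΔA_max is strictly increasing. The estimate inverts the measured ΔA_max
through a monotone shape-preserving (PCHIP) interpolant — no overshoot
between nodes, and no extrapolation: measurements outside the simulated
range return an `out_of_range` flag rather than a number, since the
method is not validated at extreme concentrations.

The reference curve is rebuilt per sample rather than pooled, because
the simulation is conditioned on that sample's thrombin input; two
samples with different thrombin exposure have different fibrinogen →
turbidity maps.

**QC.** Samples with peak thrombin < 10 nM are flagged `atypical_low_tg`;
samples whose turbidity increase is < 0.02 attenuance are
`atypical_low_turbidity`. Flagged samples never receive an estimate.
Both thresholds are package defaults (exposed as arguments): clinically,
heavily anticoagulated samples produce essentially flat TG curves, and
any threshold in the 5–20 nM range separates the synthetic regular and
suppressed populations cleanly.

## The PT/RT feature route

Features are computed on the raw transparency trace in mA on the uniform
1 s grid: minimum transparency, maximum absolute first derivative, and
both extrema of the second derivative, with Savitzky–Golay smoothing
(window 5, polyorder 2 — exact on quadratics, noise-robust at 1 s
sampling). No per-sample normalization is applied; the feature scale
itself carries fibrinogen information.

The linear model is OLS with intercept on the raw features. The network
is 4‑3‑1 with tanh hidden units and a linear output, trained full-batch
with Adam (lr 0.001, β₁ 0.9, β₂ 0.999, ε 1e-7) on the MSE, inputs
standardized with training-fold constants, Glorot-uniform initialization
from a fixed seed. The default is 20 000 epochs: full-batch Adam moves
each parameter by at most ≈ lr per step, so covering the ~17 g/L output
scale from near-zero initialization requires on the order of 2·10⁴
steps; at 2·10³ the network demonstrably underfits its own training set
(training MSE ≈ 8.8 vs ≈ 0.003 when converged).

The combined estimator returns the network prediction when the network
itself predicts ≥ 6 g/L and the linear prediction otherwise; the
boundary value 6.0 belongs to the network branch. The gate reflects the
two models' complementary failure modes: the saturating tanh layer
compresses the high end less than the linear fit's global compromise,
while OLS is the better local model at low concentrations.

Leave-one-out evaluation refits the standardizer and both models per
fold (seed offset by fold index, so folds are reproducible but not
weight-correlated); records missing the assay waveform or the reference
value are excluded with an explicit reason. Pearson r uses the sample
correlation with a two-sided p-value from the t distribution (n − 2 df),
computable for all samples or the "regular only" stratum (INR ≤ 1.1,
anti-Xa ≤ 0.10 U/mL).

## The synthetic cohort

The generator emulates the study conditions: n = 44; fibrinogen
log-uniform on 1.1–16.6 g/L (the clinical range is right-skewed); 24
samples with prolonged PT (INR drawn 2–3, vitamin-K-antagonist-like); 14
with anti-Xa 0.1–1.37 U/mL; 4 with elevated D-dimer; additive Gaussian
noise with SD 1% of each waveform's amplitude on the transparency scale
(instrument-like), clipped to [0, 4000] mA.

Challenge effect models are explicit stand-ins: anti-Xa scales the
thrombin amplitude geometrically from 1 to 0.02 across 0–1.4 U/mL
(heparin suppresses thrombin generation; the geometric form sends
> 1 U/mL samples below the QC threshold), prolonged PT multiplies the
tissue-factor burst rise time by the INR, and D-dimer touches metadata
only. Per-sample biology enters as jitter on the thrombin-curve
parameters (lag 30–90 s, peak ~150 nM log-normal ±20%, time-to-peak
240–420 s) and ±10% on PT burst amplitude and batroxobin level.

What passing tests on this cohort do **not** show: the generator shares
its forward model with the TG inference route, so TG round-trip accuracy
demonstrates internal consistency, not accuracy on real plasma; the
feature–fibrinogen relation of real PT/RT waveforms includes reagent,
instrument and patient effects (dysfibrinogenemia above all) absent
here. The cohort exists to verify the machinery — exclusion logic, QC,
leakage-free cross-validation, monotone inversion — under realistic
signal shapes and noise.

## The digitizer

Analyzer clot waveforms are published as plots with fixed axes (0–60 s,
0–4000 mA). Given a grayscale raster and the pixel box of the plot area,
each integer-second column is scanned for pixels darker than an Otsu (or
user-set) threshold; the darkness-weighted centroid row maps linearly
back to mA. Columns without curve pixels are filled by linear
interpolation from neighbors, capped at 20% of columns. On rendered
fixtures with ≥ 3 px stroke the extraction is exact to one quantization
step (axis range / box height).

## Problem sizes

Default test and acceptance runs use the full 44-sample cohort for the
estimator routes, a 24-point reference curve for the TG route, 61-point
PT/RT waveforms (1 s grid) and 31-point TG turbidity curves (30 s grid,
15 min horizon — thrombin is exhausted and attenuance plateaus well
before that), and 0–600 s trajectories for conservation audits.

## Known limitations

* The 12 + 132 process structure is one defensible realization of the
  canonical fibrin pathway at the printed state counts; it is not a
  reconstruction of any proprietary model's species list.
* Bundles neither elongate nor exchange protofibrils after formation,
  and fibrinolysis, flow and platelet effects are out of scope.
* FXIIIa is tracked but optically inert (cross-linking does not change
  the thin-rod scattering in this model).
* The anti-Xa and INR effect models are qualitative stand-ins for
  testing QC and robustness, not pharmacokinetic claims.
* The Clauss-equivalence of the synthetic "reference fibrinogen" is by
  construction; real Clauss values carry their own assay error.
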