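# Methods

This note documents the models implemented in `prestinlab`, the
assumptions behind the synthetic-data generators, the numerical choices
made where the design was genuinely open, and the known limitations of
each. Units are fixed package-wide: mV, pA, pF, fC, MΩ, pS, s, Hz, K;
every SI conversion goes through `prestinlab.constants`
(e₀ = 1.602176634×10⁻¹⁹ C, k = 1.380649×10⁻²³ J/K). The default bath
temperature is 296.15 K ("room temperature"), exposed on every
parameter object.

## Nonlinear capacitance (`nlc`)

**Model.** Two-state Boltzmann charge transfer; membrane capacitance is
its voltage derivative,

    C_m(V) = C_lin + Q_max (z e₀ / kT) b(1−b),
    b = 1/(1 + exp(−z e₀ (V − V_h)/kT)).

With charge in fC and voltage in mV, fC/mV = pF, so the implementation
uses C_m = c_lin + q_max·z/V_T·b(1−b) with V_T = kT/e₀ ≈ 25.5 mV. The
peak, at V = V_h, is C_lin + Q_max z/(4 V_T). Derived quantities:
Q_sp = Q_max/C_lin (fC/pF), molecule count N = Q_max/(z e₀), unitary
current i = I_cell/N.

**Fitting.** Trust-region least squares on (Q_max, V_h, z, C_lin).
Initialization is deterministic and peak-based: C_lin ← min C_m,
V_h ← argmax C_m, z ← 0.8, Q_max ← 4V_T/z·(C_peak − C_lin). z is
bounded to (0.05, 3) to forbid degenerate flat fits (reported values
for this protein span roughly 0.5–1). Standard errors are asymptotic
(s²(JᵀJ)⁻¹). Data that are strictly monotone over the sampled window
contain no resolvable peak and raise a `FitError`; a fitted V_h outside
the sampled window succeeds but attaches an explicit extrapolation
warning to the results (never a silent extrapolation). Q_sp is reported
from the *fit-derived* C_lin rather than a separate linear-capacitance
measurement; with model-generated data the two coincide.

**Caveat.** Over a window such as −160…110 mV the Boltzmann tails do
not reach baseline (at −150 mV the NLC of the wild-type parameter set
is still ≈1.3 pF above C_lin), so (Q_max, C_lin, z) are strongly
correlated and small systematic distortions of the curve move Q_max
several times more, in relative terms, than they move V_h. V_h is the
robust quantity; Q_max and z inherit the window.

## Single-barrier I–V (`barrier`)

**Model.** Eyring rate theory for one central barrier at electrical
distance δ ∈ (0,1):

    I(V) = g (kT/q e₀) [P e^{(1−δ)u} − e^{−δu}],   u = q e₀ V/kT,

normalized so dI/dV at 0 mV equals g[P(1−δ)+δ] — exactly g for P = 1.
For P = 1, δ = ½ this is the symmetric sinh relation
I = 2g(kT/q e₀) sinh(u/2). The reversal potential is closed-form,
E_rev = −(kT/q e₀) ln P, and is verified in the test suite against
numeric bisection of the current. Sign convention: outward current
positive, V = V_in − V_out. The functional form is reconstructed from
the variable glossary of the printed model (slope conductance at E = 0,
electrical distance, relative permeability of outward- vs
inward-carrying ions) together with its stated sinh limiting case; this
reconstruction is deliberate and documented here.

**Fitting.** Levenberg–Marquardt least squares with free parameters
transformed (log g, log P, logit δ) so positivity and δ ∈ (0,1) hold by
construction; any subset of {g, q, δ, P} can be held fixed (fixing
q = 0.75 reproduces the "reduced voltage dependence" configuration).
P is restricted to [10⁻⁴, 10⁴] — |ln P| beyond that maps to a reversal
potential far outside any practical command range — and a fit that runs
to this boundary raises `FitError` rather than returning an
extrapolated permeability: such data (e.g. strictly outward current
with no measurable reversal) contain no interior optimum, the profile
SSE decreasing monotonically as P → ∞.

**Estimator skew.** Under homoscedastic noise scaled to the maximum
current, the thiocyanate-type parameter set is strongly asymmetric: at
2% of max |I| the noise s.d. (≈7 pA/pF) is half the entire inward limb
(≈13 pA/pF at −150 mV), and the inward limb is what pins the reversal
and hence P. The least-squares estimate of P is then right-skewed:
across replicates its median sits ≈1% above truth while its mean sits
≈10–14% above (a ratio-type, log-scale parameter). The replicate-mean
of fitted P is therefore an upward-biased summary at this noise level;
this is a property of maximum-likelihood estimation under the stated
noise, not of the optimizer (multistart confirms the fits are global
minima). The slope conductance g, by contrast, is pinned by the
well-measured outward limb and its replicate mean recovers truth to a
fraction of a percent.

## GHK reversal potentials (`ghk`)

Standard monovalent GHK voltage equation; cations enter the numerator
with outside concentrations and anions with inside concentrations.
Divalent species (Mg²⁺, Co²⁺…) are carried in `SolutionComposition`
for bookkeeping only and excluded from the sums. Activity coefficients
are 1 (concentrations used directly). With one permeant ion the
expression reduces exactly to the Nernst potential, which the tests
assert.

`solve_permeability_ratio` inverts the equation for a single unknown
ratio by Brent bisection on log₁₀(ratio), starting from [10⁻⁴, 10⁴] and
widening geometrically; the returned ratio reproduces the measured
E_rev to <10⁻⁹ mV. Compositions for which E_rev is insensitive to the
ratio (symmetric solutions) are rejected as unidentifiable, and an
unattainable E_rev raises an error reporting the attainable range. The
multi-ion case (e.g. SCN⁻/Cl⁻/Na⁺) is underdetermined by a single
reversal measurement; the solver therefore fixes all but one ratio and
the documentation makes no claim of recovering a joint pair. For the
tenfold-KCl configuration (140 mM inside // 14 mM outside, both ions),
a reversal of −14.7 mV yields P_Cl/P_K ≈ 0.49 with nominal
concentrations; a published value of 0.45 for the same configuration is
bracketed by [0.40, 0.55] and the difference plausibly reflects base
solution ions not included in the nominal composition. Both the forward
computation and the inversion are exposed so either convention can be
checked.

## Patch-clamp circuit (`patch`)

**Model.** Series resistance R_s feeding R_m ∥ C(V), with
Q(V) = C_lin V + Q_max b(V) and C(V) = dQ/dV, plus an optional
single-barrier conductance (g interpreted in absolute pS inside the
circuit). Charge balance gives

    C(V_m) dV_m/dt = (V_cmd − V_m)/R_s − (V_m − E_off)/R_m − I_barrier(V_m),

with recorded current (V_cmd − V_m)/R_s. Defaults R_s = 5 MΩ,
R_m = 500 MΩ are typical whole-cell values and are configuration
fields.

**Integration.** Classical RK4 on V_m (the charge-balance equation
divided by C(V); C > 0 everywhere makes V↔Q a bijection, so this is the
charge form expressed in V without the Newton inversion). Substeps per
sample are doubled until step-halving changes the membrane-voltage
trace by <0.1% of the command span; a step still moving V_m by more
than 5 mV at the refinement cap raises an error demanding a smaller
protocol dt. Steady states at held potentials are verified against the
algebraic solution of the resistive network.

**Capacitive-current correction.** I_cap = C(V(t))·dV/dt with centered
finite differences (one-sided at the ends). Protocol corners (ramp
onsets) are the worst case for the differentiator: the error at the
corner sample scales as dt/(4τ) with τ = R_s·C, so resolving the
correction to <1% of peak I_cap requires τ/dt ≳ 25 (e.g. dt = 2 µs for
τ ≈ 85 µs); this is the sampling used by the correction tests, and is a
property of differentiating sampled data at a corner, not of the
circuit model. Over a full ramp the integral of I_cap equals
C_lin·ΔV + ΔQ_nonlinear (charge conservation, asserted within 1%), and
over any closed voltage loop the net nonlinear charge vanishes.

**Dual-sine capacitance extraction.** The command superposes sinusoids
at f₁ and 2f₁ on a hold or slow ramp; per window of one f₁ cycle the
complex admittances Y(f₁), Y(2f₁) are estimated and the three-element
circuit solved in closed form: with Z = 1/Y = R_s + R_m/(1+ia),
a = ωR_mC_m,

    r = Im Z(2f₁)/Im Z(f₁) = 2(1+a²)/(1+4a²),
    a² = (2−r)/(4r−2),   R_m = −Im Z(f₁)(1+a²)/a,
    C_m = a/(ω₁R_m),     R_s = Re Z(f₁) − R_m/(1+a²).

This admittance algebra is derived here from the circuit equations (the
acquisition software used for such measurements is closed-source; this
is an independent reconstruction). Two numerical points matter:

1. *Harmonic estimation.* The phasors are obtained by per-window least
   squares against {1, t, cos/sin ω₁t, cos/sin 2ω₁t}, not by plain
   single-bin projection: a ramp's linear trend is **not** orthogonal
   to one-cycle sinusoids, and plain projection lets it leak into the
   phasors (≈4% in V(f₁) at the default ramp rate), wrecking the
   small-difference solve for R_s. The joint fit removes the leakage
   exactly and reduces the C_m error on a ramp from ≈1.3% to <0.01%.
2. *DC axis.* Each window's capacitance is plotted against the window's
   DC *membrane* potential, i.e. the command DC minus the I·R_s drop
   computed from the window-mean current — a standard series-resistance
   correction worth ~1 mV of V_h here.

Windows where Y(f₁) ≈ Y(2f₁) (no capacitive phase separation), or where
the solve leaves the physical branch (a² ≤ 0, R_m ≤ 0), are flagged
invalid rather than returned. Defaults: 10 mV amplitudes at
f₁ = 390.625 Hz (256 samples per cycle at 10 µs) — the amplitudes and
frequencies are arbitrary defaults, exposed on `Protocol`. Large
amplitudes smear the NLC bell (the instantaneous potential excursion is
±(A₁+A₂)); the end-to-end recovery of V_h is unaffected (<1 mV) but
Q_max acquires a percent-level bias through the window-truncation
correlation discussed under `nlc`.

## Stationary noise analysis (`noise`)

**Pipeline.** Per record: remove the mean, apply a full-length Hamming
window, take a one-sided periodogram (window power compensated, DC bin
dropped; resolution 1/(n·dt) ≈ 0.094 Hz for the default 1,061,306
points at 10 µs — a single periodogram per record mirrors that
resolution; a Welch segment-averaged mode exists behind a flag).
Spectra are averaged across replicate patches; the averaged 0-mV
spectrum is the instrumentation background and is subtracted pointwise,
negative densities being *retained* (clipping would bias the variance
upward — the flag `has_negative` marks them). Excess variance is the
trapezoidal integral of (S(f) − 2|⟨I⟩|e₀) over 0.1–1000 Hz on the
native linear grid (dense, 0.094 Hz, relative to the band edges); the
shot density uses the test-potential mean current. The unitary-current
estimate is i = σ²/⟨I⟩ (sign following the mean), which assumes
two-state switching at low open probability with fluctuations confined
to the band — a deliberately rough, order-of-magnitude estimator; the
package's end-to-end check holds it to a factor of two.

**Parseval convention.** The integral of the windowed, compensated
periodogram equals the *windowed* signal variance Σ(wx)²/Σw² — exactly,
up to the removed DC bin and trapezoid ends (<0.1%). For white-dominated
records this coincides with the plain variance to ~0.1%; for records
dominated by slow 1/f fluctuations the two can differ by ~1% in a
single realization (the window weights slow excursions unevenly). Tests
assert closure against the windowed variance, within 1%.

**Power-law fit.** Least squares in log f–log S. By default the
spectrum is first averaged into 40 log-spaced bins: raw periodogram
bins are exponentially distributed and their log is skewed, so binning
both symmetrizes the scatter and weights decades evenly. Exact A/f and
A/f² inputs are recovered to α = 1.000/2.000.

## Synthetic data (`synth`)

**What is emulated.** The generators produce every input the pipeline
consumes with the statistical structure the analysis assumes:

- C–V curves: model + i.i.d. Gaussian noise (default σ = 0.05 pF);
- I–V curves: model + Gaussian noise with σ = 2% of the curve's maximum
  |I| (homoscedastic across the voltage grid);
- patch records: n = 10,000 independent two-state channels, unitary
  current 2 fA (sign following the holding potential), open probability
  0.1, switching rates λ = k_open + k_close log-uniform over 0.2–2000 Hz;
  each channel contributes a Lorentzian with corner λ/2π, and the
  log-uniform superposition yields an ≈1/f spectrum across 0.1–100 Hz
  (fitted slope α ∈ [0.8, 1.2]). Shot noise of the mean current
  (density 2⟨I⟩e₀) and white instrument noise (0.3 pA rms) are added,
  and the sum passes a 4-pole 10 kHz Bessel filter emulating the
  acquisition chain. Records are 1,061,306 points at 10 µs to match the
  analysis' spectral grid; experiments default to 11 replicate patches
  at −50/0/+50 mV, the 0 mV records carrying instrument noise only.

The channel-model defaults are chosen once as plausible for a
macroscopic patch of a high-density membrane protein (they put the mean
patch current at 2 pA and the ensemble variance n·i²·p(1−p) at
3.6×10⁻²⁷ A²); the switching-rate floor keeps λ·T ≳ 2 so even the
slowest channels equilibrate within one record — without that, the
time-domain variance of a single record systematically undershoots the
ensemble variance. Two-state switchers were chosen over spectral
shaping of Gaussian noise deliberately: mean, variance and unitary
current then have physical meaning consistent with the σ²/⟨I⟩
estimator's assumptions.

**Determinism.** All randomness flows from `GeneratorSpec.seed`;
per-patch/per-potential streams are spawned with `SeedSequence.spawn`
(counter-based splitting), so outputs are bit-identical under a fixed
seed and patches are statistically independent.

**What is not emulated — hence what passing tests do not show.** Real
patches have seal instability, drift, line interference, Lorentzian
components from well-behaved gating, filter phase distortion near the
corner, and channel populations with correlated or voltage-dependent
kinetics. The generator's channels are stationary, independent, and
voltage-independent apart from the sign of i. Recovery of the
programmed unitary current within a factor of two therefore validates
the pipeline's bookkeeping (windowing, background and shot subtraction,
band integration, unit conversions) and the estimator's intrinsic
capture fraction — not its robustness to real-world artifacts. The
expected capture is quantifiable: channels slower than the 0.1 Hz band
edge and the (1−p) factor put the expected estimate near 0.65–0.75 of
the programmed i, well inside the factor-of-two band.

## Problem sizes in the standard runs

Recovery studies use 100 replicates per condition (C–V and I–V); the
noise pipeline uses one full 11-patch × 3-potential experiment at full
record length; circuit checks use single simulations at 10 µs (2 µs for
the corner-resolving correction test). These sizes make the whole suite
run in a few minutes while leaving replicate-mean standard errors an
order of magnitude below the tolerances being asserted.

## Known limitations

- Two-state NLC only; no higher-state models, no membrane-tension or
  temperature-dependence terms.
- Single barrier, single effective ion species per direction; no
  multi-barrier chains or diffusion limitation.
- GHK is monovalent with unit activities.
- The circuit model omits pipette capacitance, compensation circuitry
  and electrode drift.
- Nonstationary (ensemble) variance–mean analysis and Lorentzian
  fitting are out of scope.
- The σ²/⟨I⟩ estimator inherits its stated assumptions; its use of the
  0-mV spectrum as background is slightly wrong for nonzero reversal
  potentials (the error is quadratically small in the 0-mV current).
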