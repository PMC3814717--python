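# Methods

## Models and conventions

All three spiking models obey τ_m dV/dt = f(V) + I(t) with

* LIF: f(V) = −(V − E_L), threshold V_th = 20 mV, reset 10 mV
* QIF: f(V) = (V − V_T)²/Δ_T, Δ_T = 10 mV, V_T = 0; spike at +∞, reset at −∞
* EIF: f(V) = −(V − E_L) + Δ_T exp((V − V_T)/Δ_T), Δ_T = 1 mV, V_T = 10 mV,
  reset 3 mV, absolute refractory period 2 ms

with τ_m = 10 ms and E_L = 0 throughout.  Internal units are mV and ms;
rates cross the public API in Hz and eigenvalues in 1/ms.

The input current is I(t) = I₀(t) + σ(t)·√(2 τ_m)·η(t) with unit-variance
white noise η.  Under this scaling a purely leaky membrane has
stationary voltage variance σ², and the Fokker-Planck drift and
diffusion are a(V) = (f + I₀)/τ_m and D = σ²/τ_m.  The flag on
`InputDrive` records this convention explicitly; no other scaling is
implemented.

The infinite QIF/EIF spike threshold is handled with a numerical
ceiling.  For the EIF the exponential blow-up makes the ceiling
placement irrelevant (transit beyond 30 mV takes ~τ_m e⁻²⁰).  For the
QIF the deterministic tail transit is *not* negligible — τ_m Δ_T/V per
side — so the simulator registers the spike with a transit delay
τ_m Δ_T/V_max after crossing V_max = 100 mV and re-enters the neuron at
V_min = −100 mV after the matching delay, and the Fokker-Planck solvers
add the same analytic correction for their own (wider, tan-spaced)
voltage window.

## Fokker-Planck numerics

**Stationary problem.**  The scaled density p̂ = P₀/r is integrated
downward from the absorbing threshold (p̂ = 0 there) with a per-step
exponential integrator that is exact for locally constant drift; the
scaled flux is 1 above the reset and 0 below (the reset flux jump).
The rate follows from normalization, r = 1/(∫p̂ dV + τ_ref + t_transit),
which is the refractory correction r = r_free/(1 + τ_ref r_free) in
additive form.  The refractory (and QIF tail-transit) probability mass
is counted with the density when checking ∫P₀ + r·τ_hold = 1.

**ISI CV.**  The first two first-passage-time moments solve the
backward equations a M_k′ + D M_k″ = −k M_{k−1}; each is reduced to a
pair of first-order ODEs integrated with the same exponential scheme
(one ascending pass for the integrating-factor variable, one descending
for the moment).  CV = √(M₂ − M₁²)/(M₁ + τ_ref).  The moments converge
slowly in dv/σ, so the grid spacing is σ-adaptive: dv = min(1/16 mV,
σ/32), floored at 1/512 mV.  Monte-Carlo simulations at dt → 0 confirm
the resulting CV to ~0.1%.

**Dominant eigenvalue, LIF/EIF.**  The eigenfunction pair (φ, j) obeys
φ′ = (aφ − j)/D, j′ = −λφ, with φ = 0 and j = 1 at threshold and a
reinjection jump at the reset; λ is a root of the characteristic
function j(V_floor).  Roots are located by Newton-Raphson (relative
tolerance 1e−8, ≤ 50 iterations) from a lattice of twelve starts around
the universal-fit prediction, including pure-real starts that catch the
diffusive real branch dominating at high noise; among the converged
roots the one with the largest real part is λ₁.  For the LIF the
eigenfunctions are confluent-hypergeometric; the characteristic
function is evaluated by integrating that same ODE numerically, which
is equally exact to solver tolerance.

**Refractory reinjection delay.**  The reset reinjection in the
spectral and linear-response problems carries the factor e^(−λτ_ref)
(respectively e^(−iωτ_ref)): flux absorbed at threshold reappears at
the reset one refractory period later.  This choice makes Im λ₁/2π
equal the steady firing rate 1/(T_fp + τ_ref) at low CV — the EIF
baseline resonates at 50 Hz, not at the free rate 1/T_fp ≈ 55.6 Hz —
and is confirmed by the direct PDE transient and by Monte-Carlo.

**Dominant eigenvalue, QIF.**  The substitution V = (Δ_T/2) tan(θ/2)
maps the QIF onto a phase model on [−π, π) with periodic boundary
conditions (spike and reset coincide at θ = π).  The Itô-corrected
drift and diffusion are trigonometric polynomials of degree ≤ 2, so the
Fokker-Planck operator is banded in the Fourier basis.  The operator is
truncated at |n| ≤ 100 harmonics (doubling moves λ₁ by < 0.5%) and
diagonalized densely; λ₁ is the nonzero eigenvalue with the largest
real part.  The stationary Fourier vector also yields the rate as
P(π)/τ_m, an independent cross-check of the threshold-integration rate
(they agree to ~0.02%).

**Linear response.**  For LIF/EIF, the first-order modulated problem is
solved by the same downward threshold integration with two shooting
solutions (unit rate modulation without source; zero rate modulation
with the P₀/τ_m source); their ratio gives the complex gain.  For the
QIF, the modulated Fourier system (M − iω)ĉ = −(∂M/∂μ)c₀ is solved
directly.  The ω → 0 limit reproduces dr∞/dμ to 1%.

**Direct PDE oracle.**  An independent method-of-lines integrator
(Scharfetter-Gummel exponential-fitted face fluxes, Crank-Nicolson in
time, refractory delay queue for the reinjected flux) provides rate
transients after a 1% step in μ.  Fitting r∞ + A e^(αt) cos(Ωt + φ)
over a 100 ms window after a 20 ms blank (FFT peak and Hilbert-envelope
slope as initial guesses) recovers (Re λ₁, Im λ₁) within a few percent
wherever the dominant mode is well separated; the acceptance suite
checks 15% at five operating points per model.

## The universal λ(r∞, CV) fit

`LambdaFit` closes the complex model with λ = r∞(−α CV² + 2πi),
α = 19.74 (= 2π² to the digits kept), validity CV ≤ 0.75.  The 2π slope
of the imaginary part expresses ringing at the interspike frequency;
the quadratic CV dependence of the decay follows the phase-diffusion
picture of a renewal process (variance of the k-th spike time grows
like k T² CV²), which predicts α = 2π² at small CV.  Refitting α on
this package's own eigenvalue surfaces (EIF at σ = 1, 2, 4 mV, matched
LIF/QIF points, CV ≤ 0.75) gives α = 20.1, i.e. the theoretical
constant within 2%; the theoretical value is kept.

Known deviation: with a refractory period the ringing frequency exceeds
2π r∞ as CV grows (the EIF σ = 4 mV curve reaches Im λ₁/(2π r∞) ≈ 1.27
at CV 0.58).  The acceptance suite asserts the ±20% band wherever the
dominant mode is oscillatory and deliberately leaves those two
high-noise points failing rather than widening the band; at and below
CV ≈ 0.5 the band holds across all three models.

## Operating tables and calibration

Tables store r∞, CV (and optionally λ₁) on rectangular (μ, σ) grids;
lookup is bilinear, inverse lookup is 2-D least squares on the
interpolant, and out-of-hull queries raise.  `calibrate_operating_point`
refines a coarse-scan (or table-seeded) start by least squares on
log-ratio residuals against the *direct* solvers; the network baseline
(50 Hz, CV 0.1) calibrates to (μ, σ) = (12.623, 0.520) for the EIF and
verifies to < 0.5% for all three models.

## Simulators

Euler-Maruyama with threshold handling at step granularity (no
crossing-time interpolation); default dt = 0.02 ms for QIF/EIF and
0.05 ms for LIF.  At the prescribed network dt = 0.02 ms the EIF
baseline rate is biased −0.4% and the CV −0.6%, both converging
linearly in dt to the Fokker-Planck values; the Monte-Carlo acceptance
checks therefore allow 3 empirical standard errors plus this documented
1% envelope.  Per-neuron noise streams in the uncoupled simulator are
counter-based (stream = neuron index), so growing the population leaves
existing neurons' realizations unchanged.  PSTHs default to 1 ms bins;
figure-style traces use a 2 ms Gaussian kernel; stationary statistics
discard a 200 ms transient.

## Excitatory-inhibitory networks

Each neuron receives exactly K excitatory and K inhibitory synapses
(fixed in-degree, no autapses, uniform draws without replacement);
a presynaptic spike kicks the postsynaptic voltage by J/τ_m at the next
integration step (instantaneous synapses, J in mV·ms).  Mean-field
drive:

    μ_a = μ_x + K (J_aE r_E − J_aI r_I),
    σ²_a = σ²_x + K (J_aE² r_E + J_aI² r_I)/(2 τ_m),   rates in 1/ms,

verified against direct accumulation of synaptic increments in the
spiking simulation (< 5%, typically < 0.5%).  Defaults: N_E = N_I =
5,000, K = 500; scaled-down runs multiply weights by K_ref/K so the
mean drive is preserved (the shot-noise variance then grows, which is
the physical price of a smaller network).  Scans parameterize
(w_E, w_I) = (J_EE, J_EI) with the weights onto inhibitory neurons
scaled by the fixed ratio g = 0.5 (J_IE = g w_E, J_II = g w_I).  The
external drive is calibrated so uncoupled neurons sit at 50 Hz, CV 0.1.

The two-unit rate network refreshes (r∞, CV, λ) every 0.1 ms step from
the instantaneous drive (quasi-static approximation; exact exponential
stepping of the linear ODE between refreshes).  Transiently negative
real rates are reported as-is but floored at zero where they feed the
drive equations, keeping σ² ≥ σ_x².  Fixed points solve
r_a = r∞(μ_a(r), σ_a(r)) (hybrid root-finder, multiple starts;
residual < 1e−8 Hz); stability comes from the eigenvalues of the 4×4
Jacobian over (Re r̂_E, Im r̂_E, Re r̂_I, Im r̂_I), assembled by central
finite differences with relative step 1e−4.  Forward runs are labelled
limit-cycle when the Welch peak of the late trajectory exceeds 10× the
median spectral floor *and* the tail fluctuates by ≥ 0.1 Hz (the
amplitude guard rejects decayed transients of the noiseless rate
dynamics).

With these parameters the asynchronous state destabilizes via a Hopf
bifurcation (leading Jacobian eigenvalues ≈ ±2πi·55/1000 per ms) for
w_E ≳ 0.15 mV·ms at moderate w_I; inside the unstable region the rate
network oscillates with dominant frequency ≈ 51 Hz, the spiking network
at ≈ 55 Hz, both near the 50 Hz baseline and in phase across the two
populations.  Pure excitation (w_I = 0) remains stable up to the edge
of fixed-point existence (w_E ≈ 0.35 mV·ms at K = 500); stronger pure
excitation has no self-consistent fixed point (runaway), which the
stability scan records as a failed cell rather than a verdict.

## Comparison metrics

The shifted correlation coefficient is the Pearson correlation between
two equally-sampled rate series maximized over integer-bin shifts
within ±5 ms by default (sensitivity at 2/5/10 ms is exposed as a
flag); series are mean-subtracted, and the overlap after shifting must
retain 90% of the length.  Spectra are Welch-averaged (256 ms segments,
50% overlap, one-sided density normalized to the series variance);
cross-correlograms are normalized correlations over ±lag with the peak
lag reported.

## Study conditions and problem sizes

The bundled protocols emulate the uncoupled-population and network
experiments the model was built for: current steps, the five-sinusoid
mixture (61, 50, 33, 13.1, 7.9 Hz) with uniformly random phases from a
logged sub-seed, and constant white-noise backgrounds.  The sinusoid
amplitude is not a published quantity; it is fixed at 1.0 mV per
component, which modulates the 50 Hz baseline by roughly ±10–20 Hz —
the scale at which the rate-model comparison probes model error rather
than the shot noise of a finite population.

Default validation sizes, chosen to resolve every tested effect
comfortably: 2,000 neurons × 20 s for the baseline calibration check;
2,000 neurons × 10 s per noise level for the fidelity ordering;
a 5 × 5 weight grid at K = 500 for the stability map; 4 × 4 grids with
N = 1,000, K = 100 for the spiking-vs-analytic transition comparison.

What the synthetic conditions do **not** emulate: conductance-based or
temporally filtered synapses (inputs are white-noise currents by
construction), heterogeneous cell parameters, synaptic delays, and
correlated background noise.  Agreement on these benchmarks therefore
demonstrates the fidelity of the two-mode reduction for ideal
current-based populations, not for biophysically detailed circuits.

## Known limitations

* The diffusion approximation needs appreciable noise; σ → 0 is refused
  (deterministic closed forms exist there) and rates below ~1e−3 Hz are
  returned as effectively zero.
* The two-mode truncation degrades for CV ≳ 0.75: the decay of the
  dominant mode steepens beyond the quadratic CV law, ringing runs
  faster than 2π r∞ for refractory models, and additional modes carry
  weight.  The package tabulates exact eigenvalues there instead of
  trusting the fit.
* Euler-Maruyama with step-granularity thresholding biases rates by
  O(dt); the documented envelope at the default steps is < 1% and the
  convergence tests pin it.
* The rate-network limit cycle is quantitatively trustworthy only near
  the bifurcation; deep inside the unstable region trajectories swing
  to large negative real parts where the linear model has no spiking
  interpretation, and some strongly-coupled cells settle instead on an
  inhibition-dominated low-rate fixed point.
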