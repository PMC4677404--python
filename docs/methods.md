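# Methods

This note documents the models, estimator conventions, numerical choices
and known limitations of the package. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Synthetic processes

**Fractional Brownian motion.** Trajectories are built from fractional
Gaussian noise with autocovariance
γ(k) = σ²/2 (|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H}), σ = `step_scale`·dt^H,
synthesized by circulant (Davies–Harte-style) embedding: the covariance
sequence up to lag n is reflected into a length-2n circulant whose FFT
eigenvalues weight Hermitian Gaussian noise. The embedding is exact when
the eigenvalues are non-negative (always observed for the fGn family
here); if it fails, a Cholesky factorization of the Toeplitz covariance is
used for n ≤ 4096 and an error is raised beyond. Exactness of the
increment covariance is the test surface: the suite checks the sample
autocovariance against the closed form within 3 SE over 10³ paths.
Dimensions are independent; each path starts at the origin; TAMSD scales
as Δ^{2H}.

**Tempered fBM (the crossover surrogate).** The measured phenomenology —
subdiffusion with α ≈ 0.65 at short lags crossing to α = 1 beyond a
memory time — is emulated by multiplying the fGn autocovariance by
exp(−k·dt/t_c). This preserves the Δ^{2H} short-lag scaling and, because
the damped covariance is absolutely summable with positive sum, yields
strictly linear MSD growth at long lags; one parameter (t_c) controls the
crossover. The underlying stochastic model of the real protein's motion
is not claimed to be tempered fBM; it is a surrogate that reproduces both
limits. `tempered_msd` computes the theoretical MSD by summing the
damped covariance and serves as the slope oracle in tests. Note the
crossover in a TAMSD plot is soft: the fitted two-segment breakpoint
lands a factor 2–3 above t_c, which the tests assert only within a factor
of three.

**CTRW.** Pareto waiting times P(w > t) = (t/τ_min)^{−a} with a ∈ (0, 1),
Gaussian jumps, piecewise-constant sampling on a unit grid. The limit
a = 1 is implemented as the degenerate fixed-wait case (every wait equals
τ_min), which recovers a lattice-time random walk; a genuine Pareto law
with a = 1 has an infinite mean and no such limit exists through it.
CTRW is included as the non-ergodic counterpoint: its single-trajectory
TAMSD scatter stays O(1) as T grows, while fBM's shrinks.

**Sojourn sampling.** The cutoff power law
P(τ) = A τ^{−1−γ} e^{−τ/τ_c} on [τ_min, ∞) is sampled exactly by Pareto
inverse transform plus acceptance with probability
exp(−(τ−τ_min)/τ_c). The acceptance rate degrades when τ_c < τ_min (a
warning is emitted). The sampler is validated against the analytic
Pareto CCDF (τ_c = ∞) and the quadrature CDF (finite τ_c) by KS tests at
the 1% level, n = 10⁴.

**Alternating renewal and contact counts.** The ±1 series records, at
each grid time i·dt, the state of the continuous-time sojourn covering
it; the final sojourn is truncated at the horizon and flagged censored.
Sub-dt sojourns can be skipped entirely by the grid — a deliberate
consequence of sampling, identical to what happens when MD frames
undersample fast contact flickering. Contact counts superpose K
independent ON/OFF processes; the suite checks the mean against the
renewal-reward ratio K·E[ON]/(E[ON]+E[OFF]) and the PSD against K times
the single-process PSD.

**Toy membrane frames.** A scripted protein (3 particles per residue)
approaches a flat lipid layer linearly from distance 9 to 1.5; after the
scripted binding frame, a chosen fraction of each lipid species is placed
within 0.35 (half the 0.7 cutoff) of designated protein particles, so
per-frame contact counts are known by construction. Fixtures are
geometric only — no lipid chemistry is emulated.

## Estimators

**TAMSD.** The overlapping-window estimator
δ²(mΔt) = (N−m)^{-1} Σ_i |r_{i+m} − r_i|² — the universal convention in
the single-particle-tracking literature. Exactness is asserted against a
brute-force double loop. The default lag grid is log-spaced at 25
points/decade up to T/10 (bias–variance compromise; longer lags average
too few windows). Exponent fits are ordinary least squares on
(log Δ, log δ²) over an explicit, reported lag range; D_a =
exp(intercept)/(2d). The crossover detector fits a continuous two-segment
line with the breakpoint searched on the lag grid (global SSE, ties to
the smaller lag) and flags breakpoints that improve the single-line SSE
by less than 5% as not significant. Trajectories are assumed unwrapped;
periodic-boundary handling lives only in the contacts module.

**Rotational TAMSD.** Per-frame relative rotations (quaternion mode:
axis–angle of q_i^{-1}q_{i+1}, short-arc branch; vector mode:
(u_i × u_{i+1}) normalized, arccos of the clipped dot product) are
accumulated into the unbounded rotation vector φ(t); the translational
estimator is applied to φ. Consecutive orientations must be separated by
less than π (antipodal frames have no unique axis and raise). Vector
mode tracks each supplied body vector independently. Because large
per-frame rotations alias through the double cover, orientation series
should be sampled so that typical increments are well below π.

**Spectra.** One-sided periodogram with mean removal and no taper by
default (optional Hann), normalized so Σ S·df equals the series variance
exactly. Exponent fits log-bin the PSD (10 bins/decade, geometric
edges), average log S per bin, and regress against the bin-mean log f —
bin means of logs reduce the scatter bias of raw periodogram ordinates.
The fit band is always explicit and echoed in the report.

**Aging diagnostic.** For each measurement time T_m the ensemble PSD of
the window [0, T_m] is computed; the overlap statistic is the largest
log-binned |log S_{T_m} − log S_{T_m'}| over common bins and pairs. The
verdict threshold is the 95th percentile of the same statistic under a
stationary white-noise null at matched lengths and ensemble size,
simulated directly on the Fourier grid (periodogram ordinates of white
noise are exponential; an n-series ensemble mean is Gamma(n)/n), with 200
null draws by default.

**Sojourn MLE.** The cutoff-family likelihood uses
A = [τ_c^{−γ} Γ(−γ, τ_min/τ_c)]^{-1}; the upper incomplete gamma at
negative shape is evaluated by the downward recurrence
Γ(s, x) = (Γ(s+1, x) − x^s e^{−x})/s on top of the scipy gammaincc/exp1
routines, property-tested against quadrature. Optimization is L-BFGS-B
over (γ, log τ_c) from 12 starts, γ constrained to (0, 2] and τ_c to
[τ_min, 10⁶ τ_min]; boundary-hitting fits are flagged, and standard
errors come from the numerical Hessian. The pure power law uses the Hill
estimator γ̂ = 1/mean(log τ/τ_min) and the exponential family the
closed-form rate. τ_min defaults to the smallest observation and should
normally be set to the sampling interval; γ̂ is sensitive to it, so it is
an explicit argument echoed in every report. MLE was chosen over
histogram least squares (fewer arbitrary choices, testable closed-form
special cases).

**Dichotomous processes.** State +1 strictly above the threshold, −1 at
or below (ties to low). The mean threshold is computed on the analyzed
window. First and last sojourns are censored and excluded from default
statistics (a flag includes them). Surrogates permute high durations
among high slots and low among low slots independently, rebuild from the
original initial state, and truncate/pad the tail to the original grid
length so PSDs are length-comparable.

## The β = 2 − γ relation and its range of validity

For alternating renewal with sojourn tails τ^{−1−γ}, γ < 2, the PSD obeys
S(f) ∝ f^{−(2−γ)} in the scale-free band. Two practical caveats that the
package makes explicit rather than hiding:

1. The asymptote needs ω·τ_min ≲ 10⁻³ — about three decades of clearance
   below the smallest-sojourn scale. The exact stationary spectrum,
   S(ω) ∝ ω^{−2} Re[(1−ψ̂(iω))/(1+ψ̂(iω))] with ψ̂ the sojourn
   characteristic function, can be evaluated by quadrature: for
   γ = 0.57, τ_c/τ_min = 600 its local log–log slope peaks at ≈ 1.32
   (near f ≈ 0.016/τ_min) and never reaches 2 − γ = 1.43 anywhere above
   the cutoff frequency, because the analytic ω^γ term competes with the
   mean-sojourn iωμ term until ω is very small. Simulations with this
   package reproduce the exact curve; fits over f ∈ [0.01, 0.1] at these
   parameters therefore report β ≈ 1.25–1.26, not 2 − γ. This is a
   property of the model at that scale separation, not an estimator bias.
2. The relation is consequently verified in the genuinely scale-free
   regime — τ_c = ∞, T = 10⁶, fit band f ∈ [10⁻⁴, 10⁻³] — where the
   suite asserts |β̂ − (2 − γ)| ≤ 0.08 for γ ∈ {0.3, 0.57, 0.8}. For
   γ ∈ (1, 2) (finite mean) the same band recovers β = 2 − γ as well
   (checked at γ = 1.5).

Aging follows the same cutoff logic: ensembles measured over windows
shorter than τ_c are non-stationary and their PSD magnitude depends on
T_m; windows far above τ_c do not age. With τ_c = ∞ the process ages at
every measurement time.

## Dissociation model

Simulations start in the high state, matching the expansion
T_e = H₁ + L₁ + ⋯ + H_n + U_n; at each low state an escape clock
U ~ Exp(c) races the sojourn, ties (measure zero) resolving to
dissociation. H and L share one law, and the three families are
mean-matched to a target mean of 1 (the natural dimensionless scale):
exponential by its rate; Pareto via τ_min = mean·(γ−1)/γ (γ > 1
required — an infinite-mean family without cutoff is rejected); the
cutoff family by root-bracketing the scale against the closed-form mean
τ_c·Γ(1−γ, τ_min/τ_c)/Γ(−γ, τ_min/τ_c). The exponential closed form
E[T_e] = (2λ+c)/(cλ) (geometric number of cycles; survived low states
and the final escape are competing-exponential minima of mean 1/(λ+c))
anchors the simulator within 3 SE across a (λ, c) grid.

Normalized mean residence times of the heavy-tailed families satisfy
≥ 1 − 2·SE across the 1/c grid, but they are **not** monotone in 1/c:
both limits c → 0 and c → ∞ force the ratio to 1 (many-cycle averaging
and instant escape respectively), so the deviation peaks at intermediate
1/c. The tests assert the ≥ 1 property and the true monotonicity — raw
mean T_e non-increasing in c for every family.

## Contacts

A lipid molecule is in contact when **any** of its particles lies
strictly within the cutoff of **any** protein particle under orthorhombic
minimum image (molecule-level deduplication, matching "number of lipid
molecules around the protein"). Neighbor search uses a periodic KD-tree
with an exact distance recheck to enforce the strict inequality; equality
with the O(N·M) double loop is asserted on random frames. Binding is
declared where the protein/bilayer COM distance (along z by default —
for a flat bilayer the normal component is the meaningful one; full 3D
behind a flag) stays below 4 length units, with the first 100 time units
of each window discarded as relaxation. Triclinic boxes and
chemistry-aware contacts (hydrogen bonds, headgroup specificity) are out
of scope.

## Problem sizes and determinism

Default study conditions are 25 realizations of 10⁵ steps/samples for
TAMSD and spectral ensembles (the β = 2 − γ verification uses T = 10⁶ to
reach its asymptotic band), 10⁴–10⁵ samples for MLE recovery, and
2–20 × 10⁴ realizations for dissociation means. Every generator and
pipeline stage takes an explicit seed; a config rerun is byte-identical.
The synthetic generators emulate the statistical structure of
membrane-protein observables (increment memory, heavy-tailed contact
kinetics, renewal superposition) but not their physics — no force
fields, no lipid chemistry, no hydrodynamics — so passing tests validate
the estimators and the stochastic models, not any particular molecular
system.
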