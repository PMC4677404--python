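# anomemb

Anomalous-dynamics analysis for peripheral membrane proteins — the
statistical toolkit behind questions like: *how does a PH domain move on a
PIP-containing bilayer, why does its lipid-contact signal carry 1/f noise,
and what does that noise do to its residence time on the membrane?*

It is written for computational biophysicists who have (or want to emulate)
single-particle trajectories, orientation series and lipid-contact counts,
and who need the standard estimators of the anomalous-dynamics literature
as tested, composable Python functions rather than one-off scripts.

## What it computes

**Time-averaged MSD (TAMSD).** For a trajectory r(t) of measurement time
*T*, at lag Δ:

    δ²(Δ; T) = 1/(T−Δ) ∫₀^{T−Δ} |r(t+Δ) − r(t)|² dt  ≃  2 d D_a Δ^α

with subdiffusive exponent α and generalized diffusion coefficient D_a.
The package fits α over explicit lag ranges, detects the sub-to-normal
crossover with a continuous two-segment log–log fit, extracts D from the
linear regime, computes the ergodicity-breaking scatter (relative SD of
single-trajectory TAMSDs), and conditions the TAMSD on the state of a
dichotomous process.  Rotational TAMSD applies the same estimator to the
accumulated rotation vector φ(t) built from quaternions or tracked body
vectors.

**Ensemble power spectra and 1/f noise.** One-sided periodograms
S(f) = (dt/N)|DFT(x − x̄)|² (Parseval-exact), ensemble averaging,
log-binned fits of S(f) ∝ f^(−β), and an aging diagnostic that compares
PSDs across measurement times against a Monte-Carlo white-noise null.

**Dichotomous contact processes.** Thresholding a lipid-contact count
N(t) at its mean into ±1 states (ties to low), run-length residence
times with censoring, and shuffled surrogates that preserve the per-state
sojourn multisets while destroying sojourn-order memory.

**Heavy-tailed sojourn fitting.** Maximum likelihood for
P(τ) = A τ^(−1−γ) exp(−τ/τ_c) on [τ_min, ∞) — the normalization uses the
upper incomplete gamma function of negative shape — plus pure power-law
(Hill estimator) and exponential families, with AIC model ranking.

**Renewal theory.** For alternating renewal processes with sojourn tail
exponent γ < 2 the spectral exponent obeys β = 2 − γ in the scale-free
band; the package predicts, simulates and verifies this, including the
aging dichotomy (spectra age below the cutoff timescale τ_c, not above).

**Membrane dissociation model.** The protein alternates high/low
lipid-contact states H₁, L₁, H₂, … and can leave only from a low state,
racing an exponential escape clock U ~ Exp(c):
T_e = H₁ + L₁ + ⋯ + H_n + U_n.  Mean-matched comparison of exponential,
power-law and power-law-with-cutoff sojourn families shows how heavy
tails prolong membrane residence.  (Exponential sojourns admit the closed
form E[T_e] = (2λ + c)/(cλ), used as the simulation oracle.)

**Contact analytics.** Minimum-image, molecule-deduplicated lipid-contact
counting at a strict cutoff (0.7 length units for coarse-grained, 0.4 for
atomistic particles), per-residue normalized contact profiles, COM-
distance series along the membrane normal, and binding-window detection
(distance < 4, first 100 time units discarded).

**Synthetic data.** Every input can be generated with known structure:
fractional Brownian motion by exact circulant embedding (TAMSD exponent
α = 2H), tempered fBM for the crossover, CTRW as the non-ergodic
counterpoint, exact rejection sampling of cutoff power-law sojourns,
alternating renewal and superposed ON/OFF contact processes, and scripted
toy membrane frames with contacts known by construction.

## Worked example

```python
from anomemb import (FbmParams, gen_tempered_fbm, tamsd, ensemble_tamsd,
                     fit_exponent, detect_crossover)

params = FbmParams(hurst=0.325, n_steps=100_000, dim=2, n_traj=25, seed=1)
trajs = gen_tempered_fbm(params, crossover_time=10.0)
ens = ensemble_tamsd([tamsd(t) for t in trajs])
print(fit_exponent(ens, (1, 5)).alpha)        # 0.703
print(fit_exponent(ens, (1000, 10_000)).alpha)  # 0.995
print(detect_crossover(ens).crossover_lag)    # 28.0
```

The short-lag exponent sits near 2H = 0.65 (tempering pulls it slightly
up), the long-lag exponent is 1 (normal diffusion), and the fitted
breakpoint lands within a factor of three of the generator's crossover
time — the crossover is soft, so the two-segment fit places it late.
The `examples/` directory has one short script per capability
(subdiffusion, rotation, contact-noise spectra, sojourn fitting, the
β = 2 − γ relation, dissociation, contact analytics), each printing the
numbers it computes and what they mean.

A thin CLI mirrors the library for shell use:
`anomemb generate|tamsd|psd|dichotomize|fit-sojourns|renewal|dissoc|run`.

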