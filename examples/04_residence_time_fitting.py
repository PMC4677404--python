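"""Maximum-likelihood fitting of residence-time distributions.

Draws sojourn times from the power-law-with-cutoff density
P(tau) = A tau^(-1-gamma) exp(-tau/tau_c) with the high-state parameters
(gamma = 0.57, tau_c = 600) and recovers them by MLE; then ranks the three
candidate families by AIC.
"""

from anomemb import SojournParams, sample_sojourns, fit_sojourns, compare_models

truth = SojournParams(gamma=0.57, tau_c=600.0, tau_min=1.0)
data = sample_sojourns(truth, 50_000, seed=4)

fit = fit_sojourns(data, family="plaw_cutoff", tau_min=1.0)
print(f"recovered gamma = {fit.gamma:.3f} +- {fit.stderr['gamma']:.3f} "
      "(truth 0.57)")
print(f"recovered tau_c = {fit.tau_c:.0f} +- {fit.stderr['tau_c']:.0f} "
      "(truth 600)")

ranked = compare_models(data, tau_min=1.0)
print("model ranking by AIC:")
for f in ranked:
    print(f"  {f.family:12s}  AIC = {f.aic:12.1f}")
# The cutoff family should rank first: the data have a Pareto bulk
# (gamma < 1, diverging mean without the cutoff) tempered at tau_c.
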