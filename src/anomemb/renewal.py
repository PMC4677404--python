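"""Renewal theory tying sojourn statistics to 1/f spectra.

For an alternating two-state renewal process whose sojourn times follow a
power law (with or without cutoff) of exponent gamma < 2, the power
spectral density decays as S(f) ~ f^(-beta) with beta = 2 - gamma, in the
frequency band above the inverse cutoff 1/tau_c.  Below the cutoff
timescale the process is non-stationary: PSDs measured over windows
shorter than tau_c depend on the measurement time (aging); windows much
longer than tau_c do not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from anomemb.spectra import AgingResult, aging_test, ensemble_psd, fit_psd_exponent
from anomemb.dichotomy import residence_times

__all__ = [
    "RenewalPrediction",
    "BetaVerification",
    "predict_beta",
    "verify_beta",
    "aging_regimes",
]


@dataclass
class RenewalPrediction:
    gamma: float
    predicted_beta: float
    validity: str


@dataclass
class BetaVerification:
    beta_hat: float
    beta_stderr: float
    predicted_beta: float
    residual: float
    f_range: tuple[float, float]
    n_series: int


def predict_beta(gamma: float) -> RenewalPrediction:
    """beta = 2 - gamma, valid for 0 < gamma < 2 and for fit bands above
    the cutoff frequency 1/tau_c."""
    if not (0.0 < gamma < 2.0):
        raise ValueError(
            f"beta = 2 - gamma holds only for gamma in (0, 2); got {gamma}"
        )
    return RenewalPrediction(
        gamma=gamma,
        predicted_beta=2.0 - gamma,
        validity="valid for 0 < gamma < 2; fit the PSD above 1/tau_c",
    )


def verify_beta(
    sojourn_params,
    T: float,
    n_real: int = 25,
    f_range: tuple[float, float] = (0.01, 0.1),
    seed: int = 0,
    dt: float = 1.0,
) -> BetaVerification:
    """Simulate the renewal ensemble, fit the ensemble-PSD exponent, and
    report the residual against the beta = 2 - gamma prediction.

    ``sojourn_params`` (a :class:`~anomemb.synthgen.SojournParams`) is used
    for both states.  Refuses spectra of degenerate (fixed-sojourn)
    processes, which are line combs rather than scale-free.
    """
    from anomemb.synthgen import RenewalSeriesParams, gen_alternating_renewal

    if np.isfinite(sojourn_params.tau_c) and f_range[0] < 1.0 / sojourn_params.tau_c:
        raise ValueError("fit band must lie above the cutoff frequency 1/tau_c")
    ss = np.random.SeedSequence(seed)
    series = []
    for child in ss.spawn(n_real):
        p = RenewalSeriesParams(
            high=sojourn_params, low=sojourn_params, total_time=T, dt=dt,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        series.append(gen_alternating_renewal(p))
    # guard: a (near-)periodic square wave has no scale-free spectrum
    res = residence_times(series[0])
    d = res.durations[~res.censored]
    if len(d) >= 2 and np.std(d) < 1e-9 * np.mean(d):
        raise ValueError("degenerate fixed sojourns: spectrum is a line comb, "
                         "not scale-free")
    pred = predict_beta(sojourn_params.gamma)
    psd = ensemble_psd(series, dt=dt)
    fit = fit_psd_exponent(psd, f_range)
    return BetaVerification(
        beta_hat=fit.beta,
        beta_stderr=fit.stderr,
        predicted_beta=pred.predicted_beta,
        residual=abs(fit.beta - pred.predicted_beta),
        f_range=f_range,
        n_series=n_real,
    )


def aging_regimes(
    sojourn_params,
    measurement_times,
    seed: int = 0,
    n_real: int = 25,
    dt: float = 1.0,
    n_null: int = 200,
) -> dict[float, AgingResult]:
    """Aging verdict for pairs of measurement times straddling tau_c.

    For each requested T_m the ensemble PSD over [0, T_m] is compared with
    the PSD over the full window max(measurement_times); the expected
    pattern for a power-law-with-cutoff renewal process is "aging" for
    T_m < tau_c and "no aging" for T_m >> tau_c.
    """
    from anomemb.synthgen import RenewalSeriesParams, gen_alternating_renewal

    measurement_times = sorted(measurement_times)
    if len(measurement_times) < 2:
        raise ValueError("need at least two measurement times")
    T = float(measurement_times[-1])
    ss = np.random.SeedSequence(seed)
    series = []
    for child in ss.spawn(n_real):
        p = RenewalSeriesParams(
            high=sojourn_params, low=sojourn_params, total_time=T, dt=dt,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        series.append(gen_alternating_renewal(p))
    out = {}
    for T_m in measurement_times[:-1]:
        out[T_m] = aging_test(series, [T_m, T], dt=dt, seed=seed + 1,
                              n_null=n_null)
    return out
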