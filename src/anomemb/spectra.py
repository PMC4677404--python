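"""Ensemble power spectral density, 1/f exponent fitting, aging tests.

A process whose contact fluctuations are governed by heavy-tailed sojourn
times shows 1/f noise, S(f) ~ 1/f^beta; for an alternating renewal process
with sojourn exponent gamma < 2 the spectral exponent is beta = 2 - gamma.
Aging (dependence of the PSD magnitude on the measurement time T_m) is the
spectral fingerprint of non-ergodicity and disappears once T_m greatly
exceeds the exponential cutoff of the sojourn law.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PsdCurve",
    "PsdExponentFit",
    "AgingResult",
    "periodogram",
    "ensemble_psd",
    "fit_psd_exponent",
    "aging_test",
]


@dataclass
class PsdCurve:
    """One-sided spectral density on positive Fourier frequencies.

    Normalised so that sum(values) * df equals the series variance
    (Parseval, mean-removed input).
    """

    frequencies: np.ndarray
    values: np.ndarray
    T: float
    n_series: int = 1
    detrended: bool = True

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.frequencies.shape != self.values.shape:
            raise ValueError("frequency and value grids must match")
        if np.any(self.frequencies <= 0) or np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be positive ascending")
        if np.any(self.values < 0):
            raise ValueError("spectral density must be non-negative")


@dataclass
class PsdExponentFit:
    """1/f^beta fit on a log-binned band."""

    beta: float
    stderr: float
    f_range: tuple[float, float]
    n_bins: int
    r2: float


@dataclass
class AgingResult:
    """Outcome of the measurement-time-dependence (aging) diagnostic."""

    psds: dict
    statistic: float
    threshold: float
    aging: bool

    @property
    def verdict(self) -> str:
        return "aging" if self.aging else "no aging"


def periodogram(series, dt: float = 1.0, remove_mean: bool = True,
                hann: bool = False) -> PsdCurve:
    """One-sided periodogram S(f_k) = (dt/N) |DFT(x - mean)|^2.

    Positive frequencies only; interior bins carry the factor two so that
    sum(S) * df reproduces the input variance exactly (Parseval).
    An optional Hann taper is available; default is the raw periodogram.
    """
    x = np.asarray(getattr(series, "states", getattr(series, "counts", series)),
                   dtype=float)
    n = x.size
    if n < 8:
        raise ValueError("series too short (need >= 8 samples)")
    t = getattr(series, "times", None)
    if t is not None:
        d = np.diff(np.asarray(t, dtype=float))
        if not np.allclose(d, d[0], rtol=0, atol=1e-6 * d[0]):
            raise ValueError("non-uniform sampling")
        dt = float(d[0])
    if remove_mean:
        x = x - x.mean()
    if hann:
        w = np.hanning(n)
        x = x * w / np.sqrt(np.mean(w**2))
    X = np.fft.rfft(x)
    raw = (dt / n) * np.abs(X) ** 2
    freqs = np.fft.rfftfreq(n, d=dt)
    S = raw[1:].copy()
    S[:-1] *= 2.0 if n % 2 == 0 else 1.0
    if n % 2 == 1:
        S *= 2.0
    return PsdCurve(frequencies=freqs[1:], values=S, T=n * dt,
                    n_series=1, detrended=remove_mean)


def ensemble_psd(series_list, dt: float = 1.0, remove_mean: bool = True) -> PsdCurve:
    """Pointwise mean of single-series periodograms (equal length, dt)."""
    if not series_list:
        raise ValueError("no series supplied")
    curves = [periodogram(s, dt=dt, remove_mean=remove_mean) for s in series_list]
    n0 = len(curves[0].frequencies)
    for c in curves[1:]:
        if len(c.frequencies) != n0:
            raise ValueError("series lengths differ")
    vals = np.mean([c.values for c in curves], axis=0)
    return PsdCurve(frequencies=curves[0].frequencies, values=vals,
                    T=curves[0].T, n_series=len(curves),
                    detrended=remove_mean)


def _log_bin(freqs, values, f_range, bins_per_decade=10):
    """Geometric binning; returns (mean log f, mean log S, counts) per bin."""
    lo, hi = f_range
    m = (freqs >= lo) & (freqs <= hi) & (values > 0)
    f = freqs[m]
    s = values[m]
    if f.size == 0:
        raise ValueError("no positive spectral values inside the band")
    n_bins = max(1, int(np.ceil(bins_per_decade * np.log10(hi / lo))))
    edges = np.geomspace(lo, hi, n_bins + 1)
    idx = np.clip(np.searchsorted(edges, f, side="right") - 1, 0, n_bins - 1)
    xs, ys, cs = [], [], []
    for b in range(n_bins):
        sel = idx == b
        if not np.any(sel):
            continue
        xs.append(np.mean(np.log10(f[sel])))
        ys.append(np.mean(np.log10(s[sel])))
        cs.append(int(sel.sum()))
    return np.asarray(xs), np.asarray(ys), np.asarray(cs)


def fit_psd_exponent(psd: PsdCurve, f_range, bins_per_decade: int = 10) -> PsdExponentFit:
    """Fit S(f) ~ f^(-beta) by least squares on log-binned log S."""
    x, y, _ = _log_bin(psd.frequencies, psd.values, f_range, bins_per_decade)
    if len(x) < 4:
        raise ValueError(
            f"only {len(x)} non-empty log bins inside {f_range}; need >= 4"
        )
    res = stats.linregress(x, y)
    return PsdExponentFit(
        beta=float(-res.slope),
        stderr=float(res.stderr),
        f_range=(float(f_range[0]), float(f_range[1])),
        n_bins=len(x),
        r2=float(res.rvalue**2),
    )


def _overlap_statistic(psd_a: PsdCurve, psd_b: PsdCurve,
                       bins_per_decade: int = 10) -> float:
    lo = max(psd_a.frequencies[0], psd_b.frequencies[0])
    hi = min(psd_a.frequencies[-1], psd_b.frequencies[-1])
    if hi <= lo:
        raise ValueError("no common frequency band")
    xa, ya, _ = _log_bin(psd_a.frequencies, psd_a.values, (lo, hi), bins_per_decade)
    xb, yb, _ = _log_bin(psd_b.frequencies, psd_b.values, (lo, hi), bins_per_decade)
    # align on common bins (bin centers may differ when grids differ)
    common = {}
    for x, y in zip(xa, ya):
        common[round(x * bins_per_decade)] = [y, None]
    for x, y in zip(xb, yb):
        key = round(x * bins_per_decade)
        if key in common:
            common[key][1] = y
    diffs = [abs(a - b) for a, b in common.values() if b is not None]
    if not diffs:
        raise ValueError("no overlapping log bins")
    return float(np.max(diffs)) * np.log(10.0)  # natural-log scale


def _null_threshold(lengths, dt, n_series, bins_per_decade, rng, n_null=200,
                    q=0.95):
    """Monte-Carlo 95th percentile of the overlap statistic for white noise.

    Periodogram ordinates of Gaussian white noise are independent
    exponentials; the ensemble mean over n_series is Gamma(n)/n, so the
    null is simulated directly on the Fourier grids without FFTs.
    """
    grids = [np.fft.rfftfreq(n, d=dt)[1:] for n in lengths]
    stats_null = np.empty(n_null)
    for i in range(n_null):
        psds = []
        for f in grids:
            vals = rng.gamma(n_series, 1.0 / n_series, size=f.size)
            psds.append(PsdCurve(frequencies=f, values=vals,
                                 T=2 * len(f) * dt, n_series=n_series))
        pair_stats = [
            _overlap_statistic(psds[a], psds[b], bins_per_decade)
            for a in range(len(psds)) for b in range(a + 1, len(psds))
        ]
        stats_null[i] = max(pair_stats)
    return float(np.quantile(stats_null, q))


def aging_test(series_list, measurement_times, dt: float = 1.0,
               bins_per_decade: int = 10, n_null: int = 200,
               seed: int = 0) -> AgingResult:
    """Test whether the ensemble PSD depends on the measurement time.

    For each T_m the ensemble PSD is computed on the window [0, T_m] of
    every series; the overlap statistic is the largest log-binned
    |log S_Tm - log S_Tm'| over common frequencies, maximised over pairs.
    The verdict is "aging" when it exceeds the 95th percentile of the same
    statistic under a stationary white-noise null at matched lengths.
    """
    if len(measurement_times) < 2:
        raise ValueError("need at least two measurement times")
    n_total = len(np.asarray(
        getattr(series_list[0], "states", getattr(series_list[0], "counts",
                                                  series_list[0]))))
    lengths = []
    psds = {}
    for T_m in measurement_times:
        n_m = int(round(T_m / dt))
        if n_m < 64:
            raise ValueError("each window needs >= 64 samples")
        if n_m > n_total:
            raise ValueError(f"window {T_m} exceeds the available data")
        lengths.append(n_m)
        segs = [
            np.asarray(getattr(s, "states", getattr(s, "counts", s)),
                       dtype=float)[:n_m]
            for s in series_list
        ]
        psds[T_m] = ensemble_psd(segs, dt=dt)
    keys = list(psds)
    stat = max(
        _overlap_statistic(psds[a], psds[b], bins_per_decade)
        for i, a in enumerate(keys) for b in keys[i + 1:]
    )
    rng = np.random.default_rng(seed)
    thr = _null_threshold(lengths, dt, len(series_list), bins_per_decade,
                          rng, n_null=n_null)
    return AgingResult(psds=psds, statistic=stat, threshold=thr,
                       aging=bool(stat > thr))
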