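"""Translational time-averaged mean squared displacement (TAMSD) analysis.

The TAMSD of a trajectory r(t) of measurement time T at lag Delta is the
sliding average over all start points,

    delta^2(Delta; T) = 1/(T - Delta) * integral_0^{T-Delta}
                        |r(t + Delta) - r(t)|^2 dt,

estimated on a uniform grid as the overlapping-window average.  Anomalous
diffusion shows up as delta^2 ~ 2 d D_a Delta^alpha with subdiffusive
exponent alpha < 1 and generalized diffusion coefficient D_a; membrane
proteins co-diffusing with bound lipids typically show a transient
subdiffusive regime crossing over to normal diffusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from anomemb.dichotomy import DichotomousSeries

__all__ = [
    "Trajectory",
    "TamsdCurve",
    "PowerLawFit",
    "CrossoverFit",
    "subtract_reference",
    "tamsd",
    "ensemble_tamsd",
    "fit_exponent",
    "local_slope",
    "detect_crossover",
    "diffusion_coefficient",
    "relative_sd",
    "tamsd_by_state",
    "default_lags",
]

_REL_DT_TOL = 1e-6


@dataclass
class Trajectory:
    """Uniformly sampled particle/COM trajectory, optionally with a
    per-frame reference (e.g. the leaflet COM) to subtract."""

    times: np.ndarray
    positions: np.ndarray
    reference: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim == 1:
            self.positions = self.positions[:, None]
        if len(self.times) != len(self.positions):
            raise ValueError("times and positions must have equal length")
        if len(self.times) < 2:
            raise ValueError("need at least two frames")
        d = np.diff(self.times)
        if np.any(d <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.allclose(d, d[0], rtol=0, atol=_REL_DT_TOL * d[0]):
            raise ValueError("non-uniform sampling; resample before analysis")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.reference is not None:
            self.reference = np.asarray(self.reference, dtype=float)
            if self.reference.ndim == 1:
                self.reference = self.reference[:, None]
            if self.reference.shape != self.positions.shape:
                raise ValueError("reference must match positions in shape")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def T(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def dim(self) -> int:
        return self.positions.shape[1]


@dataclass
class TamsdCurve:
    """TAMSD values on a lag grid, possibly ensemble-averaged."""

    lags: np.ndarray
    values: np.ndarray
    T: float
    dim: int
    n_source: int = 1
    label: str = ""

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.lags) != len(self.values):
            raise ValueError("lags and values must have equal length")
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("TAMSD values must be non-negative")


@dataclass
class PowerLawFit:
    """Result of fitting delta^2 = 2 d D_a Delta^alpha on a lag range."""

    alpha: float
    D_a: float
    fit_range: tuple[float, float]
    stderr: float
    r2: float
    n_points: int


@dataclass
class CrossoverFit:
    """Two-segment continuous log-log fit of a TAMSD curve."""

    crossover_lag: float
    alpha_short: float
    alpha_long: float
    significant: bool
    sse_two: float
    sse_one: float


def default_lags(T: float, dt: float, per_decade: int = 25, max_frac: float = 0.1) -> np.ndarray:
    """Log-spaced lag grid from dt to max_frac*T, deduplicated in steps."""
    max_lag = max_frac * T
    n_dec = np.log10(max_lag / dt)
    n_pts = max(2, int(np.ceil(per_decade * n_dec)) + 1)
    steps = np.unique(np.round(np.logspace(0, np.log10(max_lag / dt), n_pts)).astype(int))
    steps = steps[steps >= 1]
    return steps * dt


def subtract_reference(traj: Trajectory) -> Trajectory:
    """Subtract the per-frame reference (leaflet COM) from the positions."""
    if traj.reference is None:
        raise ValueError("trajectory has no reference series")
    return Trajectory(
        times=traj.times,
        positions=traj.positions - traj.reference,
        reference=None,
        label=traj.label,
    )


def _lags_to_steps(lags, dt: float, n: int) -> np.ndarray:
    lags = np.atleast_1d(np.asarray(lags, dtype=float))
    steps = np.unique(np.round(lags / dt).astype(int))
    steps = steps[steps >= 1]
    if len(steps) == 0:
        raise ValueError("no valid lags (all below dt)")
    if steps.max() >= n:
        raise ValueError("lag must be smaller than the measurement time")
    return steps


def tamsd(traj: Trajectory, lags=None) -> TamsdCurve:
    """Time-averaged MSD over all overlapping windows.

    For lag Delta = m*dt:
    value = 1/(N - m) * sum_i |r(t_i + Delta) - r(t_i)|^2.
    """
    pos = traj.positions if traj.reference is None else traj.positions
    n = len(pos)
    if lags is None:
        lags = default_lags(traj.T, traj.dt)
    steps = _lags_to_steps(lags, traj.dt, n)
    vals = np.empty(len(steps))
    for j, m in enumerate(steps):
        d = pos[m:] - pos[:-m]
        vals[j] = np.mean(np.einsum("ij,ij->i", d, d))
    return TamsdCurve(
        lags=steps * traj.dt, values=vals, T=traj.T, dim=traj.dim,
        n_source=1, label=traj.label,
    )


def ensemble_tamsd(curves: list[TamsdCurve]) -> TamsdCurve:
    """Pointwise mean of TAMSD curves sharing one lag grid."""
    if not curves:
        raise ValueError("no curves supplied")
    base = curves[0]
    for c in curves[1:]:
        if len(c.lags) != len(base.lags) or not np.allclose(c.lags, base.lags):
            raise ValueError("curves must share an identical lag grid")
    vals = np.mean([c.values for c in curves], axis=0)
    return TamsdCurve(
        lags=base.lags.copy(), values=vals, T=base.T, dim=base.dim,
        n_source=sum(c.n_source for c in curves), label="ensemble",
    )


def _select_range(curve: TamsdCurve, fit_range) -> np.ndarray:
    lo, hi = fit_range
    return (curve.lags >= lo) & (curve.lags <= hi)


def fit_exponent(curve: TamsdCurve, fit_range) -> PowerLawFit:
    """Least-squares line on (log lag, log value); alpha is the slope and
    D_a = exp(intercept) / (2 d)."""
    mask = _select_range(curve, fit_range)
    if mask.sum() < 4:
        raise ValueError("need at least 4 lags inside the fit range")
    if np.any(curve.values[mask] <= 0):
        raise ValueError("non-positive TAMSD values inside the fit range")
    x = np.log(curve.lags[mask])
    y = np.log(curve.values[mask])
    res = stats.linregress(x, y)
    return PowerLawFit(
        alpha=float(res.slope),
        D_a=float(np.exp(res.intercept) / (2 * curve.dim)),
        fit_range=(float(fit_range[0]), float(fit_range[1])),
        stderr=float(res.stderr),
        r2=float(res.rvalue**2),
        n_points=int(mask.sum()),
    )


def local_slope(curve: TamsdCurve, window: int = 5) -> np.ndarray:
    """Centered rolling log-log regression slope; returns (lag, slope) rows."""
    if window < 3:
        raise ValueError("window must be >= 3")
    n = len(curve.lags)
    if window > n:
        raise ValueError("window larger than the curve")
    if np.any(curve.values <= 0):
        raise ValueError("non-positive TAMSD values")
    x = np.log(curve.lags)
    y = np.log(curve.values)
    half = window // 2
    out = []
    for i in range(half, n - half):
        sl = slice(i - half, i - half + window)
        res = stats.linregress(x[sl], y[sl])
        out.append((curve.lags[i], res.slope))
    return np.asarray(out)


def detect_crossover(curve: TamsdCurve, min_seg: int = 3) -> CrossoverFit:
    """Best continuous two-segment power-law fit of a TAMSD curve.

    The breakpoint is searched on the lag grid by global SSE minimization
    in log-log space; ties break toward the smaller lag.  The breakpoint
    is flagged not significant when the two-segment model improves the
    single-line SSE by less than 5% (or the single line is already an
    essentially exact fit).
    """
    n = len(curve.lags)
    if n < 10:
        raise ValueError("need at least 10 lags")
    if curve.lags[-1] / curve.lags[0] < 100:
        raise ValueError("lag grid must span at least two decades")
    if np.any(curve.values <= 0):
        raise ValueError("non-positive TAMSD values")
    x = np.log(curve.lags)
    y = np.log(curve.values)

    res1 = stats.linregress(x, y)
    sse_one = float(np.sum((y - (res1.intercept + res1.slope * x)) ** 2))

    best = None
    for b in range(min_seg - 1, n - min_seg):
        xb = x[b]
        # y = a + s1*min(x-xb, 0) + s2*max(x-xb, 0): continuous at xb
        left = np.minimum(x - xb, 0.0)
        right = np.maximum(x - xb, 0.0)
        A = np.column_stack([np.ones(n), left, right])
        coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
        sse = float(np.sum((A @ coef - y) ** 2))
        if best is None or sse < best[0] - 1e-15:
            best = (sse, b, coef)
    sse_two, b, coef = best
    improvement = 0.0 if sse_one <= 1e-18 else 1.0 - sse_two / sse_one
    return CrossoverFit(
        crossover_lag=float(curve.lags[b]),
        alpha_short=float(coef[1]),
        alpha_long=float(coef[2]),
        significant=bool(improvement > 0.05 and sse_one > 1e-18),
        sse_two=sse_two,
        sse_one=sse_one,
    )


def diffusion_coefficient(curve: TamsdCurve, fit_range) -> float:
    """Ordinary diffusion coefficient from the linear TAMSD regime:
    D = slope of value vs lag / (2 d).  The caller asserts the range lies
    in the alpha ~ 1 regime."""
    mask = _select_range(curve, fit_range)
    if mask.sum() < 2:
        raise ValueError("need at least 2 lags inside the fit range")
    res = stats.linregress(curve.lags[mask], curve.values[mask])
    return float(res.slope / (2 * curve.dim))


def relative_sd(curves: list[TamsdCurve], lag: float) -> float:
    """Ergodicity-breaking scatter: SD across curves at a lag over mean.

    Of order (n_traj)^{-1/2}-small for ergodic processes (fBM) but O(1)
    for heavy-tailed CTRW even at long measurement times.
    """
    if len(curves) < 2:
        raise ValueError("need at least two curves")
    vals = []
    for c in curves:
        i = np.argmin(np.abs(c.lags - lag))
        if not np.isclose(c.lags[i], lag, rtol=1e-6):
            raise ValueError(f"lag {lag} not on the curve grid")
        vals.append(c.values[i])
    vals = np.asarray(vals)
    m = vals.mean()
    if m == 0:
        raise ValueError("zero mean TAMSD at this lag")
    return float(vals.std(ddof=0) / m)


def tamsd_by_state(
    traj: Trajectory,
    states: DichotomousSeries,
    min_dwell: float,
    lags=None,
) -> dict[int, TamsdCurve | None]:
    """TAMSD conditioned on the state of a dichotomous process.

    The trajectory is cut into maximal constant-state runs; runs shorter
    than ``min_dwell`` are discarded and no displacement spans a state
    change.  Per state, squared displacements are pooled across all
    qualifying runs.  Returns ``{+1: curve-or-None, -1: curve-or-None}``.
    """
    if len(states.states) != len(traj.times) or not np.allclose(states.times, traj.times):
        raise ValueError("state series must be aligned with the trajectory")
    dt = traj.dt
    if lags is None:
        lags = default_lags(max(min_dwell * 4, 20 * dt), dt)
    st = states.states
    # maximal runs
    change = np.nonzero(np.diff(st))[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(st)]])
    out: dict[int, TamsdCurve | None] = {}
    for s in (+1, -1):
        sums: dict[int, float] = {}
        cnts: dict[int, int] = {}
        for a, b in zip(starts, ends):
            if st[a] != s:
                continue
            span = (b - a - 1) * dt
            if span < min_dwell:
                continue
            seg = traj.positions[a:b]
            nseg = len(seg)
            for m in np.unique(np.round(np.atleast_1d(lags) / dt).astype(int)):
                if m < 1 or m >= nseg:
                    continue
                d = seg[m:] - seg[:-m]
                sums[m] = sums.get(m, 0.0) + float(np.sum(np.einsum("ij,ij->i", d, d)))
                cnts[m] = cnts.get(m, 0) + (nseg - m)
        if not sums:
            out[s] = None
            continue
        ms = np.array(sorted(sums))
        vals = np.array([sums[m] / cnts[m] for m in ms])
        out[s] = TamsdCurve(
            lags=ms * dt, values=vals, T=traj.T, dim=traj.dim,
            n_source=1, label=f"state {s:+d}",
        )
    return out
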