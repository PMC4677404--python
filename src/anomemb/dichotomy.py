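"""Two-state (dichotomous) processes from contact-count series.

A count series N(t) (number of signalling lipids touching the protein) is
thresholded into a +1/-1 process: "high" (+1) when N exceeds the threshold
N_t, "low" (-1) when N <= N_t (ties go low).  Residence (sojourn) times of
the two states and shuffled surrogates — which destroy any correlation
between successive sojourns while preserving their marginal distribution —
are the raw material for 1/f-noise analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DichotomousSeries",
    "ResidenceTimes",
    "dichotomize",
    "residence_times",
    "shuffle_surrogate",
]


@dataclass
class DichotomousSeries:
    """+1/-1 state series on a uniform time grid."""

    times: np.ndarray
    states: np.ndarray
    threshold: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=int)
        if self.times.shape != self.states.shape:
            raise ValueError("times and states must have equal length")
        if not np.all(np.isin(self.states, (-1, 1))):
            raise ValueError("states must be +1 or -1")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class ResidenceTimes:
    """Alternating sojourn durations extracted from a dichotomous series.

    ``durations`` and ``states`` are in series order; ``censored`` marks
    the first and last runs, whose true length is unobserved.  The default
    accessors ``high``/``low`` exclude censored runs.
    """

    durations: np.ndarray
    states: np.ndarray
    censored: np.ndarray
    dt: float
    initial_state: int

    def _sel(self, state: int, include_censored: bool) -> np.ndarray:
        m = self.states == state
        if not include_censored:
            m &= ~self.censored
        return self.durations[m]

    def high(self, include_censored: bool = False) -> np.ndarray:
        return self._sel(+1, include_censored)

    def low(self, include_censored: bool = False) -> np.ndarray:
        return self._sel(-1, include_censored)


def dichotomize(series, threshold="mean", times=None, source="") -> DichotomousSeries:
    """Threshold a numeric series into a +1/-1 process.

    ``threshold='mean'`` uses the series mean as N_t.  State is +1 where
    the value strictly exceeds N_t and -1 where value <= N_t.
    """
    values = np.asarray(getattr(series, "counts", series), dtype=float)
    if values.size == 0:
        raise ValueError("empty series")
    if times is None:
        times = getattr(series, "times", None)
    if times is None:
        times = np.arange(values.size, dtype=float)
    if threshold == "mean":
        nt = float(values.mean())
    else:
        nt = float(threshold)
    states = np.where(values > nt, 1, -1)
    if np.all(states == states[0]):
        warnings.warn("series never crosses the threshold; single-state output",
                      RuntimeWarning)
    return DichotomousSeries(times=np.asarray(times, dtype=float),
                             states=states, threshold=nt, source=source)


def residence_times(dich: DichotomousSeries) -> ResidenceTimes:
    """Run-length encode the state series into sojourn durations (x dt).

    The first and last runs are flagged censored (their entry/exit is not
    observed) and excluded from default statistics.
    """
    st = dich.states
    if len(st) < 2:
        raise ValueError("need at least two samples")
    change = np.nonzero(np.diff(st))[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(st)]])
    lengths = (ends - starts).astype(float) * dich.dt
    run_states = st[starts]
    censored = np.zeros(len(lengths), dtype=bool)
    censored[0] = True
    censored[-1] = True
    return ResidenceTimes(
        durations=lengths, states=run_states, censored=censored,
        dt=dich.dt, initial_state=int(st[0]),
    )


def reconstruct(res: ResidenceTimes, times: np.ndarray | None = None) -> DichotomousSeries:
    """Rebuild the grid series from run-length encoding (round-trip)."""
    reps = np.round(res.durations / res.dt).astype(int)
    states = np.repeat(res.states, reps)
    if times is None:
        times = np.arange(len(states)) * res.dt
    return DichotomousSeries(times=times, states=states, source="reconstructed")


def shuffle_surrogate(res: ResidenceTimes, seed: int = 0,
                      total_length: int | None = None) -> DichotomousSeries:
    """Shuffled surrogate: permute high sojourns among high slots and low
    sojourns among low slots, independently, then rebuild the alternating
    series from the original initial state.

    The per-state duration multisets are preserved exactly; any temporal
    correlation between successive sojourns is destroyed, so a long-memory
    series and its surrogate differ at low frequencies while sharing the
    same sojourn marginals.  The rebuilt series is truncated or padded
    (by extending the final sojourn) to the original grid length so PSDs
    are length-comparable.
    """
    rng = np.random.default_rng(seed)
    n_high = int(np.sum(res.states == +1))
    n_low = int(np.sum(res.states == -1))
    if n_high < 1 or n_low < 1:
        raise ValueError("need sojourns in both states to shuffle")
    durations = res.durations.copy()
    for s in (+1, -1):
        idx = np.nonzero(res.states == s)[0]
        durations[idx] = durations[idx[rng.permutation(len(idx))]]
    reps = np.round(durations / res.dt).astype(int)
    states = np.repeat(res.states, reps)
    if total_length is None:
        total_length = int(np.round(res.durations.sum() / res.dt))
    if len(states) >= total_length:
        states = states[:total_length]
    else:
        states = np.concatenate(
            [states, np.full(total_length - len(states), states[-1])]
        )
    times = np.arange(total_length) * res.dt
    return DichotomousSeries(times=times, states=states, source="shuffled-surrogate")
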