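"""Synthetic-data generators for membrane anomalous-dynamics analysis.

Every input the analysis pipeline consumes can be produced here with known
statistical structure: fractional Brownian motion (fBM) ensembles for
viscoelastic subdiffusion, tempered fBM for the sub-to-normal diffusion
crossover, continuous-time random walks (CTRW) as the non-ergodic
counterpoint, heavy-tailed sojourn samples, alternating two-state renewal
series, superposed ON/OFF contact-count series, and scripted toy membrane
frames for the coordinate-level contact analytics.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.linalg import cholesky
from scipy.linalg import toeplitz

from anomemb.tamsd import Trajectory
from anomemb.dichotomy import DichotomousSeries

__all__ = [
    "FbmParams",
    "SojournParams",
    "RenewalSeriesParams",
    "CountSeries",
    "ToyMembrane",
    "gen_fbm",
    "gen_tempered_fbm",
    "gen_ctrw",
    "sample_sojourns",
    "gen_alternating_renewal",
    "gen_contact_count",
    "gen_toy_membrane_frames",
    "fgn_autocovariance",
    "tempered_msd",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FbmParams:
    """Parameters of a fractional Brownian motion ensemble.

    ``hurst`` is the Hurst exponent H in (0, 1); the TAMSD scaling exponent
    of the resulting paths is alpha = 2H.  ``step_scale`` sets the length
    scale: the standard deviation of a single increment over ``dt`` is
    ``step_scale * dt**hurst``.
    """

    hurst: float
    n_steps: int
    dt: float = 1.0
    dim: int = 2
    n_traj: int = 1
    step_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.hurst < 1.0):
            raise ValueError(f"hurst must be in (0, 1), got {self.hurst}")
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        if self.dim not in (1, 2, 3):
            raise ValueError("dim must be 1, 2 or 3")
        if self.n_traj < 1:
            raise ValueError("n_traj must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass(frozen=True)
class SojournParams:
    """Power-law-with-exponential-cutoff sojourn law.

    Density proportional to ``tau**(-1 - gamma) * exp(-tau / tau_c)`` on
    ``[tau_min, inf)``.  ``tau_c = inf`` gives the pure Pareto law, whose
    mean diverges for gamma <= 1.
    """

    gamma: float
    tau_c: float = np.inf
    tau_min: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if not (self.tau_c > 0):
            raise ValueError(f"tau_c must be > 0 (may be inf), got {self.tau_c}")
        if self.tau_min <= 0:
            raise ValueError(f"tau_min must be > 0, got {self.tau_min}")


@dataclass(frozen=True)
class RenewalSeriesParams:
    """Alternating two-state (+1/-1) renewal series on a regular grid."""

    high: SojournParams
    low: SojournParams
    total_time: float
    dt: float = 1.0
    initial_state: int | str = "random"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_time < self.dt:
            raise ValueError("total_time must be >= dt")
        if self.total_time / self.dt < 2:
            raise ValueError("need at least two samples (total_time/dt >= 2)")
        if self.initial_state not in (+1, -1, "random"):
            raise ValueError("initial_state must be +1, -1 or 'random'")


@dataclass
class CountSeries:
    """Integer-valued contact-count time series (e.g. lipids in contact)."""

    times: np.ndarray
    counts: np.ndarray
    n_processes: int = 1

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.times.shape != self.counts.shape:
            raise ValueError("times and counts must have equal length")


# ---------------------------------------------------------------------------
# fractional Gaussian noise synthesis
# ---------------------------------------------------------------------------

def fgn_autocovariance(lags: np.ndarray, hurst: float, sigma2: float = 1.0) -> np.ndarray:
    """Closed-form autocovariance of fractional Gaussian noise.

    gamma(k) = sigma^2/2 * (|k+1|^2H - 2|k|^2H + |k-1|^2H)
    """
    k = np.abs(np.asarray(lags, dtype=float))
    h2 = 2.0 * hurst
    return 0.5 * sigma2 * (np.abs(k + 1) ** h2 - 2 * k ** h2 + np.abs(k - 1) ** h2)


def _sample_stationary_gaussian(
    acov: np.ndarray, n: int, n_series: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n_series`` stationary Gaussian series of length ``n``.

    Uses circulant (Davies-Harte-style) embedding of the autocovariance
    ``acov`` (lags 0..n); falls back to a Cholesky factorisation of the
    Toeplitz covariance when the embedding is not positive semidefinite
    (only feasible for short series).
    """
    if len(acov) < n + 1:
        raise ValueError("need autocovariance up to lag n")
    m = 2 * n
    row = np.concatenate([acov[: n + 1], acov[n - 1:0:-1]])
    lam = np.fft.fft(row).real
    tol = -1e-8 * np.max(np.abs(lam))
    if np.min(lam) < tol:
        # embedding failed; exact but O(n^3) route
        if n > 4096:
            raise np.linalg.LinAlgError(
                "circulant embedding non-positive and series too long for "
                "Cholesky fallback"
            )
        cov = toeplitz(acov[:n])
        L = cholesky(cov + 1e-12 * acov[0] * np.eye(n))
        z = rng.standard_normal((n_series, n))
        return z @ L.T
    lam = np.clip(lam, 0.0, None)
    # spectral synthesis: hermitian random weights -> FFT -> real series
    z0 = rng.standard_normal(n_series)
    zh = rng.standard_normal(n_series)
    u = rng.standard_normal((n_series, n - 1))
    v = rng.standard_normal((n_series, n - 1))
    w = np.zeros((n_series, m), dtype=complex)
    w[:, 0] = np.sqrt(lam[0] / m) * z0
    w[:, n] = np.sqrt(lam[n] / m) * zh
    half = np.sqrt(lam[1:n] / (2.0 * m))
    w[:, 1:n] = half * (u + 1j * v)
    w[:, n + 1:] = np.conj(w[:, n - 1:0:-1])
    return np.fft.fft(w, axis=1)[:, :n].real


def _gaussian_increment_paths(params: FbmParams, damping_time: float | None) -> list[Trajectory]:
    sigma2 = (params.step_scale * params.dt ** params.hurst) ** 2
    n = params.n_steps
    acov = fgn_autocovariance(np.arange(n + 1), params.hurst, sigma2)
    if damping_time is not None and np.isfinite(damping_time):
        acov = acov * np.exp(-np.arange(n + 1) * params.dt / damping_time)
    rng = np.random.default_rng(params.seed)
    incs = _sample_stationary_gaussian(acov, n, params.n_traj * params.dim, rng)
    incs = incs.reshape(params.n_traj, params.dim, n)
    times = np.arange(n + 1) * params.dt
    out = []
    for i in range(params.n_traj):
        pos = np.zeros((n + 1, params.dim))
        pos[1:] = np.cumsum(incs[i], axis=1).T
        out.append(Trajectory(times=times, positions=pos, label=f"fbm-{i}"))
    return out


def gen_fbm(params: FbmParams) -> list[Trajectory]:
    """Generate an ensemble of fractional Brownian motion trajectories.

    Each trajectory starts at the origin and has ``n_steps + 1`` frames.
    Increments are stationary Gaussian with the fractional-Gaussian-noise
    autocovariance; dimensions are independent.  TAMSD of the ensemble
    scales as ``Delta**(2 * hurst)``.
    """
    return _gaussian_increment_paths(params, None)


def gen_tempered_fbm(params: FbmParams, crossover_time: float) -> list[Trajectory]:
    """fBM with exponentially tempered increment correlations.

    The fGn autocovariance is multiplied by ``exp(-k dt / crossover_time)``,
    which preserves the short-lag scaling ``Delta**2H`` and crosses over to
    ordinary diffusion (slope 1) for lags well beyond ``crossover_time`` —
    the transient-subdiffusion phenomenology of a protein whose bound
    lipids move viscoelastically at short times.

    ``crossover_time = inf`` reproduces :func:`gen_fbm` exactly (same seed,
    same paths).
    """
    if not crossover_time > 0:
        raise ValueError("crossover_time must be positive")
    if np.isfinite(crossover_time) and crossover_time <= params.dt:
        raise ValueError("crossover_time must exceed dt")
    return _gaussian_increment_paths(params, crossover_time)


def tempered_msd(params: FbmParams, crossover_time: float, max_lag_steps: int) -> np.ndarray:
    """Theoretical ensemble MSD (per trajectory, all dims) of tempered fBM.

    Computed by summing the tempered increment autocovariance:
    MSD(m) = dim * [ m c0 + 2 sum_{k=1}^{m-1} (m - k) c_k ].
    Serves as an independent oracle for slope checks.
    """
    sigma2 = (params.step_scale * params.dt ** params.hurst) ** 2
    k = np.arange(max_lag_steps + 1)
    c = fgn_autocovariance(k, params.hurst, sigma2)
    if np.isfinite(crossover_time):
        c = c * np.exp(-k * params.dt / crossover_time)
    msd = np.empty(max_lag_steps + 1)
    msd[0] = 0.0
    for m in range(1, max_lag_steps + 1):
        msd[m] = m * c[0] + 2.0 * np.sum((m - k[1:m]) * c[1:m])
    return params.dim * msd


# ---------------------------------------------------------------------------
# continuous-time random walk
# ---------------------------------------------------------------------------

def gen_ctrw(
    n_steps: int,
    waiting_exponent: float,
    jump_scale: float = 1.0,
    dim: int = 2,
    n_traj: int = 1,
    seed: int = 0,
    tau_min: float = 1.0,
) -> list[Trajectory]:
    """Continuous-time random walk with Pareto waiting times.

    Waiting times follow ``P(w > t) = (t / tau_min)**(-a)`` for exponent
    ``a = waiting_exponent`` in (0, 1); jumps are isotropic Gaussian with
    per-axis standard deviation ``jump_scale``.  Positions are sampled on a
    unit-spaced grid of ``n_steps + 1`` points and are piecewise constant
    between jumps.  ``waiting_exponent = 1`` is taken as the degenerate
    fixed-wait limit (every wait equals ``tau_min``), which recovers a
    lattice-time random walk.
    """
    if not (0.0 < waiting_exponent <= 1.0):
        raise ValueError("waiting_exponent must be in (0, 1]")
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    rng = np.random.default_rng(seed)
    total_time = float(n_steps)
    times = np.arange(n_steps + 1, dtype=float)
    out = []
    for i in range(n_traj):
        waits = []
        acc = 0.0
        while acc < total_time:
            chunk = max(64, int(total_time / tau_min) // 4 + 1)
            if waiting_exponent == 1.0:
                w = np.full(chunk, tau_min)
            else:
                w = tau_min * rng.random(chunk) ** (-1.0 / waiting_exponent)
            waits.append(w)
            acc += w.sum()
        waits = np.concatenate(waits)
        jump_t = np.cumsum(waits)
        n_jumps = int(np.searchsorted(jump_t, total_time, side="right")) + 1
        jump_t = jump_t[:n_jumps]
        jumps = jump_scale * rng.standard_normal((n_jumps, dim))
        path = np.vstack([np.zeros((1, dim)), np.cumsum(jumps, axis=0)])
        # number of jumps completed by each grid time
        idx = np.searchsorted(jump_t, times, side="right")
        out.append(Trajectory(times=times, positions=path[idx], label=f"ctrw-{i}"))
    return out


# ---------------------------------------------------------------------------
# heavy-tailed sojourn sampling
# ---------------------------------------------------------------------------

def sample_sojourns(
    params: SojournParams,
    n: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Sample sojourn times from the power-law-with-cutoff density.

    Pareto inverse-transform proposals ``tau = tau_min * U**(-1/gamma)``
    accepted with probability ``exp(-(tau - tau_min) / tau_c)``; this is an
    exact rejection sampler for the target density
    ``A tau**(-1-gamma) exp(-tau/tau_c)`` on ``[tau_min, inf)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    if params.tau_c < params.tau_min:
        warnings.warn(
            "tau_c below tau_min: rejection acceptance rate will be poor",
            RuntimeWarning,
        )
    out = np.empty(n)
    filled = 0
    while filled < n:
        todo = n - filled
        m = max(2 * todo, 128)
        tau = params.tau_min * rng.random(m) ** (-1.0 / params.gamma)
        if np.isfinite(params.tau_c):
            keep = rng.random(m) < np.exp(-(tau - params.tau_min) / params.tau_c)
            tau = tau[keep]
        take = min(len(tau), todo)
        out[filled: filled + take] = tau[:take]
        filled += take
    return out


def sojourn_mean(params: SojournParams) -> float:
    """Mean of the sojourn law (inf if divergent).

    For a finite cutoff the mean has the closed form
    tau_c * Gamma(1-gamma, x) / Gamma(-gamma, x) with x = tau_min/tau_c.
    """
    from anomemb.restfit import upper_incomplete_gamma

    if not np.isfinite(params.tau_c):
        if params.gamma <= 1:
            return np.inf
        return params.gamma * params.tau_min / (params.gamma - 1.0)
    x = params.tau_min / params.tau_c
    return params.tau_c * (upper_incomplete_gamma(1.0 - params.gamma, x)
                           / upper_incomplete_gamma(-params.gamma, x))


# ---------------------------------------------------------------------------
# alternating renewal series
# ---------------------------------------------------------------------------

def gen_alternating_renewal(
    params: RenewalSeriesParams,
    return_sojourns: bool = False,
):
    """Simulate a +1/-1 alternating renewal series sampled on a dt grid.

    Sojourn durations of the continuous-time construction are drawn from
    ``params.high`` / ``params.low``; the series records the state of the
    sojourn covering each grid time ``i * dt``.  The final sojourn is
    truncated at ``total_time`` (censored).

    With ``return_sojourns=True`` also returns ``(durations, states,
    censored)`` of the continuous construction, the last entry censored.
    """
    rng = np.random.default_rng(params.seed)
    if params.initial_state == "random":
        state0 = +1 if rng.random() < 0.5 else -1
    else:
        state0 = int(params.initial_state)

    dur = np.empty(0)
    st = np.empty(0, dtype=int)
    total = 0.0
    # draw per-state blocks and interleave until the horizon is covered
    while total < params.total_time:
        m = 64
        first = sample_sojourns(params.high if state0 == +1 else params.low,
                                m, rng=rng)
        second = sample_sojourns(params.low if state0 == +1 else params.high,
                                 m, rng=rng)
        block = np.empty(2 * m)
        block[0::2] = first
        block[1::2] = second
        states_blk = np.empty(2 * m, dtype=int)
        states_blk[0::2] = state0
        states_blk[1::2] = -state0
        dur = np.concatenate([dur, block])
        st = np.concatenate([st, states_blk])
        total += block.sum()
    bounds = np.cumsum(dur)
    n_keep = int(np.searchsorted(bounds, params.total_time, side="left")) + 1
    dur = dur[:n_keep]
    st = st[:n_keep]
    bounds = bounds[:n_keep]

    n = int(round(params.total_time / params.dt))
    t = np.arange(n) * params.dt
    idx = np.searchsorted(bounds, t, side="right")
    series = DichotomousSeries(
        times=t, states=st[idx], threshold=None, source="alternating-renewal"
    )
    if not return_sojourns:
        return series
    censored = np.zeros(len(dur), dtype=bool)
    censored[-1] = True
    dur = dur.copy()
    dur[-1] -= bounds[-1] - params.total_time  # truncate at the horizon
    return series, (dur, st, censored)


def gen_contact_count(
    K: int,
    per_lipid: tuple[SojournParams, SojournParams],
    T: float,
    dt: float = 1.0,
    seed: int = 0,
    initial_state: int | str = "random",
) -> CountSeries:
    """Superpose K independent ON/OFF renewal processes into a count series.

    ``per_lipid`` is ``(bound, unbound)`` sojourn laws shared by all K
    lipids; ``N(t)`` counts how many processes are ON (bound) at each grid
    time.  Emulates the number of signalling lipids in contact with the
    protein.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    bound, unbound = per_lipid
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(K)
    counts = None
    times = None
    for k in range(K):
        sub_seed = int(children[k].generate_state(1)[0] % (2**31))
        p = RenewalSeriesParams(
            high=bound, low=unbound, total_time=T, dt=dt,
            initial_state=initial_state, seed=sub_seed,
        )
        s = gen_alternating_renewal(p)
        on = (s.states == 1).astype(int)
        counts = on if counts is None else counts + on
        times = s.times
    return CountSeries(times=times, counts=counts, n_processes=K)


# ---------------------------------------------------------------------------
# toy membrane frames for the contacts module
# ---------------------------------------------------------------------------

@dataclass
class ToyMembrane:
    """Scripted coordinate fixture with contacts known by construction."""

    frames: list  # FrameCoordinates
    bind_frame: int | None
    expected_contacts: dict = field(default_factory=dict)
    scripted_distance: np.ndarray | None = None


def gen_toy_membrane_frames(
    n_frames: int,
    n_residues: int,
    lipid_counts: dict[str, int],
    box: tuple[float, float, float] = (20.0, 20.0, 20.0),
    bound_fraction: float = 0.5,
    seed: int = 0,
    cutoff: float = 0.7,
) -> ToyMembrane:
    """Build a scripted sequence of membrane frames for contact analytics.

    A toy protein (``n_residues`` residues, 3 particles each) starts high
    above a flat lipid layer at z ~ 0.5 and approaches it linearly; after
    the scripted binding frame a ``bound_fraction`` of each lipid species
    is placed within ``cutoff / 2`` of designated residues so expected
    per-frame contact counts are known by construction.  Unbound lipids are
    kept laterally clear of the protein by more than ``cutoff``.
    """
    from anomemb.contacts import FrameCoordinates

    if n_frames < 2 or n_residues < 1 or min(lipid_counts.values(), default=1) < 1:
        raise ValueError("need n_frames >= 2, n_residues >= 1, positive lipid counts")
    if not (0.0 <= bound_fraction <= 1.0):
        raise ValueError("bound_fraction must be in [0, 1]")
    lx, ly, lz = box
    if min(lx, ly, lz) <= 0:
        raise ValueError("box edges must be positive")

    rng = np.random.default_rng(seed)
    n_bound = {sp: int(round(bound_fraction * c)) for sp, c in lipid_counts.items()}
    total_bound = sum(n_bound.values())
    if total_bound > 3 * n_residues:
        raise ValueError(
            f"cannot script {total_bound} in-contact lipids onto "
            f"{3 * n_residues} protein particles at this cutoff"
        )

    # protein template around its own COM (x-y centred at box middle)
    res_centers = 1.2 * rng.standard_normal((n_residues, 3))
    res_centers -= res_centers.mean(axis=0)
    prot_local = np.concatenate(
        [rc + 0.3 * rng.standard_normal((3, 3)) for rc in res_centers]
    )
    prot_local -= prot_local.mean(axis=0)
    residue_ids = np.repeat(np.arange(n_residues), 3)

    # lipid lattice: 2 particles per lipid at z in [0, 1]
    species, mol_ids, lip_base = [], [], []
    clear = cutoff + 1.0  # lateral exclusion radius around the protein column
    mol = 0
    for sp, count in lipid_counts.items():
        for _ in range(count):
            while True:
                xy = rng.random(2) * [lx, ly]
                if np.hypot(xy[0] - lx / 2, xy[1] - ly / 2) > clear + 2.5:
                    break
            head = np.array([xy[0], xy[1], 0.5 + 0.3 * rng.random()])
            tail = head + [0.2, 0.0, -0.4]
            lip_base.append(np.vstack([head, tail]))
            species.extend([sp, sp])
            mol_ids.extend([mol, mol])
            mol += 1
    lip_base = np.concatenate(lip_base) if lip_base else np.empty((0, 3))
    species = np.asarray(species)
    mol_ids = np.asarray(mol_ids)

    # scripted COM approach: z-distance from lipid plane 9 -> 1.5
    d0, d1 = 9.0, 1.5
    dists = np.linspace(d0, d1, n_frames)
    below = np.nonzero(dists < 4.0)[0]
    bind_frame = int(below[0]) if len(below) else None

    frames = []
    for f in range(n_frames):
        prot = prot_local + [lx / 2, ly / 2, 0.5 + dists[f]]
        lip = lip_base.copy()
        if bind_frame is not None and f >= bind_frame and total_bound:
            # park the designated lipids' head particles next to residues
            slot = 0
            for sp in lipid_counts:
                mols = np.unique(mol_ids[species == sp])[: n_bound[sp]]
                for m in mols:
                    anchor = prot[slot % len(prot)]
                    head_idx = np.nonzero(mol_ids == m)[0][0]
                    offset = rng.standard_normal(3)
                    offset *= (0.4 * cutoff) / np.linalg.norm(offset)
                    lip[head_idx] = anchor + offset
                    lip[head_idx + 1] = lip[head_idx] + [0.1, 0.0, -0.4]
                    slot += 1
        frames.append(
            FrameCoordinates(
                protein_xyz=prot,
                residue_ids=residue_ids,
                lipid_xyz=lip,
                lipid_mol_ids=mol_ids,
                lipid_species=species,
                box=np.array(box, dtype=float),
                time=float(f),
            )
        )
    expected = {
        sp: (n_bound[sp] if bind_frame is not None else 0) for sp in lipid_counts
    }
    return ToyMembrane(
        frames=frames,
        bind_frame=bind_frame,
        expected_contacts=expected,
        scripted_distance=dists,
    )
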