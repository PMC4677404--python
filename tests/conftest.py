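"""Shared fixtures: the expensive synthetic ensembles are session-scoped so
the TAMSD/spectral tests and the acceptance checks reuse one generation."""

import numpy as np
import pytest

from anomemb.synthgen import (
    FbmParams,
    RenewalSeriesParams,
    SojournParams,
    gen_alternating_renewal,
    gen_contact_count,
    gen_fbm,
    gen_tempered_fbm,
)
from anomemb.tamsd import ensemble_tamsd, tamsd

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50,
                              deadline=None)
    settings.load_profile("ci")
except ImportError:
    pass


def spawn_seeds(base: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(base)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


@pytest.fixture(scope="session")
def fbm_h0325_ensemble():
    """25 x 1e5-step 2D fBM paths at H=0.325 (subdiffusive regime)."""
    return gen_fbm(FbmParams(hurst=0.325, n_steps=100_000, dim=2, n_traj=25,
                             seed=20_001))


@pytest.fixture(scope="session")
def fbm_h0325_mean_tamsd(fbm_h0325_ensemble):
    return ensemble_tamsd([tamsd(t) for t in fbm_h0325_ensemble])


@pytest.fixture(scope="session")
def tempered_mean_tamsd():
    """Ensemble TAMSD of tempered fBM (H=0.325, crossover 10)."""
    trajs = gen_tempered_fbm(
        FbmParams(hurst=0.325, n_steps=100_000, dim=2, n_traj=25, seed=20_002),
        crossover_time=10.0,
    )
    return ensemble_tamsd([tamsd(t) for t in trajs])


@pytest.fixture(scope="session")
def rotation_fbm_paths():
    """25 x 1e5-step 3D fBM paths at H=0.27 (rotation-vector surrogates)."""
    return gen_fbm(FbmParams(hurst=0.27, n_steps=100_000, dim=3, n_traj=25,
                             seed=20_003))


@pytest.fixture(scope="session")
def renewal_ensemble_057():
    """25 alternating renewal series, gamma=0.57, tau_c=600, T=1e5."""
    soj = SojournParams(gamma=0.57, tau_c=600.0, tau_min=1.0)
    return [
        gen_alternating_renewal(
            RenewalSeriesParams(high=soj, low=soj, total_time=1e5, seed=s)
        )
        for s in spawn_seeds(20_004, 25)
    ]


@pytest.fixture(scope="session")
def contact_count_ensemble_055():
    """25 count series: 4 superposed ON/OFF processes, gamma=0.55."""
    on = SojournParams(gamma=0.55, tau_c=600.0, tau_min=1.0)
    off = SojournParams(gamma=0.55, tau_c=300.0, tau_min=1.0)
    return [
        gen_contact_count(4, (on, off), 1e5, seed=s)
        for s in spawn_seeds(20_005, 25)
    ]
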