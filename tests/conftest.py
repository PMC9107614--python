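"""Shared fixtures: small synthetic datasets reused across test modules."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from eptkit.preprocess import clean_run
from eptkit.synthetic_data import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """Small, fast grid used by unit tests (not the acceptance conditions)."""
    return SimConfig(nx=12, ny=12, nz=6, blob_sigma=1.5, n_networks=3,
                     n_frames=120, seed=21)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config, 4)


def build_two_tier_runs(n_subjects=8, seed=5):
    """Weak-target fixture: 3 dominant confounds at 10x the target variance.

    Courses are orthogonalised within subject so chance temporal
    correlations cannot leak the target into the confound components.
    """
    from eptkit.core import SpatialMap, zscore
    from eptkit.synthetic_data import assemble_bold, make_network_maps, make_timecourses

    cfg = SimConfig(seed=seed, n_networks=4, n_frames=120, noise_sd=0.5,
                    trend_coeffs=(0, 0, 0), spike_rate=0, motion_amp=0)
    maps = make_network_maps(cfg)
    tm = np.vstack([m.values for m in maps])
    runs = []
    for s in range(n_subjects):
        tcs, _ = make_timecourses(cfg, subject=s)
        q, _ = np.linalg.qr(tcs - tcs.mean(axis=0))
        tcs = q / q.std(axis=0, keepdims=True)
        tcs[:, 3] /= np.sqrt(10.0)
        run, _, _ = assemble_bold(maps, tcs, cfg, subject=s)
        runs.append(run)
    target = SpatialMap(zscore(tm[3]), zscored=True)
    return runs, tm, target


@pytest.fixture(scope="session")
def weak_target_fixture():
    return build_two_tier_runs()


@pytest.fixture(scope="session")
def snr2_cohort():
    """The 10-subject, 5-network, SNR-2, 20x20x10 continuous-regime cohort.

    The canonical study conditions; cleaned once and shared because
    cleaning 4000 voxels x 10 subjects is the expensive step.
    """
    cfg = SimConfig(seed=1, snr=2.0)
    runs, nuis, truths = simulate_dataset(cfg, 10)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cleaned = [clean_run(r, n)[0] for r, n in zip(runs, nuis)]
    return cfg, cleaned, truths


@pytest.fixture(scope="session")
def snr2_event_cohort():
    """Same conditions as :func:`snr2_cohort` but strictly event-driven."""
    cfg = SimConfig(seed=1, snr=2.0, regime="event")
    runs, nuis, truths = simulate_dataset(cfg, 10)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cleaned = [clean_run(r, n)[0] for r, n in zip(runs, nuis)]
    return cfg, cleaned, truths
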