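"""Shared fixtures: small synthetic groups and their downstream products.

Everything is generated programmatically with fixed seeds; session scope
keeps the heavier end-to-end products to a single computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from bmsmaps import (
    INTERACTION,
    OPPOSITION,
    build_scalp_time_volumes,
    evidence_maps,
    simulate_group,
    smooth_map,
    voxelwise_bms,
)

CONDITIONS = ("UP", "AP", "UU", "AU")


@pytest.fixture(scope="session")
def small_group():
    """8 subjects, all generated by the Opposition model, on a 16x16x20 grid."""
    return simulate_group(
        n_subjects=8,
        subject_assignments=[1] * 8,
        n_trials_per_condition=20,
        grid_size=(16, 16),
        n_time=20,
        effect_extent=5,
        effect_time_window=(8, 13),
        seed=3,
    )


@pytest.fixture(scope="session")
def small_maps(small_group):
    """Smoothed log-evidence maps for the small homogeneous group."""
    images = [build_scalp_time_volumes(ds, (16, 16)) for ds in small_group.datasets]
    maps = evidence_maps(images, [OPPOSITION, INTERACTION])
    grid = maps.mask.shape
    for n in range(maps.n_subjects):
        for k in range(maps.n_models):
            maps.evidences[n, k] = smooth_map(
                maps.evidences[n, k].reshape(grid), 1.0, mask=maps.mask
            ).ravel()
    return maps


@pytest.fixture(scope="session")
def small_result(small_maps):
    return voxelwise_bms(small_maps, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def exact_rfx_posterior_mean_k2(log_evidences: np.ndarray, n_grid: int = 100_001):
    """Brute-force inversion of the two-model Dirichlet hierarchy.

    Integrates the exact posterior p(r1 | Y) proportional to
    Dir(r; 1, 1) * prod_n [r1 exp(lnE_n1) + (1 - r1) exp(lnE_n2)]
    on a fine grid and returns E[r1 | Y].  Independent of the variational
    fixed-point code path it is used to check.
    """
    lev = np.asarray(log_evidences, dtype=float)
    r = np.linspace(1e-9, 1 - 1e-9, n_grid)
    logpost = np.zeros_like(r)
    for row in lev:
        m = row.max()
        logpost += np.log(r * np.exp(row[0] - m) + (1 - r) * np.exp(row[1] - m))
    logpost -= logpost.max()
    p = np.exp(logpost)
    return float(np.trapezoid(r * p, r) / np.trapezoid(p, r))
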