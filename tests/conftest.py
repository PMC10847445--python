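"""Shared fixtures and independent numerical oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

from plscore.energy import CachingBackend, make_test_backend
from plscore.fixtures import FixtureConfig, make_toy_pocket

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")

# --------------------------------------------------------------------------
# oracles (kept independent of the implementation paths they check)
# --------------------------------------------------------------------------


def quaternion_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Optimal-superposition RMSD via the quaternion (Davenport K-matrix)
    eigenvalue method — independent of the SVD-based Kabsch code path."""
    m = mobile - mobile.mean(axis=0)
    r = reference - reference.mean(axis=0)
    n = len(m)
    s = m.T @ r
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.max(np.linalg.eigvalsh(k))
    msd = (np.sum(m ** 2) + np.sum(r ** 2) - 2.0 * lam) / n
    return float(np.sqrt(max(msd, 0.0)))


def pairwise_sum_oracle(coords: np.ndarray, pair_fn) -> float:
    """Exhaustive double-loop sum of pair_fn(i, j, r_ij)."""
    total = 0.0
    for i in range(len(coords)):
        for j in range(i + 1, len(coords)):
            r = float(np.linalg.norm(coords[i] - coords[j]))
            total += pair_fn(i, j, r)
    return total


def central_difference_gradient(fn, coords: np.ndarray, h: float = 1e-5) -> np.ndarray:
    g = np.zeros_like(coords)
    for i in range(coords.shape[0]):
        for k in range(3):
            up = coords.copy()
            dn = coords.copy()
            up[i, k] += h
            dn[i, k] -= h
            g[i, k] = (fn(up) - fn(dn)) / (2 * h)
    return g


def pearson_r2_covariance_oracle(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((np.sum(xc * yc) ** 2) / (np.sum(xc ** 2) * np.sum(yc ** 2)))


# --------------------------------------------------------------------------
# shared fixtures
# --------------------------------------------------------------------------


@pytest.fixture(scope="session")
def toy_config() -> FixtureConfig:
    return FixtureConfig(seed=1, n_ligands=12, rotbond_range=(0, 8))


@pytest.fixture(scope="session")
def toy_structure(toy_config):
    return make_toy_pocket(toy_config)


@pytest.fixture()
def backend():
    return make_test_backend()


@pytest.fixture()
def caching_backend():
    return CachingBackend(make_test_backend())
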