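import numpy as np
import pytest
from scipy.stats import nbinom

import spotbench as sb


def clamped_nb_pmf(mean, theta, lower=1, upper=None, tail=4000):
    """Exact pmf of clamp(NB(mean, theta), lower, upper) by direct summation."""
    ks = np.arange(tail)
    p = nbinom.pmf(ks, theta, theta / (theta + mean))
    vals = np.clip(ks, lower, upper if upper is not None else tail)
    out = {}
    for v, pr in zip(vals, p):
        out[int(v)] = out.get(int(v), 0.0) + pr
    return out


def clamped_nb_moments(mean, theta, lower=1, upper=None):
    d = clamped_nb_pmf(mean, theta, lower, upper)
    m1 = sum(v * p for v, p in d.items())
    m2 = sum(v * v * p for v, p in d.items())
    return m1, m2 - m1**2


def coupled_cells_moments(mean_k, theta, k_upper, mean_n):
    """Moments of max(K', N') with K' = clamp(NB(mean_k), 1, k_upper) and
    N' = clamp(NB(mean_n), 1, inf) independent (the simulator's cell count)."""
    dk = clamped_nb_pmf(mean_k, theta, 1, k_upper)
    ns = np.arange(4000)
    pn = nbinom.pmf(ns, theta, theta / (theta + mean_n))
    m1 = m2 = 0.0
    for k, pk in dk.items():
        vals = np.maximum(np.maximum(ns, 1), k)
        m1 += pk * float((vals * pn).sum())
        m2 += pk * float((vals**2 * pn).sum())
    return m1, m2 - m1**2


@pytest.fixture(scope="session")
def small_reference():
    """600-cell, 12-type multiome reference used across module tests."""
    return sb.generate_reference(sb.ReferenceConfig(
        n_cells=600, n_genes=300, n_peaks=400, n_cell_types=12,
        markers_per_type=10, marker_fold_change=8.0, seed=11))


@pytest.fixture(scope="session")
def four_type_reference():
    return sb.generate_reference(sb.ReferenceConfig(
        n_cells=400, n_genes=120, n_peaks=160, n_cell_types=4,
        markers_per_type=10, seed=5))
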