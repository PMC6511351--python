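"""Shared fixtures and independent oracles.

The oracles here are deliberately naive re-derivations (threshold-sum TFCE
via scipy labelling, the step-up FDR definition applied literally, pooled-t
from the textbook formula) so the implementation is checked against an
independent path, not against itself.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage, stats

from visionet import SimConfig, generate_atlas


def brute_force_tfce(
    stat: np.ndarray, E: float = 0.5, H: float = 2.0, dh: float = 1.0, connectivity: int = 26
) -> np.ndarray:
    """Literal threshold-sum TFCE of the positive part, via scipy labelling."""
    stat = np.asarray(stat, dtype=float)
    out = np.zeros_like(stat)
    vmax = stat.max(initial=0.0)
    structure = ndimage.generate_binary_structure(3, 3 if connectivity == 26 else 1)
    h = dh
    while h <= vmax + 1e-12:
        labelled, n = ndimage.label(stat >= h - 1e-12, structure=structure)
        for c in range(1, n + 1):
            mask = labelled == c
            out[mask] += mask.sum() ** E * h**H * dh
        h += dh
    return out


def brute_force_bh_reject(pvals: np.ndarray, alpha: float) -> np.ndarray:
    """Benjamini-Hochberg by its definition: largest k with p_(k) <= k/m*alpha."""
    pvals = np.asarray(pvals, dtype=float)
    m = pvals.size
    order = np.argsort(pvals, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if pvals[order[k - 1]] <= k * alpha / m:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    if k_star:
        reject[order[:k_star]] = True
    return reject


def pooled_t_by_hand(a, b) -> float:
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))


def two_tailed_p(t: float, df: int) -> float:
    return 2 * stats.t.sf(abs(t), df)


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(seed=7)


@pytest.fixture(scope="session")
def default_atlas(default_config):
    return generate_atlas(default_config)


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    """Small grid still holding all 19 ROIs, short runs — for voxel-level tests."""
    return SimConfig(grid_shape=(16, 16, 16), n_volumes=40, seed=11)


@pytest.fixture(scope="session")
def tiny_atlas(tiny_config):
    return generate_atlas(tiny_config)
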