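"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from patchdev import Image2D


def naive_autocorrelogram(px: np.ndarray, mask: np.ndarray, max_lag: int,
                          min_overlap: int = 20):
    """Brute-force per-lag Pearson oracle: explicit double loop over pixels.

    Independent of the package's FFT path; used to pin down the vectorized
    autocorrelogram on small images.
    """
    h, w = px.shape
    L = max_lag
    r = np.full((2 * L + 1, 2 * L + 1), np.nan)
    n = np.zeros((2 * L + 1, 2 * L + 1), dtype=int)
    for ty in range(-L, L + 1):
        for tx in range(-L, L + 1):
            a, b = [], []
            for y in range(h):
                for x in range(w):
                    y2, x2 = y - ty, x - tx
                    if 0 <= y2 < h and 0 <= x2 < w and mask[y, x] and mask[y2, x2]:
                        a.append(px[y, x])
                        b.append(px[y2, x2])
            n[ty + L, tx + L] = len(a)
            if len(a) >= min_overlap:
                a, b = np.asarray(a), np.asarray(b)
                if a.std() > 0 and b.std() > 0:
                    r[ty + L, tx + L] = np.corrcoef(a, b)[0, 1]
    return r, n


def exact_mw_two_tailed_by_permutation(a, b) -> float:
    """Two-tailed Mann-Whitney p by full enumeration of group assignments.

    Enumerates every way of choosing which pooled values belong to sample a,
    computes U for each, and doubles the smaller tail at the observed U.
    Only valid without ties; independent of the package's DP enumeration.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n_a = len(a)
    ranks = pooled.argsort().argsort() + 1  # ok: no ties by construction
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
    us = []
    for idx in itertools.combinations(range(len(pooled)), n_a):
        us.append(ranks[list(idx)].sum() - n_a * (n_a + 1) / 2)
    us = np.asarray(us)
    p_low = (us <= u_obs).mean()
    p_high = (us >= u_obs).mean()
    return min(1.0, 2.0 * min(p_low, p_high))


@pytest.fixture(scope="session")
def rng_image() -> Image2D:
    """A 32x32 random image with an irregular validity mask."""
    rng = np.random.default_rng(42)
    px = rng.random((32, 32))
    mask = np.ones((32, 32), dtype=bool)
    mask[:5, :7] = False
    mask[28:, 25:] = False
    return Image2D(pixels=px, pixel_size_um=2.0, mask=mask)


@pytest.fixture(scope="session")
def checkerboard() -> Image2D:
    """A 1-pixel checkerboard tiled to 64x64."""
    px = (np.indices((64, 64)).sum(axis=0) % 2).astype(float)
    return Image2D(pixels=px, pixel_size_um=1.0)
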