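"""Shared fixtures and the exhaustive-enumeration decoding oracle."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from slmcnv import GenomicProfile, LevelGrid, Scale


def brute_force_viterbi(
    values: np.ndarray,
    grid: LevelGrid,
    matrices: np.ndarray,
    sigma2_eps: float,
) -> np.ndarray:
    """Exhaustive argmax over all K^N state paths (lexicographic tie-break).

    ``matrices`` holds the N-1 per-step transition matrices (a homogeneous
    chain passes the same matrix repeated).  Paths are scored with scipy's
    normal logpdf — an arithmetic route independent of the production
    decoder — and enumerated in lexicographic order, keeping the first
    maximum, i.e. the lexicographically smallest optimal path.
    """
    values = np.asarray(values, float)
    N, K = len(values), grid.K
    # all K^N paths, row-major = lexicographic order
    paths = np.stack(np.meshgrid(*[np.arange(K)] * N, indexing="ij"), axis=-1)
    paths = paths.reshape(-1, N)
    emis = stats.norm.logpdf(values[:, None], grid.levels[None, :],
                             np.sqrt(sigma2_eps))  # (N, K)
    scores = np.log(grid.prior)[paths[:, 0]]
    for t in range(N):
        scores = scores + emis[t, paths[:, t]]
    for t in range(N - 1):
        scores = scores + np.log(matrices[t][paths[:, t], paths[:, t + 1]])
    return paths[int(np.argmax(scores))]


def random_instance(rng: np.random.Generator, heterogeneous: bool = False):
    """Small random decoding instance (N <= 8, K <= 4) for oracle comparison."""
    N = int(rng.integers(2, 9))
    K = int(rng.integers(2, 5))
    levels = np.sort(rng.normal(0, 1, K))
    while np.any(np.diff(levels) <= 0):
        levels = np.sort(rng.normal(0, 1, K))
    prior = rng.dirichlet(np.ones(K) * 2)
    prior = np.maximum(prior, 1e-6)
    prior /= prior.sum()
    grid = LevelGrid(levels, prior)
    sigma2_eps = float(rng.uniform(0.01, 0.5))
    values = rng.normal(0, 1, N)
    if heterogeneous:
        etas = rng.uniform(0.01, 0.6, N - 1)
    else:
        etas = np.full(N - 1, float(rng.uniform(0.01, 0.6)))
    return values, grid, etas, sigma2_eps


def dense_profile(values, chrom: str = "chr1", window_bp: int = 100) -> GenomicProfile:
    """Contiguously tiled log2 profile from a bare value vector."""
    values = np.asarray(values, float)
    starts = np.arange(len(values), dtype=np.int64) * window_bp
    return GenomicProfile(chrom, starts, starts + window_bp, values, Scale.LOG2RATIO)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
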