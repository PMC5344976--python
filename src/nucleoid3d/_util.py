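"""Shared helpers: circular arithmetic, validation, seeded substreams."""

from __future__ import annotations

import numpy as np


def circular_distance(i, j, n: int):
    """Circular bin distance d(i,j) = min(|i-j|, n-|i-j|) on an n-bin ring."""
    d = np.abs(np.asarray(i) - np.asarray(j))
    return np.minimum(d, n - d)


def circular_distance_matrix(n: int) -> np.ndarray:
    idx = np.arange(n)
    return circular_distance(idx[:, None], idx[None, :], n)


def n_bins_for(genome_length: int, bin_size: int) -> int:
    """Number of half-open bins covering a genome; the final partial bin is kept."""
    if genome_length <= 0 or bin_size <= 0:
        raise ValueError("genome_length and bin_size must be positive")
    return -(-genome_length // bin_size)


def check_symmetric(m: np.ndarray, tol: float = 0.0) -> None:
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"matrix must be square, got shape {m.shape}")
    if not np.allclose(m, m.T, atol=tol, rtol=0):
        raise ValueError("matrix is not symmetric")


def child_seed(seed: int, *stream: int) -> int:
    """Derive a deterministic 31-bit substream seed from a master seed."""
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *[int(s) & 0x7FFFFFFF for s in stream]])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)
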