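"""Shared sliding-window arithmetic for calibration and footprint calling.

All windows are computed on the Watson-strand sequence: the adenine count of a
window is (#A + #T) in the Watson window, which equals the number of adenines
on both strands of the duplex; called m6A on either strand projects onto the
same Watson base pair.
"""

from __future__ import annotations

import numpy as np

from .read_model import MethylatedRead, ReferenceGenome


def sliding_sum(x: np.ndarray, w: int) -> np.ndarray:
    """Sums over every complete length-``w`` window (output length n - w + 1)."""
    c = np.concatenate([[0], np.cumsum(x, dtype=np.int64)])
    return c[w:] - c[:-w]


def window_at_counts(seq: np.ndarray, w: int) -> np.ndarray:
    """A+T count of every complete w-bp window of a uint8 ASCII sequence."""
    is_at = (seq == ord("A")) | (seq == ord("T"))
    return sliding_sum(is_at, w)


def read_window_counts(
    read: MethylatedRead, genome: ReferenceGenome, w: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-window (centers, n_adenines, k_m6a) for one read.

    Window ``i`` covers read offsets ``[i, i + w)`` and is centred at genome
    position ``start + i + w // 2``; centers therefore span
    ``[start + w//2, end - w//2)`` for odd ``w``.
    """
    L = len(read)
    if L < w:
        empty = np.zeros(0, dtype=np.int64)
        return empty, empty, empty
    seq = genome.fetch_array(read.chrom, read.start, read.end)
    n = window_at_counts(seq, w)
    ind = np.zeros(L, dtype=np.int64)
    ind[read.m6a_watson - read.start] = 1
    k = sliding_sum(ind, w)
    centers = read.start + w // 2 + np.arange(n.size, dtype=np.int64)
    return centers, n, k
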