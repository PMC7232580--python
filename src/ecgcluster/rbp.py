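"""Reduced binary pattern (RBP) features.

The trace x = {x_1 ... x_N} is reduced to a binary sequence of length N-1 by
the sign of consecutive differences (1 for an increase, 0 for a decrease or
a tie), every sliding m-bit word is read as a decimal (first bit most
significant), and the feature vector is the relative occurrence frequency of
each of the 2^m possible words. The feature depends only on the ordering of
samples, so it is invariant to any positive affine rescaling of the signal.
"""

from __future__ import annotations

import numpy as np

from .io import ECGSignal


def binarize(samples) -> np.ndarray:
    """Map consecutive-sample comparisons to bits: y_i = 1 iff x_{i+1} > x_i.

    Ties count as decreases (bit 0). Accepts an :class:`ECGSignal` or any
    1-D sequence; returns a uint8 array of length N-1.
    """
    x = samples.samples if isinstance(samples, ECGSignal) else np.asarray(samples, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D signal of length >= 2")
    return (x[1:] > x[:-1]).astype(np.uint8)


def to_words(bits: np.ndarray, m: int) -> np.ndarray:
    """Sliding (stride-1) m-bit words as decimals, first bit most significant.

    A bit sequence of length L yields L - m + 1 words in [0, 2^m - 1].
    """
    bits = np.asarray(bits)
    if not 1 <= m <= 16:
        raise ValueError(f"word length m must be in [1, 16], got {m}")
    if bits.size < m:
        raise ValueError(f"need at least m={m} bits, got {bits.size}")
    weights = 1 << np.arange(m - 1, -1, -1)  # MSB first
    return np.correlate(bits.astype(np.int64), weights, mode="valid")


def rbp_histogram(words: np.ndarray, m: int) -> np.ndarray:
    """Relative occurrence frequency of each of the 2^m words.

    Returns a vector of length 2^m that sums to 1.
    """
    words = np.asarray(words)
    if words.size == 0:
        raise ValueError("empty word sequence")
    counts = np.bincount(words, minlength=2**m)
    if counts.size > 2**m:
        raise ValueError("word value exceeds 2^m - 1; inconsistent m")
    return counts / words.size


def subject_rbp_feature(signal: ECGSignal, m: int = 8) -> np.ndarray:
    """RBP feature vector of a full record: binarize, slide m-bit words,
    histogram. Computed on the (denoised) record without beat segmentation."""
    return rbp_histogram(to_words(binarize(signal), m), m)
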