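"""Wavelet features of R-R-segmented beats.

Each R-R cycle contributes one 256-point segment assembled from its first
169 and last 85 samples (254 values, padded to 256 by repeating the final
value twice; a strict mode keeps the raw 254). Segments are grouped four at
a time; each segment in a group is decomposed with an n-level DWT and the
four coefficient vectors are concatenated into one group-level wavelet
vector. A subject's feature is the mean over its group vectors.

With an orthogonal family and periodization boundary handling the transform
of a 256-point segment has exactly 256 coefficients at any level, is
perfectly invertible, and preserves energy.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pywt

from .io import ECGSignal
from .preprocess import Beat, RPeakList, segment_beats

log = logging.getLogger(__name__)

SEGMENT_HEAD = 169
SEGMENT_TAIL = 85
SEGMENT_LEN = 256


def build_segments(beats: Sequence, strict_254: bool = False) -> list[np.ndarray]:
    """Assemble one segment per R-R cycle.

    ``beats`` may hold :class:`Beat` objects (their R-to-next-R cycle is
    used) or plain sample arrays. Cycles shorter than 169+85 samples are
    skipped; the skip count is logged.
    """
    segments = []
    skipped = 0
    for b in beats:
        cycle = b.cycle if isinstance(b, Beat) else np.asarray(b, dtype=float)
        if cycle.size < SEGMENT_HEAD + SEGMENT_TAIL:
            skipped += 1
            continue
        seg = np.concatenate([cycle[:SEGMENT_HEAD], cycle[-SEGMENT_TAIL:]])
        if not strict_254:
            seg = np.concatenate([seg, np.repeat(seg[-1], SEGMENT_LEN - seg.size)])
        segments.append(seg)
    if skipped:
        log.info("skipped %d cycles shorter than %d samples", skipped, SEGMENT_HEAD + SEGMENT_TAIL)
    if not segments:
        warnings.warn("all R-R cycles too short for 256-point segments")
    return segments


def max_level(segment_len: int = SEGMENT_LEN, family: str = "db4") -> int:
    """Deepest usable level: with periodization every halving down to a
    length-1 approximation is orthogonal and invertible (8 for 256 points)."""
    return int(np.floor(np.log2(segment_len)))


def dwt_coeffs(segment: np.ndarray, n: int, family: str = "db4") -> list[np.ndarray]:
    """n-level DWT coefficient arrays (approximation first), periodized."""
    segment = np.asarray(segment, dtype=float)
    lim = max_level(segment.size, family)
    if not 1 <= n <= lim:
        raise ValueError(
            f"level {n} invalid for {segment.size}-point segment with {family} (max {lim})"
        )
    with warnings.catch_warnings():
        # beyond dwt_max_level pywt warns about boundary effects; with
        # periodization the transform stays orthogonal and invertible
        warnings.simplefilter("ignore", UserWarning)
        return pywt.wavedec(segment, family, mode="periodization", level=n)


def dwt_features(group: Sequence[np.ndarray], n: int = 6, family: str = "db4") -> np.ndarray:
    """Concatenated coefficient vector of a four-segment group."""
    if len(group) != 4:
        raise ValueError(f"a segment group holds exactly 4 segments, got {len(group)}")
    parts = []
    for seg in group:
        coeffs = dwt_coeffs(seg, n, family)
        parts.append(np.concatenate(coeffs))
    return np.concatenate(parts)


def inverse_dwt(coeff_arrays: list[np.ndarray], family: str = "db4") -> np.ndarray:
    """Reconstruct a segment from its coefficient arrays (round-trip check)."""
    return pywt.waverec(coeff_arrays, family, mode="periodization")


def subject_wavelet_feature(
    signal: ECGSignal,
    peaks: RPeakList,
    n: int = 6,
    family: str = "db4",
) -> np.ndarray | None:
    """Subject-level wavelet feature: mean of all group-level vectors.

    Returns ``None`` (subject unusable) when fewer than four 256-point
    segments are available; the reason is logged so cohort runs can report
    exclusions.
    """
    beats = segment_beats(signal, peaks)
    segments = build_segments(beats)
    if len(segments) < 4:
        log.info(
            "subject %s: only %d usable segments (<4); excluded from wavelet feature",
            signal.subject_id,
            len(segments),
        )
        return None
    groups = [segments[i : i + 4] for i in range(0, len(segments) - 3, 4)]
    vectors = np.stack([dwt_features(g, n, family) for g in groups])
    return vectors.mean(axis=0)
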