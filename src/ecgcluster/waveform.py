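"""Morphological (waveform) features from fiducial points.

Per beat, the five fiducial points P, Q, R, S, T are located in standard
physiological windows around the R apex (Q/S: nearest minima within 80 ms;
P: maximum 80-300 ms before R; T: largest baseline deviation 80-400 ms after
S). From these, 24 features are computed in five classes:

* 5 positions — fiducial times relative to R, in ms;
* 10 amplitude differences (mV) — PQ, RQ, TQ, RT, PS, RP, TS, RS, PT, QS,
  each the signed difference amp(first) - amp(second);
* 5 durations (ms) — QS, PR, QR, ST, QT, absolute time spans;
* 3 slopes (mV/ms) — RS, ST, QR, amplitude difference over signed time
  difference;
* 1 area (mV*ms) — the QRS triangle spanned by (t_Q, a_Q), (t_R, a_R),
  (t_S, a_S), by the shoelace formula.

Positions are R-relative so the features do not depend on where the beat
window sits in the record; the subject-level vector is the element-wise
median across beats, which tolerates occasional mis-delineation.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .io import ECGSignal
from .preprocess import Beat, RPeakList, segment_beats

log = logging.getLogger(__name__)

_POINTS = ("P", "Q", "R", "S", "T")

WAVEFORM_FEATURE_NAMES: tuple[str, ...] = (
    "pos_P", "pos_Q", "pos_R", "pos_S", "pos_T",
    "amp_PQ", "amp_RQ", "amp_TQ", "amp_RT", "amp_PS",
    "amp_RP", "amp_TS", "amp_RS", "amp_PT", "amp_QS",
    "dur_QS", "dur_PR", "dur_QR", "dur_ST", "dur_QT",
    "slope_RS", "slope_ST", "slope_QR",
    "area_QRS",
)

#: Default fiducial search windows (ms), standard physiological bounds.
QS_WINDOW_MS = 80.0
P_WINDOW_MS = (80.0, 300.0)  # before R
T_WINDOW_MS = (80.0, 400.0)  # after S


class UnusableBeatError(ValueError):
    """A beat where fiducial points cannot be delineated."""


@dataclasses.dataclass
class FiducialPoints:
    """Sample index and amplitude of P, Q, R, S, T within one beat window."""

    indices: dict[str, int]
    amplitudes: dict[str, float]
    fs: float

    def __post_init__(self) -> None:
        order = [self.indices[p] for p in _POINTS]
        if not all(a < b for a, b in zip(order, order[1:])):
            raise UnusableBeatError(f"fiducials out of order: {dict(zip(_POINTS, order))}")

    def time_ms(self, point: str) -> float:
        """Time of a fiducial relative to R, in ms."""
        return (self.indices[point] - self.indices["R"]) / self.fs * 1000.0


def locate_fiducials(
    beat: Beat,
    fs: float,
    qs_window_ms: float = QS_WINDOW_MS,
    p_window_ms: tuple[float, float] = P_WINDOW_MS,
    t_window_ms: tuple[float, float] = T_WINDOW_MS,
) -> FiducialPoints:
    """Delineate P, Q, R, S, T in one beat (windows truncated at beat edges).

    Raises :class:`UnusableBeatError` when a search window is empty after
    truncation.
    """
    x = beat.samples
    r = beat.r_index
    ms = fs / 1000.0

    def span(lo_ms: float, hi_ms: float) -> tuple[int, int]:
        lo = max(0, r + int(round(lo_ms * ms)))
        hi = min(x.size, r + int(round(hi_ms * ms)))
        if hi <= lo:
            raise UnusableBeatError(f"empty fiducial window [{lo_ms}, {hi_ms}] ms around R")
        return lo, hi

    def local_minima(lo: int, hi: int) -> np.ndarray:
        w = x[max(lo - 1, 0) : min(hi + 1, x.size)]
        rel = np.flatnonzero((w[1:-1] <= w[:-2]) & (w[1:-1] <= w[2:]))
        return rel + max(lo - 1, 0) + 1

    # Q and S are the local minima nearest R: filtering can pull the window's
    # global minimum onto baseline undershoot further out, but the notch
    # adjacent to R survives as a local minimum
    lo, hi = span(-qs_window_ms, 0)
    minima = local_minima(lo, hi)
    q = int(minima[-1]) if minima.size else lo + int(np.argmin(x[lo:hi]))
    lo, hi = span(1000.0 / fs, qs_window_ms)
    minima = local_minima(lo, hi)
    s = int(minima[0]) if minima.size else lo + int(np.argmin(x[lo:hi]))
    lo, hi = span(-p_window_ms[1], -p_window_ms[0])
    p = lo + int(np.argmax(x[lo:hi]))
    baseline = float(np.median(x))
    s_off_ms = (s - r) / ms
    lo, hi = span(s_off_ms + t_window_ms[0], s_off_ms + t_window_ms[1])
    t = lo + int(np.argmax(np.abs(x[lo:hi] - baseline)))
    idx = {"P": p, "Q": q, "R": r, "S": s, "T": t}
    return FiducialPoints(
        indices=idx, amplitudes={k: float(x[v]) for k, v in idx.items()}, fs=fs
    )


def extract_waveform_features(points: FiducialPoints, fs: float | None = None) -> np.ndarray:
    """The 24-element descriptor, ordered as :data:`WAVEFORM_FEATURE_NAMES`."""
    t = {p: points.time_ms(p) for p in _POINTS}
    a = points.amplitudes

    def amp(pair: str) -> float:
        return a[pair[0]] - a[pair[1]]

    def dur(pair: str) -> float:
        return abs(t[pair[0]] - t[pair[1]])

    def slope(pair: str) -> float:
        dt = t[pair[0]] - t[pair[1]]
        if dt == 0:
            raise UnusableBeatError(f"coincident fiducials {pair}; slope undefined")
        return amp(pair) / dt

    area = 0.5 * abs(
        t["Q"] * (a["R"] - a["S"])
        + t["R"] * (a["S"] - a["Q"])
        + t["S"] * (a["Q"] - a["R"])
    )
    values = [
        t["P"], t["Q"], t["R"], t["S"], t["T"],
        amp("PQ"), amp("RQ"), amp("TQ"), amp("RT"), amp("PS"),
        amp("RP"), amp("TS"), amp("RS"), amp("PT"), amp("QS"),
        dur("QS"), dur("PR"), dur("QR"), dur("ST"), dur("QT"),
        slope("RS"), slope("ST"), slope("QR"),
        area,
    ]
    return np.asarray(values, dtype=float)


def beat_waveform_features(beat: Beat, fs: float) -> np.ndarray:
    """Fiducial location + feature extraction for one beat."""
    return extract_waveform_features(locate_fiducials(beat, fs))


def subject_waveform_feature(signal: ECGSignal, peaks: RPeakList) -> np.ndarray | None:
    """Element-wise median of the per-beat descriptors; ``None`` (excluded)
    when no beat is delineable."""
    rows = []
    for beat in segment_beats(signal, peaks):
        try:
            rows.append(beat_waveform_features(beat, signal.fs))
        except UnusableBeatError:
            continue
    if not rows:
        log.info("subject %s: no delineable beats; excluded from waveform feature", signal.subject_id)
        return None
    return np.median(np.stack(rows), axis=0)
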