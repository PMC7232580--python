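"""Denoising and beat segmentation.

Denoising is a linear-phase FIR band-pass (applied forward and backward, so
the net phase is zero), with an optional power-line notch and optional
wavelet shrinkage. QRS detection finds zero crossings of the first-order
derivative (positive-to-negative, i.e. local maxima) on a QRS-band-limited
copy of the signal, then applies the two classical non-linear suppressions:
an amplitude floor that cuts off low-amplitude noise, and a refractory
period that discards spikes shortly after an accepted QRS.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pywt
from scipy import signal as sps

from .io import ECGSignal


@dataclasses.dataclass
class FilterSpec:
    """Band-pass + optional notch + optional wavelet shrinkage.

    fir_order=None picks 4*fs/low taps (rounded odd), capped at a third of
    the record so the convolution stays well conditioned on short signals.
    """

    low: float = 0.5
    high: float = 40.0
    notch: float | None = None
    fir_order: int | None = None
    wavelet_shrinkage: bool = False
    wavelet_family: str = "db4"
    wavelet_levels: int = 4

    def validate(self, fs: float) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(f"need 0 < low < high, got {self.low}, {self.high}")
        if self.high >= fs / 2:
            raise ValueError(f"high cutoff {self.high} Hz >= Nyquist ({fs / 2} Hz)")
        if self.notch is not None and not 0 < self.notch < fs / 2:
            raise ValueError("notch frequency outside (0, Nyquist)")


@dataclasses.dataclass
class RPeakList:
    """Ordered R-peak sample indices with their sampling rate."""

    indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size > 1 and not np.all(np.diff(self.indices) > 0):
            raise ValueError("R-peak indices must be strictly increasing")

    def __len__(self) -> int:
        return self.indices.size

    @property
    def times(self) -> np.ndarray:
        return self.indices / self.fs


@dataclasses.dataclass
class Beat:
    """One cardiac cycle window spanning previous R to next R (open at next)."""

    samples: np.ndarray
    r_index: int  # index of this beat's R within the window
    rr_prev: int  # samples from previous R to this R
    rr_next: int  # samples from this R to the next R

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not 0 <= self.r_index < self.samples.size:
            raise ValueError("R index outside beat window")

    @property
    def cycle(self) -> np.ndarray:
        """The R-to-next-R span (one R-R cycle)."""
        return self.samples[self.r_index :]


def _fir_bandpass(x: np.ndarray, fs: float, low: float, high: float, numtaps: int) -> np.ndarray:
    taps = sps.firwin(numtaps, [low, high], pass_zero=False, fs=fs)
    # symmetric FIR run forward then backward: exactly zero phase, |H|^2 gain
    y = sps.fftconvolve(x, taps, mode="same")
    return sps.fftconvolve(y[::-1], taps, mode="same")[::-1]


def _wavelet_shrink(x: np.ndarray, family: str, levels: int) -> np.ndarray:
    levels = min(levels, pywt.dwt_max_level(x.size, pywt.Wavelet(family).dec_len))
    if levels < 1:
        return x
    coeffs = pywt.wavedec(x, family, level=levels)
    sigma = np.median(np.abs(coeffs[-1])) / 0.6745 if coeffs[-1].size else 0.0
    thr = sigma * np.sqrt(2.0 * np.log(max(x.size, 2)))  # universal threshold
    shrunk = [coeffs[0]] + [pywt.threshold(c, thr, mode="soft") for c in coeffs[1:]]
    return pywt.waverec(shrunk, family)[: x.size]


def denoise(signal: ECGSignal, spec: FilterSpec | None = None) -> ECGSignal:
    """Zero-phase FIR band-pass, optional notch, optional wavelet shrinkage.

    Length and sampling rate are preserved; a zero signal stays zero.
    """
    spec = spec or FilterSpec()
    spec.validate(signal.fs)
    x = signal.samples
    numtaps = spec.fir_order or int(round(4 * signal.fs / spec.low))
    numtaps = min(numtaps, max(x.size // 3, 5))
    numtaps |= 1  # odd length -> symmetric type-I FIR
    y = _fir_bandpass(x, signal.fs, spec.low, spec.high, numtaps)
    if spec.notch is not None:
        b, a = sps.iirnotch(spec.notch, Q=30.0, fs=signal.fs)
        y = sps.filtfilt(b, a, y)
    if spec.wavelet_shrinkage:
        y = _wavelet_shrink(y, spec.wavelet_family, spec.wavelet_levels)
    return ECGSignal(y, fs=signal.fs, lead=signal.lead, subject_id=signal.subject_id)


def detect_qrs(
    signal: ECGSignal,
    refractory_ms: float = 200.0,
    min_amplitude_fraction: float = 0.3,
    qrs_band: tuple[float, float] = (5.0, 25.0),
) -> RPeakList:
    """Locate R apexes.

    Candidates are positive-to-negative zero crossings of the first-order
    derivative of a QRS-band-limited copy of the signal (the band-limiting
    suppresses P/T waves and baseline so the derivative test keys on the QRS
    upstroke). A candidate is kept only if its band-limited amplitude reaches
    ``min_amplitude_fraction`` times a running median of recently accepted
    peak amplitudes, and only if it falls outside ``refractory_ms`` of the
    previously accepted peak. Accepted candidates are finally refined to the
    raw-signal maximum within +/-40 ms.
    """
    fs = signal.fs
    refractory = int(round(refractory_ms * fs / 1000.0))
    if len(signal) < refractory or len(signal) < 16:
        warnings.warn("signal shorter than one refractory interval; no peaks")
        return RPeakList(np.empty(0, dtype=int), fs)

    numtaps = min(int(0.2 * fs) | 1, max(len(signal) // 3, 5) | 1)
    taps = sps.firwin(numtaps, [qrs_band[0], min(qrs_band[1], 0.45 * fs)], pass_zero=False, fs=fs)
    f = sps.fftconvolve(signal.samples, taps, mode="same")

    d = np.diff(f)
    cand = np.flatnonzero((d[:-1] > 0) & (d[1:] <= 0)) + 1  # local maxima of f
    cand = cand[f[cand] > 0]
    if cand.size == 0:
        return RPeakList(np.empty(0, dtype=int), fs)

    bootstrap = float(np.percentile(f[cand], 95))
    if bootstrap <= 0:
        return RPeakList(np.empty(0, dtype=int), fs)

    accepted: list[int] = []
    recent_amps: list[float] = []
    for i in cand:
        est = float(np.median(recent_amps[-8:])) if recent_amps else bootstrap
        if f[i] < min_amplitude_fraction * est:
            continue
        if accepted and i - accepted[-1] < refractory:
            continue
        accepted.append(int(i))
        recent_amps.append(float(f[i]))

    # refine each accepted peak to the raw-signal apex nearby
    half = int(round(0.040 * fs))
    refined: list[int] = []
    for i in accepted:
        lo, hi = max(0, i - half), min(len(signal), i + half + 1)
        r = lo + int(np.argmax(signal.samples[lo:hi]))
        if refined and r - refined[-1] < refractory:
            continue
        refined.append(r)
    return RPeakList(np.asarray(refined, dtype=int), fs)


def segment_beats(signal: ECGSignal, peaks: RPeakList) -> list[Beat]:
    """One Beat per interior R peak; its window runs from the previous R to
    the next R (open at the next), so consecutive windows tile the span
    between the first and last peak. The first and last peaks have no
    complete cycle and are dropped."""
    idx = peaks.indices
    if idx.size < 2:
        warnings.warn("fewer than 2 R peaks; no complete beats")
        return []
    beats = []
    for j in range(1, idx.size - 1):
        prev_r, r, next_r = idx[j - 1], idx[j], idx[j + 1]
        beats.append(
            Beat(
                samples=signal.samples[prev_r:next_r],
                r_index=int(r - prev_r),
                rr_prev=int(r - prev_r),
                rr_next=int(next_r - r),
            )
        )
    return beats
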