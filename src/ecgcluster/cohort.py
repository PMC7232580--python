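"""Synthetic labeled ECG cohorts.

Each subject's trace is a quasi-periodic sum of five Gaussian bumps per beat
(P, Q, R, S, T), placed at R-R intervals drawn from a normal distribution —
the same sum-of-Gaussians idealization popularized by ECGSYN. The generator
layers on the five classical contamination sources of ambulatory ECG
(baseline wander at 0.05-2.00 Hz, power-line interference, EMG noise,
electrode-motion transients, broadband extraneous noise) and applies
configurable disease-conditioned morphology shifts, so that the association
between condition labels and ECG features is known by construction and
recoverable by the downstream clustering.

All Gaussian parameters are analytically known, which makes fiducial-point
and QRS-detection tests exact rather than approximate.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import signal as sps

from .io import CONDITIONS, ECGSignal, MedicalRecord, write_records_csv, write_signal_csv

_COMPONENTS = ("P", "Q", "R", "S", "T")


class ConfigError(ValueError):
    """A cohort configuration is internally inconsistent."""


@dataclasses.dataclass
class GaussianWave:
    """One ECG wave component: a Gaussian bump.

    amplitude in mV (signed), center in ms relative to the R apex (signed),
    width = Gaussian sigma in ms (> 0).
    """

    amplitude: float
    center_ms: float
    width_ms: float

    def __post_init__(self) -> None:
        if not self.width_ms > 0:
            raise ValueError(f"wave width must be positive, got {self.width_ms}")


@dataclasses.dataclass
class WaveParams:
    """Morphology of one beat: the five component waves.

    Invariants: all widths > 0 (checked per wave), R amplitude > 0, and the
    wave centers are ordered P < Q < R < S < T in time.
    """

    P: GaussianWave
    Q: GaussianWave
    R: GaussianWave
    S: GaussianWave
    T: GaussianWave

    def __post_init__(self) -> None:
        if not self.R.amplitude > 0:
            raise ValueError("R amplitude must be positive")
        centers = [getattr(self, c).center_ms for c in _COMPONENTS]
        if not all(a < b for a, b in zip(centers, centers[1:])):
            raise ValueError(f"wave centers must be ordered P<Q<R<S<T, got {centers}")

    def waves(self) -> dict[str, GaussianWave]:
        return {c: getattr(self, c) for c in _COMPONENTS}

    def copy(self) -> "WaveParams":
        return WaveParams(**{c: dataclasses.replace(getattr(self, c)) for c in _COMPONENTS})

    @classmethod
    def typical(cls) -> "WaveParams":
        """Textbook limb-lead morphology (R apex 1 mV)."""
        return cls(
            P=GaussianWave(0.15, -160.0, 22.0),
            Q=GaussianWave(-0.10, -28.0, 9.0),
            R=GaussianWave(1.00, 0.0, 11.0),
            S=GaussianWave(-0.18, 28.0, 9.0),
            T=GaussianWave(0.30, 260.0, 45.0),
        )

    @classmethod
    def zero(cls) -> "WaveParams":
        """All wave amplitudes zero (degenerate flat-line morphology).

        R amplitude is set to a tiny positive epsilon to satisfy the R > 0
        invariant while producing a numerically all-zero trace.
        """
        p = cls.typical()
        for c in _COMPONENTS:
            getattr(p, c).amplitude = 0.0 if c != "R" else 1e-300
        return p


@dataclasses.dataclass
class NoiseSpec:
    """Amplitudes and bands for the five contamination classes.

    All amplitudes in mV and >= 0; an all-zero spec is the identity.
    Baseline wander lives in the 0.05-2.00 Hz band by default.
    """

    baseline_amplitude: float = 0.0
    baseline_band: tuple[float, float] = (0.05, 2.00)
    powerline_freq: float = 50.0
    powerline_amplitude: float = 0.0
    emg_band: tuple[float, float] = (20.0, 150.0)
    emg_amplitude: float = 0.0
    electrode_rate_per_min: float = 0.0
    electrode_amplitude: float = 0.0
    white_sigma: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "baseline_amplitude",
            "powerline_amplitude",
            "emg_amplitude",
            "electrode_amplitude",
            "white_sigma",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def typical(cls) -> "NoiseSpec":
        """Mild contamination representative of a resting recording."""
        return cls(
            baseline_amplitude=0.10,
            powerline_amplitude=0.02,
            emg_amplitude=0.02,
            electrode_rate_per_min=0.5,
            electrode_amplitude=0.3,
            white_sigma=0.01,
        )


@dataclasses.dataclass
class SubjectProfile:
    """Realized per-subject generating parameters."""

    subject_id: str
    age: float
    sex: str
    flags: dict[str, bool]
    waves: WaveParams
    heart_rate_bpm: float
    rr_sd_ms: float = 0.0

    def __post_init__(self) -> None:
        if not 30.0 <= self.heart_rate_bpm <= 200.0:
            raise ValueError(f"heart rate {self.heart_rate_bpm} outside [30, 200] bpm")
        if self.rr_sd_ms < 0:
            raise ValueError("RR variability must be >= 0")


@dataclasses.dataclass
class Effect:
    """One morphology shift applied to subjects positive for a condition.

    component: one of P/Q/R/S/T, '*' (all five waves) or 'heart_rate';
    field: 'amplitude' | 'width' | 'center' (ignored for heart_rate);
    op: 'mul' or 'add'.
    """

    component: str
    field: str
    op: str
    value: float

    def __post_init__(self) -> None:
        if self.component not in (*_COMPONENTS, "*", "heart_rate"):
            raise ConfigError(f"effect references unknown component {self.component!r}")
        if self.component != "heart_rate" and self.field not in ("amplitude", "width", "center"):
            raise ConfigError(f"unknown wave field {self.field!r}")
        if self.op not in ("mul", "add"):
            raise ConfigError(f"unknown op {self.op!r}")


def qrs_width_effect(factor: float) -> list[Effect]:
    """Widen the QRS complex by ``factor``: scales Q/R/S widths and the Q and
    S center offsets, so both the wave shapes and the Q-to-S span stretch."""
    return [
        Effect("Q", "width", "mul", factor),
        Effect("R", "width", "mul", factor),
        Effect("S", "width", "mul", factor),
        Effect("Q", "center", "mul", factor),
        Effect("S", "center", "mul", factor),
    ]


def default_effects() -> dict[str, list[Effect]]:
    """Shipped disease/habit morphology shifts.

    These are plausibility defaults motivated by the clinical literature
    (diabetic QRS prolongation and T flattening, hypertensive R-amplitude
    increase, smoker tachycardia, obesity-attenuated voltages), not measured
    effect sizes — every entry is configurable.
    """
    return {
        "diabetes": qrs_width_effect(1.4) + [Effect("T", "amplitude", "mul", 0.7)],
        "hypertension": [Effect("R", "amplitude", "mul", 1.3)],
        "smoker": [Effect("heart_rate", "value", "add", 15.0)],
        "obesity": [Effect("*", "amplitude", "mul", 0.8)],
    }


def default_prevalence() -> dict[str, float]:
    """Condition prevalences of the PTB diagnostic cohort (counts over 290
    subjects: hypertension 63, smoker 73, diabetes 29, obesity 20)."""
    return {
        "obesity": 20 / 290,
        "smoker": 73 / 290,
        "hypertension": 63 / 290,
        "diabetes": 29 / 290,
    }


@dataclasses.dataclass
class CohortConfig:
    """Everything needed to regenerate a cohort bit-for-bit."""

    n_subjects: int = 100
    prevalence: dict[str, float] = dataclasses.field(default_factory=default_prevalence)
    effects: dict[str, list[Effect]] = dataclasses.field(default_factory=default_effects)
    fs: float = 1000.0
    duration: float = 10.0
    seed: int = 0
    heart_rate_mean: float = 72.0
    heart_rate_sd: float = 8.0
    rr_sd_ms: float = 15.0
    morphology_jitter: float = 0.08
    noise: NoiseSpec = dataclasses.field(default_factory=NoiseSpec.typical)
    unknown_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("need at least one subject")
        if self.fs < 100:
            raise ConfigError("sampling rate must be >= 100 Hz")
        for cond, p in self.prevalence.items():
            if cond not in CONDITIONS:
                raise ConfigError(f"unknown condition {cond!r}")
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"prevalence for {cond} outside [0, 1]")
        for cond, effs in self.effects.items():
            if cond not in CONDITIONS:
                raise ConfigError(f"effect map references unknown condition {cond!r}")
            for e in effs:
                if not isinstance(e, Effect):
                    raise ConfigError("effects must be Effect instances")
        if not 0.0 <= self.unknown_fraction <= 1.0:
            raise ConfigError("unknown_fraction outside [0, 1]")


# ---------------------------------------------------------------------------
# seed derivation: fixed arithmetic so each subject and each noise stream is
# independently reproducible from the master seed

_MOD = 2**31


def subject_seeds(master: int, index: int) -> tuple[int, int]:
    """(clean-signal seed, noise seed) for subject ``index``."""
    base = (master * 1_000_003 + 2 * index) % _MOD
    return base, (base + 1) % _MOD


def _profile_seed(master: int) -> int:
    return (master * 1_000_003 + 999_983) % _MOD


# ---------------------------------------------------------------------------
# clean-signal synthesis


def true_r_times(profile: SubjectProfile, fs: float, duration: float, seed: int) -> np.ndarray:
    """Ground-truth R-apex times (s) for ``generate_clean_ecg`` with the same
    arguments. The first beat sits half an R-R interval into the record."""
    rr_mean_ms = 60_000.0 / profile.heart_rate_bpm
    rng = np.random.default_rng(seed)
    times = []
    t = rr_mean_ms / 2000.0  # seconds
    while t < duration:
        times.append(t)
        rr = rng.normal(rr_mean_ms, profile.rr_sd_ms) if profile.rr_sd_ms > 0 else rr_mean_ms
        t += max(rr, 1.0) / 1000.0
    return np.asarray(times)


def generate_clean_ecg(
    profile: SubjectProfile, fs: float, duration: float, seed: int
) -> ECGSignal:
    """Synthesize a noise-free trace: five Gaussian bumps per beat at R-R
    intervals drawn from Normal(60000/hr, rr_sd) ms, clipped positive.

    Deterministic given ``seed``.
    """
    if fs <= 0 or duration <= 0:
        raise ValueError("fs and duration must be positive")
    if duration * profile.heart_rate_bpm / 60.0 < 2:
        raise ValueError("duration must cover at least two beats")
    r_times = true_r_times(profile, fs, duration, seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    for r in r_times:
        for wave in profile.waves.waves().values():
            if abs(wave.amplitude) < 1e-12:
                continue
            c = r + wave.center_ms / 1000.0
            sigma = wave.width_ms / 1000.0
            lo = max(0, int((c - 5 * sigma) * fs))
            hi = min(n, int((c + 5 * sigma) * fs) + 1)
            if hi <= lo:
                continue
            tt = t[lo:hi]
            x[lo:hi] += wave.amplitude * np.exp(-0.5 * ((tt - c) / sigma) ** 2)
    return ECGSignal(x, fs=fs, lead="synth", subject_id=profile.subject_id)


# ---------------------------------------------------------------------------
# noise synthesis


def _bandpass_white(rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    hi = min(hi, 0.49 * fs)
    white = rng.standard_normal(n)
    taps = sps.firwin(101, [lo, hi], pass_zero=False, fs=fs)
    shaped = sps.fftconvolve(white, taps, mode="same")
    sd = shaped.std()
    return shaped / sd if sd > 0 else shaped


def add_noise(signal: ECGSignal, spec: NoiseSpec, seed: int) -> ECGSignal:
    """Return signal + the five contamination classes; length and fs unchanged.

    Each class draws from its own child RNG stream, so zeroing one class
    leaves the realizations of the others untouched.
    """
    n = len(signal)
    t = signal.times
    fs = signal.fs
    streams = np.random.SeedSequence(seed).spawn(5)
    out = signal.samples.copy()

    if spec.baseline_amplitude > 0:
        rng = np.random.default_rng(streams[0])
        k = 5  # a handful of drifting tones spanning the band
        freqs = rng.uniform(*spec.baseline_band, size=k)
        phases = rng.uniform(0, 2 * np.pi, size=k)
        for f, ph in zip(freqs, phases):
            out += (spec.baseline_amplitude / k) * np.sin(2 * np.pi * f * t + ph)

    if spec.powerline_amplitude > 0:
        rng = np.random.default_rng(streams[1])
        ph = rng.uniform(0, 2 * np.pi)
        out += spec.powerline_amplitude * np.sin(2 * np.pi * spec.powerline_freq * t + ph)

    if spec.emg_amplitude > 0:
        rng = np.random.default_rng(streams[2])
        out += spec.emg_amplitude * _bandpass_white(rng, n, fs, spec.emg_band)

    if spec.electrode_amplitude > 0 and spec.electrode_rate_per_min > 0:
        rng = np.random.default_rng(streams[3])
        n_events = rng.poisson(spec.electrode_rate_per_min * signal.duration / 60.0)
        sigma = 0.060  # 60 ms transient
        for _ in range(n_events):
            center = rng.uniform(0, signal.duration)
            amp = spec.electrode_amplitude * rng.choice([-1.0, 1.0])
            out += amp * np.exp(-0.5 * ((t - center) / sigma) ** 2)

    if spec.white_sigma > 0:
        rng = np.random.default_rng(streams[4])
        out += rng.normal(0.0, spec.white_sigma, size=n)

    return ECGSignal(out, fs=fs, lead=signal.lead, subject_id=signal.subject_id)


# ---------------------------------------------------------------------------
# cohort assembly


def _apply_effects(waves: WaveParams, hr: float, effects: list[Effect]) -> tuple[WaveParams, float]:
    waves = waves.copy()
    for e in effects:
        if e.component == "heart_rate":
            hr = hr * e.value if e.op == "mul" else hr + e.value
            continue
        targets = _COMPONENTS if e.component == "*" else (e.component,)
        for comp in targets:
            wave = getattr(waves, comp)
            field = {"amplitude": "amplitude", "width": "width_ms", "center": "center_ms"}[e.field]
            old = getattr(wave, field)
            setattr(wave, field, old * e.value if e.op == "mul" else old + e.value)
    return waves, hr


def generate_profiles(config: CohortConfig) -> list[SubjectProfile]:
    """Draw per-subject flags, demographics and realized morphology.

    Subjects whose flag is false keep base-distribution morphology for that
    condition; flagged subjects receive the configured effect deltas.
    """
    rng = np.random.default_rng(_profile_seed(config.seed))
    base = WaveParams.typical()
    profiles = []
    for i in range(config.n_subjects):
        flags = {
            cond: bool(rng.random() < config.prevalence.get(cond, 0.0))
            for cond in CONDITIONS
        }
        age = float(np.clip(rng.normal(57.0, 12.0), 18.0, 90.0))
        sex = "M" if rng.random() < 209 / 290 else "F"
        hr = float(np.clip(rng.normal(config.heart_rate_mean, config.heart_rate_sd), 40.0, 160.0))
        waves = base.copy()
        for comp in _COMPONENTS:
            wave = getattr(waves, comp)
            jf = config.morphology_jitter
            za, zw, zc = np.clip(rng.standard_normal(3), -2.5, 2.5)
            wave.amplitude *= 1.0 + jf * za
            wave.width_ms *= max(1.0 + jf * zw, 0.2)
            if comp != "R":
                wave.center_ms *= max(1.0 + jf * zc, 0.2)
        for cond in CONDITIONS:
            if flags[cond] and cond in config.effects:
                waves, hr = _apply_effects(waves, hr, config.effects[cond])
        hr = float(np.clip(hr, 30.0, 200.0))
        profiles.append(
            SubjectProfile(
                subject_id=f"s{i:04d}",
                age=age,
                sex=sex,
                flags=flags,
                waves=waves,
                heart_rate_bpm=hr,
                rr_sd_ms=config.rr_sd_ms,
            )
        )
    return profiles


def generate_cohort(config: CohortConfig) -> tuple[list[ECGSignal], list[MedicalRecord]]:
    """Generate one noisy signal plus one medical record per subject,
    reproducible bit-for-bit from the master seed."""
    profiles = generate_profiles(config)
    rng_unknown = np.random.default_rng((_profile_seed(config.seed) + 1) % _MOD)
    signals, records = [], []
    for i, prof in enumerate(profiles):
        clean_seed, noise_seed = subject_seeds(config.seed, i)
        sig = generate_clean_ecg(prof, config.fs, config.duration, clean_seed)
        sig = add_noise(sig, config.noise, noise_seed)
        signals.append(sig)
        rec_flags: dict[str, Optional[bool]] = {}
        for cond in CONDITIONS:
            if config.unknown_fraction > 0 and rng_unknown.random() < config.unknown_fraction:
                rec_flags[cond] = None
            else:
                rec_flags[cond] = prof.flags[cond]
        records.append(
            MedicalRecord(
                subject_id=prof.subject_id, age=prof.age, sex=prof.sex, **rec_flags
            )
        )
    return signals, records


# ---------------------------------------------------------------------------
# on-disk cohort


def _config_to_dict(config: CohortConfig) -> dict:
    d = dataclasses.asdict(config)
    d["noise"]["baseline_band"] = list(config.noise.baseline_band)
    d["noise"]["emg_band"] = list(config.noise.emg_band)
    return d


def write_cohort(directory, config: CohortConfig) -> tuple[list[ECGSignal], list[MedicalRecord]]:
    """Materialize a cohort: one two-column signal file per subject, a
    records CSV, and a JSON manifest holding the full config and seed."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    signals, records = generate_cohort(config)
    for sig in signals:
        write_signal_csv(sig, directory / f"{sig.subject_id}.csv")
    write_records_csv(records, directory / "records.csv")
    manifest = {"config": _config_to_dict(config), "n_signals": len(signals)}
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return signals, records
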