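"""On-disk formats: two-column signal text files, medical-record CSV tables,
and read-only support for WFDB-style format-16 records (.hea/.dat), the
layout used by the PTB Diagnostic ECG Database.

Signal files are plain text with two numeric columns (time in seconds,
voltage in mV). Record tables are CSV with a header row; condition flags may
be left empty, in which case the flag is *unknown* and the subject is
excluded from that condition's association denominators downstream (never
silently coerced to False).
"""

from __future__ import annotations

import csv
import dataclasses
import re
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

#: Condition flags tracked per subject, in canonical reporting order.
CONDITIONS = ("obesity", "smoker", "hypertension", "diabetes")


class FormatError(ValueError):
    """A file does not conform to one of the package's on-disk formats."""


class UnsupportedDialectError(FormatError):
    """A WFDB record uses a storage format this reader does not support."""


@dataclasses.dataclass
class ECGSignal:
    """A sampled single-lead voltage trace.

    Attributes
    ----------
    samples : ndarray
        Voltage in mV, ordered in time, length >= 2.
    fs : float
        Sampling rate in Hz, > 0.
    lead : str
        Lead label (e.g. ``"i"``, ``"v5"``; synthetic data uses ``"synth"``).
    subject_id : str
        Identifier linking the signal to a medical record.
    """

    samples: np.ndarray
    fs: float
    lead: str = "synth"
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("signal needs at least 2 samples in one lead")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("signal contains non-finite samples")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds (0-based index / fs)."""
        return np.arange(self.samples.size) / self.fs


@dataclasses.dataclass
class MedicalRecord:
    """Per-subject demographics and condition flags.

    Flags are ``True``/``False``/``None``; ``None`` means the clinical
    summary did not state the condition, mirroring cohorts where a subset of
    subjects has no clinical summary at all.
    """

    subject_id: str
    age: Optional[float] = None
    sex: Optional[str] = None
    diabetes: Optional[bool] = None
    obesity: Optional[bool] = None
    hypertension: Optional[bool] = None
    smoker: Optional[bool] = None

    def flag(self, condition: str) -> Optional[bool]:
        if condition not in CONDITIONS:
            raise KeyError(f"unknown condition {condition!r}")
        return getattr(self, condition)


# ---------------------------------------------------------------------------
# signal CSV


def read_signal_csv(path, lead: str = "synth", subject_id: str = "") -> ECGSignal:
    """Read a two-column (time_s, voltage_mV) text file.

    The sampling rate is inferred as the reciprocal of the median time step;
    the time column must be strictly increasing.
    """
    path = Path(path)
    times, volts = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = re.split(r"[,\s]+", line)
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected two columns")
            try:
                times.append(float(parts[0]))
                volts.append(float(parts[1]))
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric cell") from None
    if len(times) < 2:
        raise FormatError(f"{path}: need at least 2 samples, got {len(times)}")
    t = np.asarray(times)
    steps = np.diff(t)
    if np.any(steps <= 0):
        bad = int(np.argmax(steps <= 0)) + 2
        raise FormatError(f"{path}: time column not strictly increasing at row {bad}")
    fs = 1.0 / float(np.median(steps))
    if not subject_id:
        subject_id = path.stem
    return ECGSignal(np.asarray(volts), fs=fs, lead=lead, subject_id=subject_id)


def write_signal_csv(signal: ECGSignal, path) -> None:
    """Write a signal as two-column text (time_s, voltage_mV)."""
    data = np.column_stack([signal.times, signal.samples])
    np.savetxt(path, data, fmt="%.9g", delimiter=",")


# ---------------------------------------------------------------------------
# records CSV

_TRUE = {"1", "true", "t", "yes", "y"}
_FALSE = {"0", "false", "f", "no", "n"}


def _parse_flag(cell: str, path, row: int, column: str) -> Optional[bool]:
    cell = cell.strip().lower()
    if cell == "":
        return None
    if cell in _TRUE:
        return True
    if cell in _FALSE:
        return False
    raise FormatError(f"{path}: row {row}: bad boolean {cell!r} in column {column!r}")


def read_records_csv(path) -> list[MedicalRecord]:
    """Read the medical-record table (id,age,sex,<condition flags>).

    Empty flag cells become unknown (``None``); duplicate subject ids are a
    format error.
    """
    path = Path(path)
    records: list[MedicalRecord] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"id", *CONDITIONS}
        fields = set(reader.fieldnames or ())
        if not required <= fields:
            raise FormatError(f"{path}: missing columns {sorted(required - fields)}")
        for rowno, row in enumerate(reader, start=2):
            sid = row["id"].strip()
            if not sid:
                raise FormatError(f"{path}: row {rowno}: empty subject id")
            if sid in seen:
                raise FormatError(f"{path}: duplicate subject id {sid!r}")
            seen.add(sid)
            age_cell = (row.get("age") or "").strip()
            sex_cell = (row.get("sex") or "").strip()
            flags = {
                cond: _parse_flag(row[cond], path, rowno, cond) for cond in CONDITIONS
            }
            records.append(
                MedicalRecord(
                    subject_id=sid,
                    age=float(age_cell) if age_cell else None,
                    sex=sex_cell or None,
                    **flags,
                )
            )
    return records


def write_records_csv(records: Sequence[MedicalRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "age", "sex", *CONDITIONS])
        for rec in records:
            flags = [
                "" if rec.flag(c) is None else ("1" if rec.flag(c) else "0")
                for c in CONDITIONS
            ]
            age = "" if rec.age is None else f"{rec.age:g}"
            writer.writerow([rec.subject_id, age, rec.sex or "", *flags])


# ---------------------------------------------------------------------------
# WFDB format-16 records (read-only)


@dataclasses.dataclass
class WFDBLead:
    file_name: str
    fmt: str
    gain: float  # ADC units per mV
    baseline: int  # ADC value corresponding to 0 mV
    units: str
    description: str


@dataclasses.dataclass
class WFDBHeader:
    record_name: str
    n_sig: int
    fs: float
    n_samples: int
    leads: list[WFDBLead]

    @property
    def lead_names(self) -> list[str]:
        return [l.description for l in self.leads]


# signal line: file format[xN][:skew][+offset] gain[(baseline)][/units] ...
_SIGLINE = re.compile(
    r"^(?P<file>\S+)\s+(?P<fmt>\d+)(?:x\d+)?(?::\d+)?(?:\+\d+)?"
    r"(?:\s+(?P<gain>-?[\d.]+)(?:\((?P<baseline>-?\d+)\))?(?:/(?P<units>\S+))?)?"
    r"(?:\s+(?P<adcres>-?\d+))?(?:\s+(?P<adczero>-?\d+))?"
    r"(?:\s+(?P<initval>-?\d+))?(?:\s+(?P<checksum>-?\d+))?"
    r"(?:\s+(?P<blocksize>-?\d+))?(?:\s+(?P<desc>.*\S))?\s*$"
)


def read_wfdb_header(path) -> WFDBHeader:
    """Parse a WFDB .hea file (single-segment, storage format 16 only).

    Any other storage format raises :class:`UnsupportedDialectError` rather
    than silently mis-decoding the companion .dat file.
    """
    path = Path(path)
    lines = [
        ln.strip()
        for ln in path.read_text().splitlines()
        if ln.strip() and not ln.strip().startswith("#")
    ]
    if not lines:
        raise FormatError(f"{path}: empty header")
    head = lines[0].split()
    if len(head) < 2:
        raise FormatError(f"{path}: malformed record line {lines[0]!r}")
    record_name = head[0]
    if "/" in record_name:
        raise UnsupportedDialectError(f"{path}: multi-segment records not supported")
    n_sig = int(head[1])
    fs = float(head[2].split("/")[0]) if len(head) > 2 else 250.0
    n_samples = int(head[3]) if len(head) > 3 else 0
    leads: list[WFDBLead] = []
    for ln in lines[1 : 1 + n_sig]:
        m = _SIGLINE.match(ln)
        if not m:
            raise FormatError(f"{path}: malformed signal line {ln!r}")
        fmt = m.group("fmt")
        if fmt != "16":
            raise UnsupportedDialectError(
                f"{path}: storage format {fmt} not supported (only format 16)"
            )
        gain = float(m.group("gain") or 200.0)
        if gain == 0:
            gain = 200.0  # WFDB convention: 0 means default
        if m.group("baseline") is not None:
            baseline = int(m.group("baseline"))
        elif m.group("adczero") is not None:
            baseline = int(m.group("adczero"))
        else:
            baseline = 0
        leads.append(
            WFDBLead(
                file_name=m.group("file"),
                fmt=fmt,
                gain=gain,
                baseline=baseline,
                units=m.group("units") or "mV",
                description=m.group("desc") or f"sig{len(leads)}",
            )
        )
    if len(leads) != n_sig:
        raise FormatError(f"{path}: header declares {n_sig} signals, found {len(leads)}")
    return WFDBHeader(record_name, n_sig, fs, n_samples, leads)


def read_wfdb_signal(header_path, lead: Optional[str] = None) -> ECGSignal:
    """Decode one lead of a WFDB format-16 record into mV.

    mV = (raw - baseline) / gain, per lead. ``lead`` selects by description
    (default: first lead).
    """
    header_path = Path(header_path)
    hdr = read_wfdb_header(header_path)
    if lead is None:
        idx = 0
    else:
        try:
            idx = hdr.lead_names.index(lead)
        except ValueError:
            raise KeyError(f"lead {lead!r} not in {hdr.lead_names}") from None
    dat_path = header_path.with_name(hdr.leads[idx].file_name)
    if not dat_path.exists():
        raise FileNotFoundError(f"missing signal file {dat_path}")
    raw = np.fromfile(dat_path, dtype="<i2")
    # format 16 interleaves samples across signals, frame by frame
    n_frames = raw.size // hdr.n_sig
    frames = raw[: n_frames * hdr.n_sig].reshape(n_frames, hdr.n_sig)
    li = hdr.leads[idx]
    mv = (frames[:, idx].astype(float) - li.baseline) / li.gain
    return ECGSignal(mv, fs=hdr.fs, lead=li.description, subject_id=hdr.record_name)
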