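"""Reading, writing and validation of single-channel ECoG recordings.

Two interchange formats are supported:

* **EDF** (European Data Format) — 16-bit, single signal, physical
  dimension fixed to microvolts.  Group/phase/animal metadata travel in
  the EDF recording-identification field as ``group/phase/animal_id``.
* **delimited** — CSV with header ``time_s,voltage_uV``, full float
  precision, '.' decimal separator.

The EDF codec here is a deliberately minimal implementation of the
fixed-layout EDF header (one signal, 1-s data records, integer sampling
rate); files it writes are readable by standard EDF tools.
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import FormatError, ParameterError

#: Closed set of study-phase kinds: awake baseline, anesthetized baseline
#: (the control condition for the acute comparisons), ischemic stroke phase,
#: immediate reperfusion phase, and the seven daily subacute sessions.
PHASE_KINDS = (
    "baseline_awake",
    "anesthetized",
    "isp",
    "irp",
    "d1", "d2", "d3", "d4", "d5", "d6", "d7",
)

#: Nominal session length per phase (s): 5 min for the ischemic window and
#: the daily subacute sessions, 10 min for the reperfusion window and the
#: baseline/anesthetized recordings.
PHASE_DURATIONS_S = {
    "baseline_awake": 600.0,
    "anesthetized": 600.0,
    "isp": 300.0,
    "irp": 600.0,
    **{f"d{i}": 300.0 for i in range(1, 8)},
}

GROUPS = ("sham", "mcao")


@dataclass(frozen=True)
class PhaseLabel:
    """A study phase together with its nominal recording length."""

    phase_kind: str
    duration_s: float

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ParameterError(f"duration_s must be > 0, got {self.duration_s}")

    @classmethod
    def of(cls, kind: str) -> "PhaseLabel":
        """Phase label with the study's nominal duration for *kind*."""
        if kind not in PHASE_DURATIONS_S:
            raise ParameterError(f"unknown phase kind {kind!r}; expected one of {PHASE_KINDS}")
        return cls(kind, PHASE_DURATIONS_S[kind])


@dataclass
class Recording:
    """A uniformly sampled single-channel voltage trace (µV).

    ``samples`` are stored as float64 µV; ``rate_hz`` is the sampling rate.
    Metadata (animal, group, phase, session-clock offset) is carried along
    so downstream tables can be keyed without sidecar files.
    """

    samples: np.ndarray
    rate_hz: float
    animal_id: str = ""
    group: str = ""
    phase: PhaseLabel | None = None
    start_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ParameterError("samples must be a non-empty 1-D sequence")
        if not self.rate_hz > 0:
            raise ParameterError(f"rate_hz must be > 0, got {self.rate_hz}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate_hz

    def with_samples(self, samples: np.ndarray) -> "Recording":
        """Copy of this recording with the voltage trace replaced."""
        return replace(self, samples=samples)


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_recording`; empty iff the recording is valid."""

    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:  # truthiness == validity
        return self.ok


def _infer_format(path: str, format: str | None) -> str:
    if format is not None:
        if format not in ("edf", "delimited"):
            raise ParameterError(f"unknown format {format!r}")
        return format
    ext = os.path.splitext(path)[1].lower()
    return "edf" if ext == ".edf" else "delimited"


def read_recording(path: str, format: str | None = None) -> Recording:
    """Read a recording from *path* (``edf`` or ``delimited``; inferred
    from the extension when *format* is None).

    For delimited files the sampling rate is inferred from the time column,
    which must be strictly increasing and uniform to within 1 ppm.
    """
    fmt = _infer_format(path, format)
    if fmt == "edf":
        return _read_edf(path)
    return _read_delimited(path)


def write_recording(rec: Recording, path: str, format: str | None = None) -> str:
    """Write *rec* to *path*; returns the path written."""
    fmt = _infer_format(path, format)
    if fmt == "edf":
        _write_edf(rec, path)
    else:
        _write_delimited(rec, path)
    return path


def validate_recording(rec: Recording) -> ValidationReport:
    """Pure consistency check: reports violations without mutating *rec*.

    Flags non-finite samples, an unknown group or phase kind, and a
    duration that does not match the phase's nominal length.
    """
    report = ValidationReport()
    n_bad = int(np.count_nonzero(~np.isfinite(rec.samples)))
    if n_bad:
        report.violations.append(f"{n_bad} non-finite sample(s)")
    if rec.group and rec.group not in GROUPS:
        report.violations.append(f"unknown group {rec.group!r}")
    if rec.phase is not None:
        if rec.phase.phase_kind not in PHASE_KINDS:
            report.violations.append(f"unknown phase kind {rec.phase.phase_kind!r}")
        elif abs(rec.duration_s - rec.phase.duration_s) > 1.0 / rec.rate_hz:
            report.violations.append(
                f"duration {rec.duration_s:g} s does not match nominal "
                f"{rec.phase.duration_s:g} s for phase {rec.phase.phase_kind!r}"
            )
    return report


# ---------------------------------------------------------------------------
# delimited CSV
# ---------------------------------------------------------------------------

_DELIM_HEADER = "time_s,voltage_uV"


def _read_delimited(path: str) -> Recording:
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # empty files handled below
            data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot parse delimited recording {path}: {exc}") from exc
    if data.size == 0:
        raise FormatError(f"empty recording file {path}")
    if data.shape[1] != 2:
        raise FormatError(f"expected two columns (time_s, voltage_uV) in {path}")
    t, v = data[:, 0], data[:, 1]
    if t.size < 2:
        raise FormatError(f"need at least 2 samples to infer a rate in {path}")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise FormatError(f"time column not strictly increasing in {path}")
    dt0 = (t[-1] - t[0]) / (t.size - 1)
    if np.max(np.abs(dt - dt0)) > 1e-6 * dt0:
        raise FormatError(f"non-uniform sampling (>1 ppm deviation) in {path}")
    rate = 1.0 / dt0
    if abs(rate - round(rate)) < 1e-6 * rate:  # absorb float noise on integer rates
        rate = float(round(rate))
    return Recording(samples=v, rate_hz=rate, start_s=float(t[0]))


def _write_delimited(rec: Recording, path: str) -> None:
    t = rec.start_s + np.arange(rec.samples.size) / rec.rate_hz
    with open(path, "w", newline="\n") as fh:
        fh.write(_DELIM_HEADER + "\n")
        for ti, vi in zip(t, rec.samples):
            fh.write(f"{float(ti)!r},{float(vi)!r}\n")


# ---------------------------------------------------------------------------
# EDF (single signal, 16-bit, 1-s data records)
# ---------------------------------------------------------------------------

_DIG_MIN, _DIG_MAX = -32768, 32767


def _edf_field(value: str, width: int) -> bytes:
    b = value.encode("ascii")
    if len(b) > width:
        b = b[:width]
    return b.ljust(width)


def _edf_num(value: float, width: int) -> bytes:
    """Format a number into a fixed-width ASCII EDF field."""
    for prec in range(width, -1, -1):
        s = f"{value:.{prec}g}"
        if len(s) <= width and "e" not in s and "E" not in s:
            return _edf_field(s, width)
    raise FormatError(f"cannot format {value} into {width} EDF chars")


def _write_edf(rec: Recording, path: str) -> None:
    rate = rec.rate_hz
    if abs(rate - round(rate)) > 1e-9:
        raise FormatError("EDF export requires an integer sampling rate; use the delimited format")
    rate = int(round(rate))
    n = rec.samples.size
    if n % rate != 0:
        raise FormatError(
            "EDF export requires a whole number of seconds; use the delimited format"
        )
    if not np.all(np.isfinite(rec.samples)):
        raise FormatError("EDF export requires finite samples")
    n_records = n // rate

    pmin = float(np.min(rec.samples))
    pmax = float(np.max(rec.samples))
    if pmin == pmax:  # EDF requires a non-degenerate physical range
        half = max(1.0, abs(pmin))
        pmin, pmax = pmin - half, pmin + half
    # Round-trip consistency: quantize against the *written* (8-char) values.
    pmin = float(_edf_num(pmin, 8).decode())
    pmax = float(_edf_num(pmax, 8).decode())
    if pmax <= pmin:
        pmax = pmin + 1.0

    phase_kind = rec.phase.phase_kind if rec.phase is not None else ""
    rec_id = f"{rec.group}/{phase_kind}/{rec.animal_id}"

    header = b"".join([
        _edf_field("0", 8),
        _edf_field(rec.animal_id or "X", 80),
        _edf_field(rec_id, 80),
        _edf_field("01.01.00", 8),
        _edf_field("00.00.00", 8),
        _edf_field(str(256 + 256), 8),
        _edf_field("", 44),
        _edf_field(str(n_records), 8),
        _edf_field("1", 8),
        _edf_field("1", 4),
        # per-signal header fields
        _edf_field("ECoG", 16),
        _edf_field("", 80),
        _edf_field("uV", 8),
        _edf_num(pmin, 8),
        _edf_num(pmax, 8),
        _edf_field(str(_DIG_MIN), 8),
        _edf_field(str(_DIG_MAX), 8),
        _edf_field("", 80),
        _edf_field(str(rate), 8),
        _edf_field("", 32),
    ])
    assert len(header) == 512

    scale = (pmax - pmin) / (_DIG_MAX - _DIG_MIN)
    digital = np.round((rec.samples - pmin) / scale + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(digital.tobytes())


def _read_edf(path: str) -> Recording:
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise FormatError(f"truncated EDF header in {path}")
        try:
            n_records = int(head[236:244].decode().strip())
            record_s = float(head[244:252].decode().strip())
            n_signals = int(head[252:256].decode().strip())
            rec_id = head[88:168].decode().strip()
            animal = head[8:88].decode().strip()
        except (UnicodeDecodeError, ValueError) as exc:
            raise FormatError(f"malformed EDF header in {path}: {exc}") from exc
        if n_signals != 1:
            raise FormatError(f"expected a single-signal EDF, found {n_signals} signals")
        sig = fh.read(256)
        if len(sig) < 256:
            raise FormatError(f"truncated EDF signal header in {path}")
        try:
            pmin = float(sig[96 + 8:96 + 16].decode().strip())
            pmax = float(sig[96 + 16:96 + 24].decode().strip())
            dmin = int(sig[96 + 24:96 + 32].decode().strip())
            dmax = int(sig[96 + 32:96 + 40].decode().strip())
            spr = int(sig[96 + 120:96 + 128].decode().strip())
        except (UnicodeDecodeError, ValueError) as exc:
            raise FormatError(f"malformed EDF signal header in {path}: {exc}") from exc
        raw = np.frombuffer(fh.read(2 * spr * n_records), dtype="<i2")
    if raw.size != spr * n_records:
        raise FormatError(f"truncated EDF data in {path}")
    samples = pmin + (raw.astype(np.float64) - dmin) * (pmax - pmin) / (dmax - dmin)

    group, phase, animal_id = "", None, animal
    parts = rec_id.split("/")
    if len(parts) == 3:
        group = parts[0]
        if parts[1] in PHASE_DURATIONS_S:
            phase = PhaseLabel.of(parts[1])
        animal_id = parts[2] or animal
    rate = spr / record_s
    return Recording(samples=samples, rate_hz=rate, animal_id=animal_id,
                     group=group, phase=phase)


def edf_quantization_bound(rec: Recording) -> float:
    """Worst-case absolute round-trip error of the 16-bit EDF encoding:
    half a digital step of the physical range actually written."""
    pmin, pmax = float(np.min(rec.samples)), float(np.max(rec.samples))
    if pmin == pmax:
        half = max(1.0, abs(pmin))
        pmin, pmax = pmin - half, pmin + half
    pmin = float(_edf_num(pmin, 8).decode())
    pmax = float(_edf_num(pmax, 8).decode())
    return 0.5 * (pmax - pmin) / (_DIG_MAX - _DIG_MIN) + math.ulp(pmax)
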