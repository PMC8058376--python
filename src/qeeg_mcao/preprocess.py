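"""Signal conditioning ahead of spectral analysis.

The acquisition chain the package emulates applies an analog 0.3 Hz
high-pass; :func:`highpass_filter` replicates it digitally with a
zero-phase Butterworth filter.  Sessions are then cut into fixed-length
epochs and epochs containing large-amplitude excursions are flagged for
exclusion.  Artifact rejection never alters sample values — only the
keep mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .errors import DegenerateDataError, ParameterError
from .io_signals import Recording

DEFAULT_HIGHPASS_HZ = 0.3
DEFAULT_EPOCH_S = 30.0
DEFAULT_ARTIFACT_UV = 500.0


@dataclass
class EpochSet:
    """Equal-length analysis windows cut from one recording.

    ``epochs`` is an (n_epochs, n_samples) array; ``keep_mask`` marks the
    epochs admitted to spectral analysis.  ``rate_hz`` and the source
    metadata are carried so downstream tables stay self-describing.
    """

    epochs: np.ndarray
    epoch_s: float
    keep_mask: np.ndarray
    rate_hz: float
    animal_id: str = ""
    group: str = ""
    phase_kind: str = ""

    def __post_init__(self) -> None:
        self.epochs = np.atleast_2d(np.asarray(self.epochs, dtype=np.float64))
        self.keep_mask = np.asarray(self.keep_mask, dtype=bool)
        if self.keep_mask.shape != (self.epochs.shape[0],):
            raise ParameterError("keep_mask length must equal the epoch count")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def kept(self) -> np.ndarray:
        """The accepted epochs, stacked."""
        return self.epochs[self.keep_mask]


def highpass_filter(rec: Recording, cutoff_hz: float = DEFAULT_HIGHPASS_HZ) -> Recording:
    """Zero-phase 4th-order Butterworth high-pass.

    Forward-backward application (``sosfiltfilt``) keeps band phases
    untouched; edges are padded reflectively over three filter time
    constants so the DC step at the boundaries does not ring into the
    analysis span.  Output length equals input length.
    """
    nyq = rec.rate_hz / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ParameterError(
            f"cutoff_hz must lie in (0, Nyquist={nyq:g}), got {cutoff_hz}")
    sos = signal.butter(4, cutoff_hz, btype="highpass", fs=rec.rate_hz, output="sos")
    # three time constants of the cutoff, capped by the data length
    padlen = min(int(3 * rec.rate_hz / (2 * math.pi * cutoff_hz)), rec.samples.size - 1)
    filtered = signal.sosfiltfilt(sos, rec.samples, padtype="even", padlen=padlen)
    return rec.with_samples(filtered)


def epoch(rec: Recording, epoch_s: float = DEFAULT_EPOCH_S) -> EpochSet:
    """Cut *rec* into non-overlapping ``epoch_s`` windows.

    A trailing partial window is dropped.  Raises if the recording is
    shorter than a single epoch.
    """
    if epoch_s <= 0:
        raise ParameterError(f"epoch_s must be > 0, got {epoch_s}")
    n_per = int(round(epoch_s * rec.rate_hz))
    if rec.samples.size < n_per:
        raise ParameterError(
            f"recording ({rec.duration_s:g} s) is shorter than one epoch ({epoch_s:g} s)")
    n_epochs = rec.samples.size // n_per
    windows = rec.samples[: n_epochs * n_per].reshape(n_epochs, n_per)
    return EpochSet(
        epochs=windows,
        epoch_s=epoch_s,
        keep_mask=np.ones(n_epochs, dtype=bool),
        rate_hz=rec.rate_hz,
        animal_id=rec.animal_id,
        group=rec.group,
        phase_kind=rec.phase.phase_kind if rec.phase is not None else "",
    )


def reject_artifacts(es: EpochSet, amp_threshold_uv: float = DEFAULT_ARTIFACT_UV) -> EpochSet:
    """Flag epochs containing any sample with \\|v\\| above the threshold.

    Returns a new :class:`EpochSet`; sample values are never modified.
    Raises :class:`DegenerateDataError` if nothing survives.
    """
    if amp_threshold_uv <= 0:
        raise ParameterError(f"amp_threshold_uv must be > 0, got {amp_threshold_uv}")
    clean = np.all(np.abs(es.epochs) <= amp_threshold_uv, axis=1)
    mask = es.keep_mask & clean
    if not mask.any():
        raise DegenerateDataError(
            f"all {es.n_epochs} epochs exceed {amp_threshold_uv:g} µV — nothing to analyze")
    return replace(es, epochs=es.epochs, keep_mask=mask)
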