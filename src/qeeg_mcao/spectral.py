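"""Power spectral density and band-power decomposition.

The analysis ceiling is 40 Hz and four canonical rodent-ECoG bands are
quantified below it: delta [1, 4), theta [4, 8), alpha [8, 12) and beta
[12, 28) Hz.  Relative band power is normalized by the total power in
the reference band [1, 40); the 28–40 Hz remainder is tracked as the
``residual`` band so the five relative fractions sum to one exactly.

PSD estimation is Welch's method with a Hann window.  The default
segment length is 16 s (0.0625 Hz resolution): the spectra analyzed
here have a steep density step at the 4 Hz delta/theta edge, and coarse
bins smear enough delta power across that edge to bias the delta/alpha
ratio well outside its sampling error.  Fine resolution costs some
per-bin variance, which band integration averages back out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .errors import DegenerateDataError, ParameterError
from .preprocess import EpochSet

DEFAULT_SEG_S = 16.0
DEFAULT_OVERLAP_FRAC = 0.5
MAX_RESOLUTION_HZ = 0.5  # must resolve the 1 Hz delta edge
ANALYSIS_CEILING_HZ = 40.0


@dataclass(frozen=True)
class Band:
    """Half-open frequency band [lo_hz, hi_hz)."""

    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self) -> None:
        if not self.lo_hz < self.hi_hz:
            raise ParameterError(f"band {self.name}: need lo_hz < hi_hz")


#: The four analysis bands, the 28-40 Hz residual, and the reference band.
CANONICAL_BANDS: dict[str, Band] = {
    "delta": Band("delta", 1.0, 4.0),
    "theta": Band("theta", 4.0, 8.0),
    "alpha": Band("alpha", 8.0, 12.0),
    "beta": Band("beta", 12.0, 28.0),
    "residual": Band("residual", 28.0, 40.0),
    "reference": Band("reference", 1.0, ANALYSIS_CEILING_HZ),
}

#: Bands whose relative powers partition the reference band.
COMPONENT_BANDS = ("delta", "theta", "alpha", "beta", "residual")


@dataclass
class PowerSpectrum:
    """One-sided PSD (µV²/Hz) on a uniform frequency grid."""

    freqs_hz: np.ndarray
    psd: np.ndarray
    resolution_hz: float
    n_segments: int

    @property
    def nyquist_hz(self) -> float:
        return float(self.freqs_hz[-1])


@dataclass
class BandPowerSet:
    """Absolute (µV²) and relative (fraction of reference) power per band."""

    absolute: dict[str, float]
    relative: dict[str, float]
    reference_power: float


def compute_psd(es: EpochSet, seg_s: float = DEFAULT_SEG_S,
                overlap_frac: float = DEFAULT_OVERLAP_FRAC) -> PowerSpectrum:
    """Welch PSD averaged over all kept epochs.

    Hann-windowed segments of ``seg_s`` seconds with fractional overlap
    ``overlap_frac``; the one-sided density integrates to the signal
    variance (Parseval, within windowing tolerance).
    """
    kept = es.kept
    if kept.shape[0] == 0:
        raise DegenerateDataError("no kept epochs to analyze")
    if seg_s > es.epoch_s:
        raise ParameterError(f"seg_s ({seg_s:g}) exceeds epoch length ({es.epoch_s:g})")
    if not 0 <= overlap_frac < 1:
        raise ParameterError(f"overlap_frac must be in [0, 1), got {overlap_frac}")
    if 1.0 / seg_s > MAX_RESOLUTION_HZ:
        raise ParameterError(
            f"seg_s = {seg_s:g} s gives {1.0 / seg_s:g} Hz resolution; "
            f"need <= {MAX_RESOLUTION_HZ} Hz to resolve the 1 Hz band edge")
    nperseg = int(round(seg_s * es.rate_hz))
    noverlap = int(round(overlap_frac * nperseg))
    freqs, psds = signal.welch(
        kept, fs=es.rate_hz, window="hann", nperseg=nperseg,
        noverlap=noverlap, detrend="constant", axis=-1)
    psd = psds.mean(axis=0) if psds.ndim == 2 else psds
    step = nperseg - noverlap
    segs_per_epoch = 1 + (kept.shape[1] - nperseg) // step
    return PowerSpectrum(
        freqs_hz=freqs,
        psd=psd,
        resolution_hz=float(freqs[1] - freqs[0]),
        n_segments=int(segs_per_epoch * kept.shape[0]),
    )


def band_power(ps: PowerSpectrum, band: Band) -> float:
    """Absolute power in *band*: sum of PSD bins with lo <= f < hi,
    times the grid resolution (rectangle rule on half-open bins)."""
    if band.lo_hz < ps.freqs_hz[0] or band.hi_hz > ps.nyquist_hz + ps.resolution_hz:
        raise ParameterError(
            f"band {band.name} [{band.lo_hz}, {band.hi_hz}) Hz lies outside the "
            f"spectrum grid [{ps.freqs_hz[0]}, {ps.nyquist_hz}] Hz")
    mask = (ps.freqs_hz >= band.lo_hz) & (ps.freqs_hz < band.hi_hz)
    return float(ps.psd[mask].sum() * ps.resolution_hz)


def relative_bandpower(ps: PowerSpectrum) -> BandPowerSet:
    """Absolute and relative power in the five component bands.

    Relative power is each band's share of the reference-band [1, 40) Hz
    total; shares sum to one by construction.
    """
    ref = band_power(ps, CANONICAL_BANDS["reference"])
    if ref <= 0:
        raise DegenerateDataError("zero power in the 1-40 Hz reference band")
    absolute = {name: band_power(ps, CANONICAL_BANDS[name]) for name in COMPONENT_BANDS}
    relative = {name: p / ref for name, p in absolute.items()}
    return BandPowerSet(absolute=absolute, relative=relative, reference_power=ref)


def frequency_distribution(ps: PowerSpectrum, max_hz: float = ANALYSIS_CEILING_HZ) -> pd.DataFrame:
    """PSD restricted to [0, max_hz) as a two-column table
    (``freq_hz``, ``psd_uv2_per_hz``) for reporting and plotting."""
    if max_hz > ps.nyquist_hz:
        raise ParameterError(f"max_hz ({max_hz:g}) exceeds Nyquist ({ps.nyquist_hz:g})")
    mask = ps.freqs_hz < max_hz
    return pd.DataFrame({"freq_hz": ps.freqs_hz[mask], "psd_uv2_per_hz": ps.psd[mask]})
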