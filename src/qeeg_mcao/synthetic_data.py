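"""Synthetic phase-labeled ECoG cohorts.

No public recordings exist for the ischemia–reperfusion study this
package emulates, so cohorts are generated from spectral profiles that
the analysis pipeline must then invert.  A profile fixes the relative
power fraction of each canonical band plus a total power; a recording is
synthesized as a sum of independent band-limited Gaussian noises.

Band limiting is done in the frequency domain: white Gaussian noise is
transformed, coefficients outside the band's half-open interval are
zeroed, and the result is transformed back and rescaled to unit
empirical variance.  This makes each component's power lie *exactly*
inside its band, so the generated band-power signature equals the
profile up to estimator error.  (IIR band-pass filtering was evaluated
for this role and rejected: its roll-off leaks several percent of each
band's power into neighbours, which biases the delta/alpha ratio of
ischemic profiles by more than 10% — larger than the effects under
study.)

The acute-phase profiles are calibrated exactly, by inverting the
published index triples (anesthetized, ischemic stroke phase, immediate
reperfusion) into band fractions.  The awake-baseline and subacute
day-1…7 profiles are qualitative: they encode the reported direction of
change (all band fractions below the awake control, theta elevated on
days 3-4, alpha elevated on days 4, 6 and 7, DTABR peaking on day 3,
globally suppressed total power) without claiming numeric fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .io_signals import GROUPS, PHASE_KINDS, PhaseLabel, Recording
from .spectral import CANONICAL_BANDS, COMPONENT_BANDS

PRESET_VERSION = "1.0"

#: Published acute-phase index means (DTR, DAR, DTABR) used to calibrate
#: the acute presets by inversion.
ACUTE_INDEX_MEANS = {
    "anesthetized": (1.62, 6.45, 4.95),
    "isp": (4.20, 13.07, 8.68),
    "irp": (0.74, 3.08, 2.80),
}

ACUTE_RESIDUAL_FRACTION = 0.05
DEFAULT_JITTER_SIGMA = 0.10
DEFAULT_RATE_HZ = 1000.0


@dataclass
class SpectralProfile:
    """Generator ground truth: band fractions, total power and jitter."""

    fractions: dict[str, float]
    total_power_uv2: float
    jitter_sigma: float
    phase: PhaseLabel

    def __post_init__(self) -> None:
        missing = set(COMPONENT_BANDS) - set(self.fractions)
        if missing:
            raise ParameterError(f"profile missing band fractions: {sorted(missing)}")
        vals = np.array([self.fractions[b] for b in COMPONENT_BANDS])
        if np.any(vals < 0) or abs(vals.sum() - 1.0) > 1e-12:
            raise ParameterError("fractions must be >= 0 and sum to 1 within 1e-12")
        if self.total_power_uv2 <= 0:
            raise ParameterError("total_power_uv2 must be > 0")
        if self.jitter_sigma < 0:
            raise ParameterError("jitter_sigma must be >= 0")


@dataclass
class StudyDesign:
    """Cohort layout: groups x animals x phases, plus the master seed."""

    groups: tuple[str, ...] = GROUPS
    n_per_group: int = 6
    phases: tuple[PhaseLabel, ...] = field(
        default_factory=lambda: tuple(PhaseLabel.of(k) for k in PHASE_KINDS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ParameterError("n_per_group must be >= 2")
        if not self.phases:
            raise ParameterError("phases must be non-empty")

    @property
    def n_recordings(self) -> int:
        return len(self.groups) * self.n_per_group * len(self.phases)


def invert_indices_to_fractions(dtr: float, dar: float, dtabr: float,
                                residual: float = ACUTE_RESIDUAL_FRACTION) -> dict[str, float]:
    """Band fractions whose forward indices reproduce (dtr, dar, dtabr).

    With alpha as the unit, delta = dar, theta = dar/dtr and
    beta = (delta+theta)/dtabr - alpha; the four are then scaled to sum
    to ``1 - residual``.  The round trip through the index definitions is
    an exact algebraic identity.  Raises when the triple is infeasible
    (implied beta <= 0).
    """
    if min(dtr, dar, dtabr) <= 0:
        raise ParameterError("indices must be > 0")
    if not 0 <= residual < 1:
        raise ParameterError(f"residual fraction must be in [0, 1), got {residual}")
    a = 1.0
    d = dar
    t = dar / dtr
    b = (d + t) / dtabr - a
    if b <= 0:
        raise ParameterError(
            f"infeasible index triple (DTR={dtr}, DAR={dar}, DTABR={dtabr}): "
            f"implied beta fraction {b:g} <= 0")
    total = d + t + a + b
    scale = (1.0 - residual) / total
    return {"delta": d * scale, "theta": t * scale, "alpha": a * scale,
            "beta": b * scale, "residual": residual}


#: Qualitative band fractions (delta, theta, alpha, beta, residual) and total
#: power (µV²) for the phases the source study reports only graphically.
#: Subacute days keep every component fraction below the awake control's and
#: push the remainder into the residual band (globally suppressed activity);
#: theta is elevated on d3-d4, alpha on d4/d6/d7, and DTABR peaks on d3.
_QUALITATIVE_PRESETS = {
    "baseline_awake": ((0.36, 0.30, 0.15, 0.11, 0.08), 3000.0),
    "d1": ((0.300, 0.220, 0.100, 0.080, 0.300), 900.0),
    "d2": ((0.310, 0.230, 0.105, 0.085, 0.270), 1000.0),
    "d3": ((0.345, 0.270, 0.105, 0.080, 0.200), 1100.0),
    "d4": ((0.330, 0.265, 0.125, 0.080, 0.200), 1200.0),
    "d5": ((0.320, 0.240, 0.110, 0.085, 0.245), 1300.0),
    "d6": ((0.315, 0.230, 0.120, 0.085, 0.250), 1400.0),
    "d7": ((0.310, 0.225, 0.120, 0.090, 0.255), 1500.0),
}

#: Total power for the calibrated acute presets (µV²).  The source study
#: reports no absolute-power units; these set realistic rodent-ECoG scale
#: and the reperfusion doubling of total power, and cancel out of every
#: relative-power quantity and index.
_ACUTE_TOTAL_POWER = {"anesthetized": 2000.0, "isp": 2500.0, "irp": 4000.0}


def phase_presets(jitter_sigma: float = DEFAULT_JITTER_SIGMA) -> dict[str, SpectralProfile]:
    """Per-phase spectral profiles (preset table version %s).

    Acute phases are inverted exactly from the published index means with
    a fixed 0.05 residual fraction; baseline and subacute phases are the
    qualitative table above.
    """ % PRESET_VERSION
    presets: dict[str, SpectralProfile] = {}
    for kind, (dtr, dar, dtabr) in ACUTE_INDEX_MEANS.items():
        presets[kind] = SpectralProfile(
            fractions=invert_indices_to_fractions(dtr, dar, dtabr),
            total_power_uv2=_ACUTE_TOTAL_POWER[kind],
            jitter_sigma=jitter_sigma,
            phase=PhaseLabel.of(kind),
        )
    for kind, (fracs, power) in _QUALITATIVE_PRESETS.items():
        presets[kind] = SpectralProfile(
            fractions=dict(zip(COMPONENT_BANDS, fracs)),
            total_power_uv2=power,
            jitter_sigma=jitter_sigma,
            phase=PhaseLabel.of(kind),
        )
    return presets


def export_presets_csv(path: str, jitter_sigma: float = DEFAULT_JITTER_SIGMA) -> str:
    """Write the preset table as CSV (phase,delta,...,total_power,jitter)."""
    presets = phase_presets(jitter_sigma)
    with open(path, "w", newline="\n") as fh:
        fh.write("phase,delta,theta,alpha,beta,residual,total_power,jitter\n")
        for kind in PHASE_KINDS:
            p = presets[kind]
            fracs = ",".join(f"{p.fractions[b]:.12g}" for b in COMPONENT_BANDS)
            fh.write(f"{kind},{fracs},{p.total_power_uv2:.12g},{p.jitter_sigma:.12g}\n")
    return path


def _as_rng(seed: int | np.random.SeedSequence | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def jitter_fractions(fractions: dict[str, float], sigma: float,
                     rng: np.random.Generator) -> dict[str, float]:
    """Multiply each band fraction by LogNormal(0, sigma), renormalize."""
    if sigma == 0:
        return dict(fractions)
    vals = np.array([fractions[b] for b in COMPONENT_BANDS])
    vals = vals * rng.lognormal(mean=0.0, sigma=sigma, size=vals.size)
    vals /= vals.sum()
    return dict(zip(COMPONENT_BANDS, vals))


def generate_recording(profile: SpectralProfile, duration_s: float | None = None,
                       rate_hz: float = DEFAULT_RATE_HZ,
                       seed: int | np.random.SeedSequence | np.random.Generator = 0,
                       animal_id: str = "", group: str = "") -> Recording:
    """Synthesize one recording realizing *profile*.

    The trace is ``sqrt(total_power) * sum_b sqrt(fraction_b) * u_b`` with
    each ``u_b`` an independent Gaussian noise whose spectrum is confined
    exactly to band *b* and whose empirical variance is one.  Duration
    defaults to the profile's phase duration.  Deterministic given seed.
    """
    if duration_s is None:
        duration_s = profile.phase.duration_s
    if duration_s < 10:
        raise ParameterError("duration_s must be >= 10 s")
    if rate_hz < 2 * CANONICAL_BANDS["residual"].hi_hz:
        raise ParameterError(
            f"rate_hz must be >= {2 * CANONICAL_BANDS['residual'].hi_hz:g} Hz "
            "to carry the 40 Hz analysis ceiling")
    rng = _as_rng(seed)
    n = int(round(duration_s * rate_hz))
    freqs = np.fft.rfftfreq(n, 1.0 / rate_hz)
    x = np.zeros(n)
    for name in COMPONENT_BANDS:
        frac = profile.fractions[name]
        band = CANONICAL_BANDS[name]
        w = rng.standard_normal(n)  # drawn unconditionally: keeps the stream layout fixed
        if frac == 0:
            continue
        spec = np.fft.rfft(w)
        spec[(freqs < band.lo_hz) | (freqs >= band.hi_hz)] = 0.0
        u = np.fft.irfft(spec, n)
        sd = u.std()
        if sd == 0:
            raise ParameterError(f"band {name} carries no grid frequencies at n={n}")
        x += np.sqrt(frac) * (u / sd)
    x *= np.sqrt(profile.total_power_uv2)
    return Recording(samples=x, rate_hz=rate_hz, animal_id=animal_id,
                     group=group, phase=profile.phase)


def generate_cohort(design: StudyDesign,
                    presets: dict[str, SpectralProfile] | None = None,
                    rate_hz: float = DEFAULT_RATE_HZ) -> list[Recording]:
    """One recording per animal per phase.

    Sham animals realize the anesthetized (control) profile in every
    phase; occluded animals realize each phase's own profile.  Every
    recording gets an independent sub-stream spawned from ``design.seed``
    keyed by (group index, animal index, phase index), so cohorts are
    reproducible and order-independent.  Per-animal-session band
    fractions are log-normally jittered then renormalized.
    """
    if presets is None:
        presets = phase_presets()
    recordings: list[Recording] = []
    for gi, group in enumerate(design.groups):
        for ai in range(design.n_per_group):
            animal = f"{group}{ai + 1:02d}"
            for pi, phase in enumerate(design.phases):
                kind = "anesthetized" if group == "sham" else phase.phase_kind
                if kind not in presets:
                    raise ParameterError(f"no preset for phase {kind!r}")
                base = presets[kind]
                rng = np.random.default_rng(
                    np.random.SeedSequence(design.seed, spawn_key=(gi, ai, pi)))
                profile = SpectralProfile(
                    fractions=jitter_fractions(base.fractions, base.jitter_sigma, rng),
                    total_power_uv2=base.total_power_uv2,
                    jitter_sigma=base.jitter_sigma,
                    phase=phase,
                )
                recordings.append(generate_recording(
                    profile, duration_s=phase.duration_s, rate_hz=rate_hz,
                    seed=rng, animal_id=animal, group=group))
    return recordings
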