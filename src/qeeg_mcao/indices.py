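"""qEEG stroke indices: DTR, DAR and DTABR, with ischemia classification.

DTR = delta/theta, DAR = delta/alpha, DTABR = (delta+theta)/(alpha+beta),
all computed from band powers.  Because each index is a ratio of powers
sharing the same reference denominator, relative and absolute powers give
identical values and the indices are invariant to overall signal gain.

Published discrimination thresholds for acute ischemic injury are 3.7
for the DAR (1:1 sensitivity:specificity) and 3.5 for the DTABR (100%
sensitivity above it); classification here is strict exceedance, so a
value exactly at the threshold is not flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .errors import DegenerateDataError, ParameterError
from .spectral import BandPowerSet

DAR_THRESHOLD = 3.7
DTABR_THRESHOLD = 3.5


@dataclass
class QeegIndices:
    dtr: float
    dar: float
    dtabr: float
    dar_ischemic: bool | None = None
    dtabr_ischemic: bool | None = None


def compute_indices(bp: BandPowerSet) -> QeegIndices:
    """DTR, DAR and DTABR from a band-power decomposition.

    Raises :class:`DegenerateDataError` naming the offending band when a
    denominator is zero.
    """
    rel = bp.relative
    for name in ("theta", "alpha"):
        if rel[name] <= 0:
            raise DegenerateDataError(f"zero {name}-band power: index denominators undefined")
    if rel["alpha"] + rel["beta"] <= 0:
        raise DegenerateDataError("zero alpha+beta power: DTABR denominator undefined")
    return QeegIndices(
        dtr=rel["delta"] / rel["theta"],
        dar=rel["delta"] / rel["alpha"],
        dtabr=(rel["delta"] + rel["theta"]) / (rel["alpha"] + rel["beta"]),
    )


def classify_ischemia(qi: QeegIndices, dar_threshold: float = DAR_THRESHOLD,
                      dtabr_threshold: float = DTABR_THRESHOLD) -> QeegIndices:
    """Set the ischemia flags by strict threshold exceedance."""
    if dar_threshold <= 0 or dtabr_threshold <= 0:
        raise ParameterError("thresholds must be > 0")
    return replace(qi,
                   dar_ischemic=qi.dar > dar_threshold,
                   dtabr_ischemic=qi.dtabr > dtabr_threshold)
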