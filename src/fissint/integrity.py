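"""Fissure integrity: the area fraction of the complete lobar boundary
actually depicted as fissure.

Integrity is reported as a percentage, per fissure (ROF, RHF, LOF) and
aggregated over the entire lung (ELF) as an area-weighted ratio
(sum of depicted areas over sum of complete areas, so the smaller
horizontal fissure contributes proportionally less).  Percentages are
assigned to six conventional levels; only the top level (90, 100] is
regarded as a "complete" fissure, allowing for the error of CT in
depicting thin fissures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

logger = logging.getLogger(__name__)

#: six integrity levels; lower edge closed only for the first
BIN_EDGES = (0.0, 20.0, 40.0, 60.0, 80.0, 90.0, 100.0)
BIN_LABELS = (
    "[0, 20%]",
    "(20%, 40%]",
    "(40%, 60%]",
    "(60%, 80%]",
    "(80%, 90%]",
    "(90%, 100%]",
)

COMPLETE_BIN = BIN_LABELS[-1]


class QuantificationError(ValueError):
    """Raised for invalid area inputs."""


@dataclass
class IntegrityResult:
    """Integrity of one fissure (or the entire lung aggregate)."""

    label: str  # ROF, RHF, LOF or ELF
    area_detected_mm2: float
    area_complete_mm2: float
    integrity_pct: float
    bin: str
    complete_flag: bool

    @classmethod
    def from_areas(cls, label: str, detected: float, complete: float):
        pct = compute_integrity(detected, complete)
        return cls(
            label=label,
            area_detected_mm2=float(detected),
            area_complete_mm2=float(complete),
            integrity_pct=pct,
            bin=bin_integrity(pct),
            complete_flag=pct > 90.0,
        )


def compute_integrity(area_detected: float, area_complete: float) -> float:
    """100 x detected area / complete area, clamped to [0, 100].

    The raw ratio can exceed 1 when the area estimators disagree
    slightly; the clamp keeps the statistic a percentage while the raw
    value is preserved in the debug log.
    """
    if area_complete <= 0:
        raise QuantificationError("complete-boundary area must be positive")
    if area_detected < 0:
        raise QuantificationError("detected area cannot be negative")
    raw = 100.0 * area_detected / area_complete
    if raw > 100.0:
        logger.debug("raw integrity %.2f%% clamped to 100%%", raw)
    return float(min(max(raw, 0.0), 100.0))


def entire_lung_integrity(results, allow_missing: bool = False) -> float:
    """Area-weighted integrity over all fissures of both lungs.

    ``results`` maps labels (or is an iterable of
    :class:`IntegrityResult`) covering ROF, RHF and LOF; all three must
    be present unless ``allow_missing`` is set.
    """
    if hasattr(results, "values"):
        results = list(results.values())
    labels = {r.label for r in results}
    expected = {"ROF", "RHF", "LOF"}
    if not allow_missing and labels != expected:
        raise QuantificationError(
            f"entire-lung integrity needs all of {sorted(expected)}, got {sorted(labels)}"
        )
    detected = sum(r.area_detected_mm2 for r in results)
    complete = sum(r.area_complete_mm2 for r in results)
    return compute_integrity(detected, complete)


def bin_integrity(integrity_pct: float) -> str:
    """Assign an integrity percentage to one of the six levels.

    Levels are left-open/right-closed except the first, which includes
    0: exactly 20 falls in [0, 20%], exactly 90 in (80%, 90%], and
    anything strictly above 90 is "complete".
    """
    if not 0.0 <= integrity_pct <= 100.0:
        raise QuantificationError(f"integrity {integrity_pct} outside [0, 100]")
    for lo, hi, lab in zip(BIN_EDGES[:-1], BIN_EDGES[1:], BIN_LABELS):
        if integrity_pct <= hi:
            return lab
    return BIN_LABELS[-1]  # pragma: no cover (100 handled above)
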