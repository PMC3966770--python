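"""PSM rejection rules and the auditable rejection log.

Three rules, applied in a fixed order so logs are deterministic:

1. ``low_confidence`` — identification q-value at or above ``max_q``
   (retain iff q < max_q; the 5%-FDR boundary itself is rejected);
2. ``poor_localization`` — phosphopeptide whose localization probability is
   at or below ``min_phosphors`` (retain iff pRS > min_phosphors; the 75%
   boundary is rejected; the rule never applies to non-phospho PSMs);
3. ``missing_channel`` — any of the plex's eight reporter channels absent or
   with intensity exactly 0 (a reporter peak that is not visible has no
   area), unless ``require_complete_channels`` is off.

Filtering never raises on data values: every input PSM ends up either
retained or in the rejection log with the first failing reason.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .design import DesignTable
from .psm import PSMRecord

REASONS = ("low_confidence", "poor_localization", "missing_channel")


@dataclass(frozen=True)
class FilterThresholds:
    """Rejection thresholds; defaults follow the 5% FDR / 75% pRS convention."""

    max_q: float = 0.05
    min_phosphors: float = 0.75
    require_complete_channels: bool = True

    def __post_init__(self):
        if not 0.0 <= self.max_q <= 1.0:
            raise ValueError("max_q must be in [0, 1]")
        if not 0.0 <= self.min_phosphors <= 1.0:
            raise ValueError("min_phosphors must be in [0, 1]")


def rejection_reason(
    record: PSMRecord, thresholds: FilterThresholds, design: DesignTable
) -> str | None:
    """First failing rule for *record*, or None when it passes all filters."""
    if record.q_value >= thresholds.max_q:
        return "low_confidence"
    if record.is_phospho:
        prs = record.phosphors_probability
        if prs is None or prs <= thresholds.min_phosphors:
            return "poor_localization"
    if thresholds.require_complete_channels:
        for ch in design.channels(record.plex):
            v = record.intensities.get(ch)
            if v is None or v <= 0.0:
                return "missing_channel"
    return None


def filter_psms(
    records: list[PSMRecord],
    thresholds: FilterThresholds = FilterThresholds(),
    design: DesignTable | None = None,
) -> tuple[list[PSMRecord], pd.DataFrame]:
    """Partition *records* into (retained, rejection log).

    The log has one row per rejected PSM: ``psm_id``, ``reason``.
    Retained and rejected sets partition the input exactly.
    """
    if design is None:
        raise ValueError("filter_psms requires the design to resolve channels")
    retained: list[PSMRecord] = []
    log_rows: list[tuple[str, str]] = []
    for rec in records:
        reason = rejection_reason(rec, thresholds, design)
        if reason is None:
            retained.append(rec)
        else:
            log_rows.append((rec.psm_id, reason))
    log = pd.DataFrame(log_rows, columns=["psm_id", "reason"])
    return retained, log
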