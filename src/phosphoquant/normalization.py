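"""Sum-scaling normalization of reporter intensities and MA diagnostics.

Sum-scaling equalizes the total reporter intensity of every channel within a
normalization group, removing per-channel loading/labelling bias: for group
channel sums S(c), each intensity in channel c is multiplied by
``factor(c) = target_sum / S(c)`` with ``target_sum`` the mean of the eight
channel sums (any common constant cancels in ratios; the mean keeps data on
the original intensity scale for MA plots).  If the raw data equal clean
intensities times a per-channel constant, the scaled data are algebraically
independent of that constant.

The default group is one (plex, arm) pooled over fractions and runs:
fractions are disjoint peptide populations of one labelled mixture, so the
bias is channel-wise per mixture.  Per-plex and per-fraction groupings are
available behind the ``grouping`` argument.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .design import DesignTable
from .psm import PSMRecord
from .errors import DegenerateGroupError

GROUPINGS = ("plex_arm", "plex", "plex_arm_fraction")


@dataclass
class ScaleFactors:
    """Per-group channel multipliers; ``frame`` columns:
    plex, arm, fraction, channel, channel_sum, target_sum, factor."""

    frame: pd.DataFrame
    grouping: str = "plex_arm"

    def factor(self, plex: str, channel: str, arm: str = "", fraction: str = "") -> float:
        f = self.frame
        sel = (f["plex"] == plex) & (f["channel"] == channel)
        if arm:
            sel &= f["arm"] == arm
        if fraction:
            sel &= f["fraction"] == fraction
        sub = f[sel]
        if len(sub) != 1:
            raise KeyError(f"no unique factor for {(plex, arm, fraction, channel)}")
        return float(sub["factor"].iloc[0])


def _group_key(record: PSMRecord, grouping: str) -> tuple:
    if grouping == "plex_arm":
        return (record.plex, record.arm, "")
    if grouping == "plex":
        return (record.plex, "", "")
    if grouping == "plex_arm_fraction":
        return (record.plex, record.arm, str(record.fraction))
    raise ValueError(f"unknown grouping {grouping!r}; choose from {GROUPINGS}")


def sum_scale(
    records: list[PSMRecord],
    design: DesignTable,
    grouping: str = "plex_arm",
    target_sum: float | None = None,
) -> tuple[list[PSMRecord], ScaleFactors]:
    """Sum-scale *records*; returns (scaled copies, the factors used).

    Expects filter-passing records (scaling is computed on the same records
    it is applied to).  A channel with zero total intensity in a group makes
    that group degenerate and raises.

    With the default data-derived target (the mean of the group's channel
    sums) a pure per-channel bias cancels exactly in every between-channel
    ratio but leaves a common per-group constant in the intensities; passing
    an explicit *target_sum* makes the scaled intensities themselves exactly
    bias-independent.
    """
    sums: dict[tuple, dict[str, float]] = {}
    for rec in records:
        key = _group_key(rec, grouping)
        acc = sums.setdefault(key, {ch: 0.0 for ch in design.channels(rec.plex)})
        for ch, v in rec.intensities.items():
            if v is not None:
                acc[ch] += v

    factors: dict[tuple, dict[str, float]] = {}
    rows = []
    for key in sorted(sums):
        plex, arm, fraction = key
        channel_sums = sums[key]
        for ch, s in channel_sums.items():
            if s <= 0.0:
                raise DegenerateGroupError(
                    f"channel {ch!r} has zero total intensity in group "
                    f"plex={plex!r} arm={arm!r} fraction={fraction!r}"
                )
        target = (
            float(target_sum)
            if target_sum is not None
            else sum(channel_sums.values()) / len(channel_sums)
        )
        factors[key] = {ch: target / s for ch, s in channel_sums.items()}
        for ch in design.channels(plex):
            rows.append(
                (plex, arm, fraction, ch, channel_sums[ch], target, factors[key][ch])
            )
    frame = pd.DataFrame(
        rows,
        columns=["plex", "arm", "fraction", "channel", "channel_sum", "target_sum", "factor"],
    )
    scaled = [rec.scaled(factors[_group_key(rec, grouping)]) for rec in records]
    return scaled, ScaleFactors(frame, grouping)


def ma_points(
    records: list[PSMRecord], design: DesignTable
) -> tuple[pd.DataFrame, int]:
    """Per-PSM (A, M) pairs for every case: M = log2(T/NT), A = mean log2.

    Returns the points plus a count of pairs excluded for non-positive
    intensity (those cannot be log-transformed).
    """
    rows = []
    n_excluded = 0
    for rec in records:
        for case in design.cases(rec.plex):
            t_ch, nt_ch = design.pair(case)
            t, nt = rec.intensities.get(t_ch), rec.intensities.get(nt_ch)
            if t is None or nt is None or t <= 0 or nt <= 0:
                n_excluded += 1
                continue
            lt, lnt = math.log2(t), math.log2(nt)
            rows.append((rec.psm_id, rec.plex, rec.arm, case, 0.5 * (lt + lnt), lt - lnt))
    frame = pd.DataFrame(rows, columns=["psm_id", "plex", "arm", "case", "A", "M"])
    return frame, n_excluded
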