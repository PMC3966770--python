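"""Experimental-design handling for TMT 8-plex tumor / non-tumor experiments.

An 8-plex labels tumor (T) and non-tumor (NT) tissue from four cases with
eight isobaric reporter channels.  The design table maps each (plex, channel) to
a (case, tissue) pair; each case appears exactly twice in one plex — once as
T and once as NT — which defines the T/NT channel pair used for every ratio
downstream.  Channel labels are opaque strings: the 6-mDa isotopologue pairs
(e.g. "127e" vs "127") are distinguished upstream by the search engine.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

from .errors import InvalidDesignError

#: The three parallel sample-preparation arms of the workflow.
ARMS = ("non_enriched", "tio2", "imac")

TISSUES = ("T", "NT")

#: Conventional 8-plex reporter labels (ordered by nominal mass).
DEFAULT_CHANNELS = ("126", "127e", "127", "128e", "128", "129e", "129", "130")

_REQUIRED_COLUMNS = ("plex", "channel", "case", "tissue")


class DesignTable:
    """Validated plex/channel → case/tissue mapping.

    Parameters
    ----------
    frame
        DataFrame with columns ``plex``, ``channel``, ``case``, ``tissue``
        (one row per labelled specimen; eight rows per plex).
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise InvalidDesignError(f"design table missing column(s): {missing}")
        frame = frame.loc[:, list(_REQUIRED_COLUMNS)].astype(str).reset_index(drop=True)
        self._frame = frame
        self._validate()
        # (plex, channel) -> (case, tissue)
        self._by_channel = {
            (r.plex, r.channel): (r.case, r.tissue) for r in frame.itertuples()
        }
        # case -> {tissue: channel}, and case -> plex
        self._by_case: dict[str, dict[str, str]] = {}
        self._plex_of_case: dict[str, str] = {}
        for r in frame.itertuples():
            self._by_case.setdefault(r.case, {})[r.tissue] = r.channel
            self._plex_of_case[r.case] = r.plex

    def _validate(self) -> None:
        f = self._frame
        bad_tissue = set(f["tissue"]) - set(TISSUES)
        if bad_tissue:
            raise InvalidDesignError(f"unknown tissue label(s): {sorted(bad_tissue)}")
        for plex, sub in f.groupby("plex", sort=False):
            if sub["channel"].nunique() != len(sub) or len(sub) != 8:
                raise InvalidDesignError(
                    f"plex {plex!r} must have exactly 8 distinct channels, "
                    f"got {len(sub)} rows / {sub['channel'].nunique()} distinct"
                )
        for case, sub in f.groupby("case", sort=False):
            if len(sub) != 2 or set(sub["tissue"]) != set(TISSUES):
                raise InvalidDesignError(
                    f"case {case!r} must appear exactly twice (one T, one NT)"
                )
            if sub["plex"].nunique() != 1:
                raise InvalidDesignError(f"case {case!r} spans more than one plex")

    # -- accessors ---------------------------------------------------------

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame.copy()

    @property
    def plexes(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self._frame["plex"]))

    def channels(self, plex: str) -> tuple[str, ...]:
        """The eight channel labels of *plex*, in design order."""
        sub = self._frame[self._frame["plex"] == plex]
        if sub.empty:
            raise InvalidDesignError(f"unknown plex {plex!r}")
        return tuple(sub["channel"])

    @property
    def all_channels(self) -> frozenset[str]:
        return frozenset(self._frame["channel"])

    def cases(self, plex: str | None = None) -> tuple[str, ...]:
        f = self._frame if plex is None else self._frame[self._frame["plex"] == plex]
        return tuple(dict.fromkeys(f["case"]))

    def plex_of(self, case: str) -> str:
        return self._plex_of_case[case]

    def pair(self, case: str) -> tuple[str, str]:
        """(tumor channel, non-tumor channel) for *case*."""
        d = self._by_case[case]
        return d["T"], d["NT"]

    def partner(self, plex: str, channel: str) -> str:
        """The channel carrying the same case's other tissue."""
        case, tissue = self._by_channel[(plex, channel)]
        other = "NT" if tissue == "T" else "T"
        return self._by_case[case][other]

    def case_of(self, plex: str, channel: str) -> tuple[str, str]:
        """(case, tissue) labelled on *channel* of *plex*."""
        return self._by_channel[(plex, channel)]

    def swap_tissues(self, cases: Iterable[str] | None = None) -> "DesignTable":
        """Return a design with T/NT exchanged for *cases* (all, if None)."""
        f = self.frame
        sel = slice(None) if cases is None else f["case"].isin(set(cases))
        f.loc[sel, "tissue"] = f.loc[sel, "tissue"].map({"T": "NT", "NT": "T"})
        return DesignTable(f)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, DesignTable) and self._frame.equals(other._frame)


def read_design(path) -> DesignTable:
    """Read a design TSV (columns plex, channel, case, tissue) and validate it."""
    frame = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    return DesignTable(frame)


def write_design(design: DesignTable, path) -> None:
    design.frame.to_csv(path, sep="\t", index=False)


def paired_design(
    n_plexes: int = 3,
    cases_per_plex: int = 4,
    channels: tuple[str, ...] = DEFAULT_CHANNELS,
) -> DesignTable:
    """Build the study-style balanced design.

    Consecutive channel pairs carry one case's T and NT tissue; the
    orientation (which channel of the pair carries tumor) alternates between
    plexes so labelling bias is not confounded with tissue.
    """
    rows = []
    case_no = 1
    for p in range(n_plexes):
        plex = f"plex{p + 1}"
        t_first = p % 2 == 0
        for c in range(cases_per_plex):
            case = f"case{case_no}"
            case_no += 1
            ch_a, ch_b = channels[2 * c], channels[2 * c + 1]
            if t_first:
                rows += [(plex, ch_a, case, "T"), (plex, ch_b, case, "NT")]
            else:
                rows += [(plex, ch_a, case, "NT"), (plex, ch_b, case, "T")]
    return DesignTable(pd.DataFrame(rows, columns=list(_REQUIRED_COLUMNS)))
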