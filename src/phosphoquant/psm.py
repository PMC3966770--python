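"""PSM (peptide-spectrum match) records, table I/O and feature keys.

A PSM is the atomic quantification unit: one identification of a peptide
from one MS/MS spectrum, carrying identification confidence (Percolator-style
q-value), phospho-site localization probability, and the eight reporter-ion
intensities of its plex.

Table schema (TSV, header row, ``#`` comment lines allowed):

``psm_id  sequence  phospho_positions  protein_accessions  plex  arm
fraction  run  q_value  phosphors_probability  <one column per channel label>``

``phospho_positions`` and ``protein_accessions`` are semicolon-separated;
empty intensity cells mean the reporter peak was absent (never coerced to 0).
Columns that look like reporter labels but are not in the design raise
:class:`~phosphoquant.errors.DesignMismatchError`; any other extra column is
carried through as opaque metadata.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import pandas as pd

from .design import ARMS, DesignTable
from .errors import DesignMismatchError, SchemaError

MANDATORY_COLUMNS = (
    "psm_id",
    "sequence",
    "phospho_positions",
    "protein_accessions",
    "plex",
    "arm",
    "fraction",
    "run",
    "q_value",
    "phosphors_probability",
)

#: Reporter-label shape: 2-3 digits with an optional isotopologue letter.
_CHANNEL_RE = re.compile(r"\d{2,3}[a-z]?")


@dataclass
class PSMRecord:
    """One peptide-spectrum match with its reporter intensities.

    ``phospho_positions`` are 1-based indices into ``sequence``; a non-empty
    tuple marks the record as a phosphopeptide PSM.  ``intensities`` maps the
    plex's eight channel labels to a non-negative intensity or ``None`` when
    the reporter peak was not observed.
    """

    psm_id: str
    sequence: str
    phospho_positions: tuple[int, ...]
    protein_accessions: tuple[str, ...]
    plex: str
    arm: str
    fraction: int
    run: int
    q_value: float
    phosphors_probability: float | None
    intensities: dict[str, float | None]
    extras: dict[str, str] = field(default_factory=dict)

    @property
    def is_phospho(self) -> bool:
        return len(self.phospho_positions) > 0

    @property
    def is_shared(self) -> bool:
        """True when the peptide maps to more than one protein accession."""
        return len(self.protein_accessions) > 1

    def validate(self, design: DesignTable) -> None:
        if not self.protein_accessions:
            raise SchemaError(f"PSM {self.psm_id}: no protein accession")
        if self.arm not in ARMS:
            raise SchemaError(f"PSM {self.psm_id}: unknown arm {self.arm!r}")
        for pos in self.phospho_positions:
            if not 1 <= pos <= len(self.sequence):
                raise SchemaError(
                    f"PSM {self.psm_id}: phospho position {pos} outside "
                    f"sequence of length {len(self.sequence)}"
                )
        if self.is_phospho and self.phosphors_probability is None:
            raise SchemaError(
                f"PSM {self.psm_id}: phosphopeptide without localization probability"
            )
        expected = set(design.channels(self.plex))
        if set(self.intensities) != expected:
            raise DesignMismatchError(
                f"PSM {self.psm_id}: channels {sorted(self.intensities)} do not "
                f"match design channels {sorted(expected)} for plex {self.plex!r}"
            )

    def scaled(self, factors: dict[str, float]) -> "PSMRecord":
        """A copy with each present intensity multiplied by its channel factor."""
        new = {
            ch: (None if v is None else v * factors[ch])
            for ch, v in self.intensities.items()
        }
        return replace(self, intensities=new)


def feature_key(sequence_or_record, phospho_positions=None) -> str:
    """Deterministic peptide-feature key: ``SEQUENCE@pos1;pos2;...``.

    Distinct phospho positional isoforms of one sequence are distinct
    features; a non-phospho peptide keys as ``SEQUENCE@``.  The key is
    invariant under permutation of the position list.
    """
    if isinstance(sequence_or_record, PSMRecord):
        sequence = sequence_or_record.sequence
        phospho_positions = sequence_or_record.phospho_positions
    else:
        sequence = sequence_or_record
        phospho_positions = phospho_positions or ()
    return sequence + "@" + ";".join(str(p) for p in sorted(phospho_positions))


def _parse_positions(cell: str) -> tuple[int, ...]:
    cell = cell.strip()
    if not cell:
        return ()
    try:
        return tuple(int(tok) for tok in cell.split(";"))
    except ValueError as exc:
        raise SchemaError(f"unparseable phospho_positions cell {cell!r}") from exc


def split_columns(
    columns, design: DesignTable
) -> tuple[list[str], list[str]]:
    """Partition non-mandatory *columns* into (channel columns, extra columns).

    A column whose name has the reporter-label shape must be a design
    channel, otherwise the table disagrees with the design.
    """
    channel_cols: list[str] = []
    extra_cols: list[str] = []
    known = design.all_channels
    for col in columns:
        if col in MANDATORY_COLUMNS:
            continue
        if col in known:
            channel_cols.append(col)
        elif _CHANNEL_RE.fullmatch(col):
            raise DesignMismatchError(
                f"intensity column {col!r} is not a channel in the design"
            )
        else:
            extra_cols.append(col)
    return channel_cols, extra_cols


def read_psm_table(path, design: DesignTable) -> list[PSMRecord]:
    """Read a PSM TSV into validated records.

    Raises :class:`SchemaError` on missing mandatory columns and
    :class:`DesignMismatchError` on channel columns absent from the design.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    return frame_to_records(frame, design)


def frame_to_records(frame: pd.DataFrame, design: DesignTable) -> list[PSMRecord]:
    missing = [c for c in MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"PSM table missing mandatory column(s): {missing}")
    channel_cols, extra_cols = split_columns(frame.columns, design)
    records: list[PSMRecord] = []
    for row in frame.itertuples(index=False):
        d = dict(zip(frame.columns, row))
        plex = str(d["plex"])
        plex_channels = design.channels(plex)
        intensities: dict[str, float | None] = {}
        for ch in plex_channels:
            if ch not in channel_cols:
                raise DesignMismatchError(
                    f"PSM table lacks intensity column for channel {ch!r} "
                    f"of plex {plex!r}"
                )
            cell = str(d[ch]).strip()
            intensities[ch] = float(cell) if cell else None
        prs_cell = str(d["phosphors_probability"]).strip()
        rec = PSMRecord(
            psm_id=str(d["psm_id"]),
            sequence=str(d["sequence"]),
            phospho_positions=_parse_positions(str(d["phospho_positions"])),
            protein_accessions=tuple(
                tok for tok in str(d["protein_accessions"]).split(";") if tok
            ),
            plex=plex,
            arm=str(d["arm"]),
            fraction=int(d["fraction"]),
            run=int(d["run"]),
            q_value=float(d["q_value"]),
            phosphors_probability=float(prs_cell) if prs_cell else None,
            intensities=intensities,
            extras={c: str(d[c]) for c in extra_cols},
        )
        rec.validate(design)
        records.append(rec)
    return records


def records_to_frame(records: list[PSMRecord], design: DesignTable) -> pd.DataFrame:
    """Flatten records to the canonical table layout (one column per channel).

    Channels not belonging to a record's plex are left empty; intensities are
    rendered by the caller (kept as floats here, formatted at write time).
    """
    all_channels = list(dict.fromkeys(
        ch for plex in design.plexes for ch in design.channels(plex)
    ))
    extra_cols = list(dict.fromkeys(k for r in records for k in r.extras))
    rows = []
    for r in records:
        row = {
            "psm_id": r.psm_id,
            "sequence": r.sequence,
            "phospho_positions": ";".join(str(p) for p in r.phospho_positions),
            "protein_accessions": ";".join(r.protein_accessions),
            "plex": r.plex,
            "arm": r.arm,
            "fraction": r.fraction,
            "run": r.run,
            "q_value": r.q_value,
            "phosphors_probability": r.phosphors_probability,
        }
        for ch in all_channels:
            row[ch] = r.intensities.get(ch)
        for c in extra_cols:
            row[c] = r.extras.get(c, "")
        rows.append(row)
    cols = list(MANDATORY_COLUMNS) + all_channels + extra_cols
    return pd.DataFrame(rows, columns=cols)


def write_psm_table(records: list[PSMRecord], path, design: DesignTable) -> None:
    """Write records as TSV; floats use repr so a read round-trips bit-for-bit."""
    frame = records_to_frame(records, design)

    def fmt(v):
        if v is None or v != v:  # None or NaN
            return ""
        return repr(float(v))

    out = frame.copy()
    float_cols = ["q_value", "phosphors_probability"] + [
        c for c in frame.columns if c in design.all_channels
    ]
    for c in float_cols:
        out[c] = out[c].map(fmt)
    out.to_csv(path, sep="\t", index=False)
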