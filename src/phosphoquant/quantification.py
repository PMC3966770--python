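"""Per-case log2 T/NT ratios and hierarchical median aggregation.

The quantification chain:

1. every filter-passing, sum-scaled PSM yields one log2(T/NT) ratio per case
   of its plex (four per 8-plex PSM);
2. a peptide feature's per-(case, arm) ratio is the median over its PSM
   ratios (PSMs pooled across fractions and runs within an arm);
3. a protein's per-(case, arm) ratio is the median over its *unique*
   non-phosphorylated peptides (shared peptides contribute to no protein);
4. arms are merged per case as the median of the arm values present;
5. a phosphopeptide's protein-normalized ratio is its merged ratio minus the
   merged ratio of its protein (absent protein ⇒ absent normalized value).

Medians of even counts use the arithmetic mean of the two central values.
Absent values propagate as NaN and are never coerced to 0.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .design import DesignTable
from .psm import PSMRecord, feature_key

LEVELS = ("phosphopeptide", "nonphospho_peptide", "protein")


class RatioTable:
    """Per-feature, per-(case, arm) log2 T/NT values plus feature metadata.

    ``values`` is a DataFrame indexed by feature key with a (case, arm)
    column MultiIndex; ``meta`` is indexed the same way with columns
    ``level``, ``accession`` (single accession or empty when shared) and
    ``n_accessions``.
    """

    def __init__(self, values: pd.DataFrame, meta: pd.DataFrame, level: str | None = None):
        self.values = values
        self.meta = meta.loc[values.index]
        self.level = level

    def __len__(self) -> int:
        return len(self.values)

    @property
    def features(self) -> pd.Index:
        return self.values.index

    def subset_level(self, level: str) -> "RatioTable":
        keep = self.meta.index[self.meta["level"] == level]
        return RatioTable(self.values.loc[keep], self.meta.loc[keep], level)

    def for_arm(self, arm: str) -> pd.DataFrame:
        """feature × case matrix of the given arm (NaN where absent)."""
        cols = [c for c in self.values.columns if c[1] == arm]
        out = self.values.loc[:, cols]
        out.columns = [c[0] for c in cols]
        return out

    @property
    def arms(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(c[1] for c in self.values.columns))

    def merged(self) -> pd.DataFrame:
        """feature × case cross-arm medians (median of arm values present)."""
        return merge_arms(self)


def psm_log_ratios(records: list[PSMRecord], design: DesignTable) -> pd.DataFrame:
    """One row per (PSM, case): the case's log2(T/NT) from scaled intensities.

    Requires strictly positive intensities in both channels of a pair
    (guaranteed post-filter with complete channels); pairs violating this
    are skipped.  Columns: psm_id, feature_key, level, accession,
    n_accessions, plex, arm, run, fraction, case, log2_ratio.
    """
    rows = []
    for rec in records:
        key = feature_key(rec)
        level = "phosphopeptide" if rec.is_phospho else "nonphospho_peptide"
        accession = rec.protein_accessions[0] if not rec.is_shared else ""
        for case in design.cases(rec.plex):
            t_ch, nt_ch = design.pair(case)
            t, nt = rec.intensities.get(t_ch), rec.intensities.get(nt_ch)
            if t is None or nt is None or t <= 0 or nt <= 0:
                continue
            rows.append(
                (
                    rec.psm_id, key, level, accession, len(rec.protein_accessions),
                    rec.plex, rec.arm, rec.run, rec.fraction, case,
                    math.log2(t / nt),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "psm_id", "feature_key", "level", "accession", "n_accessions",
            "plex", "arm", "run", "fraction", "case", "log2_ratio",
        ],
    )


def aggregate_peptide(psm_ratios: pd.DataFrame) -> RatioTable:
    """Median PSM ratio per (feature, case, arm) — the peptide-level table."""
    if psm_ratios.empty:
        empty = pd.DataFrame()
        return RatioTable(empty, pd.DataFrame(columns=["level", "accession", "n_accessions"]))
    med = psm_ratios.groupby(["feature_key", "case", "arm"], sort=True)["log2_ratio"].median()
    values = med.unstack(["case", "arm"])
    values = values.sort_index(axis=1)
    meta = (
        psm_ratios.drop_duplicates("feature_key")
        .set_index("feature_key")[["level", "accession", "n_accessions"]]
    )
    return RatioTable(values, meta)


def aggregate_protein(peptide_table: RatioTable) -> RatioTable:
    """Protein-level medians over unique non-phospho peptide ratios.

    Peptides mapping to more than one accession are excluded; proteins
    observed only through phosphopeptides get no protein-level ratio.
    """
    meta = peptide_table.meta
    keep = meta.index[(meta["level"] == "nonphospho_peptide") & (meta["n_accessions"] == 1)]
    sub = peptide_table.values.loc[keep]
    accession = meta.loc[keep, "accession"]
    if sub.empty:
        return RatioTable(
            pd.DataFrame(),
            pd.DataFrame(columns=["level", "accession", "n_accessions"]),
            "protein",
        )
    values = sub.groupby(accession.values).median()
    values.index.name = "feature_key"
    prot_meta = pd.DataFrame(
        {"level": "protein", "accession": values.index, "n_accessions": 1},
        index=values.index,
    )
    return RatioTable(values, prot_meta, "protein")


def merge_arms(table: RatioTable, how: str = "median") -> pd.DataFrame:
    """feature × case matrix combining arms (median by default, mean optional).

    A case's merged value is the median (or mean) of the 1–3 arm values
    present; cases with no arm value stay absent.
    """
    if table.values.empty:
        return pd.DataFrame()
    grouped = table.values.T.groupby(level="case")
    agg = grouped.median() if how == "median" else grouped.mean()
    return agg.T


def normalize_phospho_to_protein(
    phospho_table: RatioTable, protein_table: RatioTable, how: str = "median"
) -> pd.DataFrame:
    """Phosphopeptide merged ratios minus the host protein's merged ratio.

    The result isolates phosphorylation-level regulation from expression
    change of the parent protein.  Phosphopeptides shared between proteins,
    or whose protein has no non-phospho peptide ratio, get NaN everywhere.
    """
    phospho_merged = merge_arms(phospho_table, how)
    protein_merged = merge_arms(protein_table, how)
    meta = phospho_table.meta
    acc = meta["accession"].where(meta["n_accessions"] == 1, "")
    prot_rows = protein_merged.reindex(acc.values)
    prot_rows.index = phospho_merged.index
    prot_rows = prot_rows.reindex(columns=phospho_merged.columns)
    return phospho_merged - prot_rows


def write_ratio_table(table: RatioTable, path, header_comment: str = "") -> None:
    """TSV with flattened (case|arm) columns plus merged per-case columns."""
    flat = table.values.copy()
    flat.columns = [f"{case}|{arm}" for case, arm in flat.columns]
    merged = merge_arms(table)
    merged.columns = [f"{case}|merged" for case in merged.columns]
    out = pd.concat([table.meta, flat, merged], axis=1)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        out.to_csv(fh, sep="\t", index_label="feature_key")


def channel_cv(records: list[PSMRecord], design: DesignTable) -> pd.DataFrame:
    """Coefficient of variation of channel sums per (plex, arm) — a quick
    loading-bias diagnostic used in QC summaries."""
    rows = []
    sums: dict[tuple[str, str], dict[str, float]] = {}
    for rec in records:
        acc = sums.setdefault((rec.plex, rec.arm), {})
        for ch, v in rec.intensities.items():
            if v is not None:
                acc[ch] = acc.get(ch, 0.0) + v
    for (plex, arm), chans in sorted(sums.items()):
        vals = np.array(list(chans.values()))
        rows.append((plex, arm, float(vals.std() / vals.mean()) if vals.mean() else np.nan))
    return pd.DataFrame(rows, columns=["plex", "arm", "channel_sum_cv"])
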