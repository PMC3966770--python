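"""Joining differential results to user-supplied annotation tables.

Annotation sources are plain TSVs keyed by protein accession (and optionally
the 1-based phosphosite position on the full-length protein): site function,
drug targets, GO-style term lists.  The pipeline ships no databases — the
tables are the user's responsibility, which keeps licensing and versioning
out of scope.  Joins are left joins: they never change the row count of the
results side, and unmatched features simply carry empty annotation.
"""

from __future__ import annotations

import pandas as pd

from .errors import AnnotationError


def load_annotation(path, key_cols: tuple[str, ...] = ("accession",)) -> pd.DataFrame:
    """Read an annotation TSV and enforce key uniqueness.

    ``key_cols`` name the join key (e.g. ``("accession",)`` for protein-level
    tables, ``("accession", "position")`` for site-level tables).
    """
    table = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    missing = [c for c in key_cols if c not in table.columns]
    if missing:
        raise AnnotationError(f"annotation table missing key column(s): {missing}")
    dup = table.duplicated(subset=list(key_cols))
    if dup.any():
        dup_keys = table.loc[dup, list(key_cols)].iloc[0].tolist()
        raise AnnotationError(f"duplicate annotation key (first: {dup_keys})")
    return table


def annotate_results(
    results: pd.DataFrame,
    table: pd.DataFrame,
    on: tuple[str, ...] = ("accession",),
    prefix: str = "",
) -> pd.DataFrame:
    """Left-join *table* onto *results* by the shared key columns *on*.

    Annotation columns may be prefixed to avoid collisions.  Unmatched rows
    get empty strings, not NaN, so reports stay plain text.
    """
    missing = [c for c in on if c not in results.columns]
    if missing:
        raise AnnotationError(f"results lack join column(s): {missing}")
    ann = table.copy()
    value_cols = [c for c in ann.columns if c not in on]
    if prefix:
        ann = ann.rename(columns={c: prefix + c for c in value_cols})
        value_cols = [prefix + c for c in value_cols]
    out = results.merge(ann, how="left", on=list(on))
    out.index = results.index
    out[value_cols] = out[value_cols].fillna("")
    return out


def term_filter(
    annotated: pd.DataFrame, column: str, term: str, sep: str = ";"
) -> pd.DataFrame:
    """Rows whose *column* term list contains *term*.

    Matching is case-insensitive and exact-token based: the cell is split on
    *sep*, tokens are stripped and lower-cased, and the query must equal one
    token (so "adhesion" does not match "focal adhesion").
    """
    want = term.strip().lower()

    def has_term(cell) -> bool:
        if not isinstance(cell, str) or not cell:
            return False
        return any(tok.strip().lower() == want for tok in cell.split(sep))

    return annotated[annotated[column].map(has_term)]
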