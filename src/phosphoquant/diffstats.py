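"""Differential statistics: one-sided location tests, volcano calls,
arm/run overlap accounting, and EASE/Fisher gene-set enrichment.

Per-feature significance follows the volcano convention: a feature is
significant when |median log2 T/NT| meets the effect-size cut AND the
one-sided one-sample t-test p-value meets the p cut (both boundaries
inclusive), with ratios from at least ``min_cases`` cases.

Direction convention.  With ``direction="auto"`` the one-sided p is taken in
the direction of the observed mean, p = P(T_{n-1} >= |t|), i.e. half the
two-sided p.  This is the convention a volcano that calls both up- and
down-regulation implies, but note its null rejection rate at p <= 0.05 is 5%
*per direction* (10% combined).  Fixed directions ("greater"/"less") give a
p that is uniform under the null.  See docs/methods.md.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import PhosphoQuantError

DIRECTIONS = ("auto", "greater", "less")

#: Smallest positive double; reported when the sample variance is zero but
#: the mean is not (the t statistic is unbounded).
MIN_P = float(np.nextafter(0, 1))


@dataclass(frozen=True)
class VolcanoConfig:
    """Significance thresholds: 0.3 is the protein default, 0.75 the
    phosphopeptide default, both with p <= 0.05 over >= 2 cases."""

    ratio_cut: float = 0.3
    p_cut: float = 0.05
    min_cases: int = 2

    def __post_init__(self):
        if self.ratio_cut <= 0:
            raise ValueError("ratio_cut must be positive")
        if not 0 < self.p_cut <= 1:
            raise ValueError("p_cut must be in (0, 1]")
        if self.min_cases < 2:
            raise ValueError("min_cases must be >= 2")


PROTEIN_VOLCANO = VolcanoConfig(ratio_cut=0.3)
PHOSPHO_VOLCANO = VolcanoConfig(ratio_cut=0.75)


def one_sided_ttest(values, direction: str = "auto") -> tuple[float, float]:
    """One-sample one-sided t-test of *values* against 0.

    Returns (t, p).  With fewer than two finite values both are NaN; with
    zero sample variance and nonzero mean, p is the smallest positive double
    and t is signed infinity.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    n = v.size
    if n < 2:
        return (float("nan"), float("nan"))
    mean = v.mean()
    sd = v.std(ddof=1)
    if sd == 0.0:
        if mean == 0.0:
            return (0.0, 0.5)
        t = math_inf_signed(mean)
        return (t, MIN_P)
    t = mean / (sd / np.sqrt(n))
    return (float(t), _t_tail(t, n - 1, direction))


def math_inf_signed(x: float) -> float:
    return float("inf") if x > 0 else float("-inf")


def _t_tail(t, df, direction: str):
    if direction == "auto":
        return float(stats.t.sf(np.abs(t), df))
    if direction == "greater":
        return float(stats.t.sf(t, df))
    if direction == "less":
        return float(stats.t.cdf(t, df))
    raise ValueError(f"unknown direction {direction!r}; choose from {DIRECTIONS}")


def ttest_frame(
    matrix: pd.DataFrame, direction: str = "auto", min_cases: int = 2
) -> pd.DataFrame:
    """Vectorized per-row one-sided t-test of a feature × case matrix.

    Columns of the result: n_cases, mean, median_log2_ratio, t_stat,
    p_one_sided, zero_variance.  Rows with fewer than *min_cases* values get
    NaN statistics.
    """
    x = matrix.to_numpy(dtype=float)
    finite = np.isfinite(x)
    n = finite.sum(axis=1)
    xm = np.where(finite, x, np.nan)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(xm, axis=1)
        median = np.nanmedian(xm, axis=1)
        sd = np.nanstd(xm, axis=1, ddof=1)
    ok = n >= max(min_cases, 2)
    t = np.full(x.shape[0], np.nan)
    p = np.full(x.shape[0], np.nan)
    zero_var = ok & (sd == 0.0)
    reg = ok & (sd > 0.0)
    t[reg] = mean[reg] / (sd[reg] / np.sqrt(n[reg]))
    df = n[reg] - 1
    if direction == "auto":
        p[reg] = stats.t.sf(np.abs(t[reg]), df)
    elif direction == "greater":
        p[reg] = stats.t.sf(t[reg], df)
    elif direction == "less":
        p[reg] = stats.t.cdf(t[reg], df)
    else:
        raise ValueError(f"unknown direction {direction!r}; choose from {DIRECTIONS}")
    # degenerate zero-variance rows
    zm = zero_var & (mean == 0.0)
    t[zm], p[zm] = 0.0, 0.5
    znz = zero_var & (mean != 0.0)
    t[znz] = np.where(mean[znz] > 0, np.inf, -np.inf)
    p[znz] = MIN_P
    return pd.DataFrame(
        {
            "n_cases": n,
            "mean": mean,
            "median_log2_ratio": median,
            "t_stat": t,
            "p_one_sided": p,
            "zero_variance": zero_var,
        },
        index=matrix.index,
    )


def volcano_classify(results: pd.DataFrame, config: VolcanoConfig) -> pd.DataFrame:
    """Add the ``significant`` flag: |median| >= ratio_cut AND p <= p_cut
    AND n_cases >= min_cases (boundaries inclusive)."""
    out = results.copy()
    out["significant"] = (
        (out["median_log2_ratio"].abs() >= config.ratio_cut)
        & (out["p_one_sided"] <= config.p_cut)
        & (out["n_cases"] >= config.min_cases)
    ).fillna(False)
    out.attrs["thresholds_used"] = (config.ratio_cut, config.p_cut)
    return out


def volcano_by_arm(
    ratio_table,
    config: VolcanoConfig,
    direction: str = "auto",
    complete_cases: bool = False,
    n_total_cases: int | None = None,
) -> tuple[dict[str, pd.DataFrame], pd.Series]:
    """Per-arm volcano results plus the union significance flag.

    The union rule matches the per-arm volcano reading: a feature counts as
    significant when it is significant in at least one arm.  With
    ``complete_cases`` only features quantified in every case of an arm are
    eligible there.
    """
    per_arm: dict[str, pd.DataFrame] = {}
    union = pd.Series(False, index=ratio_table.features)
    for arm in ratio_table.arms:
        mat = ratio_table.for_arm(arm)
        res = ttest_frame(mat, direction=direction, min_cases=config.min_cases)
        res = volcano_classify(res, config)
        if complete_cases:
            want = n_total_cases if n_total_cases is not None else mat.shape[1]
            res.loc[res["n_cases"] < want, "significant"] = False
        per_arm[arm] = res
        union |= res["significant"].reindex(union.index, fill_value=False)
    return per_arm, union


def overlap_counts(sets_by_label: dict[str, set]) -> dict[str, int]:
    """Exact disjoint-region counts of a 2- or 3-set Venn diagram.

    Keys: ``"a&b"``-style region names (labels sorted, joined by ``&``) for
    the exclusive regions, ``total_<label>`` per set, and ``union``.
    Region counts always sum to the union cardinality.
    """
    labels = sorted(sets_by_label)
    if not 2 <= len(labels) <= 3:
        raise ValueError("overlap_counts expects 2 or 3 sets")
    counts: dict[str, int] = {}
    universe = set().union(*sets_by_label.values())
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            inside = set.intersection(*(sets_by_label[l] for l in combo))
            outside = set().union(
                *(sets_by_label[l] for l in labels if l not in combo), set()
            )
            counts["&".join(combo)] = len(inside - outside)
    for l in labels:
        counts[f"total_{l}"] = len(sets_by_label[l])
    counts["union"] = len(universe)
    return counts


def read_gmt(path) -> dict[str, list[str]]:
    """Read GMT gene sets: set_id <tab> description <tab> member..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [m for m in parts[2:] if m]
    return sets


def enrichment_test(
    hits,
    background,
    gene_sets: dict[str, list[str]],
    ease: bool = True,
) -> pd.DataFrame:
    """Gene-set over-representation by one-sided Fisher exact test.

    With ``ease=True`` the conservative EASE variant is used: one hit is
    removed from the in-set overlap before computing the hypergeometric
    upper tail (floored at zero, so an empty overlap keeps p = 1).
    Benjamini–Hochberg adjustment is applied across the tested sets.
    """
    background = set(background)
    hits = set(hits)
    if not background:
        raise PhosphoQuantError("enrichment_test: empty background")
    if not hits <= background:
        raise PhosphoQuantError("enrichment_test: hits must be a subset of background")
    N, n = len(background), len(hits)
    rows = []
    for set_id in sorted(gene_sets):
        members = set(gene_sets[set_id]) & background
        K = len(members)
        a = len(hits & members)
        a_eff = max(a - 1, 0) if ease else a
        # P(X >= a_eff), X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(a_eff - 1, N, K, n)) if K else 1.0
        p = min(p, 1.0)
        rows.append((set_id, a, n, K, N, p))
    out = pd.DataFrame(
        rows,
        columns=[
            "set_id", "n_hits_in_set", "n_hits",
            "n_background_in_set", "n_background", "p_raw",
        ],
    )
    if len(out):
        out["p_bh"] = multipletests(out["p_raw"], method="fdr_bh")[1]
    else:
        out["p_bh"] = pd.Series(dtype=float)
    return out
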