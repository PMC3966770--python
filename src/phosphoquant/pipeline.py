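"""Stage orchestration: read → filter → scale → ratios → aggregate → merge
→ normalize-to-protein → stats → overlap → PLS → annotate.

``analyze`` is the in-memory engine (records in, results out);
``run_pipeline`` wraps it with file I/O, a run directory of TSV outputs,
and a machine-readable summary JSON recording counts at every stage.
Stages are pure functions of their inputs: two runs with the same inputs
and configuration produce byte-identical outputs (every table carries the
configuration hash in its header comment).
"""

from __future__ import annotations

import hashlib
import json
import pathlib
from dataclasses import dataclass, field, asdict

import pandas as pd
import yaml

from . import __version__
from .design import ARMS, DesignTable, read_design
from .diffstats import (
    PHOSPHO_VOLCANO,
    PROTEIN_VOLCANO,
    VolcanoConfig,
    overlap_counts,
    volcano_by_arm,
)
from .errors import PipelineError
from .filtering import FilterThresholds, filter_psms
from .multivariate import NipalsPLS, intensity_matrix
from .normalization import ma_points, sum_scale
from .psm import PSMRecord, feature_key, read_psm_table
from .quantification import (
    RatioTable,
    aggregate_peptide,
    aggregate_protein,
    merge_arms,
    normalize_phospho_to_protein,
    psm_log_ratios,
    write_ratio_table,
)


@dataclass
class AnalysisOptions:
    """Knobs of the in-memory analysis (defaults follow the study)."""

    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    grouping: str = "plex_arm"
    merge_how: str = "median"
    direction: str = "auto"
    protein_volcano: VolcanoConfig = PROTEIN_VOLCANO
    phospho_volcano: VolcanoConfig = PHOSPHO_VOLCANO
    complete_cases: bool = False
    pls: bool = True
    pls_components: int = 3


@dataclass
class AnalysisResult:
    retained: list
    rejection_log: pd.DataFrame
    scale_factors: object
    psm_ratios: pd.DataFrame
    peptide_table: RatioTable
    phospho_table: RatioTable
    nonphospho_table: RatioTable
    protein_table: RatioTable
    merged_phospho: pd.DataFrame
    merged_protein: pd.DataFrame
    normalized_phospho: pd.DataFrame
    protein_volcano: dict
    protein_union: pd.Series
    phospho_volcano: dict
    phospho_union: pd.Series
    venn_arms: dict
    venn_runs: dict
    pls_intensity: NipalsPLS | None
    pls_ratio: NipalsPLS | None
    summary: dict


def analyze(
    records: list[PSMRecord],
    design: DesignTable,
    options: AnalysisOptions = AnalysisOptions(),
) -> AnalysisResult:
    """Run the full quantification / differential chain in memory."""
    summary: dict = {"psms_total": len(records)}

    retained, rejection_log = filter_psms(records, options.thresholds, design)
    summary["psms_retained"] = len(retained)
    summary["psms_rejected"] = len(rejection_log)
    summary["rejected_by_reason"] = (
        rejection_log["reason"].value_counts().to_dict() if len(rejection_log) else {}
    )
    if not retained:
        raise PipelineError("filter", "no PSMs pass the filters")

    scaled, factors = sum_scale(retained, design, options.grouping)
    ratios = psm_log_ratios(scaled, design)
    summary["psm_case_ratios"] = len(ratios)

    peptide_table = aggregate_peptide(ratios)
    phospho_table = peptide_table.subset_level("phosphopeptide")
    nonphospho_table = peptide_table.subset_level("nonphospho_peptide")
    protein_table = aggregate_protein(peptide_table)
    summary["unique_phosphopeptides"] = len(phospho_table)
    summary["unique_nonphospho_peptides"] = len(nonphospho_table)
    summary["proteins_quantified"] = len(protein_table)

    merged_phospho = merge_arms(phospho_table, options.merge_how)
    merged_protein = merge_arms(protein_table, options.merge_how)
    normalized = normalize_phospho_to_protein(
        phospho_table, protein_table, options.merge_how
    )
    summary["quantifiable_phosphopeptides"] = int(
        merged_phospho.notna().any(axis=1).sum()
    ) if len(merged_phospho) else 0
    summary["phospho_normalizable"] = int(
        normalized.notna().any(axis=1).sum()
    ) if len(normalized) else 0

    n_cases = len(design.cases())
    prot_volc, prot_union = volcano_by_arm(
        protein_table, options.protein_volcano, options.direction,
        options.complete_cases, n_cases,
    )
    phos_volc, phos_union = volcano_by_arm(
        phospho_table, options.phospho_volcano, options.direction,
        options.complete_cases, n_cases,
    )
    summary["significant_proteins"] = {
        arm: int(v["significant"].sum()) for arm, v in prot_volc.items()
    }
    summary["significant_proteins_union"] = int(prot_union.sum())
    summary["significant_phosphopeptides"] = {
        arm: int(v["significant"].sum()) for arm, v in phos_volc.items()
    }
    summary["significant_phosphopeptides_union"] = int(phos_union.sum())

    # arm / run identification overlap (unique phosphopeptide features)
    phos_sets_arm = {
        arm: {feature_key(r) for r in retained if r.arm == arm and r.phospho_positions}
        for arm in ARMS
    }
    run_sets = {
        f"run{run}": {feature_key(r) for r in retained if r.run == run}
        for run in sorted({r.run for r in retained})
    }
    venn_arms = overlap_counts(phos_sets_arm)
    venn_runs = overlap_counts(run_sets) if 2 <= len(run_sets) <= 3 else {}
    summary["venn_phospho_arms"] = venn_arms
    summary["venn_runs"] = venn_runs

    pls_int = pls_ratio = None
    if options.pls:
        X, tissues = intensity_matrix(retained, design)
        k = min(options.pls_components, X.shape[0] - 1)
        pls_int = NipalsPLS(n_components=k).fit(X, tissues.values)
        summary["pls_intensity_evr"] = [
            round(float(v), 6) for v in pls_int.explained_variance_ratio_
        ]
        if len(merged_phospho) and merged_phospho.shape[1] >= 3:
            Xr = merged_phospho.T  # cases × features
            keep = Xr.notna().sum(axis=0) >= 2
            Xr = Xr.loc[:, keep]
            if Xr.shape[1] >= 2:
                kr = min(options.pls_components, Xr.shape[0] - 1)
                pls_ratio = NipalsPLS(n_components=kr).fit(Xr)
                summary["pls_ratio_evr"] = [
                    round(float(v), 6) for v in pls_ratio.explained_variance_ratio_
                ]

    return AnalysisResult(
        retained, rejection_log, factors, ratios,
        peptide_table, phospho_table, nonphospho_table, protein_table,
        merged_phospho, merged_protein, normalized,
        prot_volc, prot_union, phos_volc, phos_union,
        venn_arms, venn_runs, pls_int, pls_ratio, summary,
    )


@dataclass
class PipelineConfig:
    """File-level configuration of a pipeline run (YAML-serializable)."""

    psm_tables: list[str]
    design: str
    out_dir: str
    max_q: float = 0.05
    min_phosphors: float = 0.75
    require_complete_channels: bool = True
    grouping: str = "plex_arm"
    merge_how: str = "median"
    direction: str = "auto"
    ratio_cut_protein: float = 0.3
    ratio_cut_phospho: float = 0.75
    p_cut: float = 0.05
    min_cases: int = 2
    complete_cases: bool = False
    pls: bool = True
    pls_components: int = 3
    write_ma_points: bool = False

    def to_options(self) -> AnalysisOptions:
        return AnalysisOptions(
            thresholds=FilterThresholds(
                self.max_q, self.min_phosphors, self.require_complete_channels
            ),
            grouping=self.grouping,
            merge_how=self.merge_how,
            direction=self.direction,
            protein_volcano=VolcanoConfig(self.ratio_cut_protein, self.p_cut, self.min_cases),
            phospho_volcano=VolcanoConfig(self.ratio_cut_phospho, self.p_cut, self.min_cases),
            complete_cases=self.complete_cases,
            pls=self.pls,
            pls_components=self.pls_components,
        )

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (the output location
        does not influence any result and is excluded)."""
        payload = asdict(self)
        payload.pop("out_dir")
        return hashlib.sha256(
            yaml.safe_dump(payload, sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def _write_tsv(frame: pd.DataFrame, path, header: str, index_label=None) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        frame.to_csv(fh, sep="\t", index=index_label is not None, index_label=index_label)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the pipeline per *config*, writing a run directory.

    Returns the summary dict (also written as ``summary.json``).  Any stage
    failure aborts with :class:`PipelineError` naming the stage.
    """
    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = (
        f"phosphoquant {__version__} config_hash={config.config_hash()} "
        f"thresholds=q<{config.max_q},pRS>{config.min_phosphors} "
        f"volcano=({config.ratio_cut_protein}/{config.ratio_cut_phospho},p<={config.p_cut})"
    )
    try:
        design = read_design(config.design)
        records: list[PSMRecord] = []
        for p in config.psm_tables:
            records.extend(read_psm_table(p, design))
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError("read", str(exc)) from exc

    result = analyze(records, design, config.to_options())

    _write_tsv(result.rejection_log, out / "rejection_log.tsv", header)
    _write_tsv(result.scale_factors.frame, out / "scale_factors.tsv", header)
    if config.write_ma_points:
        points, n_excluded = ma_points(result.retained, design)
        _write_tsv(points, out / "ma_points.tsv", f"{header} excluded={n_excluded}")
    write_ratio_table(result.phospho_table, out / "ratios_phosphopeptide.tsv", header)
    write_ratio_table(result.nonphospho_table, out / "ratios_nonphospho_peptide.tsv", header)
    write_ratio_table(result.protein_table, out / "ratios_protein.tsv", header)
    _write_tsv(
        result.normalized_phospho, out / "phospho_normalized_to_protein.tsv",
        header, index_label="feature_key",
    )
    for arm, frame in result.protein_volcano.items():
        _write_tsv(frame, out / f"volcano_protein_{arm}.tsv", header, "feature_key")
    for arm, frame in result.phospho_volcano.items():
        _write_tsv(frame, out / f"volcano_phosphopeptide_{arm}.tsv", header, "feature_key")
    venn = pd.DataFrame(
        sorted(result.venn_arms.items()), columns=["region", "count"]
    )
    _write_tsv(venn, out / "venn_phospho_arms.tsv", header)
    if result.venn_runs:
        venn_r = pd.DataFrame(sorted(result.venn_runs.items()), columns=["region", "count"])
        _write_tsv(venn_r, out / "venn_runs.tsv", header)
    if result.pls_intensity is not None:
        scores = pd.DataFrame(
            result.pls_intensity.x_scores_,
            columns=[f"PC{i + 1}" for i in range(result.pls_intensity.n_components_)],
        )
        _write_tsv(scores, out / "pls_intensity_scores.tsv", header)
    if result.pls_ratio is not None:
        scores = pd.DataFrame(
            result.pls_ratio.x_scores_,
            columns=[f"PC{i + 1}" for i in range(result.pls_ratio.n_components_)],
        )
        _write_tsv(scores, out / "pls_ratio_scores.tsv", header)

    summary = dict(result.summary)
    summary["config_hash"] = config.config_hash()
    summary["version"] = __version__
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
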