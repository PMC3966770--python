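"""Generative model of TMT 8-plex phosphoproteomics PSM tables with known truth.

The generator emulates the statistical structure of a three-plex tumor /
non-tumor study: 8 channels per plex carrying paired T/NT tissue from four
cases, three parallel preparation arms (non-enriched, TiO2, IMAC) with
phosphopeptides over-sampled in the enrichment arms, 12 SCX fractions, and
three analytical runs per arm where the third run uses a time-dependent
rejection list (it only acquires features missed by runs 1 and 2).

Intensity model per PSM and channel::

    I = base_abundance * psm_scatter * 2^(±fc/2) * channel_bias * e^N(0, σ)

where ``fc`` is the feature's true per-case log2 T/NT fold change, split
symmetrically between the tumor (+fc/2) and non-tumor (−fc/2) channel so the
total abundance is fold-change invariant and sum-scaling stays neutral;
``channel_bias`` is a per-(plex, channel) loading factor that sum-scaling
must remove; σ is the lognormal noise level in natural-log units.
Contaminating PSMs carry q ≥ 0.05 or pRS ≤ 0.75 at configured rates, and
whole channels go missing at ``missing_channel_rate``.

Randomness: one stream per (plex, arm), spawned from the master seed, so
sub-datasets are individually reproducible; the catalog and ground truth use
the master stream.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .design import ARMS, DesignTable, paired_design
from .errors import SimulationError
from .psm import PSMRecord, feature_key

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_PHOSPHOACCEPTORS = "STY"


@dataclass
class SimConfig:
    """Generation parameters; defaults mirror the study design
    (3 plexes × 8 channels, 4 paired cases per plex, 3 arms, 12 fractions,
    3 runs) at a desk-scale catalog size."""

    n_plexes: int = 3
    cases_per_plex: int = 4
    n_fractions: int = 12
    n_runs: int = 3
    n_proteins: int = 120
    peptides_per_protein_mean: float = 4.0
    phospho_fraction: float = 0.22
    multi_site_fraction: float = 0.15
    shared_peptide_fraction: float = 0.03
    # true fold-change model
    regulated_fraction: float = 0.10
    regulated_fc: float = 1.0
    fc_positive_prob: float = 0.5
    site_regulated_fraction: float = 0.10
    site_fc: float = 1.0
    case_effect_sd: float = 0.0
    # intensity model
    log_abundance_mean: float = 13.0
    log_abundance_sd: float = 1.2
    psm_abundance_sd: float = 0.5
    noise_sigma: float = 0.25
    channel_bias_sd: float = 0.15
    # PSM sampling rates (expected PSMs per peptide per run, by arm)
    phospho_rates: dict = field(
        default_factory=lambda: {"imac": 1.5, "tio2": 0.6, "non_enriched": 0.15}
    )
    nonphospho_rates: dict = field(
        default_factory=lambda: {"imac": 0.4, "tio2": 0.4, "non_enriched": 1.5}
    )
    # contamination
    missing_channel_rate: float = 0.02
    low_confidence_rate: float = 0.05
    poor_localization_rate: float = 0.05
    rejection_list_emulation: bool = True
    # balance controls (see class docstring of the noise-free constructor)
    mirrored_regulation: bool = False
    deterministic_psm_counts: bool = False
    seed: int = 0

    @classmethod
    def noise_free(cls, **overrides) -> "SimConfig":
        """A configuration under which the quantification chain is exact.

        Sum-scaling estimates loading factors from the data, so it is only
        signal-neutral when the clean channel sums are balanced.  This
        constructor generates data satisfying that assumption exactly:
        regulated proteins come in ±fc mirror pairs with identical peptide
        structure, base abundances and (deterministic) PSM counts, and all
        noise, bias and contamination terms are switched off.  Every merged
        log2 T/NT ratio then equals its true fold change to machine
        precision — a strong end-to-end exactness check of the pipeline.
        """
        params = dict(
            noise_sigma=0.0, psm_abundance_sd=0.0, channel_bias_sd=0.0,
            missing_channel_rate=0.0, low_confidence_rate=0.0,
            poor_localization_rate=0.0, site_regulated_fraction=0.0,
            case_effect_sd=0.0, shared_peptide_fraction=0.0,
            mirrored_regulation=True, deterministic_psm_counts=True,
        )
        params.update(overrides)
        return cls(**params)

    def validate(self) -> None:
        if self.n_proteins <= 0:
            raise SimulationError("n_proteins must be positive")
        if self.n_plexes <= 0 or self.cases_per_plex <= 0:
            raise SimulationError("need at least one plex with one case")
        for name in (
            "phospho_fraction", "multi_site_fraction", "shared_peptide_fraction",
            "regulated_fraction", "site_regulated_fraction", "fc_positive_prob",
            "missing_channel_rate", "low_confidence_rate", "poor_localization_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must be in [0, 1], got {v}")
        if self.noise_sigma < 0 or self.channel_bias_sd < 0:
            raise SimulationError("noise/bias sigmas must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth: per-case true log2 T/NT fold changes for every protein
    and phosphopeptide feature, plus the scalar base effects and flags."""

    protein_fc: pd.DataFrame  # accession × case
    phospho_fc: pd.DataFrame  # feature_key × case
    protein_base_fc: pd.Series
    phospho_base_fc: pd.Series
    config: SimConfig

    @property
    def protein_regulated(self) -> pd.Series:
        return self.protein_base_fc != 0.0

    @property
    def phospho_regulated(self) -> pd.Series:
        return self.phospho_base_fc != 0.0


@dataclass
class SimResult:
    records: list
    design: DesignTable
    truth: SyntheticTruth
    config: SimConfig


def _random_peptide(rng, min_len=8, max_len=22) -> str:
    length = int(rng.integers(min_len, max_len + 1))
    body = "".join(rng.choice(list(_AMINO_ACIDS), size=length - 1))
    return body + str(rng.choice(["K", "R"]))  # tryptic C-terminus


def _home_fraction(sequence: str, n_fractions: int) -> int:
    """Deterministic SCX elution fraction from a sequence hash."""
    return (zlib.crc32(sequence.encode()) % n_fractions) + 1


def generate_dataset(config: SimConfig = SimConfig()) -> SimResult:
    """Generate a full synthetic dataset (records, design, truth).

    Deterministic for a fixed ``config.seed``: calling twice yields
    identical records and truth tables.
    """
    config.validate()
    master = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    design = paired_design(config.n_plexes, config.cases_per_plex)
    cases = design.cases()

    # --- catalog ----------------------------------------------------------
    proteins = [f"P{i + 1:04d}" for i in range(config.n_proteins)]
    peptides = []  # dicts: sequence, positions, accessions, base_abundance
    seen_seq: set[str] = set()

    def fresh_sequence() -> str:
        seq = _random_peptide(master)
        while seq in seen_seq:
            seq = _random_peptide(master)
        seen_seq.add(seq)
        return seq

    def make_peptide(acc: str, template: dict | None = None) -> dict:
        """New peptide for *acc*; with a template, mirror its phospho-site
        count and base abundance so a ±fc protein pair contributes equal
        intensity to tumor and non-tumor channel sums."""
        seq = fresh_sequence()
        if template is not None:
            is_phos = bool(template["positions"])
            n_sites = len(template["positions"])
            abundance = template["base_abundance"]
        else:
            is_phos = master.random() < config.phospho_fraction
            n_sites = 2 if (is_phos and master.random() < config.multi_site_fraction) else 1
            abundance = float(
                np.exp(master.normal(config.log_abundance_mean, config.log_abundance_sd))
            )
        positions: tuple[int, ...] = ()
        if is_phos:
            acceptors = [i + 1 for i, aa in enumerate(seq) if aa in _PHOSPHOACCEPTORS]
            while len(acceptors) < n_sites:  # inject an acceptor residue
                pos = int(master.integers(0, len(seq) - 1))
                seq = seq[:pos] + "S" + seq[pos + 1:]
                acceptors = [i + 1 for i, aa in enumerate(seq) if aa in _PHOSPHOACCEPTORS]
            positions = tuple(
                sorted(int(p) for p in master.choice(acceptors, size=n_sites, replace=False))
            )
        accessions = (acc,)
        if not is_phos and template is None and master.random() < config.shared_peptide_fraction:
            other = str(master.choice([p for p in proteins if p != acc]))
            accessions = (acc, other)
        return dict(
            sequence=seq, positions=positions, accessions=accessions,
            base_abundance=abundance,
        )

    protein_peptides: dict[str, list[dict]] = {}
    if config.mirrored_regulation:
        # proteins built in structure-identical pairs (odd leftover is null)
        for i in range(0, config.n_proteins - 1, 2):
            acc_a, acc_b = proteins[i], proteins[i + 1]
            n_pep = 1 + int(master.poisson(max(config.peptides_per_protein_mean - 1.0, 0.0)))
            protein_peptides[acc_a] = [make_peptide(acc_a) for _ in range(n_pep)]
            protein_peptides[acc_b] = [
                make_peptide(acc_b, template=t) for t in protein_peptides[acc_a]
            ]
        if config.n_proteins % 2:
            acc = proteins[-1]
            n_pep = 1 + int(master.poisson(max(config.peptides_per_protein_mean - 1.0, 0.0)))
            protein_peptides[acc] = [make_peptide(acc) for _ in range(n_pep)]
    else:
        for acc in proteins:
            n_pep = 1 + int(master.poisson(max(config.peptides_per_protein_mean - 1.0, 0.0)))
            protein_peptides[acc] = [make_peptide(acc) for _ in range(n_pep)]
    for acc in proteins:
        peptides.extend(protein_peptides[acc])

    # --- ground-truth fold changes ---------------------------------------
    if config.mirrored_regulation:
        base_vals = np.zeros(config.n_proteins)
        n_pairs = config.n_proteins // 2
        pair_reg = master.random(n_pairs) < config.regulated_fraction
        for pi_, is_reg in enumerate(pair_reg):
            if is_reg:
                base_vals[2 * pi_] = config.regulated_fc
                base_vals[2 * pi_ + 1] = -config.regulated_fc
        protein_base = pd.Series(base_vals, index=proteins)
    else:
        signs = np.where(
            master.random(config.n_proteins) < config.fc_positive_prob, 1.0, -1.0
        )
        regulated = master.random(config.n_proteins) < config.regulated_fraction
        protein_base = pd.Series(
            np.where(regulated, signs * config.regulated_fc, 0.0), index=proteins
        )
    protein_fc = pd.DataFrame(
        protein_base.values[:, None]
        + master.normal(0.0, config.case_effect_sd, size=(config.n_proteins, len(cases))),
        index=proteins,
        columns=list(cases),
    )
    phospho_keys, phospho_base_vals, phospho_rows = [], [], []
    for pep in peptides:
        if not pep["positions"]:
            continue
        key = feature_key(pep["sequence"], pep["positions"])
        site_reg = master.random() < config.site_regulated_fraction
        site_sign = 1.0 if master.random() < config.fc_positive_prob else -1.0
        site_effect = site_sign * config.site_fc if site_reg else 0.0
        acc = pep["accessions"][0]
        phospho_keys.append(key)
        phospho_base_vals.append(protein_base[acc] + site_effect)
        phospho_rows.append(protein_fc.loc[acc].values + site_effect)
        pep["truth_row"] = phospho_rows[-1]
    phospho_fc = pd.DataFrame(phospho_rows, index=phospho_keys, columns=list(cases))
    phospho_base = pd.Series(phospho_base_vals, index=phospho_keys, dtype=float)
    for pep in peptides:
        if not pep["positions"]:
            acc = pep["accessions"][0]
            pep["truth_row"] = protein_fc.loc[acc].values

    # per-(plex, channel) loading bias
    bias: dict[tuple[str, str], float] = {}
    for plex in design.plexes:
        for ch in design.channels(plex):
            bias[(plex, ch)] = (
                float(np.exp(master.normal(0.0, config.channel_bias_sd)))
                if config.channel_bias_sd > 0
                else 1.0
            )

    # --- PSM emission per (plex, arm) stream ------------------------------
    records: list[PSMRecord] = []
    case_index = {c: i for i, c in enumerate(cases)}
    n_pep = len(peptides)
    is_phospho = np.array([bool(p["positions"]) for p in peptides])
    for pi, plex in enumerate(design.plexes):
        channels = design.channels(plex)
        channel_cases = [design.case_of(plex, ch) for ch in channels]
        for ai, arm in enumerate(ARMS):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(config.seed), 1 + pi, ai])
            )
            rates = np.where(
                is_phospho,
                config.phospho_rates.get(arm, 0.0),
                config.nonphospho_rates.get(arm, 0.0),
            )
            seen = np.zeros(n_pep, dtype=bool)
            counter = 0
            for run in range(1, config.n_runs + 1):
                if config.deterministic_psm_counts:
                    counts = np.rint(rates).astype(int)
                    counts[(rates > 0) & (counts == 0)] = 1
                else:
                    counts = rng.poisson(rates)
                if run == 3 and config.rejection_list_emulation:
                    counts[seen] = 0
                for j in np.nonzero(counts)[0]:
                    pep = peptides[j]
                    truth_row = pep["truth_row"]
                    for _ in range(int(counts[j])):
                        counter += 1
                        psm_scatter = (
                            float(np.exp(rng.normal(0.0, config.psm_abundance_sd)))
                            if config.psm_abundance_sd > 0
                            else 1.0
                        )
                        low_conf = rng.random() < config.low_confidence_rate
                        q = (
                            float(rng.uniform(0.05, 0.5))
                            if low_conf
                            else float(rng.uniform(0.0005, 0.049))
                        )
                        prs = None
                        if pep["positions"]:
                            poor_loc = rng.random() < config.poor_localization_rate
                            prs = (
                                float(rng.uniform(0.0, 0.75))
                                if poor_loc
                                else float(rng.uniform(0.751, 1.0))
                            )
                        intensities: dict[str, float | None] = {}
                        for ch, (case, tissue) in zip(channels, channel_cases):
                            fc = float(truth_row[case_index[case]])
                            signed = 0.5 * fc if tissue == "T" else -0.5 * fc
                            noise = (
                                float(np.exp(rng.normal(0.0, config.noise_sigma)))
                                if config.noise_sigma > 0
                                else 1.0
                            )
                            intensities[ch] = (
                                pep["base_abundance"] * psm_scatter
                                * float(2.0**signed) * bias[(plex, ch)] * noise
                            )
                        if rng.random() < config.missing_channel_rate:
                            drop = str(rng.choice(channels))
                            intensities[drop] = None
                        records.append(
                            PSMRecord(
                                psm_id=f"{plex}:{arm}:r{run}:{counter:06d}",
                                sequence=pep["sequence"],
                                phospho_positions=pep["positions"],
                                protein_accessions=pep["accessions"],
                                plex=plex,
                                arm=arm,
                                fraction=_home_fraction(pep["sequence"], config.n_fractions),
                                run=run,
                                q_value=q,
                                phosphors_probability=prs,
                                intensities=intensities,
                            )
                        )
                    seen[j] = True
    truth = SyntheticTruth(protein_fc, phospho_fc, protein_base, phospho_base, config)
    return SimResult(records, design, truth, config)


def write_dataset(result: SimResult, out_dir) -> None:
    """Write the dataset as TSVs (one PSM table per plex, design, truth)
    plus the configuration echoed as YAML."""
    import pathlib

    import yaml

    from .design import write_design
    from .psm import write_psm_table

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_design(result.design, out / "design.tsv")
    for plex in result.design.plexes:
        subset = [r for r in result.records if r.plex == plex]
        write_psm_table(subset, out / f"psms_{plex}.tsv", result.design)
    result.truth.protein_fc.to_csv(out / "truth_protein_fc.tsv", sep="\t", index_label="accession")
    result.truth.phospho_fc.to_csv(out / "truth_phospho_fc.tsv", sep="\t", index_label="feature_key")
    with open(out / "sim_config.yaml", "w") as fh:
        yaml.safe_dump(asdict(result.config), fh, sort_keys=True)


def truth_evaluation(
    recovered: pd.DataFrame,
    truth_fc: pd.DataFrame,
    significant: pd.Series | None = None,
    regulated: pd.Series | None = None,
) -> dict:
    """Recovery metrics of pipeline output against ground truth.

    *recovered* and *truth_fc* are feature × case matrices; metrics are
    computed over cells present in both.  If per-feature significance calls
    and true regulation flags are given, a confusion matrix with
    sensitivity and false-discovery rate is added.
    """
    common = recovered.index.intersection(truth_fc.index)
    if len(common) == 0:
        raise SimulationError("no overlapping features between output and truth")
    cols = recovered.columns.intersection(truth_fc.columns)
    rec = recovered.loc[common, cols].to_numpy(dtype=float)
    tru = truth_fc.loc[common, cols].to_numpy(dtype=float)
    mask = np.isfinite(rec) & np.isfinite(tru)
    err = rec[mask] - tru[mask]
    metrics = {
        "n_features": int(len(common)),
        "n_cells": int(mask.sum()),
        "bias": float(err.mean()) if err.size else float("nan"),
        "rmse": float(np.sqrt((err**2).mean())) if err.size else float("nan"),
        "max_abs_error": float(np.abs(err).max()) if err.size else float("nan"),
    }
    if significant is not None and regulated is not None:
        idx = common.intersection(significant.index).intersection(regulated.index)
        sig = significant.loc[idx].astype(bool)
        reg = regulated.loc[idx].astype(bool)
        tp = int((sig & reg).sum())
        fp = int((sig & ~reg).sum())
        fn = int((~sig & reg).sum())
        tn = int((~sig & ~reg).sum())
        metrics.update(
            tp=tp, fp=fp, fn=fn, tn=tn, n_evaluable=int(len(idx)),
            sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
            fdr=fp / (tp + fp) if tp + fp else float("nan"),
        )
    return metrics
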