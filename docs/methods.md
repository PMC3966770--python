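# Methods

This note records the modelling assumptions, parameter choices and known
limitations behind `phosphoquant`.  It complements the README's overview of
the quantification chain.

## Experimental design model

A TMT 8-plex carries tumor (T) and non-tumor (NT) peptides from four cases
on eight reporter channels; a case appears in exactly one plex, once per
tissue.  The design table is the single source of pairing: every ratio in
the package is `log2 I(T channel) − log2 I(NT channel)` for a case's two
channels, so exchanging the T/NT assignment of a case negates all of its
ratios at every level (a tested invariant).  Channel labels are opaque
strings; the 6-mDa isotopologue pairs (127e/127, 129e/129) are assumed
resolved upstream by the search engine.

Three preparation arms are modelled — `non_enriched`, `tio2`, `imac` — and
treated as parallel measurements of the same mixture.  Fractions and runs
are pooled within an arm for quantification: fractions are disjoint peptide
populations of one labelled mixture and the loading bias being corrected is
channel-wise per mixture, so per-fraction normalization groups (available
behind `grouping="plex_arm_fraction"`) add variance without addressing any
additional bias term.

## Filtering

Retain a PSM iff `q < 0.05` AND (non-phospho OR `pRS > 0.75`) AND all eight
reporter channels present with strictly positive intensity.  Both stated
boundaries are rejections ("at or above 5% FDR", "at or below 75%"), and an
intensity of exactly 0 counts as a missing reporter peak — a peak that is
not visible has no area, and admitting zeros would put −∞ into the log
ratios.  Rejection reasons are evaluated in the fixed order confidence →
localization → channels so the log is deterministic; only the first failing
rule is recorded.

## Sum-scaling and its compositional limit

Within a normalization group, channel `c` is multiplied by
`target / S(c)`, with `S(c)` the channel total and `target` the mean of
the eight totals by default.  Two algebraic facts matter:

* a pure per-channel multiplicative bias `b(c)` cancels **exactly** in
  every between-channel ratio (the `target` shift is common to the group),
  and cancels exactly in the intensities themselves when an explicit fixed
  `target_sum` is supplied;
* the factors are estimated **from the data**, so when regulation is
  abundance-unbalanced (more up- than down-regulated intensity, or vice
  versa) the factors absorb part of the signal and every ratio in a case
  shifts by a common constant `log2(S_NT/S_T)`.  This compositional bias is
  a property of sum-scaling itself, not of this implementation; it shrinks
  as the catalog grows and regulation stays sparse and sign-balanced, and
  it is why the fold-change recovery checks require the mean signed error
  below 0.05 rather than exact agreement on noisy data.

The noise-free exactness check uses `SimConfig.noise_free()`, which
generates regulated proteins in ±fc mirror pairs with identical peptide
structure, abundance and (deterministic) PSM counts.  Clean channel sums
are then balanced by construction, the factors are exactly 1, and the whole
chain must return every true fold change to machine precision — an
end-to-end exactness test of the pipeline under the normalization's own
model assumption.

## Aggregation conventions

* Medians of even counts are the arithmetic mean of the two central values.
* Every PSM row is one observation: charge states or repeated spectra of
  one peptide are not collapsed before the median.
* Peptide features are keyed by sequence plus the sorted phospho-position
  set, so positional isoforms are distinct features; non-phospho peptides
  key on bare sequence.  Modifications other than phosphorylation do not
  enter feature identity.
* Protein ratios use only non-phospho peptides mapping to a single
  accession; shared peptides contribute to no protein.  Arm-level protein
  medians are computed first and arms merged afterwards, with the cross-arm
  combination being the median (a mean is available via `merge_how="mean"`;
  with one or two arm values present the two conventions coincide or
  differ only through the even-count rule).
* Phospho-to-protein normalization subtracts merged protein from merged
  phosphopeptide ratios per case, and is undefined (absent) when the
  protein has no non-phospho peptide ratio — absence always propagates,
  never coerces to zero.

## One-sided testing and calibration

Per feature and arm, the case ratios are tested against zero with a
one-sample t-test.  The pipeline default reports the one-sided p in the
direction of the observed mean, `p = P(T_{n−1} ≥ |t|)`, which is what a
volcano that calls both up- and down-regulation implies.  **This convention
halves the two-sided p**: under the null the rate of `p ≤ 0.05` is 5% per
direction, 10% combined.  Calibration checks therefore use a fixed
direction (`direction="greater"`), whose null p is uniform; the null
simulation confirms the 5% rate within the binomial band.  Features
quantified in fewer than two cases get no p-value; zero-variance nonzero
means report the smallest positive double with a `zero_variance` flag.

Significance is the joint volcano rule with inclusive boundaries:
`|median log2 T/NT| ≥ 0.3` (protein) or `≥ 0.75` (phosphopeptide) and
`p ≤ 0.05`.  Calls are made per arm; the headline count is the union
(significant in at least one arm).  No multiple-testing correction is
applied at feature level; Benjamini–Hochberg adjustment is used only inside
gene-set enrichment, where the EASE variant (one hit removed from the
overlap, floored at zero) is the default.

## Multivariate QC

NIPALS extracts components one at a time so every inner product can skip
missing cells pairwise — the ratio matrix has structural absences.  Data
are mean-centered only by default (unit-variance scaling behind a flag);
sign is fixed by making the largest-magnitude loading positive; explained
variance is the observed-cell sum of squares of each rank-1 reconstruction
over the total centered sum of squares.  The Hotelling limit is
`k(n−1)/(n−k)·F_{1−α}(k, n−k)`.

Two QC matrices are wired into the pipeline.  The intensity analysis uses
one row per (plex, arm, channel) sample labelled by tissue; its variables
are peptide features with each cell the median log2 intensity of the
feature's PSMs in that plex and arm.  Aggregating to features (rather than
raw PSM columns) lets variables align across plexes — a PSM exists in
exactly one plex, so a PSM-level cross-plex matrix is two-thirds
structurally missing per column; the PSM-level builder remains available
via `intensity_matrix(..., level="psm")`.  The ratio analysis runs
unsupervised on the cases × merged-phosphopeptide-ratio matrix.

## Synthetic-data generator

The generator emulates the paired-tissue study structure: 3 plexes × 8
channels (4 paired cases each), three arms, 12 SCX fractions, three runs
with the third run drawing only features unseen in the first two of the
same (plex, arm) stream.  Intensities follow

    I = base · psm_scatter · 2^(±fc/2) · bias(c) · e^N(0, σ)

with the tissue effect split symmetrically (±fc/2) so a feature's total
abundance is fold-change invariant.  Defaults and their reasoning:

| parameter | default | why |
|---|---|---|
| `phospho_fraction` | 0.22 | phosphopeptide share of unique peptides in deep paired-tissue TMT studies |
| `phospho_rates` (imac/tio2/non) | 1.5/0.6/0.15 PSM·peptide⁻¹·run⁻¹ | IMAC dominates phosphopeptide yield, TiO₂ contributes a smaller partially-overlapping set, enrichment depletes them from the non-enriched arm |
| `nonphospho_rates` | 0.4/0.4/1.5 | mirror image for unmodified peptides |
| `noise_sigma` | 0.25 | lognormal reporter noise (natural-log units) giving per-PSM ratio scatter of ≈0.5 log2 units |
| `psm_abundance_sd` | 0.5 | between-spectrum sampling depth scatter; cancels in ratios |
| `channel_bias_sd` | 0.15 | per-channel loading/labelling bias that sum-scaling must remove |
| `log_abundance_mean/sd` | 13.0/1.2 | heavy-tailed base abundances on a realistic reporter-intensity scale |
| contamination rates | 0.05/0.05/0.02 | low-confidence IDs, poorly localized sites, missing channels |

Per-case truth tables are stored for every protein and phosphosite
feature (site effects add to the protein effect), and one RNG stream per
(plex, arm) spawned from the master seed keeps sub-datasets individually
reproducible.

What the generator does **not** model: retention time and isotopic
envelopes, co-isolation interference between reporter channels, charge
states, decoy/target score distributions, and real SCX elution chemistry
(the fraction is a deterministic sequence hash).  Passing tests on this
generator demonstrate the correctness and calibration of the analysis
chain, not robustness to those instrument-level artefacts.

## Problem sizes and numerical choices

Validation runs use desk-scale catalogs chosen to make the statistical
bands meaningful: calibration and recovery checks simulate 600 proteins at
a 0.9 phospho fraction, giving ≈2,200 phosphopeptide features and ≈36,000
PSMs across 12 cases, where the ±3·SE binomial band on the 5% rejection
rate is ±1.4 points; exactness and invariance checks use smaller catalogs
since their tolerances are machine-precision.  NIPALS convergence is
`‖t_new − t‖ ≤ 10⁻¹² ‖t_new‖` with a 2,000-iteration cap (raised for
oracle comparisons where eigenvalue gaps of random matrices can be tiny);
ties in the significance boundaries are inclusive by the volcano rule;
intensity cells absent from a TSV stay absent through every stage.

## Known limitations

* Sum-scaling's compositional bias under abundance-unbalanced regulation
  (above) — common per-case offsets on the order of 0.01–0.03 log2 units
  at desk scale.
* The per-arm t-test treats cases as exchangeable replicates; plex effects
  beyond channel loading are assumed removed by within-plex ratios.
* Enrichment is a Fisher/EASE surrogate over user-supplied gene sets; it
  does not reproduce any external annotation service's curated background.
* PLS-DA on the intensity matrix is a QC device; no cross-validated
  component selection or outlier rejection is automated.
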