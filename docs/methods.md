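# Methods

This note documents the statistical models behind `evsubtype`, the defaults
and why they were chosen, what the synthetic-data generator does and does not
emulate, and the design decisions taken where more than one reasonable choice
existed.

## Data model and preprocessing

**Peptide tables.** Input is MaxQuant-style label-free quantification: one
row per peptide, a gene-symbol protein column, one linear-scale intensity
column per EV isolation. Zero or blank entries are treated as *not detected*
— LFQ zeros are censoring events, not measurements — and the pre-imputation
detection mask is carried through the whole pipeline so that detection-based
statistics (consensus Venn counts, the ≥ 2-peptide detection call) never see
imputed values.

**Left-censored imputation.** Undetected cells are drawn from `N(q, s²)` on
the log2 scale and back-transformed, where `q` is the 1% quantile of all
detected log2 intensities pooled over samples and `s` is the median over
peptides (with ≥ 2 detected values) of the per-peptide SD of detected log2
intensities. The low centre encodes the missing-not-at-random assumption:
intensity-dependent censoring implies a missing peptide most likely sat below
the detection limit. The quantile is computed globally by default — the
per-sample variant is available via `RunConfig.impute_per_sample` — and
`impute_quantile` defaults to 0.01.

**Aggregation.** Protein intensity is the arithmetic mean of its peptides'
linear intensities, computed after imputation so every peptide contributes in
every sample. Proteins backed by fewer than `min_peptides = 2` peptides are
dropped; the retained peptide counts are carried in the output for auditing.

**Variance-stabilising normalisation.** The calibration model is the
additive–multiplicative error model: `x = a_i + b_i e^η μ + ε` with
multiplicative noise η and additive noise ε. The transform
`t_pi = arcsinh((x_pi − a_i)/b_i)` then has approximately constant variance
across the intensity range. Parameters are fitted by minimising the negative
profile log-likelihood

```
(N/2)·log SSR(t) + ½ Σ log(b_i² + (x − a_i)²)
```

where SSR is the pooled within-protein sum of squared residuals (protein
means and the common variance are profiled out) and the second term is the
log-Jacobian of the transform. Numerics: `b` is optimised as `log b` (never
non-positive), offsets are optimised in units of the median intensity with
box bounds so the quasi-Newton (L-BFGS-B, analytic gradient) line search
stays stable, and the first sample in design order is fixed at `(a=0, b=1)`
because the model is invariant under a common affine change of all
calibrations. Convergence: relative objective change < 1e-8 or 100 outer
iterations.

*Robustness.* Each outer iteration refits after discarding the `trim`
fraction of proteins with the largest within-protein residuals
(least-trimmed-squares). The default is `trim = 0.25`. This is deliberately
larger than the traditional 10%: in a three-subtype design with disjoint
marker programmes, the genuinely differential share of the proteome can
reach 20–25%, and a trim below that share leaves enough structured proteins
in the fit that the per-sample calibrations absorb part of the subtype
signal. The visible symptom is not poor variance stabilisation but small
coherent between-group shifts of *all* proteins, which inflate the observed
false discovery rate of the downstream volcano tests well past the nominal
level. With the trim above the differential share the calibration is driven
by the non-differential majority and FDR control is restored. The fraction
remains exposed in `RunConfig.vsn_trim` for cohorts with different amounts
of structure.

*Identifiability of the offsets.* The profile likelihood is nearly flat
along the direction `a_i → a_i + c·b_i` (for large intensities the
transform degenerates to `log`, where an offset is invisible); the gauge
sample pins this direction only weakly. Consequently the scale ratios
`b_i/b_ref` are estimated sharply (≈ 1% relative error at 2000 proteins)
while offsets are only recovered to a few additive-noise SDs. Calibration
recovery should therefore be judged on the scales and on the mean–variance
diagnostic, not on the offsets. Recovery is also only a clean experiment on
cohorts without left-censoring: the imputation stage (by design, following
the analysis order impute → aggregate → normalise) fills censored cells
with globally-centred draws that do not carry the per-sample distortion,
which corrupts the low-intensity region where calibration information
lives.

## Structure summaries

Hierarchical clustering uses average linkage (UPGMA) on `d = 1 − Pearson r`
between profiles; items are sorted lexicographically before linkage so
equal-distance merges resolve deterministically, and zero-variance items are
assigned correlation 0 (distance 1) and flagged. PCA projects samples after
per-protein centring. Consensus detection per subtype ("found in every EV
isolation of the subtype") feeds three-set Venn region counts, with the
all-subtype core also reported as a percentage of all proteins in the
detection matrix.

## Signature scores

The **summative z-score** of a gene set z-scores each found gene across the
cohort's samples, sums the z's per sample and min–max rescales the sums to
[0, 1], so 0/1 mark the cohort's extremes; the score is invariant to
per-gene affine rescaling of the input. Degenerate cases (all raw scores
equal) return 0.5 for every sample plus an explicit flag rather than NaN, so
report tables stay rectangular and honest. Replicate averaging
(`mean-of-replicates`) pools the raw sums per cell line *before* rescaling.
Coverage — genes found / signature size — is recorded with every score.

The **neuroendocrine score** is the Pearson correlation (Spearman optional)
between a sample's z-scored levels over the NE-set genes and a reference
NEPC profile restricted to the same genes, requiring ≥ 3 overlapping genes.
Because cross-sample z-scoring removes each gene's baseline, the reference
must itself be a *differential* profile (how much each gene deviates in
NEPC), not absolute abundances; the reference is user-supplied, and the
pipeline driver builds a cohort-internal analogue (mean z-profile of the
NE+ isolations) when none is given.

## Differential enrichment and biomarkers

Per protein, a Welch two-sample t-test on glog values compares one subtype
against the rest (three contrasts: AR+ vs AR−, AR−/NE− vs rest, AR−/NE+ vs
rest); q-values are Benjamini–Hochberg over all tested proteins (Storey's
π₀-corrected variant is a config option) with significance at q < 0.05.
Welch rather than pooled-variance is used because subtypes are expected to
be heteroscedastic; moderated (empirical-Bayes) tests were deliberately left
out of scope. A protein with identical values everywhere gets p = 1, never
NaN.

Ternary subtype fractions are computed on the *linear*-scale aggregated
matrix (percent-of-signal needs non-negativity; the glog matrix is refused):
`f_s = 100·m_s/Σ m_s` with `m_s` the subtype mean, plus a protein-count
density on a triangular grid with 6 divisions per edge. Fractions are
invariant to global positive rescaling and each protein lands in exactly
one density bin.

Subtype biomarker signatures pass three audited filters: (1) significantly
enriched in the subtype's contrast (ordered by q, then |mean difference|);
(2) present in the patient protein matrix ("patient-detected" means present
as a row — that cohort's detection filtering is assumed upstream); (3) not
on the healthy-plasma EV list. All three counts are reported, and
`n₁ ≥ n₂ ≥ n₃` holds by construction. Patient subtype scores average each
signature protein's z-score across patients (raw-mean option available);
empty signatures yield missing scores rather than errors.

## GSEA

Ranking uses the signal-to-noise metric `(μ_A − μ_B)/(s_A + s_B)` with each
group SD floored at `max(0.2·|μ|, 0.2)` — the desktop tool's convention, not
a choice made here — sorted descending with lexicographic tie-break. The
enrichment score is the signed extremum of the weighted running sum: hits
advance by `|r|^w` normalised over the set's hits (uniform steps if all hit
metrics are zero), misses retreat by `1/(N − N_hits)`; at `w = 0` this is
exactly the classical KS statistic on hit positions, an equality the tests
assert to 1e-12. The null is **gene_set permutation**: random same-size gene
sets drawn without replacement from the ranked universe, appropriate when a
handful of samples cannot support phenotype permutation; 100 permutations by
default. Each set gets an independent RNG substream keyed by (master seed,
CRC32 of the set name), so results do not depend on how many or which other
sets are tested. The nominal p uses same-sign nulls with a +1 pseudocount
(floor `1/(1 + n_same_sign)`); NES divides ES by the mean magnitude of
same-sign nulls; FDR follows the sign-stratified NES-pooling of the original
method, with BH on nominal p as the simpler config alternative.

## Synthetic cohorts and what they do (not) show

`simulate_cellline_cohort` emulates the study design: 9 cell lines (4 AR+,
3 AR−/NE+, 2 AR−/NE−) × 2 replicate EV isolations, 2000 proteins with
log-normal abundance (log2 mean 10, SD 1.5), `Poisson(4)+1` peptides per
protein with a per-peptide efficiency (log2 SD 0.7) shared across samples,
150 disjoint marker proteins per subtype shifted +δ = 1.5 log2 units in
their subtype, Rocke–Durbin noise (σ_add = 30 intensity units,
σ_mult = 0.15), optional per-sample affine distortions `(a_i, b_i)`, and
logistic intensity-dependent detection (midpoint m0 = 7 log2 units, scale
k = 1, ≈ 10% censored cells at the defaults). `simulate_patient_cohort`
builds 27 plasma profiles as Dirichlet-weighted mixtures of the three
subtype mean profiles plus a boosted plasma-background component whose
proteins are a subset of the healthy-plasma list by construction, with
logistic dropout so the patient cohort covers only part of the cell-line
proteome. `simulate_ne_reference_cohort` provides the dedicated construction
for the correlation score: samples that equal a heterogeneous reference
profile plus small noise versus independent background samples.

The generator does **not** emulate: peptide sequences or spectra, shared
peptides between proteins, correlated protein programmes beyond the planted
markers, batch effects, inter-patient biology beyond mixture weights, or
isoform-level ambiguity. Passing recovery tests therefore demonstrates that
the *statistical machinery* is correct under its stated model — not that
real EV data meet those assumptions.

Problem sizes used by the test suite and the acceptance script (2000
proteins for the main cohort, 400-protein cohorts × 20 replicates for the
null-FDR check, 50 decoy sets × 100 permutations for GSEA) were chosen as
the smallest sizes at which the recovery statistics are stable; they mirror
the study scale rather than the full deposited dataset.

## Known limitations

- VSN offsets are weakly identified (see above); only scale ratios should be
  interpreted.
- BH q-values assume independence or positive dependence across proteins;
  imputation introduces weak dependence that the null-calibration test
  bounds empirically but does not model.
- The gene_set permutation null conditions on the observed ranking, so NES
  values are comparable within a contrast but not across datasets.
- The ternary density uses fraction floors to assign boundary points, which
  puts simplex lattice points into the adjacent upward triangle by
  convention.
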