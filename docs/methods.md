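# Methods

`timascan` implements a blood-based assay pipeline for detecting brain-tissue
damage from monocytes that carry the astrocytic protein GFAP (and, as a second
tissue marker, the myelin protein PLP1) in their phagolysosomes. The pipeline
has five analytic stages — hierarchical gating, rare-event positivity calling,
per-sample quantification, diagnostic cutoff derivation/validation, and
prognostic/monitoring analyses — plus a synthetic cytometry cohort generator
that provides ground truth for every stage.

## Gating model

Events are gated on a fixed, configuration-defined tree with half-open
rectangular bounds `[low, high)` (and one convex-polygon singlet band), in
consecutive stages:

1. **Singlets** — FSC-A vs FSC-H band `|FSC-H − a·FSC-A| ≤ b` (defaults
   a = 0.95, b = 180); doublets sit near half the singlet ratio.
2. **Debris exclusion** — FSC-A lower bound (default 200).
   Events failing stages 1–2 are labelled `debris_doublets_excluded`.
3. **Leukocyte/monocyte scatter region** — FSC-A × SSC-A rectangle; high-SSC
   granulocytes fall outside and stay ungated (they play no role in the assay).
4. **CD45+** — CD45 lower bound.
5. **Lymphocytes** — CD45-high/SSC-low and HLA-DR⁻CD300e⁻. Lymphocytes are
   retained because they are the assay's internal negative control.
6. **Monocytes** — HLA-DR+ then CD300e+; HLA-DR+CD300e⁻ events are dendritic
   cells.
7. **CD300e vs CD14 confirmation** region.
8. **Subsets** on CD14 vs CD16: classical (CD14+CD16⁻), intermediate
   (CD14+CD16+), non-classical (CD14⁻CD16+). "CD16+ monocytes" always means
   intermediate ∪ non-classical.

Gates are static: no clustering or data-driven adjustment is performed, so
gating is a deterministic function of the event table and the gate
configuration, and the configuration hash is recorded in every output. The
CD14⁻CD16⁻ corner of the subset quadrant is left ungated; the reported
monocyte count is defined as the sum of the three subset counts, which makes
the subset partition exact by construction.

All gating coordinates live on the analysis scale: fluorescence channels are
`asinh(x / cofactor)`-transformed (cofactor 150, configurable), scatter stays
linear. The gating outcome is invariant under any strictly monotone
re-scaling applied jointly to a channel and its gate bounds (property-tested).
Because the display transform used during the original manual analysis is not
knowable, the transform setting is part of output provenance.

## Rare-event positivity

GFAP/PLP1 positivity is called per sample against the fluorescent background
of that sample's own gated lymphocytes: the threshold is the empirical
type-7 quantile (default q = 0.995) of the lymphocyte marker intensities, and
an event is positive iff its intensity is strictly above the threshold
(boundary events negative — conservative for a rare-event assay). At least
500 gated lymphocytes are required; otherwise the sample is flagged rather
than silently thresholded.

This construction implies an expected false-positive floor of 1 − q (0.5% at
the default) in any population whose marker-negative background matches the
lymphocytes'. Reported percentages are raw (no background subtraction) by
default; the background-corrected estimator

    f̂ = (m − (1 − q)) / q,   m = measured positive fraction

inverts `m = f + (1 − f)(1 − q)` and is available via
`monocyte_profile(..., background_correct=True)`. Note an irreducible
consequence: for true fractions comparable to 1 − q, the corrected
estimator's variance exceeds the binomial variance of the true fraction by a
factor ≈ (f + (1 − q))/f, regardless of how many events are acquired.

## Per-sample metrics

`monocyte_profile` reduces a gated, positivity-labelled sample to:
subset fractions; `pct_gfap_cd16` (% GFAP+ among CD16+ monocytes — the
diagnostic score); `pct_gfap_nonclassical` (% GFAP+ among CD14⁻CD16+
monocytes — the prognostic marker); PLP1 and dual-positive analogues; and
absolute counts `(population events / leukocyte events) × WBC` in cells/µl,
where leukocyte events are the post-singlet, post-debris events. Absent WBC
counts leave absolute fields missing, never zero. CD16+ denominators below
100 events raise a low-confidence flag instead of failing, mirroring
leukopenic clinical samples.

## Diagnostic cutoff

Per-patient scores (first sample per patient) are split at patient level:
a stratified random `train_fraction` (default 33%) of lesion patients trains;
all remaining lesion patients validate. Healthy controls never enter the
training split; since a ROC needs a negative class, the training ROC uses all
healthy controls as negatives, and the same controls then serve in validation
as the described design dictates — a known optimism source, stated in every
report.

The empirical ROC uses candidate thresholds at midpoints between adjacent
distinct scores plus ±∞ sentinels; a positive call is `score ≥ threshold`;
AUC is the rank statistic `(concordant + ½·ties)/(n₊·n₋)`, identical to the
trapezoidal area. The cutoff is the candidate minimizing |sensitivity −
specificity| (ties: larger sensitivity + specificity, then smaller
threshold). Validation reports the 2×2 cross-tabulation, Wilson 95% CIs
(better small-sample behaviour than Wald, which remains available), and
Pearson's chi-square without continuity correction (df = 1).

## Prognostic dichotomization

A continuous-marker Cox screen gates the cutoff scan (p < 0.05, overridable
with `force=True`; every override is visible in the report). The scan walks
candidate cutoffs (unique observed marker values, or a user grid),
dichotomizes at `marker ≥ cutoff`, and keeps candidates where both arms hold
at least `min_arm_fraction` (default 10%) of the cohort and both Kaplan–Meier
medians are defined; among those it maximizes |median₁ − median₀| (ties: the
smaller cutoff). The selected cutoff is evaluated by the Mantel–Cox log-rank
test and by a Cox model adjusted for sex, age, Karnofsky score and tumour
size. The selected-cutoff log-rank p is reported unadjusted, and every result
carries a multiple-testing warning: the scan maximizes over a grid, so the p
value is anti-conservative.

**Identifiability caveat.** The maximal-median-difference objective is flat
in the cutoff above the true change point: restricting the high arm to a
higher cutoff leaves its survival distribution unchanged, while the low arm
is contaminated only gradually. The argmax therefore rides a noise-dominated
plateau, and at a hundred-odd patients with a between-arm hazard ratio near 2
the selected cutoff frequently overshoots the true threshold (the package's
own simulations reproduce this). The scan is implemented exactly as
described; users should treat the located cutoff as exploratory.

Kaplan–Meier estimation and the log-rank test wrap lifelines; the median is
the first time with S(t) ≤ 0.5 (undefined while S stays above 0.5), with a
1e-9 tolerance absorbing float round-off when S hits 0.5 exactly, and events
precede censorings at tied times. Cox regression is a Newton–Raphson partial
likelihood maximizer with Breslow ties by default (Efron available),
internally standardized covariates, a step-halving line search, and a
convergence criterion of gradient norm < 1e-8 relative to the null
log-likelihood magnitude; complete separation and zero-variance covariates
raise errors.

## Stroke monitoring

For acute ischaemic stroke, per-timepoint exceedance of the diagnostic cutoff
(default 0.6%, strict >) is computed over each patient's time course; an
infarct is called large when at least `min_points` (default 2, encoding
"multiple") exceedances occur within `window_hours` (default 8 h) of onset.
Ground-truth large means infarct volume ≥ 100 cm³. Raising the cutoff can
never create a large call (property-tested).

## Synthetic cohort generator

The generator is the package's study-condition definition, not a tuning dial.

* **Event model** — each population (debris, doublets, lymphocytes, three
  monocyte subsets, dendritic cells, granulocytes/other) is a diagonal
  Gaussian on the analysis scale with ≥ 4 SD separation on every gated
  channel; population counts are multinomial; doublets have ≈ 2× singlet
  FSC-A at similar FSC-H. Every GFAP/PLP1-negative event in every population
  draws its marker intensity from the same background distribution
  (N(0.8, 0.25) on the asinh scale) as the lymphocytes — this makes the
  lymphocyte-background rule exact by construction — and marker-positive
  events receive a +2.0 shift (8 background SDs).
* **Cohort model** — each sample's true GFAP+ fraction among non-classical
  monocytes is lognormal per diagnosis group (healthy median 2%, glioma
  grades 4–8.5%, metastasis 9%, σ = 0.8–1.0); the intermediate-subset rate is
  a fixed ratio (0.05) of it. These defaults produce the qualitative group
  ordering of the assay (healthy below gliomas/metastasis) and put roughly
  a fifth of glioblastoma patients above the 20% prognostic threshold; they
  are configuration, not estimates of any dataset.
* **Survival** — two-arm Weibull, shape 2.3, low-arm median 11.8 months and
  hazard ratio 1.96 applied when the true non-classical fraction exceeds the
  prognostic threshold (20%), giving a high-arm median of 8.8 months.
  The shape was fixed once so that this median pair implies the hazard ratio
  observed in the adjusted clinical analysis the assay mirrors. Censoring is
  independent uniform on [0, H], with H solved numerically (Brent on
  E[min(T, H)]/H) so the expected censoring fraction equals the requested
  rate (default 0.30); rate 0 disables censoring.
* **Stroke time courses** — linear rise to a peak (default at 4 h) with
  exponential decay (half-life 10 h); peaks ≈ 1.5–2.2% for the three large
  infarcts, ≤ 0.25% for small ones, and a single early marginal excursion
  (peak 0.75%, half-life 1.5 h) for the two borderline patients, plus
  Gaussian measurement noise (SD 0.05 percentage points).
* Default sample size is 30 000 events (≈ 27 500 leukocytes, satisfying the
  20 000-leukocyte QC default; ≈ 1 300 CD16+ monocytes). A real acquisition
  aiming at rare-fraction precision would collect more CD16+ events; the
  default trades precision for runtime, and the measurement noise it implies
  is visible in the validation sensitivity/specificity the pipeline reports.

What the generator does **not** emulate: spectral spillover/compensation,
acquisition drift, non-Gaussian population shapes, correlated marker
backgrounds, doublet mixtures of unlike cell types, informative censoring,
and any real between-patient covariance structure. Passing tests therefore
demonstrate internal correctness and statistical calibration of the methods
— not clinical performance on real cytometry data.

## Metadata column dictionary

`read_cohort_metadata` expects a CSV with one row per sample:

| column | type / units | notes |
|---|---|---|
| `sample_id` | text, unique | required |
| `patient_id` | text | defaults to `sample_id` |
| `diagnosis_group` | one of `WHO-I`, `diffuse-astrocytoma`, `oligodendroglioma`, `GBM`, `metastasis`, `other-tumour`, `healthy`, `AIS` | required |
| `age` | years | |
| `sex` | `M`/`F` | |
| `kps` | integer 0–100 | Karnofsky Performance Score |
| `dexamethasone_use` | boolean | use in the days before sampling |
| `dexamethasone_dose` | mg/day | |
| `tumour_diameter_1..3` | cm | broadest diameter in three directions |
| `tumour_size` | cm | derived as the mean of the three diameters |
| `wbc_count` | leukocytes/µl | enables absolute counts |
| `plasma_gfap` | µg/l | optional |
| `os_months`, `os_event` | months ≥ 0, boolean | overall survival |
| `pfs_months`, `pfs_event` | months ≥ 0, boolean | optional |
| `hours_since_onset` | hours | stroke samples only |
| `infarct_volume` | cm³ | stroke patients only |
| `sampling_timing` | `pre-operative`/`per-operative` | |

Event CSVs carry one column per channel (analysis scale), optionally
`truth_label`, `truth_gfap`, `truth_plp1` from the simulator. FCS 3.1 files
hold raw linear intensities; the reader applies the configured transform.

## Known limitations

* FCS support covers list-mode float data with `$PnN` names — sufficient for
  this pipeline's round trip and for typical compensated exports, not a
  general-purpose FCS implementation.
* Fixed gates assume the instrument setup the configuration was written for;
  real data need per-panel gate coordinates.
* The diagnostic validation re-uses healthy controls seen by the training
  ROC (see above).
* The prognostic scan's selected cutoff is exploratory (see the
  identifiability caveat); the log-rank p at the selected cutoff must not be
  read as confirmatory.
* Progression-free survival runs through the identical machinery by passing
  `pfs_months`/`pfs_event`; no bespoke handling exists.
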