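# Methods

## The index and the stratification rule

Intrathecal CXCL13 production is quantified by the CXCL13 index
`I = (CXCL13_CSF/CXCL13_serum) / (albumin_CSF/albumin_serum)`. Dividing by
the albumin quotient corrects for blood–CSF barrier permeability: albumin
is synthesised only peripherally, so its CSF/serum ratio measures passive
protein transfer, and normalising by it isolates the intrathecally produced
CXCL13 fraction. The index is dimensionless and invariant under any common
rescaling of the two CXCL13 or the two albumin measurements; consequently
albumin may be supplied in any unit as long as CSF and serum use the same
one (validated via per-field unit tags).

Classification uses fixed clinical cuts, not values estimated from data:
index-high above 30, index-low below 20. When the index cannot be computed
(no serum sample), the CSF concentration alone is classified with
harmonized cuts — high above 14 pg/mL, low below 5 pg/mL — derived in the
motivating series from the empirical relationship between index and CSF
concentration (elevated index never seen below 5 pg/mL, always seen above
14 pg/mL). Two deliberate choices:

- **Ties.** A value exactly equal to a cut is indeterminate. The rule is
  stated with strict inequalities ("above"/"below"), ties are measure-zero
  in continuous data, and treating them as indeterminate is the
  conservative reading. This is this package's decision; the source
  analysis does not state how an exact tie was handled.
- **Precedence.** When both rules are computable the index rule wins; the
  CSF-only path exists only for patients whose index cannot be calculated.

Indeterminate patients (index in [20, 30], or CSF in [5, 14] pg/mL on the
fallback path) are retained in the stratification mapping but excluded from
every group comparison and confusion table.

The stratifier is also exposed as a scikit-learn estimator
(`IndexStratifier`) so it composes with pipelines and parameter search;
`fit` only validates the cuts and records the label set, since nothing is
learned from data.

## Outcomes and diagnostic performance

Binary outcomes over follow-up: CDMS conversion (a second clinical attack
under strict clinical criteria, consumed as a recorded boolean), one or
more clinical attacks, and one or more MRIs showing new lesions. Patients
with no surveillance MRIs count as lesion-negative: this is forced by
reconciling the published per-group MRI category counts (5 low-group
patients with no MRIs, 14 with lesion-free MRIs) with the published
true-negative count of 19 for the lesion outcome.

A positive "test" is index-high membership. Sensitivity tp/(tp+fn),
specificity tn/(tn+fp), PPV and NPV each carry an exact two-sided 95%
Clopper–Pearson interval (beta-quantile form, via statsmodels). The source
tables report no intervals; at n ≈ 37 the intervals are wide and reporting
point estimates alone would overstate precision. A zero denominator yields
a flagged-undefined estimate rather than NaN. Note: the published
sensitivity/specificity columns are consistent with their own TP/FP/TN/FN
counts only if the two rate columns are exchanged; this package reports the
standard definitions computed from the counts.

## Statistical tests

**Fisher exact, two-sided.** Conditioning on the margins, the probability
of each table is hypergeometric; the two-sided p-value sums the
probabilities of all tables with the observed margins whose probability
does not exceed the observed table's. The implementation enumerates the
support with exact integer weights `C(r1,k)·C(r2,c1−k)` (the common
denominator `C(n,c1)` cancels from every comparison), so tie comparison is
exact and the only floating-point operation is the final big-integer
division, which Python rounds correctly. No tie tolerance is therefore
needed, and the implementation agrees with an exhaustive rational-
arithmetic oracle to better than 12 significant digits for every margin
configuration with N ≤ 40 (135,750 tables; verified in the test suite).
This definition — rather than a one-sided test — reproduces the published
group-comparison p-values (0.002 for attacks, 0.048 for OCB). Runtime is
linear in the support size and exact for any cohort-scale table. No
multiple-testing correction is applied, matching the reporting style of the
motivating analysis.

**Test-to-variable assignment.** Fisher for binary variables, Kruskal–
Wallis for continuous/ordinal ones, categorical variables with more than
two levels summarised without a p-value. Kruskal–Wallis (tie-corrected H,
chi-square approximation with k−1 df) and the OLS fit (slope, R², t-test
p) are delegated to scipy behind this module's interface; with two groups
and no ties the KW p equals the two-sided normal-approximation rank-sum p,
which the suite verifies. Pooled-constant data short-circuits to H = 0,
p = 1 (flagged degenerate).

**Rendering.** Percentages to 1 decimal place, medians/IQRs and means/SDs
to 2, p-values to 3 with a "<0.001" floor; significance marks * p<0.05,
** p<0.01, *** p<0.001.

## Synthetic cohort generator

The generator emulates the group-level structure of the motivating cohort
(default sizes 17 high / 20 low / 9 indeterminate):

- **Biomarkers** are log-normal per latent group. Log-medians are the
  published medians (index 67.07 / 5.99; CSF CXCL13 17.83 / 2.02 pg/mL);
  log-spreads are back-solved from the published IQRs assuming
  log-normality, σ = ln(Q3/Q1)/(2·0.6745). Concentrations are positive and
  right-skewed, which a log-normal captures with two parameters.
- **Serum availability** is Bernoulli (7/17 high, 6/20 low), driving the
  CSF-only pathway. When serum is present it is derived from the latent
  index and albumin quotient (serum = CSF/(I·Q_alb)), so the latent group
  is exactly what the index rule recovers up to distributional overlap.
- **Albumin quotient** ~ log-normal, median 0.005 (a typical adult value;
  the source prints none), log-spread 0.35; serum albumin median
  4200 mg/dL.
- **Outcomes** are Bernoulli per group at the published rates (CDMS
  0.824/0.100, attacks 0.529/0.050, OCB 0.941/0.650), independently given
  group — the joint within-patient distribution is not published, so
  real-data correlation between (say) attacks and CDMS conversion is
  understated. Attack-positive patients get 1 + Poisson(0.3) attacks.
- **MRI surveillance**: follow-up = 5-year eligibility floor plus a
  log-normal offset matching the published medians; MRI count Poisson at a
  per-year rate of (published median MRIs)/(published median follow-up)
  (0.63 high, 0.44 low); lesion-positive MRIs Binomial per MRI (0.33 high
  — the published median percent-of-MRIs-with-lesions — 0.02 low); lesion
  totals add Poisson extras on lesion-positive MRIs.
- **TNC** = 4.0 + 0.2·CSF_CXCL13 + N(0, 6.5), truncated at zero and
  rounded to a count. Slope and intercept were fixed first (cells/µL per
  pg/mL, plausible pleocytosis scale); the noise SD was then solved by
  Monte Carlo so the median OLS R² at cohort size 37 sits near the
  published 0.13 (achieved ≈ 0.14–0.15, within the documented acceptance
  band [0.05, 0.25]).
- **Indeterminate patients** draw index ~ U(20, 30) and CSF ~ U(5, 14)
  with mid-range outcome rates; nothing distributional is published about
  them beyond "intermediate activity".
- **Reproducibility**: every patient has an independent RNG substream
  seeded by (master seed, group code, patient ordinal), so enlarging one
  group never perturbs other draws; identical config + seed gives
  byte-identical cohorts.

What the generator does **not** emulate: treatment effects, RIS→CIS
transitions, time-to-event structure (outcomes are endpoint summaries),
within-patient outcome correlation, assay noise or detection limits, and
any index–outcome dependence beyond group membership. Passing tests
therefore demonstrate the pipeline's correctness and calibration under the
stated generative model, not clinical validity on real cohorts.

`calibration_report` compares generated statistics to their targets with
Monte-Carlo tolerances (2 binomial SEs for rates; 2 large-sample median SEs,
1.2533·σ/√n on the log scale, for medians) and flags exceedances — common
by design at clinical group sizes, rare at n = 10,000.

## Reference cohort

`reference_cohort()` is a deterministic 37-patient synthetic cohort whose
group-level margins equal the published counts (group sizes, converters,
attacks, OCB, serum availability, MRI-lesion categories), with biomarkers
pinned at the published group medians. Within-group joint assignments are
not published and are made positionally; all group-level margins — hence
all published rates, confusion cells and exact-test p-values — are exact.
It is synthetic: per-patient values are constructed, not measured.

## Problem sizes and numerical choices

The test suite exercises: exhaustive Fisher validation at N ≤ 40; parameter
recovery and rate calibration at 10,000 patients per group; type-I error of
Kruskal–Wallis at 1,000 null replicates (3×15 samples); TNC R² over 200
replicate 37-patient cohorts; property-based I/O round-trips. These sizes
give Monte-Carlo standard errors small enough for 2-SE checks while keeping
the default suite fast. Index internal consistency uses relative tolerance
1e-9; hypergeometric normalization is verified to 1e-12. CSV floats are
written in shortest round-trippable form so read∘write is the identity.

## Known limitations

- Single-laboratory threshold provenance: the 30/20 and 14/5 cuts are
  consumed as constants (configurable), never re-derived from data.
- The published cohort accounting (29 CSF-only + 18 index patients versus a
  37-patient comparison table) cannot be reconciled from the published
  numbers; the data model carries whatever cohort it is given and the
  reference cohort follows the internally consistent 37-patient table.
- Group medians/IQRs, lesion-count means and the TNC regression of the
  motivating analysis are not recomputable without patient-level data; the
  simulator targets them distributionally instead.
- No ROC/AUC over continuous index values: only the fixed-threshold rule
  is evaluated, and no survival/time-to-event modelling is attempted.
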