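# Methods

This note records the scientific model behind `gcas-kit`, the conventions
and calibrations it commits to, and the limits of what its synthetic tests
demonstrate.

## Data model and scoring rules

A cohort is a set of patients, each with visits ordered by months since
diagnosis; the month-0 visit is the diagnosis visit and is the only visit at
which clinical relapse is undefined (relapse presupposes a prior remission
period, so the flag is constrained to false there and the visit is excluded
from all relapse analytics). Each visit carries the clinician's
relapse/remission call — treated throughout as the gold standard, never
inferred from symptoms — an optional CRP (mg/L), treatment fields, and an
ultrasound exam.

The exam covers up to 18 bilateral segments: four cranial vessels per side
(common temporal trunk, frontal and parietal branches, facial artery) read
as a binary halo sign, and five large vessels per side (vertebral, carotid,
subclavian, proximal and distal axillary). The vertebral artery is read as a
halo sign like the cranial vessels but is classified as a large vessel for
subtype and counting purposes; the remaining large vessels are read as a
maximal IMT in millimetres. Segments absent from an exam were not assessed
and never contribute to any rule — absence of evidence is treated as neither
progression nor regression.

A single involvement predicate underlies every rule: a halo-assessed segment
is involved iff its halo is positive; an IMT-assessed segment is involved
iff IMT ≥ the per-vessel cutoff. The cutoffs default to 1.0 mm for carotid,
subclavian and both axillary segments. This default is a convention adopted
by this package, configurable per vessel, not a universal standard; site
settings differ and should be set explicitly in `config.yaml` when known.

**Subtype** is assigned once, from the diagnosis exam: involvement entirely
in the cranial class → c-GCA, entirely in the large-vessel class → LV-GCA,
both → mixed-GCA. An exam with no involvement is "not classifiable"
(diagnosis in this design requires positive imaging); `score_cohort`
records a null subtype for such patients instead of failing.

**Halo counts** quantify extent at any performed exam: the simple count
scores one point per side whose temporal tree (trunk/frontal/parietal) has
any involvement, one per involved facial artery, and one per involved
large-vessel segment (maximum 14); the extended count scores every involved
segment once (maximum 18); the modified extended count doubles large
vessels (maximum 28). By construction simple ≤ extended ≤ modified, and
modified − extended equals the number of involved large vessels — both are
enforced as property tests.

**Ultrasound relapse** at a follow-up visit is judged against the *previous
performed* exam (skipped exams are bridged; the first follow-up references
the diagnosis exam). The visit is relapse iff (a) some segment is involved
now that was not involved at the reference exam, or (b) some non-vertebral
large vessel involved at the reference exam shows an IMT increase of at
least the delta cutoff (default 0.2 mm; a tie counts). "Already involved"
is read against the reference exam only, not cumulative history, so the
re-appearance of a previously resolved halo triggers rule (a) — the closest
literal reading of a visit-to-visit comparison. If either exam is missing
the status is "not assessed", which is distinct from remission. The status
object enumerates every triggering segment with its delta.

**GCAS** combines three binary components per visit: clinical symptoms (the
clinician's call, taken as input), CRP strictly greater than 5 mg/L (the
usual upper reference limit in Norway, where such cohorts are followed), and
positive imaging (ultrasound relapse). The score is their sum, defined only
when all three are defined; active disease is score ≥ 2 by default (the
threshold is configurable over {1,2,3}). At the diagnosis visit there is no
reference exam, so the imaging component — and hence the score — is
undefined there; we deliberately do not substitute baseline positivity,
because no visit-to-visit comparison exists yet and the diagnosis visit is
outside all relapse analytics anyway.

## Accuracy analytics

Each index test is tabulated against clinical relapse over follow-up visits
only, on the maximal visit set with the data that test needs: the
ultrasound test uses all visits with an assessed status; the CRP test, the
AND/OR combinations and GCAS use visits with *both* a CRP value and an
assessed status. This mirrors the mixed denominators of visit-level
monitoring studies (an "all assessable exams" set and a smaller "complete
data" set) and every output therefore states its own n and the number of
visits excluded for missingness.

Sensitivity and specificity are exact ratios; the phi coefficient is the
Pearson correlation of the two binaries, and n·φ² equals the uncorrected
Pearson chi-square on every 2×2 (verified to 1e-9 as a property test).
Chi-square (via `scipy.stats.chi2_contingency`) is uncorrected by default;
Yates' correction is opt-in and only meaningful for 2×2 tables. A zero
margin makes these statistics undefined, and the package raises a dedicated
error rather than reporting 0 — except inside cutoff sweeps, where an
undefined cell is reported as NaN so the rest of the curve survives.

The IMT-delta cutoff sweep rescores every visit at each cutoff. Because
raising the cutoff can only remove IMT-increase triggers (new-segment
triggers do not depend on it), sensitivity is non-increasing and specificity
non-decreasing in the cutoff; this monotonicity is asserted over 100 seeded
cohorts.

Cohort summaries are patient-level: a patient counts as relapsed if any
follow-up visit carries a clinical relapse, and patients with no follow-up
visits (drop-outs after diagnosis) are excluded from relapse-rate
denominators. Medians and IQRs (Q3 − Q1) use linear interpolation between
order statistics (`numpy.percentile` default). Printed percentages are
rounded to one decimal with ties away from zero, phi to two decimals — the
convention of the clinical tables this package is designed to reproduce.

## Synthetic cohort generator

The generator emulates the structure of a prospectively followed GCA
cohort. Defaults, with provenance:

| parameter | default | why |
|---|---|---|
| `n_patients` | 132 | reference cohort size |
| `subtype_probs` | (0.311, 0.152, 0.538) | published subtype mixture; sums to 1.001 because the source percentages are rounded, so draws renormalise |
| `per_visit_relapse_prob` | 0.1621 | solved numerically so that, under the schedule and horizon below, the expected fraction of patients with ≥ 1 relapse is 0.606 |
| `p_us_pos_given_relapse` | 0.61 | target visit-level sensitivity of ultrasound |
| `p_us_pos_given_remission` | 0.28 | target visit-level false-positive rate (specificity 0.72) |
| `crp_relapse_median_mg_l` / `crp_remission_median_mg_l` | 13 / 3 | reported median CRP at relapse visits; a normal-range median in remission |
| `crp_log_sd_relapse` / `crp_log_sd_remission` | 1.748 / 1.824 | solved so P(CRP > 5 \| relapse) = 0.708 and P(CRP > 5 \| remission) = 0.390, the margins of the reference cross-tables; a calibration, not a measured dispersion |
| `imt_baseline_mean_mm` | 0.7 | normal axillary/carotid wall thickness |
| `imt_noise_sd_mm` | 0.03 | exam-to-exam measurement noise, clipped at 3 SD |
| `imt_relapse_jump_range_mm` | (0.2, 0.6) | relapse-sized IMT increases, at or above the relapse threshold |
| `p_missing_ultrasound` / `p_missing_crp` | 0.040 / 0.146 | observed missingness rates (30/750 exams, 105/720 CRPs) |
| `followup_months_range` | (6, 48) uniform | gives median 27 and IQR 21 months of follow-up, the scale of the reference cohort's "25 (IQR 21)" |
| `p_dmard` | 0.477 | steroid-sparing agent use at patient level |

Each patient draws a subtype and a diagnosis involvement pattern of the
matching class(es) (1 + Binomial(7, 0.4) cranial and/or 1 + Binomial(9,
0.35) large-vessel segments — chosen to give diagnosis halo counts of a few
to several involved vessels, the typical extent in newly diagnosed GCA).
Visits follow the clinical schedule: monthly for a drawn 1–3 months until
remission, then months 3, 6 and 12, then yearly, truncated at the patient's
follow-up horizon; unscheduled relapse visits are not simulated.

Ultrasound positivity is *mechanistic*: at each performed follow-up exam a
Bernoulli draw (probability conditional on the visit's clinical state)
decides whether a relapse-rule trigger is planted — either a newly involved
segment or an IMT jump applied to the value recorded at the previous
performed exam, which guarantees the recorded delta reaches the threshold —
and otherwise all values drift only within ±3 noise SD (±0.09 mm), which
cannot reach the 0.2 mm threshold between any two exams. The generator
never writes a status flag; scoring its output recovers the conditional
probabilities, and this mechanism-consistency is itself a test. Involvement
is persistent (halos may persist in remission, as observed clinically), so
a planted trigger cannot re-trigger at later visits.

What the generator does **not** emulate: within-patient relapse clustering
(relapses are independent Bernoulli draws per visit), treatment effects
(prednisolone taper and DMARD fields are descriptive noise, causally
unlinked to relapse), demographics, reader variability beyond IMT noise,
halo-feature detail, and unscheduled relapse-triggered visits. Passing
tests on synthetic cohorts therefore demonstrates the *pipeline's*
correctness and calibration, not the clinical performance of ultrasound on
any real population.

## Numerical choices

* IMT comparisons (involvement ≥ cutoff, delta ≥ cutoff) use an absolute
  tolerance of 1e-9 so that decimal measurements such as 1.3 − 1.1 meet a
  0.2 threshold despite binary floating point; ties count as positive, as
  the "≥" in the clinical definitions requires.
* Generated IMT values are rounded to 0.01 mm (measurement resolution);
  CRP to 0.1 mg/L.
* CRP positivity is strictly greater than 5 mg/L; a CRP of exactly 5 is
  negative.
* Degenerate inputs: an unperformed exam raises a distinct "no exam" error
  where an answer would otherwise be ambiguous; empty analysis sets raise
  (CLI exit code 3) rather than emitting empty CSVs; statistics with zero
  margins raise rather than returning 0.
* Determinism: one `numpy.random.Generator` seeded from `params.seed`
  drives the whole generation sequentially, so identical parameters give
  byte-identical CSV output.

## File formats

`visits.csv`: `patient_id, month, clinical_relapse {0,1}, crp_mg_l (blank
allowed), prednisolone_mg (blank), dmard (blank), ultrasound_performed
{0,1}`. `vessels.csv`: `patient_id, month, vessel, side {left,right}, halo
{0,1,blank}, imt_mm (blank)`; each row carries exactly one of halo/IMT
matching its vessel class. `config.yaml` mirrors `AnalysisConfig` field
names. Blank means missing; missing is never imputed, and validation errors
name the offending file and row.

## Problem sizes

The test suite and the acceptance script run desk-scale problems chosen to
give tight statistical checks at interactive runtimes: printed-cell
reproductions are O(1); property suites use cohorts of 6–25 patients (100
seeds for sweep monotonicity, 20-patient cohorts for oracle equivalence);
calibration-recovery checks use 200-patient cohorts (≈ 1,300 visits) at
three seeds, where 3-binomial-SE bands are a few percentage points wide;
one 1,000-patient cohort checks the subtype mixture.

## Known limitations

* Halo signs are present/absent only; no halo thickness or segment-count
  grading within a vessel, and no quantitative ultrasound scores (OGUS,
  GUSTO) — different instruments with different aims.
* The clinical relapse call is an input; the package cannot detect
  adjudication error in it, and all accuracy figures inherit the absence of
  a true gold standard for GCA activity.
* The left subclavian is typically only partially visualisable; the data
  model handles this only as "segment not assessed", with no side-specific
  convention.
* The IMT involvement cutoffs (1.0 mm default) and the GCAS threshold are
  conventions; results are sensitive to them, which is why the sweep and
  the per-vessel configuration exist.
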