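# Methods

## The question the package answers

An AI reader for screening mammography produces a continuous malignancy
score per examination; clinical use requires a threshold. The standard
practice is to calibrate that threshold so the AI's cancer detection rate
(CDR, true positives per 1000 exams) matches the radiologist double-reading
CDR on a retrospective validation dataset, then deploy it. `calibdrift`
measures what happens when the validation dataset differs systematically
from the deployment population: every experiment compares a threshold
calibrated on a *mismatched* selection against one calibrated on the
representative target, both evaluated on the target, and reports the signed
percent change in CDR and FPR.

Because the real registry-linked populations such audits run on are
proprietary, the package ships a synthetic-cohort generator whose structure
carries the features the audit depends on. All conclusions from the test
suite are therefore statements about mechanism and direction, not about the
magnitudes any particular screening program would observe.

## Population model

Participants enter the program at a uniformly random month of the study
window (default 2008–2021) at a uniformly random age within the screening
range (default 40–74) and are screened every 24 months until they age out,
the window ends, or they are diagnosed. All dates are (year, month);
nothing in the audit needs day resolution.

Cancer onset is a per-round hazard, by age band (defaults 0.007 / 0.012 /
0.016 per round for 40–49 / 50–69 / 70+) multiplied by a density relative
risk (A 0.5, B 0.8, C 1.4, D 2.2). The density multiplier is what lets the
generator reproduce the empirical pattern that cancer cases are both older
*and* denser-breasted than controls even though density declines with age —
density is itself a risk factor strong enough to beat the age correlation.
It is also the prevalence mechanism behind the density-mismatch scenarios:
a low-density-only calibration set is case-poor relative to the population.
Diagnosis follows the onset round by a uniform lag of 0–23 months (one
screening interval), which smears months-to-diagnosis across the whole
window range; screening stops at diagnosis. Cancer type is in-situ with
probability 0.133, invasive otherwise. Mammographic density is drawn per
exam from an age-band-conditional distribution; vendor is drawn per exam
from a per-year mix that drifts from GE-dominated (85 %) to Philips-heavy
(45 % GE) across the window, making equipment the default temporal
confounder.

## Score and reader model

Each AI system has an equal-variance binormal latent per class, shifted
additively per vendor, density, age band and (for cases) cancer type, then
mapped to [0, 1] by the logistic function. Shifts are (control, case)
pairs: a class-symmetric pair is a pure location effect, an asymmetric pair
changes the separation, which is how "the AI discriminates better on vendor
X" is expressed. The monotone squashing leaves every rank statistic
untouched, so with all shifts zero each system's AUC has the closed form
`Phi(delta / (sigma * sqrt(2)))` — the oracle the parameter-recovery tests
use.

The radiologist consensus recall is Bernoulli: probability
`1 - specificity` (default specificity 0.93) for healthy exams, and for
pre-diagnosis exams of diagnosed participants a decreasing piecewise-linear
function of months-to-diagnosis `m`,
`r(m) = clip(0.95 - 0.02 m, 1 - specificity, 1)`. Reader and AI latents
share a common "conspicuity" factor (correlation 0.3 by default), as do the
AI systems among themselves.

### Why the default case separation is 1.703

The follow-up-window experiments need the reader and the AI to sit on the
same operating point at the 36-month reference standard, so that shortening
the window isolates the reader's short-horizon advantage. With the uniform
diagnosis lag, every months-to-diagnosis value `m = 0..w` is (up to edge
effects) equally represented among case exams at window `w`, so the
expected reader sensitivity is `S(w) = mean(r(m), m = 0..w)`; at `w = 36`,
`S = 0.59`. The AI true-positive rate at the reader's FPR `f = 0.07` is
`Phi(delta - z_{1-f})`, and equating the two gives
`delta = z_{0.93} + Phi^{-1}(0.59) ≈ 1.703` (`matched_case_mean` computes
this for any reader configuration). The resulting ordering — reader far
above every AI ROC at 12 months, on the ROC at 36 — is a designed property
of the default conditions, verified empirically by the acceptance suite.

### Default subgroup shifts

The three default systems share the matched base separation and differ by a
scale factor (0.8 / 1.0 / 1.2) on all shifts, imitating a panel of
commercial systems that react in a common direction with different
magnitude. Directions encode the qualitative mechanisms of the screening
setting: GE exams shifted up in location for both classes (+0.4) while
Philips separates better (−0.2 control, +0.6 case); discrimination improves
with age (case shift −0.25 → +0.25 across bands) and degrades with density
(A +0.2 → D −0.45 for cases, with controls drifting the other way); in-situ
cancers score 0.4 lower. Cases within a detectability horizon of 36 months
before diagnosis draw the case latent; earlier exams of the same woman are
radiologically normal and draw the control latent, which is what makes a
48-month reference standard dilute both reader and AI sensitivity.

With vendor drift as the only temporal confounder, the temporal-mismatch
scenario inherits its sign from the vendor geometry: early-control /
late-case selections land on the *deflation* side here, whereas audits of
real programs have attributed inflation at that selection to within-vendor
model and software-version drift — substructure this generator deliberately
does not model. The temporal scenario is therefore exercised for mechanism,
not for sign fidelity.

## Reference standards and datasets

An exam is a case under window `w` iff diagnosis occurs `0 <= Delta <= w`
whole months after it. Exams later than `collection_end - w` are excluded
because a healthy outcome cannot be confirmed for them; the cutoff
generalizes the usual registry practice of truncating the study population
one follow-up period before the last registry record. A cohort dataset is
one calendar year of labelled exams at true prevalence. The case-control
construction works per screening year in descending order: case
participants with a case exam that year contribute *all* their case exams;
five times as many healthy participants (never diagnosed) with an exam that
year are drawn at random and contribute their most recent exam (ties broken
by exam id); selected participants leave the pool before earlier years are
processed. The case set is deterministic; only the control draw is seeded.

## Metrics, prevalence correction, uncertainty

Metrics derive from the exam-level confusion matrix; PPV (and sensitivity,
when a dataset has no positives) is reported as missing with a flag rather
than NaN or zero. Case-enriched data misstate PPV/CDR/AIR, so two
corrections to cohort prevalence are provided: *upscaling* duplicates every
control exam the same whole number of times `r = round(target ratio /
observed ratio)` — whole copies only; datasets already leaner than the
cohort are redirected to the bootstrap — and the *weighted bootstrap*
resamples participants with class weights chosen so the expected case
fraction equals the cohort's, averaging metrics over replicates.

All confidence intervals are participant-level stratified bootstrap
percentile intervals (B = 1000 by default, seeded): participants, not
exams, are resampled so that the several exams of one woman travel
together. Distortion CIs resample the target population once per replicate
and evaluate both thresholds on the same resample, so the interval reflects
the joint uncertainty of the two operating points; the calibration sets are
held fixed, i.e. the CIs condition on the thresholds as deployed.

## Calibration and its tie-breaks

Candidate thresholds are the observed scores plus ±infinity sentinels; an
exam is positive when its score is strictly greater than the threshold.
Among candidates the one with CDR nearest the target wins; ties in distance
break toward the higher CDR (higher sensitivity), and candidates achieving
that same CDR resolve to the highest threshold, which adds no false
positives for the same detection rate. When the target is at or beyond the
maximum achievable CDR the call-everything sentinel is returned with a
saturation flag.

The calibration target inside `run_scenario` is the radiologist CDR on the
*representative target*, for every scenario. The alternative — measuring
the radiologist on the mismatched selection itself — would cancel the
prevalence component of the distortion and leave only the score-shift
component; fixing the target on the representative population keeps both
mechanisms in view and matches the deployment question ("we want the AI to
detect at the rate our radiologists achieve in this program").

## AUC comparisons

AUC is the trapezoid integral of the empirical ROC, equal to the normalized
Mann–Whitney statistic with ties counted one half. Variances and tests use
DeLong structural components via midranks; the paired variant includes the
covariance term, the unpaired variant sums per-dataset variances. Scenario
runs compare overlapping selections (a filtered subset against the full
target) with the unpaired test; the positive dependence makes that test
conservative, which is documented rather than corrected.

## Problem sizes and numerical choices

Default experiment sizes were chosen so that Monte-Carlo noise is well below
each effect being measured: 30,000 participants (~70,000 labelled exams,
~1,200 case exams) for distortion-direction experiments, 20,000 for the
follow-up study, 40,000 for the cohort/case-control comparison, and 2,000
simulated dataset pairs (100 cases / 400 controls each) for the DeLong size
check. Generation is vectorized and runs at roughly one second per 30,000
participants; the full acceptance script completes in well under a minute.
Probability vectors must sum to 1 within 1e-9; config objects reject
unknown keys outright.

## What passing tests do and do not show

The generator emulates the statistical skeleton of a screening program:
longitudinal exams, subgroup-dependent score distributions, a reader whose
advantage concentrates near diagnosis, density–age–risk confounding and a
vendor mix that drifts over calendar time. It does not emulate images,
per-view scores, multiple cancers per participant (at most one diagnosis is
emitted), within-vendor software drift, region/site structure beyond a
label, or non-stationary radiologist behaviour. Directional reproduction of
the mismatch mechanisms on this synthetic population demonstrates that the
pipeline detects and signs each distortion correctly; it does not predict
the magnitude of any of these effects in a real program, which depends on
the local score geometry and case mix.
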