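# Methods

This note records the models the package implements, the conventions it
fixes where the underlying procedures are ambiguous, the defaults of the
synthetic-cohort generator, and the limits of what the test suite shows.

## The composite index

MuSSDAI is an end-of-study snapshot: one score per surviving mouse at the
final (week-16) assessment, summing five organ-domain scores. The
functional domains (glandular, PNS, CNS) split their weights equally over
their sub-tests — 1.5 × grade for each of SFR and phenol red, 2.5 × grade
for each of Von Frey and cold plate, 2 × grade for each of forced swim,
open field and sucrose — so each domain's maximum is weight × 3.
Lymphadenopathy contributes 4 × (palpation grade, 0–2) and renal
5 × (dipstick grade, 0–3). The ceiling is therefore
9 + 15 + 18 + 8 + 15 = 65.

Grading is calibrated once, on the pooled premorbid values of all 52 mice
(both cohorts): the premorbid population defines "no activity", and the
grade edges are the severity-side CI95 limit shifted by 15% and 30% of the
premorbid mean. Conventions the package fixes:

- **CI95 of the mean** uses the normal quantile (mean ± 1.96·SD/√n). At
  n = 52 the Student-t interval differs by < 1%; `ci_method="t"` switches
  to the t(n−1) quantile for smaller calibration sets.
- **Band closure.** "Between limit A and limit B" needs a tie rule. The CI
  itself is closed (a value exactly at the CI limit grades 0); each outer
  band is closed at its edge nearer the mean, open at the farther edge
  (a value exactly at e₂ grades 2, exactly at e₃ grades 3). Any single
  consistent rule reproduces the same scores except on a measure-zero set;
  this one is property-tested against an independent edge-enumeration
  oracle.
- **The 15%/30% offsets are anchored at the CI limit**, not at the mean
  (an anchored-at-mean reading exists; the CI-limit anchor is the one
  implemented).
- **Lymphadenopathy aggregation** over the four palpated areas (cervical,
  axillary, brachial, inguinal) takes the maximum — the worst finding, as
  the human index's lymphadenopathy domain does. `sum` (capped) and `mean`
  are available alternatives; the choice is a convention, not a derivation.
- **Renal grade** is the final (week-16) dipstick reading.
- Mice dead before the final test day are excluded; a mouse with any
  missing sub-test or grade gets no total and is flagged `incomplete`
  rather than imputed.

Degenerate calibration (zero premorbid variance) collapses the CI to a
point; any severity-side deviation then grades ≥ 1, which is the intended
limiting behaviour.

## Serology

Endpoint titers: replicate wells are averaged per dilution first; OD.max is
the per-curve maximum (each serum/day is titered independently, no
plate-level normalisation); the titer is where the straight line through
the two points bracketing OD.max/2 crosses it. The line is drawn on the
**log10 reciprocal-dilution axis** by default: serial dilutions are
geometric, so the two-point chord is well-conditioned there;
`interp_axis="linear"` preserves the literal linear reading. NC50 uses the
same machinery on neutralization fractions
(response − virus-only)/(cells-only − virus-only), clamped to [0, 1] for
crossing detection (noisy controls can push raw fractions outside the unit
interval; the raw values are still reported).

Censoring: estimates are never extrapolated beyond the tested dilutions.
A series that never decays to half-maximum is `above_range`; a
neutralization series never reaching 50% is `below_range`. Because OD.max
is taken from the curve itself, a blank plate would otherwise "titer" its
own noise — `od_max_floor` marks plates whose every mean OD is below half
a user-supplied floor as `below_range` (the pipeline default, 1.0 OD with
a 2.5 plateau, sits far above blank noise and far below a real titration's
peak). A non-monotone series crossing half-maximum more than once uses the
crossing adjacent to the maximum and emits a warning. Exact grid-point
crossings return the tested dilution itself. The estimators are invariant
to uniform response scaling and to replicate order.

Interpolation error: against a 10⁴-point brute-force oracle on the same
bracketing segment, both estimators agree to < 0.1%. Recovery of a known
half-maximal location is limited by the chord approximation — on the
trial-style 2-fold dilution series with a slope-2 sigmoid the worst-case
bias is ≈ 1%, dropping to ≈ 0.1% at √2-spaced points; the recovery tests
therefore use densely sampled noiseless curves whose lowest dilution sits
well below the true titer (so OD.max is on the plateau).

Autoantibody positivity: threshold = control mean + 5 sample SDs (n−1
denominator — the calibrating control group is small, n = 5); positivity is
strict inequality, so with zero-variance controls a value equal to the
threshold is negative. ELISpot: per-condition replicate means, background =
the unstimulated (NONE) condition, subtracted means floored at 0.

## Interferon signature

The reference gene is the panel gene with the smallest CT standard
deviation across all samples, both groups pooled (the trial's array
software auto-selected IFNA4 this way); it can be pinned. Replicate wells
are averaged to one CT per (sample, gene) before ΔCT. ΔΔCT = mean
ΔCT(treated) − mean ΔCT(pooled NT+PBS+KLH controls); fold change =
2^(−ΔΔCT); fold regulation is the fold change for up-regulation and its
negative reciprocal for down-regulation. The regulation call uses an
**inclusive** 2-fold cutoff (|fold regulation| ≥ 2 ⇔ |log2 FC| ≥ 1),
matching the vendor convention for this array family. p-values come from a
two-sample t-test on the per-sample 2^(−ΔCT) values — **Welch's** variant
by default because the control pool is 2–3× the treated group, switchable
to classic Student. Undetermined wells exclude that sample for that gene
only (never imputed as CT 40). No multiple-testing correction is applied by
default, matching per-gene reporting practice; `fdr=True` adds
Benjamini-Hochberg q-values.

## Histology

Focus scores pool counts and areas (Σ foci / Σ area) across all sections of
both left and right organs — unbiased under varying section areas, and
invariant to splitting a section proportionally; a mean-of-densities
alternative is exposed. Lung ratios pool counts across sections. BAFF
immunostaining is the arithmetic mean of exactly 3 non-overlapping ×40
fields. Focus/spot identification is upstream of this package: counts are
inputs, images are not processed.

## Statistics

- **Mann-Whitney U** (primary comparison: IFN-K vs pooled NT+PBS+KLH within
  cohort): exact two-sided p by full enumeration over index subsets with
  midranks whenever n₁+n₂ ≤ 20 — this handles ties exactly (identical
  samples give p = 1) where standard exact routines refuse ties. The
  two-sided rule counts tables with |U − n₁n₂/2| at least as large as
  observed. Larger layouts use the tie-corrected normal approximation with
  a 0.5 continuity correction; on 500 null cohorts the nominal 5% level is
  held within binomial tolerance.
- **Kruskal-Wallis + Dunn**: scipy's omnibus H (all-tied data returns
  H = 0, p = 1 by convention); Dunn's post-hoc is the standard mean-rank z
  with tie correction, implemented here directly and verified against the
  k = 2 identity z² = H. Family-wise adjustment of the Dunn p-values
  (Holm/Bonferroni) is available, off by default; endpoints are not
  multiplicity-corrected across tests, matching per-endpoint reporting.
- **Proteinuria-free survival**: the event is the first scheduled dipstick
  week (0, 3, 6, 9, 12, 16) at grade ≥ 1 (0.3 g/l; threshold
  configurable), recorded at that week's day — onset between visits is
  right-endpoint–recorded because the schedule is sparse. The default
  endpoint is the composite (first of proteinuria onset or death);
  death-only and proteinuria-only variants exist, the latter censoring at
  death. Kaplan-Meier curves and the log-rank test come from lifelines; a
  dataset with no events at all returns p = 1 (all curves flat at 1).

## The synthetic-cohort generator

The generator emulates the *design*: 2 cohorts × (6+6+7+7) mice, premorbid
values drawn from one shared distribution for all groups, follow-up values
= premorbid mean + per-(test, group, timepoint) shift + Gaussian noise
truncated to the legal range (counts rounded), assay curves as monotone
sigmoids in log dilution (slope 2, a typical immunoassay steepness) with
the half-maximal point at the configured titer/NC50 and per-mouse
log-normal scatter, CTs Gaussian about ΔCT-shifted means with a per-sample
RNA-input offset, gland foci Poisson with rate = intensity × area and
log-normal section areas, lung counts binomial, BAFF fields Poisson.

Default effect magnitudes are transcribed from one cohort's printed group
means (e.g. week-8 salivary flow 3.4 vs 2.0 ml/g treated vs control; Von
Frey thresholds 0.03 vs 0.15 g) and applied to both cohorts; CNS endpoints
and sucrose worsen equally in all groups, and proteinuria onset is
group-independent, because no treatment effect was observed there. Noise
SDs default to the premorbid SDs: back-computing follow-up SDs from the
printed standard errors gives values that exceed the effects themselves
and contradict the printed significance levels, so the premorbid spread is
used as the plausible within-group variability. These defaults
parameterise *plausibility*; they are configuration, not ground truth.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: within-mouse longitudinal correlation (an
optional random intercept exists, default off, since the repeated-measures
covariance is undescribed), plate/batch effects and assay drift,
non-Gaussian heavy tails in behavioural endpoints, cohort-by-treatment
interactions (one shift table serves both cohorts), mortality (default
hazard 0 so all 52 mice reach day 122; a per-day exponential hazard is
available and produces validated, properly truncated records), and any
mechanistic antibody kinetics.

Determinism: one `numpy.random.default_rng(seed)` stream consumed in a
documented fixed order (cohort → group → mouse → table; gene panel in
sorted order), so a seed fully determines the dataset across platforms.

## Problem sizes

The test suite runs the full default trial (52 mice) for end-to-end checks;
grading equivalence uses 200 random schemes × a 101-point value grid plus
1,000 random mice for monotonicity; interpolation equivalence uses 100
random noiseless curves against a 10⁴-point oracle; signature recovery uses
200 replicate panels at n = 7 vs 14 with replicate SD 0.2; statistical
calibration uses 500 null cohorts; exact-test agreement enumerates every
layout with n₁+n₂ ≤ 10. The whole suite completes in well under a minute
on one CPU. `scripts/acceptance.py` calibrates on the default 52-mouse
premorbid population and scores one maximal-severity mouse.

## Known limitations

- The index is a snapshot; no longitudinal MuSSDAI trajectories.
- Titer/NC50 use bracketing-point interpolation as specified, not 4PL
  fitting — on coarse 2-fold series the chord bias can reach ~1%.
- Group summaries over censored titers substitute the bounding dilution
  and flag the summary; there is no parametric censored-data model.
- The focus-score definition ("≥ 50 mononuclear cells" vs "≥ 50 cells/mm²")
  is inconsistent across its published descriptions; focus identification
  is treated as an upstream input contract and the discrepancy is only
  documented here.
- Dunn p-values are asymptotic (normal); at the trial's group sizes this is
  the standard practice the package mirrors, not an exact test.
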