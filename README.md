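# mussdai

Analytics for preclinical trials of anti-IFNα vaccination in the MRL/lpr
mouse model of Sjögren's syndrome. The package implements, as tested and
reusable code, the quantitative machinery such a trial needs:

- **MuSSDAI**, a murine composite disease-activity index modelled on the
  human ESSDAI (weighted organ-domain scores, total 0–65), with its
  premorbid-population grading calibration;
- **serology estimators**: endpoint ELISA titers and 50% virus-neutralization
  capacity (NC50) by half-maximal two-point interpolation, ELISpot
  summaries, and mean + 5 SD autoantibody positivity thresholds;
- **type 1 interferon signature**: ΔΔCT fold-change/fold-regulation analysis
  of a qPCR gene panel with stability-based reference-gene selection;
- **histopathology scores**: gland focus scores (foci/mm²), lung
  infiltration ratios, BAFF immunostaining field means;
- **trial statistics**: exact/tie-corrected Mann-Whitney U,
  Kruskal-Wallis + Dunn post-hoc tests, Kaplan-Meier proteinuria-free
  survival with log-rank tests, and a deterministic report builder;
- a **seeded synthetic-cohort generator** emulating the study design
  (two adjuvant cohorts × four groups, 52 mice, 122-day follow-up), so the
  whole pipeline runs end-to-end with no animal data.

It is aimed at biostatisticians and pharmacologists who analyse
small-group preclinical autoimmunity studies and want the bespoke parts of
such an analysis to be reproducible and unit-tested.

## The index

Each functional test (salivary flow rate, phenol red thread, Von Frey,
cold plate, open field, forced swim, sucrose preference) is graded 0–3
against the pooled *premorbid* population of all 52 mice:

- grade 0 — value inside the 95% CI of the premorbid mean
  (CI = mean ± 1.96·SD/√n), or beyond it on the healthy side;
- grade 1 — between the severity-side CI limit *e₁* and
  *e₂ = e₁ ± 0.15·mean*;
- grade 2 — between *e₂* and *e₃ = e₁ ± 0.30·mean*;
- grade 3 — beyond *e₃*,

where the severity direction is test-specific (a *drop* in salivary flow is
pathological, a *rise* in the Von Frey withdrawal threshold is). The domain
weights are glandular 3 (split over 2 tests), lymphadenopathy 4 (palpation
grade 0–2), renal 5 (dipstick grade 0–3), PNS 5 (2 tests), CNS 6 (3 tests):

```
MuSSDAI = Σ_domains  weight_d × grade_d   ∈ [0, 65]
```

Titers interpolate OD.max/2 on the log10 reciprocal-dilution axis between
the two bracketing points; NC50 interpolates the 50% crossing of
neutralization(d) = (response − virus-only)/(cells-only − virus-only).
The signature uses ΔCT = CT(gene) − CT(reference), ΔΔCT = mean ΔCT(treated)
− mean ΔCT(controls), fold change 2^(−ΔΔCT), with an inclusive 2-fold
regulation cutoff and Welch t-tests on the per-sample 2^(−ΔCT) values.

## Worked example

```python
import mussdai as m

ds = m.generate_cohorts(m.GeneratorConfig(seed=1))   # 52 mice, 2 cohorts
scorer = m.MussdaiScorer().fit(ds)                   # premorbid calibration
print(m.summarize_mussdai(scorer.transform(ds)))

an = m.IFNSignatureAnalyzer().fit(ds.ct)
print(an.reference_gene_, an.count("DOWN"))
```

prints

```
cohort  n_control  mean_control  sem_control  n_treated  mean_treated  sem_treated  statistic  p_value
 ISA51         19        50.895        1.687          7        38.143        2.876      118.5    0.003
 SWE01         19        50.053        1.887          7        34.571        2.460      125.0    0.001
Ifna4 19
```

Per cohort, the 7 treated (IFN-K) mice score a lower disease-activity index
than the 19 pooled controls (Mann-Whitney two-sided p ≈ 0.003 and 0.001),
and the signature analysis auto-selects Ifna4 as the stable reference and
calls 19 panel genes downregulated at the 2-fold cutoff — the direction and
style of result the vaccination is designed to produce. The same dataset can
be driven from the shell:

```sh
mussdai simulate --seed 1 --out trial/
mussdai score --data trial/ --out mussdai.csv --schemes schemes.csv
mussdai report --data trial/ --out report/
```

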