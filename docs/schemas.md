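# CSV schemas

All tables are tidy (long) CSVs with an explicit header, one row per
observation. Missing optional values are empty cells — never sentinel
numbers. `read_cohort(dir)` expects these files in one directory;
`write_cohort` emits them deterministically (fixed column order, stable
sort, full float precision).

## mice.csv

| column | type | notes |
| --- | --- | --- |
| mouse_id | string | unique |
| cohort | enum | `SWE01`, `ISA51` |
| group | enum | `NT`, `PBS`, `KLH`, `IFN_K` |
| alive_at_end | bool | |
| death_day | int, optional | in [0, 122]; measurements after it are invalid |

## measurements.csv

| column | type | notes |
| --- | --- | --- |
| mouse_id | string | must exist in mice.csv |
| test | enum | `SFR`, `PHENOL_RED`, `VON_FREY`, `COLD_PLATE`, `OPEN_FIELD_CENTER_PCT`, `FORCED_SWIM_IMMOBILITY_PCT`, `SUCROSE_RATIO` |
| timepoint | enum | `PRE`, `WK8`, `WK16` (sucrose's −1/+9/+17-week clock maps onto the same slots) |
| day | int | study day: −14/56/112 behavioural, −7/63/119 sucrose |
| value | float | native units: ml/g (SFR), mm (phenol red), g (Von Frey, in [0.008, 1]), paw lifts (cold plate), % (open field, forced swim), ratio (sucrose) |

One row per (mouse, test, timepoint); duplicates are a validation error.

## grades.csv

| column | type | notes |
| --- | --- | --- |
| mouse_id | string | |
| kind | enum | `LYMPH_NODE`, `PROTEINURIA` |
| week | int | study week of the observation |
| site | enum, optional | lymph nodes only: `cervical`, `axillary`, `brachial`, `inguinal` |
| level | int | lymph node ∈ {0,1,2} (0 not palpable, 1 ≤5 mm, 2 >5 mm); proteinuria ∈ {0,1,2,3} (0 negative–traces, 1 = 0.3 g/l, 2 = 1 g/l, 3 ≥ 3 g/l) |

## curves.csv

One row per dilution × replicate well.

| column | type | notes |
| --- | --- | --- |
| mouse_id | string | |
| assay | enum | `ELISA_IFNA`, `ELISA_KLH`, `NEUTRALIZATION` |
| day | int | bleed day |
| reciprocal_dilution | float > 0 | strictly increasing per curve, ≥ 2 points |
| replicate | int | 1-based |
| response | float ≥ 0 | OD (ELISA) or viability signal (neutralization) |
| cells_only_response | float | neutralization only; plate control |
| virus_only_response | float | neutralization only; plate control |

## ct.csv

| column | type | notes |
| --- | --- | --- |
| mouse_id | string | |
| group | enum | as in mice.csv |
| gene | string | panel gene symbol |
| replicate | int | wells per (mouse, gene); averaged before ΔCT |
| ct | float, optional | cycles in [0, 45]; empty = undetermined well (sample excluded for that gene, never imputed) |

## histology.csv

One row per section (SMG/LG/LUNG) or microscope field (SMG_BAFF); only the
columns relevant to the organ are filled.

| column | type | notes |
| --- | --- | --- |
| mouse_id | string | |
| organ | enum | `SMG`, `LG`, `LUNG`, `SMG_BAFF` |
| section | int | section or field index |
| focus_count | int ≥ 0 | SMG/LG |
| section_area_mm2 | float > 0 | SMG/LG; 2–12 sections per (mouse, organ), left + right pooled |
| infiltrated_vessels / total_vessels | int | LUNG; infiltrated ≤ total |
| infiltrated_bronchioles / total_bronchioles | int | LUNG |
| baff_spots | int ≥ 0 | SMG_BAFF; exactly 3 fields per mouse |
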