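# vertpattern

Homeotic transformations of vertebrae — a seventh "cervical" vertebra that
bears a rib, a twelfth thoracic rib that is rudimentary or missing, a lumbar
vertebra recruited into the sacrum — are among the most common congenital
variations in humans, and in deceased fetuses they co-occur strikingly often
with malformations of other organ systems. `vertpattern` is an analysis
package for exactly this kind of fetal radiographic + autopsy cohort. It is
aimed at researchers in teratology, developmental biology and perinatal
pathology who want to classify vertebral-column morphology reproducibly and
quantify how malformation risk scales with the abnormality of the vertebral
formula.

## What it computes

**Pattern classes and severity.** Each presacral column (ordered vertebrae
with per-side rib state and rib-length ratio) is reduced to three boundary
shifts — cervico-thoracic (CT), thoraco-lumbar (TL) and lumbo-sacral (LS) —
by deterministic rules: a rib on the seventh vertebra (or an enlarged
transverse process exceeding T1's) marks an anterior CT shift; a first or
twelfth thoracic rib shorter than half its neighbour (`length_ratio < 0.5`)
is rudimentary; a rib-bearing vertebra in first lumbar position is a
posterior TL shift; a presacral count ≠ 24 or a flagged transitional
lumbo-sacral vertebra is an LS shift. The flag triple maps bijectively onto
eight pattern classes, scored on an ordinal severity scale that ranks
anterior changes above posterior ones:

| pattern  | R | LS | TL | TL_LS | CT | CT_LS | CT_TL | CT_TL_LS |
|----------|---|----|----|-------|----|-------|-------|----------|
| severity | 0 | 1  | 3  | 4     | 6  | 7     | 8     | 9        |

Transitional vertebrae count half toward each neighbouring region, so
regional counts come in half units and always sum to the presacral count.

**Malformation coding.** Autopsy findings (controlled vocabulary) are coded
into ten organ systems (BP, CV, CF, DS, LD, MS, NS, SK, UG, VBW) under
primary/secondary causal rules so no defect is counted twice — e.g. a
tracheo-esophageal fistula is primary for the digestive system and only
secondary for the bronchopulmonary system; findings caused by hypoxic
stress are not counted at all. Germ-layer and morphogenetic-process
involvement (midline, neural crest, left-right, segmentation) is derived
from a configurable coding map through primary findings only. Macerated or
non-autopsied systems are "non-available" and drop out of every denominator.

**Statistics.** Pattern × malformation contingency tables (two groupings:
all eight classes, or four merged severity groups) are decomposed by simple
correspondence analysis — SVD of the standardised residuals
`S = D_r^{-1/2}(P − rcᵀ)D_c^{-1/2}`, principal inertias = squared singular
values, total inertia = χ²/n. Severity associations are fitted by a
hand-written IRLS Bernoulli GLM, `logit P(outcome) = a + b·severity` (+ sex
and gestational-age factors), with Wald tests, Pearson-χ²/df overdispersion
checks, joint-model slope comparisons, likelihood-ratio interaction tests
and frequency-trend correlations.

**Synthetic cohorts.** Because such autopsy archives cannot be shared, the
package ships a seeded generator that emulates the study population: an
eight-class multinomial over patterns (regular 20.6 %, any CT shift 67.4 %,
CT+TL 33.4 %, all three boundaries 10.6 %), class-exact morphology
synthesis (the classifier recovers the latent class for 100 % of subjects),
per-system malformation events logit-linear in severity with published
slopes and intercepts calibrated to published case counts, independent
per-system missingness, and demographics with no effect on pattern.

## Worked example

```python
from vertpattern import classify_column
from vertpattern.examples import three_boundary_column

res = classify_column(three_boundary_column())
print(res.pattern.value, res.severity)

from vertpattern.simulate import slope_recovery
rec = slope_recovery(slope=0.36, target_count=64,
                     n_replicates=50, n_subjects=1062, seed=1)
print(f"recovered {rec.mean_slope:.3f} (generating 0.36, MC SE {rec.mc_se:.3f})")
```

prints

```
CT_TL_LS 9
recovered 0.360 (generating 0.36, MC SE 0.011)
```

The first block classifies the canonical three-boundary column (bilateral
cervical ribs, a unilateral rudimentary twelfth rib, four lumbar vertebrae,
23 presacral): shifts at CT, TL and LS give pattern `CT_TL_LS`, the top of
the severity scale. The second block is a parameter-recovery check: cohorts
of 1,062 subjects are simulated with a craniofacial-malformation risk whose
log-odds rise by 0.36 per severity unit (intercept calibrated to 64
expected cases), refitted by IRLS each time — the mean estimate returns the
generating slope.

## Pipeline

Either through the numbered drivers

```
python analysis/01_simulate_cohort.py --seed 42
python analysis/02_classify_columns.py
python analysis/03_code_malformations.py
python analysis/04_correspondence.py
python analysis/05_severity_glms.py
python analysis/06_parameter_recovery.py
```

(each prints what it found and writes its tables under `results/`), or
through the equivalent CLI: `vertpattern simulate|classify|code|analyze|report`.
Stages compose via CSV files; every output carries the schema version, seed
and config hash in a comment header, and a fixed seed reproduces every file
byte-for-byte.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's headline quantities from scratch: the severity
scores and presacral count of hand-built example columns; the pattern-class
percentages of a freshly generated 10,000-subject cohort after morphology
synthesis and rule-based classification; and the mean IRLS-recovered
severity slopes for three published association models (craniofacial,
segmentation-defect and no-malformation outcomes) over 200 simulation
replicates at n = 1062. Results are written as JSON keyed by target id.

See `docs/methods.md` for the model details, generator assumptions, default
parameters and known limitations.
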