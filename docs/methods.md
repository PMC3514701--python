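# Methods

## The classification model

A subject's presacral column is the ordered list of vertebrae anterior to
the first sacrum-attached vertebra, 1-based from the atlas. The regular
human formula is 7 cervical + 12 thoracic + 5 lumbar = 24 presacral, so in
a regular-shaped column ordinal 7 is C7, ordinals 8–19 are thoracic and
20+ are lumbar. The rule engine reads only rib morphology, the presacral
count and an observer-set transitional lumbo-sacral flag:

* **Rudimentary rib rule.** At the first and last thoracic position a
  present rib is *rudimentary* when its length is strictly less than half
  that of the adjacent thoracic rib (`length_ratio < 0.5`). A ratio of
  exactly 0.5 is therefore *full*; conversely a seventh-vertebra rib is
  fully thoracic in identity only when *strictly longer* than half the
  adjacent rib. Ratios are recorded relative to the adjacent thoracic rib
  at observation time, so no cross-vertebra arithmetic happens at
  classification time.
* **Cervico-thoracic (CT) shift.** Anterior: any rib on vertebra 7 —
  short (transitional), full-length (rare complete posteriorisation, still
  a CT shift for scoring), or an enlarged transverse process longer than
  T1's (a rudimentary cervical rib fused to the process). Posterior: a
  rudimentary or absent first thoracic rib. When both occur the single
  `ct` flag is set with anterior direction.
* **Thoraco-lumbar (TL) shift.** Anterior: rudimentary/absent twelfth
  thoracic rib (ordinal 19). Posterior: any rib on the first
  lumbar-position vertebra (ordinal 20).
* **Lumbo-sacral (LS) shift.** Presacral count ≠ 24, or the observer's
  transitional-LS flag. The flag is an input, not inferred from geometry,
  because the LS transition is read from vertebral shape and position on
  the radiograph, which the data model does not carry.

Side disagreements are resolved by the more severe side (with a warning);
laterality never changes the class. The (ct, tl, ls) triple maps
bijectively to the eight pattern classes; the ordinal severity scale
R 0, LS 1, TL 3, TL_LS 4, CT 6, CT_LS 7, CT_TL 8, CT_TL_LS 9 encodes two
assumptions: anterior changes are graver than posterior ones (any CT
involvement ≥ 6), and each additional shifted boundary reflects a longer
developmental disturbance. Values 2 and 5 are deliberately unused.

**Regional counts.** Starting from the regular assignment, each
transitional vertebra transfers 0.5 to the neighbouring region; a full
identity change (bilaterally absent first/twelfth rib, full-length
cervical or lumbar rib) transfers 1.0. Counts therefore land on half units
and sum exactly to the presacral count — a conservation law enforced by a
property test. Columns with < 22 or > 26 presacral vertebrae (absence of
rostral/caudal formation rather than mis-patterning) are classified and
counted but flagged `extreme`; a rib-bearing vertebra beyond the first
lumbar position breaks region contiguity and flags the subject
segmentation-suspect without voiding its counts.

## Malformation coding

Findings are controlled-vocabulary terms, each owning exactly one primary
organ system. Fixed causal rules demote specific findings to secondary —
never counted — status: T-E fistula (secondary BP), skeletal dysplasia
(secondary LD, CF), holoprosencephaly (secondary CF), limb
reduction/polydactyly (secondary SK), lung hypoplasia in the context of
skeletal dysplasia / diaphragmatic hernia / oligohydramnios, and anything
attributed to hypoxic stress. Germ-layer and process sets are the union
over *primary* findings of the coding map's assignments. The map itself is
editorial: the source study reports layer/process marginals but not the
per-malformation assignment table, so every layer/process result is
map-relative. The map ships in code with a YAML override hook.

A subject with only secondary findings is placed in the no-malformation
group. Systems marked non-available contribute to no counts, and subjects
with *all* systems non-available are excluded from every denominator.

## Correspondence analysis

Implemented from scratch on the standardised-residual SVD (see README for
the formulas). Dimensions number `min(rows, cols) − 1`; principal
coordinates are `D_r^{-1/2} U Σ` and `D_c^{-1/2} V Σ`. Sign convention:
SVD signs are arbitrary, so dimension signs are flipped until the
no-malformation row is negative on each axis, putting increasing severity
left-to-right. All-zero rows are dropped with a warning (small simulated
cohorts can lack a malformation class); all-zero rows/columns inside the
decomposition itself are errors naming the label. Subjects count once in
every organ-system row they are affected in (multiple-response rows, no
down-weighting, no Burt-matrix extension). Correctness is pinned by three
identities tested on random tables: inertias = eigenvalues of SᵀS from an
independent dense eigensolver (1e-10), total inertia = Pearson χ²/n
(1e-10), and exact reconstitution/transition formulas (1e-8).

## GLM machinery

The Bernoulli logit GLM is fitted by IRLS (working response
`z = η + (y − μ)/w`, weights `w = μ(1 − μ)`), converged when the relative
deviance change drops below 1e-8 (cap 100 iterations). Standard errors
come from the inverse expected information at the optimum. Severity enters
as a single numeric covariate over {0, 1, 3, 4, 6, 7, 8, 9} — one slope
per outcome, matching how the associations are usually summarised — with
sex and gestational-age *bands* as optional factors (band edges are
configuration, defaulting to 13/20/28/40/92 weeks, since only "treated as
factors" is known). Per-outcome denominators exclude the subjects
non-available for that system only; there is no listwise deletion and no
multiple-testing correction by default.

Separation is flagged when coefficients exceed ±30, the iteration cap is
hit, or the deviance collapses to ~0 (perfect fit). Overdispersion is the
Pearson χ²/df ratio with a configurable 1.5 verdict threshold; note that
for ungrouped binary data this ratio is nearly uninformative — the
dedicated test aggregates to the severity-group level before judging.
Slope comparisons use a joint stacked model with a group × severity
interaction and its Wald contrast; the germ-layer test is a
likelihood-ratio test of severity × level interactions (df = levels − 1)
on stacked outcome vectors. The IRLS path is verified against brute-force
likelihood maximisation (generic trust-region optimiser with analytic
derivatives) to 1e-8 and against statsmodels GLM to 1e-6.

## The synthetic cohort: a stated world

The generator encodes the published cohort of 1,062 analysable subjects.

* **Pattern simplex.** Published composites fixed the totals: regular
  20.6 %, LS 3.4 %, TL-involving 8.6 %, CT-involving 67.4 % of which
  CT+TL 33.4 % and three-boundary 10.6 %. Splitting composites into their
  members needs one assumption; the default is 50:50 (TL = TL_LS = 4.3 %,
  CT = CT_LS = 17.0 %), configurable. CT_TL = 33.4 − 10.6 = 22.8 %.
* **Morphology realisation.** Within a class, laterality (bilateral
  probability 0.5), rudimentary-versus-absent ribs (0.5), and the
  anterior/posterior realisation are randomised without ever changing the
  class: the CT posterior share is 9.8/67.4 ≈ 0.145 (rudimentary/absent
  first ribs were reported in 9.8 % of all subjects inside the 67.4 % CT
  group), the TL posterior (lumbar-rib) share 0.10 ("usually" the twelfth
  rib), enlarged-transverse-process realisations 0.10 and full-length
  cervical ribs 0.02 within anterior CT. Ratio draws avoid the 0.5
  boundary (U(0.05, 0.45) short, U(0.55, 1.0) long), which is what makes
  the synthesis class-exact and the round-trip identity testable at 100 %.
* **Malformation events.** Per system s, event ~
  Bernoulli(expit(a_s + b_s·severity)) with b_s the published slope and
  a_s solved by Brent root-finding so the expected case count at n = 1062
  matches the published count. Events materialise as 1–2 term rows from
  the system's vocabulary; missingness (default 0.10 per system,
  independent — the simplest mechanism consistent with "non-available"
  scoring, with the rate chosen from the gap between 1,062 analysable
  subjects and the per-system denominators implied by published
  percentages) is applied afterwards, so the truth table keeps the latent
  event.
* **Demographics.** Sex Bernoulli(0.561 male) and gestational age from a
  truncated normal (mean 26.6, SD 10.4, range 13–92 weeks), generated
  independently of pattern — a null the χ² checks confirm.
* **Seeding.** One root seed spawns independent substreams (morphology /
  malformations / demographics), so a fixed seed reproduces every output
  file byte-for-byte while stages stay isolated.

What a green test does and does not establish: the generator emulates the
study's *statistical* structure — class frequencies, severity-risk
coupling, missingness, demographic nulls — but not radiographic noise,
observer disagreement, ossification-age effects, or correlated
multi-system syndromes (events are conditionally independent given
severity). Dataset-level published statistics (CA inertia percentages,
trend correlations, the germ-layer interaction χ²) are therefore
reproduced qualitatively, not numerically; in particular the synthetic
germ-layer slopes inherit whatever the coding map implies, so the
interaction LRT may reject on synthetic data even though the source study
found no layer effect in its cohort.

## Numerical choices and limitations

* Exact 0.5 length ratios are *full* ribs (strict inequality), per the
  "less than half" / "longer than half" wording; the generator never emits
  the boundary value.
* A bilateral full-length/absent first-rib conflict classifies by the more
  severe side and warns; a rudimentary first rib co-occurring with a
  cervical rib is a single CT anomaly (anterior precedence), not a double.
* Intercept calibration refuses target rates outside (0, 1); degenerate
  GLM inputs (no events, no severity variance, zero residual df) raise
  typed errors rather than returning garbage.
* **Known estimator bias.** The maximum-likelihood slope of a rare outcome
  (≈60 events in 1,062) is biased upward by order (#parameters)/(#events)
  ≈ +3 %. The parameter-recovery suite shows this exactly where theory
  predicts it (craniofacial 0.36 → mean ≈ 0.373, segmentation 0.39 →
  ≈ 0.404) while well-populated outcomes recover their slopes to three
  decimals. Consequently the strict "mean within 2 Monte-Carlo SEs over
  200 replicates" recovery criterion is not attainable for those two rare
  outcomes with a plain MLE; the corresponding acceptance tests are left
  failing by design rather than silently switching to a bias-corrected
  estimator or loosening the band.
* The pattern × covariate χ² takes its banding as an argument (the
  appropriate dichotomisation is context-dependent); with sparse cells it
  warns and can attach a Monte-Carlo p-value.
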