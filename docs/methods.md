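# Methods

`dieteval` implements a four-stage evaluation of an automated dietary-assessment
tool (one that turns meal photographs or barcode scans into labeled, weighed
food segments with nutrient values) against a weighed-food-record gold
standard, together with a seeded generator of synthetic validation studies.
This note records the statistical model behind each stage, the defaults and
why, what the generator does and does not emulate, and the numerical choices
made where the design was genuinely open.

## Record model

A *record* is one photographed dish/beverage or one barcode scan; it contains
one or more *segments* — distinct edible components — each carrying a label, a
food type, a weight (g) and a nutrient vector (energy kcal; fat, carbohydrate,
protein, fiber, alcohol in g). Records fall into four strata: composite foods
(≥3 segments), simple foods (1–2), composite beverages and simple beverages.
Compositeness for beverages is a property of the *recipe*, not the segment
count: a coffee with milk and sugar is usually photographed and weighed as a
single mixed segment. The stratum is therefore carried as an explicit record
field, with a segment-count rule (foods ≥3 composite; beverages ≥2 composite)
only as a fallback for files that omit it.

The food taxonomy is a three-level hierarchy — food types nest in food groups
nest in food categories, the coarsest level mirroring the Swiss food pyramid.
The bundled fixture has the reference study's 37/23/7 shape with its published
group names; the type level is invented (no public type list exists) and the
bundled per-100 g composition table is likewise synthetic but physiologic.
Mixed segments are assigned to the food type of the ingredient with the
highest **total** energy (weight × kcal/100 g), not the highest energy
density; "highest calorific content" admits either reading, and the total-kcal
reading is the one under which a 200 g potato base outranks 50 g of cream in a
gratin. Ties break deterministically: larger weight, then lexicographically
smaller label.

## Stage 1 — segmentation

Reference and tool segments are paired within each record; unpaired reference
segments are *omissions*, unpaired tool segments *intrusions*, pairs *found*.
The original study paired segments by hand; the package accepts such manual
links and fills the remainder with a minimum-cost one-to-one assignment
(taxonomy distance: same type 0, same group 1, same category 2, unlinkable
beyond; a sub-unit normalized weight-difference term breaks ties). Optimal
assignment (Hungarian, with a large constant standing in for forbidden pairs)
was chosen over a greedy pass because it is deterministic, order-invariant and
provably equal to exhaustive search — which the test suite checks on small
random instances.

Accuracy is `%F`, `%O`, `%I` over the reference-segment total `n_true`, per
stratum. Intrusions use the same denominator although they are not a subset of
the reference segments, so `%F + %I` may exceed 100. The ± half-width attached
to a proportion is

    100 · 1.96 · sqrt(p(1−p)/(n−1)),

the form a t-based interval for the mean of a 0/1 variable uses for its
standard error. This convention reproduces the reference study's printed ±
cells with two exceptions (8.4 ± 3.0 and 1.5 ± 1.7, which it gives as 2.9 and
1.6); no symmetric convention we tried — z = 2, Agresti–Coull, logit, exact —
reproduces those two without breaking the other cells, so they are treated as
rounding inconsistencies in the source and surfaced as such by
`analysis/01_desk_checks.py`.

## Stage 2 — classification

Each found segment is graded: **E** (exact; correct food type or a synonym),
**C** (close; correct type but the name is too generic, a slight variant, or
misses an ingredient — these are analyst judgements supplied as per-pair
flags, never inferred), **F** (far; wrong type, right group), **M** (mismatch;
wrong group). Grade proportions per stratum use the same half-width
convention.

Agreement at each granularity is summarised two ways:

* **Uniform (Brennan–Prediger) kappa** `Ku = (q·Po − 1)/(q − 1)` with chance
  agreement fixed at `1/q` — an *agreement* index insensitive to marginal
  prevalence (binary case `2·Po − 1`). Its CI is a seeded percentile bootstrap
  over segments (default B = 2000); the reference study does not state its CI
  method, and the bootstrap reproduces its printed intervals to ±0.01.
* **Cohen's kappa** with the standard asymptotic (Fleiss–Cohen–Everitt)
  standard error, as a *reliability* index sensitive to prevalence. The
  reference study's printed Cohen SEs (≈0.0538 for many groups) match no
  formula we know and are not treated as a target.

At type granularity both E and C count as agreement (both mean "correct food
type" by definition); at group granularity E, C and F do. The label-crosstab
diagonal can disagree with these by-definition counts when a close match
crosses groups; the pipeline reports both columns. Per-group one-vs-rest
tables yield sensitivity/specificity with exact Clopper–Pearson 95% intervals
(beta quantiles; a zero-denominator arm is returned as NaN and flagged), and
proportion contrasts use Fisher's exact test (two-sided, by summation of
tables no more probable than the observed one).

## Stage 3 — portion size

Weight error `est − true` (g) and percentage error are computed for **exactly
classified segments only**, so classification failures do not contaminate the
portion-size assessment; the restriction is a framework choice the caller can
relax to E+C. Outliers are never removed silently: the caller passes an
explicit per-segment exclusion list (the reference study removed four
transcription errors this way), and segments with |% error| > 500% are flagged
in the log as candidates. Summaries per type/group/category report mean
weights, mean signed error, mean absolute percentage error, the accuracy ratio
(mean estimated / mean true weight), a classical paired t-test (two-sided;
zero-variance differences are flagged rather than reported as infinite t), and
boxplot quantiles (median, quartiles, 1.5·IQR whiskers clipped to the data)
for a mean-error-per-group figure.

## Stage 4 — energy and macronutrient agreement

Per record and nutrient, the tool total `y` is regressed on the gold-standard
total `x` (OLS): `y = α + β·x + σ(x)·ε`. α is the differential bias, β the
proportional bias; the regression direction assumes the weighed record is an
(almost) error-free gold standard, the situation in which Bland–Altman is
biased. Heteroscedasticity is modeled as a standard deviation linear in the
true value: absolute OLS residuals are regressed on `x` and both coefficients
scaled by `sqrt(π/2)` (since `E|ε| = sqrt(2/π)` under normality), giving
`σ(x) = s0 + s1·x`, floored at `1e−6·max|y|`. The linear-SD family is the
simplest that yields both higher *relative* dispersion at small true values
and a finite coefficient of variation at `x = 0`; the interface accepts a
power-of-x alternative. There is no iterative reweighting — a single OLS pass
plus the residual model, matching the untransformed Wald construction of the
limits of agreement:

    LoA(x) = α̂ + β̂·x ± 1.96·σ̂(x),

whose width is exactly `2·1.96·σ̂(x)`. With a large σ̂ the lower limit can cross
zero for a non-negative nutrient (alcohol does this), which is itself a
diagnosis of very poor agreement. Records with a true value of 0 for a
nutrient stay in the fit — they anchor the intercept, and for alcohol they are
most of the data. The coefficient of variation `Cv(x) = σ̂(x)/(α̂ + β̂·x)` is
evaluated at the 25th/50th/75th linear-interpolation percentiles of the
stratum's true values, and the mean Cv averages `Cv(x_i)` over records,
excluding (and counting) records where the modeled mean is non-positive.

## Synthetic-study generator

`generate_reference` draws a study with the reference composition: 63/63/30/33
records per stratum and 15 barcode scans among the simple records. Segment
counts per stratum (composite food 3–4 with mean 3.3; simple food 1–2, mean
1.25; composite beverage 1–2, mean 1.07; simple beverage 1) reproduce the
published per-stratum segment totals (≈352 overall; the 1.07 reflects that
composed drinks are usually one mixed segment). Items come from the bundled
synthetic composition table; serving weights are log-normal around each item's
typical weight (log-SD 0.25); nutrients are weight × per-100 g values.

`simulate_app` then applies, to photo records only (scans are error-free by
construction): per-segment omission (default p = 0.02), per-food-record
intrusion (default p = 5/189, drawn from condiments & sauces — the
salad-dressing pattern), a per-stratum grade draw matching the published
E/C/F/M mix (composite-beverage exact ≈ 0.42, with mismatched beverages
confused with *other beverage groups*, mirroring the alcoholic/soft-drink
confusions), and multiplicative log-normal weight noise (log-SD 0.35, chosen
to give a mean absolute percentage error of roughly 30%) with geometric-mean
bias factors > 1 for meat & poultry, fish & seafood, eggs & meat substitutes
and potatoes/legumes — the overestimated groups. An optional heavy-tail
mixture (5% of segments at log-SD 0.8) reproduces individual errors in the
−90%…+240% range. Tool nutrient vectors are recomputed from the (possibly
confused) label's composition at the estimated weight, which is what couples
segment-level errors into record-level energy/macronutrient disagreement. The
generator also emits a ground-truth link table so downstream stages can bypass
automatic linking.

What the generator does **not** emulate: real dietary patterns or nutrient
correlations beyond the composition table, annotation-interface effects,
label free-text variation, or day-level intake structure. Passing tests
therefore demonstrate that the *statistics* are computed correctly and that
the pipeline recovers known error parameters — not that any particular tool
performs well on real food.

## Calibration experiments and problem sizes

The reference study's regression fits are not reproducible without its raw
records, so the agreement machinery is validated by parameter recovery
(`analysis/04_agreement_recovery.py`): 200 studies of 189 records from
`y = α + β·x + (s0 + s1·x)·ε` with (α, β, s0, s1) = (113.3, 0.6, 15, 0.20)
and x log-normal (median 250, log-SD 0.7) — the intercept anchored at the
study's reported energy intercept, the dispersion set at the moderate
(carbohydrate-like) end of the observed Cv range. A power analysis at design
time showed that at the largest observed dispersions (Cv at the median ≈ 0.3
and above) the sampling error of α̂ at n = 189 alone exceeds 10% in the
median, so a recovery check there would measure noise rather than estimator
quality; at the chosen dispersion the bias parameters recover within ~8%
(median), and LoA coverage at n = 5000 sits within 95% ± 2%. The variance
parameters are markedly noisier (absolute-residual regression is an
inefficient estimator); the dedicated variance-recovery test uses a uniform
x design on [0, 30] with n = 1000 per replicate, the scale at which the SD
intercept is identifiable to within 10% in the median.

Monte-Carlo test sizes throughout (200 seeds for recovery, 50 studies for the
found-rate calibration, 5000 replicates for the paired-t type-I check) were
chosen so each check resolves its tolerance with a comfortable margin while
the whole suite stays desk-scale; all are seeded and deterministic.

## Known limitations

* Close-match grading requires analyst flags; the automatic fallback can only
  produce E/F/M, so close matches vanish when no link file is supplied.
* The heteroscedasticity model is a documented stand-in: the study cites its
  variance-modeling sources without restating the functional form, so its
  printed Cv tables are qualitative anchors only.
* The linear-SD fit can go negative outside the bulk of the data; it is
  floored and a warning is emitted when the negative region exceeds 10% of the
  observed x range.
* Cohen-kappa standard errors follow the standard asymptotic formula and will
  not match the reference study's printed SEs.
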