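# Methods

## Rule engine

A criterion is a tuple (predicates, mandatory set or gate, minimum count).
Predicates carry the printed comparator literally: waist is inclusive
(≥ 90/80 harmonized and IDF, ≥ 94/80 EGIR) except for the NCEP-ATPIII
(> 102/88) and Barbosa 2006 (> 88/84) cutoffs, which are strict; HDL is
strict `<`; TG, BP and glucose are inclusive `≥`. Boundary behaviour is
asserted at every cutoff in the tests because a participant measured exactly
at a cutoff flips classification under the wrong comparator. The blood
pressure component is the union event SBP ≥ s OR DBP ≥ d (130/85, or 140/90
for EGIR).

Treatment/diagnosis substitutions: prior DM diagnosis or DM treatment makes
the glucose component positive, and antihypertensive (SAH) treatment makes
the BP component positive, in every criterion that has those components.
Lipid-treatment substitution is not implemented: the source cohort was not
asked about dyslipidemia treatment, and adding it would change what the
reproduced numbers mean.

Two definitions need gates the cohort's measurements cannot express
directly:

* **EGIR** requires insulin resistance (top-quartile fasting insulin), but
  the cohort has no insulin assays. The gate is operationalized as fasting
  glucose ≥ 110 mg/dL or prior DM diagnosis/treatment — the only
  EGIR-specific glycemic threshold the study tabulates — and is a
  configurable predicate, not a constant. This proxy is a documented guess;
  its only external validation is that it produces a low prevalence of the
  right order (4.68% in the reference counts against 7.47% glucose-110
  positivity).
* **AACE** gates on *risk* of insulin resistance: any one of CVD,
  hypertension diagnosis, PCOS, NAFLD, Acanthosis nigricans, family history
  of T2DM/HTN/CVD, gestational-DM or glucose-intolerance history, non-white
  ethnicity, sedentary lifestyle, age > 40 years, BMI ≥ 25 kg/m², or
  WC > 94/80 cm (M/F). The two history flags are tri-state; unknown never
  satisfies the gate (conservative — the cohort was not asked). The AACE
  component set is TG, HDL and BP only: the study could not apply the
  oral-glucose-tolerance component, and its tabulated AACE rules carry no
  waist or glucose row. A switch (`aace_glucose_component=True`) restores an
  impaired-fasting-glucose component for canonical AACE use.

The published cutoff table's footnote markers are internally shifted by one
relative to its footnote list; the implementation adopts the alignment under
which every row matches the canonical published definition (EGIR HDL < 39
and BP ≥ 140/90; AACE without waist/glucose rows). Internal consistency was
preferred over a literal reading of the markers.

## Accuracy metrics

2×2 construction, the Se/Sp/PPV/NPV formulas, LR definitions and the 2×2
kappa closed form are implemented directly (they are the package's subject
matter); Clopper-Pearson bounds come from statsmodels' beta-quantile
implementation. Choices the reference tables pin down:

* **Proportion CIs**: Clopper-Pearson exact. The study does not name its
  method; CP reproduces all three printed boundary bounds (52/52 → 93.2%,
  290/290 → 98.7%, 330/330 → 98.9%), which Wilson/Wald do not.
* **LR CIs**: Simel log method, ln LR ± 1.96·√(1/a − 1/(a+c) + 1/b − 1/(b+d))
  for LR+ and the (c, d) analogue for LR−; validated against the printed
  AACE LR+ interval (29.6–212).
* **Undefined metrics**: a zero denominator yields an undefined estimate
  ("-" in tables, null in JSON) rather than an exception or an infinity —
  matching how accuracy studies print LR+ when a test produces no false
  positives.
* **Kappa bands**: ≤ 0.20 slight, ≤ 0.40 fair, ≤ 0.60 moderate, ≤ 0.80
  substantial, > 0.80 almost perfect (upper bounds inclusive). Under these
  bands κ = 0.8750 is "almost perfect".
* **Rounding** in formatted output: percentages to 1 decimal, κ to 4
  decimals, LRs to 3 significant figures; full precision is kept internally.

`reconstruct_confusion(n, gold_pos, test_pos, ppv)` inverts the published
summary counts: a = round(ppv·test_pos), b = test_pos − a, c = gold_pos − a,
d = n − gold_pos − b, erroring on any negative cell. With PPV printed to 3
figures this recovers a exactly for every criterion here (the rounding
ambiguity is < 0.5 counts); the induced slack on κ is below 2×10⁻⁴ and is
the tolerance used where the published PPV is the input.

## Descriptive comparisons

Sex comparisons of categorical variables use Pearson chi-square without
continuity correction — the variant that reproduces the study's printed
p-values (0.450, 0.557); Yates does not. Continuous variables are routed by
a per-stratum Kolmogorov-Smirnov check against a normal with the sample's
own mean/SD at α = 0.05: both strata normal → pooled-variance t-test,
otherwise Mann-Whitney U (two-sided, scipy's exact/asymptotic-with-ties
policy). Using estimated parameters makes the nominal KS p-value
anti-conservative (the Lilliefors caveat); this mirrors common practice and
the study's stated procedure rather than correcting it. Whether the study
ran KS per stratum or pooled is unstated; per-stratum is implemented.
Component-positivity rows in summary tables are computed from the same
predicate objects the classifier uses (measurement-only, substitutions
excluded, as clinical descriptive tables do), so cutoffs have a single
source of truth.

## Synthetic cohort

The generator's defaults are the study conditions: n = 1111, 87.7% female,
per-sex means/SDs of the seven continuous measures (e.g. female fasting
glucose 84.48 ± 18.04 mg/dL), and per-sex component positivity at the
harmonized cutoffs (e.g. female WC ≥ 80: 68.31%; male HDL < 40: 22.79%; TG ≥
150: 32.31%/41.18% F/M).

Mechanism: five component latents under a Gaussian copula with exchangeable
correlation ρ = 0.3 (the study reports no component correlations; ρ is a
modeling assumption, configurable, and a trend test asserts that prevalence
rises with ρ at fixed marginals). Each measure is a location-shifted normal
keeping the reference SD, with the location chosen so the cutoff quantile
equals the target positivity (quantile matching). The reference means/SDs
alone cannot reproduce the reference positivity fractions — the real
distributions are skewed — and downstream classification consumes
exceedances, not means, so positivity wins and means shift slightly (≈1–6
mg/dL or cm). SBP and DBP share one latent (comonotone within subject) with
both margins matched to the same target, so the 130/85 union event hits the
target exactly; the price is a perfect within-subject SBP-DBP rank
correlation, which is not realistic but harmless to every rule evaluated
here (BP enters all six criteria only through threshold-union events, whose
rates remain calibrated at both the 130/85 and — approximately — the 140/90
pair). BMI rides on the waist latent (loading 0.8); age is normal
(34.5 ± 9 y, clipped to 20–70) placing 52% below 35 as in the reference
cohort; treatment/diagnosis flags are drawn conditionally on raw component
positivity (0.5/0.02 treated given positive/negative) so substitution code
paths are exercised; the remaining AACE risk flags use small fixed
probabilities, with sedentary (43.3%) and non-white (74.8%) at the reference
fractions.

Calibration targets refer to the *measured* predicate (value vs cutoff) —
the quantity the reference positivity rows tabulate — not the
flag-substituted component, which the treatment flags deliberately inflate.
Targets of exactly 0 or 1 are admitted for inclusive comparators (pushed to
the 10⁻¹² quantile, so no finite cohort produces a positive) and rejected
for strict ones. Physiological floors (e.g. glucose ≥ 40 mg/dL) keep records
valid without touching any cutoff neighbourhood.

What the generator does *not* emulate: the real joint distribution of
components (only one exchangeable correlation), skewness of the marginals,
measurement error, or clustering by municipality. Consequently simulated
prevalences and agreement statistics are close to but not equal to the
published ones (harmonized prevalence ≈ 29–30% vs 31.23%; the κ ordering
IDF > Barbosa > NCEP > AACE > EGIR is reproduced, the EGIR/AACE values are
not, because they hinge on flag-component dependence the study does not
report). The published accuracy numbers are therefore reproduced from the
reconstructed 2×2 tables, never from simulation; passing synthetic tests
demonstrates correctness of the rules and metrics, not fidelity of the
simulated population.

## Numerical and scale choices

Everything is deterministic given the seed (numpy `default_rng`). Test and
script problem sizes — 500 records for the dual-implementation oracle,
20,000 for 3-SE marginal calibration, 50,000 for the Poisson-binomial
prevalence limit, 10,000 replicates for CP coverage — were chosen so each
check's Monte-Carlo error is well below the effect it guards, while the full
suite runs in seconds. The ≥3-of-5 closed form used as the independence
limit is the exact Poisson-binomial tail mixed over the sex strata.

## Known limitations

* The EGIR insulin-resistance proxy is unvalidated against insulin assays.
* Reconstruction from published counts inherits the counts' printed
  rounding (only the κ slack above is affected).
* The marital-status female cell of the published descriptive table is
  internally inconsistent (sums to 1005, not 975); the package uses the
  percentage-consistent count (447), which reconciles the totals and
  reproduces the published p = 0.557.
* Sex-stratified *accuracy* is intentionally not computed (the reference
  analysis found sex differences insufficient to justify it); sex-stratified
  prevalence is.
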