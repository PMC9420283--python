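# Methods

## Model and assumptions

The pipeline is a theoretical comparative risk assessment. Its inputs are
summary relative risk estimates (SRREs) from published meta-analyses of
prospective studies, comparing the highest against the lowest dairy-intake
stratum, together with cause-level disability-adjusted life year (DALY)
totals. Nothing in the package pools studies or estimates relative risks:
SRREs and DALY totals are data.

Three assumptions are inherited from the attributable-risk framework and
are worth stating plainly:

1. **Counterfactual causality.** Attributable and preventive fractions are
   only interpretable if the exposure causes (or prevents) the outcome.
   The inputs are observational meta-analyses; no causal assessment is
   performed, so all outputs are scenario quantities, not forecasts.
2. **Single-factor attribution.** No adjustment for other risk factors or
   interactions; attributable fractions across causes of one outcome may
   sum past 100%.
3. **Transportability.** The SRREs pool cohorts from several countries,
   while the DALY totals are US 2019 values.

## Statistics

For prevalence of exposure Pr ∈ (0, 1] and a protective relative risk
RR ∈ (0, 1]:

* preventive fraction: `PF = Pr (1 − RR)`
* inverted risk (low intake as the harmful exposure): `RR_I = 1 / RR`
* population attributable risk proportion:
  `PARP = Pr (RR_I − 1) / [1 + Pr (RR_I − 1)]`

Algebraically `PARP = Pr (1 − RR) / (RR + Pr (1 − RR))`, which the test
suite uses as an independent closed-form cross-check (≤ 1e−12 relative).
Since RR ≤ 1 implies the denominator ≤ 1, PARP ≥ PF everywhere, strictly
so for RR < 1 and Pr < 1; both vanish at the null. Harmful-direction
inputs (RR > 1 in `preventive_fraction`, RR_I < 1 in `parp`) raise domain
errors rather than returning negative fractions: the workflow is defined
for protective evidence only, and routing a harmful estimate through it
silently would flip the sign of every downstream number.

Burden application is plain scaling: preventable DALYs = PF × DALY total,
attributable DALYs = PARP × DALY total. The DALY decomposition
DALY = YLL + YLD with YLL = N × L and YLD = I × DW × L is implemented for
stratified inputs (cause × sex × age × year); age-weighting and time
discounting are omitted because the cause-level totals used in the main
analysis are already aggregated that way, and the standard loss function
L(s, a) is always a lookup-table input, never hard-coded.

## Inclusion logic

Two deterministic gates replace the judgment calls of a literature review:

* **Significance gate:** the 95% CI must lie entirely below 1.0 (strict
  inequality). A CI touching the null exactly — as in one considered
  prostate-cancer meta-analysis with CI 1.00–1.78 — is treated as
  marginal and excluded; this is the conservative reading.
* **Burden gate:** the outcome must have a cause-level DALY entry.
  Outcomes like osteoporosis, with significant SRREs but no DALY estimate,
  drop out here with a logged warning rather than an error.

When several meta-analyses cover one (outcome, exposure) cell, the most
recent publication wins; ties go to the larger study count, then to the
lexicographically smallest first author. "Most analytically
comprehensive" is operationalized as study count because no other
measurable definition is available; the final author tie-break is a
repository convention chosen only to make selection a pure function of
the candidate set.

## Parameters

| Parameter | Default | Units | Why |
|---|---|---|---|
| prevalence grid | 0.15, 0.25, 0.35, 0.50 | proportion | conservative range for the share of the population at the studies' highest intake stratum (current US adherence to dairy recommendations is ~12%) |
| significance threshold | CI upper < 1.0 | — | strict protective significance |
| fraction display rounding | 2 decimals (percent) | % | matches published precision |
| burden display rounding | 1 decimal | person-years | matches published precision |

All computation keeps full double precision; rounding happens once at
report time, and burden cells round the product of the *unrounded*
fraction with the DALY total — rounding the fraction first does not
reproduce the published tables.

## Numerical choices

Display rounding is half-up (ties away from zero), implemented through
`decimal.Decimal` with a two-stage quantization: values are first
quantized six digits below the target precision, then to the target. This
recovers intended exact decimals from their binary representation —
e.g. 0.0135 × 4,275,100 = 57,713.85 exactly, but the nearest double is
57,713.849999…, which naive half-up rounding would truncate to 57,713.8
instead of the published 57,713.9. The guard stage can only affect values
within 5e-7 of a rounding boundary, far coarser than the ~1e-16 relative
error of the arithmetic itself.

Golden-table verification compares cells after display rounding with an
exact-match tolerance (1e-9 on the rounded values). Two cells in the
published low-fat-dairy × breast-cancer row (Pr 35%: PF 4.80%, preventable
DALYs 62,016.0) are inconsistent with the stated formula, which gives
5.60% and 72,352.0 — the printed cell corresponds to Pr 30%. The pipeline
always outputs the formula value; the golden file flags these two cells
`known_discrepancy`, and the harness reports them separately instead of
counting them as failures. Results prose and tables disagree on one other
cell (high-fat stroke PF "1.4%" vs 1.35%); tables are treated as
authoritative.

## Synthetic data

The generators emulate the statistical *shape* of the real inputs, not
their content:

* **Evidence:** true RRs drawn log-normally (log-mean −0.18, log-sd 0.10,
  rejection-truncated to (0, 1)), putting most draws in the 0.68–0.95 band
  the real registry spans; symmetric 1.96-SE log-scale CIs with SE 0.04;
  study counts uniform on 2–21, matching the registry's range.
* **DALY inputs:** sex × age strata with deaths up to 20,000, loss years
  1–45, incidence up to 200,000, disability weights uniform on [0, 1] and
  durations 0.1–15 years — magnitudes loosely shaped like national
  chronic-disease inputs, chosen so aggregates land in the 10⁵–10⁷
  person-year range of the real cause totals.
* **Cohorts:** binary exposure where the *exposed* group has LOW intake
  (the harmful direction, matching the reference-group inversion in the
  PARP formula, and avoiding sign confusion between PF and PARP
  validation); disease is Bernoulli with baseline risk 0.05 in the
  high-intake group, a cumulative-incidence-style model consistent with
  how the input relative risks are defined. Cohorts of 10⁶ individuals
  give binomial standard errors small enough to resolve formula errors of
  a fraction of a percentage point; the empirical attributable fraction is
  computed from case counts alone (observed minus counterfactual cases
  over observed), independently of the closed form it validates.

What passing synthetic tests does **not** show: anything about real
meta-analytic heterogeneity, publication bias, confounding, measurement
error in dietary recall, or between-country transportability. The
generators draw exactly the quantities the formulas consume, so they
validate the arithmetic and the pipeline contracts, not the epidemiology.

All randomness flows through `numpy.random.default_rng(seed)`; every
generator is reproducible given its config.

## Problem sizes

The analysis path is tiny (14 estimates × 4 scenarios) and runs in
milliseconds. Property suites use dense grids (200 × 200 for the
closed-form identity, 50 × 50 for orderings); the microsimulation check
uses 20 (Pr, RR) cells at 10⁶ individuals each, drawn as group-level
binomial counts, so the full suite completes in a few seconds.

## Known limitations

* Point estimates only in the published-table pathway; the
  CI-substitution bounds (`interval_fractions`) are a package extension,
  clearly separated and excluded from golden comparisons.
* No multi-factor joint attribution, no dose–response integration over a
  continuous exposure distribution, no comorbidity adjustment of YLD.
* The evidence registry records heterogeneity statistics (I², p) as
  metadata only; no computation consumes them.
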