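# Methods

## The models

All four models estimate the probability of in-hospital survival of an
adult trauma patient from admission data, via the logistic form

    Ps = 1 / (1 + e^(-b)),

with a linear predictor `b` built from coded covariates and a separate
coefficient set per trauma mechanism (blunt vs penetrating):

| model id           | linear predictor                                         |
|--------------------|----------------------------------------------------------|
| `adjusted_triss`   | b0 + b1·RTS + b2·ISS + b3·age                            |
| `ntriss_like`      | b0 + b1·BMR + b2·SBPc + b3·NISS + b4·age                 |
| `triss_spo2`       | b0 + b1·GCSc + b2·SBPc + b3·SpO2c + b4·ISS + b5·age      |
| `ntriss_like_spo2` | b0 + b1·BMR + b2·SBPc + b3·SpO2c + b4·NISS + b5·age      |

Covariate codings:

* **GCSc, SBPc, RRc** — the Revised Trauma Score ordinal codes 0–4
  (GCS 13–15→4 … 3→0; SBP >89→4 … 0→0; RR 10–29→4, >29→3, 6–9→2,
  1–5→1, 0→0). Real-valued inputs band by interval membership.
* **RTS** — either the weighted total 0.9368·GCSc + 0.7326·SBPc +
  0.2908·RRc (range 0–7.8408) or the unweighted triage sum (0–12).
  The source description of the TRISS equation is internally
  inconsistent on this point (it defines RTS as the 0–12 total yet
  reports a cohort mean of 7.4, which lies on the weighted scale), so
  the scale is an explicit switch (`rts_scale`), defaulting to
  `weighted`; both settings are covered by tests and the discrepancy is
  documented rather than resolved.
* **BMR** — the best motor response item of the GCS, 1–6, taken from its
  own field. It is never reconstructed from a total GCS, because the
  decomposition of a total into eye/verbal/motor is not unique.
* **SpO2c** — 0 or not-measurable → 0; 1–80 → 1; 81–90 → 2; 91–95 → 3;
  96–100 → 4. "Not measurable" is a distinct token from missing: the
  former is a clinical finding that codes to 0 by rule, the latter a
  recording gap handled by policy (below).
* **ISS / NISS** — sum of squares of the highest AIS severity in the
  three most severely injured of six body regions (ISS) or of the three
  highest severities regardless of region (NISS); any AIS-6 lesion
  forces 75; an unknown severity (sentinel 9) makes both unscoreable.
* **age** — 0 below 55 years, 1 at 55 or older.

`e` is the true Euler constant; a `truncated_e` switch substitutes
the truncated 2.718282 some calculators print, shifting Ps by < 2e-7.

## Missing data

Policies (`resolve_missing`): the default
`spo2-zero-if-unmeasurable-only` codes not-measurable SpO2 to 0 but
leaves a truly absent SpO2 missing, so the record is refused by the two
SpO2 models and scoreable by the others. `spo2-zero-always` zero-fills
absent SpO2 (flagged); `complete-case` flags any record with any absent
covariate for outright exclusion. Absent GCS/BMR, SBP or RR always make
the models that need them refuse the record; nothing is imputed. How the
original derivation handled the 29.6% of records without SpO2 is not
stated in the source, which is why this is a switch rather than a fixed
rule.

## Coefficient derivation

The derivation recipe (module `derivation`):

1. **Split** — a seeded uniform draw without replacement of
   `n_test_per_site` (default 300) records per site forms the test set;
   the remainder is the derived set. The reference cohort (2416 + 8172
   records) thus leaves derived sites of 2116 and 7872.
2. **Site weights** — with two sites, each minority-site record gets
   weight majority/minority; `mode="published"` rounds to two decimals
   (3.72 for 7872/2116), `mode="exact"` (default) keeps the full ratio.
   Weights are computed on the whole derived set before mechanism
   stratification (a per-stratum recomputation switch exists).
3. **Fit** — per mechanism, the weight-multiplied Bernoulli
   log-likelihood is maximised by IRLS (Newton–Raphson with
   step-halving), initialised at β = 0, stopping when max |score| <
   1e-8 or the relative log-likelihood change < 1e-10, capped at 100
   iterations. Standard errors come from the inverse weighted observed
   information. Integer weights are exactly equivalent to row
   replication (tested to 1e-8). Separation is reported as
   `converged=False` with a named diagnostic — detected when the fit
   saturates every fitted probability or drives any coefficient beyond
   30 on the coded-covariate scale, both far outside the plausible
   range for these models. Rank-deficient designs raise an error naming
   the collinear columns. A mechanism stratum under 50 usable records
   is refused with a warning.

Whether the original coefficients came from separate per-mechanism fits
or a single interaction model is unstated; separate fits are used,
matching the two-column layout of the published table.

## Evaluation

AUC is the Mann–Whitney probability that a random survivor outranks a
random non-survivor (ties ½), identical to the trapezoidal area under
the empirical ROC. The 95% CI uses the DeLong closed-form variance by
default (deterministic and fast) or a class-stratified percentile
bootstrap (seeded, ≥200 replicates). The reported cutoff maximises the
Youden index, ties broken toward the higher threshold (favouring
specificity); the published table prints cutoffs without naming a
selection rule, so rule and tie-break are explicit configuration.
Scores are survival probabilities and the positive class is "survived";
`predict_death` relabels both, leaving the AUC unchanged.

## Synthetic registries

`synth.simulate_registry` generates cohorts with the reference margins:
90.4% blunt, mean age ≈ 42 (truncated normal, ≥14 years), a mean of
~2.1 injured regions, mean ISS ≈ 9.7 / NISS ≈ 12.8, ~5.9% mortality,
missingness SpO2 29.6%, RR 8.3%, GCS/BMR 4.3% (jointly), SBP 0.9%, and
0.5% of patients with an uncodable AIS severity.

Because only margins are published, the joint structure is invented: a
latent case-severity class (minor/moderate/serious/critical) selects an
AIS severity mixture, and admission physiology is drawn conditionally
on the worst AIS severity, which induces the anatomy–physiology
correlation the models rely on. Survival is Bernoulli(Ps) under a
packaged truth model (default `ntriss_like`, per mechanism) applied to
the complete pre-missingness covariates; recording missingness is then
applied missing-at-random, and "not measurable" SpO2 is a separate rare
state concentrated in severe patients. The free parameters were
calibrated once against the margins above and frozen.

Each record draws from its own counter-derived random substream, so
changing `n` never reshuffles earlier records and equal seeds give
byte-identical registries.

What passing tests on these registries show — and do not show: they
demonstrate that the pipeline recovers generating coefficients, that
the evaluation machinery matches its oracles, and that the packaged
models discriminate comparably on data with realistic margins. They do
not certify joint realism (the real ISS–physiology copula is unknown),
nor the models' calibration on any real cohort.

## Problem sizes and numerical choices

The test suite uses n = 4 000–20 000 registries (50 replicates at
20 000 for the recovery study, one 50 000 draw for calibration), chosen
so the whole suite runs in a few minutes on one core while keeping
Monte-Carlo error well inside the asserted tolerances. Logistic
evaluation is numerically stable up to |b| = 700 (log-sum-exp /
`expit`); Ps is kept at full double precision, rounding being a
presentation concern. Eligibility counts each excluded record once
under its first failing rule in the fixed order age → late admission →
transfer → mechanism, making reports deterministic. A record with
missing hours-from-event is eligible by default (most registry exports
omit the field); `strict_hours=True` excludes instead.

## Known limitations

* Penetrating strata are rare (~9.6%), so penetrating refits at small
  n are noisy — as in the source cohort, where the authors flag the
  penetrating results as needing external validation.
* The published 95% CI (0.85–0.94) is identical for all five reported
  models; whether that is per-model or a typographical collapse cannot
  be determined from the text, and no attempt is made to reproduce it
  as a constraint.
* MTOS coefficient sets (1987, 1995) ship as optional,
  literature-flagged extras for comparison; which revision the original
  comparator used is unstated, so both are provided.
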