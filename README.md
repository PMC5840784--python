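# trisskit

Survival-probability scoring for trauma registries.

Trauma services audit their quality of care by comparing observed
outcomes with the survival probability each patient had on admission.
The standard tool is TRISS, a logistic model combining the Revised
Trauma Score (RTS), the Injury Severity Score (ISS), age and trauma
mechanism. TRISS is hard to apply when prehospital intubation removes
the GCS and respiratory rate needed for the RTS, and the ISS ignores
multiple lesions in one body region. `trisskit` implements a family of
four models that address this — a population-adjusted TRISS plus three
variants that replace the RTS with directly measured physiology (best
motor response, systolic blood pressure, an SpO2 band) and/or the ISS
with the NISS:

    Ps = 1 / (1 + e^(-b))

    adjusted TRISS:    b = b0 + b1·RTS  + b2·ISS  + b3·age
    NTRISS-like:       b = b0 + b1·BMR  + b2·SBPc + b3·NISS + b4·age
    TRISS-SpO2:        b = b0 + b1·GCSc + b2·SBPc + b3·SpO2c + b4·ISS  + b5·age
    NTRISS-like-SpO2:  b = b0 + b1·BMR  + b2·SBPc + b3·SpO2c + b4·NISS + b5·age

each with separate published blunt and penetrating coefficient sets
(packaged, reproduced digit for digit), age dichotomised at 55 years
and SpO2 banded 0–4 (0 or not measurable → 0, …, 96–100 → 4).

The package is aimed at trauma registrars and outcome researchers and
covers the full workflow:

* **registry** — CSV I/O with configurable schema and missing /
  not-measurable tokens, eligibility filtering (age ≥ 14, admission
  ≤ 24 h, not transferred, known mechanism), explicit missing-data
  policies;
* **severity** — ISS, NISS, RTS component codes and totals, SpO2 band,
  age indicator;
* **models / estimators** — scoring with the packaged coefficients, or
  as sklearn-style `CovariateCoder` + `TraumaSurvivalModel` estimators
  that compose with pipelines;
* **derivation** — re-derive coefficients on your own registry:
  per-site test/derived split, site-balancing weights (e.g. 3.72 for a
  7872 vs 2116 imbalance), weighted logistic regression by IRLS with
  separation diagnostics;
* **evaluation** — ROC, Mann–Whitney AUC, DeLong or bootstrap 95% CI,
  Youden cutoff with sensitivity/specificity;
* **synth** — a calibrated synthetic-registry generator for end-to-end
  testing without patient data.

See `docs/methods.md` for the model details, numerical choices and
limitations.

## Worked example

Score a hypotensive, obtunded 61-year-old with a severe head injury
(head AIS 4 and 3, chest 3, extremity 2 → ISS 29, NISS 34; GCS 11,
BMR 5, SBP 82 mmHg, RR 31, SpO2 88%):

```python
import trisskit as tk

rec = tk.PatientRecord(
    patient_id="example-1", site="SDEUA", age_years=61, mechanism="blunt",
    gcs_total=11, bmr=5, sbp_mmhg=82, rr_bpm=31, spo2_pct=88,
    injuries=(tk.Injury("head_or_neck", 4), tk.Injury("head_or_neck", 3),
              tk.Injury("chest", 3), tk.Injury("extremities", 2)),
)
for model in tk.ADJUSTED_MODELS:
    p = tk.score_record(rec, model)
    print(f"{model:18s} b = {p.b:+.4f}   Ps = {p.ps:.4f}")
```

prints

```
adjusted_triss     b = +0.0209   Ps = 0.5052
ntriss_like        b = +0.2982   Ps = 0.5740
triss_spo2         b = -2.2252   Ps = 0.0975
ntriss_like_spo2   b = -0.4106   Ps = 0.3988
```

All three RTS components code to 3, so the weighted RTS is 5.8806; the
SpO2 of 88% codes to band 2 and the age term is 1. The TRISS-SpO2
blunt set weighs this patient's desaturation and age heavily (its age
slope is the steepest of the blunt sets), hence the much lower Ps —
exactly the kind of disagreement the audit workflow is meant to
surface, since all four models discriminate survivors comparably well
in aggregate.

The same workflow from the shell:

```sh
trisskit simulate --n 20000 --seed 7 --out registry.csv
trisskit derive   --registry registry.csv --model ntriss_like --out coeffs.json
trisskit score    --registry registry.csv --model ntriss_like \
                  --coeffs coeffs.json --out scored.csv
trisskit evaluate --scored scored.csv --out report.json
```

`report.json` mirrors the usual validation table: AUC with 95% CI,
Youden cutoff, sensitivity and specificity.

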