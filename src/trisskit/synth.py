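"""Synthetic trauma-registry generator.

Emulates the marginal structure of a two-center adult trauma cohort:
90.4% blunt mechanism, mean age 41.9 (SD 19.9, truncated at 14), a mean
of about 2.1 injured body regions, mean ISS 9.7 and NISS 12.8, 5.9%
in-hospital mortality, and per-field missingness (SpO2 29.6%, RR 8.3%,
GCS/BMR 4.3%, SBP 0.9%).

Generation model (per record, one counter-based substream each, so
growing ``n`` never reshuffles earlier records):

1. site, mechanism, age;
2. a latent case-severity class (minor/moderate/serious/critical)
   selects the AIS severity distribution; injured regions are drawn
   without replacement, each carrying one or more lesions;
3. admission physiology (GCS/BMR, SBP, RR, SpO2) is drawn conditionally
   on the worst AIS severity, inducing the realistic correlation between
   anatomy and physiology.  A rare "not measurable" SpO2 state is more
   likely in the most severe patients;
4. survival is Bernoulli(Ps) under a packaged truth model applied to the
   *complete* generated covariates;
5. recording missingness (missing-at-random) and the rare unknown-AIS
   recording failure are applied last, so the hidden truth table keeps
   the generating b and Ps.

The exact conditional distributions are package parameters: the real
cohort publishes margins only, so joint realism is calibrated, not
claimed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .models import (
    CoefficientLibrary,
    default_library,
    linear_predictor,
    survival_probability,
)
from .registry import NOT_MEASURABLE, Injury, PatientRecord
from .severity import AIS_UNKNOWN, ISS_REGIONS

_CONSCIOUSNESS = ("normal", "mild", "moderate", "severe")


@dataclass
class SimParams:
    """Parameters of the synthetic registry (defaults are the calibrated
    cohort margins; see :func:`default_params`)."""

    n: int = 10_000
    seed: int = 0
    #: probability a record comes from the minority site (SPBRA)
    site_mix: float = 2416 / 10588
    mech_blunt_prob: float = 0.904
    # age: normal(loc, scale) truncated at age_min by resampling; the
    # truncated distribution has mean ~42 y with ~26% aged 55+
    age_loc: float = 36.8
    age_scale: float = 22.5
    age_min: float = 14.0
    #: latent case-severity class probabilities (minor/moderate/serious/critical)
    case_mix: tuple[float, ...] = (0.68, 0.24, 0.058, 0.022)
    #: AIS severity distribution (AIS 1..6) per case class
    ais_probs: tuple[tuple[float, ...], ...] = (
        (0.62, 0.34, 0.04, 0.00, 0.00, 0.00),
        (0.33, 0.45, 0.19, 0.03, 0.00, 0.00),
        (0.11, 0.29, 0.40, 0.16, 0.04, 0.00),
        (0.04, 0.13, 0.29, 0.30, 0.20, 0.04),
    )
    #: injured regions = 1 + Poisson(lambda), capped at 6
    region_count_lambda: float = 1.1
    #: lesions per injured region = 1 + Poisson(lambda)
    within_region_lambda: float = 1.5
    #: sampling weights of the six ISS body regions
    region_weights: tuple[float, ...] = (0.27, 0.10, 0.14, 0.10, 0.24, 0.15)
    #: P(consciousness class | worst AIS 1..6), rows over
    #: normal/mild/moderate/severe
    consciousness_probs: tuple[tuple[float, ...], ...] = (
        (0.915, 0.030, 0.032, 0.023),
        (0.875, 0.050, 0.046, 0.029),
        (0.730, 0.090, 0.095, 0.085),
        (0.480, 0.130, 0.150, 0.240),
        (0.200, 0.110, 0.180, 0.510),
        (0.020, 0.030, 0.100, 0.850),
    )
    #: SBP mean/SD and cardiac-arrest (SBP 0) probability per worst AIS
    sbp_mu: tuple[float, ...] = (137.0, 136.0, 132.0, 115.0, 90.0, 60.0)
    sbp_sd: tuple[float, ...] = (26.0, 27.0, 29.0, 33.0, 38.0, 45.0)
    sbp_zero_prob: tuple[float, ...] = (0.0, 0.0, 0.002, 0.015, 0.09, 0.38)
    #: probability of an abnormal respiratory pattern per worst AIS
    rr_mu: float = 18.2
    rr_sd: float = 4.6
    rr_abnormal_prob: tuple[float, ...] = (0.01, 0.01, 0.03, 0.10, 0.30, 0.70)
    #: SpO2 mean/SD and not-measurable probability per worst AIS
    spo2_mu: tuple[float, ...] = (98.2, 98.0, 97.0, 94.5, 88.0, 60.0)
    spo2_sd: tuple[float, ...] = (1.8, 2.2, 3.5, 6.0, 12.0, 25.0)
    spo2_nm_prob: tuple[float, ...] = (0.002, 0.003, 0.005, 0.02, 0.08, 0.30)
    # missing-at-random recording rates
    missing_spo2: float = 0.296
    missing_rr: float = 0.083
    missing_gcs: float = 0.043  # GCS and BMR jointly
    missing_sbp: float = 0.009
    #: rate at which one lesion's AIS severity is recorded as unknown,
    #: making ISS/NISS unscoreable (the cohort's 0.5%)
    ais_unknown_rate: float = 0.005
    #: model id whose packaged blunt/penetrating sets generate survival
    truth_model: str = "ntriss_like"
    truth_library: Optional[CoefficientLibrary] = field(
        default=None, repr=False, compare=False
    )

    def validate(self) -> None:
        for name in ("site_mix", "mech_blunt_prob", "missing_spo2",
                     "missing_rr", "missing_gcs", "missing_sbp",
                     "ais_unknown_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be a probability, got {v}")
        if abs(sum(self.case_mix) - 1.0) > 1e-9:
            raise ConfigurationError("case_mix must sum to 1")
        for row in self.ais_probs:
            if abs(sum(row) - 1.0) > 1e-9:
                raise ConfigurationError("each ais_probs row must sum to 1")


def default_params(n: int = 10_000, seed: int = 0) -> SimParams:
    """The packaged parameterization calibrated to the cohort margins."""
    return SimParams(n=n, seed=seed)


class _Tables:
    """Cumulative-probability tables precomputed once per simulation."""

    def __init__(self, params: SimParams):
        self.case_cum = np.cumsum(params.case_mix)
        self.ais_cum = [np.cumsum(row) for row in params.ais_probs]
        self.cons_cum = [np.cumsum(row) for row in params.consciousness_probs]
        rw = np.asarray(params.region_weights, dtype=float)
        self.region_w = rw / rw.sum()


def _cat(rng: np.random.Generator, cum: np.ndarray) -> int:
    return int(np.searchsorted(cum, rng.random(), side="right"))


def _draw_gcs(rng: np.random.Generator, cls: str) -> tuple[int, int]:
    """(gcs_total, bmr) consistent with eye 1-4, verbal 1-5, motor 1-6."""
    if cls == "normal":
        return 15, 6
    if cls == "mild":
        gcs = int(rng.integers(13, 15))  # 13 or 14
        bmr = 6
    elif cls == "moderate":
        gcs = int(rng.integers(9, 13))
        lo, hi = max(1, gcs - 9), min(6, gcs - 2)
        bmr = int(rng.integers(lo, hi + 1))
    else:  # severe
        gcs = int(rng.integers(3, 9))
        lo, hi = max(1, gcs - 9), min(6, gcs - 2)
        bmr = int(rng.integers(lo, hi + 1))
    return gcs, bmr


def _simulate_one(
    i: int,
    params: SimParams,
    library: CoefficientLibrary,
    tables: _Tables,
) -> tuple[PatientRecord, dict]:
    from .severity import (
        age_indicator,
        code_gcs,
        code_rr,
        code_sbp,
        code_spo2,
        rts_totals,
        severity_scores,
    )

    rng = np.random.default_rng((params.seed, i))
    site = "SPBRA" if rng.random() < params.site_mix else "SDEUA"
    mechanism = "blunt" if rng.random() < params.mech_blunt_prob else "penetrating"
    # truncated-normal age
    age = float(rng.normal(params.age_loc, params.age_scale))
    while age < params.age_min:
        age = float(rng.normal(params.age_loc, params.age_scale))
    age = round(age, 1)

    cls_idx = _cat(rng, tables.case_cum)
    ais_cum = tables.ais_cum[cls_idx]
    n_regions = min(6, 1 + int(rng.poisson(params.region_count_lambda)))
    # weighted sampling without replacement (Efraimidis-Spirakis keys)
    keys = rng.random(6) ** (1.0 / tables.region_w)
    regions = np.argsort(keys)[-n_regions:]
    injuries: list[Injury] = []
    for reg in regions:
        n_les = 1 + int(rng.poisson(params.within_region_lambda))
        for u in rng.random(n_les):
            injuries.append(
                Injury(
                    body_region=ISS_REGIONS[reg],
                    ais_severity=1 + int(np.searchsorted(ais_cum, u, side="right")),
                )
            )
    worst = max(i_.ais_severity for i_ in injuries)

    cons = _CONSCIOUSNESS[_cat(rng, tables.cons_cum[worst - 1])]
    gcs, bmr = _draw_gcs(rng, cons)

    if rng.random() < params.sbp_zero_prob[worst - 1]:
        sbp = 0.0
    else:
        sbp = max(0.0, float(rng.normal(params.sbp_mu[worst - 1],
                                        params.sbp_sd[worst - 1])))
    sbp = round(sbp, 0)

    if rng.random() < params.rr_abnormal_prob[worst - 1]:
        u = rng.random()
        if u < 0.3:
            rr = 0.0
        elif u < 0.7:
            rr = float(rng.uniform(30.0, 45.0))
        else:
            rr = float(rng.uniform(1.0, 9.0))
    else:
        rr = max(0.0, float(rng.normal(params.rr_mu, params.rr_sd)))
    rr = round(rr, 0)

    spo2_nm = rng.random() < params.spo2_nm_prob[worst - 1]
    spo2_val = round(
        min(100.0, max(0.0, float(
            rng.normal(params.spo2_mu[worst - 1], params.spo2_sd[worst - 1])
        ))), 0,
    )
    spo2_true = NOT_MEASURABLE if spo2_nm else spo2_val

    # truth covariates from the complete (pre-missingness) values
    scores = severity_scores(injuries)
    gcs_code = code_gcs(gcs)
    sbp_code = code_sbp(sbp)
    rr_code = code_rr(rr)
    rts_weighted, trts = rts_totals(gcs_code, sbp_code, rr_code)
    values = {
        "rts": rts_weighted,
        "gcs": gcs_code,
        "sbp": sbp_code,
        "spo2": code_spo2(spo2_true),
        "bmr": bmr,
        "iss": scores.iss,
        "niss": scores.niss,
        "age": age_indicator(age),
    }
    coeffs = library.get(params.truth_model, mechanism)
    b = linear_predictor(coeffs, values)
    ps = survival_probability(b)
    survived = bool(rng.random() < ps)

    # recording failures, applied after the truth draw
    if rng.random() < params.ais_unknown_rate:
        k = int(rng.integers(len(injuries)))
        injuries[k] = Injury(
            body_region=injuries[k].body_region, ais_severity=AIS_UNKNOWN
        )
    gcs_missing = rng.random() < params.missing_gcs
    rec = PatientRecord(
        patient_id=f"P{i:07d}",
        site=site,
        age_years=age,
        mechanism=mechanism,
        gcs_total=None if gcs_missing else gcs,
        bmr=None if gcs_missing else bmr,
        sbp_mmhg=None if rng.random() < params.missing_sbp else sbp,
        rr_bpm=None if rng.random() < params.missing_rr else rr,
        spo2_pct=None if rng.random() < params.missing_spo2 else spo2_true,
        injuries=tuple(injuries),
        hours_from_event=round(float(rng.uniform(0.2, 12.0)), 1),
        transferred=False,
        survived=survived,
    )
    truth = {
        "patient_id": rec.patient_id,
        "b": b,
        "ps": ps,
        "survived": survived,
        "iss": scores.iss,
        "niss": scores.niss,
        "worst_ais": worst,
        "mechanism": mechanism,
    }
    return rec, truth


def simulate_registry(
    params: SimParams,
) -> tuple[list[PatientRecord], pd.DataFrame]:
    """Generate ``params.n`` records plus the hidden truth table.

    The truth table (generating linear predictor ``b``, survival
    probability ``ps``, worst AIS) is returned separately and must never
    be written into the registry file handed to derivation or scoring.
    """
    params.validate()
    library = params.truth_library or default_library()
    if (params.truth_model, "blunt") not in library:
        raise ConfigurationError(
            f"truth model {params.truth_model!r} not in the coefficient library"
        )
    tables = _Tables(params)
    records: list[PatientRecord] = []
    truths: list[dict] = []
    for i in range(params.n):
        rec, truth = _simulate_one(i, params, library, tables)
        records.append(rec)
        truths.append(truth)
    return records, pd.DataFrame(truths)


__all__ = ["SimParams", "default_params", "simulate_registry"]
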