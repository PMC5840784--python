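"""Survival-probability models: Ps = 1 / (1 + e^-b).

Four model equations are supported, each with separate blunt and
penetrating coefficient sets:

* ``adjusted_triss``:      b = b0 + b1*RTS + b2*ISS + b3*age
* ``ntriss_like``:         b = b0 + b1*BMR + b2*SBPc + b3*NISS + b4*age
* ``triss_spo2``:          b = b0 + b1*GCSc + b2*SBPc + b3*SpO2c + b4*ISS + b5*age
* ``ntriss_like_spo2``:    b = b0 + b1*BMR + b2*SBPc + b3*SpO2c + b4*NISS + b5*age

where RTS is either the weighted Revised Trauma Score (default) or the
unweighted 0-12 triage sum, GCSc/SBPc are the 0-4 RTS component codes,
BMR is the best motor response (1-6), SpO2c the 0-4 saturation band and
age the 55-year indicator.  The original MTOS TRISS coefficient sets
(1987 and 1995 revisions, external literature) ship as optional extras
under ``triss_mtos_1987`` / ``triss_mtos_1995``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional

from scipy.special import expit

from .exceptions import ModelInputError, SchemaError, ScoringError
from .registry import MECHANISMS, PatientRecord, resolve_missing
from .severity import severity_scores

#: Covariate order of each model equation.  Keys are model ids; the
#: "custom" id accepts any arity.
MODEL_COVARIATES: dict[str, tuple[str, ...]] = {
    "adjusted_triss": ("rts", "iss", "age"),
    "ntriss_like": ("bmr", "sbp", "niss", "age"),
    "triss_spo2": ("gcs", "sbp", "spo2", "iss", "age"),
    "ntriss_like_spo2": ("bmr", "sbp", "spo2", "niss", "age"),
    "triss_mtos_1987": ("rts", "iss", "age"),
    "triss_mtos_1995": ("rts", "iss", "age"),
}

#: The four model ids whose coefficients were re-derived on the
#: two-center cohort (i.e. excluding the external MTOS extras).
ADJUSTED_MODELS: tuple[str, ...] = (
    "adjusted_triss",
    "ntriss_like",
    "triss_spo2",
    "ntriss_like_spo2",
)

# Sign expectations asserted when loading non-custom sets: physiology
# improves survival, anatomy/age worsen it.
_POSITIVE_COVARIATES = frozenset({"rts", "bmr", "sbp", "gcs", "spo2"})
_NEGATIVE_COVARIATES = frozenset({"iss", "niss", "age"})

#: Truncated value of Euler's number used by strict-replication mode.
E_TRUNCATED = 2.718282


@dataclass(frozen=True)
class CoefficientSet:
    """Intercept plus ordered slopes for one model x one mechanism."""

    model_id: str
    mechanism: str
    intercept: float
    slopes: tuple[float, ...]
    covariate_order: tuple[str, ...]
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        object.__setattr__(self, "slopes", tuple(float(s) for s in self.slopes))
        object.__setattr__(self, "covariate_order", tuple(self.covariate_order))
        if self.mechanism not in ("blunt", "penetrating"):
            raise SchemaError(
                f"mechanism must be blunt or penetrating, got {self.mechanism!r}"
            )
        if len(self.slopes) != len(self.covariate_order):
            raise SchemaError(
                f"{len(self.slopes)} slopes for "
                f"{len(self.covariate_order)} covariates"
            )
        expected = MODEL_COVARIATES.get(self.model_id)
        if self.model_id != "custom":
            if expected is None:
                raise SchemaError(f"unknown model_id {self.model_id!r}")
            if self.covariate_order != expected:
                raise SchemaError(
                    f"{self.model_id} expects covariates {expected}, "
                    f"got {self.covariate_order}"
                )

    def check_signs(self) -> None:
        """Assert the slope-sign pattern all packaged sets satisfy."""
        for name, slope in zip(self.covariate_order, self.slopes):
            if name in _POSITIVE_COVARIATES and slope <= 0:
                raise SchemaError(
                    f"{self.model_id}/{self.mechanism}: slope on {name} "
                    f"should be positive, got {slope}"
                )
            if name in _NEGATIVE_COVARIATES and slope >= 0:
                raise SchemaError(
                    f"{self.model_id}/{self.mechanism}: slope on {name} "
                    f"should be negative, got {slope}"
                )


@dataclass(frozen=True)
class Prediction:
    """One scored record: linear predictor, survival probability and the
    audit trail of covariate values and coding flags."""

    b: float
    ps: float
    model_id: str
    mechanism: str
    covariates_used: Mapping[str, float]
    flags: tuple[str, ...] = ()


def linear_predictor(coeffs: CoefficientSet, covariates: Mapping[str, float]) -> float:
    """Evaluate b = b0 + sum(b_i * x_i) in the model's covariate order."""
    b = coeffs.intercept
    for name, slope in zip(coeffs.covariate_order, coeffs.slopes):
        if name not in covariates or covariates[name] is None:
            raise ModelInputError(
                f"covariate {name!r} required by {coeffs.model_id} is missing"
            )
        b += slope * float(covariates[name])
    return b


def survival_probability(b: float, *, truncated_e: bool = False) -> float:
    """Logistic transform Ps = 1/(1 + e^-b), numerically stable.

    ``truncated_e`` replaces Euler's number with the truncated
    constant 2.718282 for byte-level replication experiments; the
    difference in Ps is below 2e-7.
    """
    if not math.isfinite(b):
        raise ModelInputError(f"linear predictor must be finite, got {b!r}")
    if truncated_e:
        if b >= 0:
            return 1.0 / (1.0 + E_TRUNCATED ** (-b))
        num = E_TRUNCATED**b
        return num / (1.0 + num)
    return float(expit(b))


class CoefficientLibrary:
    """Coefficient sets keyed by ``(model_id, mechanism)``."""

    def __init__(self, sets: Mapping[tuple[str, str], CoefficientSet] | None = None):
        self._sets: dict[tuple[str, str], CoefficientSet] = dict(sets or {})

    def add(self, cs: CoefficientSet) -> None:
        self._sets[(cs.model_id, cs.mechanism)] = cs

    def get(self, model_id: str, mechanism: str) -> CoefficientSet:
        try:
            return self._sets[(model_id, mechanism)]
        except KeyError:
            raise SchemaError(
                f"no coefficient set for model {model_id!r}, "
                f"mechanism {mechanism!r}"
            ) from None

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._sets

    def __iter__(self):
        return iter(self._sets.values())

    def __len__(self) -> int:
        return len(self._sets)

    def __eq__(self, other) -> bool:
        return isinstance(other, CoefficientLibrary) and self._sets == other._sets

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "sets": [
                {
                    "model_id": cs.model_id,
                    "mechanism": cs.mechanism,
                    "intercept": cs.intercept,
                    "slopes": list(cs.slopes),
                    "covariate_order": list(cs.covariate_order),
                    "provenance": cs.provenance,
                }
                for cs in self._sets.values()
            ],
        }


def _library_from_document(doc: dict, *, validate_signs: bool) -> CoefficientLibrary:
    if not isinstance(doc, dict) or "sets" not in doc:
        raise SchemaError("coefficient document must contain a 'sets' list")
    lib = CoefficientLibrary()
    for raw in doc["sets"]:
        try:
            cs = CoefficientSet(
                model_id=raw["model_id"],
                mechanism=raw["mechanism"],
                intercept=float(raw["intercept"]),
                slopes=tuple(raw["slopes"]),
                covariate_order=tuple(raw["covariate_order"]),
                provenance=raw.get("provenance", "unspecified"),
            )
        except KeyError as exc:
            raise SchemaError(f"coefficient set missing field {exc}") from None
        if validate_signs and cs.model_id != "custom":
            cs.check_signs()
        lib.add(cs)
    return lib


def load_coefficients(path: str, *, validate_signs: bool = False) -> CoefficientLibrary:
    """Load a coefficient library from a JSON document, validating arity
    (and, optionally, the slope-sign pattern) on load."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    return _library_from_document(doc, validate_signs=validate_signs)


def save_coefficients(library: CoefficientLibrary, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(library.to_dict(), fh, indent=2)


def default_library() -> CoefficientLibrary:
    """The packaged library: the four re-derived model equations (blunt
    and penetrating) plus the optional external MTOS TRISS sets.
    Slope signs are asserted on load."""
    text = resources.files("trisskit").joinpath("data/coefficients.json").read_text()
    return _library_from_document(json.loads(text), validate_signs=True)


def build_covariates(
    record: PatientRecord,
    model_id: str,
    *,
    rts_scale: str = "weighted",
    missing_policy: str = "spo2-zero-if-unmeasurable-only",
) -> tuple[dict[str, Optional[float]], list[str]]:
    """Code one record into the named model's covariates.

    Returns ``(covariates, flags)``; a covariate that cannot be coded
    (missing measurement, unscoreable ISS/NISS) is ``None`` and a flag
    explains why.  ``rts_scale`` selects the weighted RTS (default) or
    the unweighted 0-12 sum for the TRISS equations.
    """
    if model_id not in MODEL_COVARIATES:
        raise ModelInputError(f"unknown model_id {model_id!r}")
    if rts_scale not in ("weighted", "trts"):
        raise ModelInputError(f"rts_scale must be 'weighted' or 'trts', got {rts_scale!r}")
    coded = resolve_missing(record, policy=missing_policy)
    scores = severity_scores(record.injuries)
    flags = list(coded.flags)
    if not scores.scoreable:
        flags.append("iss-niss-unscoreable")
    values: dict[str, Optional[float]] = {
        "rts": coded.rts_weighted if rts_scale == "weighted" else coded.trts,
        "gcs": coded.gcs_code,
        "sbp": coded.sbp_code,
        "spo2": coded.spo2_code,
        "bmr": coded.bmr,
        "iss": scores.iss,
        "niss": scores.niss,
        "age": coded.age_ind,
    }
    needed = MODEL_COVARIATES[model_id]
    return {name: values[name] for name in needed}, flags


def score_record(
    record: PatientRecord,
    model_id: str,
    library: CoefficientLibrary | None = None,
    *,
    rts_scale: str = "weighted",
    missing_policy: str = "spo2-zero-if-unmeasurable-only",
    truncated_e: bool = False,
) -> Prediction:
    """Score one eligible record with the mechanism-matched coefficient set.

    Raises :class:`ScoringError` when the mechanism is unknown or a
    required covariate cannot be coded (the message names it).
    """
    if library is None:
        library = default_library()
    if record.mechanism not in ("blunt", "penetrating"):
        raise ScoringError(
            f"record {record.patient_id}: mechanism {record.mechanism!r} "
            "does not select a coefficient set"
        )
    coeffs = library.get(model_id, record.mechanism)
    covariates, flags = build_covariates(
        record, model_id, rts_scale=rts_scale, missing_policy=missing_policy
    )
    missing = [k for k, v in covariates.items() if v is None]
    if missing:
        raise ScoringError(
            f"record {record.patient_id}: cannot score {model_id}, "
            f"missing covariate(s) {missing} (flags: {flags})"
        )
    b = linear_predictor(coeffs, covariates)
    return Prediction(
        b=b,
        ps=survival_probability(b, truncated_e=truncated_e),
        model_id=model_id,
        mechanism=record.mechanism,
        covariates_used=dict(covariates),
        flags=tuple(flags),
    )


# re-export for callers that only import models
__all__ = [
    "MODEL_COVARIATES",
    "ADJUSTED_MODELS",
    "CoefficientSet",
    "CoefficientLibrary",
    "Prediction",
    "linear_predictor",
    "survival_probability",
    "load_coefficients",
    "save_coefficients",
    "default_library",
    "build_covariates",
    "score_record",
    "MECHANISMS",
]
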