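"""Anatomical and physiological severity coding for trauma survival models.

This module computes every covariate the survival equations consume:

* ISS / NISS from a list of AIS-coded injuries (six body regions,
  sum of squares of the three worst region maxima for ISS, of the three
  worst lesions anywhere for NISS, AIS 6 anywhere forcing the 75 ceiling);
* the Revised Trauma Score (RTS) ordinal codes (0-4) for Glasgow Coma
  Scale, systolic blood pressure and respiratory rate, plus the weighted
  RTS (0-7.8408) and the unweighted triage sum (0-12);
* the five-band SpO2 code (0-4), where a saturation of zero or a
  "not measurable" reading both code to 0;
* the dichotomous age term (0 below 55 years, 1 at or above).

All coding functions are pure, total over their declared domains, and
raise :class:`~trisskit.exceptions.CodingError` outside them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .exceptions import CodingError, RecordValidationError

# The six ISS body regions.  "head_or_neck" covers head and cervical spine,
# "external" covers skin/burns/general.
ISS_REGIONS: tuple[str, ...] = (
    "head_or_neck",
    "face",
    "chest",
    "abdomen",
    "extremities",
    "external",
)

#: Sentinel AIS severity for a lesion whose severity could not be coded.
#: Any injury carrying it makes the patient's ISS/NISS unscoreable.
AIS_UNKNOWN = 9

_VALID_AIS = frozenset({1, 2, 3, 4, 5, 6, AIS_UNKNOWN})

# Coefficients of the weighted Revised Trauma Score.
RTS_WEIGHT_GCS = 0.9368
RTS_WEIGHT_SBP = 0.7326
RTS_WEIGHT_RR = 0.2908
RTS_WEIGHTED_MAX = 4 * (RTS_WEIGHT_GCS + RTS_WEIGHT_SBP + RTS_WEIGHT_RR)  # 7.8408


class _NotMeasurable:
    """Singleton token for an SpO2 reading the oximeter could not obtain.

    Distinct from a missing (unrecorded) value: "not measurable" always
    codes to the lowest SpO2 band, while a missing value is a data gap
    handled by the missing-data policy.
    """

    _instance: Optional["_NotMeasurable"] = None

    def __new__(cls) -> "_NotMeasurable":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "NOT_MEASURABLE"


NOT_MEASURABLE = _NotMeasurable()


@dataclass(frozen=True)
class Injury:
    """One AIS-coded lesion: body region plus AIS severity.

    ``ais_severity`` is 1 (minor) to 6 (currently untreatable); the
    sentinel :data:`AIS_UNKNOWN` (9) marks a lesion whose severity could
    not be established, which renders ISS/NISS unscoreable.
    """

    body_region: str
    ais_severity: int

    def __post_init__(self) -> None:
        if self.body_region not in ISS_REGIONS:
            raise RecordValidationError(
                f"unknown body region {self.body_region!r}; "
                f"expected one of {ISS_REGIONS}"
            )
        if self.ais_severity not in _VALID_AIS:
            raise RecordValidationError(
                f"AIS severity must be 1-6 (or {AIS_UNKNOWN} for unknown), "
                f"got {self.ais_severity!r}"
            )


@dataclass(frozen=True)
class SeverityScores:
    """ISS and NISS for one patient; ``scoreable`` is False when any
    lesion has unknown severity, in which case both scores are None."""

    iss: Optional[int]
    niss: Optional[int]
    scoreable: bool


@dataclass
class CodedPhysiology:
    """Model covariates after coding.

    Optional fields are ``None`` when the underlying measurement is
    missing; ``flags`` records every policy decision taken while coding
    (e.g. ``"spo2-coded-zero-by-policy"``) for the scoring audit trail.
    """

    gcs_code: Optional[int] = None
    sbp_code: Optional[int] = None
    rr_code: Optional[int] = None
    spo2_code: Optional[int] = None
    bmr: Optional[int] = None
    age_ind: Optional[int] = None
    rts_weighted: Optional[float] = None
    trts: Optional[int] = None
    flags: list[str] = field(default_factory=list)


def _check_ais(injuries: Iterable[Injury]) -> list[Injury]:
    out = list(injuries)
    for inj in out:
        if inj.ais_severity not in _VALID_AIS:
            raise CodingError(f"AIS severity out of range: {inj.ais_severity!r}")
    return out


def compute_iss(injuries: Sequence[Injury]) -> int:
    """Injury Severity Score: sum of squares of the highest AIS in each of
    the three most severely injured distinct body regions.

    Any AIS-6 lesion forces the conventional ceiling of 75.  An empty
    injury list scores 0.  Raises :class:`CodingError` on an unknown
    severity; use :func:`severity_scores` to get a ``scoreable`` flag
    instead.
    """
    injuries = _check_ais(injuries)
    if any(i.ais_severity == AIS_UNKNOWN for i in injuries):
        raise CodingError("ISS undefined: injury with unknown AIS severity")
    if any(i.ais_severity == 6 for i in injuries):
        return 75
    region_max: dict[str, int] = {}
    for inj in injuries:
        region_max[inj.body_region] = max(
            region_max.get(inj.body_region, 0), inj.ais_severity
        )
    top3 = sorted(region_max.values(), reverse=True)[:3]
    return sum(v * v for v in top3)


def compute_niss(injuries: Sequence[Injury]) -> int:
    """New Injury Severity Score: sum of squares of the three highest AIS
    severities regardless of body region; AIS-6 convention as for ISS."""
    injuries = _check_ais(injuries)
    if any(i.ais_severity == AIS_UNKNOWN for i in injuries):
        raise CodingError("NISS undefined: injury with unknown AIS severity")
    if any(i.ais_severity == 6 for i in injuries):
        return 75
    top3 = sorted((i.ais_severity for i in injuries), reverse=True)[:3]
    return sum(v * v for v in top3)


def severity_scores(injuries: Sequence[Injury]) -> SeverityScores:
    """ISS and NISS together; unknown AIS severities yield
    ``scoreable=False`` rather than an exception."""
    injuries = _check_ais(injuries)
    if any(i.ais_severity == AIS_UNKNOWN for i in injuries):
        return SeverityScores(iss=None, niss=None, scoreable=False)
    return SeverityScores(
        iss=compute_iss(injuries), niss=compute_niss(injuries), scoreable=True
    )


def code_gcs(gcs_total: Optional[float]) -> Optional[int]:
    """RTS band for the total Glasgow Coma Scale: 13-15 -> 4, 9-12 -> 3,
    6-8 -> 2, 4-5 -> 1, 3 -> 0.  Missing input -> missing code."""
    if gcs_total is None:
        return None
    if not 3 <= gcs_total <= 15:
        raise CodingError(f"GCS total must be 3-15, got {gcs_total!r}")
    if gcs_total >= 13:
        return 4
    if gcs_total >= 9:
        return 3
    if gcs_total >= 6:
        return 2
    if gcs_total >= 4:
        return 1
    return 0


def code_sbp(sbp_mmhg: Optional[float]) -> Optional[int]:
    """RTS band for systolic blood pressure (mmHg): >89 -> 4, 76-89 -> 3,
    50-75 -> 2, 1-49 -> 1, 0 -> 0.  Real-valued inputs band by interval
    membership with breaks at 50, 76 and 90."""
    if sbp_mmhg is None:
        return None
    if sbp_mmhg < 0:
        raise CodingError(f"SBP must be non-negative, got {sbp_mmhg!r}")
    if sbp_mmhg > 89:
        return 4
    if sbp_mmhg >= 76:
        return 3
    if sbp_mmhg >= 50:
        return 2
    if sbp_mmhg > 0:
        return 1
    return 0


def code_rr(rr_bpm: Optional[float]) -> Optional[int]:
    """RTS band for respiratory rate (breaths/min): 10-29 -> 4, >29 -> 3,
    6-9 -> 2, 1-5 -> 1, 0 -> 0."""
    if rr_bpm is None:
        return None
    if rr_bpm < 0:
        raise CodingError(f"RR must be non-negative, got {rr_bpm!r}")
    if rr_bpm > 29:
        return 3
    if rr_bpm >= 10:
        return 4
    if rr_bpm >= 6:
        return 2
    if rr_bpm > 0:
        return 1
    return 0


def code_rts_components(
    gcs_total: Optional[float],
    sbp_mmhg: Optional[float],
    rr_bpm: Optional[float],
) -> tuple[Optional[int], Optional[int], Optional[int]]:
    """Code the three RTS components at once; each missing input yields a
    missing code."""
    return code_gcs(gcs_total), code_sbp(sbp_mmhg), code_rr(rr_bpm)


def rts_totals(
    gcs_code: Optional[int],
    sbp_code: Optional[int],
    rr_code: Optional[int],
) -> tuple[Optional[float], Optional[int]]:
    """Weighted RTS and triage (unweighted) RTS from the component codes.

    Returns ``(rts_weighted, trts)`` where

    * ``rts_weighted = 0.9368*GCSc + 0.7326*SBPc + 0.2908*RRc`` (0-7.8408),
    * ``trts = GCSc + SBPc + RRc`` (0-12).

    Any missing component makes both totals missing.
    """
    if gcs_code is None or sbp_code is None or rr_code is None:
        return None, None
    for name, c in (("gcs", gcs_code), ("sbp", sbp_code), ("rr", rr_code)):
        if c not in (0, 1, 2, 3, 4):
            raise CodingError(f"{name} code must be 0-4, got {c!r}")
    weighted = (
        RTS_WEIGHT_GCS * gcs_code + RTS_WEIGHT_SBP * sbp_code + RTS_WEIGHT_RR * rr_code
    )
    return weighted, gcs_code + sbp_code + rr_code


def code_spo2(spo2) -> int:
    """Five-band code for peripheral oxygen saturation (percent).

    0 or not measurable -> 0; (0, 80] -> 1; (80, 90] -> 2; (90, 95] -> 3;
    (95, 100] -> 4.  Accepts the :data:`NOT_MEASURABLE` token; values
    outside [0, 100] raise.
    """
    if spo2 is NOT_MEASURABLE:
        return 0
    if spo2 is None:
        raise CodingError("SpO2 is missing; handle via the missing-data policy")
    v = float(spo2)
    if not 0.0 <= v <= 100.0:
        raise CodingError(f"SpO2 must lie in [0, 100], got {spo2!r}")
    if v == 0.0:
        return 0
    if v <= 80.0:
        return 1
    if v <= 90.0:
        return 2
    if v <= 95.0:
        return 3
    return 4


def age_indicator(age_years: float) -> int:
    """Dichotomous age term: 0 below 55 years, 1 at 55 or older."""
    if age_years < 0:
        raise CodingError(f"age must be non-negative, got {age_years!r}")
    return 1 if age_years >= 55 else 0


def coding_tables() -> dict:
    """All banding rules as a machine-readable document (for audit)."""
    return {
        "iss_regions": list(ISS_REGIONS),
        "ais_valid": [1, 2, 3, 4, 5, 6],
        "ais_unknown_sentinel": AIS_UNKNOWN,
        "gcs_bands": [
            {"range": [13, 15], "code": 4},
            {"range": [9, 12], "code": 3},
            {"range": [6, 8], "code": 2},
            {"range": [4, 5], "code": 1},
            {"range": [3, 3], "code": 0},
        ],
        "sbp_bands": [
            {"range": [">89", None], "code": 4},
            {"range": [76, 89], "code": 3},
            {"range": [50, 75], "code": 2},
            {"range": [1, 49], "code": 1},
            {"range": [0, 0], "code": 0},
        ],
        "rr_bands": [
            {"range": [10, 29], "code": 4},
            {"range": [">29", None], "code": 3},
            {"range": [6, 9], "code": 2},
            {"range": [1, 5], "code": 1},
            {"range": [0, 0], "code": 0},
        ],
        "spo2_bands": [
            {"range": ["0 or not measurable", None], "code": 0},
            {"range": [1, 80], "code": 1},
            {"range": [81, 90], "code": 2},
            {"range": [91, 95], "code": 3},
            {"range": [96, 100], "code": 4},
        ],
        "rts_weights": {
            "gcs": RTS_WEIGHT_GCS,
            "sbp": RTS_WEIGHT_SBP,
            "rr": RTS_WEIGHT_RR,
        },
        "age_threshold_years": 55,
    }


def export_coding_tables(path: str) -> None:
    """Write :func:`coding_tables` as JSON to *path*."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(coding_tables(), fh, indent=2)
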