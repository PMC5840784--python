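"""Trauma-registry records: I/O, eligibility filtering, missing data.

A registry is a delimited text table with one row per patient.  Injury
lists travel either packed into a single column
(``"head_or_neck:3;chest:2"``) or as a long-format companion table with
columns ``patient_id, body_region, ais_severity``.  Tokens for missing
values (default ``""`` and ``"NA"``) and for a not-measurable SpO2
reading (default ``"NM"``) are configurable.

Eligibility follows the derivation cohort's rules: age >= 14 years,
admission within 24 h of the event, not transferred from another
hospital, and a known (blunt or penetrating) trauma mechanism.  Each
excluded record is counted once, under the first rule it fails, in that
fixed order, so the report is deterministic.
"""

from __future__ import annotations

import csv
import logging
import numbers
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .exceptions import ConfigurationError, RecordValidationError, SchemaError
from .severity import (
    AIS_UNKNOWN,
    NOT_MEASURABLE,
    CodedPhysiology,
    Injury,
    age_indicator,
    code_gcs,
    code_rr,
    code_sbp,
    code_spo2,
    rts_totals,
)

logger = logging.getLogger(__name__)

MECHANISMS = ("blunt", "penetrating", "unknown")
SITES_DEFAULT = ("SPBRA", "SDEUA")

#: Supported missing-SpO2 policies (see :func:`resolve_missing`).
MISSING_POLICIES = (
    "complete-case",
    "spo2-zero-if-unmeasurable-only",
    "spo2-zero-always",
)

#: Canonical registry column names; users remap via the ``schema`` argument.
CANONICAL_COLUMNS = (
    "patient_id",
    "site",
    "age_years",
    "mechanism",
    "gcs_total",
    "bmr",
    "sbp_mmhg",
    "rr_bpm",
    "spo2_pct",
    "injuries",
    "hours_from_event",
    "transferred",
    "survived",
)


@dataclass
class PatientRecord:
    """One registry row: demographics, admission physiology, injury list,
    mechanism and outcome.  ``None`` encodes a missing value; SpO2 may
    also hold the :data:`~trisskit.severity.NOT_MEASURABLE` token."""

    patient_id: str
    site: str = "SPBRA"
    age_years: float = 0.0
    mechanism: str = "unknown"
    gcs_total: Optional[int] = None
    bmr: Optional[int] = None
    sbp_mmhg: Optional[float] = None
    rr_bpm: Optional[float] = None
    spo2_pct: object = None
    injuries: tuple[Injury, ...] = ()
    hours_from_event: Optional[float] = None
    transferred: bool = False
    survived: Optional[bool] = None

    def __post_init__(self) -> None:
        self.injuries = tuple(self.injuries)
        if self.age_years is None or self.age_years < 0:
            raise RecordValidationError(
                f"record {self.patient_id!r}: age must be non-negative, "
                f"got {self.age_years!r}"
            )
        if self.mechanism not in MECHANISMS:
            raise RecordValidationError(
                f"record {self.patient_id!r}: mechanism must be one of "
                f"{MECHANISMS}, got {self.mechanism!r}"
            )
        if self.gcs_total is not None and not 3 <= self.gcs_total <= 15:
            raise RecordValidationError(
                f"record {self.patient_id!r}: GCS total out of 3-15: "
                f"{self.gcs_total!r}"
            )
        if self.bmr is not None:
            if not 1 <= self.bmr <= 6:
                raise RecordValidationError(
                    f"record {self.patient_id!r}: BMR out of 1-6: {self.bmr!r}"
                )
            if self.gcs_total is not None and self.bmr > self.gcs_total - 2:
                raise RecordValidationError(
                    f"record {self.patient_id!r}: BMR {self.bmr} inconsistent "
                    f"with GCS total {self.gcs_total} (needs BMR <= GCS - 2)"
                )
        for name, v in (("SBP", self.sbp_mmhg), ("RR", self.rr_bpm),
                        ("hours_from_event", self.hours_from_event)):
            if v is not None and v < 0:
                raise RecordValidationError(
                    f"record {self.patient_id!r}: {name} must be "
                    f"non-negative, got {v!r}"
                )
        if self.spo2_pct is not None and self.spo2_pct is not NOT_MEASURABLE:
            if not isinstance(self.spo2_pct, numbers.Real) or not (
                0 <= float(self.spo2_pct) <= 100
            ):
                raise RecordValidationError(
                    f"record {self.patient_id!r}: SpO2 must be in [0, 100] "
                    f"or not-measurable, got {self.spo2_pct!r}"
                )


@dataclass(frozen=True)
class EligibilityReport:
    """Exhaustive, mutually exclusive exclusion counts in the fixed rule
    order (age, late admission, transfer, mechanism)."""

    n_input: int
    n_excluded_age: int
    n_excluded_late: int
    n_excluded_transfer: int
    n_excluded_mechanism: int
    n_retained: int

    def __post_init__(self) -> None:
        total = (
            self.n_excluded_age
            + self.n_excluded_late
            + self.n_excluded_transfer
            + self.n_excluded_mechanism
            + self.n_retained
        )
        if total != self.n_input:
            raise RecordValidationError(
                f"eligibility counts do not reconcile: {total} != {self.n_input}"
            )


# ---------------------------------------------------------------------------
# parsing helpers

_TRUE_TOKENS = {"true", "1", "yes", "y", "t"}
_FALSE_TOKENS = {"false", "0", "no", "n", "f"}


def _parse_float(tok: str, missing: frozenset[str]) -> Optional[float]:
    if tok.strip() in missing:
        return None
    try:
        return float(tok)
    except ValueError:
        return None


def _parse_int(tok: str, missing: frozenset[str]) -> Optional[int]:
    v = _parse_float(tok, missing)
    return None if v is None else int(round(v))


def _parse_bool(tok: str, missing: frozenset[str]) -> Optional[bool]:
    t = tok.strip().lower()
    if t in missing or t == "":
        return None
    if t in _TRUE_TOKENS:
        return True
    if t in _FALSE_TOKENS:
        return False
    return None


def parse_packed_injuries(tok: str, missing: frozenset[str] = frozenset({"", "NA"})) -> tuple[Injury, ...]:
    """Parse a packed injury column ``"region:ais;region:ais"``."""
    if tok.strip() in missing:
        return ()
    out = []
    for part in tok.split(";"):
        part = part.strip()
        if not part:
            continue
        try:
            region, sev = part.rsplit(":", 1)
            out.append(Injury(body_region=region.strip(), ais_severity=int(sev)))
        except (ValueError, RecordValidationError) as exc:
            raise RecordValidationError(
                f"cannot parse packed injury {part!r}: {exc}"
            ) from None
    return tuple(out)


def pack_injuries(injuries: Sequence[Injury]) -> str:
    return ";".join(f"{i.body_region}:{i.ais_severity}" for i in injuries)


def read_registry(
    path: str,
    schema: Optional[dict[str, str]] = None,
    *,
    injuries_path: Optional[str] = None,
    delimiter: str = ",",
    missing_tokens: Iterable[str] = ("", "NA"),
    not_measurable_token: str = "NM",
) -> list[PatientRecord]:
    """Read a registry CSV into :class:`PatientRecord` objects.

    ``schema`` remaps canonical column names to the file's actual
    headers (``{"age_years": "AGE"}``).  Injuries come from the packed
    ``injuries`` column or, when ``injuries_path`` is given, from a
    long-format companion file (which then takes precedence).
    Unparseable optional fields become missing; an invalid required
    field (or an invariant violation) raises with the row number.
    """
    schema = schema or {}
    missing = frozenset(str(t).strip() for t in missing_tokens)
    colmap = {canon: schema.get(canon, canon) for canon in CANONICAL_COLUMNS}

    injuries_by_id: dict[str, list[Injury]] = {}
    if injuries_path is not None:
        with open(injuries_path, newline="", encoding="utf-8") as fh:
            rdr = csv.DictReader(fh, delimiter=delimiter)
            required = {"patient_id", "body_region", "ais_severity"}
            if rdr.fieldnames is None or not required <= set(rdr.fieldnames):
                raise SchemaError(
                    f"injuries file must have columns {sorted(required)}, "
                    f"got {rdr.fieldnames}"
                )
            for row in rdr:
                injuries_by_id.setdefault(row["patient_id"], []).append(
                    Injury(
                        body_region=row["body_region"].strip(),
                        ais_severity=int(row["ais_severity"]),
                    )
                )

    records: list[PatientRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        rdr = csv.DictReader(fh, delimiter=delimiter)
        if rdr.fieldnames is None:
            logger.warning("registry file %s is empty", path)
            return []
        if colmap["patient_id"] not in rdr.fieldnames:
            raise SchemaError(
                f"required column {colmap['patient_id']!r} (patient_id) "
                f"not found in {path}"
            )

        def get(row: dict, canon: str) -> str:
            return row.get(colmap[canon], "") or ""

        for lineno, row in enumerate(rdr, start=2):
            pid = get(row, "patient_id").strip()
            if pid in missing:
                raise RecordValidationError(f"{path}:{lineno}: missing patient_id")
            spo2_tok = get(row, "spo2_pct").strip()
            if spo2_tok == not_measurable_token:
                spo2 = NOT_MEASURABLE
            else:
                spo2 = _parse_float(spo2_tok, missing)
            mech = get(row, "mechanism").strip().lower() or "unknown"
            if injuries_path is not None:
                injuries = tuple(injuries_by_id.get(pid, ()))
            else:
                injuries = parse_packed_injuries(get(row, "injuries"), missing)
            transferred = _parse_bool(get(row, "transferred"), missing)
            try:
                rec = PatientRecord(
                    patient_id=pid,
                    site=get(row, "site").strip() or "unknown",
                    age_years=_parse_float(get(row, "age_years"), missing),
                    mechanism=mech,
                    gcs_total=_parse_int(get(row, "gcs_total"), missing),
                    bmr=_parse_int(get(row, "bmr"), missing),
                    sbp_mmhg=_parse_float(get(row, "sbp_mmhg"), missing),
                    rr_bpm=_parse_float(get(row, "rr_bpm"), missing),
                    spo2_pct=spo2,
                    injuries=injuries,
                    hours_from_event=_parse_float(get(row, "hours_from_event"), missing),
                    transferred=bool(transferred) if transferred is not None else False,
                    survived=_parse_bool(get(row, "survived"), missing),
                )
            except RecordValidationError as exc:
                raise RecordValidationError(f"{path}:{lineno}: {exc}") from None
            records.append(rec)
    if not records:
        logger.warning("registry file %s contains a header but no rows", path)
    return records


def write_registry(
    records: Sequence[PatientRecord],
    path: str,
    *,
    injuries_path: Optional[str] = None,
    delimiter: str = ",",
    not_measurable_token: str = "NM",
) -> None:
    """Write records as a canonical-schema CSV (packed injuries column,
    or a long-format companion file when ``injuries_path`` is given)."""

    def fmt(v) -> str:
        if v is None:
            return ""
        if v is NOT_MEASURABLE:
            return not_measurable_token
        if isinstance(v, bool):
            return "true" if v else "false"
        if isinstance(v, float) and v.is_integer():
            return str(int(v))
        return str(v)

    with open(path, "w", newline="", encoding="utf-8") as fh:
        wtr = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        wtr.writerow(CANONICAL_COLUMNS)
        for r in records:
            packed = "" if injuries_path is not None else pack_injuries(r.injuries)
            wtr.writerow(
                [
                    r.patient_id,
                    r.site,
                    fmt(r.age_years),
                    r.mechanism,
                    fmt(r.gcs_total),
                    fmt(r.bmr),
                    fmt(r.sbp_mmhg),
                    fmt(r.rr_bpm),
                    fmt(r.spo2_pct),
                    packed,
                    fmt(r.hours_from_event),
                    fmt(r.transferred),
                    fmt(r.survived),
                ]
            )
    if injuries_path is not None:
        with open(injuries_path, "w", newline="", encoding="utf-8") as fh:
            wtr = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
            wtr.writerow(["patient_id", "body_region", "ais_severity"])
            for r in records:
                for inj in r.injuries:
                    wtr.writerow([r.patient_id, inj.body_region, inj.ais_severity])


def apply_eligibility(
    records: Sequence[PatientRecord],
    *,
    min_age: float = 14.0,
    max_hours: float = 24.0,
    strict_hours: bool = False,
) -> tuple[list[PatientRecord], EligibilityReport]:
    """Filter to the scoring-eligible cohort.

    Rules, applied in fixed order (each record counted once under its
    first failing rule): age >= ``min_age``; admitted within
    ``max_hours`` of the event (a missing delay is eligible unless
    ``strict_hours``); not transferred; mechanism blunt or penetrating.
    """
    kept: list[PatientRecord] = []
    n_age = n_late = n_transfer = n_mech = 0
    for r in records:
        if r.age_years < min_age:
            n_age += 1
        elif (r.hours_from_event is not None and r.hours_from_event > max_hours) or (
            strict_hours and r.hours_from_event is None
        ):
            n_late += 1
        elif r.transferred:
            n_transfer += 1
        elif r.mechanism not in ("blunt", "penetrating"):
            n_mech += 1
        else:
            kept.append(r)
    report = EligibilityReport(
        n_input=len(records),
        n_excluded_age=n_age,
        n_excluded_late=n_late,
        n_excluded_transfer=n_transfer,
        n_excluded_mechanism=n_mech,
        n_retained=len(kept),
    )
    return kept, report


def resolve_missing(
    record: PatientRecord,
    policy: str = "spo2-zero-if-unmeasurable-only",
) -> CodedPhysiology:
    """Code a record's physiology under an explicit missing-data policy.

    A "not measurable" SpO2 always codes to 0 (that is the banding rule,
    not an imputation).  A truly absent SpO2 is handled per policy:

    * ``spo2-zero-if-unmeasurable-only`` (default): the SpO2 code stays
      missing, flagging the record ineligible for the SpO2 models only;
    * ``spo2-zero-always``: absent SpO2 is coded 0 (flagged);
    * ``complete-case``: any absent covariate leaves its code missing, and
      an additional ``incomplete-case`` flag is raised if anything is
      absent, so callers can drop the record outright.

    Missing GCS/BMR, SBP or RR simply leave the corresponding codes
    missing; the scoring layer refuses models that need them.
    """
    if policy not in MISSING_POLICIES:
        raise ConfigurationError(
            f"unknown missing-data policy {policy!r}; expected one of "
            f"{MISSING_POLICIES}"
        )
    flags: list[str] = []
    gcs_code = code_gcs(record.gcs_total)
    sbp_code = code_sbp(record.sbp_mmhg)
    rr_code = code_rr(record.rr_bpm)
    if record.gcs_total is None:
        flags.append("gcs-missing")
    if record.bmr is None:
        flags.append("bmr-missing")
    if record.sbp_mmhg is None:
        flags.append("sbp-missing")
    if record.rr_bpm is None:
        flags.append("rr-missing")

    if record.spo2_pct is NOT_MEASURABLE:
        spo2_code: Optional[int] = 0
        flags.append("spo2-not-measurable")
    elif record.spo2_pct is None:
        if policy == "spo2-zero-always":
            spo2_code = 0
            flags.append("spo2-coded-zero-by-policy")
        else:
            spo2_code = None
            flags.append("spo2-missing")
    else:
        spo2_code = code_spo2(record.spo2_pct)

    if policy == "complete-case" and any(
        f.endswith("-missing") for f in flags
    ):
        flags.append("incomplete-case")

    rts_weighted, trts = rts_totals(gcs_code, sbp_code, rr_code)
    return CodedPhysiology(
        gcs_code=gcs_code,
        sbp_code=sbp_code,
        rr_code=rr_code,
        spo2_code=spo2_code,
        bmr=record.bmr,
        age_ind=age_indicator(record.age_years),
        rts_weighted=rts_weighted,
        trts=trts,
        flags=flags,
    )


__all__ = [
    "PatientRecord",
    "EligibilityReport",
    "Injury",
    "NOT_MEASURABLE",
    "AIS_UNKNOWN",
    "MECHANISMS",
    "MISSING_POLICIES",
    "CANONICAL_COLUMNS",
    "read_registry",
    "write_registry",
    "apply_eligibility",
    "resolve_missing",
    "parse_packed_injuries",
    "pack_injuries",
    "replace",
]
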