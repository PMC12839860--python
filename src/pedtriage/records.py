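"""Domain types for synthetic trauma-registry records and their CSV formats.

A cohort is a list of :class:`PatientRecord`; the diagnosis-code universe is a
list of :class:`DiagnosisCode`.  Both round-trip losslessly through plain CSV
files whose exact column layouts are documented on the writer functions, so
cohorts can be exchanged with external tools without a binary dependency.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .exceptions import CohortParseError

#: The six ISS body regions.
BODY_REGIONS = ("head_neck", "face", "chest", "abdomen", "extremities", "external")

#: Controlled vocabulary of urgent-procedure types that qualify a patient as
#: needing trauma-center resources when performed within 72 h of arrival.
PROCEDURE_TYPES = (
    "tube_thoracostomy",
    "pericardiocentesis",
    "icp_monitoring",
    "craniotomy",
    "laparotomy",
    "hemorrhage_control",
    "invasive_angiography",
    "solid_organ_repair",
)

MECHANISMS = ("abuse", "penetrating", "transport", "other_blunt")
ED_DISPOSITIONS = ("home", "admit_ward", "admit_icu", "transfer", "died_ed")
SEXES = ("F", "M")

COHORT_COLUMNS = [
    "patient_id", "year", "age_years", "sex", "mechanism", "codes",
    "ais_profile", "transfusion_hours", "procedures", "anesthesia",
    "mech_vent", "ed_disposition", "icu_days", "abuse_flag", "died",
    "hospital_hours",
]

VOCAB_COLUMNS = ["code_id", "p_survive", "p_critcare", "body_region", "ais_severity"]


@dataclass(frozen=True)
class DiagnosisCode:
    """A synthetic ICD-like diagnosis code with latent outcome propensities.

    ``p_survive`` and ``p_critcare`` are generator-side ground truth: the
    probability that a patient carrying only this code survives, and the
    probability that the code triggers a critical-care episode.  The derived
    survival risk ratio (SRR) and critical-care risk ratio (CCRR) estimate
    them from cohort data.
    """

    code_id: str
    p_survive: float
    p_critcare: float
    body_region: str
    ais_severity: int

    def __post_init__(self):
        if not (0.0 <= self.p_survive <= 1.0):
            raise ValueError(f"p_survive must be in [0,1], got {self.p_survive}")
        if not (0.0 <= self.p_critcare <= 1.0):
            raise ValueError(f"p_critcare must be in [0,1], got {self.p_critcare}")
        if self.body_region not in BODY_REGIONS:
            raise ValueError(f"unknown body_region {self.body_region!r}")
        if self.ais_severity not in (1, 2, 3, 4, 5, 6):
            raise ValueError(f"ais_severity must be 1-6, got {self.ais_severity}")


@dataclass
class PatientRecord:
    """One registry row: demographics, diagnoses, AIS profile, timed events.

    ``ais_profile`` maps body region to the maximum AIS severity sustained in
    that region (regions with no injury may be omitted).  ``procedures`` is a
    list of ``(procedure_type, hours_from_arrival)`` pairs drawn from the
    :data:`PROCEDURE_TYPES` controlled vocabulary.  ``transfusion_hours`` is
    the time of the earliest blood-product transfusion, or ``None`` if the
    patient was never transfused.
    """

    patient_id: str
    year: int
    age_years: int
    sex: str
    mechanism: str
    codes: list[str]
    ais_profile: dict[str, int] = field(default_factory=dict)
    transfusion_hours: float | None = None
    procedures: list[tuple[str, float]] = field(default_factory=list)
    anesthesia: bool = False
    mech_vent: bool = False
    ed_disposition: str = "home"
    icu_days: int = 0
    abuse_flag: bool = False
    died: bool = False
    hospital_hours: float = 0.0

    def validate(self, vocabulary_ids: set[str] | None = None) -> None:
        """Raise ``ValueError`` on any invariant violation."""
        if not self.codes:
            raise ValueError(f"{self.patient_id}: codes must be non-empty")
        if vocabulary_ids is not None:
            unknown = [c for c in self.codes if c not in vocabulary_ids]
            if unknown:
                raise ValueError(f"{self.patient_id}: unknown codes {unknown}")
        if self.age_years < 0:
            raise ValueError(f"{self.patient_id}: negative age")
        if self.sex not in SEXES:
            raise ValueError(f"{self.patient_id}: unknown sex {self.sex!r}")
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"{self.patient_id}: unknown mechanism {self.mechanism!r}")
        if self.ed_disposition not in ED_DISPOSITIONS:
            raise ValueError(
                f"{self.patient_id}: unknown ed_disposition {self.ed_disposition!r}")
        for region, sev in self.ais_profile.items():
            if region not in BODY_REGIONS:
                raise ValueError(f"{self.patient_id}: unknown body region {region!r}")
            if not (0 <= int(sev) <= 6):
                raise ValueError(f"{self.patient_id}: AIS severity {sev} outside 0-6")
        for ptype, hours in self.procedures:
            if ptype not in PROCEDURE_TYPES:
                raise ValueError(f"{self.patient_id}: unknown procedure {ptype!r}")
            if not (hours >= 0):
                raise ValueError(f"{self.patient_id}: negative procedure time")
        if self.transfusion_hours is not None and not (self.transfusion_hours >= 0):
            raise ValueError(f"{self.patient_id}: negative transfusion_hours")
        if self.icu_days < 0:
            raise ValueError(f"{self.patient_id}: negative icu_days")
        if self.ed_disposition == "admit_icu" and self.icu_days < 1:
            raise ValueError(
                f"{self.patient_id}: admit_icu requires icu_days >= 1")
        if not (self.hospital_hours >= 0):
            raise ValueError(f"{self.patient_id}: negative hospital_hours")


# ---------------------------------------------------------------------------
# CSV serialization
# ---------------------------------------------------------------------------

def _fmt_float(x: float | None) -> str:
    return "" if x is None else repr(float(x))


def _fmt_bool(x: bool) -> str:
    return "1" if x else "0"


def write_cohort_csv(cohort: Iterable[PatientRecord], path) -> None:
    """Write a cohort to CSV, one row per patient.

    Columns (in order): ``patient_id,year,age_years,sex,mechanism,codes,
    ais_profile,transfusion_hours,procedures,anesthesia,mech_vent,
    ed_disposition,icu_days,abuse_flag,died,hospital_hours``.
    ``codes`` is ``;``-separated; ``procedures`` is ``;``-separated
    ``type@hours`` tokens; ``ais_profile`` is ``;``-separated
    ``region:severity`` tokens; absent numerics are empty; booleans are 0/1.
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(COHORT_COLUMNS)
        for r in cohort:
            w.writerow([
                r.patient_id,
                r.year,
                r.age_years,
                r.sex,
                r.mechanism,
                ";".join(r.codes),
                ";".join(f"{k}:{int(v)}" for k, v in r.ais_profile.items()),
                _fmt_float(r.transfusion_hours),
                ";".join(f"{t}@{repr(float(h))}" for t, h in r.procedures),
                _fmt_bool(r.anesthesia),
                _fmt_bool(r.mech_vent),
                r.ed_disposition,
                r.icu_days,
                _fmt_bool(r.abuse_flag),
                _fmt_bool(r.died),
                _fmt_float(r.hospital_hours),
            ])


def _parse(row_no: int, fieldname: str, raw: str, kind: str):
    try:
        if kind == "int":
            return int(raw)
        if kind == "float":
            return float(raw)
        if kind == "bool":
            if raw not in ("0", "1"):
                raise ValueError(f"boolean field must be 0/1, got {raw!r}")
            return raw == "1"
    except ValueError as exc:
        raise CohortParseError(row_no, fieldname, str(exc)) from None
    raise AssertionError(kind)


def read_cohort_csv(path) -> list[PatientRecord]:
    """Read a cohort CSV written by :func:`write_cohort_csv`.

    Malformed rows raise :class:`~pedtriage.exceptions.CohortParseError`
    naming the row number and field.
    """
    cohort: list[PatientRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != COHORT_COLUMNS:
            raise CohortParseError(0, "header",
                                   f"expected columns {COHORT_COLUMNS}, got {reader.fieldnames}")
        for i, row in enumerate(reader, start=1):
            ais: dict[str, int] = {}
            for tok in filter(None, row["ais_profile"].split(";")):
                if ":" not in tok:
                    raise CohortParseError(i, "ais_profile", f"bad token {tok!r}")
                region, sev = tok.split(":", 1)
                ais[region] = _parse(i, "ais_profile", sev, "int")
            procedures: list[tuple[str, float]] = []
            for tok in filter(None, row["procedures"].split(";")):
                if "@" not in tok:
                    raise CohortParseError(i, "procedures", f"bad token {tok!r}")
                ptype, hours = tok.split("@", 1)
                if ptype not in PROCEDURE_TYPES:
                    raise CohortParseError(i, "procedures",
                                           f"unknown procedure type {ptype!r}")
                procedures.append((ptype, _parse(i, "procedures", hours, "float")))
            rec = PatientRecord(
                patient_id=row["patient_id"],
                year=_parse(i, "year", row["year"], "int"),
                age_years=_parse(i, "age_years", row["age_years"], "int"),
                sex=row["sex"],
                mechanism=row["mechanism"],
                codes=[c for c in row["codes"].split(";") if c],
                ais_profile=ais,
                transfusion_hours=(None if row["transfusion_hours"] == ""
                                   else _parse(i, "transfusion_hours",
                                               row["transfusion_hours"], "float")),
                procedures=procedures,
                anesthesia=_parse(i, "anesthesia", row["anesthesia"], "bool"),
                mech_vent=_parse(i, "mech_vent", row["mech_vent"], "bool"),
                ed_disposition=row["ed_disposition"],
                icu_days=_parse(i, "icu_days", row["icu_days"], "int"),
                abuse_flag=_parse(i, "abuse_flag", row["abuse_flag"], "bool"),
                died=_parse(i, "died", row["died"], "bool"),
                hospital_hours=_parse(i, "hospital_hours", row["hospital_hours"],
                                      "float"),
            )
            try:
                rec.validate()
            except ValueError as exc:
                raise CohortParseError(i, "record", str(exc)) from None
            cohort.append(rec)
    return cohort


def write_vocabulary_csv(vocabulary: Sequence[DiagnosisCode], path) -> None:
    """Write a code vocabulary as ``code_id,p_survive,p_critcare,body_region,ais_severity``."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(VOCAB_COLUMNS)
        for c in vocabulary:
            w.writerow([c.code_id, repr(c.p_survive), repr(c.p_critcare),
                        c.body_region, c.ais_severity])


def read_vocabulary_csv(path) -> list[DiagnosisCode]:
    vocab: list[DiagnosisCode] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != VOCAB_COLUMNS:
            raise CohortParseError(0, "header",
                                   f"expected columns {VOCAB_COLUMNS}, got {reader.fieldnames}")
        for i, row in enumerate(reader, start=1):
            if row["code_id"] in seen:
                raise CohortParseError(i, "code_id", f"duplicate {row['code_id']!r}")
            seen.add(row["code_id"])
            try:
                vocab.append(DiagnosisCode(
                    code_id=row["code_id"],
                    p_survive=_parse(i, "p_survive", row["p_survive"], "float"),
                    p_critcare=_parse(i, "p_critcare", row["p_critcare"], "float"),
                    body_region=row["body_region"],
                    ais_severity=_parse(i, "ais_severity", row["ais_severity"], "int"),
                ))
            except ValueError as exc:
                raise CohortParseError(i, "record", str(exc)) from None
    return vocab
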