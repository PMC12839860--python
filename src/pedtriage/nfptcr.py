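"""Need-for-pediatric-trauma-center-resources (NFPTCR) classification.

A patient is NFPTCR+ if any one of five composite criteria fires:

* ``transfusion`` — emergent transfusion of any blood product within 4 h of
  arrival;
* ``urgent_procedure`` — any qualifying procedure (tube thoracostomy,
  pericardiocentesis, ICP monitoring, craniotomy, laparotomy, hemorrhage
  control, invasive angiography, solid-organ/hollow-viscus repair) within
  72 h of arrival;
* ``anesthesia_le5`` — any general anesthesia or mechanical ventilation in a
  patient 5 years old or younger;
* ``icu`` — admission from the emergency department to the ICU, or any ICU
  stay of 3 days or more;
* ``abuse`` — a physical child-abuse report or investigation.

All time and age boundaries are inclusive ("within 4 h", "5 years old or
younger", ">= 3 days").  Death is deliberately not a criterion.
Classification is a pure function of the record.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Sequence, Union

from .records import PatientRecord

CRITERIA = ("transfusion", "urgent_procedure", "anesthesia_le5", "icu", "abuse")

TRANSFUSION_WINDOW_H = 4.0
PROCEDURE_WINDOW_H = 72.0
ANESTHESIA_MAX_AGE = 5
ICU_DAYS_MIN = 3


@dataclass(frozen=True)
class NfptcrResult:
    """Classification outcome with a per-criterion audit trail."""

    patient_id: str
    positive: bool
    fired: frozenset[str]


def classify_nfptcr(record: PatientRecord) -> NfptcrResult:
    """Classify one record; ``positive`` iff any criterion fired."""
    fired: set[str] = set()
    if (record.transfusion_hours is not None
            and record.transfusion_hours <= TRANSFUSION_WINDOW_H):
        fired.add("transfusion")
    if any(hours <= PROCEDURE_WINDOW_H for _, hours in record.procedures):
        fired.add("urgent_procedure")
    if (record.anesthesia or record.mech_vent) and record.age_years <= ANESTHESIA_MAX_AGE:
        fired.add("anesthesia_le5")
    if record.ed_disposition == "admit_icu" or record.icu_days >= ICU_DAYS_MIN:
        fired.add("icu")
    if record.abuse_flag:
        fired.add("abuse")
    return NfptcrResult(record.patient_id, bool(fired), frozenset(fired))


def classify_cohort(cohort: Sequence[PatientRecord]) -> list[NfptcrResult]:
    return [classify_nfptcr(rec) for rec in cohort]


def nfptcr_prevalence(
    cohort: Sequence[Union[PatientRecord, NfptcrResult]]
) -> tuple[int, float]:
    """Count of positives and the positive fraction over a non-empty cohort.

    Accepts either raw records (classified on the fly) or precomputed
    :class:`NfptcrResult` objects.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    n_pos = 0
    for item in cohort:
        res = item if isinstance(item, NfptcrResult) else classify_nfptcr(item)
        n_pos += res.positive
    return n_pos, n_pos / len(cohort)


def write_nfptcr_csv(results: Iterable[NfptcrResult], path) -> None:
    """Write results as ``patient_id,positive,fired`` (fired ``;``-separated)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "positive", "fired"])
        for r in results:
            w.writerow([r.patient_id, "1" if r.positive else "0",
                        ";".join(sorted(r.fired))])


def read_nfptcr_csv(path) -> list[NfptcrResult]:
    out: list[NfptcrResult] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            fired = frozenset(filter(None, row["fired"].split(";")))
            out.append(NfptcrResult(row["patient_id"], row["positive"] == "1", fired))
    return out
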