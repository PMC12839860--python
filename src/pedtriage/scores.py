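"""Diagnosis-code severity scores: SRR/CCRR derivation, ISS, ICISS, ICASS.

The central object is :class:`DiagnosisRiskModel`, which is fitted to a
derivation cohort and estimates, for every diagnosis code seen often enough,

* the survival risk ratio ``SRR = n_survivors / n_patients`` — the fraction
  of patients carrying the code who survived to discharge; and
* the critical-care risk ratio ``CCRR = 100 * n_critcare / n_patients`` —
  the percentage of patients carrying the code who had a critical-care
  episode under a configurable rule set.

The fitted :class:`DiagnosisRiskResults` applies those per-code ratios to
any cohort to produce per-patient scores on a common 0-100 scale (higher =
more severe):

* ``iciss_scaled = (1 - prod SRR) * 100`` over the patient's distinct codes
  (the ICD-based injury severity score, inverted and rescaled so it points
  the same way as ISS);
* ``icass = max CCRR`` over the patient's distinct codes (the ICD
  critical-care severity score); and
* ``iss``, the standard Abbreviated Injury Scale summary (sum of squares of
  the three worst region severities, 75 if any region is AIS 6).

Functional wrappers (:func:`derive_score_table`, :func:`score_iciss`,
:func:`score_icass`, :func:`apply_scores`, :func:`compute_iss`) expose the
same operations for scripting.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import UnresolvableScoreError
from .records import PatientRecord

SCORE_TABLE_COLUMNS = ["code_id", "n_patients", "n_survivors", "n_critcare",
                       "srr", "ccrr"]

UNSEEN_POLICIES = ("neutral", "cohort_mean", "strict")
ICISS_VARIANTS = ("product", "worst")


@dataclass(frozen=True)
class CritCareRule:
    """Rule set defining a critical-care episode for CCRR derivation.

    The default — ICU admission from the ED or any ICU stay of at least
    ``icu_days_min`` days, mechanical ventilation, or in-hospital death —
    captures generic critical-care services.  It is deliberately distinct
    from the trauma-center resource (NFPTCR) criteria so that the score and
    the outcome it is later evaluated against are not the same rule.
    """

    icu_admit: bool = True
    icu_days_min: int = 1
    mech_vent: bool = True
    death: bool = True

    def __call__(self, record: PatientRecord) -> bool:
        if self.icu_admit and record.ed_disposition == "admit_icu":
            return True
        if record.icu_days >= self.icu_days_min:
            return True
        if self.mech_vent and record.mech_vent:
            return True
        if self.death and record.died:
            return True
        return False

    def to_dict(self) -> dict:
        return {"icu_admit": self.icu_admit, "icu_days_min": self.icu_days_min,
                "mech_vent": self.mech_vent, "death": self.death}


DEFAULT_CRITCARE_RULE = CritCareRule()


def compute_iss(ais_profile: Mapping[str, int]) -> int:
    """Injury Severity Score from a region -> max-AIS map.

    Any AIS 6 injury scores the maximum of 75; otherwise the ISS is the sum
    of squares of the three highest region severities.  Missing regions
    count as uninjured (severity 0).
    """
    sevs = []
    for region, sev in ais_profile.items():
        sev = int(sev)
        if not (0 <= sev <= 6):
            raise ValueError(f"AIS severity must be 0-6, got {sev} for {region!r}")
        sevs.append(sev)
    if any(s == 6 for s in sevs):
        return 75
    top3 = sorted(sevs, reverse=True)[:3]
    return int(sum(s * s for s in top3))


class DiagnosisRiskModel:
    """Per-diagnosis-code outcome model for a derivation cohort.

    Parameters
    ----------
    cohort : list of PatientRecord
        Non-empty derivation cohort.
    critcare_rule : callable, optional
        Predicate ``record -> bool`` marking a critical-care episode;
        defaults to :data:`DEFAULT_CRITCARE_RULE`.
    min_count : int
        Minimum number of carriers for a code to enter the table.  Ratios
        from very few carriers are noisy; the default of 1 keeps every
        observed code.
    """

    def __init__(self, cohort: Sequence[PatientRecord],
                 critcare_rule: Callable[[PatientRecord], bool] | None = None,
                 min_count: int = 1):
        if not cohort:
            raise ValueError("derivation cohort must be non-empty")
        if min_count < 1:
            raise ValueError(f"min_count must be >= 1, got {min_count}")
        self.cohort = list(cohort)
        self.critcare_rule = critcare_rule or DEFAULT_CRITCARE_RULE
        self.min_count = min_count

    def fit(self) -> "DiagnosisRiskResults":
        """Tally carriers, survivors and critical-care episodes per code."""
        n: dict[str, int] = {}
        surv: dict[str, int] = {}
        cc: dict[str, int] = {}
        for rec in self.cohort:
            fired = bool(self.critcare_rule(rec))
            survived = not rec.died
            for code in set(rec.codes):  # duplicates within a patient count once
                n[code] = n.get(code, 0) + 1
                surv[code] = surv.get(code, 0) + survived
                cc[code] = cc.get(code, 0) + fired
        rows = [(c, n[c], surv[c], cc[c], surv[c] / n[c], 100.0 * cc[c] / n[c])
                for c in sorted(n) if n[c] >= self.min_count]
        table = pd.DataFrame(rows, columns=SCORE_TABLE_COLUMNS)
        years = sorted({rec.year for rec in self.cohort})
        return DiagnosisRiskResults(table, model=self, derivation_years=years)


class DiagnosisRiskResults:
    """Fitted per-code score table with application and summary methods."""

    def __init__(self, table: pd.DataFrame, model: DiagnosisRiskModel | None = None,
                 derivation_years: Sequence[int] = (), min_count: int | None = None,
                 critcare_rule=None):
        self.table = table.reset_index(drop=True)
        self.model = model
        self.derivation_years = list(derivation_years)
        self.min_count = (model.min_count if model is not None
                          else (min_count if min_count is not None else 1))
        self.critcare_rule = (model.critcare_rule if model is not None
                              else critcare_rule)
        self._srr = dict(zip(self.table["code_id"], self.table["srr"]))
        self._ccrr = dict(zip(self.table["code_id"], self.table["ccrr"]))

    # -- accessors ---------------------------------------------------------
    @property
    def srr(self) -> Mapping[str, float]:
        return self._srr

    @property
    def ccrr(self) -> Mapping[str, float]:
        return self._ccrr

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Wilson score intervals for each code's SRR and CCRR/100."""
        z = stats.norm.ppf(1 - alpha / 2)
        out = self.table[["code_id", "n_patients"]].copy()
        for name, count_col in (("srr", "n_survivors"), ("ccrr", "n_critcare")):
            k = self.table[count_col].to_numpy(dtype=float)
            n = self.table["n_patients"].to_numpy(dtype=float)
            p = k / n
            denom = 1 + z * z / n
            centre = (p + z * z / (2 * n)) / denom
            half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
            scale = 100.0 if name == "ccrr" else 1.0
            out[f"{name}_lo"] = scale * np.clip(centre - half, 0, 1)
            out[f"{name}_hi"] = scale * np.clip(centre + half, 0, 1)
        return out

    def summary(self, max_rows: int = 20) -> str:
        """Human-readable fit summary (top codes by CCRR)."""
        head = (self.table.sort_values("ccrr", ascending=False)
                .head(max_rows)
                .to_string(index=False, float_format=lambda x: f"{x:.3f}"))
        lines = [
            "Diagnosis-code risk model",
            "=" * 60,
            f"codes in table:    {len(self.table)}",
            f"derivation years:  {self.derivation_years or 'n/a'}",
            f"min carrier count: {self.min_count}",
            "",
            f"Top codes by critical-care risk ratio (CCRR):",
            head,
        ]
        return "\n".join(lines)

    # -- scoring -----------------------------------------------------------
    def _resolve(self, codes: Iterable[str], unseen_policy: str,
                 patient_id: str | None = None) -> tuple[list[float], list[float]]:
        if unseen_policy not in UNSEEN_POLICIES:
            raise ValueError(f"unknown unseen_policy {unseen_policy!r}")
        codes = sorted(set(codes))
        if not codes:
            raise ValueError("record has no diagnosis codes")
        srrs: list[float] = []
        ccrrs: list[float] = []
        mean_srr = float(self.table["srr"].mean()) if len(self.table) else 1.0
        mean_ccrr = float(self.table["ccrr"].mean()) if len(self.table) else 0.0
        n_seen = 0
        for c in codes:
            if c in self._srr:
                srrs.append(self._srr[c])
                ccrrs.append(self._ccrr[c])
                n_seen += 1
            elif unseen_policy == "neutral":
                srrs.append(1.0)
                ccrrs.append(0.0)
            elif unseen_policy == "cohort_mean":
                srrs.append(mean_srr)
                ccrrs.append(mean_ccrr)
            # strict: unseen codes are dropped
        if unseen_policy == "strict" and n_seen == 0:
            who = f" for patient {patient_id}" if patient_id else ""
            raise UnresolvableScoreError(
                f"no diagnosis code{who} resolves against the score table: {codes}")
        return srrs, ccrrs

    def score_iciss(self, record: PatientRecord, unseen_policy: str = "neutral",
                    variant: str = "product") -> float:
        """Scaled ICISS for one record: ``(1 - combined SRR) * 100``.

        ``variant="product"`` combines SRRs multiplicatively over the
        patient's distinct codes (the conventional rule); ``"worst"`` uses
        the single lowest SRR.
        """
        if variant not in ICISS_VARIANTS:
            raise ValueError(f"unknown iciss variant {variant!r}")
        srrs, _ = self._resolve(record.codes, unseen_policy, record.patient_id)
        combined = float(np.prod(srrs)) if variant == "product" else min(srrs)
        return (1.0 - combined) * 100.0

    def score_icass(self, record: PatientRecord,
                    unseen_policy: str = "neutral") -> float:
        """ICASS for one record: the maximum CCRR over its distinct codes."""
        _, ccrrs = self._resolve(record.codes, unseen_policy, record.patient_id)
        return float(max(ccrrs)) if ccrrs else 0.0

    def apply(self, cohort: Sequence[PatientRecord],
              unseen_policy: str = "neutral",
              iciss_variant: str = "product") -> pd.DataFrame:
        """Score a cohort; returns ``patient_id,iss,iciss_scaled,icass`` rows.

        Row order follows the input cohort.  If the application cohort
        shares calendar years with the derivation cohort a warning is issued
        (the temporal split should normally be disjoint).
        """
        if self.derivation_years:
            overlap = {r.year for r in cohort} & set(self.derivation_years)
            if overlap:
                warnings.warn(
                    f"application cohort shares years {sorted(overlap)} with the "
                    "derivation cohort; scores are not out-of-sample",
                    UserWarning, stacklevel=2)
        rows = []
        for rec in cohort:
            rows.append((rec.patient_id,
                         compute_iss(rec.ais_profile),
                         self.score_iciss(rec, unseen_policy, iciss_variant),
                         self.score_icass(rec, unseen_policy)))
        return pd.DataFrame(rows,
                            columns=["patient_id", "iss", "iciss_scaled", "icass"])

    # -- persistence -------------------------------------------------------
    def to_csv(self, path, meta_path=None) -> None:
        """Write the score table; metadata goes to a sidecar JSON."""
        self.table.to_csv(path, index=False)
        if meta_path is not None:
            rule = self.critcare_rule
            meta = {
                "derivation_years": self.derivation_years,
                "min_count": self.min_count,
                "critcare_rule": (rule.to_dict()
                                  if isinstance(rule, CritCareRule) else repr(rule)),
            }
            with open(meta_path, "w") as fh:
                json.dump(meta, fh, indent=2, sort_keys=True)

    @classmethod
    def from_csv(cls, path, meta_path=None) -> "DiagnosisRiskResults":
        table = pd.read_csv(path)
        years: list[int] = []
        min_count = 1
        if meta_path is not None:
            with open(meta_path) as fh:
                meta = json.load(fh)
            years = meta.get("derivation_years", [])
            min_count = meta.get("min_count", 1)
        return cls(table, derivation_years=years, min_count=min_count)


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------

def derive_score_table(derivation_cohort: Sequence[PatientRecord],
                       critcare_definition: Callable[[PatientRecord], bool] | None = None,
                       min_count: int = 1) -> DiagnosisRiskResults:
    """Fit :class:`DiagnosisRiskModel` and return the per-code score table."""
    return DiagnosisRiskModel(derivation_cohort, critcare_definition,
                              min_count).fit()


def _as_results(table) -> DiagnosisRiskResults:
    if isinstance(table, DiagnosisRiskResults):
        return table
    if isinstance(table, pd.DataFrame):
        return DiagnosisRiskResults(table)
    raise TypeError(f"expected DiagnosisRiskResults or DataFrame, got {type(table)}")


def score_iciss(record: PatientRecord, table, unseen_policy: str = "neutral",
                variant: str = "product") -> float:
    return _as_results(table).score_iciss(record, unseen_policy, variant)


def score_icass(record: PatientRecord, table,
                unseen_policy: str = "neutral") -> float:
    return _as_results(table).score_icass(record, unseen_policy)


def apply_scores(application_cohort: Sequence[PatientRecord], table,
                 unseen_policy: str = "neutral",
                 iciss_variant: str = "product") -> pd.DataFrame:
    return _as_results(table).apply(application_cohort, unseen_policy,
                                    iciss_variant)
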