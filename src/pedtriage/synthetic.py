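"""Seeded synthetic trauma-registry generator.

Real trauma-registry extracts (e.g. national quality-improvement program
files) cannot be redistributed, so this module generates cohorts with the
statistical structure the downstream analysis assumes:

* a vocabulary of ICD-like diagnosis codes, each carrying a latent survival
  probability ``p_survive`` and a latent critical-care propensity
  ``p_critcare``, positively coupled through AIS severity (worse codes kill
  more and consume more critical care);
* patients carrying 1..k codes, with death and critical-care episodes
  generated from the per-code propensities under a multiplicative
  (independence-across-codes) model, so that survival risk ratios and
  critical-care risk ratios derived from a large cohort recover the latent
  propensities;
* timed resource-utilization events (transfusion, urgent procedures,
  anesthesia/ventilation, ICU stays, abuse investigations) planted so that a
  critical-care episode produces at least one qualifying trauma-center
  resource event, while patients without an episode receive qualifying
  events only at a low background rate plus deliberately out-of-window
  events that exercise the timeframe filters.

Deaths are nested within critical-care episodes whenever the patient's
marginal death probability does not exceed the episode probability (fatal
trauma courses pass through critical care); both marginals are preserved
exactly.  All randomness flows from the single integer seed in
:class:`CohortSpec` through one ``numpy`` generator stream, so identical
specs give byte-identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .records import (BODY_REGIONS, MECHANISMS, PROCEDURE_TYPES,
                      DiagnosisCode, PatientRecord)

#: Default marginal mix of injury mechanisms (abuse, penetrating, transport,
#: other blunt), matching the descriptive margins of a large US pediatric
#: trauma registry cohort.
DEFAULT_MECHANISM_PROBS = (0.013, 0.019, 0.316, 0.652)

#: Default AIS severity distribution over codes (severities 1..6), skewed
#: toward minor injuries as in registry data.
DEFAULT_AIS_WEIGHTS = (0.30, 0.28, 0.20, 0.12, 0.07, 0.03)

#: Which trauma-center resource event realizes a critical-care episode:
#: transfusion, urgent procedure, anesthesia/ventilation, ICU, abuse.
DEFAULT_EVENT_MIX = {
    "transfusion": 0.15,
    "urgent_procedure": 0.20,
    "anesthesia_le5": 0.15,
    "icu": 0.45,
    "abuse": 0.05,
}


def generate_vocabulary(
    n_codes: int,
    seed: int,
    *,
    critcare_scale: float = 0.20,
    death_scale: float = 0.04,
    concentration: float = 8.0,
    ais_weights: Sequence[float] = DEFAULT_AIS_WEIGHTS,
) -> list[DiagnosisCode]:
    """Generate ``n_codes`` synthetic diagnosis codes.

    Each code gets an AIS severity (1-6, weighted by ``ais_weights``), a body
    region (uniform over the six ISS regions), and latent propensities drawn
    from Beta distributions whose means rise with severity:

    * ``p_critcare`` has mean ``critcare_scale * ais/6``;
    * ``1 - p_survive`` has mean ``death_scale * (ais/6)**2`` (lethality
      concentrates in the most severe codes).

    ``concentration`` is the Beta pseudo-count; a scale of 0 degenerates to
    the constant ``p_critcare = 0`` / ``p_survive = 1``.  Because both means
    rise with the shared AIS severity, ``p_critcare`` and ``1 - p_survive``
    are positively coupled across the vocabulary.

    Deterministic for a fixed seed.
    """
    if n_codes < 1:
        raise ValueError(f"n_codes must be >= 1, got {n_codes}")
    rng = np.random.default_rng(seed)
    width = len(str(max(n_codes - 1, 1)))
    vocab: list[DiagnosisCode] = []
    for i in range(n_codes):
        ais = int(rng.choice(6, p=np.asarray(ais_weights) / np.sum(ais_weights))) + 1
        region = str(rng.choice(BODY_REGIONS))
        m_cc = critcare_scale * ais / 6.0
        m_die = death_scale * (ais / 6.0) ** 2
        p_cc = _beta_mean(rng, m_cc, concentration)
        p_die = _beta_mean(rng, m_die, concentration)
        vocab.append(DiagnosisCode(
            code_id=f"SYN{i:0{max(width, 4)}d}",
            p_survive=1.0 - p_die,
            p_critcare=p_cc,
            body_region=region,
            ais_severity=ais,
        ))
    return vocab


def _beta_mean(rng: np.random.Generator, mean: float, concentration: float) -> float:
    """Beta draw with given mean; degenerate at the boundary means."""
    if mean <= 0.0:
        return 0.0
    if mean >= 1.0:
        return 1.0
    return float(rng.beta(concentration * mean, concentration * (1.0 - mean)))


@dataclass
class CohortSpec:
    """Full parameterization of one synthetic cohort draw.

    ``code_count_geom_p`` is the success probability of the truncated
    geometric governing how many distinct codes a patient carries (real
    injury records list few distinct codes).  ``background_event_rate`` is
    the probability that a patient *without* a critical-care episode still
    has one qualifying resource event; ``out_of_window_rate`` plants events
    with disqualifying timestamps (transfusion after 4 h, procedures after
    72 h) on episode-free patients to exercise the timeframe filters.
    """

    n_patients: int
    years: Sequence[int]
    seed: int
    n_codes: int = 500
    max_codes_per_patient: int = 6
    code_count_geom_p: float = 0.55
    background_event_rate: float = 0.02
    out_of_window_rate: float = 0.05
    mechanism_probs: Sequence[float] = DEFAULT_MECHANISM_PROBS
    female_frac: float = 0.63
    age_low: int = 0
    age_high: int = 15
    event_mix: dict = field(default_factory=lambda: dict(DEFAULT_EVENT_MIX))

    def __post_init__(self):
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if not self.years:
            raise ValueError("years must be non-empty")
        if self.max_codes_per_patient < 1:
            raise ValueError("max_codes_per_patient must be >= 1")


def generate_cohort(spec: CohortSpec,
                    vocabulary: Sequence[DiagnosisCode]) -> list[PatientRecord]:
    """Generate a synthetic cohort against ``vocabulary``.

    Per patient: codes are drawn without replacement (count truncated
    geometric, capped at ``max_codes_per_patient`` and the vocabulary size);
    death occurs with probability ``1 - prod(p_survive)`` and a critical-care
    episode with probability ``1 - prod(1 - p_critcare)`` over the patient's
    codes, coupled so that death implies an episode whenever the marginals
    permit.  An episode plants an ICU stay of at least one day (the
    critical-care service) plus one qualifying trauma-center resource event
    drawn from ``spec.event_mix``; the AIS profile is the per-region maximum
    severity over the patient's codes.
    """
    if not vocabulary:
        raise ValueError("vocabulary must be non-empty")
    rng = np.random.default_rng(spec.seed)
    mech_p = np.asarray(spec.mechanism_probs, dtype=float)
    mech_p = mech_p / mech_p.sum()

    p_cc = np.array([c.p_critcare for c in vocabulary])
    p_surv = np.array([c.p_survive for c in vocabulary])
    regions = [c.body_region for c in vocabulary]
    severities = np.array([c.ais_severity for c in vocabulary])
    code_ids = [c.code_id for c in vocabulary]

    width = len(str(max(spec.n_patients - 1, 1)))
    cohort: list[PatientRecord] = []
    for i in range(spec.n_patients):
        year = int(rng.choice(np.asarray(spec.years)))
        age = int(rng.integers(spec.age_low, spec.age_high + 1))
        sex = "F" if rng.random() < spec.female_frac else "M"
        mechanism = MECHANISMS[int(rng.choice(4, p=mech_p))]

        k = min(int(rng.geometric(spec.code_count_geom_p)),
                spec.max_codes_per_patient, len(vocabulary))
        idx = rng.choice(len(vocabulary), size=k, replace=False)

        q_episode = 1.0 - float(np.prod(1.0 - p_cc[idx]))
        q_death = 1.0 - float(np.prod(p_surv[idx]))
        episode = rng.random() < q_episode
        # Couple death to the episode: P(die) = q_death is preserved and
        # death => episode whenever q_death <= q_episode.
        if episode:
            died = rng.random() < (min(1.0, q_death / q_episode) if q_episode > 0 else 0.0)
        else:
            leak = (max(0.0, q_death - q_episode) / (1.0 - q_episode)
                    if q_episode < 1.0 else 0.0)
            died = rng.random() < leak

        ais_profile: dict[str, int] = {}
        for j in idx:
            r = regions[j]
            ais_profile[r] = max(ais_profile.get(r, 0), int(severities[j]))

        rec = PatientRecord(
            patient_id=f"P{i:0{max(width, 5)}d}",
            year=year,
            age_years=age,
            sex=sex,
            mechanism=mechanism,
            codes=[code_ids[j] for j in idx],
            ais_profile=ais_profile,
        )

        if episode:
            # Critical-care service: at least one ICU day.
            rec.icu_days = 1 + int(rng.integers(0, 2))
            rec.ed_disposition = "admit_ward"
            _plant_qualifying_event(rec, rng, spec.event_mix)
            rec.hospital_hours = float(np.exp(rng.normal(math.log(62.0), 0.8)))
        else:
            rec.ed_disposition = str(rng.choice(
                ["home", "admit_ward", "transfer"], p=[0.25, 0.63, 0.12]))
            if rng.random() < spec.background_event_rate:
                _plant_qualifying_event(rec, rng, spec.event_mix)
            if rng.random() < spec.out_of_window_rate:
                _plant_out_of_window_event(rec, rng)
            rec.hospital_hours = float(np.exp(rng.normal(math.log(18.0), 0.8)))
        if died:
            rec.died = True
            if not episode:
                # Rare leak case (death risk exceeding episode risk): an
                # early ED death without critical-care services.
                rec.ed_disposition = "died_ed"
                rec.icu_days = 0
                rec.hospital_hours = float(rng.uniform(0.5, 6.0))
        cohort.append(rec)
    return cohort


def _plant_qualifying_event(rec: PatientRecord, rng: np.random.Generator,
                            event_mix: dict) -> None:
    """Plant one in-window trauma-center resource event on ``rec``."""
    mix = dict(event_mix)
    if rec.age_years > 5:
        # Anesthesia/ventilation only qualifies at age <= 5.
        mix.pop("anesthesia_le5", None)
    names = list(mix)
    probs = np.array([mix[n] for n in names], dtype=float)
    probs /= probs.sum()
    event = names[int(rng.choice(len(names), p=probs))]
    if event == "transfusion":
        rec.transfusion_hours = float(rng.uniform(0.0, 4.0))
    elif event == "urgent_procedure":
        ptype = PROCEDURE_TYPES[int(rng.integers(len(PROCEDURE_TYPES)))]
        rec.procedures.append((ptype, float(rng.uniform(0.0, 72.0))))
    elif event == "anesthesia_le5":
        if rng.random() < 0.5:
            rec.anesthesia = True
        else:
            rec.mech_vent = True
    elif event == "icu":
        if rng.random() < 0.6:
            rec.ed_disposition = "admit_icu"
            rec.icu_days = max(rec.icu_days, 1 + int(rng.integers(0, 3)))
        else:
            rec.icu_days = 3 + int(rng.integers(0, 5))
    elif event == "abuse":
        rec.abuse_flag = True
        rec.mechanism = "abuse"


def _plant_out_of_window_event(rec: PatientRecord, rng: np.random.Generator) -> None:
    """Plant an event whose timestamp disqualifies it (exercises filters)."""
    if rng.random() < 0.5:
        rec.transfusion_hours = float(rng.uniform(4.5, 24.0))
    else:
        ptype = PROCEDURE_TYPES[int(rng.integers(len(PROCEDURE_TYPES)))]
        rec.procedures.append((ptype, float(rng.uniform(72.5, 168.0))))
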