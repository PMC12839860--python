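"""Study orchestration: inclusion, temporal derive/apply split, outputs.

:func:`run_study` executes the full analysis — derive per-code risk ratios
on the derivation years, apply them to the held-out application year,
classify trauma-center resource need, and evaluate discrimination — and
writes all artifacts (score table, patient scores, NFPTCR classifications,
descriptive and threshold tables, AUC comparisons, run manifest) to an
output directory.  Re-running with an identical config and seed reproduces
the outputs byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import (compare_auc, describe_cohort, plot_roc, roc_auc,
                         sens_spec_at, threshold_table)
from .nfptcr import classify_cohort, nfptcr_prevalence, write_nfptcr_csv
from .records import (PatientRecord, read_cohort_csv, read_vocabulary_csv,
                      write_cohort_csv, write_vocabulary_csv)
from .scores import CritCareRule, DiagnosisRiskModel
from .synthetic import CohortSpec, generate_cohort, generate_vocabulary

log = logging.getLogger("pedtriage")


@dataclass
class RunConfig:
    """Configuration of one derive -> apply -> classify -> evaluate run."""

    derivation_years: Sequence[int] = (2014, 2015, 2016, 2017, 2018)
    application_year: int = 2019
    max_age_years: int = 15
    require_iss: bool = True
    unseen_policy: str = "neutral"
    min_count: int = 1
    iciss_variant: str = "product"
    critcare_rule: dict = field(default_factory=lambda: CritCareRule().to_dict())
    thresholds: Sequence[float] = (5.0, 10.0, 15.0, 20.0)
    threshold_mode: str = "strict_greater"
    seed: int = 0
    outdir: str = "pedtriage_run"
    # simulation settings (used when no cohort file is supplied)
    n_patients: int = 20000
    n_codes: int = 500

    def __post_init__(self):
        if self.application_year in tuple(self.derivation_years):
            raise ValueError(
                f"application_year {self.application_year} must not be among "
                f"derivation_years {list(self.derivation_years)}")
        if self.max_age_years < 0:
            raise ValueError("max_age_years must be >= 0")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load a config from YAML or JSON (same schema as the dataclass)."""
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["derivation_years"] = list(self.derivation_years)
        d["thresholds"] = list(self.thresholds)
        return d


def apply_inclusion(cohort: Sequence[PatientRecord],
                    config: RunConfig) -> tuple[list[PatientRecord], list[tuple[str, str]]]:
    """Apply the study inclusion rules.

    Retains records with ``age_years <= max_age_years`` and, when
    ``require_iss`` is set, a computable ISS (non-empty AIS profile).  The
    exclusion log lists ``(patient_id, reason)`` pairs with reasons ``age``
    or ``missing_iss``.
    """
    included: list[PatientRecord] = []
    excluded: list[tuple[str, str]] = []
    for rec in cohort:
        if rec.age_years > config.max_age_years:
            excluded.append((rec.patient_id, "age"))
        elif config.require_iss and not rec.ais_profile:
            excluded.append((rec.patient_id, "missing_iss"))
        else:
            included.append(rec)
    return included, excluded


def simulate_inputs(config: RunConfig):
    """Generate a vocabulary and cohort spanning all study years."""
    vocab = generate_vocabulary(config.n_codes, seed=config.seed)
    spec = CohortSpec(
        n_patients=config.n_patients,
        years=sorted(set(config.derivation_years) | {config.application_year}),
        seed=config.seed + 1,
        n_codes=config.n_codes,
    )
    return vocab, generate_cohort(spec, vocab)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_study(config: RunConfig,
              cohort: Sequence[PatientRecord] | None = None,
              cohort_path=None, plot: bool = False) -> dict:
    """Run the full study and write artifacts under ``config.outdir``.

    The cohort may be passed in memory, loaded from ``cohort_path``, or (if
    neither is given) simulated from the config's generator settings.
    Returns a manifest dict (also written as ``manifest.json``) with the
    headline numbers: counts, NFPTCR prevalence, AUCs and their pairwise
    comparisons.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if cohort is None and cohort_path is not None:
        cohort = read_cohort_csv(cohort_path)
    simulated = cohort is None
    if simulated:
        vocab, cohort = simulate_inputs(config)
        write_vocabulary_csv(vocab, outdir / "vocabulary.csv")
        write_cohort_csv(cohort, outdir / "cohort.csv")
    n_input = len(cohort)
    log.info("input cohort: %d patients", n_input)

    included, excluded = apply_inclusion(cohort, config)
    pd.DataFrame(excluded, columns=["patient_id", "reason"]).to_csv(
        outdir / "exclusions.csv", index=False)
    log.info("included %d, excluded %d", len(included), len(excluded))

    deriv = [r for r in included if r.year in tuple(config.derivation_years)]
    appl = [r for r in included if r.year == config.application_year]
    if not deriv:
        raise ValueError("no derivation patients after inclusion/split")
    if not appl:
        raise ValueError("no application patients after inclusion/split")

    rule = CritCareRule(**config.critcare_rule)
    results = DiagnosisRiskModel(deriv, rule, config.min_count).fit()
    results.to_csv(outdir / "score_table.csv", outdir / "score_table_meta.json")

    scores = results.apply(appl, config.unseen_policy, config.iciss_variant)
    scores.to_csv(outdir / "patient_scores.csv", index=False)

    nf = classify_cohort(appl)
    write_nfptcr_csv(nf, outdir / "nfptcr.csv")
    n_pos, prevalence = nfptcr_prevalence(nf)
    labels = np.array([r.positive for r in nf])

    score_sets = {"iss": scores["iss"].to_numpy(dtype=float),
                  "iciss": scores["iciss_scaled"].to_numpy(dtype=float),
                  "icass": scores["icass"].to_numpy(dtype=float)}
    rocs = {name: roc_auc(s, labels, metric_name=name)
            for name, s in score_sets.items()}
    pd.concat([r.points.assign(metric=name)[["metric", "threshold",
                                             "sensitivity", "specificity"]]
               for name, r in rocs.items()]).to_csv(outdir / "roc.csv",
                                                    index=False)

    comparisons = []
    for a, b in (("icass", "iss"), ("icass", "iciss"), ("iciss", "iss")):
        c = compare_auc(score_sets[a], score_sets[b], labels, a, b)
        comparisons.append({
            "metric_a": a, "metric_b": b, "auc_diff": c.auc_diff,
            "statistic": None if math.isnan(c.statistic) else c.statistic,
            "p_value": c.p_value,
        })
    auc_json = {
        name: {"auc": r.auc, "ci": list(r.auc_ci), "se": r.auc_se,
               "n_pos": r.n_pos, "n_neg": r.n_neg}
        for name, r in rocs.items()
    }
    auc_json["comparisons"] = comparisons
    with open(outdir / "auc.json", "w") as fh:
        json.dump(auc_json, fh, indent=2, sort_keys=True)

    tt = threshold_table(score_sets, labels, config.thresholds,
                         mode=config.threshold_mode)
    tt.to_csv(outdir / "threshold_table.csv", index=False,
              float_format="%.6g")

    table2 = describe_cohort(appl, nf, scores)
    table2.to_csv(outdir / "table2.csv", index=False, float_format="%.6g")

    if plot:
        plot_roc(list(rocs.values()), outdir / "roc.svg")

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "simulated": simulated,
        "n_input": n_input,
        "n_included": len(included),
        "n_excluded": len(excluded),
        "n_derivation": len(deriv),
        "n_application": len(appl),
        "n_codes_in_table": int(len(results.table)),
        "nfptcr_positive": n_pos,
        "nfptcr_prevalence": prevalence,
        "auc": {name: rocs[name].auc for name in rocs},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("NFPTCR prevalence %.1f%%; AUCs %s", 100 * prevalence,
             {k: round(v, 3) for k, v in manifest["auc"].items()})
    return manifest
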