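"""Table schemas, configuration, and end-to-end orchestration.

Interchange format is delimited text (comma or tab, auto-detected on
read): a long-format isotopologue table (patient_id, fragment_id,
tissue_class, metabolite, mass_shift, value), a clinical table
(patient_id, os_months, os_event, rfs_months, rfs_event, free covariate
columns), and wide metrics/result tables.  Missing values are empty
fields on write; empty and "NA" are accepted on read.

``run_pipeline`` chains the stages: (simulate or load) -> score ->
median dichotomization -> Kaplan-Meier / log-rank / Cox per endpoint ->
report, with every artifact stamped with the seed, a config hash, and
the package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import tcatrace
from tcatrace import cohort_stats, metrics as metrics_mod
from tcatrace.cohort_stats import Endpoint, SurvivalRecord
from tcatrace.isocorrect import (
    DEFAULT_FRAGMENTS,
    MID,
    build_correction_matrix,
    correct_mid,
    read_formula_table,
)
from tcatrace.metrics import TissueClass, TissueSample

__all__ = [
    "PatientRecord",
    "StudyConfig",
    "read_isotopologue_table",
    "write_isotopologue_table",
    "read_clinical_table",
    "write_clinical_table",
    "correct_raw_table",
    "run_pipeline",
]

log = logging.getLogger(__name__)

ISOTOPOLOGUE_COLUMNS = (
    "patient_id",
    "fragment_id",
    "tissue_class",
    "metabolite",
    "mass_shift",
    "value",
)

#: per-metabolite fraction sums outside this window are rejected
SUM_WINDOW = (0.98, 1.02)


@dataclass
class PatientRecord:
    """Clinical outcomes and covariates for one patient (times in months)."""

    patient_id: str
    os_months: float | None = None
    os_event: bool | None = None
    rfs_months: float | None = None
    rfs_event: bool | None = None
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("os_months", "rfs_months"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{self.patient_id}: {name} must be > 0")

    def survival_record(self, endpoint: Endpoint) -> SurvivalRecord | None:
        if endpoint == Endpoint.OVERALL:
            t, e = self.os_months, self.os_event
        else:
            t, e = self.rfs_months, self.rfs_event
        if t is None or e is None:
            return None
        return SurvivalRecord(self.patient_id, t, bool(e), endpoint)


# ---------------------------------------------------------------------------
# Isotopologue tables


def read_isotopologue_table(path) -> list[TissueSample]:
    """Read and validate a long-format isotopologue table into samples.

    Per (fragment, metabolite) the fractions must be contiguous in
    mass_shift from 0 and sum within [0.98, 1.02] (then renormalized);
    violations are rejected with the offending rows named.  Tissue glucose
    M+6 is taken from each fragment's glucose MID (0 when absent).
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = set(ISOTOPOLOGUE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"isotopologue table missing columns: {sorted(missing)}")
    if (df["value"] < 0).any():
        bad = df.index[df["value"] < 0].tolist()
        raise ValueError(f"negative isotopologue values at rows {bad}")
    dup = df.duplicated(subset=["fragment_id", "metabolite", "mass_shift"])
    if dup.any():
        raise ValueError(
            f"duplicate (fragment, metabolite, mass_shift) at rows "
            f"{df.index[dup].tolist()}"
        )

    samples: list[TissueSample] = []
    for (pid, fid, tclass), frag in df.groupby(
        ["patient_id", "fragment_id", "tissue_class"], sort=False
    ):
        mids: dict[str, MID] = {}
        for met, grp in frag.groupby("metabolite", sort=False):
            grp = grp.sort_values("mass_shift")
            shifts = grp["mass_shift"].to_numpy()
            if not np.array_equal(shifts, np.arange(len(shifts))):
                raise ValueError(
                    f"{fid}/{met}: mass shifts not contiguous from 0 "
                    f"(rows {grp.index.tolist()})"
                )
            fr = grp["value"].to_numpy(dtype=float)
            s = fr.sum()
            if not (SUM_WINDOW[0] <= s <= SUM_WINDOW[1]):
                raise ValueError(
                    f"{fid}/{met}: fractions sum to {s:.4f}, outside "
                    f"[{SUM_WINDOW[0]}, {SUM_WINDOW[1]}] (rows {grp.index.tolist()})"
                )
            mids[str(met)] = MID(str(met), len(fr) - 1, fr / s)
        glucose_m6 = mids["glucose"][6] if "glucose" in mids else 0.0
        samples.append(
            TissueSample(str(pid), str(fid), TissueClass(str(tclass)), mids,
                         glucose_m6)
        )
    return samples


def write_isotopologue_table(samples: list[TissueSample], path) -> None:
    rows = [
        {
            "patient_id": s.patient_id,
            "fragment_id": s.fragment_id,
            "tissue_class": s.tissue_class.value,
            "metabolite": met,
            "mass_shift": k,
            "value": v,
        }
        for s in samples
        for met, mid in sorted(s.mids.items())
        for k, v in enumerate(mid.fractions)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Clinical tables


def read_clinical_table(path) -> list[PatientRecord]:
    """Read a clinical table; unknown covariate columns are preserved."""
    df = pd.read_csv(path, sep=None, engine="python", na_values=["", "NA"])
    if "patient_id" not in df.columns:
        raise ValueError("clinical table missing patient_id column")
    known = {"patient_id", "os_months", "os_event", "rfs_months", "rfs_event"}
    records = []
    for idx, row in df.iterrows():
        def get_time(col):
            v = row.get(col)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                return None
            v = float(v)
            if v <= 0:
                raise ValueError(f"row {idx}: {col}={v} must be > 0")
            return v

        def get_event(col):
            v = row.get(col)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                return None
            return bool(int(v))

        covs = {
            c: row[c]
            for c in df.columns
            if c not in known and not pd.isna(row[c])
        }
        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                os_months=get_time("os_months"),
                os_event=get_event("os_event"),
                rfs_months=get_time("rfs_months"),
                rfs_event=get_event("rfs_event"),
                covariates=covs,
            )
        )
    return records


def write_clinical_table(records: list[PatientRecord], path) -> None:
    rows = []
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "os_months": r.os_months,
            "os_event": int(r.os_event) if r.os_event is not None else None,
            "rfs_months": r.rfs_months,
            "rfs_event": int(r.rfs_event) if r.rfs_event is not None else None,
        }
        row.update(r.covariates)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Raw-intensity correction stage


def correct_raw_table(raw_path, out_path, formula_path=None) -> pd.DataFrame:
    """Correct a long-format raw-intensity table for natural abundance.

    Input columns: sample_id, metabolite, mass_shift, value (raw
    intensities; channels contiguous from 0).  Output: same layout with
    corrected MID fractions.
    """
    df = pd.read_csv(raw_path, sep=None, engine="python")
    required = {"sample_id", "metabolite", "mass_shift", "value"}
    if required - set(df.columns):
        raise ValueError(f"raw table missing columns: {sorted(required - set(df.columns))}")
    formulas = read_formula_table(formula_path) if formula_path else DEFAULT_FRAGMENTS
    matrices = {}
    rows = []
    for (sid, met), grp in df.groupby(["sample_id", "metabolite"], sort=False):
        if met not in formulas:
            raise ValueError(f"no fragment formula for metabolite {met!r}")
        grp = grp.sort_values("mass_shift")
        raw = grp["value"].to_numpy(dtype=float)
        if met not in matrices:
            matrices[met] = build_correction_matrix(formulas[met],
                                                    m_channels=len(raw))
        mid = correct_mid(raw, matrices[met])
        rows += [
            {"sample_id": sid, "metabolite": met, "mass_shift": k, "value": v}
            for k, v in enumerate(mid.fractions)
        ]
    out = pd.DataFrame(rows)
    out.to_csv(out_path, index=False)
    return out


# ---------------------------------------------------------------------------
# Study configuration and orchestration


@dataclass
class StudyConfig:
    """Configuration of one analysis run (parsed from YAML)."""

    out_dir: str = "tcatrace_out"
    seed: int = 0
    isotopologue_table: str | None = None
    clinical_table: str | None = None
    formula_table: str | None = None
    metric: str = "tca_total_score"  # or tca_m2_score
    endpoints: tuple[str, ...] = ("os", "rfs")
    simulation: dict | None = None  # CohortSimConfig overrides

    @staticmethod
    def from_yaml(path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = StudyConfig(**data)
        if cfg.isotopologue_table is None and cfg.simulation is None:
            raise ValueError(
                "config must provide an isotopologue_table or a simulation block"
            )
        return cfg

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


_ENDPOINT_MAP = {"os": Endpoint.OVERALL, "rfs": Endpoint.RECURRENCE_FREE}


def _km_payload(curve) -> dict:
    return {
        "event_times": [float(t) for t in curve.event_times],
        "survival_probs": [float(s) for s in curve.survival_probs],
        "at_risk": [int(n) for n in curve.at_risk],
    }


def run_pipeline(cfg: StudyConfig) -> dict:
    """Execute the full analysis and write all artifacts to ``out_dir``.

    Stages: load or simulate the study -> per-fragment metrics ->
    patient-level collapse -> median dichotomization on the configured
    metric -> KM curves, log-rank, and univariate Cox per endpoint.
    Returns the machine-readable run summary (also written as
    ``summary.json``).  Reruns with the same config are bit-identical.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        if cfg.simulation is not None:
            stage = "simulate"
            from tcatrace.tca_sim import CohortSimConfig

            sim_kwargs = dict(cfg.simulation)
            group_hr = sim_kwargs.pop("group_hr", None)
            sim_kwargs.setdefault("seed", cfg.seed)
            sim_cfg = CohortSimConfig(**sim_kwargs)
            if group_hr is not None:
                sim_cfg = sim_cfg.with_group_hr(group_hr)
            from tcatrace.tca_sim import generate_cohort

            samples, records = generate_cohort(sim_cfg)
            write_isotopologue_table(samples, out / "isotopologues.csv")
            write_clinical_table(records, out / "clinical.csv")
            iso_path = out / "isotopologues.csv"
            clin_path = out / "clinical.csv"
        else:
            iso_path = cfg.isotopologue_table
            clin_path = cfg.clinical_table

        stage = "read"
        samples = read_isotopologue_table(iso_path)
        records = read_clinical_table(clin_path) if clin_path else []

        stage = "score"
        per_fragment = metrics_mod.metrics_table(
            [metrics_mod.compute_sample_metrics(s) for s in samples
             if s.tissue_class == TissueClass.TUMOR]
        )
        per_fragment.to_csv(out / "metrics_fragments.csv", index=False)
        per_patient = metrics_mod.collapse_to_patients(per_fragment)
        per_patient.to_csv(out / "metrics_patients.csv", index=False)

        class_counts = (
            pd.Series([s.tissue_class.value for s in samples])
            .value_counts()
            .to_dict()
        )
        tumor_patients = {s.patient_id for s in samples
                          if s.tissue_class == TissueClass.TUMOR}
        lung_patients = {s.patient_id for s in samples
                         if s.tissue_class == TissueClass.ADJACENT_LUNG}
        n_matched_pairs = len(tumor_patients & lung_patients)

        summary: dict = {
            "version": tcatrace.__version__,
            "seed": cfg.seed,
            "config_digest": cfg.digest(),
            "metric": cfg.metric,
            "n_patients": int(per_patient.shape[0]),
            "n_fragments": int(per_fragment.shape[0]),
            "tissue_class_counts": class_counts,
            "n_matched_tumor_lung_pairs": n_matched_pairs,
            "endpoints": {},
        }

        if records:
            stage = "stratify"
            values = dict(
                zip(per_patient["patient_id"], per_patient[cfg.metric])
            )
            groups = metrics_mod.dichotomize_by_median(values, cfg.metric)
            group_of = {g.patient_id: g.group for g in groups}
            pd.DataFrame(
                [{"patient_id": g.patient_id, "group": g.group,
                  "metric": g.metric_name, "cohort_median": g.cohort_median}
                 for g in groups]
            ).to_csv(out / "groups.csv", index=False)

            stage = "survival"
            for ep_name in cfg.endpoints:
                endpoint = _ENDPOINT_MAP[ep_name]
                recs = [
                    r.survival_record(endpoint)
                    for r in records
                    if r.survival_record(endpoint) is not None
                ]
                high = [r for r in recs if group_of.get(r.patient_id) == "high"]
                low = [r for r in recs if group_of.get(r.patient_id) == "low"]
                if not high or not low:
                    summary["endpoints"][ep_name] = {"error": "empty group"}
                    continue
                chi2, p_logrank = cohort_stats.logrank_test(high, low)
                cox = cohort_stats.cox_binary(recs, groups)
                summary["endpoints"][ep_name] = {
                    "n_high": len(high),
                    "n_low": len(low),
                    "n_events": cox.n_events,
                    "logrank_chi2": chi2,
                    "logrank_p": p_logrank,
                    "hazard_ratio": cox.hazard_ratio,
                    "hr_ci95": list(cox.ci95),
                    "cox_wald_p": cox.wald_p,
                    "km_high": _km_payload(cohort_stats.km_fit(high)),
                    "km_low": _km_payload(cohort_stats.km_fit(low)),
                }
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    log.info("pipeline complete: %s", out / "summary.json")
    return summary
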