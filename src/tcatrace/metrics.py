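"""Per-sample TCA-cycle labeling scores and cohort dichotomization.

All scores are built from natural-abundance-corrected MIDs and the tissue
glucose M+6 enrichment of the same sample.  Two scores drive the survival
stratification:

- the *total* TCA score: sum of (1 - M+0) over citrate, glutamate and
  malate, divided by tissue glucose M+6;
- the *M+2* TCA score: mean of M+2/glucose-M+6 over the same three
  metabolites (M+2 is the signature of glucose-derived acetyl-CoA entering
  the cycle via pyruvate dehydrogenase).

Aspartate is read as a TCA-cycle reporter in correlation analyses but is
deliberately excluded from the dichotomizing scores.  Undefined metrics
(e.g. glucose M+6 of zero) propagate as missing (NaN), never as zero.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from tcatrace.isocorrect import MID, labeled_fraction

__all__ = [
    "TissueClass",
    "TissueSample",
    "SampleMetrics",
    "GroupLabel",
    "TCA_SCORE_METABOLITES",
    "normalized_isotopologue",
    "tca_total_score",
    "tca_m2_score",
    "pc_index",
    "relative_to_lung",
    "compute_sample_metrics",
    "metrics_table",
    "collapse_to_patients",
    "dichotomize_by_median",
]

log = logging.getLogger(__name__)

#: Metabolites entering the dichotomizing TCA scores.
TCA_SCORE_METABOLITES = ("citrate", "glutamate", "malate")

#: Metabolites entering pairwise labeling correlations (adds aspartate).
TCA_CORRELATION_METABOLITES = ("citrate", "glutamate", "malate", "aspartate")

GLYCOLYTIC_M3_METABOLITES = ("3pg", "pyruvate", "lactate")


class TissueClass(str, Enum):
    TUMOR = "tumor"
    ADJACENT_LUNG = "adjacent_lung"
    BENIGN = "benign"
    METASTASIS = "metastasis"
    MOUSE_TUMOR = "mouse_tumor"
    MOUSE_LUNG = "mouse_lung"


@dataclass
class TissueSample:
    """One tissue fragment: corrected MIDs, tissue glucose M+6 enrichment,
    tissue class, and the patient it came from."""

    patient_id: str
    fragment_id: str
    tissue_class: TissueClass
    mids: dict[str, MID]
    glucose_m6: float
    abundances: dict[str, float] | None = None

    def __post_init__(self) -> None:
        self.tissue_class = TissueClass(self.tissue_class)
        if not (0.0 <= self.glucose_m6 <= 1.0):
            raise ValueError(
                f"{self.fragment_id}: glucose_m6={self.glucose_m6} outside [0, 1]"
            )


@dataclass
class SampleMetrics:
    """Derived labeling scores for one tissue fragment."""

    patient_id: str
    fragment_id: str
    tca_total_score: float
    tca_m2_score: float
    per_metabolite_m2_norm: dict[str, float] = field(default_factory=dict)
    pc_index: dict[str, float] = field(default_factory=dict)
    glycolytic_m3_norm: dict[str, float] = field(default_factory=dict)
    lung_ratio: dict[str, float] | None = None


@dataclass(frozen=True)
class GroupLabel:
    """Median dichotomization assignment for one patient."""

    patient_id: str
    group: str  # "high" | "low"
    metric_name: str
    cohort_median: float

    def __post_init__(self) -> None:
        if self.group not in ("high", "low"):
            raise ValueError(f"group must be 'high' or 'low', got {self.group!r}")


def normalized_isotopologue(s: TissueSample, metabolite: str, k: int) -> float:
    """Fractional M+k enrichment normalized to tissue glucose M+6.

    Returns NaN (missing) when the metabolite is absent or glucose M+6 is
    zero — an undefined ratio is never reported as zero enrichment.
    """
    if metabolite not in s.mids:
        log.debug("%s: metabolite %s absent", s.fragment_id, metabolite)
        return math.nan
    if s.glucose_m6 <= 0:
        log.debug("%s: glucose_m6 is zero, metric undefined", s.fragment_id)
        return math.nan
    return s.mids[metabolite][k] / s.glucose_m6


def tca_total_score(s: TissueSample) -> float:
    """Summed total labeling of citrate, glutamate and malate, i.e.
    sum of (1 - M+0), normalized to tissue glucose M+6."""
    if s.glucose_m6 <= 0:
        log.info("%s: glucose_m6 is zero, tca_total_score missing", s.fragment_id)
        return math.nan
    total = 0.0
    for met in TCA_SCORE_METABOLITES:
        if met not in s.mids:
            log.info("%s: %s missing, tca_total_score missing", s.fragment_id, met)
            return math.nan
        total += labeled_fraction(s.mids[met])
    return total / s.glucose_m6


def tca_m2_score(s: TissueSample) -> float:
    """Mean M+2/glucose-M+6 over citrate, glutamate and malate."""
    vals = []
    for met in TCA_SCORE_METABOLITES:
        v = normalized_isotopologue(s, met, 2)
        if math.isnan(v):
            log.info("%s: %s M+2 ratio missing, tca_m2_score missing",
                     s.fragment_id, met)
            return math.nan
        vals.append(v)
    return float(np.mean(vals))


def pc_index(s: TissueSample, metabolite: str) -> float:
    """Pyruvate-carboxylase signature: metabolite M+3 over pyruvate M+3.

    M+3 in four-carbon TCA intermediates arises from carboxylation of
    fully labeled pyruvate; normalizing to pyruvate M+3 removes the
    upstream glycolytic labeling."""
    if "pyruvate" not in s.mids or metabolite not in s.mids:
        return math.nan
    pyr_m3 = s.mids["pyruvate"][3]
    if pyr_m3 <= 0:
        log.debug("%s: pyruvate M+3 is zero, pc_index undefined", s.fragment_id)
        return math.nan
    return s.mids[metabolite][3] / pyr_m3


def relative_to_lung(tumor: TissueSample, lung: TissueSample, metabolite: str) -> float:
    """Lesion-over-adjacent-lung ratio of total enrichment (1 - M+0) for
    one metabolite, from the same patient."""
    if tumor.patient_id != lung.patient_id:
        raise ValueError(
            f"patient mismatch: {tumor.patient_id} vs {lung.patient_id}"
        )
    if metabolite not in tumor.mids or metabolite not in lung.mids:
        return math.nan
    denom = labeled_fraction(lung.mids[metabolite])
    if denom <= 0:
        log.debug("%s: lung %s unlabeled, ratio undefined",
                  lung.fragment_id, metabolite)
        return math.nan
    return labeled_fraction(tumor.mids[metabolite]) / denom


def compute_sample_metrics(
    s: TissueSample, lung: TissueSample | None = None
) -> SampleMetrics:
    """All labeling scores for one fragment; lung ratios if a matched
    adjacent-lung fragment is supplied."""
    lung_ratio = None
    if lung is not None:
        lung_ratio = {
            met: relative_to_lung(s, lung, met)
            for met in sorted(set(s.mids) & set(lung.mids))
        }
    return SampleMetrics(
        patient_id=s.patient_id,
        fragment_id=s.fragment_id,
        tca_total_score=tca_total_score(s),
        tca_m2_score=tca_m2_score(s),
        per_metabolite_m2_norm={
            met: normalized_isotopologue(s, met, 2)
            for met in TCA_CORRELATION_METABOLITES
        },
        pc_index={
            met: pc_index(s, met) for met in ("citrate", "malate", "aspartate")
        },
        glycolytic_m3_norm={
            met: normalized_isotopologue(s, met, 3)
            for met in GLYCOLYTIC_M3_METABOLITES
            if met in s.mids
        },
        lung_ratio=lung_ratio,
    )


def metrics_table(metrics: list[SampleMetrics]) -> pd.DataFrame:
    """Flatten SampleMetrics into one row per fragment (missing = NaN,
    written as empty fields)."""
    rows = []
    for m in metrics:
        row: dict[str, object] = {
            "patient_id": m.patient_id,
            "fragment_id": m.fragment_id,
            "tca_total_score": m.tca_total_score,
            "tca_m2_score": m.tca_m2_score,
        }
        row.update({f"m2_norm_{k}": v for k, v in m.per_metabolite_m2_norm.items()})
        row.update({f"pc_index_{k}": v for k, v in m.pc_index.items()})
        row.update({f"m3_norm_{k}": v for k, v in m.glycolytic_m3_norm.items()})
        if m.lung_ratio:
            row.update({f"lung_ratio_{k}": v for k, v in m.lung_ratio.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def collapse_to_patients(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse fragment-level metrics to one row per patient by averaging
    (the same convention applied to multi-fragment expression data)."""
    numeric = table.drop(columns=["fragment_id"], errors="ignore")
    return numeric.groupby("patient_id", sort=True).mean(numeric_only=True).reset_index()


def dichotomize_by_median(
    values: dict[str, float], metric_name: str
) -> list[GroupLabel]:
    """Split patients into "high"/"low" at the cohort median of a score.

    A patient is "high" iff strictly above the median; values exactly at
    the median go to "low".  Missing (NaN) values are excluded and
    reported; fewer than 4 usable values is an error.
    """
    usable = {pid: v for pid, v in values.items() if v is not None and not math.isnan(v)}
    dropped = sorted(set(values) - set(usable))
    if dropped:
        log.info("dichotomize_by_median(%s): excluded %d patients with "
                 "missing values: %s", metric_name, len(dropped), dropped)
    if len(usable) < 4:
        raise ValueError(
            f"dichotomize_by_median({metric_name}): need >= 4 non-missing "
            f"values, got {len(usable)}"
        )
    med = float(np.median(list(usable.values())))
    labels = [
        GroupLabel(pid, "high" if v > med else "low", metric_name, med)
        for pid, v in usable.items()
    ]
    if all(lab.group == "low" for lab in labels):
        warnings.warn(
            f"dichotomize_by_median({metric_name}): no value exceeds the "
            "median (constant score?); all patients assigned 'low'",
            stacklevel=2,
        )
    return labels
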