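"""Cohort statistics: paired tests, correlation matrices with multiplicity
control, survival estimation, and stratified survival comparison.

Survival estimation and Cox regression are delegated to ``lifelines``
(Kaplan–Meier product-limit estimator, Mantel–Cox log-rank test, Cox
partial likelihood with Breslow tie handling) behind thin result types.
The Wilcoxon signed-rank test, Holm–Šidák adjustment, Dunn's post hoc
test and the automatic parametric/nonparametric test selector are
implemented here.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from statsmodels.stats.multitest import multipletests

from tcatrace.metrics import GroupLabel

__all__ = [
    "SurvivalRecord",
    "KMCurve",
    "CoxResult",
    "CorrMatrixResult",
    "Endpoint",
    "km_fit",
    "logrank_test",
    "cox_binary",
    "spearman_matrix",
    "wilcoxon_signed_rank",
    "holm_sidak_adjust",
    "kruskal_wallis_dunn",
    "auto_select_test",
    "metabolite_survival_screen",
]

log = logging.getLogger(__name__)

ALPHA = 0.05  # confidence level fixed at 95% throughout


class Endpoint(str, Enum):
    OVERALL = "overall"
    RECURRENCE_FREE = "recurrence_free"


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient's follow-up for one endpoint; censoring is encoded
    solely by ``event=False``."""

    patient_id: str
    time: float  # months
    event: bool
    endpoint: Endpoint = Endpoint.OVERALL

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ValueError(f"{self.patient_id}: survival time must be > 0")


@dataclass(frozen=True)
class KMCurve:
    event_times: np.ndarray
    survival_probs: np.ndarray
    at_risk: np.ndarray


@dataclass(frozen=True)
class CoxResult:
    hazard_ratio: float
    ci95: tuple[float, float]
    wald_p: float
    n_events: int
    reference_group: str = "low"
    infinite_bound: bool = False


@dataclass(frozen=True)
class CorrMatrixResult:
    pairs: list[tuple[str, str]]
    rho: np.ndarray
    p_raw: np.ndarray
    p_adjusted: np.ndarray


# ---------------------------------------------------------------------------
# Survival machinery


def _to_arrays(records: list[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    t = np.array([r.time for r in records], dtype=float)
    e = np.array([r.event for r in records], dtype=bool)
    return t, e


def km_fit(records: list[SurvivalRecord]) -> KMCurve:
    """Kaplan–Meier product-limit estimate of the survival function."""
    if not records:
        raise ValueError("km_fit requires at least one record")
    t, e = _to_arrays(records)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    tbl = kmf.event_table.iloc[1:] if kmf.event_table.index[0] == 0 else kmf.event_table
    times = tbl.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    at_risk = tbl["at_risk"].to_numpy(dtype=int)
    return KMCurve(times, surv, at_risk)


def logrank_test(
    group_a: list[SurvivalRecord], group_b: list[SurvivalRecord]
) -> tuple[float, float]:
    """Mantel–Cox log-rank test between two groups; returns (chi2, p)."""
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    ta, ea = _to_arrays(group_a)
    tb, eb = _to_arrays(group_b)
    if ea.sum() + eb.sum() == 0:
        warnings.warn("log-rank undefined with zero events", stacklevel=2)
        return math.nan, math.nan
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def cox_binary(
    records: list[SurvivalRecord], groups: list[GroupLabel]
) -> CoxResult:
    """Univariate Cox proportional-hazards fit on a binary high/low group.

    The low group is the reference, so HR > 1 means the high-labeling
    group fares worse.  Ties are handled by Breslow's method (lifelines
    default).  If one group has no events the partial likelihood is
    monotone; the result is flagged ``infinite_bound`` instead of raising.
    """
    group_of = {g.patient_id: g.group for g in groups}
    recs = [r for r in records if r.patient_id in group_of]
    if len({g.group for g in groups}) != 2:
        raise ValueError("cox_binary requires both 'high' and 'low' groups")
    df = pd.DataFrame(
        {
            "time": [r.time for r in recs],
            "event": [int(r.event) for r in recs],
            "high": [int(group_of[r.patient_id] == "high") for r in recs],
        }
    )
    n_events = int(df["event"].sum())
    if n_events < 2:
        raise ValueError("cox_binary requires at least 2 events")
    events_by_group = df.groupby("high")["event"].sum()
    if (events_by_group == 0).any():
        warnings.warn(
            "no events in one group: hazard ratio unbounded", stacklevel=2
        )
        hr = math.inf if events_by_group.get(1, 0) > 0 else 0.0
        return CoxResult(hr, (0.0, math.inf), math.nan, n_events,
                         infinite_bound=True)
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event")
    beta = float(cph.params_["high"])
    lo, hi = cph.confidence_intervals_.loc["high"].to_numpy(dtype=float)
    return CoxResult(
        hazard_ratio=float(np.exp(beta)),
        ci95=(float(np.exp(lo)), float(np.exp(hi))),
        wald_p=float(cph.summary.loc["high", "p"]),
        n_events=n_events,
    )


# ---------------------------------------------------------------------------
# Correlation and multiplicity


def holm_sidak_adjust(p_values) -> np.ndarray:
    """Step-down Šidák adjustment.

    Sort ascending; adjusted_i = 1 - (1 - p_i)^(m - i); enforce
    monotonicity by running maximum; restore the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj = np.maximum.accumulate(adj)
    out = np.empty_like(adj)
    out[order] = np.minimum(adj, 1.0)
    return out


def spearman_matrix(
    metrics_table: pd.DataFrame, feature_list: list[str]
) -> CorrMatrixResult:
    """Pairwise Spearman correlations with Holm–Šidák adjustment over the
    family of pairs in this call.

    Uses pairwise-complete observations; a constant feature yields missing
    rho for its pairs.  Requires >= 4 complete pairs per comparison.
    """
    pairs = list(itertools.combinations(feature_list, 2))
    rho = np.full(len(pairs), math.nan)
    p_raw = np.full(len(pairs), math.nan)
    for i, (fa, fb) in enumerate(pairs):
        sub = metrics_table[[fa, fb]].dropna()
        if len(sub) < 4:
            log.info("spearman: %s vs %s has < 4 complete pairs", fa, fb)
            continue
        if sub[fa].nunique() < 2 or sub[fb].nunique() < 2:
            log.info("spearman: constant feature in (%s, %s)", fa, fb)
            continue
        r, p = stats.spearmanr(sub[fa], sub[fb])
        rho[i], p_raw[i] = r, p
    p_adj = np.full(len(pairs), math.nan)
    ok = ~np.isnan(p_raw)
    if ok.any():
        p_adj[ok] = holm_sidak_adjust(p_raw[ok])
    return CorrMatrixResult(pairs, rho, p_raw, p_adj)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


def _signed_rank_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for the signed-rank statistic by dynamic
    programming over all 2^n sign assignments (ranks may be half-integers
    from ties; everything is scaled by 2 to stay integral)."""
    r2 = np.rint(ranks * 2).astype(int)
    total = int(r2.sum())
    # dist[s] = number of sign assignments with doubled positive-rank sum s
    dist = np.zeros(total + 1, dtype=float)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(round(w_plus * 2))
    mean2 = total / 2.0
    dev = abs(w2 - mean2)
    support = np.arange(total + 1)
    p = dist[np.abs(support - mean2) >= dev - 1e-9].sum()
    return float(min(p, 1.0))


def wilcoxon_signed_rank(
    paired_a, paired_b, exact_threshold: int = 25
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; exact enumeration of sign assignments
    for n <= ``exact_threshold`` nonzero pairs, normal approximation with
    continuity and tie correction beyond.  Returns (W+, p).
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero", stacklevel=2)
        return 0.0, 1.0
    if n < 3:
        raise ValueError("need >= 3 nonzero paired differences")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_threshold:
        return w_plus, _signed_rank_exact_p(ranks, w_plus)
    mean = n * (n + 1) / 4.0
    # tie correction on the variance
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = (counts**3 - counts).sum() / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (abs(w_plus - mean) - 0.5) / math.sqrt(var)
    return w_plus, float(2 * stats.norm.sf(z))


# ---------------------------------------------------------------------------
# Kruskal–Wallis with Dunn's post hoc


def kruskal_wallis_dunn(
    groups: list, group_names: list[str] | None = None
) -> tuple[float, float, pd.DataFrame]:
    """Tie-corrected Kruskal–Wallis omnibus test plus Dunn's pairwise
    z-tests on pooled ranks, Holm–Šidák adjusted within this call.

    Returns (H, p_overall, pairwise table).
    """
    if len(groups) < 3:
        raise ValueError(
            "kruskal_wallis_dunn needs >= 3 groups; use a two-group test"
        )
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs >= 2 values")
    if group_names is None:
        group_names = [f"group{i}" for i in range(len(groups))]
    arrays = [np.asarray(g, dtype=float) for g in groups]
    h_stat, p_overall = stats.kruskal(*arrays)

    pooled = np.concatenate(arrays)
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    mean_ranks, sizes = [], []
    start = 0
    for arr in arrays:
        mean_ranks.append(ranks[start : start + arr.size].mean())
        sizes.append(arr.size)
        start += arr.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    for i, j in itertools.combinations(range(len(arrays)), 2):
        se = math.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        rows.append(
            {
                "group_a": group_names[i],
                "group_b": group_names[j],
                "z": z,
                "p_raw": 2 * stats.norm.sf(abs(z)),
            }
        )
    pairwise = pd.DataFrame(rows)
    pairwise["p_adjusted"] = holm_sidak_adjust(pairwise["p_raw"].to_numpy())
    return float(h_stat), float(p_overall), pairwise


# ---------------------------------------------------------------------------
# Automatic test selection


def _normality_p(x: np.ndarray) -> float:
    """Shapiro–Wilk for 3 <= n < 20, D'Agostino–Pearson omnibus for n >= 20."""
    if x.size < 20:
        return float(stats.shapiro(x).pvalue)
    return float(stats.normaltest(x).pvalue)


def auto_select_test(
    group_a, group_b, paired: bool = False
) -> tuple[str, float, bool]:
    """Choose and run a two-group test by the normality/variance decision
    tree.

    Normality is tested per group (Shapiro–Wilk when 3 <= n < 20,
    D'Agostino–Pearson when n >= 20; deviation at P < 0.01) and variance
    homogeneity by Levene's test (P < 0.05).  On failure the data are
    log2-transformed and retested; if the transform rescues normality and
    homogeneity a parametric test runs on the transformed data.  Normal
    but unequally variable data get Welch's t test.  Otherwise the
    nonparametric test (Mann–Whitney, or Wilcoxon signed-rank when
    paired) runs on the untransformed data.

    Returns (test_name, p, log2_transform_used).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs n >= 3")

    def assess(x: np.ndarray, y: np.ndarray) -> tuple[bool, bool]:
        normal = _normality_p(x) >= 0.01 and _normality_p(y) >= 0.01
        equal_var = stats.levene(x, y).pvalue >= 0.05
        return normal, equal_var

    def parametric(x, y, equal_var: bool) -> tuple[str, float]:
        if paired:
            return "paired_t", float(stats.ttest_rel(x, y).pvalue)
        if equal_var:
            return "student_t", float(stats.ttest_ind(x, y).pvalue)
        return "welch_t", float(stats.ttest_ind(x, y, equal_var=False).pvalue)

    normal, equal_var = assess(a, b)
    if normal and equal_var:
        name, p = parametric(a, b, equal_var=True)
        return name, p, False
    if normal and not equal_var and not paired:
        name, p = parametric(a, b, equal_var=False)
        return name, p, False

    if np.all(a > 0) and np.all(b > 0):
        la, lb = np.log2(a), np.log2(b)
        normal_t, equal_var_t = assess(la, lb)
        if normal_t and equal_var_t:
            name, p = parametric(la, lb, equal_var=True)
            return name, p, True
        if normal_t and not equal_var_t and not paired:
            name, p = parametric(la, lb, equal_var=False)
            return name, p, True
    else:
        log.info("auto_select_test: nonpositive values, log2 branch skipped")

    if paired:
        _, p = wilcoxon_signed_rank(a, b)
        return "wilcoxon", p, False
    p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return "mann_whitney", p, False


# ---------------------------------------------------------------------------
# Metabolomics survival screen


def metabolite_survival_screen(
    abundance_table: pd.DataFrame, survival_records: list[SurvivalRecord]
) -> pd.DataFrame:
    """Screen metabolite abundances against survival.

    Per-feature univariate Cox regression on log2 abundance (continuous
    covariate) with Benjamini–Hochberg control across features; the input
    table is patients x features on a positive scale.  Returns a table
    sorted by adjusted p.
    """
    surv = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in survival_records],
            "time": [r.time for r in survival_records],
            "event": [int(r.event) for r in survival_records],
        }
    ).set_index("patient_id")
    common = abundance_table.index.intersection(surv.index)
    if len(common) < 10:
        raise ValueError("survival screen requires >= 10 patients")
    rows = []
    for feat in abundance_table.columns:
        x = abundance_table.loc[common, feat].astype(float)
        if (x <= 0).any():
            raise ValueError(f"{feat}: abundances must be positive for log2")
        if x.nunique() < 2:
            log.info("survival screen: %s constant, skipped", feat)
            continue
        df = surv.loc[common].copy()
        df["log2_abundance"] = np.log2(x)
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="time", event_col="event")
        except Exception as exc:  # convergence failure on degenerate features
            log.info("survival screen: %s failed to fit (%s), skipped", feat, exc)
            continue
        rows.append(
            {
                "feature": feat,
                "hazard_ratio": float(np.exp(cph.params_["log2_abundance"])),
                "p_raw": float(cph.summary.loc["log2_abundance", "p"]),
            }
        )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = multipletests(out["p_raw"], method="fdr_bh")[1]
    return out.sort_values("p_adjusted", ignore_index=True)
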