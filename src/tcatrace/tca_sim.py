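"""Carbon-resolved steady-state simulator of [U-13C]glucose labeling in
the TCA cycle, with a forward measurement model and cohort generation.

The simulator tracks *positional* isotopomers — probability distributions
over binary label strings, one bit per backbone carbon — because two
features of the labeling data cannot be captured at the isotopologue
level: loss of specific carbons as CO2 at the two oxidative
decarboxylations, and the two-fold rotational symmetry of succinate,
which scrambles label between the carboxyl (and between the methylene)
carbons of the four-carbon pool.

Per turn of the cycle the atom map is:

1. acetyl-CoA is [1,2-13C] (both carbons labeled) with probability
   ``a_pdh`` — the pyruvate-dehydrogenase/glucose contribution — and
   unlabeled otherwise;
2. citrate = OAA (carbons O1..O4) + acetyl (A1, A2);
3. alpha-ketoglutarate (reported as glutamate) loses O1 as CO2;
4. succinate loses O4 as the second CO2, leaving [O2, O3, A1, A2];
5. succinate's symmetry averages each string with its reversal;
6. the cycle-derived malate inherits the symmetrized succinate;
7. next-turn OAA is a mixture: recycled malate (weight
   ``1 - f_pc - d_dilution``), pyruvate-carboxylase OAA built from the
   pyruvate string plus one unlabeled CO2 carbon (weight ``f_pc``), and
   unlabeled anaplerotic carbon (weight ``d_dilution``).

The *measured* malate pool is the symmetrized OAA pool: malate,
fumarate and OAA exchange rapidly through the reversible fumarase /
malate-dehydrogenase segment, and fumarate's two-fold symmetry scrambles
the string.  This exchange is what carries the pyruvate-carboxylase M+3
signature (M+3 OAA from M+3 pyruvate) into measured malate; without it
the first oxidative decarboxylations would strip the signature before
the succinate-derived malate is formed.

Acetyl carbons survive the first turn, so one turn from unlabeled OAA
gives pure M+2 citrate; subsequent turns redistribute and lose labeled
carbons, generating the M+1 species characteristic of multiple turns.
Glutamate reports alpha-ketoglutarate and aspartate reports OAA (fast
exchange); lactate reports pyruvate.

The deterministic fixed point is cross-checked by a single-molecule
Monte-Carlo tracker (:func:`simulate_tca_monte_carlo`) that follows
individual OAA skeletons through the same atom map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import beta as beta_dist

from tcatrace.isocorrect import (
    DEFAULT_FRAGMENTS,
    MID,
    CorrectionMatrix,
    FragmentFormula,
    build_correction_matrix,
    correct_mid,
)
from tcatrace.metrics import TissueClass, TissueSample

__all__ = [
    "SimConfig",
    "CohortSimConfig",
    "ExpressionEffects",
    "SimResult",
    "simulate_tca_steady_state",
    "simulate_tca_monte_carlo",
    "forward_measurement",
    "generate_patient",
    "generate_cohort",
    "generate_expression_data",
    "group_mean_gap",
]

SIMULATED_METABOLITES = {
    "pyruvate": 3,
    "lactate": 3,
    "citrate": 6,
    "glutamate": 5,
    "malate": 4,
    "aspartate": 4,
}


@dataclass(frozen=True)
class SimConfig:
    """Latent metabolic parameters of one tissue.

    a_pdh        probability an acetyl-CoA unit is M+2 (glucose/PDH-derived,
                 conflating direct PDH flux and import of circulating
                 13C-lactate re-entering as pyruvate)
    f_pc         per-turn fraction of OAA from pyruvate carboxylation
    d_dilution   per-turn fraction of OAA replaced by unlabeled anaplerosis
    pyr_m3       pyruvate M+3 fraction (upstream glycolytic labeling)
    glucose_m6   tissue glucose M+6 enrichment (the score normalizer)
    lactate_dilution  unlabeled fraction mixed into lactate relative to
                 pyruvate (circulating-lactate contribution)
    """

    a_pdh: float = 0.2
    f_pc: float = 0.05
    d_dilution: float = 0.3
    pyr_m3: float = 0.15
    glucose_m6: float = 0.45
    lactate_dilution: float = 0.0
    max_turns: int = 200
    tol: float = 1e-9
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("a_pdh", "f_pc", "d_dilution", "pyr_m3", "glucose_m6",
                     "lactate_dilution"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.f_pc + self.d_dilution > 1.0:
            raise ValueError("f_pc + d_dilution must be <= 1")
        if self.tol <= 0 or self.max_turns < 1:
            raise ValueError("tol must be > 0 and max_turns >= 1")


@dataclass
class SimResult:
    """Steady-state MIDs plus convergence diagnostics."""

    mids: dict[str, MID]
    turns: int
    converged: bool

    def __getitem__(self, met: str) -> MID:
        return self.mids[met]


# ---------------------------------------------------------------------------
# Positional-pool algebra.  A pool over n carbons is a probability vector of
# length 2^n; bit k of the index marks carbon k+1 as 13C.


def _concat(p: np.ndarray, q: np.ndarray, n_p: int) -> np.ndarray:
    """Pool of the condensation product; p's carbons occupy the low bits."""
    return (q[:, None] * p[None, :]).ravel()


def _drop_carbon(p: np.ndarray, n: int, k: int) -> np.ndarray:
    """Marginalize out carbon k+1 (bit k), e.g. loss as CO2."""
    arr = p.reshape([2] * n)  # axis 0 = highest bit, axis n-1 = bit 0
    return arr.sum(axis=n - 1 - k).ravel()


def _reverse_perm(n: int) -> np.ndarray:
    idx = np.arange(2**n)
    rev = np.zeros_like(idx)
    for k in range(n):
        rev |= ((idx >> k) & 1) << (n - 1 - k)
    return rev


def _mid_from_pool(p: np.ndarray, n: int, metabolite_id: str) -> MID:
    counts = np.array([bin(i).count("1") for i in range(2**n)])
    fr = np.bincount(counts, weights=p, minlength=n + 1)
    return MID(metabolite_id, n, fr / fr.sum())


def _pyruvate_pool(pyr_m3: float) -> np.ndarray:
    pool = np.zeros(8)
    pool[0] = 1.0 - pyr_m3
    pool[0b111] = pyr_m3
    return pool


def _acetyl_pool(a_pdh: float) -> np.ndarray:
    pool = np.zeros(4)
    pool[0] = 1.0 - a_pdh
    pool[0b11] = a_pdh
    return pool


def _turn(oaa: np.ndarray, acetyl: np.ndarray, pyr: np.ndarray,
          cfg: SimConfig, rev4: np.ndarray) -> tuple[np.ndarray, ...]:
    """One turn of the cycle; returns (citrate64, akg32, malate16, oaa16)."""
    citrate = _concat(oaa, acetyl, 4)            # [O1..O4, A1, A2]
    akg = _drop_carbon(citrate, 6, 0)            # lose O1 -> [O2, O3, O4, A1, A2]
    succ = _drop_carbon(akg, 5, 2)               # lose O4 -> [O2, O3, A1, A2]
    succ = 0.5 * (succ + succ[rev4])             # two-fold symmetry
    malate = succ
    pc_oaa = np.zeros(16)
    pc_oaa[:8] = pyr                             # [P1, P2, P3, CO2(unlabeled)]
    oaa_next = (1.0 - cfg.f_pc - cfg.d_dilution) * malate + cfg.f_pc * pc_oaa
    oaa_next[0] += cfg.d_dilution
    return citrate, akg, malate, oaa_next


def simulate_tca_steady_state(cfg: SimConfig) -> SimResult:
    """Deterministic fixed-point iteration of the per-turn atom map.

    Iterates until the largest absolute change in any reported MID falls
    below ``cfg.tol`` or ``cfg.max_turns`` is reached (the result then
    carries ``converged=False``).
    """
    pyr = _pyruvate_pool(cfg.pyr_m3)
    acetyl = _acetyl_pool(cfg.a_pdh)
    rev4 = _reverse_perm(4)
    oaa = np.zeros(16)
    oaa[0] = 1.0

    prev: np.ndarray | None = None
    converged = False
    turns = 0
    for turns in range(1, cfg.max_turns + 1):
        citrate, akg, malate, oaa = _turn(oaa, acetyl, pyr, cfg, rev4)
        snapshot = np.concatenate([citrate, akg, malate, oaa])
        if prev is not None and np.max(np.abs(snapshot - prev)) < cfg.tol:
            converged = True
            break
        prev = snapshot

    lac_pool = (1.0 - cfg.lactate_dilution) * pyr.copy()
    lac_pool[0] += cfg.lactate_dilution
    measured_malate = 0.5 * (oaa + oaa[rev4])  # fumarase exchange + symmetry
    mids = {
        "pyruvate": _mid_from_pool(pyr, 3, "pyruvate"),
        "lactate": _mid_from_pool(lac_pool, 3, "lactate"),
        "citrate": _mid_from_pool(citrate, 6, "citrate"),
        "glutamate": _mid_from_pool(akg, 5, "glutamate"),
        "malate": _mid_from_pool(measured_malate, 4, "malate"),
        "aspartate": _mid_from_pool(oaa, 4, "aspartate"),
    }
    return SimResult(mids=mids, turns=turns, converged=converged)


def simulate_tca_monte_carlo(
    cfg: SimConfig,
    n_molecules: int = 1_000_000,
    burn_in_turns: int = 80,
    rng: np.random.Generator | None = None,
) -> dict[str, MID]:
    """Single-molecule Monte-Carlo tracker of the same atom map.

    Follows ``n_molecules`` independent OAA skeletons (4-bit label
    strings) through ``burn_in_turns`` turns of the cycle, then reads out
    one condensation per molecule.  Serves as the stochastic cross-check
    of the deterministic fixed point; agreement is expected within
    binomial sampling error.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    rev4_perm = _reverse_perm(4)

    def draw_acetyl(n: int) -> np.ndarray:
        return np.where(rng.random(n) < cfg.a_pdh, 0b11, 0).astype(np.int64)

    def draw_pyruvate(n: int) -> np.ndarray:
        return np.where(rng.random(n) < cfg.pyr_m3, 0b111, 0).astype(np.int64)

    oaa = np.zeros(n_molecules, dtype=np.int64)
    for _ in range(burn_in_turns):
        acetyl = draw_acetyl(n_molecules)
        citrate = oaa | (acetyl << 4)
        akg = citrate >> 1                       # lose O1
        succ = (akg & 0b11) | ((akg >> 1) & 0b1100)  # lose O4
        flip = rng.random(n_molecules) < 0.5
        succ = np.where(flip, rev4_perm[succ], succ)
        malate = succ
        u = rng.random(n_molecules)
        pc = draw_pyruvate(n_molecules)          # [P1,P2,P3] + unlabeled CO2
        keep = u < 1.0 - cfg.f_pc - cfg.d_dilution
        from_pc = (~keep) & (u < 1.0 - cfg.d_dilution)
        oaa = np.where(keep, malate, np.where(from_pc, pc, 0))

    acetyl = draw_acetyl(n_molecules)
    citrate = oaa | (acetyl << 4)
    akg = citrate >> 1
    flip = rng.random(n_molecules) < 0.5
    malate = np.where(flip, rev4_perm[oaa], oaa)  # fumarase-exchanged OAA
    pyr = draw_pyruvate(n_molecules)

    def mid_of(codes: np.ndarray, n_carbons: int, name: str) -> MID:
        counts = np.bincount(
            np.bitwise_count(codes.astype(np.uint64)), minlength=n_carbons + 1
        ).astype(float)
        return MID(name, n_carbons, counts / counts.sum())

    return {
        "pyruvate": mid_of(pyr, 3, "pyruvate"),
        "lactate": mid_of(pyr, 3, "lactate"),
        "citrate": mid_of(citrate, 6, "citrate"),
        "glutamate": mid_of(akg, 5, "glutamate"),
        "malate": mid_of(malate, 4, "malate"),
        "aspartate": mid_of(oaa, 4, "aspartate"),
    }


# ---------------------------------------------------------------------------
# Forward measurement model


def forward_measurement(
    true_mid: MID,
    formula: FragmentFormula,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    cm: CorrectionMatrix | None = None,
) -> np.ndarray:
    """Simulate raw GC-MS channel intensities for a known tracer MID.

    Applies the natural-abundance/tracer-purity forward convolution (the
    correction matrix), adds i.i.d. Gaussian noise, clips at zero and
    renormalizes.  The exact inverse of :func:`tcatrace.isocorrect.correct_mid`
    at zero noise.
    """
    if cm is None:
        cm = build_correction_matrix(formula)
    raw = cm.matrix @ true_mid.fractions
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        raw = raw + rng.normal(0.0, noise_sd, size=raw.shape)
    raw = np.clip(raw, 0.0, None)
    total = raw.sum()
    if total <= 0:  # pathological noise draw; keep the vector usable
        raw = cm.matrix @ true_mid.fractions
        total = raw.sum()
    return raw / total


# ---------------------------------------------------------------------------
# Cohort generation


def group_mean_gap(alpha: float, beta: float) -> float:
    """Standardized mean gap between the upper and lower halves of a
    Beta(alpha, beta) distribution split at its median.

    Used to convert a desired between-group hazard ratio into the
    per-standard-deviation coefficient of the continuous latent score:
    beta_coef = log(HR_between_groups) / gap.
    """
    d = beta_dist(alpha, beta)
    med = d.median()
    mu, sd = d.mean(), d.std()
    # E[X | X > med] via the incomplete-beta identity
    upper_mass = 1.0 - d.cdf(med)
    e_upper = mu * (1.0 - beta_dist(alpha + 1, beta).cdf(med)) / upper_mass
    e_lower = (mu - e_upper * upper_mass) / (1.0 - upper_mass)
    return (e_upper - e_lower) / sd


@dataclass(frozen=True)
class ExpressionEffects:
    """Effect sizes for the synthetic single-cell expression generator."""

    epithelial_shift: float = 0.2
    myeloid_shift: float = 0.4
    tumor_epithelial_shift: float = 0.6
    tumor_epithelial_var_inflation: float = 2.0


@dataclass(frozen=True)
class CohortSimConfig:
    """Generative parameters of a synthetic tracing cohort.

    Latent tumor and lung PDH fractions are Beta-distributed per patient;
    the per-patient hazard is ``baseline_hazard * exp(log_hr_per_sd * z)``
    with ``z`` the standardized latent tumor PDH fraction.  Death times
    are exponential; censoring is exponential truncated at
    ``max_followup`` months.
    """

    n_patients: int = 66
    tumor_a_pdh: tuple[float, float] = (2.5, 10.0)   # Beta shapes, mean 0.2
    lung_a_pdh: tuple[float, float] = (1.5, 13.5)    # Beta shapes, mean 0.1
    tumor_f_pc: float = 0.08
    lung_f_pc: float = 0.03
    d_dilution: float = 0.3
    pyr_m3: float = 0.15
    glucose_m6: float = 0.45
    noise_sd: float = 0.002
    baseline_hazard: float = 0.007   # deaths per month
    log_hr_per_sd: float = 0.0
    recurrence_hazard_frac: float = 0.5  # extra recurrence hazard vs death
    censor_rate: float = 0.004       # per month
    max_followup: float = 120.0      # months
    n_benign: int = 0
    n_metastasis: int = 0
    n_missing_lung: int = 0          # tumor patients without adjacent lung
    metastasis_a_pdh: tuple[float, float] = (5.0, 10.0)  # mean ~0.33
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 4:
            raise ValueError("n_patients must be >= 4")
        for name in ("baseline_hazard", "censor_rate", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def with_group_hr(self, hr: float) -> "CohortSimConfig":
        """Set the latent-score coefficient so that the hazard contrast
        between the above- and below-median halves of the latent tumor
        score is ``hr``."""
        gap = group_mean_gap(*self.tumor_a_pdh)
        return replace(self, log_hr_per_sd=math.log(hr) / gap)


def _measure_sample(
    patient_id: str,
    fragment_id: str,
    tissue_class: TissueClass,
    sim: SimResult,
    glucose_m6: float,
    noise_sd: float,
    rng: np.random.Generator,
    matrices: dict[str, CorrectionMatrix],
) -> TissueSample:
    """Push true MIDs through the measurement model and correction."""
    mids: dict[str, MID] = {}
    true_mids = dict(sim.mids)
    # glycolytic reporters: 3PG mirrors glucose, pyruvate its own pool
    glc = np.zeros(7)
    glc[0], glc[6] = 1.0 - glucose_m6, glucose_m6
    true_mids["glucose"] = MID("glucose", 6, glc)
    pg = np.zeros(4)
    pg[0], pg[3] = 1.0 - glucose_m6, glucose_m6
    true_mids["3pg"] = MID("3pg", 3, pg)
    for met, true in true_mids.items():
        cm = matrices[met]
        raw = forward_measurement(true, DEFAULT_FRAGMENTS[met], noise_sd, rng, cm)
        mids[met] = correct_mid(raw, cm)
    return TissueSample(
        patient_id=patient_id,
        fragment_id=fragment_id,
        tissue_class=tissue_class,
        mids=mids,
        glucose_m6=float(mids["glucose"][6]),
    )


def _default_matrices() -> dict[str, CorrectionMatrix]:
    return {met: build_correction_matrix(f) for met, f in DEFAULT_FRAGMENTS.items()}


def generate_patient(
    tumor_a_pdh: float,
    lung_a_pdh: float,
    cfg: CohortSimConfig,
    rng: np.random.Generator | None = None,
    patient_id: str = "P001",
    matrices: dict[str, CorrectionMatrix] | None = None,
    lesion_class: TissueClass = TissueClass.TUMOR,
) -> tuple[TissueSample, TissueSample]:
    """One patient's matched lesion and adjacent-lung fragments: steady
    state per tissue, forward measurement, natural-abundance correction."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if matrices is None:
        matrices = _default_matrices()
    tumor_sim = simulate_tca_steady_state(
        SimConfig(a_pdh=tumor_a_pdh, f_pc=cfg.tumor_f_pc,
                  d_dilution=cfg.d_dilution, pyr_m3=cfg.pyr_m3,
                  glucose_m6=cfg.glucose_m6)
    )
    lung_sim = simulate_tca_steady_state(
        SimConfig(a_pdh=lung_a_pdh, f_pc=cfg.lung_f_pc,
                  d_dilution=cfg.d_dilution, pyr_m3=cfg.pyr_m3,
                  glucose_m6=cfg.glucose_m6)
    )
    tumor = _measure_sample(patient_id, f"{patient_id}-T1", lesion_class,
                            tumor_sim, cfg.glucose_m6, cfg.noise_sd, rng,
                            matrices)
    lung = _measure_sample(patient_id, f"{patient_id}-L1",
                           TissueClass.ADJACENT_LUNG, lung_sim,
                           cfg.glucose_m6, cfg.noise_sd, rng, matrices)
    return tumor, lung


def generate_cohort(cfg: CohortSimConfig):
    """Synthetic tracing study: tissue samples plus survival outcomes whose
    hazard is log-linear in the standardized latent tumor labeling.

    Returns ``(samples, records)`` where ``samples`` is a flat list of
    :class:`TissueSample` (tumor + adjacent lung per NSCLC patient, plus
    optional benign and metastatic lesions with their lungs) and
    ``records`` a list of :class:`tcatrace.pipeline_io.PatientRecord` for
    the NSCLC patients only.
    """
    from tcatrace.pipeline_io import PatientRecord  # avoid import cycle

    rng = np.random.default_rng(cfg.seed)
    matrices = _default_matrices()

    ta, tb = cfg.tumor_a_pdh
    la, lb = cfg.lung_a_pdh
    tumor_latents = rng.beta(ta, tb, size=cfg.n_patients)
    lung_latents = rng.beta(la, lb, size=cfg.n_patients)
    if np.ptp(tumor_latents) == 0:
        import warnings

        warnings.warn("all latent scores equal: stratification undefined",
                      stacklevel=2)
        z = np.zeros(cfg.n_patients)
    else:
        z = (tumor_latents - tumor_latents.mean()) / tumor_latents.std()

    samples: list[TissueSample] = []
    records: list = []
    for i in range(cfg.n_patients):
        pid = f"P{i + 1:03d}"
        tumor, lung = generate_patient(
            tumor_latents[i], lung_latents[i], cfg, rng, pid, matrices
        )
        samples.append(tumor)
        if i >= cfg.n_patients - cfg.n_missing_lung:
            pass  # tumor-only patient: no adjacent-lung fragment banked
        else:
            samples.append(lung)

        hazard = cfg.baseline_hazard * math.exp(cfg.log_hr_per_sd * z[i])
        t_death = rng.exponential(1.0 / hazard) if hazard > 0 else math.inf
        t_recur = (
            rng.exponential(1.0 / (cfg.recurrence_hazard_frac * hazard))
            if cfg.recurrence_hazard_frac * hazard > 0
            else math.inf
        )
        t_censor = (
            rng.exponential(1.0 / cfg.censor_rate)
            if cfg.censor_rate > 0
            else math.inf
        )
        t_censor = min(t_censor, cfg.max_followup)
        t_rfs = min(t_death, t_recur)
        records.append(
            PatientRecord(
                patient_id=pid,
                os_months=max(min(t_death, t_censor), 1e-6),
                os_event=t_death <= t_censor,
                rfs_months=max(min(t_rfs, t_censor), 1e-6),
                rfs_event=t_rfs <= t_censor,
                covariates={"latent_tumor_a_pdh": float(tumor_latents[i])},
            )
        )

    for j in range(cfg.n_benign):
        pid = f"B{j + 1:03d}"
        latent = rng.beta(la, lb)  # benign lesions share the lung phenotype
        lesion, lung = generate_patient(latent, rng.beta(la, lb), cfg, rng,
                                        pid, matrices,
                                        lesion_class=TissueClass.BENIGN)
        samples.extend([lesion, lung])
    ma, mb = cfg.metastasis_a_pdh
    for j in range(cfg.n_metastasis):
        pid = f"M{j + 1:03d}"
        lesion, lung = generate_patient(rng.beta(ma, mb), rng.beta(la, lb),
                                        cfg, rng, pid, matrices,
                                        lesion_class=TissueClass.METASTASIS)
        samples.extend([lesion, lung])
    return samples, records


# ---------------------------------------------------------------------------
# Synthetic single-cell expression data


def generate_expression_data(
    n_cells: int = 120,
    n_samples: int = 4,
    gene_set_size: int = 40,
    n_background_genes: int = 60,
    cell_types: tuple[str, ...] = ("epithelial", "myeloid", "lymphoid"),
    sample_classes: tuple[str, ...] = ("normal_lung", "tumor"),
    effects: ExpressionEffects | None = None,
    seed: int = 0,
):
    """Synthetic annotated expression matrix for gene-set scoring.

    Log-normal expression on a log-normalized-like nonnegative scale;
    ``n_cells`` cells per (sample, cell type).  The gene-set genes get
    cell-type mean shifts (myeloid high everywhere, epithelial moderately
    high) plus a tumor-epithelial shift and variance inflation that
    recreate the malignant-cell pattern: highest mean score and highest
    score heterogeneity in tumor epithelial cells.

    Returns :class:`tcatrace.expression_scores.AnnotatedExpression`.
    """
    from tcatrace.expression_scores import AnnotatedExpression

    if len(cell_types) < 2 or len(sample_classes) < 2:
        raise ValueError("need >= 2 cell types and >= 2 sample classes")
    if effects is None:
        effects = ExpressionEffects()
    rng = np.random.default_rng(seed)
    genes = [f"OXP{i:03d}" for i in range(gene_set_size)] + [
        f"BG{i:03d}" for i in range(n_background_genes)
    ]
    n_genes = len(genes)

    cols, cell_type_ann, sample_ann, class_ann = [], [], [], []
    for cls in sample_classes:
        for s in range(n_samples):
            sid = f"{cls}-S{s + 1}"
            for ct in cell_types:
                shift = 0.0
                sigma = 0.35
                if ct == "myeloid":
                    shift += effects.myeloid_shift
                if ct == "epithelial":
                    shift += effects.epithelial_shift
                    if cls != sample_classes[0]:
                        shift += effects.tumor_epithelial_shift
                        sigma *= math.sqrt(effects.tumor_epithelial_var_inflation)
                mu = np.zeros(n_genes)
                mu[:gene_set_size] = shift
                block = rng.lognormal(
                    mean=mu[:, None] - 0.5,
                    sigma=np.where(
                        np.arange(n_genes)[:, None] < gene_set_size, sigma, 0.35
                    ),
                    size=(n_genes, n_cells),
                )
                cols.append(block)
                cell_type_ann += [ct] * n_cells
                sample_ann += [sid] * n_cells
                class_ann += [cls] * n_cells

    import pandas as pd

    matrix = pd.DataFrame(
        np.concatenate(cols, axis=1),
        index=genes,
        columns=[f"cell{i}" for i in range(len(cell_type_ann))],
    )
    return AnnotatedExpression(
        matrix=matrix,
        cell_type=pd.Series(cell_type_ann, index=matrix.columns),
        sample_id=pd.Series(sample_ann, index=matrix.columns),
        sample_class=pd.Series(class_ann, index=matrix.columns),
    )
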