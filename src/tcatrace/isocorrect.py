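"""Mass isotopologue distributions and natural-abundance correction.

GC-MS isotopologue measurements of TBDMS-derivatized metabolites mix the
signal of interest — how many tracer carbons carry 13C — with mass shifts
contributed by naturally occurring heavy isotopes (13C at ~1.07%, and for
silylated fragments especially 29Si/30Si) and by incomplete tracer purity.
This module models the fragment's theoretical mass-shift envelope for each
possible tracer labeling state, assembles those envelopes into a correction
matrix, and inverts the measurement by nonnegative least squares to recover
the tracer-only mass isotopologue distribution (MID).

The MID convention throughout the package: ``fractions[k]`` is the fraction
of the metabolite pool carrying exactly ``k`` tracer carbons ("M+k"),
ascending in mass shift, summing to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "MID",
    "FragmentFormula",
    "CorrectionMatrix",
    "DEFAULT_ABUNDANCES",
    "DEFAULT_FRAGMENTS",
    "theoretical_mass_distribution",
    "build_correction_matrix",
    "correct_mid",
    "convolve",
    "labeled_fraction",
    "read_mid_table",
    "write_mid_table",
    "read_formula_table",
]

_SUM_TOL = 1e-9

#: Natural heavy-isotope abundances, per element, as a list of
#: probabilities indexed by mass shift minus one (e.g. O -> [P(17O), P(18O)]).
#: Standard reference values; override by passing your own mapping.
DEFAULT_ABUNDANCES: dict[str, tuple[float, ...]] = {
    "C": (0.0107,),
    "H": (0.000115,),
    "N": (0.00364,),
    "O": (0.00038, 0.00205),
    "Si": (0.0468, 0.0310),
}

#: Default tracer (13C) purity of commercial [U-13C]glucose.
DEFAULT_TRACER_PURITY = 0.99

#: Extra mass channels beyond M+n to capture Si/O heavy-isotope shifts.
DEFAULT_EXTRA_CHANNELS = 4


class DegenerateInputError(ValueError):
    """Raised when an input is structurally valid but carries no signal."""


@dataclass(frozen=True)
class MID:
    """Mass isotopologue distribution of one metabolite pool.

    ``fractions[k]`` = fraction of molecules with k tracer carbons labeled.
    """

    metabolite_id: str
    n_carbons: int
    fractions: np.ndarray

    def __post_init__(self) -> None:
        fr = np.asarray(self.fractions, dtype=float)
        object.__setattr__(self, "fractions", fr)
        if self.n_carbons < 1:
            raise ValueError(f"{self.metabolite_id}: n_carbons must be >= 1")
        if fr.shape != (self.n_carbons + 1,):
            raise ValueError(
                f"{self.metabolite_id}: expected {self.n_carbons + 1} fractions, "
                f"got {fr.shape}"
            )
        if np.any(fr < -_SUM_TOL) or np.any(fr > 1 + _SUM_TOL):
            raise ValueError(f"{self.metabolite_id}: fractions outside [0, 1]")
        if abs(fr.sum() - 1.0) > 1e-6:
            raise ValueError(
                f"{self.metabolite_id}: fractions sum to {fr.sum():.6g}, not 1"
            )

    def __getitem__(self, k: int) -> float:
        return float(self.fractions[k])

    @property
    def m0(self) -> float:
        return float(self.fractions[0])

    @staticmethod
    def from_fractions(metabolite_id: str, fractions) -> "MID":
        fr = np.asarray(fractions, dtype=float)
        return MID(metabolite_id, fr.size - 1, fr)


@dataclass(frozen=True)
class FragmentFormula:
    """Elemental composition of the derivatized GC-MS fragment.

    ``n_tracer_carbons`` of the carbons belong to the metabolite backbone
    and can carry tracer label; the remainder (and all H/N/O/Si) only
    contribute natural-abundance mass shifts.
    """

    metabolite_id: str
    element_counts: dict[str, int]
    n_tracer_carbons: int
    tracer_purity: float = DEFAULT_TRACER_PURITY

    def __post_init__(self) -> None:
        counts = {el: int(n) for el, n in self.element_counts.items()}
        object.__setattr__(self, "element_counts", counts)
        if any(n < 0 for n in counts.values()):
            raise ValueError(f"{self.metabolite_id}: negative element count")
        if self.n_tracer_carbons > counts.get("C", 0):
            raise ValueError(
                f"{self.metabolite_id}: n_tracer_carbons exceeds carbon count"
            )
        if not (0.0 < self.tracer_purity <= 1.0):
            raise ValueError(f"{self.metabolite_id}: tracer_purity not in (0, 1]")


#: Default TBDMS-fragment formulas for the metabolites in scope.
#: These are the commonly monitored fragments of the TBDMS (and, for
#: pyruvate, MOX-TBDMS) derivatives; they are configuration, not algorithm —
#: override via ``read_formula_table`` for other fragments.
DEFAULT_FRAGMENTS: dict[str, FragmentFormula] = {
    "glucose": FragmentFormula("glucose", {"C": 24, "H": 55, "N": 1, "O": 6, "Si": 4}, 6),
    "3pg": FragmentFormula("3pg", {"C": 21, "H": 52, "N": 0, "O": 7, "Si": 4}, 3),
    "pyruvate": FragmentFormula("pyruvate", {"C": 6, "H": 12, "N": 1, "O": 3, "Si": 1}, 3),
    "lactate": FragmentFormula("lactate", {"C": 11, "H": 25, "N": 0, "O": 3, "Si": 2}, 3),
    "citrate": FragmentFormula("citrate", {"C": 20, "H": 39, "N": 0, "O": 6, "Si": 3}, 6),
    "glutamate": FragmentFormula("glutamate", {"C": 19, "H": 42, "N": 1, "O": 4, "Si": 3}, 5),
    "malate": FragmentFormula("malate", {"C": 18, "H": 39, "N": 0, "O": 5, "Si": 3}, 4),
    "aspartate": FragmentFormula("aspartate", {"C": 18, "H": 40, "N": 1, "O": 4, "Si": 3}, 4),
}


@dataclass(frozen=True)
class CorrectionMatrix:
    """Forward model of the measurement: column j is the theoretical
    mass-shift envelope of the fragment with j tracer carbons labeled."""

    metabolite_id: str
    matrix: np.ndarray
    channel_offset: int = 0

    @property
    def m_channels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_tracer_carbons(self) -> int:
        return self.matrix.shape[1] - 1


def _atom_distribution(heavy_probs: tuple[float, ...]) -> np.ndarray:
    """Mass-shift distribution of a single atom: [P(+0), P(+1), ...]."""
    p0 = 1.0 - sum(heavy_probs)
    if p0 < -1e-12:
        raise ValueError("heavy-isotope probabilities sum above 1")
    return np.array([max(p0, 0.0), *heavy_probs], dtype=float)


def _convolve_power(dist: np.ndarray, n: int, truncate: int) -> np.ndarray:
    """n-fold self-convolution of an atom distribution, truncated."""
    out = np.zeros(truncate)
    out[0] = 1.0
    base = dist[:truncate]
    for _ in range(n):
        out = np.convolve(out, base)[:truncate]
    return out


def theoretical_mass_distribution(
    formula: FragmentFormula,
    n_labeled: int,
    abundances: dict[str, tuple[float, ...]] | None = None,
    m_channels: int | None = None,
) -> np.ndarray:
    """Mass-shift distribution of the fragment with ``n_labeled`` tracer
    carbons carrying 13C at the tracer purity, all other atoms at natural
    abundance.

    Returns a vector of length ``m_channels`` (default:
    ``n_tracer_carbons + 4``) whose entries sum to <= 1 (truncation) and to
    1 within 1e-9 when the channels cover the full support.
    """
    if abundances is None:
        abundances = DEFAULT_ABUNDANCES
    if not (0 <= n_labeled <= formula.n_tracer_carbons):
        raise ValueError(
            f"n_labeled={n_labeled} outside [0, {formula.n_tracer_carbons}]"
        )
    if m_channels is None:
        m_channels = formula.n_tracer_carbons + 1 + DEFAULT_EXTRA_CHANNELS

    # Labeled tracer positions: each carries 13C with prob = tracer purity.
    out = _convolve_power(
        np.array([1.0 - formula.tracer_purity, formula.tracer_purity]),
        n_labeled,
        m_channels,
    )
    for el, count in formula.element_counts.items():
        if count == 0:
            continue
        if el not in abundances:
            raise KeyError(f"no natural-abundance entry for element {el!r}")
        n_natural = count - n_labeled if el == "C" else count
        dist = _atom_distribution(abundances[el])
        out = np.convolve(out, _convolve_power(dist, n_natural, m_channels))[
            :m_channels
        ]
    return out


def build_correction_matrix(
    formula: FragmentFormula,
    abundances: dict[str, tuple[float, ...]] | None = None,
    m_channels: int | None = None,
) -> CorrectionMatrix:
    """Assemble the (m_channels x n_tracer_carbons+1) correction matrix."""
    if m_channels is None:
        m_channels = formula.n_tracer_carbons + 1 + DEFAULT_EXTRA_CHANNELS
    if m_channels < formula.n_tracer_carbons + 1:
        raise ValueError("m_channels must cover at least M+0..M+n")
    cols = [
        theoretical_mass_distribution(formula, j, abundances, m_channels)
        for j in range(formula.n_tracer_carbons + 1)
    ]
    return CorrectionMatrix(formula.metabolite_id, np.column_stack(cols))


def correct_mid(raw_intensities, cm: CorrectionMatrix) -> MID:
    """Recover the tracer MID from raw mass-channel intensities.

    Solves ``raw ~ matrix @ x`` under ``x >= 0`` by nonnegative least
    squares and renormalizes; NNLS (rather than plain inversion) keeps
    noisy measurements from producing negative fractions. The result is
    invariant to uniform scaling of the raw intensities.
    """
    raw = np.asarray(raw_intensities, dtype=float)
    if raw.shape != (cm.m_channels,):
        raise ValueError(
            f"raw vector length {raw.size} != {cm.m_channels} channels"
        )
    if np.any(raw < 0):
        raise ValueError("raw intensities must be nonnegative")
    total = raw.sum()
    if total <= 0:
        raise DegenerateInputError("all-zero raw intensity vector")
    x, _ = nnls(cm.matrix, raw / total)
    s = x.sum()
    if s <= 0:
        raise DegenerateInputError("correction produced an all-zero MID")
    return MID(cm.metabolite_id, cm.n_tracer_carbons, x / s)


def convolve(a: MID, b: MID, metabolite_id: str | None = None) -> MID:
    """MID of the condensation product of two independently labeled pools
    (e.g. acetyl-CoA + oxaloacetate -> citrate)."""
    fr = np.convolve(a.fractions, b.fractions)
    fr = fr / fr.sum()
    name = metabolite_id or f"{a.metabolite_id}+{b.metabolite_id}"
    return MID(name, a.n_carbons + b.n_carbons, fr)


def labeled_fraction(m: MID) -> float:
    """Total enrichment: fraction of the pool carrying any tracer carbon,
    i.e. 1 - M+0."""
    return float(np.clip(1.0 - m.fractions[0], 0.0, 1.0))


# ---------------------------------------------------------------------------
# Table I/O: long-format MID tables and formula tables.

def read_mid_table(path) -> dict[tuple[str, str], MID]:
    """Read a long-format MID table (sample_id, metabolite, mass_shift,
    value) into ``{(sample_id, metabolite): MID}``."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"sample_id", "metabolite", "mass_shift", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"MID table missing columns: {sorted(missing)}")
    out: dict[tuple[str, str], MID] = {}
    for (sid, met), grp in df.groupby(["sample_id", "metabolite"], sort=False):
        grp = grp.sort_values("mass_shift")
        shifts = grp["mass_shift"].to_numpy()
        if not np.array_equal(shifts, np.arange(len(shifts))):
            raise ValueError(f"{sid}/{met}: mass shifts not contiguous from 0")
        fr = grp["value"].to_numpy(dtype=float)
        out[(str(sid), str(met))] = MID(str(met), len(fr) - 1, fr / fr.sum())
    return out


def write_mid_table(mids: dict[tuple[str, str], MID], path) -> None:
    rows = [
        {"sample_id": sid, "metabolite": met, "mass_shift": k, "value": v}
        for (sid, met), mid in mids.items()
        for k, v in enumerate(mid.fractions)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_formula_table(path) -> dict[str, FragmentFormula]:
    """Read a formula table (metabolite, C, H, N, O, Si, n_tracer_carbons
    [, tracer_purity])."""
    df = pd.read_csv(path, sep=None, engine="python")
    out: dict[str, FragmentFormula] = {}
    for _, row in df.iterrows():
        met = str(row["metabolite"])
        counts = {el: int(row.get(el, 0) or 0) for el in ("C", "H", "N", "O", "Si")}
        purity = float(row["tracer_purity"]) if "tracer_purity" in df.columns else DEFAULT_TRACER_PURITY
        out[met] = FragmentFormula(met, counts, int(row["n_tracer_carbons"]), purity)
    return out
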