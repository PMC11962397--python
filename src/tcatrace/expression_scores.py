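"""Single-cell gene-set scoring: per-cell mean expression over a gene set
and per-group score heterogeneity.

The per-cell score of a gene set (e.g. OXPHOS genes) is the mean
log-normalized expression of the set's genes in that cell.  Group
summaries (mean, SD, relative SD = SD/mean) are reported by cell type x
sample class and by sample; the relative SD of scores among epithelial
cells quantifies within-sample heterogeneity of the program.

The matrix is assumed already log-normalized; this module validates
nonnegativity but performs no normalization of its own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AnnotatedExpression",
    "GeneSetScoreResult",
    "geneset_mean_score",
    "score_relative_sd",
]

log = logging.getLogger(__name__)


@dataclass
class AnnotatedExpression:
    """Genes x cells expression matrix with per-cell annotations."""

    matrix: pd.DataFrame  # genes x cells, nonnegative, log-normalized scale
    cell_type: pd.Series
    sample_id: pd.Series
    sample_class: pd.Series

    def __post_init__(self) -> None:
        n_cells = self.matrix.shape[1]
        for name in ("cell_type", "sample_id", "sample_class"):
            ann = getattr(self, name)
            if len(ann) != n_cells:
                raise ValueError(f"{name} length {len(ann)} != {n_cells} cells")
        if not self.matrix.index.is_unique:
            raise ValueError("gene identifiers must be unique")
        if (self.matrix.to_numpy() < 0).any():
            raise ValueError("expression values must be nonnegative "
                             "(log-normalized scale expected)")


@dataclass
class GeneSetScoreResult:
    gene_set_name: str
    per_cell_scores: pd.Series
    genes_used: list[str]
    genes_missing: list[str]
    by_cell_type: pd.DataFrame   # (cell_type, sample_class) -> mean/sd/rel sd
    by_sample: pd.DataFrame      # (sample_id, sample_class, cell_type) -> same
    annotations: pd.DataFrame


def _summary(scores: pd.Series, keys: pd.DataFrame) -> pd.DataFrame:
    df = keys.copy()
    df["score"] = scores
    grouped = df.groupby(list(keys.columns), observed=True)["score"]
    out = grouped.agg(mean="mean", sd=lambda x: x.std(ddof=1), n="size")
    out["relative_sd"] = np.where(out["mean"] > 0, out["sd"] / out["mean"], np.nan)
    return out.reset_index()


def geneset_mean_score(
    expr: AnnotatedExpression, gene_set: list[str], name: str = "gene_set"
) -> GeneSetScoreResult:
    """Per-cell mean expression over the gene set, with group summaries.

    Genes absent from the matrix are dropped and reported; an empty
    overlap is an error naming the set.
    """
    present = [g for g in gene_set if g in expr.matrix.index]
    missing = [g for g in gene_set if g not in expr.matrix.index]
    if not present:
        raise ValueError(f"gene set {name!r}: no genes found in the matrix")
    if missing:
        log.info("gene set %s: %d/%d genes missing from matrix",
                 name, len(missing), len(gene_set))
    scores = expr.matrix.loc[present].mean(axis=0)
    ann = pd.DataFrame(
        {
            "cell_type": expr.cell_type,
            "sample_id": expr.sample_id,
            "sample_class": expr.sample_class,
        }
    )
    return GeneSetScoreResult(
        gene_set_name=name,
        per_cell_scores=scores,
        genes_used=present,
        genes_missing=missing,
        by_cell_type=_summary(scores, ann[["cell_type", "sample_class"]]),
        by_sample=_summary(scores, ann[["sample_id", "sample_class", "cell_type"]]),
        annotations=ann,
    )


def score_relative_sd(
    result: GeneSetScoreResult, cell_type_filter: str, min_cells: int = 3
) -> pd.DataFrame:
    """Per-sample relative SD (SD/mean, sample SD with n-1 denominator) of
    per-cell scores within one cell type.

    Groups with fewer than ``min_cells`` cells or nonpositive mean are
    reported as missing.  Scale-invariant: multiplying the matrix by any
    c > 0 leaves the relative SD unchanged.
    """
    mask = result.annotations["cell_type"] == cell_type_filter
    if not mask.any():
        raise ValueError(f"no cells of type {cell_type_filter!r}")
    sub = result.by_sample[result.by_sample["cell_type"] == cell_type_filter].copy()
    bad = (sub["n"] < min_cells) | (sub["mean"] <= 0)
    if bad.any():
        log.warning("score_relative_sd: %d sample groups with < %d cells or "
                    "nonpositive mean set to missing", int(bad.sum()), min_cells)
        sub.loc[bad, "relative_sd"] = np.nan
    return sub[["sample_id", "sample_class", "n", "mean", "sd", "relative_sd"]].reset_index(
        drop=True
    )
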