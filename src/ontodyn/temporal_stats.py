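"""Descriptive temporal statistics: gene expression rank, per-age
summaries, and molecule-type mean-expression profiles.

The Gene Expression Rank (GER) places each age on a 1..n_ages scale per
gene: the age with the highest replicate-mean expression gets the top
rank, ties receive the average of the tied ranks, so every gene's rank
vector sums to n(n+1)/2 (78 for twelve ages).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .expression_filter import ExpressionCalls
from .io_tables import ExpressionMatrix, GeneAnnotation

__all__ = ["gene_expression_rank", "rank_matrix", "age_summaries",
           "type_profiles"]


def gene_expression_rank(series: np.ndarray) -> np.ndarray:
    """Tie-averaged ranks of a per-age expression series (1 = lowest)."""
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("series must be 1-dimensional")
    if not np.all(np.isfinite(series)):
        raise ValueError("series contains non-finite values")
    return stats.rankdata(series, method="average")


def rank_matrix(matrix: ExpressionMatrix,
                per_replicate: bool = False) -> np.ndarray:
    """GER for every feature; ranks are computed on per-age replicate
    means by default (per-replicate ranking available as an option,
    ranking each sample column then averaging within age)."""
    if per_replicate:
        ranks = stats.rankdata(matrix.values, method="average", axis=1)
        r = matrix.design.replicates_per_age
        cube = ranks.reshape(matrix.n_features, matrix.design.n_ages, r)
        # rescale sample ranks (1..n_samples) onto the 1..n_ages scale
        return (cube.mean(axis=2) - 0.5) / r + 0.5
    return stats.rankdata(matrix.age_means(), method="average", axis=1)


def age_summaries(matrix: ExpressionMatrix, calls: ExpressionCalls,
                  restrict: str = "analysis") -> pd.DataFrame:
    """Per-age summary statistics over the selected feature set.

    ``restrict`` chooses the averaging universe: ``"analysis"`` uses all
    analysis-genes at every age, ``"expressed"`` restricts each age's
    mean/SD to the genes called expressed at that age.  Both views are
    legitimate summaries of the same matrix; the returned frame is
    labelled with the choice.
    """
    if restrict not in ("analysis", "expressed"):
        raise ValueError("restrict must be 'analysis' or 'expressed'")
    keep = calls.is_analysis_gene
    if not keep.any():
        raise ValueError("empty analysis set")
    sub_ids = [f for f, k in zip(matrix.feature_ids, keep) if k]
    sub = matrix.subset(sub_ids)
    expressed = calls.expressed[keep]
    log2 = sub.log2_age_means()
    ranks = rank_matrix(sub)
    n_ages = sub.design.n_ages

    rows = []
    for j, age in enumerate(sub.design.ages):
        if restrict == "expressed":
            m = expressed[:, j]
            vals = log2[m, j] if m.any() else np.array([np.nan])
        else:
            vals = log2[:, j]
        rows.append({
            "age": age,
            "mean_log2_fpkm": float(np.mean(vals)),
            "sd_log2_fpkm": float(np.std(vals, ddof=1))
            if vals.size > 1 else 0.0,
            "n_expressed": int(expressed[:, j].sum()),
            "median_ger": float(np.median(ranks[:, j])),
            "sd_ger": float(np.std(ranks[:, j], ddof=1))
            if ranks.shape[0] > 1 else 0.0,
            "n_at_max_rank": int((ranks[:, j] == n_ages).sum()),
        })
    df = pd.DataFrame(rows).set_index("age")
    df.attrs["restrict"] = restrict
    return df


def type_profiles(matrix: ExpressionMatrix,
                  annotation: GeneAnnotation) -> pd.DataFrame:
    """Mean FPKM per molecule type and age (mean over genes of the
    replicate-mean FPKM); unannotated genes count as ``other``."""
    means = matrix.age_means()
    types = np.array([annotation.molecule_type_of(g)
                      for g in matrix.feature_ids])
    rows = {}
    for t in sorted(set(types)):
        rows[t] = means[types == t].mean(axis=0)
    df = pd.DataFrame(rows, index=pd.Index(matrix.design.ages, name="age"))
    return df.T.rename_axis("molecule_type")
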