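"""Two-stage selection of analysis-genes.

A feature enters the analysis set when it is (1) expressed above an
absolute FPKM threshold in at least one age and (2) significantly
differentially expressed over the age series.  The differential test is
a one-way ANOVA on log2(FPKM + 1) across ages with Benjamini-Hochberg
adjustment over all tested features; both stages are fully configurable
and recorded in the run manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import ExpressionMatrix

__all__ = ["ExpressionCalls", "call_expressed", "test_differential",
           "make_calls", "select_analysis_genes"]


@dataclass
class ExpressionCalls:
    """Per-feature expression and differential calls."""

    feature_ids: list[str]
    expressed: np.ndarray            # (n_features, n_ages) bool
    p: np.ndarray                    # ANOVA p-values
    q: np.ndarray                    # BH-adjusted
    alpha: float
    theta_fpkm: float
    min_replicates: int

    @property
    def expressed_any_age(self) -> np.ndarray:
        return self.expressed.any(axis=1)

    @property
    def is_differential(self) -> np.ndarray:
        return self.q <= self.alpha

    @property
    def is_analysis_gene(self) -> np.ndarray:
        return self.expressed_any_age & self.is_differential

    def to_frame(self, ages: tuple[float, ...] | None = None) -> pd.DataFrame:
        df = pd.DataFrame({
            "n_ages_expressed": self.expressed.sum(axis=1),
            "p": self.p,
            "q": self.q,
            "is_differential": self.is_differential,
            "is_analysis_gene": self.is_analysis_gene,
        }, index=pd.Index(self.feature_ids, name="feature_id"))
        if ages is not None:
            for j, a in enumerate(ages):
                df[f"expressed_d{int(a) if float(a).is_integer() else a}"] = \
                    self.expressed[:, j]
        return df


def call_expressed(matrix: ExpressionMatrix, theta_fpkm: float = 1.0,
                   min_replicates: int = 2) -> np.ndarray:
    """Expressed(feature, age) iff at least ``min_replicates`` replicate
    FPKM values at that age reach ``theta_fpkm``."""
    if theta_fpkm < 0:
        raise ValueError("theta_fpkm must be >= 0")
    r = matrix.design.replicates_per_age
    if not 1 <= min_replicates <= r:
        raise ValueError(f"min_replicates must be in [1, {r}]")
    cube = matrix.values.reshape(matrix.n_features, matrix.design.n_ages, r)
    return (cube >= theta_fpkm).sum(axis=2) >= min_replicates


def test_differential(matrix: ExpressionMatrix, alpha: float = 0.05
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One-way ANOVA of log2(FPKM + 1) across ages, BH-adjusted.

    Returns (p, q, is_differential).  A feature whose within-age variance
    is zero in every age is handled explicitly: p = 0 when the age means
    still differ, p = 1 when the series is flat everywhere.
    """
    r = matrix.design.replicates_per_age
    if r < 2:
        raise ValueError("differential test needs >= 2 replicates per age")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    n_ages = matrix.design.n_ages
    x = matrix.log2_values().reshape(matrix.n_features, n_ages, r)
    group_means = x.mean(axis=2)
    grand = x.mean(axis=(1, 2))
    ssb = r * ((group_means - grand[:, None]) ** 2).sum(axis=1)
    ssw = ((x - group_means[:, :, None]) ** 2).sum(axis=(1, 2))
    dfb, dfw = n_ages - 1, n_ages * (r - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / dfb) / (ssw / dfw)
    p = np.where(ssw > 0, stats.f.sf(f, dfb, dfw), np.nan)
    degenerate = ssw == 0
    p[degenerate & (ssb > 0)] = 0.0
    p[degenerate & (ssb == 0)] = 1.0
    from .enrichment import bh_adjust
    q = bh_adjust(p)
    return p, q, q <= alpha


def make_calls(matrix: ExpressionMatrix, theta_fpkm: float = 1.0,
               min_replicates: int = 2, alpha: float = 0.05
               ) -> ExpressionCalls:
    expressed = call_expressed(matrix, theta_fpkm, min_replicates)
    p, q, _ = test_differential(matrix, alpha)
    return ExpressionCalls(list(matrix.feature_ids), expressed, p, q,
                           alpha, theta_fpkm, min_replicates)


def select_analysis_genes(calls: ExpressionCalls) -> list[str]:
    """Features expressed in >= 1 age AND differential at level alpha."""
    mask = calls.is_analysis_gene
    return [f for f, m in zip(calls.feature_ids, mask) if m]
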