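"""Latent temporal factors and the six temporal groups.

The gene x age matrix of standardized age-mean series is factor analyzed
on its age x age correlation structure, so the (varimax-rotated) loading
columns are temporal profiles.  Genes are then assigned to the factor
whose loading profile they correlate with most strongly, provided the
absolute Pearson correlation reaches the cutoff (default 0.7); the sign
of the correlation splits each factor into an expression (+) and a
suppression (-) sub-cluster, giving six temporal groups for a
three-factor solution.

Factor extraction is iterative principal-axis factoring: communalities
start at squared multiple correlations and are re-estimated from the
leading eigenpairs of the reduced correlation matrix until they settle.
A maximum-likelihood fit tends to be fragile with only twelve observed
variables, so it is not offered here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from statsmodels.multivariate.factor_rotation import rotate_factors

from .io_tables import ExpressionMatrix

__all__ = [
    "FactorModel", "TemporalAssignment", "ConvergenceError",
    "standardize_series", "horn_parallel_analysis", "fit_factor_model",
    "assign_temporal_groups", "hier_cluster_order", "GROUP_LABEL_MAP",
]

#: (position among factors ordered by loading-peak age, correlation sign)
#: -> temporal group label, for a three-factor solution.
GROUP_LABEL_MAP = {
    (0, +1): "Prenatal and Neonatal", (0, -1): "Adolescent and Adult",
    (1, +1): "Neonatal and Adolescent", (1, -1): "Prenatal and Adult",
    (2, +1): "Adult", (2, -1): "Neonatal",
}


class ConvergenceError(RuntimeError):
    """Principal-axis communality iteration failed to settle."""

    def __init__(self, iterations: int, delta: float):
        self.iterations = iterations
        self.delta = delta
        super().__init__(
            f"communalities did not converge in {iterations} iterations "
            f"(last change {delta:.3e})")


@dataclass
class FactorModel:
    """Varimax-rotated common-factor solution over the age series."""

    k: int
    ages: tuple[float, ...]
    loadings: np.ndarray        # (n_ages, k)
    eigenvalues: np.ndarray     # of the age correlation matrix, descending
    communalities: np.ndarray   # per age
    n_iter: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.loadings,
                          index=pd.Index(self.ages, name="age"),
                          columns=[f"factor{j + 1}" for j in range(self.k)])
        df["communality"] = self.communalities
        return df


@dataclass
class TemporalAssignment:
    """Per-gene factor membership and temporal group label."""

    table: pd.DataFrame  # index feature_id; factor, r, sign, label, assigned

    @property
    def labels(self) -> pd.Series:
        return self.table["label"]

    def genes_in_group(self, label: str) -> list[str]:
        return list(self.table.index[self.table["label"] == label])

    @property
    def n_assigned(self) -> int:
        return int(self.table["assigned"].sum())


def standardize_series(x: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Zero-mean, unit-SD rows; zero-variance rows come back all-NaN."""
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, ddof=ddof, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (x - mu) / sd


def _corr_eigenvalues(x: np.ndarray) -> np.ndarray:
    """Descending eigenvalues of the column-correlation matrix of x."""
    r = np.corrcoef(x, rowvar=False)
    return np.sort(np.linalg.eigvalsh(r))[::-1]


def horn_parallel_analysis(matrix: np.ndarray, n_sim: int = 200,
                           quantile: float = 0.95,
                           seed: int | np.random.Generator = 0
                           ) -> tuple[int, np.ndarray, np.ndarray]:
    """Choose the number of factors by Horn's parallel analysis.

    ``matrix`` is the gene x age table of (standardized) series.  The
    observed eigenvalues of the age correlation matrix are compared,
    rank by rank, with the chosen quantile of eigenvalues from ``n_sim``
    same-shaped standard-normal matrices; k is the length of the leading
    run of observed eigenvalues exceeding their simulated quantile.

    Returns (k, observed eigenvalues, simulated thresholds).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] < 3:
        raise ValueError("matrix must be 2-D with >= 3 ages")
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    if not 0.5 < quantile < 1:
        raise ValueError("quantile must be in (0.5, 1)")
    rng = np.random.default_rng(seed)
    observed = _corr_eigenvalues(matrix)
    sims = np.empty((n_sim, matrix.shape[1]))
    for s in range(n_sim):
        sims[s] = _corr_eigenvalues(rng.normal(size=matrix.shape))
    thresholds = np.quantile(sims, quantile, axis=0)
    exceed = observed > thresholds
    k = int(np.argmin(exceed)) if not exceed.all() else len(observed)
    return k, observed, thresholds


def _principal_axis(corr: np.ndarray, k: int, maxiter: int, tol: float
                    ) -> tuple[np.ndarray, np.ndarray, int]:
    """Iterative PAF on a correlation matrix; returns (loadings,
    communalities, n_iter)."""
    p = corr.shape[0]
    # SMC start; pinv guards exactly singular correlation structure
    precision_diag = np.diag(np.linalg.pinv(corr))
    with np.errstate(divide="ignore"):
        comm = np.clip(1.0 - 1.0 / precision_diag, 0.0, 1.0)
    loadings = np.zeros((p, k))
    for it in range(1, maxiter + 1):
        reduced = corr.copy()
        np.fill_diagonal(reduced, comm)
        eigval, eigvec = np.linalg.eigh(reduced)
        order = np.argsort(eigval)[::-1][:k]
        lam = np.clip(eigval[order], 0.0, None)
        loadings = eigvec[:, order] * np.sqrt(lam)
        new_comm = np.clip((loadings ** 2).sum(axis=1), 0.0, 1.0)
        delta = float(np.max(np.abs(new_comm - comm)))
        comm = new_comm
        if delta < tol:
            return loadings, comm, it
    raise ConvergenceError(maxiter, delta)


def fit_factor_model(matrix: np.ndarray | ExpressionMatrix, k: int,
                     ages: tuple[float, ...] | None = None,
                     maxiter: int = 2000, tol: float = 1e-9) -> FactorModel:
    """Fit a varimax-rotated principal-axis factor model.

    ``matrix`` is the gene x age table (an :class:`ExpressionMatrix` is
    reduced to standardized log2 age means first).  Loading columns are
    temporal profiles; communalities are invariant under the orthogonal
    rotation.
    """
    if isinstance(matrix, ExpressionMatrix):
        ages = matrix.design.ages
        matrix = standardize_series(matrix.log2_age_means())
        matrix = matrix[~np.isnan(matrix).any(axis=1)]
    matrix = np.asarray(matrix, dtype=float)
    n_ages = matrix.shape[1]
    if ages is None:
        ages = tuple(float(j) for j in range(n_ages))
    if not 1 <= k < n_ages:
        raise ValueError(f"k must be in [1, {n_ages - 1}], got {k}")
    corr = np.corrcoef(matrix, rowvar=False)
    eigenvalues = np.sort(np.linalg.eigvalsh(corr))[::-1]
    loadings, comm, n_iter = _principal_axis(corr, k, maxiter, tol)
    if k > 1:
        loadings, _ = rotate_factors(loadings, "varimax")
    loadings = _canonicalize_loadings(loadings)
    return FactorModel(k=k, ages=tuple(ages), loadings=loadings,
                       eigenvalues=eigenvalues, communalities=comm,
                       n_iter=n_iter)


def _canonicalize_loadings(loadings: np.ndarray) -> np.ndarray:
    """Resolve the rotation's sign and order ambiguity.

    Factor order and sign carry no information after an orthogonal
    rotation, so they are fixed deterministically.  For a three-factor
    solution the columns are matched to three temporal templates over
    the sampling positions -- a declining ramp (early programme), a
    central tent (mid programme) and a rising ramp (late programme) --
    by the bijection maximizing total absolute correlation; each column
    is oriented so its template correlation is positive.  This anchors
    the early/mid/late identity of the factors to the shape of the whole
    loading profile rather than to a single peak age, which is fragile
    when factors cross-load.  For other factor counts, columns are
    oriented so the sum of cubed loadings is positive and ordered by
    peak position.
    """
    loads = loadings.copy()
    n, k = loads.shape
    if k == 3:
        # The early programme is maximal at the first age and the late
        # programme at the last, so those two extremes anchor factor
        # identity: the (column, sign) candidate loading highest at the
        # first age becomes the oriented early factor, the highest at
        # the last age (among the remaining columns) the late factor,
        # and the leftover column is oriented so its interior lobe is
        # positive (the mid programme peaks between the extremes).
        candidates = {(j, s): s * loads[:, j]
                      for j in range(3) for s in (1.0, -1.0)}
        early_j, early_s = max(candidates,
                               key=lambda key: candidates[key][0])
        late_j, late_s = max(
            (key for key in candidates if key[0] != early_j),
            key=lambda key: candidates[key][-1])
        (mid_j,) = set(range(3)) - {early_j, late_j}
        interior = slice(1, n - 1)
        mid_s = max((1.0, -1.0),
                    key=lambda s: (s * loads[interior, mid_j]).max())
        order = [early_j, mid_j, late_j]
        signs = np.array([early_s, mid_s, late_s])
        return loads[:, order] * signs
    for j in range(k):
        if (loads[:, j] ** 3).sum() < 0:
            loads[:, j] *= -1
    order = np.argsort(loads.argmax(axis=0), kind="stable")
    return loads[:, order]


def assign_temporal_groups(matrix: np.ndarray | ExpressionMatrix,
                           model: FactorModel, cutoff: float = 0.7,
                           feature_ids: list[str] | None = None
                           ) -> TemporalAssignment:
    """Correlate each gene's standardized age-mean series with every
    loading profile and assign it to the argmax-|r| factor when
    |r| >= cutoff.

    For a three-factor model, (factor position by peak age, sign of r)
    maps onto the six temporal group labels; other factor counts get
    generic ``factor{i}{+|-}`` labels.  Zero-variance series are left
    unassigned and flagged.
    """
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must be in (0, 1]")
    if isinstance(matrix, ExpressionMatrix):
        feature_ids = list(matrix.feature_ids)
        series = standardize_series(matrix.log2_age_means())
    else:
        series = standardize_series(np.asarray(matrix, dtype=float))
        if feature_ids is None:
            feature_ids = [f"row{i}" for i in range(series.shape[0])]
    if series.shape[1] != len(model.ages):
        raise ValueError("series and model cover different age sets")

    zstd = standardize_series(model.loadings.T)  # (k, n_ages)
    n = series.shape[1]
    flagged = np.isnan(series).any(axis=1)
    safe = np.nan_to_num(series)
    r = safe @ zstd.T / (n - 1)                  # Pearson r per gene, factor

    best = np.abs(r).argmax(axis=1)
    r_best = r[np.arange(len(best)), best]
    assigned = (np.abs(r_best) >= cutoff) & ~flagged

    labels = []
    for i in range(len(best)):
        if not assigned[i]:
            labels.append("unassigned")
            continue
        key = (int(best[i]), 1 if r_best[i] >= 0 else -1)
        if model.k == 3:
            labels.append(GROUP_LABEL_MAP[key])
        else:
            labels.append(f"factor{key[0] + 1}{'+' if key[1] > 0 else '-'}")
    table = pd.DataFrame({
        "factor": np.where(assigned, best + 1, 0),
        "r": np.where(flagged, np.nan, r_best),
        "sign": np.where(assigned, np.sign(r_best).astype(int), 0),
        "label": labels,
        "assigned": assigned,
        "zero_variance": flagged,
    }, index=pd.Index(feature_ids, name="feature_id"))
    return TemporalAssignment(table)


def hier_cluster_order(rows: np.ndarray, distance: str = "euclidean",
                       method: str = "ward"
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic agglomerative clustering of row vectors.

    Returns (leaf order, linkage matrix).  Ward linkage is only defined
    for Euclidean distance; requesting it with correlation distance is
    an error.
    """
    rows = np.asarray(rows, dtype=float)
    if rows.ndim != 2 or rows.shape[0] < 2:
        raise ValueError("need >= 2 rows to cluster")
    if distance not in ("euclidean", "correlation"):
        raise ValueError(f"unsupported distance {distance!r}")
    if method not in ("ward", "average"):
        raise ValueError(f"unsupported linkage {method!r}")
    if method == "ward" and distance != "euclidean":
        raise ValueError("ward linkage requires euclidean distance")
    d = pdist(rows, metric=distance)
    z = linkage(d, method=method)
    return leaves_list(z), z
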