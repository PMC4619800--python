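"""Set-association statistics.

Right-tailed Fisher / hypergeometric overlap tests (computed in log
space), chi-square independence, Benjamini-Hochberg adjustment, the
sign-consistency activation z-score for upstream regulators, and the
regulator x temporal-group hit-count matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .factor_clustering import TemporalAssignment
from .io_tables import ExpressionMatrix, RegulatorNetwork

__all__ = [
    "EnrichmentResult", "hypergeom_overlap", "fisher_right_tail",
    "chi_square_independence", "activation_z", "bh_adjust",
    "hit_count_matrix", "differential_direction", "group_overlap_table",
]

P_CUTOFF = 0.05          # association significance
Z_CUTOFF = 2.0           # |activation z| significance


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    k: int              # overlap
    K: int              # term size
    n: int              # query size
    N: int              # universe size
    p: float
    q: float | None = None
    z: float | None = None

    @property
    def significant_association(self) -> bool:
        return self.p <= P_CUTOFF

    @property
    def significant_activation(self) -> bool:
        return self.z is not None and abs(self.z) >= Z_CUTOFF


def hypergeom_overlap(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    The tail is accumulated in log space for numerical stability at the
    extreme overlaps the regulator tables produce.
    """
    if min(N, K, n, k) < 0 or K > N or n > N:
        raise ValueError(f"infeasible counts N={N}, K={K}, n={n}, k={k}")
    hi = min(K, n)
    if k > hi:
        raise ValueError(f"k={k} exceeds min(K, n)={hi}")
    if k <= max(0, K + n - N):
        return 1.0
    support = np.arange(k, hi + 1)
    logp = stats.hypergeom.logpmf(support, N, K, n)
    return float(min(1.0, np.exp(logsumexp(logp))))


def fisher_right_tail(query: set[str], term: set[str],
                      universe: set[str], term_id: str = ""
                      ) -> EnrichmentResult:
    """Right-tailed Fisher's exact test on the 2x2 membership table.

    The right tail of Fisher's exact test is the hypergeometric upper
    tail on the same counts, so this shares :func:`hypergeom_overlap`.
    """
    if not universe:
        raise ValueError("empty universe")
    if not query <= universe or not term <= universe:
        raise ValueError("query and term must be subsets of the universe")
    N, K, n = len(universe), len(term), len(query)
    k = len(query & term)
    return EnrichmentResult(term_id=term_id, k=k, K=K, n=n, N=N,
                            p=hypergeom_overlap(N, K, n, k))


def chi_square_independence(table: np.ndarray | pd.DataFrame) -> float:
    """Pearson chi-square p-value for independence of rows and columns."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or min(arr.shape) < 2:
        raise ValueError("contingency table must be at least 2x2")
    if arr.sum() <= 0 or np.any(arr < 0):
        raise ValueError("table must hold non-negative counts")
    expected = stats.contingency.expected_freq(arr)
    if np.any(expected < 1):
        raise ValueError("expected count < 1; use an exact test instead")
    _, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return float(p)


def activation_z(observed: dict[str, int], expected: dict[str, int]) -> float:
    """Sign-consistency activation z-score.

    ``observed`` maps targets to their direction of change (+1/-1) and
    ``expected`` to the direction the regulator's edges predict; targets
    with expected direction 0 (unknown sign) are excluded.  Over the N
    remaining targets, z = sum(s_i) / sqrt(N) with s_i = +1 on agreement
    and -1 on disagreement, so a fully consistent regulator scores
    sqrt(N).
    """
    s = []
    for target, direction in expected.items():
        if direction == 0 or target not in observed:
            continue
        obs = observed[target]
        if obs not in (-1, 1):
            raise ValueError(f"observed direction for {target!r} must be "
                             f"+1 or -1, got {obs}")
        s.append(1 if obs == direction else -1)
    if not s:
        raise ValueError("no targets with a known expected direction")
    return float(sum(s) / np.sqrt(len(s)))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests
    flat = p.ravel()
    _, q, _, _ = multipletests(flat, method="fdr_bh")
    return q.reshape(p.shape)


def differential_direction(matrix: ExpressionMatrix) -> np.ndarray:
    """Per-gene, per-age direction of change: the sign of the gene's
    log2 expression at an age relative to its average over all ages
    (i.e. expression divided by the gene's own across-age mean)."""
    log2 = matrix.log2_age_means()
    rel = log2 - log2.mean(axis=1, keepdims=True)
    return np.sign(rel).astype(int)


def hit_count_matrix(network: RegulatorNetwork,
                     assignment: TemporalAssignment,
                     group_labels: list[str] | None = None) -> pd.DataFrame:
    """Regulator x temporal-group counts of targeted assigned genes."""
    if group_labels is None:
        group_labels = sorted(set(assignment.labels) - {"unassigned"})
    label_of = assignment.labels
    rows = {}
    for reg in sorted(network.regulators):
        counts = dict.fromkeys(group_labels, 0)
        for tgt in network.targets_of(reg):
            if tgt in label_of.index:
                lab = label_of[tgt]
                if lab in counts:
                    counts[lab] += 1
        rows[reg] = counts
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=group_labels).fillna(0).astype(int)


def group_overlap_table(group_sets: dict[str, set[str]],
                        universe_size: int) -> pd.DataFrame:
    """All pairwise upper-tail hypergeometric overlaps between per-group
    regulator sets drawn from a common regulator universe."""
    names = list(group_sets)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            sa, sb = group_sets[a], group_sets[b]
            k = len(sa & sb)
            rows.append({
                "period_1": a, "period_2": b, "universe": universe_size,
                "overlap": k, "size_1": len(sa), "size_2": len(sb),
                "p": hypergeom_overlap(universe_size, len(sa), len(sb), k),
            })
    return pd.DataFrame(rows).sort_values("p").reset_index(drop=True)
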