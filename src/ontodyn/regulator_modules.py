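"""Iterative discovery of upstream regulatory modules.

A module is a set of >= 2 regulators whose standardized expression
series agree (or are diametrically opposed) by intraclass correlation,
and which share a minimum number of downstream target genes inside the
temporal group under analysis.  Discovery starts from singleton
(regulator, targets) entries, forms all valid pairs, and keeps merging
pairs that involve a newly added entry until a cycle adds nothing.

Agreement is measured by an ANOVA-style intraclass correlation after
each series is reduced to a common scale (centered and scaled to unit
variance, the anchor-point adjustment), so a pair of perfectly opposite
series scores -1 rather than 0: anti-correlated modules are first-class
citizens here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .factor_clustering import standardize_series
from .io_tables import ExpressionMatrix, RegulatorNetwork

__all__ = ["RegulatoryModule", "icc_winer", "find_modules",
           "summarize_modules", "validate_module"]

logger = logging.getLogger(__name__)

ICC_CUTOFF = 0.6
MIN_TARGETS = 5


@dataclass(frozen=True)
class RegulatoryModule:
    regulators: frozenset[str]
    targets: frozenset[str]
    icc: float

    def __post_init__(self) -> None:
        if len(self.regulators) < 2:
            raise ValueError("a module needs >= 2 regulators")


def icc_winer(series_set: np.ndarray) -> float:
    """Intraclass correlation of m standardized series over n ages.

    Each series is centered and scaled to unit variance (the anchor
    adjustment), then a two-way decomposition over ages gives
    ``ICC = (MSB - MSE) / (MSB + (m - 1) * MSE)`` with MSB the
    between-age mean square of the per-age means and MSE the residual
    mean square.  The result lies in [-1, 1]; for m = 2 it equals the
    Pearson correlation of the two standardized series.
    """
    x = np.asarray(series_set, dtype=float)
    if x.ndim != 2:
        raise ValueError("series_set must be a 2-D (m, n) array")
    m, n = x.shape
    if m < 2:
        raise ValueError("need at least 2 series")
    if n < 3:
        raise ValueError("series must cover at least 3 ages")
    if np.any(x.std(axis=1) == 0):
        raise ValueError("zero-variance series")
    z = standardize_series(x)
    col_means = z.mean(axis=0)
    msb = m * (col_means ** 2).sum() / (n - 1)
    sse = ((z - col_means) ** 2).sum()
    mse = sse / ((n - 1) * (m - 1))
    icc = (msb - mse) / (msb + (m - 1) * mse)
    return float(np.clip(icc, -1.0, 1.0))


def _regulator_series(regulator_expression: ExpressionMatrix
                      ) -> dict[str, np.ndarray]:
    means = regulator_expression.log2_age_means()
    return {rid: means[i]
            for i, rid in enumerate(regulator_expression.feature_ids)}


def find_modules(network: RegulatorNetwork,
                 regulator_expression: ExpressionMatrix,
                 group_genes: set[str],
                 icc_cutoff: float = ICC_CUTOFF,
                 min_targets: int = MIN_TARGETS,
                 min_targets_throughout: bool = True
                 ) -> list[RegulatoryModule]:
    """Discover regulatory modules for one temporal group.

    Cycle 0 seeds one entry per regulator (its targets intersected with
    the group).  Cycle 1 merges all pairs of seeds; every later cycle
    merges all pairs involving at least one entry added in the previous
    cycle.  A merge (union of regulators, intersection of targets) is
    kept when |ICC| of the merged regulators reaches ``icc_cutoff`` and,
    unless ``min_targets_throughout`` is relaxed to pair-formation only,
    the intersected target set keeps at least ``min_targets`` genes.
    Entries are de-duplicated by regulator set; merging terminates when
    a cycle adds nothing.

    Regulators in the network without an expression series are excluded
    with a logged warning.
    """
    if not group_genes:
        raise ValueError("group_genes must be nonempty")
    if not 0 < icc_cutoff <= 1:
        raise ValueError("icc_cutoff must be in (0, 1]")
    series = _regulator_series(regulator_expression)
    regulators = sorted(network.regulators)
    missing = [r for r in regulators if r not in series]
    if missing:
        logger.warning("excluding %d regulator(s) without expression: %s",
                       len(missing), ", ".join(missing))
    regulators = [r for r in regulators if r in series]
    constant = [r for r in regulators if np.std(series[r]) == 0]
    if constant:
        logger.warning("excluding %d constant-expression regulator(s): %s",
                       len(constant), ", ".join(constant))
        regulators = [r for r in regulators if r not in constant]

    seed_targets = {r: frozenset(network.targets_of(r) & group_genes)
                    for r in regulators}

    icc_cache: dict[frozenset[str], float] = {}

    def icc_of(regs: frozenset[str]) -> float:
        if regs not in icc_cache:
            stack = np.vstack([series[r] for r in sorted(regs)])
            icc_cache[regs] = icc_winer(stack)
        return icc_cache[regs]

    entries: dict[frozenset[str], frozenset[str]] = {
        frozenset({r}): seed_targets[r] for r in regulators}
    new = list(entries.items())

    while new:
        added: dict[frozenset[str], frozenset[str]] = {}
        all_items = sorted(entries.items(),
                           key=lambda kv: tuple(sorted(kv[0])))
        new_keys = {k for k, _ in new}
        for regs_b, tgts_b in sorted(new, key=lambda kv: tuple(sorted(kv[0]))):
            for regs_a, tgts_a in all_items:
                if regs_a == regs_b:
                    continue
                # avoid double-visiting new x new pairs
                if regs_a in new_keys and tuple(sorted(regs_a)) > \
                        tuple(sorted(regs_b)):
                    continue
                merged_regs = regs_a | regs_b
                if merged_regs in entries or merged_regs in added:
                    continue
                merged_tgts = tgts_a & tgts_b
                is_pair = len(merged_regs) == 2
                if (min_targets_throughout or is_pair) and \
                        len(merged_tgts) < min_targets:
                    continue
                if abs(icc_of(merged_regs)) < icc_cutoff:
                    continue
                added[merged_regs] = merged_tgts
        entries.update(added)
        new = list(added.items())

    out = [RegulatoryModule(regs, tgts, icc_of(regs))
           for regs, tgts in entries.items() if len(regs) >= 2]
    out.sort(key=lambda m: (-len(m.regulators), tuple(sorted(m.regulators))))
    return out


def validate_module(module: RegulatoryModule,
                    network: RegulatorNetwork,
                    regulator_expression: ExpressionMatrix,
                    group_genes: set[str],
                    icc_cutoff: float = ICC_CUTOFF,
                    min_targets: int = MIN_TARGETS) -> bool:
    """Independent post-hoc check that a module satisfies the discovery
    constraints exactly (recomputing ICC and the target intersection)."""
    series = _regulator_series(regulator_expression)
    if any(r not in series for r in module.regulators):
        return False
    stack = np.vstack([series[r] for r in sorted(module.regulators)])
    icc = icc_winer(stack)
    shared: frozenset[str] | None = None
    for r in module.regulators:
        t = frozenset(network.targets_of(r) & group_genes)
        shared = t if shared is None else shared & t
    return (abs(icc) >= icc_cutoff and shared == module.targets
            and len(module.targets) >= min_targets
            and abs(icc - module.icc) < 1e-12)


def summarize_modules(modules: list[RegulatoryModule]) -> pd.DataFrame:
    """Per-module size, target count, ICC and correlation sign."""
    rows = [{
        "regulators": "|".join(sorted(m.regulators)),
        "size": len(m.regulators),
        "n_targets": len(m.targets),
        "icc": m.icc,
        "sign": "anti-correlated" if m.icc < 0 else "correlated",
    } for m in modules]
    return pd.DataFrame(rows, columns=["regulators", "size", "n_targets",
                                       "icc", "sign"])
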