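"""Transcript-level analyses.

Three pieces: a homogeneity test for shifts in the relative usage of a
gene's known splice variants across ages; a Durbin-Watson filter that
keeps novel-isoform candidates whose expression is coherent in time
rather than white noise (significance by permutation of the age order,
Benjamini-Hochberg adjusted); and a rule-based classifier of the splice
event distinguishing a novel transcript from its reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.stattools import durbin_watson as _sm_dw

from .enrichment import bh_adjust
from .expression_filter import ExpressionCalls
from .io_tables import ExpressionMatrix, TranscriptModel

__all__ = [
    "IsoformRecord", "SpliceEvent", "variant_usage_test", "durbin_watson",
    "dw_pvalue", "dw_pvalues_batch", "filter_novel_isoforms",
    "classify_splice_event",
]


@dataclass
class IsoformRecord:
    transcript_id: str
    gene_id: str
    series: np.ndarray          # per-age mean FPKM
    dw: float
    p_dw: float
    q_dw: float | None = None
    passes_filter: bool = False


@dataclass(frozen=True)
class SpliceEvent:
    event_type: str
    coordinates: tuple[tuple[int, int], ...]
    reference_id: str


# ---------------------------------------------------------------------------
# known-variant usage

def variant_usage_test(table: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Chi-square homogeneity test on a transcript x age FPKM table.

    The table of per-age mean FPKM is treated as weighted usage shares:
    each age column contributes its proportions weighted by the total
    expression at that age, which is exactly the Pearson chi-square on
    the raw table.  Returns (statistic, p, standardized residuals); a
    small p means variant usage shifts with age.  All-zero variants and
    ages are dropped first; a gene that reduces to a single variant
    carries no usage signal and returns p = 1.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need a 2-D table with >= 2 transcripts")
    if np.any(arr < 0):
        raise ValueError("FPKM values must be non-negative")
    if (arr.sum(axis=0) > 0).sum() < 2:
        raise ValueError("total expression must be positive at >= 2 ages")
    arr = arr[arr.sum(axis=1) > 0][:, arr.sum(axis=0) > 0]
    if arr.shape[0] < 2:
        return 0.0, 1.0, np.zeros_like(arr)
    expected = stats.contingency.expected_freq(arr)
    residuals = (arr - expected) / np.sqrt(expected)
    statistic = float((residuals ** 2).sum())
    dof = (arr.shape[0] - 1) * (arr.shape[1] - 1)
    return statistic, float(stats.chi2.sf(statistic, dof)), residuals


# ---------------------------------------------------------------------------
# Durbin-Watson filtering

def durbin_watson(series: np.ndarray) -> float:
    """Durbin-Watson statistic of a mean-centered per-age series.

    d = sum_t (e_t - e_{t-1})^2 / sum_t e_t^2 with e the residuals from
    the series mean; d is ~2 for white noise and < 2 under positive
    autocorrelation.  No regression model is posited, so centering is
    the residual definition.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("series must be 1-D with length >= 3")
    e = x - x.mean()
    if np.all(e == 0):
        raise ValueError("constant series has no Durbin-Watson statistic")
    return float(_sm_dw(e))


def _dw_rows(values: np.ndarray) -> np.ndarray:
    e = values - values.mean(axis=1, keepdims=True)
    num = (np.diff(e, axis=1) ** 2).sum(axis=1)
    den = (e ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return num / den


def dw_pvalue(series: np.ndarray, n_perm: int = 999,
              seed: int | np.random.Generator = 0) -> float:
    """One-sided permutation p-value for positive autocorrelation.

    The age order is permuted ``n_perm`` times;
    p = (1 + #{permuted d <= observed d}) / (n_perm + 1), so p is never
    below 1 / (n_perm + 1).  The classical regression-based bounds do
    not apply to a 12-point mean-centered series, hence the exchange
    null.
    """
    if n_perm < 999:
        raise ValueError("n_perm must be >= 999")
    x = np.asarray(series, dtype=float)
    observed = durbin_watson(x)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(x) for _ in range(n_perm)])
    d = _dw_rows(perms)
    return float((1 + (d <= observed).sum()) / (n_perm + 1))


def dw_pvalues_batch(series_matrix: np.ndarray, n_perm: int = 999,
                     seed: int | np.random.Generator = 0) -> np.ndarray:
    """Vectorized :func:`dw_pvalue` over rows (independent permutations
    per row)."""
    if n_perm < 999:
        raise ValueError("n_perm must be >= 999")
    x = np.asarray(series_matrix, dtype=float)
    observed = _dw_rows(x)
    rng = np.random.default_rng(seed)
    count = np.zeros(x.shape[0], dtype=int)
    for _ in range(n_perm):
        order = np.argsort(rng.random(x.shape), axis=1)
        d = _dw_rows(np.take_along_axis(x, order, axis=1))
        count += d <= observed
    return (1 + count) / (n_perm + 1)


def filter_novel_isoforms(matrix: ExpressionMatrix, calls: ExpressionCalls,
                          gene_of: dict[str, str] | None = None,
                          alpha: float = 0.05, n_perm: int = 999,
                          seed: int | np.random.Generator = 0
                          ) -> list[IsoformRecord]:
    """Two-stage novel-isoform filter.

    Stage 1 keeps candidates significantly expressed in at least one
    age; stage 2 applies the Durbin-Watson permutation test to the
    stage-1 survivors only, adjusts with Benjamini-Hochberg across
    them, and keeps q <= alpha.  Candidates whose series is constant
    carry no temporal signal and are dropped at stage 2.
    """
    if list(calls.feature_ids) != list(matrix.feature_ids):
        raise ValueError("calls and matrix cover different features")
    gene_of = gene_of or {}
    means = matrix.age_means()
    stage1 = calls.expressed_any_age
    records: list[IsoformRecord] = []
    testable: list[int] = []
    for i, tid in enumerate(matrix.feature_ids):
        rec = IsoformRecord(tid, gene_of.get(tid, tid), means[i],
                            np.nan, np.nan)
        records.append(rec)
        if stage1[i] and np.ptp(means[i]) > 0:
            testable.append(i)
    if testable:
        sub = means[testable]
        dws = _dw_rows(sub)
        ps = dw_pvalues_batch(sub, n_perm=n_perm, seed=seed)
        qs = bh_adjust(ps)
        for j, i in enumerate(testable):
            records[i].dw = float(dws[j])
            records[i].p_dw = float(ps[j])
            records[i].q_dw = float(qs[j])
            records[i].passes_filter = bool(qs[j] <= alpha)
    return records


# ---------------------------------------------------------------------------
# splice-event classification

def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _covers(outer: tuple[int, int], inner: tuple[int, int]) -> bool:
    return outer[0] <= inner[0] and inner[1] <= outer[1]


def _tx_start(model: TranscriptModel) -> int:
    return model.exons[0][0] if model.strand == "+" else model.exons[-1][1]


def _tx_end(model: TranscriptModel) -> int:
    return model.exons[-1][1] if model.strand == "+" else model.exons[0][0]


def classify_splice_event(novel: TranscriptModel,
                          references: list[TranscriptModel]
                          ) -> list[SpliceEvent]:
    """Classify the splice events separating a novel transcript from its
    best-matching reference.

    The reference sharing the most splice junctions wins (ties broken
    by shared exon-boundary count, then by transcript id).  Rules, all
    on 0-based half-open intervals:

    * a novel intron spanning a complete internal reference exon, with
      the flanking junctions joined -> ``exon_skip`` at that exon;
    * a novel exon covering a complete reference intron ->
      ``intron_retention`` at that intron;
    * an internal novel exon overlapping no reference exon ->
      ``alternative_exon``;
    * a differing transcription-start boundary -> ``alt_start`` and a
      differing termination boundary -> ``alt_termination``, both read
      in transcription direction, not genomic left/right.

    Several events may co-occur; with no usable reference the single
    event ``unclassified`` is returned.
    """
    candidates = [r for r in references
                  if r.chrom == novel.chrom and r.strand == novel.strand]
    if not candidates:
        return [SpliceEvent("unclassified", (novel.span,),
                            novel.transcript_id)]

    def match_score(ref: TranscriptModel) -> tuple[int, int, str]:
        shared_junc = len(novel.junctions & ref.junctions)
        nb = {b for ex in novel.exons for b in ex}
        rb = {b for ex in ref.exons for b in ex}
        return (shared_junc, len(nb & rb), ref.transcript_id)

    ref = max(candidates, key=lambda r: (match_score(r)[0], match_score(r)[1],
                                         r.transcript_id))
    events: list[SpliceEvent] = []

    for exon in ref.exons[1:-1]:
        if any(_covers(intron, exon) for intron in novel.introns):
            events.append(SpliceEvent("exon_skip", (exon,),
                                      ref.transcript_id))
    for intron in ref.introns:
        if any(_covers(exon, intron) for exon in novel.exons):
            events.append(SpliceEvent("intron_retention", (intron,),
                                      ref.transcript_id))
    for exon in novel.exons[1:-1]:
        if all(_overlap(exon, rex) == 0 for rex in ref.exons):
            events.append(SpliceEvent("alternative_exon", (exon,),
                                      ref.transcript_id))
    if _tx_start(novel) != _tx_start(ref):
        lo, hi = sorted((_tx_start(novel), _tx_start(ref)))
        events.append(SpliceEvent("alt_start", ((lo, hi),),
                                  ref.transcript_id))
    if _tx_end(novel) != _tx_end(ref):
        lo, hi = sorted((_tx_end(novel), _tx_end(ref)))
        events.append(SpliceEvent("alt_termination", ((lo, hi),),
                                  ref.transcript_id))
    events.sort(key=lambda ev: (ev.coordinates, ev.event_type))
    return events


def variant_usage_report(matrix: ExpressionMatrix,
                         gene_of: dict[str, str]) -> pd.DataFrame:
    """Per-gene variant-usage test over all multi-transcript genes.

    Genes with a single transcript are flagged not-applicable (p NaN).
    """
    means = matrix.age_means()
    by_gene: dict[str, list[int]] = {}
    for i, tid in enumerate(matrix.feature_ids):
        by_gene.setdefault(gene_of.get(tid, tid), []).append(i)
    rows = []
    for gene, idx in sorted(by_gene.items()):
        if len(idx) < 2:
            rows.append({"gene_id": gene, "n_transcripts": len(idx),
                         "statistic": np.nan, "p": np.nan,
                         "applicable": False})
            continue
        table = means[idx]
        if (table.sum(axis=0) > 0).sum() < 2:
            rows.append({"gene_id": gene, "n_transcripts": len(idx),
                         "statistic": np.nan, "p": np.nan,
                         "applicable": False})
            continue
        statistic, p, _ = variant_usage_test(table)
        rows.append({"gene_id": gene, "n_transcripts": len(idx),
                     "statistic": statistic, "p": p, "applicable": True})
    df = pd.DataFrame(rows).set_index("gene_id")
    applicable = df["applicable"]
    q = np.full(len(df), np.nan)
    if applicable.any():
        q[applicable.to_numpy()] = bh_adjust(
            df.loc[applicable, "p"].to_numpy())
    df["q"] = q
    return df
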