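"""Domain containers and tab-delimited / GTF readers and writers.

Every table the pipeline touches is plain text: expression matrices are
TSV with one row per feature and one column per (age, replicate) sample,
regulator networks are three-column TSV, and transcript structures come
in as GTF.  All coordinates are converted to 0-based half-open intervals
at the GTF boundary and stay that way internally.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AgeDesign",
    "ExpressionMatrix",
    "GeneAnnotation",
    "RegulatorNetwork",
    "TranscriptModel",
    "MOLECULE_TYPES",
    "LOCALIZATIONS",
    "DEFAULT_AGES",
    "read_expression_table",
    "write_expression_table",
    "read_regulator_network",
    "write_regulator_network",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_gtf",
    "write_gtf",
]

#: The study design: livers sampled at twelve ages (days relative to birth),
#: three male pups per age.
DEFAULT_AGES: tuple[float, ...] = (-2, 0, 1, 3, 5, 10, 15, 20, 25, 30, 45, 60)

MOLECULE_TYPES = frozenset({
    "enzyme", "transporter", "transcription regulator", "kinase",
    "cytokine", "ion channel", "phosphatase", "translation regulator",
    "peptidase", "transmembrane receptor", "growth factor", "other",
})

LOCALIZATIONS = frozenset({
    "cytoplasm", "nucleus", "plasma membrane", "extracellular space", "other",
})


def _fmt_age(age: float) -> str:
    return str(int(age)) if float(age).is_integer() else str(age)


@dataclass(frozen=True)
class AgeDesign:
    """Ordered age series with a fixed replicate count per age.

    Sample columns are labelled ``d{age}_r{replicate}`` (e.g. ``d-2_r1``)
    and appear age-major in column order.
    """

    ages: tuple[float, ...]
    replicates_per_age: int

    def __post_init__(self) -> None:
        ages = tuple(float(a) for a in self.ages)
        object.__setattr__(self, "ages", ages)
        if len(ages) < 3:
            raise ValueError(f"need at least 3 ages, got {len(ages)}")
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError(f"ages must be strictly increasing: {ages}")
        if self.replicates_per_age < 1:
            raise ValueError("replicates_per_age must be positive")

    @classmethod
    def default(cls) -> "AgeDesign":
        return cls(ages=DEFAULT_AGES, replicates_per_age=3)

    @property
    def n_ages(self) -> int:
        return len(self.ages)

    @property
    def n_samples(self) -> int:
        return len(self.ages) * self.replicates_per_age

    @property
    def sample_labels(self) -> list[str]:
        return [
            f"d{_fmt_age(a)}_r{r + 1}"
            for a in self.ages
            for r in range(self.replicates_per_age)
        ]

    @property
    def sample_ages(self) -> np.ndarray:
        """Age of each sample column, age-major order."""
        return np.repeat(np.asarray(self.ages, dtype=float),
                         self.replicates_per_age)


@dataclass
class ExpressionMatrix:
    """FPKM values for features over an ordered age series with replicates."""

    feature_ids: list[str]
    values: np.ndarray  # (n_features, n_samples), FPKM
    design: AgeDesign
    feature_level: str = "gene"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.feature_level not in ("gene", "transcript"):
            raise ValueError(f"feature_level must be gene or transcript, "
                             f"got {self.feature_level!r}")
        self.validate()

    def validate(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("values must be 2-dimensional")
        if self.values.shape[0] != len(self.feature_ids):
            raise ValueError(
                f"{len(self.feature_ids)} feature ids but "
                f"{self.values.shape[0]} rows")
        if self.values.shape[1] != self.design.n_samples:
            raise ValueError(
                f"design has {self.design.n_samples} samples but matrix has "
                f"{self.values.shape[1]} columns")
        seen: set[str] = set()
        for fid in self.feature_ids:
            if fid in seen:
                raise ValueError(f"duplicate feature id {fid!r}")
            seen.add(fid)
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value for feature {self.feature_ids[i]!r}, "
                f"sample {self.design.sample_labels[j]!r}")
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative FPKM {self.values[i, j]} for feature "
                f"{self.feature_ids[i]!r}, sample "
                f"{self.design.sample_labels[j]!r}")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.feature_ids,
                                                        name="feature_id"),
                            columns=self.design.sample_labels)

    def age_means(self) -> np.ndarray:
        """Replicate-mean FPKM per age, shape (n_features, n_ages)."""
        r = self.design.replicates_per_age
        return self.values.reshape(self.n_features, self.design.n_ages,
                                   r).mean(axis=2)

    def log2_values(self, pseudocount: float = 1.0) -> np.ndarray:
        """log2(FPKM + pseudocount) per sample."""
        return np.log2(self.values + pseudocount)

    def log2_age_means(self, pseudocount: float = 1.0) -> np.ndarray:
        """Per-age replicate means of log2(FPKM + pseudocount)."""
        r = self.design.replicates_per_age
        return self.log2_values(pseudocount).reshape(
            self.n_features, self.design.n_ages, r).mean(axis=2)

    def subset(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        index = {f: i for i, f in enumerate(self.feature_ids)}
        rows = [index[f] for f in feature_ids]
        return ExpressionMatrix(list(feature_ids), self.values[rows],
                                self.design, self.feature_level)


@dataclass
class GeneAnnotation:
    """Molecule type and cellular localization per gene.

    Unannotated genes fall back to the ``other`` category in both
    vocabularies when queried through :meth:`molecule_type_of`.
    """

    table: pd.DataFrame  # index gene_id; columns molecule_type, localization
    transcripts: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"molecule_type", "localization"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"annotation table needs columns {required}")
        bad_type = set(self.table["molecule_type"]) - MOLECULE_TYPES
        if bad_type:
            raise ValueError(f"unknown molecule types: {sorted(bad_type)}")
        bad_loc = set(self.table["localization"]) - LOCALIZATIONS
        if bad_loc:
            raise ValueError(f"unknown localizations: {sorted(bad_loc)}")
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r} in annotation")
        for gid, tids in self.transcripts.items():
            if len(set(tids)) != len(tids):
                raise ValueError(f"duplicate transcript ids for gene {gid!r}")

    def molecule_type_of(self, gene_id: str) -> str:
        try:
            return str(self.table.at[gene_id, "molecule_type"])
        except KeyError:
            return "other"

    def localization_of(self, gene_id: str) -> str:
        try:
            return str(self.table.at[gene_id, "localization"])
        except KeyError:
            return "other"


_DIRECTION_TOKENS = {
    "+1": 1, "1": 1, "up": 1, "-1": -1, "down": -1, "0": 0, "unknown": 0,
}


@dataclass
class RegulatorNetwork:
    """Signed regulator -> target edges.

    Direction +1 means the regulator is expected to increase the target's
    expression, -1 to decrease it, 0 an association of unknown sign.
    """

    edges: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (reg, tgt), d in self.edges.items():
            if d not in (-1, 0, 1):
                raise ValueError(
                    f"direction for edge ({reg!r}, {tgt!r}) must be in "
                    f"{{-1, 0, +1}}, got {d}")

    @property
    def regulators(self) -> set[str]:
        return {reg for reg, _ in self.edges}

    def targets_of(self, regulator: str) -> set[str]:
        return {tgt for (reg, tgt) in self.edges if reg == regulator}

    def direction(self, regulator: str, target: str) -> int:
        return self.edges[(regulator, target)]

    def add_edge(self, regulator: str, target: str, direction: int) -> None:
        key = (regulator, target)
        if key in self.edges and self.edges[key] != direction:
            raise ValueError(
                f"conflicting direction for duplicate edge {key}: "
                f"{self.edges[key]} vs {direction}")
        self.edges[key] = direction


@dataclass(frozen=True)
class TranscriptModel:
    """Exon-chain transcript structure, 0-based half-open coordinates."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id!r} has no exons")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        object.__setattr__(self, "exons", exons)
        for s, e in exons:
            if e <= s:
                raise ValueError(
                    f"transcript {self.transcript_id!r}: exon ({s}, {e}) "
                    f"has end <= start")
        for (_, e0), (s1, _) in zip(exons, exons[1:]):
            if s1 < e0:
                raise ValueError(
                    f"transcript {self.transcript_id!r}: exons overlap or "
                    f"are unsorted near position {s1}")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple((e0, s1) for (_, e0), (s1, _)
                     in zip(self.exons, self.exons[1:]))

    @property
    def junctions(self) -> frozenset[tuple[int, int]]:
        """Splice junctions as intron intervals."""
        return frozenset(self.introns)


# ---------------------------------------------------------------------------
# expression tables

def read_expression_table(path: str | Path, design: AgeDesign,
                          feature_level: str = "gene") -> ExpressionMatrix:
    """Read a tab-delimited FPKM table and validate it against a design.

    The header must contain every ``d{age}_r{rep}`` sample label of the
    design; columns are reordered to design order.  Any missing column,
    duplicate feature id, or negative/non-numeric value is an error that
    names the offending row or column.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    missing = [c for c in design.sample_labels if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing sample column(s) {missing}")
    df = df[design.sample_labels]
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate feature id {dup!r}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise ValueError(
                f"{path}: non-numeric value in column {col!r}, "
                f"feature {bad!r}") from None
    if np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise ValueError(
            f"{path}: negative value {values[i, j]} for feature "
            f"{df.index[i]!r}, column {df.columns[j]!r}")
    return ExpressionMatrix([str(i) for i in df.index], values, design,
                            feature_level)


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write an expression matrix as TSV at full float precision."""
    matrix.validate()
    df = matrix.to_frame()
    df.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# regulator networks

def read_regulator_network(path: str | Path) -> RegulatorNetwork:
    """Read a 3-column TSV of regulator, target, direction.

    Direction tokens ``up``/``down``/``unknown`` are normalized to
    +1/-1/0.  A duplicate edge with a conflicting direction is an error.
    """
    net = RegulatorNetwork()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, "
                    f"got {len(parts)}")
            reg, tgt, tok = parts
            token = tok.strip().lower()
            if token not in _DIRECTION_TOKENS:
                raise ValueError(
                    f"{path}:{lineno}: malformed direction token {tok!r}")
            try:
                net.add_edge(reg, tgt, _DIRECTION_TOKENS[token])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return net


def write_regulator_network(network: RegulatorNetwork,
                            path: str | Path) -> None:
    with open(path, "w") as fh:
        for (reg, tgt) in sorted(network.edges):
            fh.write(f"{reg}\t{tgt}\t{network.edges[(reg, tgt)]:d}\n")


# ---------------------------------------------------------------------------
# gene annotation

def read_gene_annotation(path: str | Path) -> GeneAnnotation:
    """Read a TSV with columns gene_id, molecule_type, localization
    and an optional comma-separated transcript_ids column."""
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("gene_id")
    transcripts: dict[str, tuple[str, ...]] = {}
    if "transcript_ids" in df.columns:
        for gid, cell in df["transcript_ids"].items():
            if isinstance(cell, str) and cell:
                transcripts[str(gid)] = tuple(cell.split(","))
        df = df.drop(columns=["transcript_ids"])
    return GeneAnnotation(df, transcripts)


def write_gene_annotation(annotation: GeneAnnotation,
                          path: str | Path) -> None:
    df = annotation.table.copy()
    df["transcript_ids"] = [
        ",".join(annotation.transcripts.get(g, ())) for g in df.index
    ]
    df.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# GTF

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_attributes(field9: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field9))


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read exon features from a GTF file into transcript models.

    GTF coordinates are 1-based inclusive; they are converted to 0-based
    half-open on input, so interval length is preserved as end - start.
    Exons are grouped per transcript_id and sorted by start.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ValueError(f"{path}:{lineno}: fewer than 9 GTF fields")
            chrom, _, feature, start, end, _, strand, _, attrs = parts[:9]
            if feature != "exon":
                continue
            start_i, end_i = int(start), int(end)
            if end_i < start_i:
                raise ValueError(
                    f"{path}:{lineno}: exon end {end_i} < start {start_i}")
            attr = _parse_gtf_attributes(attrs)
            if "transcript_id" not in attr:
                raise ValueError(
                    f"{path}:{lineno}: exon without transcript_id attribute")
            tid = attr["transcript_id"]
            gid = attr.get("gene_id", tid)
            if tid in meta and meta[tid] != (gid, chrom, strand):
                raise ValueError(
                    f"{path}:{lineno}: transcript {tid!r} has inconsistent "
                    f"gene/chrom/strand")
            meta[tid] = (gid, chrom, strand)
            # 1-based inclusive -> 0-based half-open
            exons.setdefault(tid, []).append((start_i - 1, end_i))
    models = []
    for tid, ex in exons.items():
        gid, chrom, strand = meta[tid]
        models.append(TranscriptModel(tid, gid, chrom, strand,
                                      tuple(sorted(ex))))
    models.sort(key=lambda m: (m.chrom, m.span, m.transcript_id))
    return models


def write_gtf(models: Iterable[TranscriptModel], path: str | Path,
              source: str = "ontodyn") -> None:
    """Write transcript models as GTF exon lines (1-based inclusive)."""
    with open(path, "w") as fh:
        for m in models:
            for s, e in m.exons:
                attrs = (f'gene_id "{m.gene_id}"; '
                         f'transcript_id "{m.transcript_id}";')
                fh.write("\t".join([
                    m.chrom, source, "exon", str(s + 1), str(e), ".",
                    m.strand, ".", attrs,
                ]) + "\n")
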