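"""Ground-truth generators for every input the pipeline consumes.

The generators emulate the statistical structure the analysis assumes:
log-normal FPKM noise around six temporal archetype profiles, planted
regulator modules with correlated or anti-correlated expression, and
planted novel isoforms whose time series are either smoothly
autocorrelated or exchangeable white noise.  Each generator is
deterministic given a seed; a single seed drives all of them through
spawned child generators so modules can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .io_tables import (
    AgeDesign,
    ExpressionMatrix,
    GeneAnnotation,
    LOCALIZATIONS,
    MOLECULE_TYPES,
    RegulatorNetwork,
    TranscriptModel,
)

__all__ = [
    "Archetypes",
    "load_archetypes",
    "GROUP_LABELS",
    "SimulationTruth",
    "PlantedModule",
    "simulate_expression",
    "simulate_annotation",
    "simulate_network",
    "simulate_isoform_series",
    "simulate_transcript_events",
]

#: The six temporal group labels in canonical (factor, sign) order.
GROUP_LABELS = (
    "Prenatal and Neonatal", "Adolescent and Adult",
    "Neonatal and Adolescent", "Prenatal and Adult",
    "Adult", "Neonatal",
)

EVENT_TYPES = ("exon_skip", "intron_retention", "alternative_exon",
               "alt_start", "alt_termination")


@dataclass(frozen=True)
class Archetypes:
    """Six signed temporal archetype profiles built from three bases."""

    ages: tuple[float, ...]
    base_names: tuple[str, ...]
    bases: np.ndarray              # (3, n_ages), zero mean, unit SD
    labels: dict[str, dict[str, str]]

    @property
    def group_labels(self) -> list[str]:
        out = []
        for name in self.base_names:
            out += [self.labels[name]["pos"], self.labels[name]["neg"]]
        return out

    def shape_for(self, label: str) -> np.ndarray:
        for i, name in enumerate(self.base_names):
            if self.labels[name]["pos"] == label:
                return self.bases[i].copy()
            if self.labels[name]["neg"] == label:
                return -self.bases[i]
        raise KeyError(f"unknown archetype label {label!r}")

    def factor_and_sign(self, label: str) -> tuple[int, int]:
        for i, name in enumerate(self.base_names):
            if self.labels[name]["pos"] == label:
                return i, +1
            if self.labels[name]["neg"] == label:
                return i, -1
        raise KeyError(f"unknown archetype label {label!r}")


def load_archetypes(path: str | Path | None = None) -> Archetypes:
    """Load archetype configuration (the packaged default, or a YAML file)."""
    if path is None:
        text = (resources.files("ontodyn") / "data" /
                "archetypes.yaml").read_text()
    else:
        text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    names = tuple(cfg["bases"])
    bases = np.array([cfg["bases"][n] for n in names], dtype=float)
    # enforce the standardization invariant exactly
    bases -= bases.mean(axis=1, keepdims=True)
    bases /= bases.std(axis=1, ddof=1, keepdims=True)
    return Archetypes(tuple(float(a) for a in cfg["ages"]), names, bases,
                      cfg["labels"])


@dataclass
class PlantedModule:
    """A co-regulating regulator set planted into a simulated network."""

    regulators: tuple[str, ...]
    targets: tuple[str, ...]
    archetype: str                       # label of the shared pattern
    anti_correlated: bool = False        # half the members follow -pattern
    member_signs: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(self.regulators) < 2:
            raise ValueError("a planted module needs >= 2 regulators")
        if not self.member_signs:
            if self.anti_correlated:
                # alternate signs so the per-age mean cancels
                signs = tuple(1 if i % 2 == 0 else -1
                              for i in range(len(self.regulators)))
            else:
                signs = (1,) * len(self.regulators)
            self.member_signs = signs
        if len(self.member_signs) != len(self.regulators):
            raise ValueError("member_signs length mismatch")


@dataclass
class SimulationTruth:
    """Everything the generators decided, for downstream validation."""

    gene_labels: dict[str, str] = field(default_factory=dict)   # label or "null"
    gene_baseline: dict[str, float] = field(default_factory=dict)
    gene_amplitude: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.0
    modules: list[PlantedModule] = field(default_factory=list)
    isoform_autocorrelated: dict[str, bool] = field(default_factory=dict)
    isoform_events: dict[str, str] = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        return {
            "gene_labels": self.gene_labels,
            "gene_baseline": self.gene_baseline,
            "gene_amplitude": self.gene_amplitude,
            "noise_sd": self.noise_sd,
            "modules": [
                {"regulators": list(m.regulators), "targets": list(m.targets),
                 "archetype": m.archetype,
                 "anti_correlated": m.anti_correlated,
                 "member_signs": list(m.member_signs)}
                for m in self.modules
            ],
            "isoform_autocorrelated": self.isoform_autocorrelated,
            "isoform_events": self.isoform_events,
        }


def _default_mix(archetypes: Archetypes,
                 null_fraction: float = 0.1) -> dict[str, float]:
    share = (1.0 - null_fraction) / 6.0
    mix = {label: share for label in archetypes.group_labels}
    mix["null"] = null_fraction
    return mix


def simulate_expression(n_genes: int,
                        mix: dict[str, float] | None = None,
                        baseline_log2_mean: float = 6.0,
                        baseline_log2_sd: float = 1.5,
                        noise_sd: float = 0.3,
                        amplitude_range: tuple[float, float] = (1.5, 3.0),
                        design: AgeDesign | None = None,
                        archetypes: Archetypes | None = None,
                        seed: int | np.random.Generator = 0,
                        ) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Simulate a gene-level FPKM matrix around the archetype profiles.

    Gene g at age a, replicate r gets
    ``FPKM = 2 ** (baseline_g + amplitude_g * shape_g(a) + eps)`` with
    ``eps ~ Normal(0, noise_sd)``; genes drawn as ``null`` have amplitude 0.
    ``mix`` gives proportions over the six archetype labels plus ``null``
    and must sum to 1.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if noise_sd <= 0 and noise_sd != 0:
        raise ValueError("noise_sd must be >= 0")
    design = design or AgeDesign.default()
    archetypes = archetypes or load_archetypes()
    if len(archetypes.ages) != design.n_ages:
        raise ValueError("archetype profiles do not match the design's ages")
    mix = dict(mix) if mix is not None else _default_mix(archetypes)
    labels = list(mix)
    known = set(archetypes.group_labels) | {"null"}
    unknown = set(labels) - known
    if unknown:
        raise ValueError(f"unknown mix labels: {sorted(unknown)}")
    probs = np.array([mix[k] for k in labels], dtype=float)
    if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
        raise ValueError("mix proportions must be non-negative and sum to 1")

    rng = np.random.default_rng(seed)
    gene_ids = [f"g{i + 1:05d}" for i in range(n_genes)]
    chosen = rng.choice(len(labels), size=n_genes, p=probs)
    baselines = rng.normal(baseline_log2_mean, baseline_log2_sd, n_genes)
    amplitudes = rng.uniform(*amplitude_range, n_genes)

    shapes = np.zeros((n_genes, design.n_ages))
    truth = SimulationTruth(noise_sd=noise_sd)
    for i, gid in enumerate(gene_ids):
        label = labels[chosen[i]]
        truth.gene_labels[gid] = label
        truth.gene_baseline[gid] = float(baselines[i])
        if label == "null":
            amplitudes[i] = 0.0
        else:
            shapes[i] = archetypes.shape_for(label)
        truth.gene_amplitude[gid] = float(amplitudes[i])

    r = design.replicates_per_age
    log2fpkm = (baselines[:, None] + amplitudes[:, None] * shapes)
    log2fpkm = np.repeat(log2fpkm, r, axis=1)
    log2fpkm += rng.normal(0.0, noise_sd, size=log2fpkm.shape)
    matrix = ExpressionMatrix(gene_ids, np.exp2(log2fpkm), design, "gene")
    return matrix, truth


_MOLECULE_WEIGHTS = {
    # roughly the composition of an annotated mammalian transcriptome
    "enzyme": 0.14, "transcription regulator": 0.08, "transporter": 0.07,
    "kinase": 0.05, "peptidase": 0.04, "transmembrane receptor": 0.04,
    "ion channel": 0.03, "phosphatase": 0.02, "growth factor": 0.02,
    "cytokine": 0.02, "translation regulator": 0.01, "other": 0.48,
}

_LOCALIZATION_WEIGHTS = {
    "cytoplasm": 0.38, "nucleus": 0.23, "plasma membrane": 0.13,
    "extracellular space": 0.07, "other": 0.19,
}


def simulate_annotation(gene_ids: Sequence[str],
                        seed: int | np.random.Generator = 0
                        ) -> GeneAnnotation:
    """Random molecule-type / localization annotation for a gene list."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    types = sorted(_MOLECULE_WEIGHTS)
    tprobs = np.array([_MOLECULE_WEIGHTS[t] for t in types])
    locs = sorted(_LOCALIZATION_WEIGHTS)
    lprobs = np.array([_LOCALIZATION_WEIGHTS[loc] for loc in locs])
    table = pd.DataFrame({
        "molecule_type": rng.choice(types, size=len(gene_ids),
                                    p=tprobs / tprobs.sum()),
        "localization": rng.choice(locs, size=len(gene_ids),
                                   p=lprobs / lprobs.sum()),
    }, index=pd.Index(list(gene_ids), name="gene_id"))
    assert set(table["molecule_type"]) <= MOLECULE_TYPES
    assert set(table["localization"]) <= LOCALIZATIONS
    return GeneAnnotation(table)


def simulate_network(matrix: ExpressionMatrix,
                     planted: Sequence[PlantedModule],
                     n_decoy_regulators: int = 0,
                     n_decoy_edges: int = 0,
                     regulator_noise_sd: float = 0.1,
                     regulator_amplitude: float = 2.5,
                     baseline_log2: float = 6.0,
                     archetypes: Archetypes | None = None,
                     seed: int | np.random.Generator = 0,
                     ) -> tuple[ExpressionMatrix, RegulatorNetwork,
                                SimulationTruth]:
    """Plant regulator modules into a network and append regulator rows.

    Each planted module's regulators follow (plus or minus) the module's
    archetype shape at low noise, so the module satisfies the discovery
    thresholds in expectation.  Decoy regulators get white-noise series
    and random target edges that never collide with planted edges.
    """
    archetypes = archetypes or load_archetypes()
    design = matrix.design
    rng = np.random.default_rng(seed)
    genes = set(matrix.feature_ids)
    for mod in planted:
        missing = set(mod.targets) - genes
        if missing:
            raise ValueError(f"planted targets absent from matrix: "
                             f"{sorted(missing)}")

    net = RegulatorNetwork()
    reg_rows: dict[str, np.ndarray] = {}
    r = design.replicates_per_age
    truth = SimulationTruth(noise_sd=regulator_noise_sd,
                            modules=list(planted))

    for mod in planted:
        shape = archetypes.shape_for(mod.archetype)
        for reg, sign in zip(mod.regulators, mod.member_signs):
            if reg not in reg_rows:
                log2 = baseline_log2 + regulator_amplitude * sign * shape
                log2 = np.repeat(log2, r)
                log2 = log2 + rng.normal(0.0, regulator_noise_sd, log2.size)
                reg_rows[reg] = np.exp2(log2)
            for tgt in mod.targets:
                direction = sign  # member raises targets it tracks, else lowers
                if (reg, tgt) in net.edges:
                    continue
                net.add_edge(reg, tgt, direction)

    planted_pairs = set(net.edges)
    gene_list = sorted(genes)
    for i in range(n_decoy_regulators):
        reg = f"decoyR{i + 1:03d}"
        log2 = baseline_log2 + rng.normal(0.0, 1.0, design.n_samples)
        reg_rows[reg] = np.exp2(log2)
    decoy_regs = [f"decoyR{i + 1:03d}" for i in range(n_decoy_regulators)]
    all_regs = decoy_regs or sorted({r_ for r_, _ in planted_pairs})
    attempts = 0
    added = 0
    while added < n_decoy_edges:
        attempts += 1
        if attempts > 100 * max(n_decoy_edges, 1):
            raise ValueError("could not place decoy edges without collision")
        reg = all_regs[rng.integers(len(all_regs))]
        tgt = gene_list[rng.integers(len(gene_list))]
        if (reg, tgt) in net.edges:
            continue
        net.add_edge(reg, tgt, int(rng.choice((-1, 1))))
        added += 1

    reg_ids = sorted(reg_rows)
    values = np.vstack([matrix.values] +
                       [reg_rows[rid][None, :] for rid in reg_ids])
    merged = ExpressionMatrix(matrix.feature_ids + reg_ids, values,
                              design, matrix.feature_level)
    return merged, net, truth


def simulate_isoform_series(n_autocorrelated: int,
                            n_whitenoise: int,
                            design: AgeDesign | None = None,
                            baseline_log2: float = 5.0,
                            autocorr_noise_sd: float = 0.15,
                            whitenoise_sd: float = 1.0,
                            amplitude_range: tuple[float, float] = (1.5, 3.0),
                            archetypes: Archetypes | None = None,
                            seed: int | np.random.Generator = 0,
                            ) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Transcript-level series that are either smooth in time or exchangeable.

    Autocorrelated series follow a randomly chosen archetype with small
    noise; white-noise series are i.i.d. across ages and replicates, so
    any permutation of their age order is equally likely.
    """
    if n_autocorrelated < 0 or n_whitenoise < 0:
        raise ValueError("counts must be >= 0")
    design = design or AgeDesign.default()
    archetypes = archetypes or load_archetypes()
    rng = np.random.default_rng(seed)
    r = design.replicates_per_age
    rows, ids = [], []
    truth = SimulationTruth(noise_sd=autocorr_noise_sd)
    group_labels = archetypes.group_labels
    for i in range(n_autocorrelated):
        tid = f"tA{i + 1:05d}"
        label = group_labels[rng.integers(len(group_labels))]
        amp = rng.uniform(*amplitude_range)
        log2 = baseline_log2 + amp * archetypes.shape_for(label)
        log2 = np.repeat(log2, r) + rng.normal(0, autocorr_noise_sd,
                                               design.n_samples)
        rows.append(np.exp2(log2))
        ids.append(tid)
        truth.isoform_autocorrelated[tid] = True
        truth.gene_labels[tid] = label
    for i in range(n_whitenoise):
        tid = f"tW{i + 1:05d}"
        log2 = baseline_log2 + rng.normal(0, whitenoise_sd, design.n_samples)
        rows.append(np.exp2(log2))
        ids.append(tid)
        truth.isoform_autocorrelated[tid] = False
        truth.gene_labels[tid] = "null"
    values = np.vstack(rows) if rows else np.empty((0, design.n_samples))
    return ExpressionMatrix(ids, values, design, "transcript"), truth


def simulate_transcript_events(reference: TranscriptModel,
                               events: Sequence[str],
                               seed: int | np.random.Generator = 0,
                               ) -> list[TranscriptModel]:
    """Derive novel transcript models differing from a reference by exactly
    one requested splice event each.

    Raises when an event is impossible for the given reference (e.g.
    skipping an exon of a transcript with fewer than three exons).
    """
    rng = np.random.default_rng(seed)
    out = []
    for idx, event in enumerate(events):
        if event not in EVENT_TYPES:
            raise ValueError(f"unknown event type {event!r}")
        exons = list(reference.exons)
        n = len(exons)
        tid = f"{reference.transcript_id}_{event}_{idx + 1}"
        if event == "exon_skip":
            if n < 3:
                raise ValueError("exon_skip needs a reference with >= 3 exons")
            k = int(rng.integers(1, n - 1))
            new_exons = exons[:k] + exons[k + 1:]
        elif event == "intron_retention":
            if n < 2:
                raise ValueError("intron_retention needs >= 2 exons")
            k = int(rng.integers(0, n - 1))
            merged = (exons[k][0], exons[k + 1][1])
            new_exons = exons[:k] + [merged] + exons[k + 2:]
        elif event == "alternative_exon":
            if n < 2:
                raise ValueError("alternative_exon needs an intron to host "
                                 "the new exon")
            introns = [(e0, s1) for (_, e0), (s1, _)
                       in zip(exons, exons[1:])]
            wide = [i for i, (s, e) in enumerate(introns) if e - s >= 30]
            if not wide:
                raise ValueError("no intron wide enough for a novel exon")
            k = wide[int(rng.integers(len(wide)))]
            s, e = introns[k]
            width = min(20, (e - s) // 3)
            start = s + (e - s - width) // 2
            new_exons = exons[:k + 1] + [(start, start + width)] + exons[k + 1:]
        elif event == "alt_start":
            first = 0 if reference.strand == "+" else n - 1
            s, e = exons[first]
            if e - s < 4:
                raise ValueError("first exon too short to shift the start")
            delta = max(1, (e - s) // 3)
            new = (s + delta, e) if reference.strand == "+" else (s, e - delta)
            new_exons = exons.copy()
            new_exons[first] = new
        else:  # alt_termination
            last = n - 1 if reference.strand == "+" else 0
            s, e = exons[last]
            if e - s < 4:
                raise ValueError("last exon too short to shift the end")
            delta = max(1, (e - s) // 3)
            new = (s, e - delta) if reference.strand == "+" else (s + delta, e)
            new_exons = exons.copy()
            new_exons[last] = new
        out.append(TranscriptModel(tid, reference.gene_id, reference.chrom,
                                   reference.strand, tuple(new_exons)))
    return out
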