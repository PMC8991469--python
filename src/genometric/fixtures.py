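"""Reproducible synthetic GDM datasets with planted ground truth.

Three generators emulate the data regimes the engine is built for, at desk
scale (two chromosomes of 100 kbp by default):

* :func:`make_dataset` — generic random datasets from a declarative
  :class:`FixtureSpec` (used heavily by the randomized operator tests);
* :func:`make_mutations_and_genes` — per-patient somatic 1-bp mutation
  samples planted inside a non-overlapping gene annotation, with the exact
  per-(patient, gene) counts returned as a ground-truth table;
* :func:`make_tf_peaks` — a ChIP-seq-like TF peak collection, one sample per
  (TF, replicate) with ``experiment_target``/``biosample_term_name``
  metadata, optionally with an interval covered by exactly k distinct TFs
  planted for HOT-zone recovery tests.

Every generator is a pure function of its seed: the same arguments produce a
byte-identical dataset after writing.  Emitting the planted truth alongside
the data turns these stochastic fixtures into exact oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import io
from .model import (
    ArgumentError,
    GDMDataset,
    MetadataSet,
    Region,
    Sample,
    Schema,
)

__all__ = [
    "FixtureSpec",
    "make_dataset",
    "MutationGeneFixture",
    "make_mutations_and_genes",
    "make_tf_peaks",
    "write_mutation_fixture",
]

DEFAULT_CHROMS = {"chr1": 100_000, "chr2": 100_000}
_STRING_VOCAB = ("alpha", "beta", "gamma", "delta")


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative recipe for a random dataset; same spec + seed => same bytes."""

    seed: int
    n_samples: int = 3
    chroms: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_CHROMS))
    regions_per_sample: Tuple[int, int] = (5, 50)
    attributes: tuple = (
        ("score", "integer"),
        ("signal", "float"),
        ("name", "string"),
    )
    metadata_vocabulary: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: {
            "biosample_term_name": ("H1", "K562"),
            "assay": ("ChIP-seq", "DNase-seq"),
        }
    )
    missing_rate: float = 0.1
    max_region_length: int = 1000


def make_dataset(spec: FixtureSpec) -> GDMDataset:
    """Generate a random dataset valid under all GDM invariants."""
    lo, hi = spec.regions_per_sample
    if hi > sum(spec.chroms.values()):
        raise ArgumentError("requested region count exceeds chromosome capacity")
    rng = np.random.default_rng(spec.seed)
    schema = Schema(tuple(spec.attributes))
    chrom_names = sorted(spec.chroms)
    samples = []
    for i in range(spec.n_samples):
        n_regions = int(rng.integers(lo, hi + 1))
        regions = []
        for _ in range(n_regions):
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            size = spec.chroms[chrom]
            length = int(rng.integers(1, min(spec.max_region_length, size) + 1))
            left = int(rng.integers(0, size - length + 1))
            strand = "+-*"[int(rng.integers(3))]
            values = []
            for _, dtype in spec.attributes:
                if rng.random() < spec.missing_rate:
                    values.append(None)
                elif dtype == "integer":
                    values.append(int(rng.integers(0, 1000)))
                elif dtype == "float":
                    values.append(float(rng.uniform(0, 100)))
                elif dtype == "boolean":
                    values.append(bool(rng.integers(2)))
                else:
                    values.append(_STRING_VOCAB[int(rng.integers(len(_STRING_VOCAB)))])
            regions.append(Region(chrom, left, left + length, strand, tuple(values)))
        metadata = MetadataSet()
        for key in sorted(spec.metadata_vocabulary):
            vocab = list(spec.metadata_vocabulary[key])
            n_values = int(rng.integers(1, min(2, len(vocab)) + 1))
            chosen = rng.choice(len(vocab), size=n_values, replace=False)
            for j in sorted(int(c) for c in chosen):
                metadata.add(key, vocab[j])
        samples.append(Sample(f"S_{i + 1:05d}", regions, metadata))
    return GDMDataset(schema, samples, name=f"synthetic_{spec.seed}")


# ---------------------------------------------------------------------------
# mutations + genes (use-case-1 regime)


@dataclass
class MutationGeneFixture:
    """Mutation and gene datasets plus the planted per-(patient, gene) counts."""

    mutations: GDMDataset
    genes: GDMDataset
    truth: pd.DataFrame  # columns: patient_id, gene_symbol, count, age


def make_mutations_and_genes(
    seed: int,
    n_patients: int = 20,
    n_genes: int = 50,
    mutation_rate: float = 0.5,
) -> MutationGeneFixture:
    """Plant Poisson(``mutation_rate``) somatic mutations per patient per gene.

    Gene regions are non-overlapping (separated by >= 50 bp gaps), so every
    1-bp mutation lies inside exactly one gene and the truth table is an
    exact oracle for map counts.  Each patient sample carries
    ``patient_id``, ``age_at_diagnosis`` and ``disease`` metadata.
    """
    if min(n_patients, n_genes) <= 0 or mutation_rate < 0:
        raise ArgumentError("fixture parameters must be positive")
    rng = np.random.default_rng(seed)

    chrom_names = sorted(DEFAULT_CHROMS)
    gene_regions = []
    gene_symbols = []
    chrom_idx, cursor = 0, 0
    for g in range(n_genes):
        length = int(rng.integers(500, 2001))
        gap = int(rng.integers(50, 201))
        if cursor + gap + length > DEFAULT_CHROMS[chrom_names[chrom_idx]]:
            chrom_idx += 1
            cursor = 0
            if chrom_idx >= len(chrom_names):
                raise ArgumentError("gene annotation exceeds chromosome capacity")
        left = cursor + gap
        symbol = f"GENE{g + 1:04d}"
        strand = "+-"[int(rng.integers(2))]
        gene_regions.append(
            Region(chrom_names[chrom_idx], left, left + length, strand, (symbol,))
        )
        gene_symbols.append(symbol)
        cursor = left + length
    genes = GDMDataset(
        Schema((("gene_symbol", "string"),)),
        [
            Sample(
                "S_00001",
                gene_regions,
                MetadataSet([("annotation_type", "gene"), ("assembly", "toy")]),
            )
        ],
        name="genes",
    )

    mutation_types = ("SNV", "insertion", "deletion")
    patients = []
    truth_rows = []
    for p in range(n_patients):
        patient_id = f"S_{p + 1:05d}"
        age = int(rng.integers(40, 86))
        counts = rng.poisson(mutation_rate, size=n_genes)
        regions = []
        for gene, symbol, count in zip(gene_regions, gene_symbols, counts):
            for _ in range(int(count)):
                pos = int(rng.integers(gene.left, gene.right))
                mtype = mutation_types[int(rng.integers(len(mutation_types)))]
                regions.append(Region(gene.chrom, pos, pos + 1, "*", (mtype,)))
            truth_rows.append((patient_id, symbol, int(count), age))
        metadata = MetadataSet(
            [
                ("patient_id", patient_id),
                ("age_at_diagnosis", str(age)),
                ("disease", "kidney_carcinoma"),
            ]
        )
        patients.append(Sample(patient_id, regions, metadata))
    mutations = GDMDataset(
        Schema((("mutation_type", "string"),)), patients, name="muts"
    )
    truth = pd.DataFrame(
        truth_rows, columns=["patient_id", "gene_symbol", "count", "age"]
    )
    return MutationGeneFixture(mutations, genes, truth)


def write_mutation_fixture(
    fixture: MutationGeneFixture, root: Union[str, Path], overwrite: bool = False
) -> Path:
    """Persist both datasets plus the truth table as a TSV sidecar."""
    root = Path(root)
    io.write_gdm_dataset(fixture.mutations, root / "mutations", overwrite=overwrite)
    io.write_gdm_dataset(fixture.genes, root / "genes", overwrite=overwrite)
    fixture.truth.to_csv(root / "truth.tsv", sep="\t", index=False)
    return root


# ---------------------------------------------------------------------------
# TF peaks (use-case-3 regime)


def make_tf_peaks(
    seed: int,
    n_tfs: int = 10,
    peaks_per_tf: int = 30,
    planted_zone: Optional[Tuple[str, int, int, int]] = None,
    n_replicates: int = 1,
    cell_line: str = "H1-hESC",
) -> GDMDataset:
    """Generate a TF ChIP-seq peak collection, one sample per (TF, replicate).

    Peak lengths are mostly 150-400 bp, with a small fraction of short
    (< 100 bp) and wide (> 3 kbp) peaks so that length-percentile filtering
    has outliers to remove.  ``planted_zone = (chrom, left, right, k)`` adds
    one peak exactly covering the interval for each of the first k TFs and
    keeps all background peaks off the interval, so the accumulation there is
    exactly k.
    """
    if planted_zone is not None:
        chrom_z, left_z, right_z, k = planted_zone
        if k > n_tfs:
            raise ArgumentError("planted k cannot exceed the number of TFs")
    rng = np.random.default_rng(seed)
    chrom_names = sorted(DEFAULT_CHROMS)
    schema = Schema((("name", "string"), ("score", "integer"), ("signalValue", "float")))

    samples = []
    counter = 0
    for t in range(n_tfs):
        tf_name = f"TF_{t + 1:02d}"
        for rep in range(n_replicates):
            counter += 1
            regions = []
            if planted_zone is not None and t < k and rep == 0:
                regions.append(
                    Region(
                        chrom_z,
                        left_z,
                        right_z,
                        "*",
                        (f"{tf_name}_planted", 1000, float(n_tfs)),
                    )
                )
            for i in range(peaks_per_tf):
                chrom = chrom_names[int(rng.integers(len(chrom_names)))]
                size = DEFAULT_CHROMS[chrom]
                draw = rng.random()
                if draw < 0.05:
                    length = int(rng.integers(30, 81))
                elif draw < 0.12:
                    length = int(rng.integers(3000, 8001))
                else:
                    length = int(rng.integers(150, 401))
                while True:
                    left = int(rng.integers(0, size - length + 1))
                    if planted_zone is None or chrom != chrom_z:
                        break
                    if left + length <= left_z or left >= right_z:
                        break
                regions.append(
                    Region(
                        chrom,
                        left,
                        left + length,
                        "*",
                        (
                            f"{tf_name}_peak_{i + 1}",
                            int(rng.integers(0, 1001)),
                            float(rng.uniform(1, 50)),
                        ),
                    )
                )
            metadata = MetadataSet(
                [
                    ("experiment_target", tf_name),
                    ("biosample_term_name", cell_line),
                    ("replicate", str(rep + 1)),
                    ("assay", "ChIP-seq"),
                ]
            )
            samples.append(Sample(f"S_{counter:05d}", regions, metadata))
    return GDMDataset(schema, samples, name="tf_peaks")
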