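"""Seeded synthetic cohorts with planted true fusions and artifacts.

The generator emulates the candidate tables a fusion caller emits on a
multi-entity tumor cohort, with per-row truth labels, so every scoring
rule and cohort-level property can be exercised without sequencing data:

* ``true_fusion`` rows mimic validated fusions: 5-200 split reads, 2-50
  spanning reads of which 80-100% map uniquely, breakpoint homology
  below 10 bases, repeat overlap below 0.8, mostly interchromosomal with
  a preserved reading frame and an exon-boundary breakpoint.  Each uses
  a fresh gene pair, so true fusions never recur across entities.
* ``artifact`` rows come in three flavors: read-through/alternative-
  splicing transcripts between adjacent genes (with modest read support,
  as these arise from ordinary transcription rather than rearrangement),
  candidates whose spanning reads all multimap, and designated recurrent
  pairs planted into samples from at least ``recurrent_min_entities``
  distinct entities so an artifact list built from the cohort blacklists
  exactly them.
* ``ambiguous`` rows sit on rule boundaries (homology exactly at the
  threshold, repeat proportion exactly on a bin edge) for boundary tests.

Identical ``(seed, params)`` reproduce the cohort bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from os import PathLike
from pathlib import Path

import numpy as np

from .artifacts import CohortManifest, ManifestEntry, write_manifest
from .records import FusionTranscript, GenePair

CHROMS = tuple(str(i) for i in range(1, 23)) + ("X",)

LABEL_TRUE = "true_fusion"
LABEL_ARTIFACT = "artifact"
LABEL_AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class CohortParams:
    """Generation parameters; defaults give a 12-sample, 5-entity cohort."""

    n_samples: int = 12
    n_entities: int = 5
    n_true_per_sample: int = 3
    n_readthrough_per_sample: int = 5
    n_multimapped_per_sample: int = 2
    n_ambiguous_per_sample: int = 1
    n_recurrent_pairs: int = 8
    recurrent_min_entities: int = 3

    def __post_init__(self):
        for name in (
            "n_samples", "n_entities", "n_true_per_sample",
            "n_readthrough_per_sample", "n_multimapped_per_sample",
            "n_ambiguous_per_sample", "n_recurrent_pairs",
        ):
            if getattr(self, name) < 0 or (name in ("n_samples", "n_entities") and getattr(self, name) < 1):
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_recurrent_pairs > 0:
            if self.n_entities < 2:
                raise ValueError("recurrent artifact pairs require at least 2 entities")
            if not 1 <= self.recurrent_min_entities <= self.n_entities:
                raise ValueError(
                    f"recurrent_min_entities must lie in [1, {self.n_entities}]"
                )


@dataclass
class SyntheticCohort:
    manifest: CohortManifest
    tables: dict[str, list[FusionTranscript]]
    labels: dict[tuple[str, str], str]
    seed: int
    params: CohortParams

    def all_records(self) -> list[FusionTranscript]:
        return [rec for entry in self.manifest for rec in self.tables[entry.sample_id]]

    def truth_pairs(self) -> frozenset[GenePair]:
        """Gene pairs of all planted true fusions."""
        return frozenset(
            rec.pair
            for rec in self.all_records()
            if self.labels[(rec.sample_id, rec.cluster_id)] == LABEL_TRUE
        )

    def planted_recurrent_pairs(self) -> frozenset[GenePair]:
        return frozenset(
            GenePair(f"ART{i:03d}X", f"ART{i:03d}Y")
            for i in range(self.params.n_recurrent_pairs)
        )


def _chrom_pair(rng: np.random.Generator, interchromosomal: bool) -> tuple[str, str]:
    if interchromosomal:
        c1, c2 = rng.choice(len(CHROMS), size=2, replace=False)
        return CHROMS[c1], CHROMS[c2]
    c = CHROMS[rng.integers(len(CHROMS))]
    return c, c


def _base_fields(rng: np.random.Generator, interchromosomal: bool) -> dict:
    c1, c2 = _chrom_pair(rng, interchromosomal)
    return {
        "chrom1": c1,
        "chrom2": c2,
        "break_pos1": int(rng.integers(1, 200_000_000)),
        "break_pos2": int(rng.integers(1, 200_000_000)),
        "strand1": "+" if rng.random() < 0.5 else "-",
        "strand2": "+" if rng.random() < 0.5 else "-",
        "interchromosomal": interchromosomal,
    }


def _true_row(rng: np.random.Generator, gene_serial: int) -> FusionTranscript:
    span = int(rng.integers(2, 50))
    unique = min(span, int(round(span * rng.uniform(0.8, 1.0))))
    return FusionTranscript(
        gene1=f"TRU{gene_serial:04d}A",
        gene2=f"TRU{gene_serial:04d}B",
        split_count=int(rng.integers(5, 200)),
        span_count=span,
        unique_span_count=unique,
        breakpoint_homology=int(rng.integers(0, 10)),
        repeat_proportion=float(rng.uniform(0.0, 0.8)),
        read_through=False,
        altsplice=False,
        adjacent=False,
        orf=bool(rng.random() < 0.9),
        exon_boundary=bool(rng.random() < 0.95),
        downstream_3prime_break=False,
        caller_probability=float(rng.uniform(0.5, 1.0)),
        **_base_fields(rng, interchromosomal=bool(rng.random() < 0.9)),
    )


def _readthrough_row(rng: np.random.Generator, gene_serial: int) -> FusionTranscript:
    read_through = bool(rng.random() < 0.5)
    altsplice = (not read_through) or bool(rng.random() < 0.3)
    span = int(rng.integers(0, 20))
    unique = min(span, int(round(span * rng.uniform(0.5, 1.0))))
    return FusionTranscript(
        gene1=f"RTG{gene_serial:04d}A",
        gene2=f"RTG{gene_serial:04d}B",
        split_count=int(rng.integers(0, 50)),
        span_count=span,
        unique_span_count=unique,
        breakpoint_homology=int(rng.integers(0, 15)),
        repeat_proportion=float(rng.uniform(0.0, 1.0)),
        read_through=read_through,
        altsplice=altsplice,
        adjacent=True,
        orf=bool(rng.random() < 0.3),
        exon_boundary=bool(rng.random() < 0.6),
        downstream_3prime_break=bool(rng.random() < 0.1),
        caller_probability=float(rng.uniform(0.0, 1.0)),
        **_base_fields(rng, interchromosomal=False),
    )


def _multimapped_row(rng: np.random.Generator, gene_serial: int) -> FusionTranscript:
    return FusionTranscript(
        gene1=f"MMG{gene_serial:04d}A",
        gene2=f"MMG{gene_serial:04d}B",
        split_count=int(rng.integers(0, 30)),
        span_count=int(rng.integers(5, 30)),
        unique_span_count=0,
        breakpoint_homology=int(rng.integers(0, 30)),
        repeat_proportion=float(rng.uniform(0.5, 1.0)),
        read_through=False,
        altsplice=False,
        adjacent=False,
        orf=bool(rng.random() < 0.4),
        exon_boundary=bool(rng.random() < 0.5),
        downstream_3prime_break=bool(rng.random() < 0.2),
        caller_probability=float(rng.uniform(0.0, 1.0)),
        **_base_fields(rng, interchromosomal=bool(rng.random() < 0.5)),
    )


def _recurrent_row(rng: np.random.Generator, pair_index: int) -> FusionTranscript:
    span = int(rng.integers(2, 20))
    unique = min(span, int(round(span * rng.uniform(0.5, 1.0))))
    return FusionTranscript(
        gene1=f"ART{pair_index:03d}X",
        gene2=f"ART{pair_index:03d}Y",
        split_count=int(rng.integers(5, 50)),
        span_count=span,
        unique_span_count=unique,
        breakpoint_homology=int(rng.integers(0, 20)),
        repeat_proportion=float(rng.uniform(0.0, 1.0)),
        read_through=False,
        altsplice=False,
        adjacent=False,
        orf=bool(rng.random() < 0.5),
        exon_boundary=bool(rng.random() < 0.5),
        downstream_3prime_break=False,
        caller_probability=float(rng.uniform(0.0, 1.0)),
        **_base_fields(rng, interchromosomal=bool(rng.random() < 0.5)),
    )


def _ambiguous_row(rng: np.random.Generator, gene_serial: int) -> FusionTranscript:
    variant = int(rng.integers(3))
    homology = 10 if variant == 0 else int(rng.integers(0, 10))
    repeat = {0: float(rng.uniform(0.0, 0.8)), 1: 0.8, 2: 0.9}[variant]
    span = int(rng.integers(2, 30))
    unique = min(span, int(round(span * rng.uniform(0.8, 1.0))))
    return FusionTranscript(
        gene1=f"AMB{gene_serial:04d}A",
        gene2=f"AMB{gene_serial:04d}B",
        split_count=int(rng.integers(5, 100)),
        span_count=span,
        unique_span_count=unique,
        breakpoint_homology=homology,
        repeat_proportion=repeat,
        read_through=False,
        altsplice=False,
        adjacent=False,
        orf=True,
        exon_boundary=True,
        downstream_3prime_break=False,
        caller_probability=float(rng.uniform(0.0, 1.0)),
        **_base_fields(rng, interchromosomal=True),
    )


def generate_cohort(params: CohortParams = CohortParams(), seed: int = 0) -> SyntheticCohort:
    """Generate a labeled cohort; identical ``(params, seed)`` reproduce
    identical cohorts."""
    rng = np.random.default_rng(seed)
    entities = [f"entity{i + 1:02d}" for i in range(params.n_entities)]
    sample_ids = [f"S{j + 1:03d}" for j in range(params.n_samples)]
    sample_entity = {s: entities[j % params.n_entities] for j, s in enumerate(sample_ids)}
    samples_of_entity: dict[str, list[str]] = {e: [] for e in entities}
    for s in sample_ids:
        samples_of_entity[sample_entity[s]].append(s)

    # Plant recurrent pairs first so the rng call order is fixed.
    planted: dict[str, list[FusionTranscript]] = {s: [] for s in sample_ids}
    for i in range(params.n_recurrent_pairs):
        k = int(rng.integers(params.recurrent_min_entities, params.n_entities + 1))
        chosen = [entities[j] for j in rng.choice(params.n_entities, size=k, replace=False)]
        for entity in chosen:
            pool = samples_of_entity[entity]
            sample = pool[int(rng.integers(len(pool)))]
            planted[sample].append(_recurrent_row(rng, i))

    tables: dict[str, list[FusionTranscript]] = {}
    labels: dict[tuple[str, str], str] = {}
    gene_serial = 0
    for sample in sample_ids:
        rows: list[tuple[FusionTranscript, str]] = []
        for _ in range(params.n_true_per_sample):
            rows.append((_true_row(rng, gene_serial), LABEL_TRUE))
            gene_serial += 1
        for _ in range(params.n_readthrough_per_sample):
            rows.append((_readthrough_row(rng, gene_serial), LABEL_ARTIFACT))
            gene_serial += 1
        for _ in range(params.n_multimapped_per_sample):
            rows.append((_multimapped_row(rng, gene_serial), LABEL_ARTIFACT))
            gene_serial += 1
        for _ in range(params.n_ambiguous_per_sample):
            rows.append((_ambiguous_row(rng, gene_serial), LABEL_AMBIGUOUS))
            gene_serial += 1
        for rec in planted[sample]:
            rows.append((rec, LABEL_ARTIFACT))
        table = []
        for i, (rec, label) in enumerate(rows, start=1):
            rec.cluster_id = f"{sample}_c{i:04d}"
            rec.sample_id = sample
            table.append(rec)
            labels[(sample, rec.cluster_id)] = label
        tables[sample] = table

    manifest = CohortManifest(
        tuple(
            ManifestEntry(sample, sample_entity[sample], Path(f"{sample}.tsv"))
            for sample in sample_ids
        )
    )
    return SyntheticCohort(manifest, tables, labels, seed, params)


def write_cohort(cohort: SyntheticCohort, directory: str | PathLike) -> Path:
    """Write per-sample tables, the manifest, truth labels, and the
    true-fusion pair list into ``directory``; returns the manifest path."""
    from .io import write_fusion_table, write_pair_list

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for entry in cohort.manifest:
        write_fusion_table(cohort.tables[entry.sample_id], directory / f"{entry.sample_id}.tsv")
    manifest_path = directory / "manifest.tsv"
    write_manifest(cohort.manifest, manifest_path)
    with open(directory / "labels.tsv", "w", encoding="utf-8") as fh:
        fh.write("sample_id\tcluster_id\tlabel\n")
        for entry in cohort.manifest:
            for rec in cohort.tables[entry.sample_id]:
                fh.write(
                    f"{rec.sample_id}\t{rec.cluster_id}\t"
                    f"{cohort.labels[(rec.sample_id, rec.cluster_id)]}\n"
                )
    write_pair_list(cohort.truth_pairs(), directory / "truth_pairs.txt")
    return manifest_path
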