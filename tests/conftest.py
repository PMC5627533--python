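"""Shared fixtures: randomized valid transcripts and an independent
brute-force scorer used as the oracle for the rule engine."""

from __future__ import annotations

import numpy as np
import pytest

from fusescore import CohortParams, FusionTranscript, generate_cohort


def random_transcript(
    rng: np.random.Generator,
    serial: int,
    sample_id: str = "S1",
    pair_pool: list[tuple[str, str]] | None = None,
) -> FusionTranscript:
    """One random transcript satisfying every record invariant, with all
    feature regimes (flags, bin edges, zero counts) reachable."""
    if pair_pool is not None and rng.random() < 0.3:
        gene1, gene2 = pair_pool[int(rng.integers(len(pair_pool)))]
    else:
        gene1, gene2 = f"G{serial:05d}A", f"G{serial:05d}B"
    span = int(rng.integers(0, 80))
    read_through = bool(rng.random() < 0.2)
    interchromosomal = bool(rng.random() < 0.5)
    chrom1 = str(rng.integers(1, 23))
    chrom2 = str(rng.integers(1, 23))
    while interchromosomal == (chrom1 == chrom2):
        chrom2 = str(rng.integers(1, 23))
    return FusionTranscript(
        cluster_id=f"c{serial:05d}",
        sample_id=sample_id,
        gene1=gene1,
        gene2=gene2,
        chrom1=chrom1,
        chrom2=chrom2,
        break_pos1=int(rng.integers(1, 10**8)),
        break_pos2=int(rng.integers(1, 10**8)),
        strand1="+" if rng.random() < 0.5 else "-",
        strand2="+" if rng.random() < 0.5 else "-",
        split_count=int(rng.integers(0, 250)),
        span_count=span,
        unique_span_count=int(rng.integers(0, span + 1)),
        breakpoint_homology=int(rng.integers(0, 25)),
        repeat_proportion=float(rng.choice([rng.uniform(0, 1), 0.8, 0.9, 1.0])),
        read_through=read_through,
        altsplice=bool(rng.random() < 0.3),
        adjacent=read_through or bool(rng.random() < 0.3),
        interchromosomal=interchromosomal,
        orf=bool(rng.random() < 0.5),
        exon_boundary=bool(rng.random() < 0.5),
        downstream_3prime_break=bool(rng.random() < 0.15),
        caller_probability=float(rng.uniform(0, 1)),
    )


def oracle_total(rec: FusionTranscript, in_artifact_list: bool, occurrence: int) -> float:
    """Naive independent restatement of the scoring rules, used to
    cross-check the engine."""
    score = 10.0
    if in_artifact_list:
        score -= 6.0
    if rec.read_through or rec.altsplice:
        score -= 4.0
    elif rec.adjacent:
        score -= 0.5
    if not rec.interchromosomal:
        score -= 0.5
    if rec.breakpoint_homology >= 10:
        score -= 1.0
    if 0.8 <= rec.repeat_proportion < 0.9:
        score -= 0.5
    if rec.repeat_proportion >= 0.9:
        score -= 1.0
    if not rec.orf:
        score -= 1.0
    if not rec.exon_boundary:
        score -= 1.5
    if rec.downstream_3prime_break:
        score -= 4.0
    if rec.span_count > 0 and rec.unique_span_count == 0:
        score -= 1.5
    else:
        tier = 0
        if rec.split_count >= 10:
            tier += 1
        if rec.split_count >= 50:
            tier += 1
        if rec.unique_span_count >= 5:
            tier += 1
        if rec.unique_span_count >= 15:
            tier += 1
        if occurrence >= 2:
            tier += 1
        score += {0: -2.0, 1: -1.0, 2: -0.5, 3: 0.5, 4: 1.5, 5: 2.5}[tier]
    return min(10.0, score)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-parameter synthetic cohort, shared across tests."""
    return generate_cohort(CohortParams(), seed=20260921)
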