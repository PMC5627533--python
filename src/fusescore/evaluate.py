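"""Recovery-rate evaluation against a list of validated fusions.

Matching is at the gene-pair level (orientation- and case-insensitive):
a validated pair counts as recovered when at least one scored transcript
for that pair reaches the score threshold.  Validated pairs with no
scored transcript at all count against recovery, mirroring fusions a
caller filtered out or never detected.
"""

from __future__ import annotations

from dataclasses import dataclass
from os import PathLike
from typing import Sequence

import pandas as pd

from .records import FusionTranscript, GenePair
from .scoring import ScoreBreakdown


@dataclass(frozen=True)
class TruthSet:
    """Canonical gene pairs with independent validation support."""

    pairs: frozenset[GenePair]
    source_label: str = "truth"

    @classmethod
    def from_file(cls, path: str | PathLike, sep: str = "--", source_label: str | None = None) -> "TruthSet":
        from .io import read_pair_list

        return cls(frozenset(read_pair_list(path, sep=sep)), source_label or str(path))


@dataclass(frozen=True)
class RecoveryResult:
    n_recovered: int
    n_truth: int

    @property
    def rate(self) -> float:
        return self.n_recovered / self.n_truth

    @property
    def percent(self) -> float:
        return 100.0 * self.rate


def _best_score_per_pair(
    scored: Sequence[tuple[FusionTranscript, ScoreBreakdown]],
) -> dict[GenePair, float]:
    best: dict[GenePair, float] = {}
    for rec, brk in scored:
        pair = rec.pair
        if pair not in best or brk.total > best[pair]:
            best[pair] = brk.total
    return best


def recovery_rate(
    truth: TruthSet,
    scored: Sequence[tuple[FusionTranscript, ScoreBreakdown]],
    threshold: float,
) -> RecoveryResult:
    """Fraction of validated pairs with a scored transcript at or above
    ``threshold``."""
    if not truth.pairs:
        raise ValueError("truth set is empty")
    best = _best_score_per_pair(scored)
    recovered = sum(
        1 for pair in truth.pairs if best.get(pair, float("-inf")) >= threshold
    )
    return RecoveryResult(recovered, len(truth.pairs))


def threshold_sweep(
    truth: TruthSet,
    scored: Sequence[tuple[FusionTranscript, ScoreBreakdown]],
    thresholds: Sequence[float],
) -> pd.DataFrame:
    """Recovery and candidate counts at each threshold (ascending).

    Returns a frame with columns ``threshold``, ``n_candidates`` (scored
    rows at or above the threshold), ``n_recovered``, ``n_truth`` and
    ``recovery``; both ``n_candidates`` and ``recovery`` are
    non-increasing in the threshold.
    """
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    totals = [brk.total for _, brk in scored]
    rows = []
    for thr in thresholds:
        result = recovery_rate(truth, scored, thr)
        rows.append(
            {
                "threshold": thr,
                "n_candidates": sum(1 for t in totals if t >= thr),
                "n_recovered": result.n_recovered,
                "n_truth": result.n_truth,
                "recovery": result.rate,
            }
        )
    return pd.DataFrame(rows)
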