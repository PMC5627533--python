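"""Confidence scoring of fusion-transcript candidates.

Every candidate starts from a baseline score of 10 and accumulates
half-integer score weights, one per feature rule that fires:

==========================  =======  ==============================================
component                   default  fires when
==========================  =======  ==============================================
artifact                    -6       gene pair is on the recurrent-artifact list
read_through_altsplice      -4       caller flagged read-through OR alt. splicing
adjacent_only               -0.5     partners adjacent, but no read-through/altsplice
intrachromosomal            -0.5     partners share a chromosome
homology                    -1       breakpoint homology >= 10 bases
repeat_mid                  -0.5     repeat proportion in [0.8, 0.9)
repeat_high                 -1       repeat proportion in [0.9, 1.0]
no_orf                      -1       open reading frame not preserved
not_exon_boundary           -1.5     splicing point not at a known exon boundary
downstream_3prime           -4       breakpoint downstream of the 3' partner
read_support                varies   always; -1.5 when every spanning read multimaps,
                                     otherwise a tier in [-2.0, +2.5] driven by
                                     split reads, uniquely mapped spanning reads,
                                     and same-pair occurrence within the sample
==========================  =======  ==============================================

The total is capped at 10 and classified as high (>= 8), medium
(6.5-7.5) or low (<= 6).  Because every weight is a multiple of 0.5, no
total can land strictly inside (6, 6.5) or (7.5, 8), so the three
classes are exhaustive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import yaml

from .errors import ConfigError, ScoreLatticeError
from .records import FusionTranscript, GenePair

if TYPE_CHECKING:  # pragma: no cover
    from .artifacts import ArtifactList

HIGH = "high"
MEDIUM = "medium"
LOW = "low"

#: Fixed component order, used for stable serialization of score tables.
COMPONENT_NAMES: tuple[str, ...] = (
    "artifact",
    "read_through_altsplice",
    "adjacent_only",
    "intrachromosomal",
    "homology",
    "repeat_mid",
    "repeat_high",
    "no_orf",
    "not_exon_boundary",
    "downstream_3prime",
    "read_support",
)


def _is_half_integer(x: float) -> bool:
    return math.isclose(x * 2, round(x * 2), abs_tol=1e-9)


@dataclass(frozen=True)
class ReadSupportTable:
    """Tiered mapping from read support to a score component.

    A support index counts how many of five evidence criteria hold:
    ``split_count`` reaching each of ``split_cuts``, ``unique_span_count``
    reaching each of ``unique_cuts``, and the within-sample occurrence of
    the gene pair reaching ``occurrence_cut``.  The index selects one of
    the six ``tier_scores``, which must be monotone non-decreasing,
    non-zero, and confined to [-2.0, +2.5].
    """

    split_cuts: tuple[int, int] = (10, 50)
    unique_cuts: tuple[int, int] = (5, 15)
    occurrence_cut: int = 2
    tier_scores: tuple[float, ...] = (-2.0, -1.0, -0.5, 0.5, 1.5, 2.5)

    def __post_init__(self):
        n_tiers = len(self.split_cuts) + len(self.unique_cuts) + 2
        if len(self.tier_scores) != n_tiers:
            raise ConfigError(
                f"read-support table needs {n_tiers} tier scores, got {len(self.tier_scores)}"
            )
        for s in self.tier_scores:
            if s == 0:
                raise ConfigError("read-support tier scores must be non-zero")
            if not -2.0 <= s <= 2.5:
                raise ConfigError(f"read-support tier score {s} outside [-2.0, +2.5]")
            if not _is_half_integer(s):
                raise ConfigError(f"read-support tier score {s} is not a multiple of 0.5")
        if list(self.tier_scores) != sorted(self.tier_scores):
            raise ConfigError("read-support tier scores must be non-decreasing")

    def index(self, split_count: int, unique_span_count: int, occurrence: int) -> int:
        idx = sum(split_count >= c for c in self.split_cuts)
        idx += sum(unique_span_count >= c for c in self.unique_cuts)
        idx += occurrence >= self.occurrence_cut
        return idx


@dataclass(frozen=True)
class WeightConfig:
    """Every weight, threshold, and bin edge of the scoring method."""

    baseline: float = 10.0
    w_artifact: float = -6.0
    w_readthrough_altsplice: float = -4.0
    w_adjacent_only: float = -0.5
    w_intrachromosomal: float = -0.5
    w_no_orf: float = -1.0
    w_not_exon_boundary: float = -1.5
    w_downstream_3prime: float = -4.0
    w_homology: float = -1.0
    homology_threshold: int = 10
    w_repeat_mid: float = -0.5
    w_repeat_high: float = -1.0
    repeat_mid_edge: float = 0.8
    repeat_high_edge: float = 0.9
    w_all_multimapped: float = -1.5
    read_support_table: ReadSupportTable = field(default_factory=ReadSupportTable)
    score_cap: float = 10.0
    high_min: float = 8.0
    medium_min: float = 6.5
    medium_max: float = 7.5
    low_max: float = 6.0
    # Partner distance (bp) beyond which the intrachromosomal penalty is
    # waived; None applies the penalty unconditionally.
    intrachromosomal_max_distance: int | None = None

    def __post_init__(self):
        for name in (
            "baseline", "w_artifact", "w_readthrough_altsplice", "w_adjacent_only",
            "w_intrachromosomal", "w_no_orf", "w_not_exon_boundary",
            "w_downstream_3prime", "w_homology", "w_repeat_mid", "w_repeat_high",
            "w_all_multimapped", "score_cap", "high_min", "medium_min",
            "medium_max", "low_max",
        ):
            if not _is_half_integer(getattr(self, name)):
                raise ConfigError(f"{name}={getattr(self, name)} is not a multiple of 0.5")
        if not self.medium_max < self.high_min <= self.score_cap:
            raise ConfigError(
                "class thresholds must satisfy medium_max < high_min <= score_cap"
            )
        if not self.low_max < self.medium_min <= self.medium_max:
            raise ConfigError(
                "class thresholds must satisfy low_max < medium_min <= medium_max"
            )
        if not 0.0 <= self.repeat_mid_edge < self.repeat_high_edge <= 1.0:
            raise ConfigError("repeat bin edges must satisfy 0 <= mid < high <= 1")

    # -- serialization -------------------------------------------------

    @classmethod
    def from_yaml(cls, path) -> "WeightConfig":
        """Load weights from a flat YAML mapping; unknown keys are rejected."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"weight config {path} must be a mapping")
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        table_keys = {f for f in ReadSupportTable.__dataclass_fields__}  # type: ignore[attr-defined]
        kwargs: dict = {}
        table_kwargs: dict = {}
        for key, value in raw.items():
            if key in table_keys:
                table_kwargs[key] = tuple(value) if isinstance(value, list) else value
            elif key == "read_support_table":
                if not isinstance(value, dict):
                    raise ConfigError("read_support_table must be a mapping")
                for k, v in value.items():
                    if k not in table_keys:
                        raise ConfigError(f"unknown weight config key: read_support_table.{k}")
                    table_kwargs[k] = tuple(v) if isinstance(v, list) else v
            elif key in known:
                kwargs[key] = value
            else:
                raise ConfigError(f"unknown weight config key: {key}")
        if table_kwargs:
            kwargs["read_support_table"] = ReadSupportTable(**table_kwargs)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["read_support_table"] = {
            "split_cuts": list(self.read_support_table.split_cuts),
            "unique_cuts": list(self.read_support_table.unique_cuts),
            "occurrence_cut": self.read_support_table.occurrence_cut,
            "tier_scores": list(self.read_support_table.tier_scores),
        }
        return d


DEFAULT_WEIGHTS = WeightConfig()


@dataclass(frozen=True)
class ScoreBreakdown:
    """Per-feature score components and the resulting class for one row."""

    components: Mapping[str, float]
    raw_total: float
    total: float
    confidence_class: str
    occurrence: int

    def component(self, name: str) -> float:
        """Value of a named component; 0.0 if the rule did not fire."""
        return self.components.get(name, 0.0)


def compute_occurrence(records: Sequence[FusionTranscript]) -> dict[GenePair, int]:
    """Count transcripts per canonical gene pair within one sample.

    The caller sometimes reports several transcripts for the same partner
    pair; that multiplicity ("occurrence") feeds the read-support tier.
    """
    samples = {r.sample_id for r in records}
    if len(samples) > 1:
        raise ValueError(f"records span multiple samples: {sorted(samples)}")
    counts: dict[GenePair, int] = {}
    for rec in records:
        p = rec.pair
        counts[p] = counts.get(p, 0) + 1
    return counts


def read_support_score(
    split_count: int,
    span_count: int,
    unique_span_count: int,
    occurrence: int,
    cfg: WeightConfig = DEFAULT_WEIGHTS,
) -> float:
    """Read-support component: positive for well-supported junctions,
    negative otherwise; exactly ``w_all_multimapped`` when spanning reads
    exist but none maps uniquely."""
    if span_count > 0 and unique_span_count == 0:
        return cfg.w_all_multimapped
    table = cfg.read_support_table
    return table.tier_scores[table.index(split_count, unique_span_count, occurrence)]


def classify(total: float, cfg: WeightConfig = DEFAULT_WEIGHTS) -> str:
    """Map a total score to high / medium / low confidence."""
    if total >= cfg.high_min:
        return HIGH
    if cfg.medium_min <= total <= cfg.medium_max:
        return MEDIUM
    if total <= cfg.low_max:
        return LOW
    raise ScoreLatticeError(
        f"total {total} falls between confidence classes; "
        "weights are expected to be multiples of 0.5"
    )


def score_candidate(
    rec: FusionTranscript,
    artifacts: ArtifactList | None = None,
    occurrence: int = 1,
    cfg: WeightConfig = DEFAULT_WEIGHTS,
) -> ScoreBreakdown:
    """Assemble the score breakdown for a single candidate.

    ``occurrence`` is the number of transcripts sharing this candidate's
    gene pair within its sample (>= 1); use :func:`score_table` to have
    it computed automatically.
    """
    if occurrence < 1:
        raise ValueError(f"occurrence must be >= 1, got {occurrence}")
    components: dict[str, float] = {}

    if artifacts is not None and artifacts.contains(rec.pair):
        components["artifact"] = cfg.w_artifact

    if rec.read_through or rec.altsplice:
        components["read_through_altsplice"] = cfg.w_readthrough_altsplice
    elif rec.adjacent:
        components["adjacent_only"] = cfg.w_adjacent_only

    if not rec.interchromosomal:
        waived = (
            cfg.intrachromosomal_max_distance is not None
            and abs(rec.break_pos1 - rec.break_pos2) > cfg.intrachromosomal_max_distance
        )
        if not waived:
            components["intrachromosomal"] = cfg.w_intrachromosomal

    if rec.breakpoint_homology >= cfg.homology_threshold:
        components["homology"] = cfg.w_homology

    if cfg.repeat_mid_edge <= rec.repeat_proportion < cfg.repeat_high_edge:
        components["repeat_mid"] = cfg.w_repeat_mid
    elif rec.repeat_proportion >= cfg.repeat_high_edge:
        components["repeat_high"] = cfg.w_repeat_high

    if not rec.orf:
        components["no_orf"] = cfg.w_no_orf
    if not rec.exon_boundary:
        components["not_exon_boundary"] = cfg.w_not_exon_boundary

    if rec.downstream_3prime_break:
        components["downstream_3prime"] = cfg.w_downstream_3prime

    components["read_support"] = read_support_score(
        rec.split_count, rec.span_count, rec.unique_span_count, occurrence, cfg
    )

    raw_total = cfg.baseline + sum(components.values())
    total = min(cfg.score_cap, raw_total)
    return ScoreBreakdown(
        components=components,
        raw_total=raw_total,
        total=total,
        confidence_class=classify(total, cfg),
        occurrence=occurrence,
    )


def score_table(
    records: Iterable[FusionTranscript],
    artifacts: ArtifactList | None = None,
    cfg: WeightConfig = DEFAULT_WEIGHTS,
) -> list[tuple[FusionTranscript, ScoreBreakdown]]:
    """Score a table of candidates, grouping rows by sample to compute
    per-pair occurrence.

    Returns one ``(record, breakdown)`` tuple per input row, ordered by
    total score descending with ties broken by ``cluster_id`` ascending;
    results are invariant to input row order.
    """
    records = list(records)
    by_sample: dict[str, list[FusionTranscript]] = {}
    for rec in records:
        by_sample.setdefault(rec.sample_id, []).append(rec)
    occurrence = {
        sample: compute_occurrence(rows) for sample, rows in by_sample.items()
    }
    scored = [
        (rec, score_candidate(rec, artifacts, occurrence[rec.sample_id][rec.pair], cfg))
        for rec in records
    ]
    scored.sort(key=lambda pair: (-pair[1].total, pair[0].cluster_id))
    return scored
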