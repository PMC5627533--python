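"""Reading and writing fusion-candidate tables.

The on-disk dialect is tab-separated UTF-8 with a header row and no
quoting, following the deFuse output convention: boolean annotation
flags are encoded ``Y``/``N`` (``true``/``false``/``1``/``0`` are also
accepted on input, case-insensitively).

Tables from other caller versions are mapped onto the canonical column
set through a column-alias mapping.  An alias value is either a source
column name, ``("max", col_a, col_b)`` to take the elementwise maximum
of two numeric columns (used for the two per-partner repeat proportions),
or ``("sub", col_a, col_b)`` to take a difference (e.g. deriving uniquely
mapping spanning reads from a total and a multimapped count).
"""

from __future__ import annotations

import logging
from os import PathLike
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigError, ValidationError
from .records import (
    BOOLEAN_FIELDS,
    CANONICAL_COLUMNS,
    FLOAT_FIELDS,
    INT_FIELDS,
    FusionTranscript,
    GenePair,
)
from .scoring import COMPONENT_NAMES, ScoreBreakdown

logger = logging.getLogger(__name__)

#: Aliases resolving genuine deFuse v0.6.x headers onto the canonical set.
DEFUSE_ALIASES: dict[str, object] = {
    "gene1": "gene_name1",
    "gene2": "gene_name2",
    "chrom1": "gene_chromosome1",
    "chrom2": "gene_chromosome2",
    "break_pos1": "genomic_break_pos1",
    "break_pos2": "genomic_break_pos2",
    "strand1": "genomic_strand1",
    "strand2": "genomic_strand2",
    "split_count": "splitr_count",
    "repeat_proportion": ("max", "repeat_proportion1", "repeat_proportion2"),
    "exon_boundary": "exonboundaries",
    "caller_probability": "probability",
}

_TRUE = {"y", "yes", "true", "1"}
_FALSE = {"n", "no", "false", "0"}


def _parse_bool(cell: str) -> bool:
    low = cell.strip().lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise ValueError(f"not a boolean (expected Y/N): {cell!r}")


def _format_bool(value: bool) -> str:
    return "Y" if value else "N"


def _resolve_columns(
    header: Sequence[str],
    column_aliases: Mapping[str, object] | None,
) -> dict[str, object]:
    """Map each canonical field to its source column (or derived spec).

    Canonical names present in the header win; user aliases override the
    built-in deFuse aliases.  ``sample_id`` is optional (supplied by the
    caller), ``unique_span_count`` falls back to ``span_count`` and
    ``downstream_3prime_break`` to false, each with a logged warning.
    """
    aliases = dict(DEFUSE_ALIASES)
    if column_aliases:
        aliases.update(column_aliases)
    present = set(header)
    resolved: dict[str, object] = {}
    for name in CANONICAL_COLUMNS:
        if name in present:
            resolved[name] = name
            continue
        spec = aliases.get(name)
        if spec is not None:
            if isinstance(spec, str):
                if spec in present:
                    resolved[name] = spec
                    continue
            else:
                op, col_a, col_b = spec
                if op not in ("max", "sub"):
                    raise ConfigError(f"unknown alias operation {op!r} for column {name!r}")
                if col_a in present and col_b in present:
                    resolved[name] = (op, col_a, col_b)
                    continue
        if name == "sample_id":
            resolved[name] = None
        elif name == "unique_span_count":
            logger.warning(
                "no column for unique_span_count; assuming all spanning reads map uniquely"
            )
            resolved[name] = "span_count" if "span_count" in present else None
            if resolved[name] is None:
                raise ConfigError("missing required column: span_count")
        elif name == "downstream_3prime_break":
            logger.warning("no column for downstream_3prime_break; assuming false")
            resolved[name] = None
        else:
            raise ConfigError(f"missing required column: {name}")
    return resolved


def _convert(name: str, cell: str):
    if name in BOOLEAN_FIELDS:
        return _parse_bool(cell)
    if name in INT_FIELDS:
        return int(cell)
    if name in FLOAT_FIELDS:
        return float(cell)
    return cell


def read_fusion_table(
    path: str | PathLike,
    column_aliases: Mapping[str, object] | None = None,
    sample_id: str | None = None,
) -> list[FusionTranscript]:
    """Read a fusion-candidate table into records, preserving row order.

    ``sample_id`` labels the rows when the table itself has no
    ``sample_id`` column; it defaults to the file's stem.  Rows violating
    a record invariant raise :class:`ValidationError` naming the row.
    An empty table yields an empty list.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"fusion table not found: {path}")
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return []
    resolved = _resolve_columns(frame.columns, column_aliases)
    fallback_sample = sample_id if sample_id is not None else path.stem
    records: list[FusionTranscript] = []
    for idx, row in enumerate(frame.to_dict(orient="records"), start=1):
        values: dict[str, object] = {}
        for name, source in resolved.items():
            try:
                if source is None:
                    if name == "sample_id":
                        values[name] = fallback_sample
                    else:  # downstream_3prime_break fallback
                        values[name] = False
                elif isinstance(source, str):
                    values[name] = _convert(name, row[source])
                else:
                    op, col_a, col_b = source
                    a = float(row[col_a])
                    b = float(row[col_b])
                    value = max(a, b) if op == "max" else a - b
                    values[name] = int(value) if name in INT_FIELDS else value
            except (ValueError, TypeError) as exc:
                raise ValidationError(f"row {idx}, column {name!r}: {exc}") from exc
        try:
            records.append(FusionTranscript(**values))
        except ValidationError as exc:
            raise ValidationError(f"row {idx}: {exc}") from exc
    return records


def _transcript_cell(rec: FusionTranscript, name: str) -> str:
    value = getattr(rec, name)
    if name in BOOLEAN_FIELDS:
        return _format_bool(value)
    return str(value)


def write_fusion_table(records: Iterable[FusionTranscript], path: str | PathLike) -> None:
    """Write records in the canonical dialect, preserving input order."""
    rows = [[_transcript_cell(r, c) for c in CANONICAL_COLUMNS] for r in records]
    frame = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
    frame.to_csv(path, sep="\t", index=False)


_SCORE_COLUMNS = tuple(f"score_{name}" for name in COMPONENT_NAMES)
_EXTRA_COLUMNS = _SCORE_COLUMNS + (
    "occurrence",
    "score_raw_total",
    "score_total",
    "confidence",
)


def write_scored_table(
    scored: Sequence[tuple[FusionTranscript, ScoreBreakdown]],
    path: str | PathLike,
) -> None:
    """Write a scored table: canonical columns plus one column per score
    component, occurrence, totals, and the confidence class.

    Rows are ordered by total score descending, ties broken by
    ``cluster_id`` ascending.  Scores are serialized with one decimal
    place (all weights are half-integer multiples), so re-reading
    reproduces them exactly.
    """
    ordered = sorted(scored, key=lambda pair: (-pair[1].total, pair[0].cluster_id))
    rows = []
    for rec, brk in ordered:
        row = [_transcript_cell(rec, c) for c in CANONICAL_COLUMNS]
        row += [f"{brk.component(name):.1f}" for name in COMPONENT_NAMES]
        row += [
            str(brk.occurrence),
            f"{brk.raw_total:.1f}",
            f"{brk.total:.1f}",
            brk.confidence_class,
        ]
        rows.append(row)
    frame = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS + _EXTRA_COLUMNS))
    frame.to_csv(path, sep="\t", index=False)


def read_scored_table(
    path: str | PathLike,
) -> list[tuple[FusionTranscript, ScoreBreakdown]]:
    """Read back a table written by :func:`write_scored_table`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"scored table not found: {path}")
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for column in CANONICAL_COLUMNS + _EXTRA_COLUMNS:
        if column not in frame.columns:
            raise ConfigError(f"missing required column: {column}")
    out: list[tuple[FusionTranscript, ScoreBreakdown]] = []
    for idx, row in enumerate(frame.to_dict(orient="records"), start=1):
        try:
            rec = FusionTranscript(
                **{c: _convert(c, row[c]) for c in CANONICAL_COLUMNS}
            )
            components = {}
            for name in COMPONENT_NAMES:
                value = float(row[f"score_{name}"])
                if value != 0.0 or name == "read_support":
                    components[name] = value
            brk = ScoreBreakdown(
                components=components,
                raw_total=float(row["score_raw_total"]),
                total=float(row["score_total"]),
                confidence_class=row["confidence"],
                occurrence=int(row["occurrence"]),
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"row {idx}: {exc}") from exc
        out.append((rec, brk))
    return out


def read_pair_list(path: str | PathLike, sep: str = "--") -> set[GenePair]:
    """Read a whitelist/truth file: one ``GENEA--GENEB`` pair per line.

    Blank lines and ``#`` comments are ignored; pairs are canonicalized.
    """
    pairs: set[GenePair] = set()
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            pairs.add(GenePair.parse(line, sep=sep))
    return pairs


def write_pair_list(pairs: Iterable[GenePair], path: str | PathLike, sep: str = "--") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pair in sorted(pairs):
            fh.write(pair.format(sep) + "\n")
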