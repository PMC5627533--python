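"""Recurrent-artifact list: gene pairs called across unrelated tumor entities.

Genuinely identical fusions recurring across multiple unrelated tumor
entities are rare; pairs that do recur are overwhelmingly mapping or
library artifacts (repeats, paralogy, misalignment).  The registry
counts, for every canonical gene pair, the number of *distinct* entity
labels in which the pair was called at least once — multiple samples or
multiple transcripts within one entity count once — and blacklists the
pairs reaching a recurrence threshold (default: three entities).
Known-true fusions can be exempted through a whitelist.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from os import PathLike
from pathlib import Path
from typing import Iterable, Mapping

from .errors import TableParseError, ValidationError
from .records import GenePair

DEFAULT_MIN_ENTITIES = 3


@dataclass(frozen=True)
class ManifestEntry:
    sample_id: str
    entity: str
    table_path: Path


@dataclass(frozen=True)
class CohortManifest:
    """Sample -> entity -> table mapping for artifact-list construction."""

    entries: tuple[ManifestEntry, ...]

    def __post_init__(self):
        seen: set[str] = set()
        for entry in self.entries:
            if entry.sample_id in seen:
                raise ValidationError(f"duplicate sample_id in manifest: {entry.sample_id}")
            seen.add(entry.sample_id)
            if not entry.entity.strip():
                raise ValidationError(f"empty entity label for sample {entry.sample_id}")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)


def read_manifest(path: str | PathLike) -> CohortManifest:
    """Read a TSV manifest (columns sample_id, entity, path).

    Relative table paths are resolved against the manifest's directory.
    """
    path = Path(path)
    base = path.parent
    entries: list[ManifestEntry] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["sample_id", "entity", "path"]:
            raise TableParseError(
                f"manifest header must be sample_id<TAB>entity<TAB>path, got {header}", line=1
            )
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise TableParseError(f"expected 3 columns, got {len(parts)}", line=lineno)
            sample_id, entity, table = parts
            table_path = Path(table)
            if not table_path.is_absolute():
                table_path = base / table_path
            entries.append(ManifestEntry(sample_id, entity, table_path))
    return CohortManifest(tuple(entries))


def write_manifest(manifest: CohortManifest, path: str | PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tentity\tpath\n")
        for entry in manifest:
            fh.write(f"{entry.sample_id}\t{entry.entity}\t{entry.table_path}\n")


@dataclass(frozen=True)
class ArtifactList:
    """Blacklist of recurrent gene pairs plus provenance counts.

    ``entity_counts`` covers every pair observed at build time, including
    sub-threshold ones, so a saved list reloads losslessly; ``pairs``
    holds only the blacklisted subset (count >= ``min_entities``, minus
    the whitelist).
    """

    pairs: frozenset[GenePair]
    entity_counts: Mapping[GenePair, int]
    min_entities: int
    whitelist: frozenset[GenePair] = frozenset()

    def __post_init__(self):
        for pair in self.pairs:
            if self.entity_counts.get(pair, 0) < self.min_entities:
                raise ValidationError(
                    f"pair {pair} listed with entity count below threshold {self.min_entities}"
                )
        if self.pairs & self.whitelist:
            raise ValidationError("artifact pairs and whitelist must be disjoint")

    def contains(self, pair: GenePair) -> bool:
        return pair in self.pairs

    def __contains__(self, pair: GenePair) -> bool:
        return self.contains(pair)

    def __len__(self) -> int:
        return len(self.pairs)

    @classmethod
    def empty(cls, min_entities: int = DEFAULT_MIN_ENTITIES) -> "ArtifactList":
        return cls(frozenset(), {}, min_entities)

    @classmethod
    def from_counts(
        cls,
        entity_counts: Mapping[GenePair, int],
        min_entities: int,
        whitelist: Iterable[GenePair] = (),
    ) -> "ArtifactList":
        whitelist = frozenset(whitelist)
        pairs = frozenset(
            p for p, n in entity_counts.items() if n >= min_entities and p not in whitelist
        )
        return cls(pairs, dict(entity_counts), min_entities, whitelist)


def build_artifact_list(
    manifest: CohortManifest,
    min_entities: int = DEFAULT_MIN_ENTITIES,
    whitelist: Iterable[GenePair] = (),
    column_aliases: Mapping[str, object] | None = None,
) -> ArtifactList:
    """Count distinct entities per gene pair across the cohort and
    blacklist pairs reaching ``min_entities``, excluding the whitelist."""
    from .io import read_fusion_table  # deferred to keep module imports acyclic

    if min_entities < 1:
        raise ValueError(f"min_entities must be >= 1, got {min_entities}")
    entities_seen: dict[GenePair, set[str]] = {}
    for entry in manifest:
        try:
            records = read_fusion_table(
                entry.table_path, column_aliases=column_aliases, sample_id=entry.sample_id
            )
        except OSError as exc:
            raise OSError(
                f"cannot read table for sample {entry.sample_id!r} "
                f"(entity {entry.entity!r}): {exc}"
            ) from exc
        for rec in records:
            entities_seen.setdefault(rec.pair, set()).add(entry.entity)
    counts = {pair: len(ents) for pair, ents in entities_seen.items()}
    return ArtifactList.from_counts(counts, min_entities, whitelist)


def save_artifact_list(artifacts: ArtifactList, path: str | PathLike) -> None:
    """Persist as TSV: comment header with build metadata, then one
    ``pair<TAB>entity_count`` row per observed pair."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# min_entities\t{artifacts.min_entities}\n")
        fh.write(f"# whitelist_size\t{len(artifacts.whitelist)}\n")
        for pair in sorted(artifacts.whitelist):
            fh.write(f"# whitelist\t{pair.format()}\n")
        fh.write("pair\tentity_count\n")
        for pair in sorted(artifacts.entity_counts):
            fh.write(f"{pair.format()}\t{artifacts.entity_counts[pair]}\n")


def load_artifact_list(path: str | PathLike) -> ArtifactList:
    """Inverse of :func:`save_artifact_list`; ``load(save(x)) == x``."""
    min_entities: int | None = None
    whitelist: set[GenePair] = set()
    counts: dict[GenePair, int] = {}
    header_seen = False
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                parts = line[1:].strip().split("\t")
                if parts[0] == "min_entities":
                    try:
                        min_entities = int(parts[1])
                    except (IndexError, ValueError) as exc:
                        raise TableParseError(f"bad min_entities header: {line!r}", line=lineno) from exc
                elif parts[0] == "whitelist":
                    try:
                        whitelist.add(GenePair.parse(parts[1]))
                    except (IndexError, ValidationError) as exc:
                        raise TableParseError(f"bad whitelist header: {line!r}", line=lineno) from exc
                continue
            if not header_seen:
                if line.split("\t") != ["pair", "entity_count"]:
                    raise TableParseError(
                        f"expected header pair<TAB>entity_count, got {line!r}", line=lineno
                    )
                header_seen = True
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise TableParseError(f"expected 2 columns, got {len(parts)}", line=lineno)
            try:
                counts[GenePair.parse(parts[0])] = int(parts[1])
            except (ValueError, ValidationError) as exc:
                raise TableParseError(f"bad row {line!r}: {exc}", line=lineno) from exc
    if min_entities is None:
        raise TableParseError(f"missing '# min_entities' header in {path}")
    return ArtifactList.from_counts(counts, min_entities, whitelist)
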