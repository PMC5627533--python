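# Methods

## Model

`fusescore` treats fusion-candidate prioritization as a deterministic,
additive rule system rather than a learned classifier. Each putative
fusion transcript receives

    total = min(score_cap, baseline + Σ components)

with `baseline = 10` and `score_cap = 10`. Every component is a
half-integer weight attached to one interpretable feature rule (see the
README table); the read-support component always fires, all others are
conditional. The assumptions are those of the underlying feature set:

* Candidates come from a caller that reports split reads, spanning
  read pairs, breakpoint homology, per-partner repeat overlap of
  spanning reads, and structural annotation flags (read-through,
  altsplice, adjacency, ORF preservation, exon-boundary breakpoints,
  downstream-3′ breakpoints). These annotations are consumed as given
  and never recomputed — in particular `downstream_3prime_break`,
  which would require transcript models the tool does not read.
* Identical fusions recurring across *unrelated* tumor entities are
  overwhelmingly artifacts; genuine recurrent fusions are handled by a
  whitelist.
* Gene-pair identity is unordered and case-insensitive. Mapping
  artifacts are orientation-unstable and validated-fusion lists rarely
  preserve 5′/3′ order, so artifact and truth matching ignore
  orientation.

## Parameters

All weights live in `WeightConfig` (YAML-serializable; unknown keys are
rejected). Units are score points; defaults are the published values:
artifact −6, read-through/altsplice −4, adjacent-only −0.5,
intrachromosomal −0.5, homology −1 at a threshold of 10 bases, repeat
bins [0.8, 0.9) → −0.5 and [0.9, 1.0] → −1, no-ORF −1, non-exon-boundary
−1.5, downstream-3′ −4, all-spanning-reads-multimapped −1.5. Class
thresholds: high ≥ 8, medium 6.5–7.5, low ≤ 6.

The read-support tier table maps a support index — how many of
`split_count ≥ 10`, `split_count ≥ 50`, `unique_span_count ≥ 5`,
`unique_span_count ≥ 15`, `occurrence ≥ 2` hold — to
(−2.0, −1.0, −0.5, +0.5, +1.5, +2.5). The published method bounds this
component (+0.5…+2.5 for well-supported fusions, −0.5…−2.0 otherwise)
and pins only the all-multimapped value (−1.5); the full cell values
are not public, so this table is the package's own monotone
interpolation within those bounds. It is configurable and can be
replaced cell-for-cell if an authoritative table is available.

The artifact-list recurrence threshold `min_entities` defaults to 3
distinct entities. Counting is strictly entity-level: any number of
samples or transcripts within one entity contributes once, so one noisy
cohort cannot blacklist a pair on its own.

## Numerical and boundary conventions

* All weights are validated to be multiples of 0.5; this makes the
  three confidence classes exhaustive (no total can land in (6, 6.5) or
  (7.5, 8) — if one does, a misconfiguration error is raised rather
  than a silent misclassification). Sums of halves are exact in binary
  floating point, so additivity is asserted with `==`, not a tolerance.
* The cap at 10 applies to the summed total. High read support can
  therefore mask part of one penalty (e.g. an altsplice candidate with
  maximal support reaches min(10, 10 − 4 + 2.5) = 8.5); the blacklist
  penalty of −6 is deep enough that no support level can lift a listed
  pair back to high.
* Repeat bins are half-open/closed: [0.8, 0.9) and [0.9, 1.0]. A
  proportion of exactly 0.9 takes the −1 penalty; this keeps the bins
  adjacent and exhaustive.
* The all-multimapped rule requires `span_count > 0`; with zero
  spanning reads it would be vacuous, and such rows fall through to the
  tier table (usually its lowest tiers).
* The intrachromosomal penalty is unconditional by default; setting
  `intrachromosomal_max_distance` waives it for same-chromosome
  partners further apart than the given distance in bp. No default
  distance is shipped — what counts as "far" depends on the genome and
  the question, so the cutoff is user-supplied.
* Homology exactly at the threshold (10 bases) is penalized (`≥`).
* Output ordering is total score descending, then `cluster_id`
  ascending, so repeated runs diff cleanly.
* Chromosome names are compared after stripping an optional `chr`
  prefix and case-folding; the `interchromosomal` flag must agree with
  that comparison or the row is rejected.

## Input dialect

Tables are TSV with a header, booleans encoded Y/N on disk
(`true/false/1/0` accepted case-insensitively on input). Caller-version
drift is absorbed by a column-alias mapping; the built-in aliases cover
deFuse v0.6.x headers (`splitr_count`, `gene_name1`, `exonboundaries`,
…), taking the per-candidate maximum of the two per-partner repeat
proportions. Two columns are optional because real caller output may
lack them: `unique_span_count` falls back to `span_count` (optimistic:
assumes all spanning reads map uniquely) and `downstream_3prime_break`
to false, each with a logged warning; an alias of the form
`("sub", "span_count", "<multimap column>")` derives the unique count
when the caller exposes multimapping as a separate column. Every other
missing column is a hard configuration error.

## Synthetic cohorts

The generator (`fusescore.simulate`) emulates a multi-entity cohort of
caller output with known per-row labels. True-fusion rows draw features
uniformly from the ranges observed for validated fusions: 5–200 split
reads, 2–50 spanning reads with 80–100% mapping uniquely, homology
below 10 bases, repeat overlap below 0.8, 90% interchromosomal, ORF
preserved 90% and exon-boundary breakpoints 95% of the time. Artifact
rows are read-through/altsplice transcripts between adjacent genes with
modest support (these arise from ordinary transcription, not
rearrangement, so they are not backed by strong unique junction
evidence), all-multimapped candidates, or designated recurrent pairs
planted into 3–5 distinct entities. Ambiguous rows sit exactly on rule
boundaries (homology 10, repeat 0.8 or 0.9) for boundary testing.
Distributions are uniform or categorical within those ranges — the
source material gives ranges, not distributions — and each row uses a
fresh gene pair so true fusions never recur across entities.

Default cohort size is 12 samples across 5 entities with 3 true, 5
read-through, 2 multimapped and 1 ambiguous row per sample plus 8
recurrent pairs (~160 rows); property suites use up to 10,000
randomized rows. These sizes keep the full suite fast while covering
every rule and tier.

What passing on synthetic data shows — and does not. The generator
plants features directly, so tests demonstrate that the rules fire
exactly as specified, that the blacklist recovers planted recurrences,
and that planted true fusions separate from planted artifacts (≥ 95%
high; read-through rows never high). It does not demonstrate
performance on real tumors: real feature distributions are correlated
(expression, mappability, library artifacts), real artifacts are not
guaranteed to recur in ≥ 3 entities, and real true fusions can carry
adverse features. Cohort-scale precision/recall claims require real
validated data.

## Known limitations

* The read-support tier table is an interpolation (see above); absolute
  totals for candidates between the pinned bounds may differ from the
  original implementation, though all conditional components and class
  thresholds match the published values exactly.
* Truth matching is gene-pair-level, not breakpoint-level; a validated
  pair is "recovered" even if the scored transcript has a different
  junction.
* No coordinate-level (region) blacklisting; the artifact list is
  purely pair-based.
* The caller's own probability is carried through for reference but
  never scored.
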