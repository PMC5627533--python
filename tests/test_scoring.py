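"""Scoring engine: component values, tiers, classes, and rule interactions."""

import dataclasses

import numpy as np
import pytest
import yaml

from fusescore import (
    ArtifactList,
    ConfigError,
    DEFAULT_WEIGHTS,
    FusionTranscript,
    GenePair,
    ReadSupportTable,
    ScoreLatticeError,
    WeightConfig,
    classify,
    compute_occurrence,
    read_support_score,
    score_candidate,
    score_table,
)

from conftest import oracle_total, random_transcript


def listed(*pairs: GenePair) -> ArtifactList:
    return ArtifactList.from_counts({p: 3 for p in pairs}, min_entities=3)


class TestComponents:
    """Each feature rule contributes exactly its configured weight."""

    def test_artifact_membership(self):
        rec = FusionTranscript(gene1="GENEA", gene2="GENEB")
        brk = score_candidate(rec, artifacts=listed(rec.pair))
        assert brk.component("artifact") == -6.0

    @pytest.mark.parametrize("flag", ["read_through", "altsplice"])
    def test_read_through_or_altsplice(self, flag):
        overrides = {flag: True, "adjacent": flag == "read_through"}
        brk = score_candidate(FusionTranscript(**overrides))
        assert brk.component("read_through_altsplice") == -4.0
        assert brk.component("adjacent_only") == 0.0

    def test_adjacent_without_readthrough_gets_reduced_penalty(self):
        brk = score_candidate(FusionTranscript(adjacent=True))
        assert brk.component("adjacent_only") == -0.5
        assert brk.component("read_through_altsplice") == 0.0

    def test_intrachromosomal_penalty(self):
        rec = FusionTranscript(chrom1="3", chrom2="3", interchromosomal=False)
        assert score_candidate(rec).component("intrachromosomal") == -0.5

    def test_intrachromosomal_waived_beyond_distance_cutoff(self):
        cfg = dataclasses.replace(DEFAULT_WEIGHTS, intrachromosomal_max_distance=1_000_000)
        near = FusionTranscript(chrom1="3", chrom2="3", interchromosomal=False,
                                break_pos1=100, break_pos2=500_000)
        far = dataclasses.replace(near, break_pos2=5_000_000)
        assert score_candidate(near, cfg=cfg).component("intrachromosomal") == -0.5
        assert score_candidate(far, cfg=cfg).component("intrachromosomal") == 0.0

    @pytest.mark.parametrize(
        "homology, expected", [(9, 0.0), (10, -1.0), (12, -1.0), (100, -1.0)]
    )
    def test_homology_threshold(self, homology, expected):
        brk = score_candidate(FusionTranscript(breakpoint_homology=homology))
        assert brk.component("homology") == expected

    @pytest.mark.parametrize(
        "proportion, mid, high",
        [(0.79, 0.0, 0.0), (0.8, -0.5, 0.0), (0.85, -0.5, 0.0),
         (0.9, 0.0, -1.0), (0.95, 0.0, -1.0), (1.0, 0.0, -1.0)],
    )
    def test_repeat_bins_never_cofire(self, proportion, mid, high):
        brk = score_candidate(FusionTranscript(repeat_proportion=proportion))
        assert brk.component("repeat_mid") == mid
        assert brk.component("repeat_high") == high

    def test_orf_and_exon_boundary_penalties(self):
        brk = score_candidate(FusionTranscript(orf=False, exon_boundary=False))
        assert brk.component("no_orf") == -1.0
        assert brk.component("not_exon_boundary") == -1.5

    def test_downstream_3prime_penalty(self):
        brk = score_candidate(FusionTranscript(downstream_3prime_break=True))
        assert brk.component("downstream_3prime") == -4.0


class TestReadSupport:
    def test_all_spanning_reads_multimapped(self):
        assert read_support_score(50, 20, 0, 1) == -1.5

    def test_no_support_at_all_hits_lowest_tier(self):
        assert read_support_score(0, 0, 0, 1) == -2.0

    def test_strong_support_hits_top_tier(self):
        assert read_support_score(150, 40, 40, 2) == 2.5

    def test_zero_span_is_not_treated_as_multimapped(self):
        # the all-multimapped rule is vacuous without spanning reads
        assert read_support_score(60, 0, 0, 1) == -0.5

    @pytest.mark.parametrize("arg", [0, 1, 2])
    def test_monotone_in_each_input(self, arg):
        rng = np.random.default_rng(3)
        for _ in range(200):
            span = 50
            base = [int(rng.integers(0, 200)), int(rng.integers(1, span + 1)),
                    int(rng.integers(1, 4))]
            bumped = list(base)
            bumped[arg] += int(rng.integers(1, 50)) if arg != 1 else span - base[1]
            bumped[1] = min(bumped[1], span)
            low = read_support_score(base[0], span, base[1], base[2])
            high = read_support_score(bumped[0], span, bumped[1], bumped[2])
            assert high >= low


class TestClassify:
    @pytest.mark.parametrize(
        "total, expected",
        [(10.0, "high"), (8.0, "high"), (7.5, "medium"), (7.0, "medium"),
         (6.5, "medium"), (6.0, "low"), (0.0, "low"), (-8.0, "low")],
    )
    def test_class_boundaries(self, total, expected):
        assert classify(total) == expected

    @pytest.mark.parametrize("total", [7.75, 6.25])
    def test_gap_totals_raise_internal_consistency_error(self, total):
        with pytest.raises(ScoreLatticeError):
            classify(total)


class TestScoreCandidate:
    def test_clean_candidate_caps_at_ten(self):
        rec = FusionTranscript(
            breakpoint_homology=3, repeat_proportion=0.1,
            split_count=150, span_count=40, unique_span_count=40,
        )
        brk = score_candidate(rec, occurrence=2)
        assert brk.components == {"read_support": 2.5}
        assert brk.raw_total == 12.5
        assert brk.total == 10.0
        assert brk.confidence_class == "high"

    def test_altsplice_penalizes_clean_candidate(self):
        # cap applies to the summed total: min(10, 10 + 2.5 - 4) = 8.5
        rec = FusionTranscript(
            breakpoint_homology=3, repeat_proportion=0.1, altsplice=True,
            split_count=150, span_count=40, unique_span_count=40,
        )
        brk = score_candidate(rec, occurrence=2)
        assert brk.component("read_through_altsplice") == -4.0
        assert brk.raw_total == 8.5 and brk.total == 8.5

    def test_altsplice_with_middling_support_is_low(self):
        brk = score_candidate(FusionTranscript(altsplice=True, split_count=20))
        # 10 - 4 + 0.5 = 6.5 with moderate support; low support drops further
        assert brk.total <= 6.5 and brk.confidence_class != "high"

    def test_artifact_membership_excludes_from_high_confidence(self):
        # even maximal read support cannot lift a blacklisted pair to high:
        # min(10, 10 + 2.5 - 6) = 6.5
        rec = FusionTranscript(
            breakpoint_homology=3, repeat_proportion=0.1,
            split_count=150, span_count=40, unique_span_count=40,
        )
        brk = score_candidate(rec, artifacts=listed(rec.pair), occurrence=2)
        assert brk.total == 6.5 and brk.confidence_class == "medium"

    def test_occurrence_below_one_rejected(self):
        with pytest.raises(ValueError, match="occurrence"):
            score_candidate(FusionTranscript(), occurrence=0)

    def test_additivity_holds_exactly_on_random_rows(self):
        rng = np.random.default_rng(17)
        cfg = DEFAULT_WEIGHTS
        for i in range(500):
            rec = random_transcript(rng, i)
            occ = int(rng.integers(1, 4))
            brk = score_candidate(rec, occurrence=occ)
            assert brk.raw_total == cfg.baseline + sum(brk.components.values())
            assert brk.total == min(cfg.score_cap, brk.raw_total)
            assert classify(brk.total) == brk.confidence_class

    @pytest.mark.parametrize(
        "adverse",
        [
            {"read_through": True, "adjacent": True},
            {"altsplice": True},
            {"adjacent": True},
            {"downstream_3prime_break": True},
            {"breakpoint_homology": 15},
            {"repeat_proportion": 0.85},
            {"repeat_proportion": 0.95},
            {"orf": False},
            {"exon_boundary": False},
            {"chrom1": "5", "chrom2": "5", "interchromosomal": False},
        ],
    )
    def test_each_adverse_feature_never_increases_total(self, adverse):
        rng = np.random.default_rng(23)
        for i in range(100):
            rec = random_transcript(rng, i)
            base = dataclasses.asdict(rec)
            # neutralize the feature under test, then flip it on
            neutral = dict(
                base,
                read_through=False, altsplice=False, adjacent=False,
                downstream_3prime_break=False, breakpoint_homology=0,
                repeat_proportion=0.0, orf=True, exon_boundary=True,
                chrom1="1", chrom2="2", interchromosomal=True,
            )
            flipped = dict(neutral, **adverse)
            occ = int(rng.integers(1, 4))
            total_neutral = score_candidate(FusionTranscript(**neutral), occurrence=occ).total
            total_flipped = score_candidate(FusionTranscript(**flipped), occurrence=occ).total
            assert total_flipped <= total_neutral

    def test_agreement_with_brute_force_oracle(self):
        rng = np.random.default_rng(29)
        pool = [(f"P{i}A", f"P{i}B") for i in range(5)]
        artifacts = listed(GenePair("P0A", "P0B"), GenePair("P1A", "P1B"))
        for i in range(2000):
            rec = random_transcript(rng, i, pair_pool=pool)
            occ = int(rng.integers(1, 4))
            brk = score_candidate(rec, artifacts=artifacts, occurrence=occ)
            assert brk.total == oracle_total(rec, artifacts.contains(rec.pair), occ)


class TestOccurrence:
    def test_distinct_pairs_count_once(self):
        recs = [FusionTranscript(cluster_id=str(i), gene1=f"A{i}", gene2=f"B{i}") for i in range(3)]
        assert set(compute_occurrence(recs).values()) == {1}

    def test_repeated_pair_counted(self):
        recs = [
            FusionTranscript(cluster_id="1", gene1="A", gene2="B"),
            FusionTranscript(cluster_id="2", gene1="B", gene2="A"),
            FusionTranscript(cluster_id="3", gene1="C", gene2="D"),
        ]
        counts = compute_occurrence(recs)
        assert counts[GenePair("A", "B")] == 2
        assert counts[GenePair("C", "D")] == 1

    def test_matches_brute_force_group_by(self):
        rng = np.random.default_rng(31)
        pool = [(f"P{i}A", f"P{i}B") for i in range(20)]
        recs = [random_transcript(rng, i, pair_pool=pool) for i in range(200)]
        counts = compute_occurrence(recs)
        for pair in counts:
            assert counts[pair] == sum(1 for r in recs if r.pair == pair)
        assert sum(counts.values()) == len(recs)

    def test_mixed_samples_rejected(self):
        recs = [
            FusionTranscript(cluster_id="1", sample_id="S1"),
            FusionTranscript(cluster_id="2", sample_id="S2"),
        ]
        with pytest.raises(ValueError, match="multiple samples"):
            compute_occurrence(recs)


class TestScoreTable:
    def test_empty_table(self):
        assert score_table([]) == []

    def test_single_clean_candidate_is_high(self):
        scored = score_table([FusionTranscript()])
        assert len(scored) == 1 and scored[0][1].confidence_class == "high"

    def test_permutation_invariance(self):
        rng = np.random.default_rng(37)
        pool = [(f"P{i}A", f"P{i}B") for i in range(30)]
        recs = [
            random_transcript(rng, i, sample_id=f"S{i % 4}", pair_pool=pool)
            for i in range(500)
        ]
        scored = score_table(recs)
        shuffled = list(recs)
        rng.shuffle(shuffled)
        rescored = score_table(shuffled)
        assert {r.cluster_id: b.total for r, b in scored} == {
            r.cluster_id: b.total for r, b in rescored
        }
        # output order itself is deterministic
        assert [r.cluster_id for r, _ in scored] == [r.cluster_id for r, _ in rescored]

    def test_occurrence_computed_per_sample(self):
        shared = dict(gene1="A", gene2="B")
        recs = [
            FusionTranscript(cluster_id="1", sample_id="S1", **shared),
            FusionTranscript(cluster_id="2", sample_id="S1", **shared),
            FusionTranscript(cluster_id="3", sample_id="S2", **shared),
        ]
        by_id = {r.cluster_id: b.occurrence for r, b in score_table(recs)}
        assert by_id == {"1": 2, "2": 2, "3": 1}


class TestWeightConfig:
    def test_defaults_match_published_weights(self):
        cfg = DEFAULT_WEIGHTS
        assert (cfg.baseline, cfg.score_cap) == (10.0, 10.0)
        assert (cfg.high_min, cfg.medium_min, cfg.medium_max, cfg.low_max) == (8.0, 6.5, 7.5, 6.0)

    def test_yaml_roundtrip(self, tmp_path):
        path = tmp_path / "w.yaml"
        path.write_text(yaml.safe_dump(DEFAULT_WEIGHTS.to_dict()))
        assert WeightConfig.from_yaml(path) == DEFAULT_WEIGHTS

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "w.yaml"
        path.write_text("w_artifcat: -6\n")
        with pytest.raises(ConfigError, match="w_artifcat"):
            WeightConfig.from_yaml(path)

    def test_non_half_integer_weight_rejected(self):
        with pytest.raises(ConfigError, match="w_artifact"):
            WeightConfig(w_artifact=-6.2)

    def test_overlapping_class_thresholds_rejected(self):
        with pytest.raises(ConfigError, match="thresholds"):
            WeightConfig(high_min=7.0)

    def test_zero_tier_score_rejected(self):
        with pytest.raises(ConfigError, match="non-zero"):
            ReadSupportTable(tier_scores=(-2.0, -1.0, 0.0, 0.5, 1.5, 2.5))
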