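"""Three-step guideline: stage behavior and whole-pipeline accounting."""

import numpy as np
import pytest

from epilift import (
    BedRecord,
    GuidelineConfig,
    LiftConfig,
    build_index,
    classify_blocks,
    lift_bed,
    run_guideline,
)
from epilift.guideline import (
    postfilter_alt_chrom,
    postfilter_conservative,
    postfilter_duplication,
    postfilter_not_cg,
    prefilter,
    split_at_insertions,
)
from epilift.regions import GapCategory, RegionTrack
from epilift.simulate import find_cpgs


@pytest.fixture
def ch1_tracks(ch1):
    tracks, _ = classify_blocks(ch1, {"chrA": 20})
    return tracks


class TestPrefilter:
    def test_gapped_in_both_removed(self, ch1_tracks):
        kept, removed = prefilter([BedRecord("chrA", 10, 12)], ch1_tracks)
        assert kept == [] and removed[0][1] == "gapped_in_both"

    def test_clean_record_kept(self, ch1_tracks):
        kept, removed = prefilter([BedRecord("chrA", 2, 8)], ch1_tracks)
        assert removed == [] and len(kept) == 1

    def test_single_bp_blacklist_overlap_removes(self, ch1_tracks):
        rec = BedRecord("chrA", 2, 8)
        kept, removed = prefilter(
            [rec], ch1_tracks, blacklist=[BedRecord("chrA", 7, 9)]
        )
        assert kept == [] and removed[0][1] == "blacklist"

    def test_wrong_space_track_rejected(self, ch1_tracks):
        bad = dict(ch1_tracks)
        bad[(GapCategory.GAPPED_IN_SOURCE, "source")] = RegionTrack(
            category=GapCategory.GAPPED_IN_SOURCE, space="target"
        )
        with pytest.raises(ValueError, match="space"):
            prefilter([BedRecord("chrA", 2, 8)], bad)


class TestSplit:
    def midtrack(self, *mids):
        return RegionTrack(
            category=GapCategory.GAPPED_IN_TARGET,
            space="source",
            intervals=[("chrA", p - 1, p + 1, 5) for p in mids],
        )

    def test_single_midpoint_cut(self):
        out = split_at_insertions([BedRecord("chrA", 5, 15, name="x")],
                                  self.midtrack(10))
        assert [(r.start, r.end, r.name) for r in out] == [
            (5, 9, "x/s0"), (11, 15, "x/s1")
        ]

    def test_record_equal_to_midpoint_vanishes(self):
        assert split_at_insertions([BedRecord("chrA", 9, 11)],
                                   self.midtrack(10)) == []

    def test_two_midpoints(self):
        out = split_at_insertions([BedRecord("chrA", 0, 30, name="y")],
                                  self.midtrack(5, 10))
        assert [(r.start, r.end) for r in out] == [(0, 4), (6, 9), (11, 30)]

    def test_untouched_record_passes_through(self):
        rec = BedRecord("chrA", 0, 3, name="z")
        assert split_at_insertions([rec], self.midtrack(10)) == [rec]


class TestPostfilters:
    def test_conservative_drops_stretched_output(self, ch2):
        tracks, _ = classify_blocks(ch2, {"chrA": 20})
        idx = build_index(ch2)
        lifted, _, _ = lift_bed(idx, [BedRecord("chrA", 9, 11)])
        kept, removed = postfilter_conservative(
            lifted, tracks[(GapCategory.GAPPED_IN_TARGET, "target")]
        )
        assert kept == [] and len(removed) == 1

    def test_conservative_keeps_clean_output(self, ch2):
        tracks, _ = classify_blocks(ch2, {"chrA": 20})
        idx = build_index(ch2)
        lifted, _, _ = lift_bed(idx, [BedRecord("chrA", 0, 8)])
        kept, removed = postfilter_conservative(
            lifted, tracks[(GapCategory.GAPPED_IN_TARGET, "target")]
        )
        assert removed == [] and kept[0].start == 0 and kept[0].end == 8

    def test_duplication_removes_whole_collision_group(self):
        recs = [
            BedRecord("chrB", 100, 101, name="a"),
            BedRecord("chrB", 100, 101, name="b"),
            BedRecord("chrB", 200, 201, name="c"),
        ]
        kept, removed = postfilter_duplication(recs)
        assert [r.name for r in kept] == ["c"]
        assert sorted(r.name for r in removed) == ["a", "b"]

    def test_duplication_removes_one_to_many_pieces(self):
        recs = [
            BedRecord("chrB", 5, 9, name="x/0"),
            BedRecord("chrB", 15, 20, name="x/1"),
        ]
        kept, removed = postfilter_duplication(recs)
        assert kept == [] and len(removed) == 2

    def test_duplication_keeps_deliberate_split_pieces(self):
        recs = [
            BedRecord("chrB", 5, 9, name="x/s0"),
            BedRecord("chrB", 15, 20, name="x/s1"),
        ]
        kept, removed = postfilter_duplication(recs)
        assert len(kept) == 2 and removed == []

    def test_alt_chromosome_rule(self):
        recs = [
            BedRecord("chr11", 1, 2),
            BedRecord("chr11_KI270831v1_alt", 1, 2),
        ]
        kept, removed = postfilter_alt_chrom(recs)
        assert [r.chrom for r in kept] == ["chr11"]
        assert [r.chrom for r in removed] == ["chr11_KI270831v1_alt"]

    def test_alt_chromosome_custom_pattern(self):
        kept, removed = postfilter_alt_chrom(
            [BedRecord("2L", 1, 2)], canonical_pattern=r"^(2L|2R|3L|3R|4|X)$"
        )
        assert len(kept) == 1 and removed == []

    def test_not_cg_plus_strand(self):
        fasta = {"chrB": "AACGT"}
        kept, _ = postfilter_not_cg([BedRecord("chrB", 2, 3, strand="+")], fasta)
        assert len(kept) == 1
        _, removed = postfilter_not_cg([BedRecord("chrB", 2, 3, strand="+")],
                                       {"chrB": "AATTT"})
        assert removed[0][1] == "not_cg"

    def test_not_cg_minus_strand_reads_upstream(self):
        # the lifted C sits on the forward-strand G of the pair
        fasta = {"chrB": "AACGT"}
        kept, _ = postfilter_not_cg([BedRecord("chrB", 3, 4, strand="-")], fasta)
        assert len(kept) == 1

    def test_not_cg_edge_removed(self):
        _, removed = postfilter_not_cg([BedRecord("chrB", 4, 5, strand="+")],
                                       {"chrB": "AACGT"})
        assert removed[0][1] == "edge"


class TestPipeline:
    def test_crafted_records_accounting(self, ch1, ch2):
        """Six records over the two toy chains, each with a hand-derived
        fate; tallies must cover the input exactly."""
        ch2[0].header = ch2[0].header.__class__(
            **{**ch2[0].header.__dict__, "t_name": "chrA2", "q_name": "chrB2"}
        )
        chains = ch1 + ch2
        records = [
            BedRecord("chrA", 2, 6, name="clean"),        # lifts
            BedRecord("chrA", 10, 12, name="gib"),        # prefiltered
            BedRecord("chrA2", 9, 11, name="mid"),        # conservative removal
            BedRecord("chrA2", 2, 6, name="clean2"),      # lifts
            BedRecord("chrZ", 1, 5, name="uncov"),        # chrZ has no chain
            BedRecord("chrA", 13, 17, name="clean3"),     # lifts
        ]
        config = GuidelineConfig(
            mode="conservative", canonical_pattern=r"^chrB2?$"
        )
        final, report = run_guideline(
            records, chains, config,
            source_chrom_sizes={"chrA": 20, "chrA2": 20, "chrZ": 30},
        )
        assert report.n_input == 6
        # chain-uncovered chrZ is itself gapped-in-source, so the record is
        # caught by the prefilter rather than failing at the lift stage
        assert report.n_removed_prefilter == {
            "gapped_in_both": 1, "gapped_in_source": 1
        }
        assert report.n_unlifted == 0
        assert report.n_removed_target_gap_overlap == 1
        assert sorted(r.name for r in final) == ["clean", "clean2", "clean3"]
        report.check_accounting()

    def test_empty_input_all_zero(self, ch1):
        final, report = run_guideline([], ch1, GuidelineConfig())
        assert final == [] and report.n_input == 0
        report.check_accounting()

    def test_conservative_output_avoids_target_insertions(self, suite):
        pair = suite[0]
        tracks, _ = classify_blocks(pair.chains, pair.source_sizes())
        rng = np.random.default_rng(5)
        records = []
        for chrom, size in pair.source_sizes().items():
            starts = rng.integers(0, size - 50, size=300)
            records += [BedRecord(chrom, int(s), int(s) + 40, name=f"{chrom}:{s}:{i}")
                        for i, s in enumerate(starts)]
        config = GuidelineConfig(mode="conservative")
        final, report = run_guideline(
            records, pair.chains, config, source_chrom_sizes=pair.source_sizes()
        )
        report.check_accounting()
        gap = tracks[(GapCategory.GAPPED_IN_TARGET, "target")].merged()
        from epilift.intervals import intersect_length

        for rec in final:
            assert intersect_length(
                [(rec.start, rec.end)], gap.get(rec.chrom, [])
            ) == 0

    def test_split_mode_preserves_more_records(self, suite):
        pair = suite[0]
        tracks, _ = classify_blocks(pair.chains, pair.source_sizes())
        mids = tracks[(GapCategory.GAPPED_IN_TARGET, "source")].intervals
        # records straddling each insertion midpoint
        records = [
            BedRecord(c, max(s - 20, 0), e + 20, name=f"m{i}")
            for i, (c, s, e, _dq) in enumerate(mids)
        ]
        cons, rep_c = run_guideline(
            records, pair.chains, GuidelineConfig(mode="conservative"),
            source_chrom_sizes=pair.source_sizes(),
        )
        split, rep_s = run_guideline(
            records, pair.chains, GuidelineConfig(mode="split"),
            source_chrom_sizes=pair.source_sizes(),
        )
        rep_c.check_accounting()
        rep_s.check_accounting()
        assert len(cons) <= len(split)
        assert len(split) > 0

    def test_split_output_preimage_avoids_midpoints(self, suite):
        pair = suite[0]
        tracks, _ = classify_blocks(pair.chains, pair.source_sizes())
        mids = tracks[(GapCategory.GAPPED_IN_TARGET, "source")]
        records = [
            BedRecord(c, max(s - 20, 0), e + 20, name=f"m{i}")
            for i, (c, s, e, _dq) in enumerate(mids.intervals)
        ]
        pieces = split_at_insertions(records, mids)
        tree = mids.merged()
        from epilift.intervals import intersect_length

        for rec in pieces:
            assert intersect_length(
                [(rec.start, rec.end)], tree.get(rec.chrom, [])
            ) == 0

    def test_not_cg_removals_match_simulator_truth(self, suite):
        """With faithful target sequence, the only CpGs failing the CG
        check are those whose target base the simulator mutated."""
        pair = next(p for p in suite if p.spec.cpg_mutation_rate > 0)
        records = [
            BedRecord(chrom, p, p + 1, name=f"{chrom}:{p}")
            for chrom, seq in pair.source.items()
            for p in find_cpgs(seq)
        ]
        config = GuidelineConfig(
            mode="conservative", cpg_check=True, target_fasta=pair.target
        )
        final, report = run_guideline(
            records, pair.chains, config, source_chrom_sizes=pair.source_sizes()
        )
        report.check_accounting()
        assert report.n_removed_not_cg > 0
        # recompute which kept-stage records were mutated
        removed_names = set()
        kept_names = {r.name for r in final}
        for chrom, muts in pair.mutated_cpgs.items():
            removed_names |= {f"{chrom}:{p}" for p in muts}
        assert kept_names.isdisjoint(removed_names)
        # every not-CG removal is explained by a simulated mutation or an
        # inversion-boundary edge case
        survivors_to_cg_stage = report.n_raw_lifted - (
            report.n_removed_target_gap_overlap
            + report.n_removed_duplication
            + report.n_removed_alt_chrom
        )
        assert report.n_filtered_final == survivors_to_cg_stage - report.n_removed_not_cg

    def test_cpg_check_requires_fasta(self):
        with pytest.raises(ValueError, match="target_fasta"):
            GuidelineConfig(cpg_check=True)
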