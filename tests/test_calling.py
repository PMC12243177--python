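"""Junction reconstruction, evidence classification, scoring, evaluation."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tiscaller.calling import (
    attach_discordant_support,
    call_tis,
    cluster_chimeric_reads,
    evaluate_calls,
    reconstruct_junction,
    score_candidate,
    select_reference_and_classify,
)
from tiscaller.records import (
    DiscordantCandidate,
    ScoringWeights,
    TdnaConstruct,
    TdnaHit,
)

from conftest import make_chimeric, make_clip_record, random_dna


def tdna_hit(strand="+", t_start=50, t_end=89, cid="vec1"):
    return TdnaHit(read_id="r1", replicate_id="repA", construct_id=cid,
                   t_start=t_start, t_end=t_end, t_strand=strand,
                   mode="end2end", matched_len=t_end - t_start + 1,
                   mismatches=0, border_distance=49)


class TestReconstructJunction:
    """The four clip-side x strand cases of the junction encoding."""

    def test_right_clip_plus(self):
        rec = make_clip_record(clip_side="right", aligned_start=1000, aligned_end=1059)
        c = reconstruct_junction(rec, tdna_hit("+"))
        assert (c.junction, c.config, c.orientation) == (1059, "R", "+")
        assert c.t_junction == 50  # clip starts at the junction

    def test_left_clip_plus(self):
        rec = make_clip_record(clip_side="left", aligned_start=500, aligned_end=569)
        c = reconstruct_junction(rec, tdna_hit("+"))
        assert (c.junction, c.config, c.orientation) == (500, "L", "+")
        assert c.t_junction == 89  # clip ends at the junction

    def test_right_clip_minus(self):
        rec = make_clip_record(clip_side="right", aligned_start=1000, aligned_end=1059)
        c = reconstruct_junction(rec, tdna_hit("-"))
        assert (c.junction, c.config, c.orientation) == (1059, "R", "-")
        assert c.t_junction == 89

    def test_flipping_strand_flips_orientation_only(self):
        rec = make_clip_record(clip_side="left", aligned_start=500, aligned_end=569)
        plus = reconstruct_junction(rec, tdna_hit("+"))
        minus = reconstruct_junction(rec, tdna_hit("-"))
        assert (plus.junction, plus.config) == (minus.junction, minus.config)
        assert {plus.orientation, minus.orientation} == {"+", "-"}

    def test_segment_lengths_recorded(self):
        rec = make_clip_record(genome_match_len=60, clip_seq="A" * 40)
        c = reconstruct_junction(rec, tdna_hit("+"))
        assert (c.genome_seg_len, c.tdna_seg_len) == (60, 40)


class TestClassification:
    def test_single_member_is_reference(self):
        ref, counts, _ = select_reference_and_classify([make_chimeric()])
        assert counts == (0, 0, 0, 0)

    def test_five_read_rule_table(self):
        """One reference plus one supporter of each of G1-G4."""
        ref = make_chimeric(read_id="a_ref", genome_seg_len=75, tdna_seg_len=75,
                            full_seq="A" * 75 + "G" * 75)
        g1 = make_chimeric(read_id="g1", genome_seg_len=60, tdna_seg_len=90,
                           full_seq="A" * 60 + "G" * 90)
        g2_seq = "C" + ref.full_seq[1:]
        g2 = make_chimeric(read_id="g2", full_seq=g2_seq)
        g3 = make_chimeric(read_id="g3", replicate_id="repB",
                           full_seq=ref.full_seq)
        g4 = make_chimeric(read_id="g4", junction=5004,
                           genome_seg_len=70, tdna_seg_len=70)
        out_ref, counts, groups = select_reference_and_classify(
            [ref, g1, g2, g3, g4], w=10
        )
        assert out_ref is ref  # most balanced split
        assert counts == (1, 1, 1, 1)
        assert groups[1] == [g1] and groups[2] == [g2]
        assert groups[3] == [g3] and groups[4] == [g4]

    def test_same_replicate_duplicate_dropped(self):
        ref = make_chimeric(read_id="ref")
        dup = make_chimeric(read_id="zzz")  # identical, same replicate
        _, counts, _ = select_reference_and_classify([ref, dup])
        assert counts == (0, 0, 0, 0)

    def test_empty_members_raise(self):
        with pytest.raises(ValueError):
            select_reference_and_classify([])

    @given(st.lists(
        st.tuples(
            st.sampled_from(["repA", "repB", "repC"]),
            st.integers(min_value=4995, max_value=5005),
            st.integers(min_value=40, max_value=110),
        ),
        min_size=1, max_size=15,
    ))
    @settings(max_examples=60, deadline=None)
    def test_classification_is_a_partition(self, specs):
        members = [
            make_chimeric(read_id=f"r{i}", replicate_id=rep, junction=j,
                          genome_seg_len=g, tdna_seg_len=150 - g)
            for i, (rep, j, g) in enumerate(specs)
        ]
        _, counts, groups = select_reference_and_classify(members, w=10)
        assigned = sum(counts)
        total_in_groups = sum(len(v) for v in groups.values())
        assert assigned == total_in_groups
        assert assigned <= len(members) - 1  # rest was dropped


class TestScoring:
    def test_minimal_three_read_configuration(self):
        assert score_candidate((1, 0, 1, 0, 0)) == 1000

    def test_zero(self):
        assert score_candidate((0, 0, 0, 0, 0)) == 0

    def test_weighted_sum(self):
        assert score_candidate((2, 0, 0, 5, 10)) == 1415

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            score_candidate((-1, 0, 0, 0, 0))

    def test_custom_weights(self):
        w = ScoringWeights(1, 2, 3, 4, 5)
        assert score_candidate((1, 1, 1, 1, 1), w) == 15

    @given(st.tuples(*[st.integers(0, 20)] * 5), st.tuples(*[st.integers(0, 20)] * 5))
    @settings(max_examples=100, deadline=None)
    def test_additivity_and_monotonicity(self, a, b):
        ab = tuple(x + y for x, y in zip(a, b))
        assert score_candidate(ab) == score_candidate(a) + score_candidate(b)
        assert score_candidate(ab) >= score_candidate(a)

    def test_no_two_read_configuration_reaches_threshold(self):
        """Brute force over supporter multisets of size <= 1 (i.e. fewer
        than three chimeric reads in total, G5 excluded): none reaches
        the default 1000 cutoff."""
        for g in range(4):
            counts = [0] * 5
            counts[g] = 1
            assert score_candidate(tuple(counts)) < 1000
        assert score_candidate((0, 0, 0, 0, 0)) < 1000
        # and with G5 pairs alone, even many never reach it cheaply:
        assert score_candidate((0, 0, 0, 0, 2)) == 2


class TestClusteringAndCalls:
    def _candidates(self):
        reads = []
        for i in range(3):  # one passing site: ref + G1 + G3
            reads.append(make_chimeric(
                read_id=f"a{i}", junction=5000,
                replicate_id="repB" if i == 2 else "repA",
                genome_seg_len=75 - 10 * (i == 1),
                tdna_seg_len=75 + 10 * (i == 1),
                full_seq=("A" * (75 - 10 * (i == 1)) + "G" * (75 + 10 * (i == 1))),
            ))
        reads.append(make_chimeric(read_id="lone", chrom="chr2", junction=900))
        return cluster_chimeric_reads(reads, w=10)

    def test_clusters_are_per_chrom_and_config(self):
        cands = self._candidates()
        assert len(cands) == 2
        assert [c.chrom for c in cands] == ["chr1", "chr2"]

    def test_threshold_boundary(self):
        cands = self._candidates()
        called = call_tis(cands, threshold=1000)
        by_chrom = {c.chrom: c for c in called}
        assert by_chrom["chr1"].score == 1000
        assert by_chrom["chr1"].status == "pass"
        assert by_chrom["chr2"].status == "fail"
        # 999 would fail; a threshold of 1001 fails the same candidate
        called = call_tis(self._candidates(), threshold=1001)
        assert all(c.status == "fail" for c in called)

    def test_blacklisted_junction_absent(self, tmp_path):
        bed = tmp_path / "bl.bed"
        bed.write_text("chr1\t4990\t5010\n")
        called = call_tis(self._candidates(), threshold=1000, blacklist=str(bed))
        assert all(c.chrom != "chr1" for c in called)

    def test_gene_annotation_attached(self, tmp_path):
        gff = tmp_path / "ann.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t4500\t5500\t.\t+\t.\tID=gene1;Name=AT1G01010\n"
        )
        called = call_tis(self._candidates(), threshold=1000, annotation=str(gff))
        target = [c for c in called if c.chrom == "chr1"][0]
        assert target.genes == ["AT1G01010"]

    def test_threshold_sweep_monotone(self):
        reads = []
        for site, n_extra in ((1000, 4), (2000, 2), (3000, 1)):
            reads.append(make_chimeric(read_id=f"ref{site}", junction=site))
            for k in range(n_extra):
                reads.append(make_chimeric(
                    read_id=f"s{site}_{k}", junction=site,
                    genome_seg_len=60 - k, tdna_seg_len=90 + k,
                    full_seq="A" * (60 - k) + "G" * (90 + k)))
        cands = cluster_chimeric_reads(reads, w=10)
        prev = None
        for thr in (1, 500, 1000, 1500, 3000, 10_000):
            passing = {
                (c.chrom, c.junction)
                for c in call_tis(cands, threshold=thr)
                if c.status == "pass"
            }
            if prev is not None:
                assert passing <= prev
            prev = passing

    def test_opposite_flanks_reported_separately(self):
        r_flank = make_chimeric(read_id="r", junction=5000, config="R")
        l_flank = make_chimeric(read_id="l", junction=5001, config="L")
        cands = cluster_chimeric_reads([r_flank, l_flank], w=10)
        assert {(c.config, c.junction) for c in cands} == {("R", 5000), ("L", 5001)}


class TestDiscordantSupport:
    def _setup(self, rng):
        construct = TdnaConstruct("vec1", random_dna(rng, 2000))
        cand = cluster_chimeric_reads([make_chimeric(junction=5000)], w=10)[0]
        return construct, cand

    def test_facing_pair_counts(self, rng):
        construct, cand = self._setup(rng)
        dc = DiscordantCandidate(
            pair_id="p1", replicate_id="repA", chrom="chr1",
            start=4600, end=4699, strand="+",
            other_mate_seq=construct.sequence[100:160],
            other_mate_quals="I" * 60,
        )
        attach_discordant_support(cand, [dc], [construct], D=1000)
        assert cand.group_counts[4] == 1

    def test_distant_pair_not_counted(self, rng):
        construct, cand = self._setup(rng)
        dc = DiscordantCandidate(
            pair_id="p1", replicate_id="repA", chrom="chr1",
            start=10_000, end=10_099, strand="-",
            other_mate_seq=construct.sequence[100:160],
            other_mate_quals="I" * 60,
        )
        attach_discordant_support(cand, [dc], [construct], D=1000)
        assert cand.group_counts[4] == 0

    def test_mate_not_on_construct_not_counted(self, rng):
        construct, cand = self._setup(rng)
        dc = DiscordantCandidate(
            pair_id="p1", replicate_id="repA", chrom="chr1",
            start=4600, end=4699, strand="+",
            other_mate_seq=random_dna(rng, 60),
            other_mate_quals="I" * 60,
        )
        attach_discordant_support(cand, [dc], [construct], D=1000)
        assert cand.group_counts[4] == 0


class TestEvaluation:
    def test_printed_dataset_level_numbers(self):
        """TP=42 of 49 annotated and 54 called -> 0.86 / 0.78."""
        truth = [("chr1", 1000 * i) for i in range(1, 50)]
        calls = [("chr1", 1000 * i) for i in range(1, 43)]
        calls += [("chr2", 10_000 * i) for i in range(1, 13)]
        res = evaluate_calls(calls, truth, match_tolerance=100)
        assert (res.TP, res.FN, res.FP) == (42, 7, 12)
        assert round(res.sensitivity, 2) == 0.86
        assert round(res.precision, 2) == 0.78

    def test_sensitivity_46_of_54(self):
        truth = [("chr1", 1000 * i) for i in range(1, 55)]
        calls = [("chr1", 1000 * i) for i in range(1, 47)]
        res = evaluate_calls(calls, truth)
        assert round(res.sensitivity, 2) == 0.85

    def test_zero_tp_all_metrics_zero(self):
        res = evaluate_calls([("chr1", 5)], [("chr2", 5)])
        assert (res.sensitivity, res.precision, res.f1) == (0.0, 0.0, 0.0)

    def test_greedy_matching_is_one_to_one(self):
        truth = [("chr1", 100), ("chr1", 130)]
        calls = [("chr1", 101), ("chr1", 129), ("chr1", 115)]
        res = evaluate_calls(calls, truth, match_tolerance=50)
        assert (res.TP, res.FN, res.FP) == (2, 0, 1)

    def test_f1_formula(self):
        res = evaluate_calls(
            [("chr1", i) for i in (100, 200, 300)],
            [("chr1", i) for i in (100, 200, 400)],
            match_tolerance=10,
        )
        s, p = res.sensitivity, res.precision
        assert res.f1 == pytest.approx(2 * s * p / (s + p))
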