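"""Junction caller: dust filter, primer anchoring, detection, grouping."""

import numpy as np
import pytest

from mutascope import (
    AmpliconRead,
    anchor_primers,
    build_reporter,
    classify_junction,
    detect_deletion,
    dust_score,
    generate_junction_reads,
    revcomp,
    run_junction_pipeline,
)
from mutascope.alignment import equivalent_placements
from mutascope.junctions import (
    filter_low_complexity,
    group_and_assign,
    length_and_identity_filter,
)


def oracle_detect(read: str, ref: str):
    """Exhaustive breakpoint-pair oracle: try every junction position,
    maximize matched bases, then left-align and scan the microhomology."""
    dlen = len(ref) - len(read)
    assert dlen > 0
    best_l, best_mm = None, None
    for l in range(len(read) + 1):
        mm = sum(read[i] != ref[i] for i in range(l))
        mm += sum(read[i] != ref[i + dlen] for i in range(l, len(read)))
        if best_mm is None or mm < best_mm:
            best_l, best_mm = l, mm
    l, r = best_l, best_l + dlen
    while l > 0 and ref[l - 1] == ref[r - 1]:
        l, r = l - 1, r - 1
    mh = 0
    while r + mh < len(ref) and ref[l + mh] == ref[r + mh]:
        mh += 1
    return l, r, mh, best_mm


class TestDustScore:
    def test_homopolymer_scores_one(self):
        assert dust_score("A" * 64) == pytest.approx(1.0)

    def test_all_distinct_trinucleotides_score_zero(self):
        seq = "AACAGATCCGCTGGTTA"
        trips = [seq[i:i + 3] for i in range(len(seq) - 2)]
        assert len(set(trips)) == len(trips)  # precondition of the example
        assert dust_score(seq) == 0.0

    def test_dimer_repeat_scores_well_above_threshold(self):
        # two alternating triplet types each repeated ~w/2 times: score ~0.5
        assert dust_score("AT" * 50) > 0.4

    def test_short_sequence_undefined(self):
        with pytest.raises(ValueError):
            dust_score("AC")

    def test_filter_direction_modes(self):
        low_complexity = AmpliconRead("lc", "A" * 300)
        normal = AmpliconRead("ok", ("AACAGATCCGCTGGT" * 30)[:300])
        kept, removed = filter_low_complexity([low_complexity, normal], 0.07,
                                              mode="conventional")
        assert [r.read_id for r in removed] == ["lc"]
        kept, removed = filter_low_complexity([low_complexity, normal], 0.07,
                                              mode="as-printed")
        assert [r.read_id for r in removed] == ["ok"]
        with pytest.raises(ValueError):
            filter_low_complexity([], 0.07, mode="weird")


class TestPrimerAnchoring:
    FWD = "GTTCGTACCCCTCTCGAGAATA"
    REV = "CCATCCACTTCTCATCTGAAAGACC"

    def test_forward_read_trimmed_to_primer(self):
        read = AmpliconRead("r", "ACGT" + self.FWD + "AAAACCCC")
        out, reason = anchor_primers(read, self.FWD, self.REV)
        assert reason == "ok"
        assert out.sequence == self.FWD + "AAAACCCC"

    def test_reverse_read_reoriented(self):
        amplicon = self.FWD + "AAAACCCCGGGG" + revcomp(self.REV)
        read = AmpliconRead("r", "TT" + revcomp(amplicon))
        out, reason = anchor_primers(read, self.FWD, self.REV)
        assert reason == "ok"
        assert out.sequence == amplicon

    def test_one_mismatch_primer_rejected(self):
        mutated = "A" + self.FWD[1:]
        assert mutated != self.FWD
        read = AmpliconRead("r", mutated + "AAAACCCC")
        out, reason = anchor_primers(read, self.FWD, self.REV)
        assert out is None and reason == "no_primer"

    def test_conflicting_orientations_ambiguous(self):
        read = AmpliconRead("r", self.FWD + "AAAA" + self.REV)
        out, reason = anchor_primers(read, self.FWD, self.REV)
        assert out is None and reason == "ambiguous"


class TestLengthAndIdentityFilter:
    def test_length_boundary(self, construct):
        ref = construct.sequence
        short = AmpliconRead("s", ref[:219])
        boundary = AmpliconRead("b", ref[:220] + "A")  # 221 bp, has a deletion-like diff
        kept, removed = length_and_identity_filter([short, boundary], ref)
        assert [r.read_id for r in removed["short"]] == ["s"]
        assert [r.read_id for r in kept] == ["b"]

    def test_no_deletion_reads_removed_within_slack(self, construct):
        ref = construct.sequence
        exact = AmpliconRead("e", ref)
        two_err = AmpliconRead("t", "AA" + ref[2:])
        three_err = AmpliconRead("x", "AAA" + ref[3:])
        assert sum(a != b for a, b in zip(two_err.sequence, ref)) <= 2
        kept, removed = length_and_identity_filter([exact, two_err, three_err], ref)
        assert {r.read_id for r in removed["no_deletion"]} == {"e", "t"}
        assert [r.read_id for r in kept] == ["x"]

    def test_empty_input(self, construct):
        kept, removed = length_and_identity_filter([], construct.sequence)
        assert kept == [] and removed["short"] == []


class TestDetectDeletion:
    @pytest.mark.parametrize("name,del_len,mh", [
        ("precise", 156, 9), ("typeI", 126, 6), ("typeII", 171, 6), ("J1", 125, 5)])
    def test_errorless_fixture_reads(self, construct, name, del_len, mh):
        fx = construct.fixture(name)
        read = construct.apply_deletion(fx.left_bp, fx.right_bp)
        call = detect_deletion(read, construct)
        assert call is not None
        assert (call.left_bp, call.right_bp) == (fx.left_bp, fx.right_bp)
        assert call.del_len == del_len
        assert call.mh_len == mh
        assert call.in_frame is (del_len % 3 == 0)
        assert classify_junction(call, construct.fixtures) == name

    def test_j1_flagged_out_of_frame(self, construct):
        fx = construct.fixture("J1")
        call = detect_deletion(construct.apply_deletion(fx.left_bp, fx.right_bp),
                               construct)
        assert not call.in_frame

    def test_reads_with_errors_within_slack(self, construct):
        fx = construct.fixture("typeI")
        read = list(construct.apply_deletion(fx.left_bp, fx.right_bp))
        read[5] = "A" if read[5] != "A" else "C"
        read[-5] = "A" if read[-5] != "A" else "C"
        call = detect_deletion("".join(read), construct)
        assert call is not None and call.mismatches == 2
        read[50] = "A" if read[50] != "A" else "C"
        assert detect_deletion("".join(read), construct) is None

    def test_two_separate_deletions_rejected(self, construct):
        seq = construct.sequence
        read = seq[:60] + seq[90:200] + seq[260:]  # two 30/60-bp deletions
        assert detect_deletion(read, construct) is None

    def test_no_deletion_returns_none(self, construct):
        assert detect_deletion(construct.sequence, construct) is None

    def test_left_alignment_canonicality(self, construct):
        """All mh+1 equivalent placements reconstruct the read; the reported
        breakpoints are the leftmost."""
        for name in ("precise", "typeI", "typeII", "J1"):
            fx = construct.fixture(name)
            read = construct.apply_deletion(fx.left_bp, fx.right_bp)
            call = detect_deletion(read, construct)
            placements = equivalent_placements(
                construct.sequence, call.left_bp, call.right_bp)
            assert len(placements) == call.mh_len + 1
            assert placements[0] == (call.left_bp, call.right_bp)
            for l, r in placements:
                assert construct.apply_deletion(l, r) == read

    def test_agrees_with_exhaustive_oracle_on_random_junctions(self, construct):
        rng = np.random.default_rng(11)
        seq = construct.sequence
        for _ in range(120):
            l = int(rng.integers(25, len(seq) - 60))
            dlen = int(rng.integers(1, min(200, len(seq) - 25 - l)))
            read = seq[:l] + seq[l + dlen:]
            call = detect_deletion(read, construct)
            ol, orr, omh, omm = oracle_detect(read, seq)
            assert call is not None
            assert (call.left_bp, call.right_bp, call.mh_len) == (ol, orr, omh)
            assert call.mismatches == omm == 0


class TestGroupingAndPipeline:
    def test_identical_reads_form_one_group(self, construct):
        fx = construct.fixture("precise")
        seq = construct.apply_deletion(fx.left_bp, fx.right_bp)
        reads = [AmpliconRead("a", seq), AmpliconRead("b", seq)]
        groups, unassigned = group_and_assign(reads, construct)
        assert len(groups) == 1 and groups[0].support == 2
        assert unassigned == []

    def test_two_error_tolerance_boundary(self, construct):
        fx = construct.fixture("typeI")
        seq = construct.apply_deletion(fx.left_bp, fx.right_bp)
        two = list(seq)
        two[10] = "A" if two[10] != "A" else "C"
        two[20] = "A" if two[20] != "A" else "C"
        three = list(two)
        three[30] = "A" if three[30] != "A" else "C"
        reads = ([AmpliconRead(f"m{i}", seq) for i in range(6)]
                 + [AmpliconRead("two", "".join(two)),
                    AmpliconRead("three", "".join(three))])
        groups, unassigned = group_and_assign(reads, construct)
        assert len(groups) == 1
        assert groups[0].support == 7  # the 2-substitution read is assigned
        assert [r.read_id for r in unassigned] == ["three"]

    def test_pipeline_conservation_and_recovery(self, construct):
        mix = {"precise": 40, "typeI": 120, "typeII": 30, "J1": 60}
        reads = generate_junction_reads(
            construct, mix, no_deletion_count=30,
            contaminant_counts={"low_complexity": 10, "short": 10},
            error_rate=0.0, seed=21, revcomp_fraction=0.0)
        result = run_junction_pipeline(reads, construct)
        assert result.conserved()
        counts = result.counts
        assert counts["rejected_dust"] == 10
        assert counts["rejected_length"] == 10
        assert counts["rejected_no_deletion"] == 30
        by_class = {g.call.class_label: g.support for g in result.groups}
        assert by_class == mix

    def test_pipeline_on_ori2_reporter(self, construct_ori2):
        reads = generate_junction_reads(
            construct_ori2, {"typeI": 50, "precise": 20}, seed=5)
        result = run_junction_pipeline(reads, construct_ori2)
        by_class = {g.call.class_label: g.support for g in result.groups}
        assert by_class == {"typeI": 50, "precise": 20}
        for g in result.groups:
            if g.call.class_label == "typeI":
                assert g.call.del_len == 126 and g.call.mh_len == 6
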