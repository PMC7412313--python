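"""Aligner contract tests against brute-force placement oracles."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from graftmobile.align import (align_pair, align_read, build_index,
                               _start_distances)
from graftmobile.seqio import TranscriptSet
from graftmobile.simulate import revcomp

from _oracles import edlib_placements, start_distance


def random_seq(n, rng):
    return "".join(rng.choice("ACGT") for _ in range(n))


@pytest.fixture(scope="module")
def toy_refs():
    rng = random.Random(31)
    return TranscriptSet("ref", {f"g{i}": random_seq(400, rng) for i in range(5)})


@pytest.fixture(scope="module")
def toy_index(toy_refs):
    return build_index(toy_refs)


class TestBuildIndex:
    def test_hand_enumerated_postings(self):
        refs = TranscriptSet("r", {"t": "ACGTACGTACGT"})
        idx = build_index(refs, k=8, step=4)
        assert set(idx.postings) == {"ACGTACGT"}
        assert idx.postings["ACGTACGT"] == [("t", 0), ("t", 4)]

    def test_empty_set(self):
        idx = build_index(TranscriptSet("r", {}), k=8, step=4)
        assert idx.postings == {}

    def test_deterministic_rebuild(self, toy_refs):
        a, b = build_index(toy_refs), build_index(toy_refs)
        assert a.postings == b.postings

    def test_short_transcript_named_in_error(self):
        refs = TranscriptSet("r", {"tiny": "ACGTACGT"})
        with pytest.raises(ValueError, match="tiny"):
            build_index(refs, k=15)


class TestStartDistances:
    def test_matches_exhaustive_windows(self):
        rng = random.Random(7)
        for _ in range(40):
            read = random_seq(rng.randint(4, 10), rng)
            seg = random_seq(rng.randint(4, 18), rng)
            got = _start_distances(read, seg)
            for s in range(len(seg) + 1):
                assert got[s] == start_distance(read, seg, s)


class TestAlignRead:
    def test_exact_substring_hit(self, toy_refs, toy_index):
        seq = toy_refs["g2"][100:185]
        recs = align_read(seq, toy_index, toy_refs, 0)
        assert recs[0].target_id == "g2"
        assert recs[0].target_start == 100
        assert recs[0].edit_distance == 0
        assert recs[0].cigar == "85M"
        assert recs[0].strand == "+"

    def test_reverse_complement_strand(self, toy_refs, toy_index):
        seq = revcomp(toy_refs["g1"][50:135])
        recs = align_read(seq, toy_index, toy_refs, 0)
        assert recs[0].strand == "-"
        assert recs[0].target_start == 50
        assert recs[0].edit_distance == 0

    def test_two_substitutions_found_at_cap_two_only(self, toy_refs, toy_index):
        seq = list(toy_refs["g0"][200:285])
        for i in (20, 60):
            seq[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[i]]
        seq = "".join(seq)
        assert start_distance(seq, toy_refs["g0"], 200) == 2  # oracle
        hits2 = align_read(seq, toy_index, toy_refs, 2)
        assert any(r.target_id == "g0" and r.target_start == 200
                   and r.edit_distance == 2 for r in hits2)
        hits1 = align_read(seq, toy_index, toy_refs, 1)
        assert all(r.edit_distance <= 1 for r in hits1)
        assert not any(r.target_id == "g0" and r.target_start == 200
                       for r in hits1)

    def test_too_short_read_returns_empty(self, toy_refs, toy_index):
        assert align_read("ACGT", toy_index, toy_refs, 2) == []

    def test_hits_match_bruteforce_all_placements(self, toy_refs, toy_index):
        """Seeded hit sets equal the exhaustive per-start oracle for planted
        reads with 0-2 substitutions or indels."""
        rng = random.Random(41)
        for trial in range(20):
            tid = f"g{rng.randrange(5)}"
            ref = toy_refs[tid]
            pos = rng.randrange(len(ref) - 90)
            read = list(ref[pos : pos + 85])
            for _ in range(rng.randrange(3)):
                op = rng.choice("sid")
                i = rng.randrange(len(read))
                if op == "s":
                    read[i] = rng.choice("ACGT")
                elif op == "i":
                    read.insert(i, rng.choice("ACGT"))
                else:
                    del read[i]
            read = "".join(read[:85])
            recs = align_read(read, toy_index, toy_refs, 2, with_cigar=False)
            got = {(r.target_id, r.strand, r.target_start): r.edit_distance
                   for r in recs}
            expect = {}
            for t, seq in toy_refs:
                for strand in "+-":
                    q = read if strand == "+" else revcomp(read)
                    for s, d in edlib_placements(q, seq, 2).items():
                        expect[(t, strand, s)] = d
            assert got == expect

    def test_cigar_consumes_read(self, toy_refs, toy_index):
        rng = random.Random(43)
        ref = toy_refs["g3"]
        read = ref[10:50] + ref[51:96]  # one deletion relative to the read
        for rec in align_read(read, toy_index, toy_refs, 2):
            consumed = 0
            num = ""
            for ch in rec.cigar:
                if ch.isdigit():
                    num += ch
                else:
                    if ch in "MI":
                        consumed += int(num)
                    num = ""
            assert consumed == len(read)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_reverse_complement_symmetry(self, toy_refs, toy_index, seed):
        rng = random.Random(seed)
        tid = f"g{rng.randrange(5)}"
        pos = rng.randrange(len(toy_refs[tid]) - 85)
        read = list(toy_refs[tid][pos : pos + 85])
        read[rng.randrange(85)] = rng.choice("ACGT")
        read = "".join(read)
        fwd = align_read(read, toy_index, toy_refs, 2, with_cigar=False)
        rev = align_read(revcomp(read), toy_index, toy_refs, 2, with_cigar=False)
        flip = {"+": "-", "-": "+"}
        assert {(r.target_id, flip[r.strand], r.target_start, r.edit_distance)
                for r in fwd} == \
               {(r.target_id, r.strand, r.target_start, r.edit_distance)
                for r in rev}


class TestAlignPair:
    def test_error_free_pair_is_proper(self, toy_refs, toy_index):
        ref = toy_refs["g4"]
        m1 = ref[30:115]
        m2 = revcomp(ref[195:280])
        res = align_pair(m1, m2, toy_index, toy_refs, 2, (40, 600))
        assert res.proper and res.summed_edit == 0
        assert res.target_id == "g4"
        assert res.rec1.strand == "+" and res.rec2.strand == "-"

    def test_mates_on_different_targets_not_proper(self, toy_refs, toy_index):
        m1 = toy_refs["g0"][0:85]
        m2 = revcomp(toy_refs["g1"][100:185])
        assert not align_pair(m1, m2, toy_index, toy_refs, 2, (40, 600)).proper

    def test_insert_bounds_enforced(self, toy_refs, toy_index):
        ref = toy_refs["g2"]
        m1 = ref[0:85]
        m2 = revcomp(ref[300:385])  # implied insert 385
        assert align_pair(m1, m2, toy_index, toy_refs, 2, (40, 300)).proper is False
        assert align_pair(m1, m2, toy_index, toy_refs, 2, (40, 600)).proper is True

    def test_per_mate_edit_caps(self, toy_refs, toy_index):
        """Edits 1 + 2 with a per-mate cap of 2 is proper; cap 1 is not."""
        ref = toy_refs["g3"]
        m1 = list(ref[20:105])
        m1[40] = {"A": "C", "C": "G", "G": "T", "T": "A"}[m1[40]]
        m2 = list(ref[200:285])
        for i in (10, 70):
            m2[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[m2[i]]
        m1, m2 = "".join(m1), revcomp("".join(m2))
        res2 = align_pair(m1, m2, toy_index, toy_refs, 2, (40, 600))
        assert res2.proper and res2.summed_edit == 3
        res1 = align_pair(m1, m2, toy_index, toy_refs, 1, (40, 600))
        assert not res1.proper
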