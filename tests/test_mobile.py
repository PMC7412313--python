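"""Cascade classification and mobile-calling rules."""

import random

import pytest

from graftmobile.align import build_index
from graftmobile.mobile import (ClassifiedPair, build_control_set, call_mobile,
                                classify_pair, classify_sample, condition_sets,
                                match_control, rpkm)
from graftmobile.pipeline import run_synthetic_experiment
from graftmobile.qc import ReadPair, Sample
from graftmobile.seqio import FastqRead, TranscriptSet
from graftmobile.simulate import SimConfig, parse_read_name, revcomp

from _oracles import start_distance


def rand_seq(n, rng):
    return "".join(rng.choice("ACGT") for _ in range(n))


def mk_pair(seq1, seq2, pid="p"):
    q = "I" * len(seq1)
    return ReadPair(pid, FastqRead(pid, seq1, "I" * len(seq1)),
                    FastqRead(pid, seq2, "I" * len(seq2)),
                    Sample("full", 1, True))


@pytest.fixture(scope="module")
def cascade_refs():
    """Rootstock transcript R; scion homolog S with 3 substitutions in every
    85-bp window; plus an unrelated scion transcript."""
    rng = random.Random(17)
    R = rand_seq(600, rng)
    S = list(R)
    for i in range(10, 600, 25):  # 3+ substitutions per 85-bp window
        S[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[S[i]]
    S = "".join(S)
    rootstock = TranscriptSet("rootstock", {"R1": R})
    scion = TranscriptSet("scion", {"S1": S, "S2": rand_seq(500, rng)})
    return rootstock, scion


@pytest.fixture(scope="module")
def cascade_indexes(cascade_refs):
    rootstock, scion = cascade_refs
    return build_index(rootstock), build_index(scion)


class TestMatchControl:
    def test_identical_and_revcomp_match(self):
        rng = random.Random(3)
        control = [FastqRead(f"c{i}", rand_seq(85, rng), "I" * 85)
                   for i in range(10)]
        cset = build_control_set(control)
        probe = control[4].sequence
        assert match_control(mk_pair(probe, rand_seq(85, rng)), cset)
        assert match_control(mk_pair(rand_seq(85, rng), revcomp(probe)), cset)

    def test_one_base_difference_never_matches(self):
        rng = random.Random(5)
        control = [FastqRead(f"c{i}", rand_seq(85, rng), "I" * 85)
                   for i in range(10)]
        cset = build_control_set(control)
        for read in control:
            mutated = list(read.sequence)
            mutated[40] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[40]]
            pair = mk_pair("".join(mutated), "".join(mutated))
            assert not match_control(pair, cset)

    def test_empty_control_set(self):
        assert not match_control(mk_pair("A" * 85, "C" * 85), frozenset())


class TestClassifyPair:
    def test_rootstock_pair_captured_first(self, cascade_refs, cascade_indexes):
        rootstock, scion = cascade_refs
        ridx, sidx = cascade_indexes
        R = rootstock["R1"]
        pair = mk_pair(R[50:135], revcomp(R[300:385]))
        cp = classify_pair(pair, ridx, rootstock, sidx, scion, frozenset())
        assert cp.label == "rootstock" and cp.assigned_targets == {"R1"}

    def test_divergent_scion_pair_is_transmitted(self, cascade_refs,
                                                 cascade_indexes):
        rootstock, scion = cascade_refs
        ridx, sidx = cascade_indexes
        S = scion["S1"]
        m1, m2 = S[50:135], revcomp(S[300:385])
        # oracle: each mate is >= 3 edits from the rootstock homolog
        assert start_distance(m1, rootstock["R1"], 50) >= 3
        assert start_distance(revcomp(m2), rootstock["R1"], 300) >= 3
        cp = classify_pair(mk_pair(m1, m2), ridx, rootstock, sidx, scion,
                           frozenset())
        assert cp.label == "transmitted"
        assert cp.assigned_targets == {"S1"}
        assert cp.summed_edit == 0

    def test_control_match_precedes_scion_mapping(self, cascade_refs,
                                                  cascade_indexes):
        rootstock, scion = cascade_refs
        ridx, sidx = cascade_indexes
        S = scion["S1"]
        m1, m2 = S[50:135], revcomp(S[300:385])
        control = build_control_set([FastqRead("c", m1, "I" * 85)])
        cp = classify_pair(mk_pair(m1, m2), ridx, rootstock, sidx, scion, control)
        assert cp.label == "control_match"

    def test_unassigned_pair(self, cascade_refs, cascade_indexes):
        rootstock, scion = cascade_refs
        ridx, sidx = cascade_indexes
        rng = random.Random(23)
        cp = classify_pair(mk_pair(rand_seq(85, rng), rand_seq(85, rng)),
                           ridx, rootstock, sidx, scion, frozenset())
        assert cp.label == "unassigned" and cp.assigned_targets == frozenset()


def _evidence(cond, rep, targets):
    return [ClassifiedPair(f"{cond}-{rep}-{i}", "transmitted", frozenset([t]), 0)
            for i, t in enumerate(targets)]


class TestCallMobile:
    def test_two_of_three_rule(self):
        classified = {
            ("full", 1): _evidence("full", 1, ["tA", "tB"]),
            ("full", 2): _evidence("full", 2, ["tA", "tC"]),
            ("full", 3): _evidence("full", 3, ["tC"]),
        }
        table = call_mobile(classified, {"tA": 1000, "tB": 1000, "tC": 1000})
        flags = {r.transcript_id: r.mobile for r in table.rows}
        assert flags == {"tA": True, "tB": False, "tC": True}

    def test_single_replicate_never_called(self):
        classified = {("lowN", r): _evidence("lowN", r, ["tX"] if r == 2 else [])
                      for r in (1, 2, 3)}
        table = call_mobile(classified, {"tX": 900})
        (row,) = table.rows
        assert row.detected_replicates == (2,) and not row.mobile

    def test_all_three_replicates_called(self):
        classified = {("full", r): _evidence("full", r, ["tZ"]) for r in (1, 2, 3)}
        table = call_mobile(classified, {"tZ": 500})
        assert table.rows[0].mobile

    def test_min_replicates_exceeding_grid_rejected(self):
        classified = {("full", 1): []}
        with pytest.raises(ValueError):
            call_mobile(classified, {}, min_replicates=2)

    def test_min_pairs_threshold(self):
        classified = {
            ("full", 1): _evidence("full", 1, ["tA", "tA"]),
            ("full", 2): _evidence("full", 2, ["tA"]),
            ("full", 3): [],
        }
        table = call_mobile(classified, {"tA": 1000}, min_pairs=2)
        (row,) = table.rows
        assert row.detected_replicates == (1,) and not row.mobile


class TestRpkm:
    @pytest.mark.parametrize("count,length,total,expected", [
        (10, 1000, 10**6, 10.0),
        (0, 1000, 10**6, 0.0),
        (7, 350, 2 * 10**6, 10.0),
    ])
    def test_closed_form(self, count, length, total, expected):
        assert rpkm(count, length, total) == pytest.approx(expected)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            rpkm(1, 0, 100)
        with pytest.raises(ValueError):
            rpkm(1, 100, 0)


class TestConditionSets:
    def test_empty_table(self):
        table = call_mobile({("full", 1): [], ("full", 2): []}, {})
        sets = condition_sets(table)
        assert sets["union"] == set()

    def test_union_identity(self):
        classified = {
            ("full", 1): _evidence("full", 1, ["a"]),
            ("full", 2): _evidence("full", 2, ["a"]),
            ("lowN", 1): _evidence("lowN", 1, ["b"]),
            ("lowN", 2): _evidence("lowN", 2, ["b"]),
        }
        sets = condition_sets(call_mobile(classified, {"a": 100, "b": 100}))
        assert sets["union"] == sets["full"] | sets["lowN"] == {"a", "b"}


@pytest.fixture(scope="module")
def small_run(small_config):
    return run_synthetic_experiment(small_config, truth_regions={
        ("full", "lowN", "lowP", "lowFe"): 5, ("lowN",): 3, ("lowFe",): 3})


class TestCascadeProperties:
    def test_labels_exhaustive_and_exclusive(self, small_run):
        for (cond, rep), cps in small_run.classified.items():
            n = small_run.stage_counts[f"{cond}/r{rep}"]["qc_pairs"]
            assert len(cps) == n
            assert all(cp.label in ("rootstock", "control_match", "transmitted",
                                    "unassigned") for cp in cps)

    def test_no_rootstock_origin_pair_called_transmitted(self, small_run):
        """Control purity: reads simulated from the rootstock never survive
        to a transmitted call."""
        for cps in small_run.classified.values():
            for cp in cps:
                if cp.label == "transmitted":
                    assert parse_read_name(cp.pair_id)["origin"] == "scion"

    def test_transmitted_targets_are_scion_ids(self, small_run):
        for cps in small_run.classified.values():
            for cp in cps:
                if cp.label == "transmitted":
                    assert cp.assigned_targets <= set(small_run.scion.ids)

    def test_edit_cap_monotonicity(self, small_run, small_config):
        """Looser rootstock cap never increases transmitted calls; looser
        scion cap never decreases them."""
        ridx = build_index(small_run.rootstock)
        sidx = build_index(small_run.scion)
        from graftmobile import qc as qc_mod
        from graftmobile import simulate as sim_mod
        r1, r2 = sim_mod.simulate_sample(small_run.rootstock, small_run.scion,
                                         small_run.truth, "lowN", 1,
                                         small_config)
        pairs = qc_mod.pair_reads(r1, r2, Sample("lowN", 1, True))[:400]

        def transmitted_count(root_cap, scion_cap):
            cps = classify_sample(pairs, ridx, small_run.rootstock, sidx,
                                  small_run.scion, frozenset(),
                                  root_max_edit=root_cap,
                                  scion_max_edit=scion_cap)
            return sum(cp.label == "transmitted" for cp in cps)

        t_caps = [transmitted_count(rc, 1) for rc in (0, 2, 4)]
        assert t_caps[0] >= t_caps[1] >= t_caps[2]
        s_caps = [transmitted_count(2, sc) for sc in (0, 1, 2)]
        assert s_caps[0] <= s_caps[1] <= s_caps[2]
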