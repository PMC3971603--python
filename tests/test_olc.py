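"""Overlap-layout-consensus assembler contracts."""

import numpy as np
import pytest

from otuasm import OlcParams, Read, find_overlaps, olc_assemble
from otuasm._align import revcomp
from otuasm.simulate import pairwise_identity

from .oracles import brute_force_overlap


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestFindOverlaps:
    def test_identical_reads_containment(self):
        rng = np.random.default_rng(0)
        s = _random_seq(rng, 200)
        edges = find_overlaps([Read(id="a", seq=s), Read(id="b", seq=s)],
                              OlcParams(min_overlap_len=100))
        plus = [e for e in edges if e.orientation == "+"]
        assert plus and plus[0].kind == "containment"
        assert plus[0].length == 200 and plus[0].identity == 100.0

    def test_dovetail_120_base_overlap(self):
        rng = np.random.default_rng(1)
        template = _random_seq(rng, 400)
        a, b = template[:260], template[140:]
        edges = find_overlaps([Read(id="a", seq=a), Read(id="b", seq=b)],
                              OlcParams(min_overlap_len=100))
        plus = [e for e in edges if e.orientation == "+"]
        assert plus and plus[0].kind == "dovetail" and plus[0].length == 120

    def test_below_threshold_no_edge(self):
        rng = np.random.default_rng(2)
        template = _random_seq(rng, 400)
        a, b = template[:240], template[160:]  # share 80 bases
        edges = find_overlaps([Read(id="a", seq=a), Read(id="b", seq=b)],
                              OlcParams(min_overlap_len=100))
        assert edges == []

    def test_matches_bruteforce_oracle_on_random_pairs(self):
        """Edge existence and best overlap geometry agree with an exhaustive
        all-offset, both-strand scan on 60 random read pairs."""
        rng = np.random.default_rng(3)
        params = OlcParams(min_overlap_len=30, min_overlap_identity=85.0)
        for _ in range(60):
            template = _random_seq(rng, 180)
            s1 = int(rng.integers(0, 60))
            a = template[s1:s1 + 100]
            s2 = int(rng.integers(0, 80))
            b = list(template[s2:s2 + 100])
            for p in rng.choice(len(b), size=rng.integers(0, 8),
                                replace=False):
                b[p] = "ACGT"[rng.integers(4)]
            b = "".join(b)
            if rng.random() < 0.5:
                b = revcomp(b)
            edges = find_overlaps([Read(id="a", seq=a), Read(id="b", seq=b)],
                                  params)
            oracle = {}
            for orient, bb in (("+", b), ("-", revcomp(b))):
                got = brute_force_overlap(a, bb, 30, min_ident=85.0)
                if got:
                    oracle[orient] = got
            assert {e.orientation for e in edges} == set(oracle)
            for e in edges:
                off, length, ident = oracle[e.orientation]
                assert (e.offset, e.length) == (off, length)
                assert e.identity == pytest.approx(ident)


class TestOlcAssemble:
    def test_perfect_tiling_reconstructs_template(self):
        rng = np.random.default_rng(4)
        template = _random_seq(rng, 500)
        # each template base covered by >= 2 reads, overlaps >= 120
        reads = [Read(id="r0", seq=template[0:260]),
                 Read(id="r1", seq=template[0:200]),
                 Read(id="r2", seq=template[120:380]),
                 Read(id="r3", seq=template[240:500]),
                 Read(id="r4", seq=template[300:500])]
        otus, unassembled = olc_assemble(reads, OlcParams(min_overlap_len=100))
        assert len(otus) == 1 and unassembled == []
        assert otus[0].consensus in (template, revcomp(template))
        assert otus[0].tracked_reads == {"r0", "r1", "r2", "r3", "r4"}

    def test_threshold_exceeding_data_leaves_all_unassembled(self):
        rng = np.random.default_rng(5)
        template = _random_seq(rng, 500)
        reads = [Read(id=f"r{i}", seq=template[s:s + 200])
                 for i, s in enumerate(range(0, 301, 80))]  # 120-base overlaps
        otus, unassembled = olc_assemble(reads, OlcParams(min_overlap_len=150))
        assert otus == []
        assert sorted(unassembled) == sorted(r.id for r in reads)

    def test_read_conservation(self, assembled):
        otus, unassembled, trimmed, _ = assembled
        tracked = [rid for o in otus for rid in o.tracked_reads]
        assert len(tracked) == len(set(tracked))  # pairwise disjoint
        assert len(tracked) + len(unassembled) == len(trimmed)

    def test_twenty_member_community_resolved(self, assembled, community):
        """Default parameters resolve each community member as one OTU at
        >= 99% identity, including the 96%-identical pair."""
        otus, _, _, _ = assembled
        assert len(otus) == 20
        members = dict(community.members)
        matched = set()
        for otu in otus:
            best = max(members, key=lambda m: max(
                pairwise_identity(otu.consensus, members[m]),
                pairwise_identity(revcomp(otu.consensus), members[m])))
            ident = max(pairwise_identity(otu.consensus, members[best]),
                        pairwise_identity(revcomp(otu.consensus),
                                          members[best]))
            assert ident >= 99.0
            matched.add(best)
        assert len(matched) == 20

    def test_strand_closure(self):
        """Reverse-complementing every input read yields identical canonical
        consensuses."""
        rng = np.random.default_rng(6)
        template = _random_seq(rng, 400)
        reads = [Read(id=f"r{i}", seq=template[s:s + 180])
                 for i, s in enumerate(range(0, 221, 55))]
        fwd, _ = olc_assemble(reads, OlcParams(min_overlap_len=100))
        flipped = [Read(id=r.id, seq=revcomp(r.seq)) for r in reads]
        rev, _ = olc_assemble(flipped, OlcParams(min_overlap_len=100))
        assert [o.consensus for o in fwd] == [o.consensus for o in rev]

    def test_unassembled_monotone_in_min_overlap(self, simulated):
        trimmed, _ = simulated
        subset = trimmed[:600]
        prev = -1
        for mol in (100, 200, 300):
            _, unassembled = olc_assemble(subset,
                                          OlcParams(min_overlap_len=mol))
            assert len(unassembled) >= prev
            prev = len(unassembled)

    def test_singletons_dissolved(self):
        rng = np.random.default_rng(7)
        reads = [Read(id="lone", seq=_random_seq(rng, 300))]
        otus, unassembled = olc_assemble(reads, OlcParams())
        assert otus == [] and unassembled == ["lone"]

    def test_consensus_majority_vote_corrects_errors(self):
        rng = np.random.default_rng(8)
        template = _random_seq(rng, 300)
        reads = []
        for i in range(9):
            seq = list(template)
            p = int(rng.integers(0, 300))
            seq[p] = "ACGT"[rng.integers(4)]  # one random error per read
            reads.append(Read(id=f"r{i}", seq="".join(seq)))
        otus, _ = olc_assemble(reads, OlcParams(min_overlap_len=100))
        assert len(otus) == 1
        assert otus[0].consensus in (template, revcomp(template))

    def test_deterministic(self, simulated):
        trimmed, _ = simulated
        subset = trimmed[:400]
        a, _ = olc_assemble(subset, OlcParams())
        b, _ = olc_assemble(subset, OlcParams())
        assert [(o.id, o.consensus, sorted(o.tracked_reads)) for o in a] == \
               [(o.id, o.consensus, sorted(o.tracked_reads)) for o in b]

    def test_params_validated(self):
        with pytest.raises(ValueError):
            OlcParams(min_overlap_len=0)
        with pytest.raises(ValueError):
            OlcParams(min_overlap_identity=0)
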