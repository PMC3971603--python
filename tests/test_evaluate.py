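"""Quality-assessment contracts: identity screen, Sn/Sp, profile error."""

import numpy as np
import pandas as pd
import pytest

from otuasm import (ReferenceSet, compare_profiles, otu_sn_sp,
                    watered_blast_identity)
from otuasm._align import revcomp
from otuasm.mapping import AbundanceTable, Assignment
from otuasm.simulate import CommunityTemplate, CommunityTruth

from .oracles import sw_identity


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


@pytest.fixture()
def refs():
    rng = np.random.default_rng(90)
    return ReferenceSet(records=[(f"ref{i}", _random_seq(rng, 500))
                                 for i in range(10)], alphabet="nt")


class TestWateredBlast:
    def test_exact_reference_hit(self, refs):
        rid, seq = refs.records[3]
        hits = watered_blast_identity(seq, refs)
        assert hits[0].ref_id == rid and hits[0].identity == 100.0

    def test_reverse_strand_hit(self, refs):
        rid, seq = refs.records[4]
        hits = watered_blast_identity(revcomp(seq), refs)
        assert hits[0].ref_id == rid and hits[0].strand == "-"

    def test_substituted_query_matches_exhaustive_smith_waterman(self, refs):
        """Short-listed identity equals full Smith-Waterman over every
        reference for queries with scattered substitutions."""
        rng = np.random.default_rng(91)
        for trial in range(20):
            rid, seq = refs.records[trial % 10]
            q = list(seq[100:400])
            for p in rng.choice(len(q), size=5, replace=False):
                q[p] = "ACGT"[rng.integers(4)]
            q = "".join(q)
            hits = watered_blast_identity(q, refs)
            # oracle applies the same minimum-column gate: short perfect
            # repeats on unrelated references are not competing hits
            oracle_best = 0.0
            for _, rseq in refs.records:
                for qq in (q, revcomp(q)):
                    _, ident, start, end = sw_identity(rseq, qq)
                    if end - start >= len(q) // 2:
                        oracle_best = max(oracle_best, ident)
            assert hits[0].identity == pytest.approx(oracle_best, abs=0.5)
            assert hits[0].ref_id == rid

    def test_all_n_query_warns_and_returns_empty(self, refs):
        with pytest.warns(UserWarning, match="no k-mers"):
            assert watered_blast_identity("N" * 100, refs) == []

    def test_tiny_perfect_match_cannot_outrank_long_alignment(self, refs):
        """A spurious short exact repeat must not beat a full-length,
        slightly imperfect alignment (minimum-column gate)."""
        rid, seq = refs.records[0]
        q = list(seq)
        q[250] = "A" if q[250] != "A" else "C"
        hits = watered_blast_identity("".join(q), refs)
        assert hits[0].ref_id == rid
        assert hits[0].identity < 100.0


class TestOtuSnSp:
    def _assignments(self, composition):
        out = []
        for otu, sources in composition.items():
            for i, src in enumerate(sources):
                out.append(Assignment(f"{otu}_{i}", "libA", otu, 99.0, 100,
                                      "+"))
        return out

    def test_perfect_assembly_sn_sp_one(self):
        reads = {f"otu_0001_{i}": "memberA" for i in range(10)}
        a = self._assignments({"otu_0001": ["memberA"] * 10})
        q = otu_sn_sp("otu_0001", "memberA", a, reads)
        assert q.sensitivity == 1.0 and q.specificity == 1.0

    def test_ninety_ten_mixture(self):
        """90 of 100 source reads captured plus 10 alien reads: Sn=Sp=0.9."""
        sources = {}
        for i in range(90):
            sources[f"otu_0001_{i}"] = "memberA"
        for i in range(90, 100):
            sources[f"otu_0001_{i}"] = "memberB"
        for i in range(10):
            sources[f"other_{i}"] = "memberA"  # memberA reads elsewhere
        a = self._assignments(
            {"otu_0001": ["memberA"] * 90 + ["memberB"] * 10})
        a += [Assignment(f"other_{i}", "libA", "otu_0002", 99.0, 100, "+")
              for i in range(10)]
        q = otu_sn_sp("otu_0001", "memberA", a, sources)
        assert q.sensitivity == pytest.approx(0.90)
        assert q.specificity == pytest.approx(0.90)

    def test_zero_denominator_flagged_not_raised(self):
        q = otu_sn_sp("otu_0001", "ghost", [], {})
        assert q.sensitivity is None and q.specificity is None


def _truth_for(members, proportions, counts):
    community = CommunityTemplate(
        members=members, proportions=np.asarray(proportions),
        identity_matrix=np.full((len(members), len(members)), 70.0))
    truth = CommunityTruth(community=community)
    truth.member_counts["libA"] = counts
    return truth


class TestCompareProfiles:
    def _members(self, n, seed=92, length=300):
        rng = np.random.default_rng(seed)
        # independent random sequences: far below any recovery threshold
        # for cross-matches, no stops needed for this metric
        out = []
        for i in range(n):
            codons = []
            while len(codons) < length // 3:
                c = _random_seq(rng, 3)
                if c not in {"TAA", "TAG", "TGA"}:
                    codons.append(c)
            out.append((f"m{i}", "".join(codons)))
        return out

    def test_exact_profile_zero_error(self):
        members = self._members(2)
        truth = _truth_for(members, [0.5, 0.5], {"m0": 50, "m1": 50})
        counts = pd.DataFrame({"libA": [50, 50]},
                              index=["otu_0001", "otu_0002"])
        table = AbundanceTable(counts, pd.Series({"libA": 0}))
        otus = [("otu_0001", members[0][1]), ("otu_0002", members[1][1])]
        cmp_ = compare_profiles(table, otus, truth)
        assert cmp_.l1_error == pytest.approx(0.0)
        assert cmp_.members_recovered == 2
        assert cmp_.unmapped_fraction == 0.0

    def test_missed_member_in_even_pair(self):
        """One member of a 50/50 pair entirely missed: recovery 1, total
        variation distance 0.5."""
        members = self._members(2)
        truth = _truth_for(members, [0.5, 0.5], {"m0": 50, "m1": 50})
        counts = pd.DataFrame({"libA": [100]}, index=["otu_0001"])
        table = AbundanceTable(counts, pd.Series({"libA": 0}))
        otus = [("otu_0001", members[0][1])]
        cmp_ = compare_profiles(table, otus, truth)
        assert cmp_.members_recovered == 1
        assert cmp_.l1_error == pytest.approx(0.5)

    def test_l1_error_bounded(self):
        members = self._members(3)
        truth = _truth_for(members, [0.6, 0.3, 0.1],
                           {"m0": 10, "m1": 30, "m2": 60})
        counts = pd.DataFrame({"libA": [60, 30, 10]},
                              index=["otu_0001", "otu_0002", "otu_0003"])
        table = AbundanceTable(counts, pd.Series({"libA": 0}))
        otus = [(f"otu_{i + 1:04d}", members[i][1]) for i in range(3)]
        cmp_ = compare_profiles(table, otus, truth)
        assert 0.0 <= cmp_.l1_error <= 1.0

    def test_unmapped_fraction_reported_separately(self):
        members = self._members(1)
        truth = _truth_for(members, [1.0], {"m0": 80})
        counts = pd.DataFrame({"libA": [60]}, index=["otu_0001"])
        table = AbundanceTable(counts, pd.Series({"libA": 20}))
        cmp_ = compare_profiles(table, [("otu_0001", members[0][1])], truth)
        assert cmp_.unmapped_fraction == pytest.approx(0.25)
        assert cmp_.l1_error == pytest.approx(0.0)  # mapped reads only
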