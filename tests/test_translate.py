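"""Dereplication, frame identification and peptide collapse contracts."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from otuasm import (ReferenceSet, collapse_peptides, dereplicate_nt,
                    find_frame)
from otuasm._align import revcomp
from otuasm.mapping import AbundanceTable
from otuasm.simulate import generate_community


def _table(counts: dict[str, int]) -> AbundanceTable:
    df = pd.DataFrame({"libA": pd.Series(counts)})
    return AbundanceTable(df, pd.Series({"libA": 0}))


class TestDereplicateNt:
    def test_identical_otus_merged_counts_summed(self):
        otus = [("otu_0001", "ACGTACGTAA"), ("otu_0002", "ACGTACGTAA")]
        reps, table, groups = dereplicate_nt(
            otus, _table({"otu_0001": 4, "otu_0002": 6}))
        assert reps == [("otu_0001", "ACGTACGTAA")]
        assert table.counts.loc["otu_0001", "libA"] == 10
        assert groups["otu_0001"] == ["otu_0001", "otu_0002"]

    def test_substring_contained_in_longer(self):
        otus = [("otu_0001", "ACGTACGT"), ("otu_0002", "GTAC")]
        reps, table, _ = dereplicate_nt(otus, _table({"otu_0001": 1,
                                                      "otu_0002": 2}))
        assert reps == [("otu_0001", "ACGTACGT")]
        assert table.counts.loc["otu_0001", "libA"] == 3

    def test_reverse_complement_merged(self):
        s = "ACGTTTGCAA"
        reps, _, _ = dereplicate_nt([("otu_0001", s), ("otu_0002", revcomp(s))],
                                    _table({"otu_0001": 1, "otu_0002": 1}))
        assert len(reps) == 1

    def test_one_base_difference_retained(self):
        otus = [("otu_0001", "ACGTACGTAA"), ("otu_0002", "ACGTACGTAC")]
        reps, _, _ = dereplicate_nt(otus, _table({"otu_0001": 1,
                                                  "otu_0002": 1}))
        assert len(reps) == 2


class TestFindFrame:
    @pytest.fixture()
    def coding(self):
        rng = np.random.default_rng(80)
        c = generate_community(n=3, length_nt=300, identity_min=70.0,
                               identity_max=90.0, synonymous_pair=False,
                               seed=80)
        seqs = [s for _, s in c.members]
        prot = ReferenceSet(records=[(n, str(Seq(s).translate()))
                                     for n, s in c.members], alphabet="aa")
        return seqs, prot

    def test_in_frame_sequence_frame_plus_one(self, coding):
        seqs, prot = coding
        fr = find_frame(seqs[0], prot)
        assert fr.frame == 1
        assert not fr.has_internal_stop
        assert fr.peptide == str(Seq(seqs[0]).translate())

    def test_strand_symmetry(self, coding):
        seqs, prot = coding
        fwd = find_frame(seqs[0], prot)
        rev = find_frame(revcomp(seqs[0]), prot)
        assert rev.frame == -1
        assert rev.peptide == fwd.peptide

    @pytest.mark.parametrize("offset, expected", [(1, 2), (2, 3)])
    def test_offset_frames(self, coding, offset, expected):
        seqs, prot = coding
        fr = find_frame("A" * offset + seqs[0], prot)
        assert fr.frame == expected

    def test_deletion_detected_by_six_frame_scan(self, coding):
        """A 1-base deletion mid-sequence leaves no clean frame: the best
        frame's translation carries a stop or the ORF fallback applies;
        verified against a brute-force scan of all six translations."""
        seqs, prot = coding
        broken = seqs[0][:150] + seqs[0][151:]
        fr = find_frame(broken, prot)
        rc = revcomp(broken)
        sixpeps = {}
        for f in (1, 2, 3):
            for frame, s in ((f, broken), (-f, rc)):
                sub = s[f - 1:]
                sub = sub[:len(sub) - len(sub) % 3]
                sixpeps[frame] = str(Seq(sub).translate())
        assert fr.peptide == sixpeps[fr.frame]
        full_orfs = {f for f, p in sixpeps.items() if "*" not in p[:-1]}
        assert fr.has_internal_stop or fr.frame in full_orfs

    def test_frame_recovery_on_seeded_suite(self):
        """find_frame recovers the generative frame for 200 simulated
        in-frame coding sequences whose peptides are in the reference."""
        c = generate_community(n=5, length_nt=453, identity_min=65.0,
                               identity_max=95.0, synonymous_pair=False,
                               seed=81)
        prot = ReferenceSet(records=[(n, str(Seq(s).translate()))
                                     for n, s in c.members], alphabet="aa")
        rng = np.random.default_rng(81)
        frames = (1, 2, 3, -1, -2, -3)
        for trial in range(200):
            name, seq = c.members[trial % 5]
            frame = frames[int(rng.integers(6))]
            pad = "G" * (abs(frame) - 1)
            if frame > 0:
                query = pad + seq
            else:
                # frame -f reads revcomp(query)[f-1:], so padding that
                # shifts a reverse frame must sit at the query's 3' end
                query = revcomp(seq) + revcomp(pad)
            fr = find_frame(query, prot)
            assert fr.frame == frame, f"trial {trial}"

    def test_too_short_rejected(self, coding):
        _, prot = coding
        with pytest.raises(ValueError):
            find_frame("AC", prot)


class TestCollapsePeptides:
    def test_synonymous_pair_collapses(self, community, community_prot_refs):
        a, b = community.synonymous_pair
        framed = {f"otu_{i}": find_frame(community.seq(n),
                                         community_prot_refs)
                  for i, n in enumerate((a, b))}
        peps, table, excluded = collapse_peptides(
            framed, _table({"otu_0": 5, "otu_1": 7}))
        assert len(peps) == 1
        assert peps[0].member_nt_otus == {"otu_0", "otu_1"}
        assert table.counts.iloc[0, 0] == 12
        assert excluded == []

    def test_single_otu_passthrough(self, community, community_prot_refs):
        framed = {"otu_0": find_frame(community.members[0][1],
                                      community_prot_refs)}
        peps, table, _ = collapse_peptides(framed, _table({"otu_0": 9}))
        assert len(peps) == 1
        assert table.counts.iloc[0, 0] == 9

    def test_twenty_members_give_nineteen_peptides(self, community,
                                                   community_prot_refs):
        """Exactly one community pair is synonymous, so the 20 nucleotide
        sequences collapse to 19 peptides."""
        framed = {f"otu_{i:02d}": find_frame(seq, community_prot_refs)
                  for i, (_, seq) in enumerate(community.members)}
        counts = {oid: 1 for oid in framed}
        peps, _, _ = collapse_peptides(framed, _table(counts))
        assert len(peps) == 19

    def test_internal_stop_excluded_and_conserved(self, community,
                                                  community_prot_refs):
        good = community.members[2][1]
        broken = good[:100] + good[101:]  # frameshift downstream
        framed = {"otu_good": find_frame(good, community_prot_refs),
                  "otu_bad": find_frame(broken, community_prot_refs)}
        if not framed["otu_bad"].has_internal_stop:
            pytest.skip("deletion did not induce a stop in this sequence")
        peps, table, excluded = collapse_peptides(
            framed, _table({"otu_good": 5, "otu_bad": 3}))
        assert excluded == ["otu_bad"]
        assert [p.member_nt_otus for p in peps] == [{"otu_good"}]
        # conservation: excluded counts are reported, total preserved
        assert table.counts.values.sum() == 5
        assert table.total["libA"] == 8

    def test_member_translation_reproduces_peptide(self, community,
                                                   community_prot_refs):
        framed = {f"otu_{i:02d}": find_frame(seq, community_prot_refs)
                  for i, (_, seq) in enumerate(community.members[:6])}
        peps, _, _ = collapse_peptides(framed,
                                       _table({o: 1 for o in framed}))
        seq_of = {f"otu_{i:02d}": s
                  for i, (_, s) in enumerate(community.members[:6])}
        for p in peps:
            for m in p.member_nt_otus:
                frame = p.frames[m]
                s = seq_of[m] if frame > 0 else revcomp(seq_of[m])
                sub = s[abs(frame) - 1:]
                sub = sub[:len(sub) - len(sub) % 3]
                assert str(Seq(sub).translate()).rstrip("*") == p.peptide
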