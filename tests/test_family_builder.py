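"""Clustering, center-star alignment, majority consensus, elongation, ORFs."""

import edlib
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tecurate.seqio import NamedSequence
from tecurate.family_builder import (
    AUTONOMOUS,
    NON_AUTONOMOUS,
    Cluster,
    FamilyError,
    MultipleAlignment,
    align_members,
    build_consensus,
    classify_autonomy,
    cluster_sequences,
    elongate_consensus,
    longest_orf,
    majority_consensus,
    pairwise_identity_coverage,
)

BASES = np.array(list("ACGT"))


def random_nt(rng, n):
    return "".join(rng.choice(BASES, size=n))


def mutate(seq, rng, frac):
    out = list(seq)
    for i in rng.choice(len(out), size=int(frac * len(out)), replace=False):
        out[i] = str(rng.choice([b for b in "ACGT" if b != out[i]]))
    return "".join(out)


class TestClustering:
    def test_high_identity_pair_links(self, rng):
        a = random_nt(rng, 1000)
        b = mutate(a, rng, 0.10)  # 90% identity, full-length overlap
        clusters = cluster_sequences([NamedSequence("a", a), NamedSequence("b", b)])
        assert len(clusters) == 1 and len(clusters[0]) == 2

    def test_unrelated_sequences_stay_singletons(self):
        rng = np.random.default_rng(11)
        a, b = random_nt(rng, 1000), random_nt(rng, 1000)
        # oracle check via unit-cost global alignment: far below threshold
        d = edlib.align(a, b, mode="NW")["editDistance"]
        assert 1 - d / 1000 < 0.6
        clusters = cluster_sequences([NamedSequence("a", a), NamedSequence("b", b)])
        assert [len(c) for c in clusters] == [1, 1]

    def test_single_linkage_chains_transitively(self):
        rng = np.random.default_rng(2)
        a = random_nt(rng, 1000)
        b = mutate(a, rng, 0.15)
        c = mutate(b, rng, 0.15)  # a~c ~ 72% expected: below threshold
        ia, _ = pairwise_identity_coverage(a, c)
        assert ia < 0.75  # a and c alone would not link
        clusters = cluster_sequences([NamedSequence(x, s) for x, s in
                                      zip("abc", (a, b, c))])
        assert len(clusters) == 1 and len(clusters[0]) == 3

    def test_empty_input_gives_empty_output(self):
        assert cluster_sequences([]) == []

    def test_zero_length_sequence_rejected(self):
        with pytest.raises(FamilyError):
            cluster_sequences([NamedSequence("a", "ACGT"), NamedSequence("b", "")])

    def test_representative_is_longest_member(self, rng):
        a = random_nt(rng, 1000)
        b = a[:900]
        (cl,) = cluster_sequences([NamedSequence("short", b), NamedSequence("long", a)])
        assert cl.representative == "long"


class TestAlignAndConsensus:
    def test_identical_members_align_without_gaps(self, rng):
        s = random_nt(rng, 200)
        cl = Cluster([NamedSequence(f"m{i}", s) for i in range(4)], "m0")
        msa = align_members(cl)
        assert all("-" not in row for row in msa.rows)
        assert majority_consensus(msa) == s

    def test_single_deletion_creates_one_gap_cell(self, rng):
        s = random_nt(rng, 200)
        deleted = s[:100] + s[101:]
        cl = Cluster([NamedSequence("rep", s), NamedSequence("del", deleted)], "rep")
        msa = align_members(cl)
        row = dict(zip(msa.ids, msa.rows))["del"]
        assert row.count("-") == 1

    def test_rows_reproduce_members_when_degapped(self, rng):
        s = random_nt(rng, 300)
        members = [NamedSequence("rep", s)] + [
            NamedSequence(f"m{i}", mutate(s, rng, 0.02)) for i in range(4)]
        msa = align_members(Cluster(members, "rep"))
        for m, row in zip(members, msa.rows):
            assert row.replace("-", "") == m.residues

    def test_low_divergence_members_gain_few_gaps(self):
        rng = np.random.default_rng(5)
        s = random_nt(rng, 500)
        members = [NamedSequence("rep", s)] + [
            NamedSequence(f"m{i}", mutate(s, rng, 0.02)) for i in range(4)]
        msa = align_members(Cluster(members, "rep"))
        for row in msa.rows:
            assert row.count("-") <= 0.02 * 500

    @pytest.mark.parametrize("column,expected", [
        (["A", "A", "A", "G", "G"], "A"),   # 3/5 majority
        (["A", "A", "G", "G"], "A"),        # 2/4 tie at threshold: order picks A
        (["-", "-", "-", "A", "A"], ""),    # gap majority deletes the column
        (["A", "C", "G", "T"], "N"),        # no majority
    ])
    def test_majority_column_rule(self, column, expected):
        msa = MultipleAlignment(ids=[f"r{i}" for i in range(len(column))],
                                rows=["C" + c + "C" for c in column])
        out = majority_consensus(msa)
        assert out == "C" + expected + "C"

    def test_consensus_of_identical_copies_is_the_copy(self, rng):
        s = random_nt(rng, 150)
        for n in (1, 3, 7):
            cl = Cluster([NamedSequence(f"m{i}", s) for i in range(n)], "m0")
            assert build_consensus(cl) == s

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.randoms(use_true_random=False))
    def test_majority_is_row_permutation_invariant(self, pyrandom):
        rng = np.random.default_rng(9)
        s = random_nt(rng, 80)
        members = [NamedSequence(f"m{i}", mutate(s, rng, 0.05)) for i in range(6)]
        msa = align_members(Cluster(members, "m0"))
        ref = majority_consensus(msa)
        order = list(range(len(msa.rows)))
        pyrandom.shuffle(order)
        shuffled = MultipleAlignment(ids=[msa.ids[i] for i in order],
                                     rows=[msa.rows[i] for i in order])
        assert majority_consensus(shuffled) == ref

    def test_empty_alignment_rejected(self):
        with pytest.raises(FamilyError):
            majority_consensus(MultipleAlignment(ids=[], rows=[]))


class TestAutonomy:
    def _orf_element(self, rng, n_codons, disrupt_at=None):
        codons = ["ATG"]
        while len(codons) < n_codons:
            c = random_nt(rng, 3)
            if c not in ("TAA", "TAG", "TGA"):
                codons.append(c)
        if disrupt_at is not None:
            codons[disrupt_at] = "TAA"
        # stop-codon barrier so no upstream ATG can extend the engineered ORF
        return (random_nt(rng, 48) + "TAATAGTGA" + "".join(codons) + "TAA"
                + random_nt(rng, 50))

    def test_long_orf_is_autonomous(self, rng):
        assert classify_autonomy(self._orf_element(rng, 400)) == AUTONOMOUS

    def test_disrupted_orf_is_non_autonomous(self, rng):
        elem = self._orf_element(rng, 400, disrupt_at=150)
        assert classify_autonomy(elem) == NON_AUTONOMOUS

    def test_threshold_boundary(self, rng):
        elem = self._orf_element(rng, 299)
        assert classify_autonomy(elem, min_orf_codons=300) == NON_AUTONOMOUS
        assert classify_autonomy(elem, min_orf_codons=299) == AUTONOMOUS

    def test_longest_orf_reports_frame_and_interval(self, rng):
        elem = self._orf_element(rng, 350)
        orf = longest_orf(elem)
        assert orf.n_codons == 350
        assert orf.protein.startswith("M") and "*" not in orf.protein
        assert elem[orf.nuc_start:orf.nuc_start + 3] in ("ATG", "CAT")


class TestElongation:
    def test_extension_halts_near_true_termini(self, single_family_sim):
        sim = single_family_sim
        template = sim.templates[0].residues
        orf = longest_orf(template)
        core = template[orf.nuc_start:orf.nuc_end]
        res = elongate_consensus(core, [sim.genome])
        assert res.converged
        a = edlib.align(template, res.residues, mode="HW", task="path")
        t0, t1 = a["locations"][0]
        # overshoot beyond either true terminus stays within 2 columns
        assert t0 <= 2
        assert len(res.residues) - (t1 + 1) <= 2
        assert a["editDistance"] == 0

    def test_identical_repeated_flanks_extend_into_the_repeat(self, rng):
        # pathological tandem context: every copy carries the same 100 bp
        # flanking repeats, so extension walks through them by construction
        elem = random_nt(rng, 400)
        fl, fr = random_nt(rng, 100), random_nt(rng, 100)
        pieces = []
        for _ in range(5):
            pieces.append(random_nt(rng, 800))
            pieces.append(fl + elem + fr)
        pieces.append(random_nt(rng, 800))
        genome = NamedSequence("chr", "".join(pieces))
        res = elongate_consensus(elem, [genome])
        assert len(res.residues) >= len(elem) + 200

    def test_single_copy_family_refuses_extension_without_error(self, rng):
        elem = random_nt(rng, 400)
        genome = NamedSequence("chr", random_nt(rng, 2000) + elem + random_nt(rng, 2000))
        res = elongate_consensus(elem, [genome])
        assert res.residues == elem  # needs >= 2 covering copies to extend
        assert res.converged

    def test_consensus_without_hits_raises_family_lost(self, rng):
        from tecurate.family_builder import FamilyLostError

        genome = NamedSequence("chr", random_nt(rng, 5000))
        with pytest.raises(FamilyLostError):
            elongate_consensus(random_nt(rng, 400), [genome])
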