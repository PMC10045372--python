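"""Seed-and-extend search against genomes with planted copies."""

import numpy as np
import pytest
from Bio import Align
from Bio.Align import substitution_matrices

from tecurate.seqio import NUCLEOTIDE, PROTEIN, NamedSequence, revcomp
from tecurate.homology_search import (
    SearchConfig,
    SearchError,
    extract_hit_regions,
    search_nucleotide,
    search_protein_seeds,
)

BASES = np.array(list("ACGT"))
AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
STOPS = {"TAA", "TAG", "TGA"}

CODON = {}
from Bio.Seq import Seq  # noqa: E402
for a in "TCAG":
    for b in "TCAG":
        for c in "TCAG":
            cod = a + b + c
            aa = str(Seq(cod).translate())
            if aa != "*":
                CODON.setdefault(aa, cod)


def random_nt(rng, n):
    return "".join(rng.choice(BASES, size=n))


def encode(protein):
    return "".join(CODON[a] for a in protein)


def plant(rng, background_len, insert, pos):
    bg = random_nt(rng, background_len)
    return bg[:pos] + insert + bg[pos:]


class TestProteinSearch:
    def setup_method(self):
        self.rng = np.random.default_rng(5)
        self.seed_prot = "".join(self.rng.choice(AA, size=100))
        self.seed = NamedSequence("seed", self.seed_prot, PROTEIN)
        self.cds = encode(self.seed_prot)

    def test_exact_planted_copy_single_full_hit(self):
        g = NamedSequence("c1", plant(self.rng, 6000, self.cds, 2000))
        hits = search_protein_seeds([g], [self.seed])
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.strand) == (2000, 2300, "+")
        assert h.identity == 1.0

    def test_minus_strand_same_forward_interval(self):
        g = NamedSequence("c1", plant(self.rng, 6000, revcomp(self.cds), 2000))
        hits = search_protein_seeds([g], [self.seed])
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.strand) == (2000, 2300, "-")

    def test_noisy_copy_covered_vs_smith_waterman_oracle(self):
        # 20% amino-acid substitutions; the local-alignment oracle defines
        # the region that should be recoverable
        rng = np.random.default_rng(7)
        prot = list(self.seed_prot)
        for i in rng.choice(len(prot), size=20, replace=False):
            prot[i] = str(rng.choice([a for a in AA if a != prot[i]]))
        mutated = "".join(prot)
        g = NamedSequence("c1", plant(rng, 6000, encode(mutated), 2000))
        hits = search_protein_seeds([g], [self.seed])
        assert hits, "diverged copy missed entirely"
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11
        aligner.extend_gap_score = -1
        aln = aligner.align(self.seed_prot, mutated)[0]
        sw_cols = aln.aligned[1][-1][1] - aln.aligned[1][0][0]  # span on copy
        best = max(hits, key=lambda h: h.score)
        covered = min(best.end, 2000 + 300) - max(best.start, 2000)
        assert covered >= 0.8 * min(300, 3 * sw_cols)

    def test_empty_seeds_rejected(self):
        g = NamedSequence("c1", random_nt(self.rng, 300))
        with pytest.raises(SearchError):
            search_protein_seeds([g], [])

    def test_alphabet_mismatch_rejected(self):
        g = NamedSequence("c1", random_nt(self.rng, 300))
        with pytest.raises(SearchError):
            search_protein_seeds([g], [NamedSequence("q", "ACGT", NUCLEOTIDE)])


class TestNucleotideSearch:
    def setup_method(self):
        self.rng = np.random.default_rng(11)
        self.query_seq = random_nt(self.rng, 400)
        self.query = NamedSequence("q", self.query_seq)

    def test_exact_planted_copy(self):
        g = NamedSequence("c1", plant(self.rng, 8000, self.query_seq, 3000))
        hits = search_nucleotide([g], self.query)
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.strand, h.identity) == (3000, 3400, "+", 1.0)

    def test_both_strands_found(self):
        bg = random_nt(self.rng, 8000)
        g = NamedSequence("c1", bg[:2000] + self.query_seq + bg[2000:5000]
                          + revcomp(self.query_seq) + bg[5000:])
        hits = search_nucleotide([g], self.query)
        assert sorted(h.strand for h in hits) == ["+", "-"]
        for h in hits:
            assert h.end - h.start == 400

    def test_substituted_copy_identity_close_to_global_alignment(self):
        rng = np.random.default_rng(3)
        mut = list(self.query_seq)
        n_subs = 20  # 5%
        for i in rng.choice(len(mut), size=n_subs, replace=False):
            mut[i] = str(rng.choice([b for b in "ACGT" if b != mut[i]]))
        mutated = "".join(mut)
        g = NamedSequence("c1", plant(rng, 8000, mutated, 3000))
        hits = search_nucleotide([g], self.query)
        assert len(hits) == 1
        true_identity = 1 - n_subs / 400
        assert abs(hits[0].identity - true_identity) <= 0.03

    def test_query_shorter_than_seed_rejected(self):
        g = NamedSequence("c1", random_nt(self.rng, 500))
        with pytest.raises(SearchError):
            search_nucleotide([g], NamedSequence("q", "ACGTACGT"))

    def test_strand_invariance_of_hit_statistics(self):
        g = NamedSequence("c1", plant(self.rng, 8000, self.query_seq, 3000))
        rc = NamedSequence("c1", revcomp(g.residues))
        h1 = search_nucleotide([g], self.query)
        h2 = search_nucleotide([rc], self.query)
        stats = lambda hs: sorted((h.end - h.start, h.score, round(h.identity, 6)) for h in hs)
        assert stats(h1) == stats(h2)
        flip = {"+": "-", "-": "+"}
        assert sorted(flip[h.strand] for h in h1) == sorted(h.strand for h in h2)

    def test_determinism(self):
        g = NamedSequence("c1", plant(self.rng, 8000, self.query_seq, 3000))
        assert search_nucleotide([g], self.query) == search_nucleotide([g], self.query)


class TestExtractRegions:
    def _hits(self, genome, n):
        q = NamedSequence("q", genome.residues[1000:1400])
        hits = search_nucleotide([genome], q)
        assert hits
        return hits[:n]

    def test_fewer_than_cap(self, rng):
        g = NamedSequence("c1", random_nt(rng, 10_000))
        hits = self._hits(g, 1)
        regions = extract_hit_regions([g], hits, flank=100, max_copies=10)
        assert len(regions) == len(hits)

    def test_cap_keeps_highest_scoring(self, rng):
        copy = random_nt(rng, 300)
        pieces, pos = [], []
        bg = random_nt(rng, 14_000)
        cur = 0
        for i in range(12):
            at = 1000 + i * 1100
            pieces.append(bg[cur:at])
            # degrade later copies so scores are distinct
            mut = list(copy)
            for j in range(i):
                mut[10 + j * 7] = "ACGT"[("ACGT".index(mut[10 + j * 7]) + 1) % 4]
            pieces.append("".join(mut))
            pos.append(at)
            cur = at
        pieces.append(bg[cur:])
        g = NamedSequence("c1", "".join(pieces))
        hits = search_nucleotide([g], NamedSequence("q", copy))
        assert len(hits) >= 12
        regions = extract_hit_regions([g], hits, flank=50, max_copies=10)
        assert len(regions) == 10
        kept_scores = [r.hit.score for r in regions]
        all_scores = sorted((h.score for h in hits), reverse=True)
        assert sorted(kept_scores, reverse=True) == all_scores[:10]

    def test_contig_edge_clamps_flank_and_flags_truncation(self, rng):
        copy = random_nt(rng, 300)
        g = NamedSequence("c1", random_nt(rng, 100) + copy + random_nt(rng, 6000))
        hits = search_nucleotide([g], NamedSequence("q", copy))
        (region,) = extract_hit_regions([g], hits, flank=5000, max_copies=1)
        assert len(region.left_flank) == 100
        assert region.left_truncated and not region.right_truncated

    def test_unknown_contig_rejected(self, rng):
        g = NamedSequence("c1", random_nt(rng, 2000))
        q = NamedSequence("q", g.residues[500:900])
        hits = search_nucleotide([g], q)
        bad = [h.__class__(**{**h.__dict__, "contig": "nope"}) for h in hits]
        with pytest.raises(SearchError):
            extract_hit_regions([g], bad, flank=10, max_copies=1)

    def test_minus_strand_region_oriented_to_element(self, rng):
        copy = random_nt(rng, 300)
        g = NamedSequence("c1", random_nt(rng, 1000) + revcomp(copy) + random_nt(rng, 1000))
        hits = search_nucleotide([g], NamedSequence("q", copy))
        (region,) = extract_hit_regions([g], hits, flank=50, max_copies=1)
        assert region.hit.strand == "-"
        assert region.core == copy
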