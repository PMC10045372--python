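"""Family construction: clustering, consensus building and elongation.

Hit sequences are clustered by single linkage under identity/coverage
thresholds (75%/75% by default, the classic BLASTCLUST-style criterion with
coverage measured on the shorter sequence), aligned with a center-star
strategy onto the longest member, collapsed into a 50%-majority consensus,
and then iteratively elongated through flanking sequence until both termini
stop gaining support.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import edlib
from Bio import Align

from .seqio import NamedSequence, translate_six_frames
from .homology_search import (
    Hit,
    Region,
    SearchConfig,
    _best_local_segment,
    _parse_cigar,
    extract_hit_regions,
    search_nucleotide,
)


class FamilyError(ValueError):
    pass


class FamilyLostError(RuntimeError):
    """The consensus no longer finds any hit in the genome."""


# Alignment scoring for member/pair alignment: match +1, mismatch -1,
# gap open -4, gap extend -1, end gaps free.
def _make_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -4
    a.extend_gap_score = -1
    a.end_insertion_score = 0
    a.end_deletion_score = 0
    return a


_ALIGNER = _make_aligner()


def pairwise_identity_coverage(a: str, b: str) -> tuple[float, float]:
    """Identity and coverage of an end-gap-free global alignment of a and b.

    Identity is computed over aligned (non-gap) columns; coverage is the
    aligned span measured on the shorter sequence divided by its length.
    """
    if not a or not b:
        raise FamilyError("cannot align an empty sequence")
    aln = _ALIGNER.align(a, b)[0]
    tb, qb = aln.aligned
    if len(tb) == 0:
        return 0.0, 0.0
    matches = 0
    cols = 0
    for (ts, te), (qs, qe) in zip(tb, qb):
        cols += te - ts
        matches += sum(1 for x, y in zip(a[ts:te], b[qs:qe]) if x == y)
    if len(a) <= len(b):
        span = tb[-1][1] - tb[0][0]
        short_len = len(a)
    else:
        span = qb[-1][1] - qb[0][0]
        short_len = len(b)
    return matches / cols, span / short_len


@dataclass
class Cluster:
    """A single-linkage cluster of copy sequences."""

    members: list[NamedSequence]
    representative: str

    def __post_init__(self) -> None:
        ids = [m.id for m in self.members]
        if not ids:
            raise FamilyError("cluster must have at least one member")
        if self.representative not in ids:
            raise FamilyError("representative must be a member")

    def member(self, mid: str) -> NamedSequence:
        for m in self.members:
            if m.id == mid:
                return m
        raise KeyError(mid)

    def __len__(self) -> int:
        return len(self.members)


def cluster_sequences(
    seqs: list[NamedSequence],
    min_coverage: float = 0.75,
    min_identity: float = 0.75,
) -> list[Cluster]:
    """Single-linkage clustering under pairwise identity/coverage thresholds.

    Two sequences are linked when an end-gap-free global alignment reaches
    ``min_identity`` over aligned columns *and* spans ``min_coverage`` of
    the shorter sequence; clusters are the connected components.  The
    representative is the longest member (ties: smallest id).  Clusters are
    returned by decreasing size (ties: smallest member id).
    """
    for s in seqs:
        if len(s.residues) == 0:
            raise FamilyError(f"zero-length sequence {s.id}")
    n = len(seqs)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            ident, cov = pairwise_identity_coverage(seqs[i].residues, seqs[j].residues)
            if ident >= min_identity and cov >= min_coverage:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    clusters = []
    for idxs in groups.values():
        members = [seqs[i] for i in idxs]
        rep = sorted(members, key=lambda m: (-len(m.residues), m.id))[0].id
        clusters.append(Cluster(members=members, representative=rep))
    clusters.sort(key=lambda c: (-len(c.members), min(m.id for m in c.members)))
    return clusters


@dataclass
class MultipleAlignment:
    """Rows of equal length over {A,C,G,T,N,-} on a shared column frame."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise FamilyError("ids/rows mismatch")
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise FamilyError("alignment rows differ in length")

    @property
    def ncols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row_spans(self) -> list[tuple[int, int]]:
        """Per row, the half-open column span between first and last residue."""
        spans = []
        for r in self.rows:
            stripped = r.strip("-")
            if not stripped:
                spans.append((0, 0))
                continue
            first = len(r) - len(r.lstrip("-"))
            last = len(r.rstrip("-"))
            spans.append((first, last))
        return spans


def align_members(cluster: Cluster) -> MultipleAlignment:
    """Center-star multiple alignment of the cluster onto its representative.

    Each member is globally aligned (end gaps free) to the representative;
    the pairwise alignments are merged on the representative's coordinate
    frame under "once a gap, always a gap".  Deterministic for fixed input.
    """
    rep = cluster.member(cluster.representative).residues
    L = len(rep)
    per_row: list[tuple[str, list[str], dict[int, str]]] = []
    ins_len = [0] * (L + 1)
    for m in cluster.members:
        if m.id == cluster.representative:
            chars = list(rep)
            ins: dict[int, str] = {}
        else:
            aln = _ALIGNER.align(rep, m.residues)[0]
            tb, qb = aln.aligned
            chars = ["-"] * L
            ins = {}
            prev_q = 0
            first = True
            for (ts, te), (qs, qe) in zip(tb, qb):
                if qs > prev_q:
                    # unaligned member residues anchored before rep position ts
                    anchor = ts if not first else tb[0][0]
                    ins[anchor] = ins.get(anchor, "") + m.residues[prev_q:qs]
                for i in range(te - ts):
                    chars[ts + i] = m.residues[qs + i]
                prev_q = qe
                first = False
            if prev_q < len(m.residues):
                ins[L] = m.residues[prev_q:]
        for p, s in ins.items():
            ins_len[p] = max(ins_len[p], len(s))
        per_row.append((m.id, chars, ins))

    ids, rows = [], []
    for mid, chars, ins in per_row:
        parts = []
        for p in range(L + 1):
            if ins_len[p]:
                s = ins.get(p, "")
                parts.append(s + "-" * (ins_len[p] - len(s)))
            if p < L:
                parts.append(chars[p])
        ids.append(mid)
        rows.append("".join(parts))
    return MultipleAlignment(ids=ids, rows=rows)


_TIE_ORDER = {"-": 0, "A": 1, "C": 2, "G": 3, "T": 4}


def _column_consensus(chars: list[str], threshold: float) -> str | None:
    """Majority call for one column; None means the column is dropped.

    ``chars`` are the characters of the rows covering the column.  Counting
    is over {A,C,G,T,-} (N contributes to the denominator only); ties are
    broken by the fixed order - > A > C > G > T.
    """
    counts: dict[str, int] = {}
    for c in chars:
        if c in _TIE_ORDER:
            counts[c] = counts.get(c, 0) + 1
    if not counts:
        return "N"
    winner = min(counts, key=lambda c: (-counts[c], _TIE_ORDER[c]))
    if counts[winner] / len(chars) < threshold:
        return "N"
    return None if winner == "-" else winner


def majority_consensus(msa: MultipleAlignment, threshold: float = 0.5) -> str:
    """Collapse an alignment into a majority-rule consensus.

    Per column, only rows covering the column (leading/trailing pad
    excluded) are counted; a character reaching ``threshold`` is emitted, a
    winning gap deletes the column, and a column with no majority becomes N.
    """
    if not msa.rows:
        raise FamilyError("empty alignment")
    spans = msa.row_spans()
    out = []
    for col in range(msa.ncols):
        chars = [r[col] for r, (s, e) in zip(msa.rows, spans) if s <= col < e]
        if not chars:
            continue
        c = _column_consensus(chars, threshold)
        if c is not None:
            out.append(c)
    return "".join(out)


def build_consensus(cluster: Cluster, threshold: float = 0.5) -> str:
    """Convenience: center-star alignment followed by majority consensus."""
    return majority_consensus(align_members(cluster), threshold)


# --- copy-to-consensus alignment (shared with boundary analysis) ------------

@dataclass
class CopyAlignment:
    """A copy-with-flanks aligned to a consensus.

    ``q0``/``qe`` give the consensus interval covered by the copy and
    ``cons2full`` maps every consensus position (0..len(consensus)) to a
    coordinate in ``full`` (the flanked copy, element orientation);
    positions outside the aligned interval are linearly extrapolated so
    candidate termini slightly outside the matched region still map into
    the copy's flanks.
    """

    copy_id: str
    full: str
    region: Region
    q0: int
    qe: int
    t0: int
    te: int
    edit_distance: int
    cons2full: list[int]

    def map(self, p: int) -> int:
        pos = self.cons2full[p] if 0 <= p < len(self.cons2full) else (
            self.cons2full[0] - (0 - p) if p < 0 else self.cons2full[-1] + (p - len(self.cons2full) + 1)
        )
        return max(0, min(len(self.full), pos))


def align_copy_to_consensus(consensus: str, region: Region) -> CopyAlignment | None:
    """Align a flanked copy to the consensus and build the coordinate map."""
    full = region.full
    res = edlib.align(consensus, full, mode="HW", task="path")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    t_begin = res["locations"][0][0]
    ops = _parse_cigar(res["cigar"])
    # keep only the maximum-scoring local segment: a truncated copy's missing
    # end then shows up as q0 > 0 (or qe < L) instead of garbage alignment
    # against its flank sequence
    ops, dq0, dt0, _score, _m, cols = _best_local_segment(ops, 1, -1, 4, 1)
    if not ops or cols == 0:
        return None
    q0 = dq0
    qe = q0 + sum(n for n, op in ops if op in "=XI")
    t0 = t_begin + dt0
    te = t0 + sum(n for n, op in ops if op in "=XD")
    L = len(consensus)
    cons2full = [0] * (L + 1)
    qi, ti = q0, t0
    for n, op in ops:
        if op in "=X":
            for i in range(n):
                cons2full[qi + i] = ti + i
            qi += n
            ti += n
        elif op == "I":  # consensus positions deleted in the copy
            for i in range(n):
                cons2full[qi + i] = ti
            qi += n
        else:  # insertion in the copy
            ti += n
    cons2full[qe] = te
    for p in range(q0 - 1, -1, -1):
        cons2full[p] = cons2full[q0] - (q0 - p)
    for p in range(qe + 1, L + 1):
        cons2full[p] = cons2full[qe] + (p - qe)
    return CopyAlignment(
        copy_id=region.copy_id, full=full, region=region,
        q0=q0, qe=qe, t0=t0, te=te,
        edit_distance=res["editDistance"], cons2full=cons2full,
    )


@dataclass
class ElongationResult:
    residues: str
    rounds: int
    converged: bool
    alignments: list[CopyAlignment] = field(default_factory=list)


# slack (bp) allowed between a copy's aligned start/end and the consensus
# end for the copy to contribute flank evidence during elongation
_END_SLACK = 3


def _extend_side(alignments: list[CopyAlignment], left: bool, threshold: float, max_ext: int) -> str:
    """Column-by-column extension into the flanks (outward from one end).

    A column is appended while at least 2 covering copies exist and the top
    character is shared by >= ``threshold`` of them (and by >= 2 of them, so
    two lone disagreeing flanks can never extend the consensus).  The
    extension threshold is deliberately stricter than the 50% consensus
    majority: on an AT-rich background a simple plurality of ~10 unrelated
    flanks passes by chance in a quarter of columns, which would creep the
    consensus past the true terminus round after round.
    """
    L = len(alignments[0].cons2full) - 1

    def column(d: int) -> list[str]:
        chars = []
        for ca in alignments:
            if left:
                if ca.q0 > _END_SLACK:
                    continue
                pos = ca.cons2full[0] - d
                if pos < 0:
                    continue
            else:
                if ca.qe < L - _END_SLACK:
                    continue
                pos = ca.cons2full[L] + d - 1
                if pos >= len(ca.full):
                    continue
            chars.append(ca.full[pos])
        return chars

    def agreed(chars: list[str]) -> str | None:
        if len(chars) < 2:
            return None
        counts: dict[str, int] = {}
        for c in chars:
            if c in "ACGT":
                counts[c] = counts.get(c, 0) + 1
        if not counts:
            return None
        top = min(counts, key=lambda c: (-counts[c], _TIE_ORDER[c]))
        if counts[top] < 2 or counts[top] < ceil(threshold * len(chars)):
            return None
        return top

    out: list[str] = []
    for d in range(1, max_ext + 1):
        chars = column(d)
        top = agreed(chars)
        if top is None:
            # a lone noisy column must not stall the walk mid-element: keep
            # going only when 5 of the next 6 columns agree (unrelated
            # flanks pass a column at ~2%, so a true boundary still halts)
            if len(chars) < 2:
                break
            ahead = [agreed(column(dd)) for dd in range(d + 1, d + 7)]
            if sum(a is not None for a in ahead) < 5:
                break
            counts = {c: chars.count(c) for c in "ACGT" if c in chars}
            top = min(counts, key=lambda c: (-counts[c], _TIE_ORDER[c]))
        out.append(top)
    return "".join(out)


def _regenerate_body(consensus: str, alignments: list[CopyAlignment], threshold: float) -> str:
    """Majority-rule regeneration of the consensus body from aligned copies.

    Works as a per-position pileup on the consensus frame (insertions in
    individual copies are not given columns; a shared insertion therefore
    requires the next search round to be picked up).
    """
    L = len(consensus)
    out = []
    for p in range(L):
        chars = []
        for ca in alignments:
            if ca.q0 <= p < ca.qe:
                a, b = ca.cons2full[p], ca.cons2full[p + 1]
                chars.append(ca.full[a] if b > a else "-")
        if not chars:
            out.append(consensus[p])
            continue
        c = _column_consensus(chars, threshold)
        if c is not None:
            out.append(c)
    return "".join(out)


def elongate_consensus(
    consensus: str,
    genome: list[NamedSequence],
    cfg: SearchConfig | None = None,
    flank: int = 5000,
    max_copies: int = 10,
    max_rounds: int = 10,
    threshold: float = 0.5,
    ext_threshold: float = 2 / 3,
) -> ElongationResult:
    """Iteratively re-search, re-align and extend a consensus to its termini.

    Each round re-searches the genome with the current consensus, extracts
    the top copies with flanks, regenerates the consensus body by majority
    and extends both ends while a supermajority (``ext_threshold``, default
    2/3) of covering copies — at least 2 — agree on a single base.  Stops
    when neither end extends and the body is stable, or after
    ``max_rounds``.
    """
    cfg = cfg or SearchConfig()
    cur = consensus
    alignments: list[CopyAlignment] = []
    for round_no in range(1, max_rounds + 1):
        hits = search_nucleotide(genome, NamedSequence("consensus", cur), cfg)
        if not hits:
            raise FamilyLostError("family lost: consensus finds no hits in the genome")
        regions = extract_hit_regions(genome, hits, flank=flank, max_copies=max_copies)
        alignments = [a for a in (align_copy_to_consensus(cur, r) for r in regions) if a]
        if not alignments:
            raise FamilyLostError("family lost: no copy aligns to the consensus")
        body = _regenerate_body(cur, alignments, threshold)
        left = _extend_side(alignments, True, ext_threshold, max_ext=flank)
        right = _extend_side(alignments, False, ext_threshold, max_ext=flank)
        new = left[::-1] + body + right
        if new == cur:
            return ElongationResult(cur, round_no, True, alignments)
        cur = new
    return ElongationResult(cur, max_rounds, False, alignments)


# --- autonomy ----------------------------------------------------------------

@dataclass(frozen=True)
class ORF:
    """Longest ATG-initiated stop-free open reading frame."""

    protein: str
    frame: int
    nuc_start: int
    nuc_end: int

    @property
    def n_codons(self) -> int:
        return len(self.protein)


def longest_orf(residues: str) -> ORF | None:
    """Scan all six frames for the longest ATG-initiated stop-free ORF."""
    best: ORF | None = None
    for fr in translate_six_frames(residues):
        prot = fr.protein
        i = 0
        while True:
            m = prot.find("M", i)
            if m == -1:
                break
            stop = prot.find("*", m)
            end = stop if stop != -1 else len(prot)
            n = end - m
            if best is None or n > best.n_codons:
                iv0 = fr.codon_interval(m)
                iv1 = fr.codon_interval(end - 1) if end > m else iv0
                best = ORF(
                    protein=prot[m:end], frame=fr.frame,
                    nuc_start=min(iv0[0], iv1[0]), nuc_end=max(iv0[1], iv1[1]),
                )
            i = (stop + 1) if stop != -1 else len(prot)
    return best


AUTONOMOUS = "autonomous"
NON_AUTONOMOUS = "non-autonomous"


def classify_autonomy(residues: str, min_orf_codons: int = 300) -> str:
    """Autonomous iff the longest ATG-initiated stop-free ORF reaches
    ``min_orf_codons`` codons (default 300, roughly the size below which a
    DDD/E transposase cannot be intact)."""
    orf = longest_orf(residues)
    if orf is not None and orf.n_codons >= min_orf_codons:
        return AUTONOMOUS
    return NON_AUTONOMOUS


@dataclass
class ConsensusRecord:
    """A family consensus with termini and autonomy annotation."""

    name: str
    residues: str
    termini_resolved: bool = False
    terminus_5: int | None = None
    terminus_3: int | None = None
    tir: object | None = None
    autonomy: str = NON_AUTONOMOUS
    copy_support: int = 0

    def __post_init__(self) -> None:
        if self.termini_resolved:
            if self.terminus_5 is None or self.terminus_3 is None or not (
                self.terminus_5 < self.terminus_3
            ):
                raise FamilyError("resolved termini must satisfy terminus_5 < terminus_3")
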