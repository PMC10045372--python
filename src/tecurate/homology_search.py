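"""Seed-and-extend homology search for protein and nucleotide queries.

A transparent, deterministic stand-in for the black-box repeat-detection
searches used when curating transposon families: exact k-mer seeding,
ungapped X-drop extension under a substitution matrix, and (for nucleotide
queries) gapped refinement of the hit around the ungapped core.  All
parameters live in :class:`SearchConfig`; identical inputs and config give
byte-identical hit tables.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, asdict

import edlib
from Bio.Align import substitution_matrices

from .seqio import (
    NUCLEOTIDE,
    PROTEIN,
    NamedSequence,
    revcomp,
    translate_six_frames,
)


class SearchError(ValueError):
    pass


@dataclass(frozen=True)
class Hit:
    """A genomic interval similar to a query.

    ``start``/``end`` are 0-based half-open positions on the forward strand
    of ``contig`` regardless of ``strand``.  ``frame`` is 0 for nucleotide
    hits and the translation frame (+-1..3) for protein hits.  ``identity``
    is computed over aligned columns, gaps excluded.
    """

    query_id: str
    contig: str
    start: int
    end: int
    strand: str
    frame: int
    score: int
    identity: float

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise SearchError(f"bad hit interval [{self.start},{self.end})")

    def length(self) -> int:
        return self.end - self.start

    def as_row(self) -> dict:
        return {
            "query_id": self.query_id, "contig": self.contig,
            "start": self.start, "end": self.end, "strand": self.strand,
            "frame": self.frame, "score": self.score,
            "identity_fraction": round(self.identity, 4),
        }


@dataclass
class SearchConfig:
    """Tunable search parameters (serialized into run logs).

    The X-drop values and minimum scores are in raw substitution-matrix
    units (BLOSUM62 for protein, +1/-1 for nucleotide); gap penalties are
    subtracted during the gapped refinement step.
    """

    protein_seed_k: int = 4
    nucleotide_seed_k: int = 11
    xdrop_protein: int = 20
    xdrop_nucleotide: int = 16
    min_score_protein: int = 50
    min_score_nucleotide: int = 30
    min_hit_len: int = 90
    protein_matrix: str = "BLOSUM62"
    nuc_match: int = 1
    nuc_mismatch: int = -1
    gap_open: int = 5
    gap_extend: int = 1
    merge_overlap: float = 0.5

    def __post_init__(self) -> None:
        if self.protein_seed_k < 2 or self.nucleotide_seed_k < 2:
            raise SearchError("seed k must be >= 2")
        if self.xdrop_protein <= 0 or self.xdrop_nucleotide <= 0:
            raise SearchError("xdrop must be positive")
        if self.min_score_protein <= 0 or self.min_score_nucleotide <= 0:
            raise SearchError("min_score must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


def _load_matrix(name: str) -> dict[tuple[str, str], int]:
    mat = substitution_matrices.load(name)
    table: dict[tuple[str, str], int] = {}
    for a in mat.alphabet:
        for b in mat.alphabet:
            table[(a, b)] = int(mat[a, b])
    return table


_MATRIX_CACHE: dict[str, dict[tuple[str, str], int]] = {}


def _matrix(name: str) -> dict[tuple[str, str], int]:
    if name not in _MATRIX_CACHE:
        _MATRIX_CACHE[name] = _load_matrix(name)
    return _MATRIX_CACHE[name]


def _xdrop_extend(a: str, b: str, a0: int, b0: int, k: int, score, xdrop: int):
    """Ungapped X-drop extension of the exact seed a[a0:a0+k] == b[b0:b0+k].

    Returns (a_start, a_end, score, matches) with the b interval implied by
    the shared diagonal.  ``score`` is a callable (char, char) -> int.
    """
    total = sum(score(a[a0 + i], b[b0 + i]) for i in range(k))
    matches = k
    # right extension
    best, run = total, total
    best_i, extra_m, run_m = 0, 0, 0
    i = 0
    la, lb = len(a), len(b)
    while a0 + k + i < la and b0 + k + i < lb:
        ca, cb = a[a0 + k + i], b[b0 + k + i]
        run += score(ca, cb)
        run_m += 1 if ca == cb else 0
        i += 1
        if run > best:
            best, best_i, extra_m = run, i, run_m
        elif best - run > xdrop:
            break
    a_end = a0 + k + best_i
    total, matches = best, matches + extra_m
    # left extension
    best, run = total, total
    best_i, extra_m, run_m = 0, 0, 0
    i = 0
    while a0 - i > 0 and b0 - i > 0:
        ca, cb = a[a0 - i - 1], b[b0 - i - 1]
        run += score(ca, cb)
        run_m += 1 if ca == cb else 0
        i += 1
        if run > best:
            best, best_i, extra_m = run, i, run_m
        elif best - run > xdrop:
            break
    a_start = a0 - best_i
    return a_start, a_end, best, matches + extra_m


def _merge_hits(hits: list[Hit], overlap: float) -> list[Hit]:
    """Greedy best-score-wins suppression of same-strand overlapping hits.

    Two hits conflict when they share >= ``overlap`` of the shorter one on
    the same contig and strand.  Ties broken by smaller start, then end.
    """
    order = sorted(hits, key=lambda h: (-h.score, h.start, h.end, h.frame))
    kept: list[Hit] = []
    for h in order:
        clash = False
        for g in kept:
            if g.contig != h.contig or g.strand != h.strand or g.query_id != h.query_id:
                continue
            ov = min(g.end, h.end) - max(g.start, h.start)
            if ov > 0 and ov >= overlap * min(g.length(), h.length()):
                clash = True
                break
        if not clash:
            kept.append(h)
    return sorted(kept, key=lambda h: (h.contig, h.start, h.end, h.query_id))


def search_protein_seeds(
    genome: list[NamedSequence],
    seeds: list[NamedSequence],
    cfg: SearchConfig | None = None,
) -> list[Hit]:
    """Find genomic regions whose translation matches protein seeds.

    Contract: six-frame translation of each contig, exact seed k-mer index,
    ungapped X-drop extension under the substitution matrix, score
    filtering, overlap merging, and mapping back to forward-strand
    nucleotide coordinates.  Output sorted by (contig, start).
    """
    cfg = cfg or SearchConfig()
    if not seeds:
        raise SearchError("no protein seeds supplied")
    for s in seeds:
        if s.alphabet != PROTEIN:
            raise SearchError(f"seed {s.id} is not protein")
    for c in genome:
        if c.alphabet != NUCLEOTIDE:
            raise SearchError(f"contig {c.id} is not nucleotide")
    mat = _matrix(cfg.protein_matrix)
    score = lambda x, y: mat.get((x, y), -4)
    k = cfg.protein_seed_k

    index: dict[str, list[tuple[int, int]]] = {}
    for si, seed in enumerate(seeds):
        for i in range(len(seed.residues) - k + 1):
            index.setdefault(seed.residues[i:i + k], []).append((si, i))

    hits: list[Hit] = []
    for contig in genome:
        frames = translate_six_frames(contig.residues)
        for fr in frames:
            prot = fr.protein
            # intervals already extended per (seed, diagonal), to skip
            # redundant seeds inside a region we have already explored
            seen: dict[tuple[int, int], list[tuple[int, int]]] = {}
            for fp in range(len(prot) - k + 1):
                entry = index.get(prot[fp:fp + k])
                if not entry:
                    continue
                for si, sp in entry:
                    diag = fp - sp
                    spans = seen.setdefault((si, diag), [])
                    if any(s <= fp < e for s, e in spans):
                        continue
                    qs, qe, sc, m = _xdrop_extend(
                        seeds[si].residues, prot, sp, fp, k, score, cfg.xdrop_protein
                    )
                    fs, fe = qs + diag, qe + diag
                    spans.append((fs, fe))
                    if sc < cfg.min_score_protein:
                        continue
                    iv0 = fr.codon_interval(fs)
                    iv1 = fr.codon_interval(fe - 1)
                    start = min(iv0[0], iv1[0])
                    end = max(iv0[1], iv1[1])
                    hits.append(Hit(
                        query_id=seeds[si].id, contig=contig.id,
                        start=start, end=end,
                        strand="+" if fr.frame > 0 else "-",
                        frame=fr.frame, score=int(sc),
                        identity=m / (qe - qs),
                    ))
    return _merge_hits(hits, cfg.merge_overlap)


_CIGAR_RE = re.compile(r"(\d+)([=XID])")


def _parse_cigar(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def _trim_terminal_indels(ops: list[tuple[int, str]]):
    """Strip leading/trailing I/D runs; return (ops, dq0, dt0, dq1, dt1)."""
    dq0 = dt0 = dq1 = dt1 = 0
    while ops and ops[0][1] in "ID":
        n, op = ops.pop(0)
        if op == "I":
            dq0 += n
        else:
            dt0 += n
    while ops and ops[-1][1] in "ID":
        n, op = ops.pop()
        if op == "I":
            dq1 += n
        else:
            dt1 += n
    return ops, dq0, dt0, dq1, dt1


def _best_local_segment(ops: list[tuple[int, str]], match: int, mismatch: int,
                        gap_open: int, gap_extend: int):
    """Maximum-scoring contiguous run of cigar operations.

    Turns a global-in-query alignment into a local one: when a copy is
    truncated or diverged at one end, the unmatched region scores negative
    and is trimmed away rather than dragging the hit below threshold.
    Kadane's algorithm at run granularity (runs are homogeneous, so optimal
    endpoints lie on run boundaries).  Returns ``(ops, dq0, dt0, score,
    matches, aligned_cols)`` where dq0/dt0 are query/target bases consumed
    before the chosen segment.
    """
    deltas = []
    for n, op in ops:
        if op == "=":
            deltas.append((n * match, n, n, n, n))
        elif op == "X":
            deltas.append((n * mismatch, n, n, 0, n))
        elif op == "I":
            deltas.append((-(gap_open + gap_extend * n), n, 0, 0, 0))
        else:
            deltas.append((-(gap_open + gap_extend * n), 0, n, 0, 0))
    best = (0, 0, 0)  # score, start, end (exclusive)
    run_score, run_start = 0, 0
    for i, (ds, _dq, _dt, _m, _c) in enumerate(deltas):
        if run_score <= 0:
            run_score, run_start = ds, i
        else:
            run_score += ds
        if run_score > best[0]:
            best = (run_score, run_start, i + 1)
    score, s, e = best
    if e <= s:
        return [], 0, 0, 0, 0, 0
    dq0 = sum(d[1] for d in deltas[:s])
    dt0 = sum(d[2] for d in deltas[:s])
    m = sum(d[3] for d in deltas[s:e])
    cols = sum(d[4] for d in deltas[s:e])
    return ops[s:e], dq0, dt0, score, m, cols


def _gapped_refine(query: str, window: str, cfg: SearchConfig):
    """Align the full query inside ``window`` (edlib infix mode) and score it.

    Returns (w_start, w_end, score, identity, q_start, q_end) with terminal
    indel runs trimmed so truncated copies are not penalized at their broken
    end, or None when no alignment is found.
    """
    res = edlib.align(query, window, mode="HW", task="path")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    t_begin = res["locations"][0][0]
    ops = _parse_cigar(res["cigar"])
    seg, dq0, dt0, score, m, cols = _best_local_segment(
        ops, cfg.nuc_match, cfg.nuc_mismatch, cfg.gap_open, cfg.gap_extend)
    if not seg or cols == 0:
        return None
    q0 = dq0
    q1 = q0 + sum(n for n, op in seg if op in "=XI")
    t0 = t_begin + dt0
    t1 = t0 + sum(n for n, op in seg if op in "=XD")
    return t0, t1, score, m / cols, q0, q1


def search_nucleotide(
    genome: list[NamedSequence],
    query: NamedSequence,
    cfg: SearchConfig | None = None,
) -> list[Hit]:
    """Find copies of a nucleotide query on both strands of the genome.

    k-mer seeding, ungapped X-drop extension, then gapped refinement of the
    full query around the ungapped core (edlib, bounded window).  Hits
    shorter than ``min_hit_len`` or scoring below ``min_score_nucleotide``
    are dropped; overlapping same-strand hits are merged best-score-wins.
    """
    cfg = cfg or SearchConfig()
    if query.alphabet != NUCLEOTIDE:
        raise SearchError("query must be nucleotide")
    k = cfg.nucleotide_seed_k
    if len(query.residues) < k:
        raise SearchError(f"query shorter than seed k={k}")
    for c in genome:
        if c.alphabet != NUCLEOTIDE:
            raise SearchError(f"contig {c.id} is not nucleotide")

    nscore = lambda x, y: cfg.nuc_match if (x == y and x != "N") else cfg.nuc_mismatch
    core_gate = max(k, cfg.min_score_nucleotide // 2)
    hits: list[Hit] = []
    for contig in genome:
        g = contig.residues
        for strand in "+-":
            q = query.residues if strand == "+" else revcomp(query.residues)
            qidx: dict[str, list[int]] = {}
            for i in range(len(q) - k + 1):
                qidx.setdefault(q[i:i + k], []).append(i)
            seen: dict[int, list[tuple[int, int]]] = {}
            for gp in range(len(g) - k + 1):
                entry = qidx.get(g[gp:gp + k])
                if not entry:
                    continue
                for qp in entry:
                    diag = gp - qp
                    spans = seen.setdefault(diag, [])
                    if any(s <= gp < e for s, e in spans):
                        continue
                    qs, qe, sc, _m = _xdrop_extend(q, g, qp, gp, k, nscore, cfg.xdrop_nucleotide)
                    gs, ge = qs + diag, qe + diag
                    spans.append((gs, ge))
                    if sc < core_gate:
                        continue
                    pad = 60
                    ws = max(0, gs - qs - pad)
                    we = min(len(g), ge + (len(q) - qe) + pad)
                    ref = _gapped_refine(q, g[ws:we], cfg)
                    if ref is None:
                        continue
                    t0, t1, score, ident, _q0, _q1 = ref
                    start, end = ws + t0, ws + t1
                    if end - start < cfg.min_hit_len or score < cfg.min_score_nucleotide:
                        continue
                    spans.append((start, end))
                    hits.append(Hit(
                        query_id=query.id, contig=contig.id,
                        start=start, end=end, strand=strand, frame=0,
                        score=int(score), identity=ident,
                    ))
    return _merge_hits(hits, cfg.merge_overlap)


@dataclass
class Region:
    """A hit extracted with flanks, oriented to the element (query) strand.

    ``left_flank`` precedes the element 5' end in element orientation; for
    minus-strand hits core and flanks are reverse-complemented and swapped.
    ``left_truncated``/``right_truncated`` record flank clipping at contig
    edges (in element orientation).
    """

    copy_id: str
    core: str
    left_flank: str
    right_flank: str
    hit: Hit
    left_truncated: bool = False
    right_truncated: bool = False

    @property
    def full(self) -> str:
        return self.left_flank + self.core + self.right_flank

    @property
    def core_offset(self) -> int:
        return len(self.left_flank)


def extract_hit_regions(
    genome: list[NamedSequence],
    hits: list[Hit],
    flank: int = 5000,
    max_copies: int = 10,
) -> list[Region]:
    """Extract the top-scoring hits with flanking sequence.

    Hits are ranked by score (descending, ties by coordinates); at most
    ``max_copies`` regions are returned, mirroring the curation practice of
    working from up to ten copies with 5000 bp flanks.
    """
    if flank < 0 or max_copies < 1:
        raise SearchError("flank must be >= 0 and max_copies >= 1")
    contigs = {c.id: c for c in genome}
    ranked = sorted(hits, key=lambda h: (-h.score, h.contig, h.start, h.end))[:max_copies]
    regions: list[Region] = []
    for h in ranked:
        if h.contig not in contigs:
            raise SearchError(f"hit references unknown contig {h.contig!r}")
        g = contigs[h.contig].residues
        ls = max(0, h.start - flank)
        re_ = min(len(g), h.end + flank)
        core = g[h.start:h.end]
        left, right = g[ls:h.start], g[h.end:re_]
        ltrunc = ls == 0 and h.start - flank < 0
        rtrunc = re_ == len(g) and h.end + flank > len(g)
        if h.strand == "-":
            core = revcomp(core)
            left, right = revcomp(right), revcomp(left)
            ltrunc, rtrunc = rtrunc, ltrunc
        regions.append(Region(
            copy_id=f"{h.contig}:{h.start}-{h.end}({h.strand})",
            core=core, left_flank=left, right_flank=right, hit=h,
            left_truncated=ltrunc, right_truncated=rtrunc,
        ))
    return regions
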