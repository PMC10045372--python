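"""Element termini, terminal inverted repeats and target site duplications.

The boundary evidence for a DNA-transposon family is threefold: a terminal
signature motif (TNT..AYA in the degenerate form, TGT..ACA strictly —
reverse-complement symmetric, as expected for termini recognized by the
same transposase), terminal inverted repeats (TIRs), and per-copy target
site duplications (TSDs) — short direct repeats of host DNA flanking each
insertion.  TSD lengths fall into discrete classes (~4, ~15 or ~25 bp) and
a single family can mix classes, so classification is per copy, never per
family.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Sequence

from .seqio import iupac_match
from .family_builder import CopyAlignment


class BoundaryError(ValueError):
    pass


# --- TSD calling -------------------------------------------------------------

def default_budget(length: int) -> int:
    """Mismatch budget for a candidate TSD: exact below 10 bp, one mismatch
    per 8 bp at or above (so degenerate 24/25 bp TSDs with up to 3
    mismatches remain callable)."""
    return 0 if length < 10 else length // 8


@dataclass
class TSDCall:
    """One copy's flank-duplication call.

    ``length`` 0 means no duplication was detected; ``left_seq`` and
    ``right_seq`` are the two copies of the duplication.  The optional
    context fields carry flank/terminus sequence for boundary listings.
    """

    copy_id: str
    length: int
    mismatches: int
    left_seq: str
    right_seq: str
    class_label: str
    left_context: str = ""
    right_context: str = ""
    element_head: str = ""
    element_tail: str = ""


def _has_long_n_run(s: str, limit: int = 10) -> bool:
    return "N" * limit in s


def call_tsd(
    left_flank: str,
    right_flank: str,
    max_len: int = 35,
    budget: Callable[[int], int] = default_budget,
    copy_id: str = "",
    bins: "ClassBins | None" = None,
) -> TSDCall:
    """Call the target site duplication at an element's insertion site.

    ``left_flank`` must end at the base immediately 5' of the element and
    ``right_flank`` start at the base immediately 3' of it (element
    orientation).  For L from ``max_len`` down to 1 the length-L suffix of
    the left flank is compared to the length-L prefix of the right flank
    (Hamming distance, N counting as a mismatch); the largest L within the
    mismatch budget is returned.  Windows crossing an assembly-gap run of
    >= 10 N are disqualified.  Empty flanks yield a length-0 call.
    """
    bins = bins or DEFAULT_BINS
    top = min(max_len, len(left_flank), len(right_flank))
    for L in range(top, 0, -1):
        ls, rs = left_flank[-L:], right_flank[:L]
        if _has_long_n_run(ls) or _has_long_n_run(rs):
            continue
        mm = sum(1 for a, b in zip(ls, rs) if a != b or a == "N")
        if mm <= budget(L):
            return TSDCall(
                copy_id=copy_id, length=L, mismatches=mm,
                left_seq=ls, right_seq=rs,
                class_label=classify_tsd_length(L, bins),
            )
    return TSDCall(copy_id=copy_id, length=0, mismatches=0,
                   left_seq="", right_seq="", class_label="none")


# --- TSD length classes ------------------------------------------------------

@dataclass(frozen=True)
class ClassBins:
    """Ordered, disjoint length bins for TSD classes."""

    bins: tuple[tuple[str, int, int], ...] = (
        ("~4", 2, 6),
        ("~15", 14, 17),
        ("~25", 24, 29),
    )

    def __post_init__(self) -> None:
        prev_hi = -1
        for label, lo, hi in self.bins:
            if lo > hi or lo <= prev_hi:
                raise BoundaryError("class bins must be disjoint and ascending")
            prev_hi = hi


DEFAULT_BINS = ClassBins()


def classify_tsd_length(length: int, bins: ClassBins = DEFAULT_BINS) -> str:
    """Map a TSD length to its discrete class label (inclusive bin bounds)."""
    if length < 0:
        raise BoundaryError("negative TSD length")
    if length == 0:
        return "none"
    for label, lo, hi in bins.bins:
        if lo <= length <= hi:
            return label
    return "other"


# --- terminal inverted repeats ----------------------------------------------

@dataclass
class TIRReport:
    length: int
    identity: float
    present: bool


def _anchored_local(s1: str, s2: str, match: int = 1, mismatch: int = -2,
                    gap_open: int = 4, gap_ext: int = 1):
    """Best-scoring alignment of prefixes of s1 and s2 anchored at (0, 0).

    Affine-gap DP; returns (score, len1, len2, matches, aligned_cols) of
    the maximal-score prefix pair, i.e. a local alignment forced to start
    at the first base of both sequences.  The mismatch penalty is twice the
    match reward so a repeat at the 0.8 identity floor still scores
    positive, while chance extension past a repeat's true end (one match in
    four random columns) almost never pays for itself.
    """
    n, m = len(s1), len(s2)
    NEG = float("-inf")
    # Per cell and state: (score, matches, aligned_cols); states are
    # M (substitution column), X (gap in s2), Y (gap in s1).
    M = [[(NEG, 0, 0)] * (m + 1) for _ in range(n + 1)]
    X = [[(NEG, 0, 0)] * (m + 1) for _ in range(n + 1)]
    Y = [[(NEG, 0, 0)] * (m + 1) for _ in range(n + 1)]
    M[0][0] = (0, 0, 0)
    best = (0, 0, 0, 0, 0)
    for i in range(n + 1):
        for j in range(m + 1):
            if i > 0:
                a = (M[i - 1][j][0] - gap_open - gap_ext,) + M[i - 1][j][1:]
                b = (X[i - 1][j][0] - gap_ext,) + X[i - 1][j][1:]
                X[i][j] = max(a, b)
            if j > 0:
                a = (M[i][j - 1][0] - gap_open - gap_ext,) + M[i][j - 1][1:]
                b = (Y[i][j - 1][0] - gap_ext,) + Y[i][j - 1][1:]
                Y[i][j] = max(a, b)
            if i > 0 and j > 0:
                s = match if s1[i - 1] == s2[j - 1] and s1[i - 1] != "N" else mismatch
                ps, pm, pc = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
                if ps > NEG:
                    M[i][j] = (ps + s, pm + (1 if s == match else 0), pc + 1)
            sc, mm, cc = M[i][j]
            if sc > best[0]:
                best = (sc, i, j, mm, cc)
    return best


def detect_tir(residues: str, max_scan: int = 100, min_tir_len: int = 8,
               min_identity: float = 0.8) -> TIRReport:
    """Detect a terminal inverted repeat on a termini-trimmed consensus.

    The first ``max_scan`` bases are aligned to the reverse complement of
    the last ``max_scan`` bases with the alignment anchored at both 5'
    terminal bases; the TIR length is the aligned span from position 0 and
    identity is measured over that span.  Present iff length >=
    ``min_tir_len`` and identity >= ``min_identity``.
    """
    from .seqio import revcomp  # local import to avoid cycle at module load

    if len(residues) < 2:
        return TIRReport(0, 0.0, False)
    head = residues[:max_scan]
    tail_rc = revcomp(residues[-max_scan:])
    score, l1, l2, m, cols = _anchored_local(head, tail_rc)
    if cols == 0:
        return TIRReport(0, 0.0, False)
    length = l1
    ident = m / cols
    return TIRReport(length, ident, length >= min_tir_len and ident >= min_identity)


def detect_tir_record(record, max_scan: int = 100, **kw) -> TIRReport:
    """TIR detection on a ConsensusRecord; requires resolved termini."""
    if not record.termini_resolved:
        raise BoundaryError("cannot scan TIRs before termini are resolved")
    return detect_tir(record.residues[record.terminus_5:record.terminus_3],
                      max_scan=max_scan, **kw)


# --- terminus determination --------------------------------------------------

@dataclass
class TerminusCall:
    terminus_5: int
    terminus_3: int
    signature_matched: bool
    pattern_used: str
    supporting_copies: int
    candidate_score: float

    def __post_init__(self) -> None:
        if self.terminus_5 >= self.terminus_3:
            raise BoundaryError("terminus_5 must precede terminus_3")


STRICT_SIGNATURE = ("TGT", "ACA")
DEGENERATE_SIGNATURE = ("TNT", "AYA")

# scoring weights: per-copy TSD support dominates; the strict signature adds
# +1 and a detectable TIR +0.5 (both logged in TerminusCall.candidate_score)
_STRICT_BONUS = 1.0
_TIR_BONUS = 0.5
# a copy contributes terminus evidence only if its alignment reaches the
# candidate position (small slack for terminal substitutions)
_COVER_SLACK = 3


# a copy supports a terminus pair only when its flank duplication reaches
# this length: a 1-2 bp "duplication" arises by chance at ~1/4 per copy and
# carries no boundary information (cf. the ~4 bp lower class)
_MIN_SUPPORT_LEN = 3


def _tsd_support(alignments: Sequence[CopyAlignment], p5: int, p3: int,
                 max_tsd: int, budget: Callable[[int], int],
                 min_support_len: int = _MIN_SUPPORT_LEN):
    support, total_len, calls = 0, 0, []
    for ca in alignments:
        if ca.q0 > p5 + _COVER_SLACK or ca.qe < p3 - _COVER_SLACK:
            continue
        c5, c3 = ca.map(p5), ca.map(p3)
        if c3 <= c5:
            continue
        call = call_tsd(ca.full[:c5], ca.full[c3:], max_len=max_tsd,
                        budget=budget, copy_id=ca.copy_id)
        calls.append(call)
        if call.length >= min_support_len:
            support += 1
            # mismatch-penalized evidence: shifting a terminus into the
            # element lengthens calls only by spending budget on junk bases,
            # which must never beat the clean duplication at the true site
            total_len += max(0, call.length - 2 * call.mismatches)
    return support, total_len, calls


def find_termini(
    elongated: str,
    alignments: Sequence[CopyAlignment],
    signature: tuple[str, str] = DEGENERATE_SIGNATURE,
    strict: tuple[str, str] = STRICT_SIGNATURE,
    window: int = 30,
    max_tsd: int = 35,
    budget: Callable[[int], int] = default_budget,
) -> TerminusCall:
    """Determine element termini from signature motifs and TSD support.

    Candidate 5' and 3' positions are signature-motif matches within
    ``window`` of the copy-flank divergence points (the median aligned
    start/end of the copies on the elongated consensus).  Every candidate
    pair is scored as (number of copies whose implied flanks yield a TSD)
    + 1 for a strict TGT..ACA match + 0.5 for a detectable TIR; ties fall
    to the larger summed mismatch-penalized TSD length, then the smaller
    5' position.
    """
    if not alignments:
        raise BoundaryError("no copy alignments supplied")
    L = len(elongated)
    # anchors: outer quartiles of the copies' aligned spans, so truncated
    # copies (which start/end inside the element) cannot drag the anchor
    # away from the terminus
    q0s = sorted(ca.q0 for ca in alignments)
    qes = sorted(ca.qe for ca in alignments)
    n = len(alignments)
    anchor5 = q0s[int(0.25 * (n - 1))]
    anchor3 = qes[int(0.75 * (n - 1) + 0.999)] if n > 1 else qes[0]
    sig5, sig3 = signature

    cand5 = [p for p in range(max(0, anchor5 - window), min(L - 3, anchor5 + window) + 1)
             if iupac_match(sig5, elongated[p:p + 3])]
    cand3 = [p for p in range(max(3, anchor3 - window), min(L, anchor3 + window) + 1)
             if iupac_match(sig3, elongated[p - 3:p])]
    pairs = [(p5, p3) for p5 in cand5 for p3 in cand3 if p5 + 3 <= p3 - 3]

    if not pairs:
        p5, p3 = anchor5, max(anchor3, anchor5 + 1)
        support, _total, _calls = _tsd_support(alignments, p5, p3, max_tsd, budget)
        return TerminusCall(p5, p3, False, f"{sig5}..{sig3}", support, float(support))

    best = None
    for p5, p3 in pairs:
        support, total_len, _calls = _tsd_support(alignments, p5, p3, max_tsd, budget)
        score = float(support)
        if elongated[p5:p5 + 3] == strict[0] and elongated[p3 - 3:p3] == strict[1]:
            score += _STRICT_BONUS
        if detect_tir(elongated[p5:p3]).present:
            score += _TIR_BONUS
        key = (score, total_len, -p5, -p3)
        if best is None or key > best[0]:
            best = (key, p5, p3, support, score)
    _key, p5, p3, support, score = best
    return TerminusCall(
        terminus_5=p5, terminus_3=p3,
        signature_matched=True, pattern_used=f"{sig5}..{sig3}",
        supporting_copies=support, candidate_score=score,
    )


def copies_with_both_termini(
    alignments: Sequence[CopyAlignment], t5: int, t3: int, slack: int = 5
) -> list[CopyAlignment]:
    """Copies whose alignment reaches within ``slack`` bp of both termini."""
    return [ca for ca in alignments if ca.q0 <= t5 + slack and ca.qe >= t3 - slack]


def call_copy_tsds(
    alignments: Sequence[CopyAlignment], t5: int, t3: int,
    max_tsd: int = 35, budget: Callable[[int], int] = default_budget,
    bins: ClassBins = DEFAULT_BINS, slack: int = 5,
    context: int = 30, term_context: int = 10,
) -> list[TSDCall]:
    """TSD calls for every copy retaining both termini, with listing context."""
    calls = []
    for ca in copies_with_both_termini(alignments, t5, t3, slack):
        c5, c3 = ca.map(t5), ca.map(t3)
        if c3 <= c5:
            continue
        call = call_tsd(ca.full[:c5], ca.full[c3:], max_len=max_tsd,
                        budget=budget, copy_id=ca.copy_id, bins=bins)
        Ltsd = call.length
        call.left_context = ca.full[max(0, c5 - Ltsd - context):c5 - Ltsd]
        call.right_context = ca.full[c3 + Ltsd:c3 + Ltsd + context]
        call.element_head = ca.full[c5:c5 + term_context]
        call.element_tail = ca.full[max(c5, c3 - term_context):c3]
        calls.append(call)
    return calls


# --- census ------------------------------------------------------------------

@dataclass
class Census:
    """Exact-length and class histograms of a family's TSD calls."""

    exact: dict[int, int] = field(default_factory=dict)
    classes: dict[str, int] = field(default_factory=dict)
    none_count: int = 0

    def class_string(self) -> str:
        return ";".join(f"{k}:{v}" for k, v in sorted(
            self.classes.items(), key=lambda kv: (kv[0] != "~4", kv[0] != "~15", kv[0] != "~25", kv[0])
        ))


def family_tsd_census(calls: Sequence[TSDCall], bins: ClassBins = DEFAULT_BINS) -> Census:
    """Histogram TSD calls by exact length and by class.

    Copies without a detectable TSD are counted separately and never enter
    the class histogram.
    """
    exact = Counter(c.length for c in calls if c.length > 0)
    classes = Counter(classify_tsd_length(c.length, bins) for c in calls if c.length > 0)
    none_count = sum(1 for c in calls if c.length == 0)
    return Census(exact=dict(sorted(exact.items())),
                  classes=dict(sorted(classes.items())),
                  none_count=none_count)
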