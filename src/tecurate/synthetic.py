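"""Synthetic genomes with implanted transposon families and ground truth.

The generator emulates the statistical structure the boundary analysis
relies on: an AT-rich background genome, element templates with TGT..ACA
terminal signatures, terminal inverted repeats, an internal long ORF for
autonomous families, copies flanked by exact or degenerate target site
duplications whose lengths are drawn from discrete regimes (~4 / ~15 /
~25 bp), per-copy substitutions and indels, and 5'/3' truncations.  Every
implanted copy is recorded in a :class:`TruthRecord` so pipeline output can
be scored copy by copy.

Insertion sites are resampled until the implanted duplication is the
maximal within-budget duplication at the junction, so the recorded TSD
length is unambiguous ground truth rather than one of several chance
repeats.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqio import NamedSequence, PROTEIN, revcomp
from .family_builder import longest_orf

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study conditions for a simulated genome.

    ``tsd_regime`` is a list of (class mean, weight, jitter set): per copy a
    class is drawn by weight and the exact length uniformly from the jitter
    set, reproducing the discrete ~4/~15/~25 bp length classes with their
    observed 4/5, 14-16 and 24/25 bp realizations.  ``gc_fraction`` defaults
    to 0.33 (AT-rich, protist-like).  Rates are per base and per copy.
    """

    genome_length: int = 200_000
    gc_fraction: float = 0.33
    n_families: int = 10
    copies_per_family: int | tuple[int, int] = 10
    element_length: tuple[int, int] = (1000, 1500)
    tir_length: int = 25
    terminal_signature: tuple[str, str] = ("TGT", "ACA")
    orf: str = "present"  # present | absent | disrupted
    orf_codons: int = 350
    tsd_regime: tuple = (
        (4, 0.7, (4, 5)),
        (15, 0.2, (14, 15, 16)),
        (25, 0.1, (24, 25)),
    )
    sub_rate: float = 0.0
    indel_rate: float = 0.0
    tsd_degeneracy_rate: float = 0.0
    truncation_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        w = sum(r[1] for r in self.tsd_regime)
        if abs(w - 1.0) > 1e-9:
            raise SimulationError("TSD regime weights must sum to 1")
        for r in (self.sub_rate, self.indel_rate, self.tsd_degeneracy_rate,
                  self.truncation_prob, self.gc_fraction):
            if not 0.0 <= r <= 1.0:
                raise SimulationError("rates must lie in [0, 1]")
        lo, hi = self.element_length
        if self.tir_length >= lo / 2:
            raise SimulationError("tir_length must be < element_length/2")
        if self.orf not in ("present", "absent", "disrupted"):
            raise SimulationError(f"unknown orf mode {self.orf!r}")

    def max_tsd_len(self) -> int:
        return max(max(jit) for _mean, _w, jit in self.tsd_regime)


@dataclass
class TruthRecord:
    """Ground truth for one implanted copy (final-genome coordinates)."""

    family: str
    copy_id: str
    contig: str
    insertion_site: int   # start of the left TSD copy
    start: int            # element interval, 0-based half-open
    end: int
    strand: str
    tsd_length: int
    tsd_sequence: str
    substitutions: int
    indels: int
    truncated_5: int      # bp removed from the element 5' end
    truncated_3: int

    @property
    def truncated(self) -> bool:
        return self.truncated_5 > 0 or self.truncated_3 > 0


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(_BASES, size=n, p=p))


def random_genome(cfg: SimulationConfig, rng: np.random.Generator,
                  contig_id: str = "chr1") -> NamedSequence:
    return NamedSequence(contig_id, _random_bases(rng, cfg.genome_length, cfg.gc_fraction))


def _random_codon(rng: np.random.Generator, gc: float) -> str:
    while True:
        c = _random_bases(rng, 3, gc)
        if c not in _STOPS:
            return c


def make_element_template(cfg: SimulationConfig, rng: np.random.Generator,
                          name: str = "template") -> NamedSequence:
    """Build one element template: signature termini, TIR, optional ORF.

    The first ``tir_length`` bases are reverse-complemented into the tail to
    create a perfect TIR; because the template starts with the 5' signature,
    the 3' end automatically carries its reverse complement (TGT..ACA).
    """
    lo, hi = cfg.element_length
    tir = cfg.tir_length
    need = 2 * tir + 20
    if cfg.orf != "absent":
        need = tir + 10 + 3 * cfg.orf_codons + 3 + 10 + tir
    if hi < need:
        raise SimulationError(
            f"element_length max {hi} too short for TIR+ORF (need {need})")
    length = int(rng.integers(max(lo, need), hi + 1))
    seq = list(_random_bases(rng, length, cfg.gc_fraction))
    if cfg.orf != "absent":
        orf_start = tir + 10
        codons = ["ATG"] + [_random_codon(rng, cfg.gc_fraction)
                            for _ in range(cfg.orf_codons - 1)]
        if cfg.orf == "disrupted":
            codons[150] = "TAA"
        body = "".join(codons) + "TAA"
        seq[orf_start:orf_start + len(body)] = list(body)
    sig5 = cfg.terminal_signature[0]
    seq[0:3] = list(sig5)
    head = "".join(seq[:tir])
    seq[length - tir:] = list(revcomp(head))
    return NamedSequence(name, "".join(seq), description="synthetic element template")


def _max_duplication(left: str, right: str, max_len: int = 35) -> int:
    """Brute-force maximal within-budget duplication at a junction.

    Independent of the caller in :mod:`tecurate.boundary_tsd`; used to make
    simulated TSD lengths unambiguous.
    """
    top = min(max_len, len(left), len(right))
    for L in range(top, 0, -1):
        mm = sum(1 for a, b in zip(left[-L:], right[:L]) if a != b or a == "N")
        if mm <= (0 if L < 10 else L // 8):
            return L
    return 0


def _mutate_element(body: str, cfg: SimulationConfig, rng: np.random.Generator,
                    truncate: bool | None):
    """Apply truncation, substitutions and indels to one copy of the template."""
    t5 = t3 = 0
    if truncate is None:
        truncate = bool(rng.random() < cfg.truncation_prob)
    if truncate:
        frac = float(rng.uniform(0.1, 0.9))
        nbp = max(1, int(round(frac * len(body))))
        if rng.random() < 0.5:
            body, t5 = body[nbp:], nbp
        else:
            body, t3 = body[:-nbp], nbp
    chars = list(body)
    nsub = 0
    if cfg.sub_rate > 0:
        hitpos = np.nonzero(rng.random(len(chars)) < cfg.sub_rate)[0]
        for p in hitpos:
            alt = [b for b in "ACGT" if b != chars[p]]
            chars[p] = alt[int(rng.integers(3))]
        nsub = len(hitpos)
    nindel = 0
    if cfg.indel_rate > 0:
        out = []
        for c in chars:
            if rng.random() < cfg.indel_rate:
                nindel += 1
                if rng.random() < 0.5:
                    continue  # deletion
                out.append(c)
                out.append(str(rng.choice(_BASES)))
            else:
                out.append(c)
        chars = out
    return "".join(chars), nsub, nindel, t5, t3


# minimum distance between insertion sites (and to contig edges / forbidden
# intervals): keeps every TSD-calling window free of neighbouring elements
_SITE_MARGIN = 150


def implant_copies(
    genome: NamedSequence,
    template: NamedSequence,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    family: str = "fam1",
    tsd_lengths: list[int] | None = None,
    truncations: list[bool] | None = None,
    forbidden: list[tuple[int, int]] | None = None,
):
    """Implant copies of a template into a genome, duplicating target sites.

    Returns ``(mutated genome, truth records, occupied intervals, shift)``
    where the occupied intervals (final coordinates) cover every insertion
    made so far, including those passed in via ``forbidden`` (shifted as
    needed), and ``shift`` maps positions of the input genome into the
    mutated one (for re-anchoring older annotations).

    Per copy: a TSD class is drawn by regime weight and its length from the
    jitter set (or taken from ``tsd_lengths``), the target site is
    duplicated on both sides of the element, the element is inserted on a
    random strand with per-copy substitutions/indels, the right TSD copy is
    degenerated at ``tsd_degeneracy_rate`` and the copy may be truncated.
    Sites are rejected near contig edges, previous insertions, or when the
    implanted duplication would not be the maximal one at the junction.
    """
    g = genome.residues
    n = len(tsd_lengths) if tsd_lengths is not None else (
        cfg.copies_per_family if isinstance(cfg.copies_per_family, int)
        else int(rng.integers(cfg.copies_per_family[0], cfg.copies_per_family[1] + 1))
    )
    if truncations is not None and len(truncations) != n:
        raise SimulationError("truncations must match the number of copies")
    forbidden = list(forbidden or [])
    weights = [w for _m, w, _j in cfg.tsd_regime]
    jitters = [jit for _m, _w, jit in cfg.tsd_regime]

    margin = max(_SITE_MARGIN, 2 * cfg.max_tsd_len())
    if len(g) < n * (len(template.residues) + 2 * margin):
        raise SimulationError("genome too small for the requested copies")

    planned = []  # (site, element_str, tsd, right_tsd, truth fields...)
    taken: list[tuple[int, int]] = list(forbidden)
    for i in range(n):
        ok = False
        for _attempt in range(2000):
            site = int(rng.integers(margin, len(g) - margin))
            if any(s - margin <= site <= e + margin for s, e in taken):
                continue
            if tsd_lengths is not None:
                L = tsd_lengths[i]
            else:
                cls = int(rng.choice(len(weights), p=weights))
                jit = jitters[cls]
                L = int(jit[int(rng.integers(len(jit)))])
            tsd = g[site:site + L]
            right = list(tsd)
            ndeg = 0
            if cfg.tsd_degeneracy_rate > 0 and L > 0:
                for p in range(L):
                    if rng.random() < cfg.tsd_degeneracy_rate:
                        alt = [b for b in "ACGT" if b != right[p]]
                        right[p] = alt[int(rng.integers(3))]
                        ndeg += 1
            right_tsd = "".join(right)
            body, nsub, nindel, t5, t3 = _mutate_element(
                template.residues, cfg, rng,
                None if truncations is None else truncations[i])
            strand = "+" if rng.random() < 0.5 else "-"
            inserted = body if strand == "+" else revcomp(body)
            # ground-truth well-definedness: the implanted duplication must
            # be the maximal within-budget duplication at this junction
            left_ctx = g[max(0, site - 80):site + L]
            right_ctx = right_tsd + g[site + L:site + L + 80]
            called = _max_duplication(left_ctx, right_ctx)
            if called > L or (ndeg == 0 and called != L):
                continue
            planned.append((site, inserted, L, tsd, right_tsd, strand,
                            nsub, nindel, t5, t3))
            taken.append((site, site + L))
            ok = True
            break
        if not ok:
            raise SimulationError("could not place all copies (genome too small?)")

    planned.sort(key=lambda x: x[0])
    pieces: list[str] = []
    truths: list[TruthRecord] = []
    occupied: list[tuple[int, int]] = []
    prev = 0
    added = 0
    for idx, (site, inserted, L, tsd, right_tsd, strand,
              nsub, nindel, t5, t3) in enumerate(planned):
        pieces.append(g[prev:site + L])
        pieces.append(inserted)
        pieces.append(right_tsd)
        start = site + L + added
        end = start + len(inserted)
        truths.append(TruthRecord(
            family=family, copy_id=f"{family}.c{idx}", contig=genome.id,
            insertion_site=site + added, start=start, end=end, strand=strand,
            tsd_length=L, tsd_sequence=tsd, substitutions=nsub, indels=nindel,
            truncated_5=t5, truncated_3=t3,
        ))
        occupied.append((site + added, end + L))
        added += len(inserted) + L
        prev = site + L
    pieces.append(g[prev:])
    new_genome = NamedSequence(genome.id, "".join(pieces),
                               description=genome.description)

    # breakpoints for shifting older annotations into the new frame
    ins_points = [(p[0] + p[2], len(p[1]) + p[2]) for p in planned]

    def shift(pos: int) -> int:
        return pos + sum(added for pt, added in ins_points if pt <= pos)

    shifted = [(shift(s), shift(e)) for s, e in forbidden]
    return new_genome, truths, shifted + occupied, shift


@dataclass
class SimulationResult:
    genome: NamedSequence
    templates: list[NamedSequence]
    truths: list[TruthRecord]
    seeds: list[NamedSequence] = field(default_factory=list)
    config: SimulationConfig | None = None


def simulate(cfg: SimulationConfig,
             tsd_lengths: dict[str, list[int]] | None = None,
             truncations: dict[str, list[bool]] | None = None) -> SimulationResult:
    """Generate a genome with ``n_families`` implanted element families.

    Per family a fresh template is drawn and implanted; protein seeds are
    the translated long ORFs of the templates (for ``orf="present"``).
    Deterministic: identical configs give byte-identical genomes and truth
    tables.  Optional per-family overrides pin exact TSD lengths and
    truncation flags (keys are family names ``fam1``..``famN``).
    """
    rng = np.random.default_rng(cfg.seed)
    genome = random_genome(cfg, rng)
    templates: list[NamedSequence] = []
    truths: list[TruthRecord] = []
    seeds: list[NamedSequence] = []
    occupied: list[tuple[int, int]] = []
    for i in range(1, cfg.n_families + 1):
        fam = f"fam{i}"
        template = make_element_template(cfg, rng, name=fam)
        genome, fam_truths, occupied, shift = implant_copies(
            genome, template, cfg, rng, family=fam,
            tsd_lengths=None if tsd_lengths is None else tsd_lengths.get(fam),
            truncations=None if truncations is None else truncations.get(fam),
            forbidden=occupied,
        )
        for t in truths:  # re-anchor earlier families' coordinates
            t.insertion_site = shift(t.insertion_site)
            t.start = shift(t.start)
            t.end = shift(t.end)
        templates.append(template)
        truths.extend(fam_truths)
        if cfg.orf != "absent":
            orf = longest_orf(template.residues)
            seeds.append(NamedSequence(fam, orf.protein, PROTEIN,
                                       description="template transposase ORF"))
    return SimulationResult(genome=genome, templates=templates,
                            truths=truths, seeds=seeds, config=cfg)


# --- truth table I/O ---------------------------------------------------------

TRUTH_COLUMNS = ["family", "copy_id", "contig", "insertion_site", "start", "end",
                 "strand", "tsd_length", "tsd_sequence", "substitutions",
                 "indels", "truncated_5", "truncated_3"]


def truths_to_frame(truths: list[TruthRecord]) -> pd.DataFrame:
    return pd.DataFrame([{c: getattr(t, c) for c in TRUTH_COLUMNS} for t in truths],
                        columns=TRUTH_COLUMNS)


def write_truth_table(truths: list[TruthRecord], path: str | os.PathLike) -> None:
    truths_to_frame(truths).to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | os.PathLike) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"tsd_sequence": str}, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        d["tsd_sequence"] = d["tsd_sequence"] or ""
        out.append(TruthRecord(**d))
    return out


# --- evaluation --------------------------------------------------------------

@dataclass
class FamilyEvaluation:
    family: str
    matched: bool
    terminus_offset_5: int | None = None
    terminus_offset_3: int | None = None
    consensus_identity: float | None = None
    tsd_exact: int = 0
    tsd_within1: int = 0
    tsd_total: int = 0
    census_l1: int | None = None
    copies_both_termini: int | None = None
    truth_untruncated: int = 0
    truncated_called: int = 0


@dataclass
class RunMetrics:
    families: list[FamilyEvaluation]

    @property
    def missed(self) -> list[str]:
        return [f.family for f in self.families if not f.matched]

    def aggregate(self) -> dict:
        done = [f for f in self.families if f.matched]
        total = sum(f.tsd_total for f in done)
        exact = sum(f.tsd_exact for f in done)
        within1 = sum(f.tsd_within1 for f in done)
        return {
            "families_total": len(self.families),
            "families_matched": len(done),
            "families_missed": len(self.missed),
            "tsd_exact_accuracy": exact / total if total else float("nan"),
            "tsd_within1_accuracy": within1 / total if total else float("nan"),
            "mean_consensus_identity": (
                sum(f.consensus_identity for f in done) / len(done) if done else float("nan")),
            "max_terminus_offset": max(
                (max(abs(f.terminus_offset_5), abs(f.terminus_offset_3)) for f in done),
                default=None),
            "census_l1_total": sum(f.census_l1 for f in done) if done else None,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(f) for f in self.families])


def _alignment_offsets(template: str, consensus: str):
    """Signed end offsets and identity of template vs consensus (end-free)."""
    from .family_builder import _ALIGNER

    aln = _ALIGNER.align(template, consensus)[0]
    tb, qb = aln.aligned
    if len(tb) == 0:
        return None, None, 0.0
    matches = sum(
        1 for (ts, te), (qs, qe) in zip(tb, qb)
        for x, y in zip(template[ts:te], consensus[qs:qe]) if x == y)
    cols = sum(te - ts for ts, te in tb)
    off5 = int(tb[0][0] - qb[0][0])
    off3 = int((len(template) - tb[-1][1]) - (len(consensus) - qb[-1][1]))
    # positive offset: consensus is short at that end; negative: it overhangs
    return off5, off3, float(matches / cols)


def _interval_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def evaluate_calls(truths: list[TruthRecord], families, templates) -> RunMetrics:
    """Score pipeline families against the simulator's ground truth.

    ``families`` are pipeline results (family_id, trimmed_residues, calls,
    copy_intervals, copy_count_both_termini); they are matched to templates
    by family id.  TSD calls are matched to truth copies by >= 50% interval
    overlap.  Families without a result are reported as missed.
    """
    by_id = {f.family_id: f for f in families}
    tmpl_by_id = {t.id: t for t in templates}
    truth_by_family: dict[str, list[TruthRecord]] = {}
    for t in truths:
        truth_by_family.setdefault(t.family, []).append(t)

    evals = []
    for fam_id, fam_truths in sorted(truth_by_family.items()):
        untrunc = [t for t in fam_truths if not t.truncated]
        ev = FamilyEvaluation(family=fam_id, matched=fam_id in by_id,
                              truth_untruncated=len(untrunc))
        if ev.matched and fam_id in tmpl_by_id:
            res = by_id[fam_id]
            off5, off3, ident = _alignment_offsets(
                tmpl_by_id[fam_id].residues, res.trimmed_residues)
            ev.terminus_offset_5, ev.terminus_offset_3 = off5, off3
            ev.consensus_identity = ident
            ev.copies_both_termini = res.copy_count_both_termini
            calls_by_iv = []
            for call in res.calls:
                iv = res.copy_intervals.get(call.copy_id)
                if iv is not None:
                    calls_by_iv.append((iv, call))
            from .boundary_tsd import classify_tsd_length
            truth_classes: dict[str, int] = {}
            called_classes: dict[str, int] = {}
            for t in untrunc:
                truth_classes[classify_tsd_length(t.tsd_length)] = (
                    truth_classes.get(classify_tsd_length(t.tsd_length), 0) + 1)
                ev.tsd_total += 1
                match = None
                for (c, s, e, _st), call in calls_by_iv:
                    if c == t.contig and _interval_overlap((s, e), (t.start, t.end)) >= \
                            0.5 * (t.end - t.start):
                        match = call
                        break
                if match is None:
                    continue
                if match.length == t.tsd_length:
                    ev.tsd_exact += 1
                if abs(match.length - t.tsd_length) <= 1:
                    ev.tsd_within1 += 1
            for call in res.calls:
                if call.length > 0:
                    lbl = classify_tsd_length(call.length)
                    called_classes[lbl] = called_classes.get(lbl, 0) + 1
                iv = res.copy_intervals.get(call.copy_id)
                if iv is not None:
                    for t in fam_truths:
                        if t.truncated and iv[0] == t.contig and _interval_overlap(
                                (iv[1], iv[2]), (t.start, t.end)) >= 0.5 * (t.end - t.start):
                            ev.truncated_called += 1
            labels = set(truth_classes) | set(called_classes)
            ev.census_l1 = sum(abs(truth_classes.get(l, 0) - called_classes.get(l, 0))
                               for l in labels)
        evals.append(ev)
    return RunMetrics(families=evals)
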