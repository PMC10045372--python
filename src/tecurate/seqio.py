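"""Sequence I/O and low-level sequence utilities.

This module owns the in-memory sequence container (:class:`NamedSequence`),
FASTA reading/writing, reverse complementation, six-frame translation and
IUPAC degenerate-pattern matching.  All coordinates handled here and
downstream are 0-based, half-open; 1-based inclusive coordinates appear only
in human-readable reports.

Soft-masking (lowercase residues) is preserved on read as a per-position
flag, but every downstream computation works on the uppercased residues and
ignores the mask.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

NUCLEOTIDE = "nucleotide"
PROTEIN = "protein"

_NUC_RESIDUES = frozenset("ACGTN")
_PROT_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX*")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: IUPAC nucleotide degeneracy sets.  ``N`` in a *window* only matches an
#: ``N`` in the pattern (an unknown base is never evidence for a motif).
IUPAC_SETS = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


class SeqIOError(ValueError):
    """Malformed sequence input (bad residue, duplicate id, empty file...)."""


@dataclass
class NamedSequence:
    """A named sequence with an explicit alphabet.

    Parameters
    ----------
    id:
        Whitespace-free identifier, unique within a file.
    residues:
        Uppercase residues; ``ACGTN`` for nucleotide records, the 20 amino
        acids plus ``X`` and ``*`` for protein records.
    alphabet:
        Either ``"nucleotide"`` or ``"protein"``.
    description:
        Free text carried from/to the FASTA header.
    mask:
        Per-position soft-mask flags (1 where the input was lowercase).
    """

    id: str
    residues: str
    alphabet: str = NUCLEOTIDE
    description: str = ""
    mask: tuple[int, ...] = field(default=(), repr=False)

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise SeqIOError(f"invalid sequence id: {self.id!r}")
        if self.alphabet not in (NUCLEOTIDE, PROTEIN):
            raise SeqIOError(f"unknown alphabet: {self.alphabet!r}")
        allowed = _NUC_RESIDUES if self.alphabet == NUCLEOTIDE else _PROT_RESIDUES
        for pos, ch in enumerate(self.residues):
            if ch not in allowed:
                raise SeqIOError(
                    f"record {self.id!r}: illegal {self.alphabet} residue "
                    f"{ch!r} at position {pos}"
                )
        if not self.mask:
            self.mask = (0,) * len(self.residues)
        elif len(self.mask) != len(self.residues):
            raise SeqIOError(f"record {self.id!r}: mask length mismatch")

    def __len__(self) -> int:
        return len(self.residues)


def _normalize(raw: str, alphabet: str) -> tuple[str, tuple[int, ...]]:
    mask = tuple(1 if c.islower() else 0 for c in raw)
    res = raw.upper()
    if alphabet == NUCLEOTIDE:
        res = res.replace("U", "T")
    return res, mask


def read_fasta(path: str | os.PathLike, alphabet: str = NUCLEOTIDE) -> list[NamedSequence]:
    """Read a FASTA file into an ordered list of :class:`NamedSequence`.

    Residues are uppercased (``U`` mapped to ``T`` in nucleotide mode) and
    the lowercase soft-mask is preserved in ``mask``.  Raises
    :class:`SeqIOError` on an empty file, an illegal residue (naming record
    and position) or a duplicated identifier.
    """
    records: list[NamedSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        if rec.id in seen:
            raise SeqIOError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        res, mask = _normalize(str(rec.seq), alphabet)
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(NamedSequence(rec.id, res, alphabet, desc, mask))
    if not records:
        raise SeqIOError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Sequence[NamedSequence], path: str | os.PathLike, width: int = 60) -> None:
    """Write records as wrapped FASTA; round-trips exactly with :func:`read_fasta`."""
    if not records:
        raise SeqIOError("refusing to write an empty FASTA file")
    if width < 1:
        raise SeqIOError("line width must be positive")
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


def revcomp(residues: str) -> str:
    """Reverse complement of a nucleotide string (``N`` maps to ``N``).

    An involution: ``revcomp(revcomp(s)) == s``.  Raises on non-nucleotide
    input rather than guessing.
    """
    bad = set(residues) - _NUC_RESIDUES
    if bad:
        raise SeqIOError(f"revcomp: non-nucleotide residues {sorted(bad)}")
    return residues.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class FrameTranslation:
    """One reading frame of a six-frame translation.

    ``frame`` is +1/+2/+3 on the forward strand and -1/-2/-3 on the
    reverse; ``codon_interval`` maps a protein index back to the 0-based
    half-open nucleotide interval of its codon *on the forward strand*.
    """

    frame: int
    protein: str
    nuc_length: int

    def codon_interval(self, prot_index: int) -> tuple[int, int]:
        if not 0 <= prot_index < len(self.protein):
            raise IndexError(f"protein index {prot_index} out of range")
        offset = abs(self.frame) - 1
        if self.frame > 0:
            start = offset + 3 * prot_index
            return start, start + 3
        # minus frames: codon i counted from the 3' end of the forward strand
        end = self.nuc_length - offset - 3 * prot_index
        return end - 3, end


def translate_six_frames(residues: str) -> list[FrameTranslation]:
    """Translate a nucleotide string in all six frames (standard code).

    Stop codons are rendered as ``*``; codons containing ``N`` translate to
    the amino acid if unambiguous, else ``X``.  Requires length >= 3.
    """
    if len(residues) < 3:
        raise SeqIOError("cannot translate a sequence shorter than one codon")
    bad = set(residues) - _NUC_RESIDUES
    if bad:
        raise SeqIOError(f"translate: non-nucleotide residues {sorted(bad)}")
    out: list[FrameTranslation] = []
    rc = revcomp(residues)
    for strand_sign, seq in ((1, residues), (-1, rc)):
        for off in range(3):
            trimmed = seq[off:off + (len(seq) - off) // 3 * 3]
            prot = str(Seq(trimmed).translate()) if trimmed else ""
            out.append(FrameTranslation(strand_sign * (off + 1), prot, len(residues)))
    return out


def iupac_match(pattern: str, window: str) -> bool:
    """True iff every window base is in the degeneracy set of the pattern.

    Both strings must have equal length.  A window ``N`` matches only a
    pattern ``N``; any other pattern code requires a determined base.
    """
    if len(pattern) != len(window):
        raise SeqIOError("iupac_match: pattern and window lengths differ")
    for p, w in zip(pattern, window):
        if p not in IUPAC_SETS:
            raise SeqIOError(f"iupac_match: unknown IUPAC code {p!r}")
        if w == "N":
            if p != "N":
                return False
        elif w not in IUPAC_SETS[p]:
            return False
    return True


# --- hit table TSV -----------------------------------------------------------

HIT_COLUMNS = ["query_id", "contig", "start", "end", "strand", "frame", "score", "identity_fraction"]


def write_hit_table(rows: Iterable[dict], path: str | os.PathLike) -> None:
    """Write hits as the canonical TSV (0-based half-open coordinates)."""
    df = pd.DataFrame(list(rows), columns=HIT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_hit_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"query_id": str, "contig": str, "strand": str})
    missing = set(HIT_COLUMNS) - set(df.columns)
    if missing:
        raise SeqIOError(f"hit table {path} lacks columns {sorted(missing)}")
    return df
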