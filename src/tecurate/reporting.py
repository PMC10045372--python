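"""Family naming and report rendering.

Families are named ``IS481EU-{serial}_{species}`` for autonomous families;
non-autonomous families carry the letter N: ``IS481EU-{k}N{j}_{species}``
when family ``k`` is their autonomous partner, or ``IS481EU-N{j}_{species}``
when no autonomous partner is known.  Reports are a per-family distribution
table and plain-text boundary listings in which the TSD spans are bracketed
(the machine-checkable substitute for color).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .boundary_tsd import Census, TIRReport, TSDCall
from .family_builder import AUTONOMOUS, ConsensusRecord


class ReportError(ValueError):
    pass


class NameRegistry:
    """Tracks issued family names and the per-parent/orphan N counters."""

    def __init__(self) -> None:
        self._used: set[str] = set()
        self._parent_counts: dict[tuple[int, str], int] = {}
        self._orphan_counts: dict[str, int] = {}

    def register(self, name: str) -> str:
        if name in self._used:
            raise ReportError(f"duplicate family name {name!r}")
        self._used.add(name)
        return name

    def next_parent_j(self, parent: int, tag: str) -> int:
        key = (parent, tag)
        self._parent_counts[key] = self._parent_counts.get(key, 0) + 1
        return self._parent_counts[key]

    def next_orphan_j(self, tag: str) -> int:
        self._orphan_counts[tag] = self._orphan_counts.get(tag, 0) + 1
        return self._orphan_counts[tag]


def name_family(
    serial: int,
    species_tag: str,
    autonomy: str,
    parent: int | None = None,
    registry: NameRegistry | None = None,
) -> str:
    """Compose a family name under the superfamily naming scheme.

    Autonomous: ``IS481EU-{serial}_{tag}``.  Non-autonomous with an
    autonomous partner family ``k``: ``IS481EU-{k}N{j}_{tag}`` with a
    per-parent counter ``j``; without a partner: ``IS481EU-N{j}_{tag}``.
    A registry enforces uniqueness and supplies the counters.
    """
    if serial is not None and serial < 1:
        raise ReportError("serial must be >= 1")
    registry = registry or NameRegistry()
    if autonomy == AUTONOMOUS:
        name = f"IS481EU-{serial}_{species_tag}"
    elif parent is not None:
        j = registry.next_parent_j(parent, species_tag)
        name = f"IS481EU-{parent}N{j}_{species_tag}"
    else:
        j = registry.next_orphan_j(species_tag)
        name = f"IS481EU-N{j}_{species_tag}"
    return registry.register(name)


@dataclass
class FamilyRecord:
    """One row of the family distribution table."""

    name: str
    species_tag: str
    serial: int
    consensus: ConsensusRecord
    autonomy: str
    copy_count_both_termini: int
    census: Census
    tir: TIRReport

    def __post_init__(self) -> None:
        if self.copy_count_both_termini < 0:
            raise ReportError("negative copy count")


def copy_boundary_listing(family: FamilyRecord, calls: Sequence[TSDCall],
                          max_shown: int = 5, flank_show: int = 30) -> str:
    """Render per-copy boundary lines with bracketed TSDs.

    One line per shown copy: left-flank tail, ``[TSD]``, the element's first
    10 bp, ``...``, its last 10 bp, ``[TSD]`` and the right-flank head.  If
    more than ``max_shown`` copies carry a TSD, the ones with the longest
    TSDs are shown (ties by copy id).
    """
    with_tsd = [c for c in calls if c.length > 0]
    with_tsd.sort(key=lambda c: (-c.length, c.copy_id))
    shown = with_tsd[:max_shown]
    lines = [f"# {family.name}  ({len(with_tsd)} copies with TSDs, {len(shown)} shown)"]
    for c in shown:
        left = c.left_context[-(max(0, flank_show - c.length)):] if flank_show > c.length else ""
        right = c.right_context[:max(0, flank_show - c.length)] if flank_show > c.length else ""
        lines.append(
            f"{c.copy_id}\t{left}[{c.left_seq}] {c.element_head}...{c.element_tail} "
            f"[{c.right_seq}]{right}"
        )
    return "\n".join(lines) + "\n"


_TABLE_COLUMNS = ["species_tag", "family", "autonomy", "copies_with_both_termini",
                  "tsd_classes", "tir_length", "consensus_length"]


def family_table(families: Sequence[FamilyRecord]) -> pd.DataFrame:
    """Family distribution table, sorted by species tag then serial."""
    rows = []
    for f in sorted(families, key=lambda f: (f.species_tag, f.serial, f.name)):
        t5, t3 = f.consensus.terminus_5, f.consensus.terminus_3
        clen = (t3 - t5) if f.consensus.termini_resolved else len(f.consensus.residues)
        rows.append({
            "species_tag": f.species_tag,
            "family": f.name,
            "autonomy": f.autonomy,
            "copies_with_both_termini": f.copy_count_both_termini,
            "tsd_classes": f.census.class_string(),
            "tir_length": f.tir.length if f.tir.present else 0,
            "consensus_length": clen,
        })
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def render_family_table(families: Sequence[FamilyRecord]) -> str:
    """Byte-stable TSV rendering of the family table."""
    buf = io.StringIO()
    family_table(families).to_csv(buf, sep="\t", index=False)
    return buf.getvalue()


def render_family_table_text(families: Sequence[FamilyRecord]) -> str:
    """Byte-stable aligned-text rendering of the family table."""
    df = family_table(families)
    if df.empty:
        return "\t".join(_TABLE_COLUMNS) + "\n"
    return df.to_string(index=False) + "\n"
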