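"""End-to-end family characterization: search, build, boundaries, census.

Mirrors the curation workflow for a transposon family: protein seeds are
searched against the genome, the hit sequences are clustered and collapsed
into a majority consensus, the consensus is elongated through flanking
sequence until its termini stop gaining support, termini are fixed from the
terminal signature plus per-copy TSD evidence, and finally every copy
retaining both termini contributes a TSD call to the family census.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seqio import NamedSequence
from .homology_search import SearchConfig, extract_hit_regions, search_nucleotide, search_protein_seeds
from .family_builder import (
    AUTONOMOUS,
    ConsensusRecord,
    CopyAlignment,
    FamilyLostError,
    align_copy_to_consensus,
    build_consensus,
    classify_autonomy,
    cluster_sequences,
    elongate_consensus,
)
from .boundary_tsd import (
    Census,
    ClassBins,
    DEFAULT_BINS,
    TerminusCall,
    TIRReport,
    TSDCall,
    call_copy_tsds,
    copies_with_both_termini,
    detect_tir,
    family_tsd_census,
    find_termini,
)
from .reporting import FamilyRecord, NameRegistry, name_family


@dataclass
class PipelineConfig:
    """Knobs for the full run; defaults follow standard curation practice
    (75%/75% clustering, up to 10 copies with 5000 bp flanks for
    elongation, TSDs scanned up to 35 bp)."""

    search: SearchConfig = field(default_factory=SearchConfig)
    flank: int = 5000
    max_copies: int = 10
    max_rounds: int = 10
    min_identity: float = 0.75
    min_coverage: float = 0.75
    max_tsd: int = 35
    tsd_flank: int = 200
    min_orf_codons: int = 300
    bins: ClassBins = field(default_factory=lambda: DEFAULT_BINS)
    terminus_slack: int = 5


@dataclass
class FamilyResult:
    """Everything the pipeline knows about one recovered family."""

    family_id: str
    consensus: ConsensusRecord
    terminus: TerminusCall
    tir: TIRReport
    autonomy: str
    census: Census
    calls: list[TSDCall]
    alignments: list[CopyAlignment]
    copy_count_both_termini: int
    n_copies_total: int
    elongation_rounds: int
    name: str | None = None

    @property
    def trimmed_residues(self) -> str:
        t5, t3 = self.consensus.terminus_5, self.consensus.terminus_3
        return self.consensus.residues[t5:t3]

    @property
    def copy_intervals(self) -> dict[str, tuple[str, int, int, str]]:
        return {
            ca.copy_id: (ca.region.hit.contig, ca.region.hit.start,
                         ca.region.hit.end, ca.region.hit.strand)
            for ca in self.alignments
        }


def run_family(
    genome: list[NamedSequence],
    seed: NamedSequence,
    cfg: PipelineConfig | None = None,
) -> FamilyResult | None:
    """Characterize one family from a protein seed; None when nothing is found."""
    cfg = cfg or PipelineConfig()
    hits = search_protein_seeds(genome, [seed], cfg.search)
    if not hits:
        return None
    regions = extract_hit_regions(genome, hits, flank=0, max_copies=cfg.max_copies)
    cores = [NamedSequence(r.copy_id, r.core) for r in regions]
    clusters = cluster_sequences(cores, cfg.min_coverage, cfg.min_identity)
    if not clusters:
        return None
    consensus0 = build_consensus(clusters[0])
    try:
        elong = elongate_consensus(
            consensus0, genome, cfg.search,
            flank=cfg.flank, max_copies=cfg.max_copies, max_rounds=cfg.max_rounds)
    except FamilyLostError:
        return None

    # final copy set: re-search with the elongated consensus, keep all hits
    cons_seq = NamedSequence(f"{seed.id}.consensus", elong.residues)
    final_hits = search_nucleotide(genome, cons_seq, cfg.search)
    if not final_hits:
        return None
    final_regions = extract_hit_regions(
        genome, final_hits, flank=cfg.tsd_flank, max_copies=len(final_hits))
    alignments = [a for a in (align_copy_to_consensus(elong.residues, r)
                              for r in final_regions) if a]
    if not alignments:
        return None

    term = find_termini(elong.residues, alignments, max_tsd=cfg.max_tsd)
    t5, t3 = term.terminus_5, term.terminus_3
    trimmed = elong.residues[t5:t3]
    tir = detect_tir(trimmed)
    autonomy = classify_autonomy(trimmed, cfg.min_orf_codons)
    # re-anchor every copy on the termini-trimmed consensus: aligning against
    # the trimmed sequence removes the end-placement ambiguity that consensus
    # overshoot bases introduce, so flank junctions are exact per copy
    alignments = [a for a in (align_copy_to_consensus(trimmed, r)
                              for r in final_regions) if a]
    calls = call_copy_tsds(alignments, 0, len(trimmed), max_tsd=cfg.max_tsd,
                           bins=cfg.bins, slack=cfg.terminus_slack)
    census = family_tsd_census(calls, cfg.bins)
    both = copies_with_both_termini(alignments, 0, len(trimmed), cfg.terminus_slack)
    record = ConsensusRecord(
        name=seed.id, residues=elong.residues,
        termini_resolved=True, terminus_5=t5, terminus_3=t3,
        tir=tir, autonomy=autonomy, copy_support=term.supporting_copies,
    )
    return FamilyResult(
        family_id=seed.id, consensus=record, terminus=term, tir=tir,
        autonomy=autonomy, census=census, calls=calls, alignments=alignments,
        copy_count_both_termini=len(both), n_copies_total=len(alignments),
        elongation_rounds=elong.rounds,
    )


def run_pipeline(
    genome: list[NamedSequence],
    seeds: list[NamedSequence],
    cfg: PipelineConfig | None = None,
    species_tag: str = "SIM",
) -> list[FamilyResult]:
    """Run every seed through family characterization and name the results."""
    cfg = cfg or PipelineConfig()
    results: list[FamilyResult] = []
    for seed in seeds:
        res = run_family(genome, seed, cfg)
        if res is not None:
            results.append(res)
    registry = NameRegistry()
    serial = 0
    for res in results:
        if res.autonomy == AUTONOMOUS:
            serial += 1
            res.name = name_family(serial, species_tag, res.autonomy, registry=registry)
        else:
            res.name = name_family(1, species_tag, res.autonomy, registry=registry)
        res.consensus.name = res.name
    return results


def family_records(results: list[FamilyResult], species_tag: str = "SIM") -> list[FamilyRecord]:
    """Convert pipeline results into report rows."""
    records = []
    auton_serial = 0
    orphan_serial = 0
    for res in results:
        if res.autonomy == AUTONOMOUS:
            auton_serial += 1
            serial = auton_serial
        else:
            orphan_serial += 1
            serial = orphan_serial
        records.append(FamilyRecord(
            name=res.name or res.family_id, species_tag=species_tag, serial=serial,
            consensus=res.consensus, autonomy=res.autonomy,
            copy_count_both_termini=res.copy_count_both_termini,
            census=res.census, tir=res.tir,
        ))
    return records
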