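"""End-to-end novel-MIRNA discovery over a set of libraries.

Glues the mapper, cluster caller, known-locus subtraction, hairpin
evaluation and precision filter into one call.  Reads are pooled across
libraries for mapping and cluster discovery; the precision criteria are
then assessed per library against the pooled alignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .discovery import (
    Alignment,
    CandidateLocus,
    call_clusters,
    intersect_known,
    map_reads,
)
from .hairpin import DuplexReport, MirnaLocus, check_duplex, derive_star, fold_hairpin
from .io_formats import Genome, GffFeature, ReadLibrary, revcomp
from .precision import PrecisionReport, apply_mirna_filters, precision_ratio

__all__ = ["DiscoveryResult", "pool_libraries", "candidate_to_locus", "discover_novel_mirnas"]

HAIRPIN_PAD = 15


@dataclass
class DiscoveryResult:
    candidates: list[CandidateLocus]
    known_overlapping: list[CandidateLocus]
    evaluated: dict[str, MirnaLocus]
    duplex_reports: dict[str, DuplexReport]
    precision_reports: dict[str, list[PrecisionReport]]
    accepted: list[str]
    rejected: dict[str, str] = field(default_factory=dict)


def pool_libraries(libraries: list[ReadLibrary]) -> ReadLibrary:
    """Union of unique reads with summed counts across libraries."""
    pooled: dict[str, int] = {}
    for lib in libraries:
        for seq, count in lib.unique_reads.items():
            pooled[seq] = pooled.get(seq, 0) + count
    return ReadLibrary("pooled", unique_reads=pooled)


def candidate_to_locus(
    genome: Genome,
    candidate: CandidateLocus,
    pad: int = HAIRPIN_PAD,
) -> MirnaLocus:
    """Build a foldable hairpin locus around a candidate cluster.

    The precursor window is the cluster span padded by ``pad`` nt on each
    side; the candidate mature is placed at the position of its
    most-supported alignment inside the window (hairpin-local coordinates
    follow the locus strand).
    """
    chrom_seq = genome.chroms[candidate.chrom]
    h_start = max(0, candidate.start - pad)
    h_end = min(len(chrom_seq), candidate.end + pad)
    hairpin = chrom_seq[h_start:h_end]
    if candidate.strand == "-":
        hairpin = revcomp(hairpin)

    mature = candidate.mature_candidate
    placements = [a for a in candidate.alignments if a.read == mature]
    if not placements:
        raise ValueError(f"candidate mature read not among alignments of {candidate.name}")
    a = placements[0]
    if candidate.strand == "+":
        local_start = a.start - h_start
    else:
        local_start = h_end - a.end
    return MirnaLocus(
        name=candidate.name,
        chrom=candidate.chrom,
        start=h_start,
        end=h_end,
        strand=candidate.strand,
        hairpin=hairpin,
        mature_start=local_start,
        mature_end=local_start + len(mature),
    )


def discover_novel_mirnas(
    genome: Genome,
    libraries: list[ReadLibrary],
    known_loci: list[GffFeature] | None = None,
    min_reads: int = 10,
    max_gap: int = 75,
    min_libraries: int = 4,
    stranded_overlap: bool = False,
    structures: dict[str, str] | None = None,
) -> DiscoveryResult:
    """Run mapping -> clustering -> subtraction -> structure -> precision.

    ``structures`` may supply precomputed dot-bracket structures keyed by
    candidate name (e.g. from an external folder); candidates without one
    are folded with the built-in folder.  Returns the full audit trail plus
    the accepted novel MIRNA names.
    """
    pooled = pool_libraries(libraries)
    alignments = map_reads(genome, pooled)
    candidates = call_clusters(alignments, pooled, min_reads=min_reads, max_gap=max_gap)
    known_overlapping, novel = intersect_known(
        candidates, known_loci or [], stranded=stranded_overlap
    )

    evaluated: dict[str, MirnaLocus] = {}
    duplex_reports: dict[str, DuplexReport] = {}
    precision_reports: dict[str, list[PrecisionReport]] = {}
    rejected: dict[str, str] = {}

    by_locus_alignments: dict[str, list[Alignment]] = {}
    for cand in novel:
        name = cand.name
        try:
            locus = candidate_to_locus(genome, cand)
        except ValueError as exc:
            rejected[name] = f"locus construction failed: {exc}"
            continue
        structure = (structures or {}).get(name) or fold_hairpin(locus.hairpin)
        locus.structure = structure
        try:
            s0, s1 = derive_star(
                locus.hairpin, structure, locus.mature_start, locus.mature_end
            )
        except ValueError as exc:
            rejected[name] = f"star derivation failed: {exc}"
            continue
        if s1 > locus.mature_start and locus.mature_end > s0:
            rejected[name] = "derived star overlaps the mature arm"
            continue
        locus.star_start, locus.star_end = s0, s1
        locus.mature_arm = "5p" if locus.mature_start < s0 else "3p"
        report = check_duplex(
            locus.hairpin,
            structure,
            (locus.mature_start, locus.mature_end),
            (s0, s1),
        )
        evaluated[name] = locus
        duplex_reports[name] = report
        by_locus_alignments[name] = cand.alignments

    for name, locus in evaluated.items():
        precision_reports[name] = [
            precision_ratio(locus, by_locus_alignments[name], lib) for lib in libraries
        ]

    accepted = apply_mirna_filters(
        precision_reports,
        {name: rep.passes for name, rep in duplex_reports.items()},
        {
            name: loc.mature_end - loc.mature_start
            for name, loc in evaluated.items()
        },
        min_libraries=min_libraries,
    )
    return DiscoveryResult(
        candidates=candidates,
        known_overlapping=known_overlapping,
        evaluated=evaluated,
        duplex_reports=duplex_reports,
        precision_reports=precision_reports,
        accepted=accepted,
        rejected=rejected,
    )
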