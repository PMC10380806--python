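"""Processing-precision scoring and the novel-MIRNA acceptance rules.

For each candidate locus and library, reads overlapping the hairpin on the
locus strand are classified as mature, star, 1-nt positional variant of
either arm, or other; the precision ratio is
(mature + star + variant) / total.  Acceptance of a candidate requires the
structural duplex check, a mature length of 20-24 nt, and a per-library
pass (>= 10 mature reads AND ratio >= the length-class threshold) in at
least ``min_libraries`` libraries.
"""

from __future__ import annotations

from dataclasses import dataclass

from .discovery import Alignment
from .hairpin import MirnaLocus
from .io_formats import ReadLibrary

__all__ = [
    "PrecisionReport",
    "precision_ratio",
    "classify_read",
    "length_class_threshold",
    "apply_mirna_filters",
    "MIN_MATURE_READS",
    "MIN_LIBRARIES",
]

MIN_MATURE_READS = 10
MIN_LIBRARIES = 4
RATIO_SHORT = 0.75  # mature length 20-22 nt
RATIO_LONG = 0.90  # mature length 23-24 nt


def length_class_threshold(mature_length: int) -> float | None:
    """Required precision ratio for a mature length, or None if out of range."""
    if 20 <= mature_length <= 22:
        return RATIO_SHORT
    if 23 <= mature_length <= 24:
        return RATIO_LONG
    return None


@dataclass
class PrecisionReport:
    """Per-locus per-library read-category tallies and the precision ratio."""

    locus_name: str
    library_id: str
    mature_reads: int
    star_reads: int
    variant_reads: int
    other_reads: int
    mature_length: int

    @property
    def total_reads(self) -> int:
        return self.mature_reads + self.star_reads + self.variant_reads + self.other_reads

    @property
    def ratio(self) -> float | None:
        if self.total_reads == 0:
            return None
        return (self.mature_reads + self.star_reads + self.variant_reads) / self.total_reads

    @property
    def passes(self) -> bool:
        threshold = length_class_threshold(self.mature_length)
        if threshold is None or self.ratio is None:
            return False
        return self.mature_reads >= MIN_MATURE_READS and self.ratio >= threshold


def classify_read(
    start: int,
    end: int,
    mature: tuple[int, int],
    star: tuple[int, int] | None,
) -> str:
    """Category of a read interval against arm reference intervals.

    Exact end matches give ``mature``/``star``; a read whose two ends are
    each within +/-1 nt of one arm's corresponding end is a ``variant``
    (ends are judged independently, so up to 9 end combinations per arm
    qualify); everything else is ``other``.
    """
    if (start, end) == mature:
        return "mature"
    if star is not None and (start, end) == star:
        return "star"
    refs = [mature] + ([star] if star is not None else [])
    for r0, r1 in refs:
        if abs(start - r0) <= 1 and abs(end - r1) <= 1:
            return "variant"
    return "other"


def precision_ratio(
    locus: MirnaLocus,
    alignments: list[Alignment],
    library: ReadLibrary,
) -> PrecisionReport:
    """Score one locus in one library.

    ``alignments`` may be the library's full alignment set; only placements
    overlapping the hairpin interval on the locus strand enter the
    denominator (antisense reads are excluded).  Counts are weighted by
    read multiplicity.
    """
    mature_g = locus.genomic_interval(locus.mature_start, locus.mature_end)
    star_g = (
        locus.genomic_interval(locus.star_start, locus.star_end)
        if locus.star_start >= 0
        else None
    )
    tallies = {"mature": 0, "star": 0, "variant": 0, "other": 0}
    for a in alignments:
        if a.chrom != locus.chrom or a.strand != locus.strand:
            continue
        if not (a.start < locus.end and locus.start < a.end):
            continue
        cat = classify_read(a.start, a.end, mature_g, star_g)
        tallies[cat] += library.unique_reads.get(a.read, 0)
    return PrecisionReport(
        locus_name=locus.name,
        library_id=library.library_id,
        mature_reads=tallies["mature"],
        star_reads=tallies["star"],
        variant_reads=tallies["variant"],
        other_reads=tallies["other"],
        mature_length=locus.mature_end - locus.mature_start,
    )


def apply_mirna_filters(
    reports_by_locus: dict[str, list[PrecisionReport]],
    duplex_passes: dict[str, bool],
    mature_lengths: dict[str, int],
    min_libraries: int = MIN_LIBRARIES,
    pooled_support: bool = False,
) -> list[str]:
    """Names of candidates accepted as novel MIRNAs.

    Accepted iff the duplex check passes, the mature length is 20-24 nt and
    the per-library criteria (>= 10 mature reads and ratio >= the
    length-class threshold) hold in at least ``min_libraries`` libraries.
    With ``pooled_support=True`` the 10-read support requirement is instead
    assessed on mature reads pooled across libraries, and the per-library
    pass only requires the ratio threshold.
    """
    accepted: list[str] = []
    for name in sorted(reports_by_locus):
        if not duplex_passes.get(name, False):
            continue
        if length_class_threshold(mature_lengths[name]) is None:
            continue
        reports = reports_by_locus[name]
        if pooled_support:
            if sum(r.mature_reads for r in reports) < MIN_MATURE_READS:
                continue
            threshold = length_class_threshold(mature_lengths[name])
            n_pass = sum(
                1
                for r in reports
                if r.ratio is not None and r.ratio >= threshold
            )
        else:
            n_pass = sum(1 for r in reports if r.passes)
        if n_pass >= min_libraries:
            accepted.append(name)
    return accepted
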