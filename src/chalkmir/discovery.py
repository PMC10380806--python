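"""Read mapping, cluster calling and known-locus subtraction.

The mapper is an exact/1-mismatch ungapped aligner over both strands built
on a seed-and-extend scan; it is exhaustive (guaranteed to report every
best-stratum hit) on the small genomes this pipeline targets.  The cluster
caller is a deterministic gap-merge stand-in for an external sRNA cluster
finder — candidates can equally be supplied as GFF3.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field

from .io_formats import Genome, GffFeature, ReadLibrary, revcomp

__all__ = [
    "Alignment",
    "CandidateLocus",
    "map_reads",
    "call_clusters",
    "intersect_known",
]

DEFAULT_MIN_READS = 10
DEFAULT_MAX_GAP = 75
MIN_READ_LEN = 18
MAX_READ_LEN = 30


@dataclass(frozen=True)
class Alignment:
    """Ungapped placement of a read; coordinates are forward-strand 0-based.

    ``read`` is always the read sequence as sequenced (for minus-strand
    hits the genome carries its reverse complement at [start, start+len)).
    """

    read: str
    chrom: str
    start: int
    strand: str
    n_mismatches: int

    @property
    def end(self) -> int:
        return self.start + len(self.read)


@dataclass
class CandidateLocus:
    chrom: str
    start: int
    end: int
    strand: str
    alignments: list[Alignment] = field(default_factory=list)
    total_count: float = 0.0
    mature_candidate: str = ""

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"


def _hamming_le(a: str, b: str, cap: int) -> int:
    """Mismatch count between equal-length strings, or cap+1 if exceeded."""
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > cap:
                return mm
    return mm


class _SeedIndex:
    """k-mer position index over the forward strand of every chromosome."""

    def __init__(self, genome: Genome):
        self.genome = genome
        self._indices: dict[int, dict[str, list[tuple[str, int]]]] = {}

    def index_for(self, k: int) -> dict[str, list[tuple[str, int]]]:
        if k not in self._indices:
            idx: dict[str, list[tuple[str, int]]] = defaultdict(list)
            for chrom, seq in self.genome.chroms.items():
                for i in range(len(seq) - k + 1):
                    idx[seq[i : i + k]].append((chrom, i))
            self._indices[k] = idx
        return self._indices[k]


def _candidate_starts(index: _SeedIndex, query: str) -> set[tuple[str, int]]:
    """Offsets where ``query`` may align with <= 1 mismatch (pigeonhole).

    Two non-overlapping half-length seeds: a single mismatch can break at
    most one of them, so every <=1-mm placement is seeded.
    """
    L = len(query)
    k = L // 2
    idx = index.index_for(k)
    starts: set[tuple[str, int]] = set()
    for seed_off in (0, k):
        seed = query[seed_off : seed_off + k]
        for chrom, pos in idx.get(seed, ()):
            start = pos - seed_off
            if start >= 0 and start + L <= len(index.genome.chroms[chrom]):
                starts.add((chrom, start))
    return starts


def map_reads(
    genome: Genome,
    library: ReadLibrary,
    max_mismatch: int = 1,
    min_len: int = MIN_READ_LEN,
    max_len: int = MAX_READ_LEN,
    _index: _SeedIndex | None = None,
) -> list[Alignment]:
    """Align every unique read to both genome strands, ungapped.

    At most ``max_mismatch`` (0 or 1) substitutions are tolerated; for each
    read only the best mismatch stratum is reported (exact hits suppress
    1-mismatch hits), but all loci within that stratum are kept.
    Minus-strand hits are recorded against the forward coordinates of their
    span.  Reads outside [min_len, max_len] are skipped.
    """
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    if genome.total_length() == 0:
        raise ValueError("empty genome")
    index = _index if _index is not None else _SeedIndex(genome)
    alignments: list[Alignment] = []
    for read in library.unique_reads:
        L = len(read)
        if not min_len <= L <= max_len:
            continue
        hits: list[Alignment] = []
        best = max_mismatch + 1
        for strand, query in (("+", read), ("-", revcomp(read))):
            for chrom, start in sorted(_candidate_starts(index, query)):
                mm = _hamming_le(
                    query, genome.chroms[chrom][start : start + L], max_mismatch
                )
                if mm <= max_mismatch:
                    hits.append(Alignment(read, chrom, start, strand, mm))
                    best = min(best, mm)
        alignments.extend(h for h in hits if h.n_mismatches == best)
    alignments.sort(key=lambda a: (a.chrom, a.start, a.strand, a.read))
    return alignments


def call_clusters(
    alignments: list[Alignment],
    library: ReadLibrary,
    min_reads: int = DEFAULT_MIN_READS,
    max_gap: int = DEFAULT_MAX_GAP,
    fractional: bool = False,
) -> list[CandidateLocus]:
    """Merge same-strand alignments separated by <= max_gap into loci.

    Each alignment contributes the full multiplicity of its read to its
    locus (documented double-counting for multi-mapped reads); with
    ``fractional=True`` a read's count is split evenly across its
    placements instead.  Loci below ``min_reads`` total are dropped.  The
    candidate mature is the most abundant distinct read in the locus (ties
    break to the lexicographically smaller sequence).
    """
    placements: dict[str, int] = defaultdict(int)
    for a in alignments:
        placements[a.read] += 1

    by_group: dict[tuple[str, str], list[Alignment]] = defaultdict(list)
    for a in alignments:
        by_group[(a.chrom, a.strand)].append(a)

    loci: list[CandidateLocus] = []
    for (chrom, strand), group in sorted(by_group.items()):
        group.sort(key=lambda a: (a.start, a.end, a.read))
        current: list[Alignment] = []
        cur_end = -1
        for a in group + [None]:  # type: ignore[list-item]
            if a is not None and (not current or a.start - cur_end <= max_gap):
                current.append(a)
                cur_end = max(cur_end, a.end)
                continue
            if current:
                loci.extend(
                    _finalize_cluster(chrom, strand, current, library, placements, fractional)
                )
            if a is not None:
                current = [a]
                cur_end = a.end
            else:
                current = []
    kept = [l for l in loci if l.total_count >= min_reads]
    kept.sort(key=lambda l: (l.chrom, l.start, l.strand))
    return kept


def _finalize_cluster(
    chrom: str,
    strand: str,
    members: list[Alignment],
    library: ReadLibrary,
    placements: dict[str, int],
    fractional: bool,
) -> list[CandidateLocus]:
    total = 0.0
    per_read: dict[str, float] = defaultdict(float)
    for a in members:
        count = library.unique_reads.get(a.read, 0)
        w = count / placements[a.read] if fractional else float(count)
        total += w
        per_read[a.read] += w
    mature = min(per_read, key=lambda s: (-per_read[s], s)) if per_read else ""
    locus = CandidateLocus(
        chrom=chrom,
        start=min(a.start for a in members),
        end=max(a.end for a in members),
        strand=strand,
        alignments=members,
        total_count=total,
        mature_candidate=mature,
    )
    return [locus]


def intersect_known(
    candidates: list[CandidateLocus],
    known: list[GffFeature],
    stranded: bool = False,
) -> tuple[list[CandidateLocus], list[CandidateLocus]]:
    """Partition candidates into (known-overlapping, novel).

    A candidate overlapping any known locus by >= 1 bp counts as known;
    by default overlap on either strand qualifies (``stranded=True``
    restricts to same-strand overlap).  Chromosome names absent from the
    known annotation trigger a warning and are treated as non-overlapping.
    """
    known_chroms = {f.chrom for f in known}
    by_chrom: dict[str, list[GffFeature]] = defaultdict(list)
    for f in known:
        by_chrom[f.chrom].append(f)

    overlapping: list[CandidateLocus] = []
    novel: list[CandidateLocus] = []
    warned: set[str] = set()
    for cand in candidates:
        if known and cand.chrom not in known_chroms and cand.chrom not in warned:
            warnings.warn(
                f"chromosome {cand.chrom!r} absent from known annotation; "
                "treating its candidates as non-overlapping",
                stacklevel=2,
            )
            warned.add(cand.chrom)
        hit = any(
            cand.start < f.end
            and f.start < cand.end
            and (not stranded or cand.strand == f.strand)
            for f in by_chrom.get(cand.chrom, ())
        )
        (overlapping if hit else novel).append(cand)
    return overlapping, novel
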