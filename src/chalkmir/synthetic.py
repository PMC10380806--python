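"""Synthetic genomes and multi-genotype sRNA libraries with known truth.

The simulator emulates the structure of a multi-genotype heat-stress small
RNA experiment: a configurable genotype x condition x replicate grid of
libraries, MIRNA loci diced with tunable positional noise, 24-nt-biased
background siRNA clusters, and negative-binomial counts with per-locus
treatment fold changes.  Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .hairpin import MirnaLocus, build_perfect_hairpin, check_duplex, derive_star, fold_hairpin
from .io_formats import Genome, GffFeature, ReadLibrary, revcomp, write_fasta, write_gff3

__all__ = [
    "SimDesign",
    "TruthSet",
    "BackgroundCluster",
    "make_genome",
    "plant_mirna_loci",
    "simulate_libraries",
    "write_library_fastq",
    "write_truth",
]


class GenerationError(RuntimeError):
    """Raised when a genome cannot accommodate the requested loci."""


@dataclass
class SimDesign:
    """Parameters of one simulated experiment.

    ``dicing_precision`` is the probability that a locus-derived read is
    exactly the mature or star sequence; otherwise each read end is shifted
    independently (1-nt shifts dominate, 2-nt shifts at one tenth the
    rate).  ``fold_changes`` maps locus name -> multiplicative treatment
    effect on the mean count.
    """

    genotypes: list[str] = field(default_factory=lambda: ["G1", "G2"])
    conditions: tuple[str, str] = ("CDT", "HDT")
    replicates_per_cell: int = 3
    n_true_loci: int = 10
    n_background_clusters: int = 5
    mature_length_weights: dict[int, float] = field(
        default_factory=lambda: {21: 0.7, 22: 0.15, 24: 0.15}
    )
    dicing_precision: float = 0.95
    arm_bias: float = 0.8
    mean_locus_count: float = 200.0
    dispersion: float = 0.1
    fold_changes: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates_per_cell < 1:
            raise ValueError("replicates_per_cell must be >= 1")
        if not 0.0 <= self.dicing_precision <= 1.0:
            raise ValueError("dicing_precision must be in [0, 1]")
        if not 0.0 <= self.arm_bias <= 1.0:
            raise ValueError("arm_bias must be in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.mature_length_weights:
            total = sum(self.mature_length_weights.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError("mature_length_weights must sum to 1")
            for length in self.mature_length_weights:
                if not 20 <= length <= 24:
                    raise ValueError("mature lengths must be within 20-24 nt")

    @property
    def library_keys(self) -> list[tuple[str, str, int]]:
        """(genotype, condition, replicate) in deterministic order."""
        return [
            (g, c, r)
            for g in self.genotypes
            for c in self.conditions
            for r in range(1, self.replicates_per_cell + 1)
        ]

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["conditions"] = list(self.conditions)
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimDesign":
        d = json.loads(Path(path).read_text())
        d["conditions"] = tuple(d.get("conditions", ("CDT", "HDT")))
        if "mature_length_weights" in d:
            d["mature_length_weights"] = {
                int(k): float(v) for k, v in d["mature_length_weights"].items()
            }
        return cls(**d)


@dataclass
class BackgroundCluster:
    """A siRNA-like interval emitting 24-nt-biased tiled reads."""

    name: str
    chrom: str
    start: int
    end: int
    strand: str


@dataclass
class TruthSet:
    """Planted loci and background intervals with generation provenance."""

    loci: list[MirnaLocus] = field(default_factory=list)
    background: list[BackgroundCluster] = field(default_factory=list)
    fold_changes: dict[str, float] = field(default_factory=dict)


def make_genome(
    n_chrom: int, chrom_length: int, gc_fraction: float = 0.43, seed: int = 0
) -> Genome:
    """Random genome with the requested GC content (deterministic per seed)."""
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if chrom_length < 0:
        raise ValueError("chrom_length must be >= 0")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p_at = (1.0 - gc_fraction) / 2.0
    p_gc = gc_fraction / 2.0
    bases = np.array(["A", "T", "G", "C"])
    chroms = {}
    for i in range(n_chrom):
        draw = rng.choice(bases, size=chrom_length, p=[p_at, p_at, p_gc, p_gc])
        chroms[f"chr{i + 1}"] = "".join(draw)
    return Genome(chroms)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(np.array(["A", "C", "G", "T"]), size=length))


def _make_planted_locus(rng: np.random.Generator, name: str, mature_len: int) -> MirnaLocus:
    """Build one hairpin that provably satisfies the duplex criteria.

    Hairpins are perfect-stem constructs; each is folded with the built-in
    folder and re-drawn (bounded retries) if the fold ever failed the
    duplex check, closing the loop with discovery.
    """
    for _attempt in range(50):
        mature = _random_seq(rng, mature_len)
        hairpin, m0, m1 = build_perfect_hairpin(mature)
        structure = fold_hairpin(hairpin)
        try:
            s0, s1 = derive_star(hairpin, structure, m0, m1)
        except ValueError:
            continue
        report = check_duplex(hairpin, structure, (m0, m1), (s0, s1))
        if report.passes and not (m1 > s0 and s1 > m0):
            return MirnaLocus(
                name=name,
                chrom="",
                start=-1,
                end=-1,
                strand="+",
                hairpin=hairpin,
                structure=structure,
                mature_start=m0,
                mature_end=m1,
                star_start=s0,
                star_end=s1,
                mature_arm="5p",
            )
    raise GenerationError(f"could not construct a passing hairpin for {name}")


def plant_mirna_loci(genome: Genome, design: SimDesign) -> tuple[Genome, TruthSet]:
    """Embed hairpin loci and background clusters into a genome.

    Loci are placed non-overlapping with >= 200 bp spacing; strand is
    random (minus-strand loci store the reverse complement in the genome).
    Returns the modified genome and the truth set.
    """
    rng = np.random.default_rng(design.seed + 1)
    truth = TruthSet(fold_changes=dict(design.fold_changes))
    if design.n_true_loci == 0 and design.n_background_clusters == 0:
        return genome, truth

    lengths = sorted(design.mature_length_weights)
    weights = np.array([design.mature_length_weights[k] for k in lengths], dtype=float)

    chrom_names = sorted(genome.chroms)
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    chroms = dict(genome.chroms)

    def _place(span: int, margin: int = 200) -> tuple[str, int]:
        for _try in range(500):
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            limit = len(chroms[chrom]) - span
            if limit <= 0:
                continue
            pos = int(rng.integers(0, limit))
            if all(
                pos >= e + margin or pos + span <= s - margin for s, e in occupied[chrom]
            ):
                occupied[chrom].append((pos, pos + span))
                return chrom, pos
        raise GenerationError("insufficient genome space for non-overlapping loci")

    for i in range(design.n_true_loci):
        mature_len = int(rng.choice(lengths, p=weights))
        locus = _make_planted_locus(rng, f"locus{i + 1:03d}", mature_len)
        strand = "+" if rng.random() < 0.5 else "-"
        span = len(locus.hairpin)
        chrom, pos = _place(span)
        insert = locus.hairpin if strand == "+" else revcomp(locus.hairpin)
        chroms[chrom] = chroms[chrom][:pos] + insert + chroms[chrom][pos + span :]
        locus.chrom = chrom
        locus.start = pos
        locus.end = pos + span
        locus.strand = strand
        truth.loci.append(locus)

    for i in range(design.n_background_clusters):
        span = int(rng.integers(120, 200))
        chrom, pos = _place(span)
        strand = "+" if rng.random() < 0.5 else "-"
        truth.background.append(
            BackgroundCluster(f"bg{i + 1:03d}", chrom, pos, pos + span, strand)
        )

    return Genome(chroms), truth


# read-end shift distribution used when dicing is imprecise: 1-nt shifts
# dominate, 2-nt shifts at one tenth their rate, remainder unshifted
_SHIFTS = np.array([-2, -1, 0, 1, 2])
_W1 = 0.35
_SHIFT_P = np.array([_W1 / 10, _W1, 1.0 - 2.2 * _W1, _W1, _W1 / 10])


def _nb_draw(rng: np.random.Generator, mean: float, phi: float) -> int:
    """NB draw parameterised by mean and dispersion (var = mu + phi*mu^2)."""
    if mean <= 0:
        return 0
    if phi <= 0:
        return int(rng.poisson(mean))
    r = 1.0 / phi
    p = r / (r + mean)
    return int(rng.negative_binomial(r, p))


def _diced_read(
    rng: np.random.Generator, locus: MirnaLocus, precision: float, arm_bias: float
) -> tuple[str, str]:
    """One locus read: (sequence, category in {mature, star, variant, other})."""
    use_mature = rng.random() < arm_bias
    a, b = (
        (locus.mature_start, locus.mature_end)
        if use_mature
        else (locus.star_start, locus.star_end)
    )
    base_cat = "mature" if use_mature else "star"
    if rng.random() < precision:
        return locus.hairpin[a:b], base_cat
    d5, d3 = rng.choice(_SHIFTS, size=2, p=_SHIFT_P)
    s, e = a + int(d5), b + int(d3)
    s = max(0, s)
    e = min(len(locus.hairpin), e)
    if e - s < 15:
        return locus.hairpin[a:b], base_cat
    if (s, e) == (a, b):
        cat = base_cat
    elif abs(s - a) <= 1 and abs(e - b) <= 1:
        cat = "variant"
    else:
        cat = "other"
    return locus.hairpin[s:e], cat


_BG_LENGTHS = np.array([20, 21, 22, 23, 24, 25])
_BG_P = np.array([0.04, 0.08, 0.08, 0.10, 0.60, 0.10])


def simulate_libraries(
    truth: TruthSet, design: SimDesign, genome: Genome
) -> list[ReadLibrary]:
    """Simulate one ReadLibrary per (genotype, condition, replicate) cell.

    Per locus per library the read count is NB(mean x size-factor x fold,
    dispersion); library size factors are log-normal (sigma = 0.2).
    Background clusters emit reads tiled uniformly over their interval with
    a 24-nt length mode.  Read provenance is recorded per library in
    ``provenance`` keyed by (source name, category).
    """
    rng = np.random.default_rng(design.seed + 2)
    control, treatment = design.conditions
    libraries: list[ReadLibrary] = []
    for genotype, condition, replicate in design.library_keys:
        lib_id = f"{genotype}_{condition}_r{replicate}"
        size_factor = float(np.exp(rng.normal(0.0, 0.2)))
        unique: dict[str, int] = {}
        provenance: dict[tuple[str, str], int] = {}

        for locus in truth.loci:
            fold = truth.fold_changes.get(locus.name, 1.0) if condition == treatment else 1.0
            mean = design.mean_locus_count * size_factor * fold
            n_reads = _nb_draw(rng, mean, design.dispersion)
            for _ in range(n_reads):
                seq, cat = _diced_read(
                    rng, locus, design.dicing_precision, design.arm_bias
                )
                unique[seq] = unique.get(seq, 0) + 1
                key = (locus.name, cat)
                provenance[key] = provenance.get(key, 0) + 1

        for cluster in truth.background:
            mean = design.mean_locus_count * size_factor
            n_reads = _nb_draw(rng, mean, design.dispersion)
            chrom_seq = genome.chroms[cluster.chrom]
            for _ in range(n_reads):
                length = int(rng.choice(_BG_LENGTHS, p=_BG_P))
                hi = cluster.end - length
                if hi <= cluster.start:
                    continue
                pos = int(rng.integers(cluster.start, hi))
                seq = chrom_seq[pos : pos + length]
                if cluster.strand == "-":
                    seq = revcomp(seq)
                unique[seq] = unique.get(seq, 0) + 1
                key = (cluster.name, "background")
                provenance[key] = provenance.get(key, 0) + 1

        lib = ReadLibrary(lib_id, genotype, condition, replicate, unique)
        lib.provenance = provenance  # type: ignore[attr-defined]
        lib.size_factor = size_factor  # type: ignore[attr-defined]
        libraries.append(lib)
    return libraries


def write_library_fastq(library: ReadLibrary, path: str | Path) -> int:
    """Write a collapsed library as FASTQ (constant 'I' qualities).

    Reads are expanded back to full multiplicity in deterministic
    (sequence-sorted) order; returns the number of records written.
    """
    n = 0
    with open(path, "wt") as fh:
        for seq in sorted(library.unique_reads):
            count = library.unique_reads[seq]
            for k in range(count):
                n += 1
                fh.write(f"@{library.library_id}.{n}\n{seq}\n+\n{'I' * len(seq)}\n")
    return n


def write_truth(truth: TruthSet, out_dir: str | Path) -> None:
    """Write truth loci (GFF3 + hairpin/mature FASTA) and fold changes (TSV)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    feats = []
    for locus in truth.loci:
        feats.append(
            GffFeature(
                chrom=locus.chrom,
                start=locus.start,
                end=locus.end,
                strand=locus.strand,
                feature_type="miRNA_primary_transcript",
                attributes={"ID": locus.name, "Name": locus.name},
            )
        )
    for bg in truth.background:
        feats.append(
            GffFeature(
                chrom=bg.chrom,
                start=bg.start,
                end=bg.end,
                strand=bg.strand,
                feature_type="siRNA_cluster",
                attributes={"ID": bg.name, "Name": bg.name},
            )
        )
    write_gff3(out / "truth_loci.gff3", feats)
    write_fasta(out / "truth_hairpins.fa", {l.name: l.hairpin for l in truth.loci})
    write_fasta(
        out / "truth_mature.fa",
        {
            **{f"{l.name}-5p" if l.mature_arm == "5p" else f"{l.name}-3p": l.mature_seq for l in truth.loci},
            **{f"{l.name}-3p" if l.mature_arm == "5p" else f"{l.name}-5p": l.star_seq for l in truth.loci},
        },
    )
    with open(out / "truth_fold_changes.tsv", "wt") as fh:
        fh.write("locus\tfold_change\n")
        for name in sorted(truth.fold_changes):
            fh.write(f"{name}\t{truth.fold_changes[name]}\n")
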