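"""Readers/writers for the plain-text formats the pipeline touches.

Coordinate convention: everything in memory is 0-based half-open.
GFF3 on disk is 1-based inclusive; the conversion happens only at the
file boundary (:func:`read_gff3` / :func:`write_gff3`).

Sequences are normalised to the DNA alphabet internally (``U`` -> ``T``,
uppercase).  Mature miRNA sequences destined for reports can be rendered
back to RNA with :func:`to_rna`.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "Genome",
    "GffFeature",
    "ReadLibrary",
    "collapse_reads",
    "length_distribution",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_dbn",
    "write_dbn",
    "normalize_seq",
    "to_rna",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def normalize_seq(seq: str) -> str:
    """Uppercase and convert RNA to DNA alphabet (U -> T)."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """Render a DNA-alphabet sequence in RNA alphabet (T -> U)."""
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    """Reverse complement over {A, C, G, T, N}."""
    return seq.translate(_COMPLEMENT)[::-1]


def _open_text(path: str | Path):
    """Open a possibly gzip-compressed text file for reading."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------


@dataclass
class Genome:
    """A named collection of chromosome sequences (DNA alphabet)."""

    chroms: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.chroms)

    def total_length(self) -> int:
        return sum(len(s) for s in self.chroms.values())

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of ``chrom[start:end)`` (0-based half-open)."""
        return self.chroms[chrom][start:end]


def read_fasta(path: str | Path) -> Genome:
    """Load a FASTA file into a :class:`Genome` (sequences normalised)."""
    chroms: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            chroms[rec.id] = normalize_seq(str(rec.seq))
    return Genome(chroms)


def write_fasta(path: str | Path, records: Mapping[str, str], width: int = 70) -> None:
    with open(path, "wt") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Read libraries
# ---------------------------------------------------------------------------


@dataclass
class ReadLibrary:
    """One sample's collapsed unique reads.

    ``unique_reads`` maps each distinct sequence (DNA alphabet) to its
    multiplicity; ``clean_size`` is the total number of clean reads and is
    the CPM denominator downstream.
    """

    library_id: str
    genotype: str = ""
    condition: str = ""
    replicate: int = 0
    unique_reads: dict[str, int] = field(default_factory=dict)

    @property
    def clean_size(self) -> int:
        return sum(self.unique_reads.values())

    @property
    def n_unique(self) -> int:
        return len(self.unique_reads)


class FastqParseError(ValueError):
    """Malformed FASTQ record; carries the 1-based record index."""

    def __init__(self, record_index: int, message: str):
        self.record_index = record_index
        super().__init__(f"malformed FASTQ record #{record_index}: {message}")


def collapse_reads(
    fastq_path: str | Path,
    library_id: str | None = None,
    genotype: str = "",
    condition: str = "",
    replicate: int = 0,
) -> ReadLibrary:
    """Pool identical reads of an adapter-trimmed FASTQ into unique reads.

    Each distinct sequence maps to its multiplicity; ``clean_size`` equals
    the number of input reads.  U is converted to T.
    """
    if library_id is None:
        library_id = Path(fastq_path).stem.replace(".fastq", "").replace(".fq", "")
    unique: dict[str, int] = {}
    n = 0
    try:
        with _open_text(fastq_path) as fh:
            for _title, seq, qual in FastqGeneralIterator(fh):
                n += 1
                if len(seq) != len(qual):
                    raise FastqParseError(n, "sequence/quality length mismatch")
                s = normalize_seq(seq)
                unique[s] = unique.get(s, 0) + 1
    except FastqParseError:
        raise
    except ValueError as exc:  # biopython reports structural problems as ValueError
        raise FastqParseError(n + 1, str(exc)) from exc
    return ReadLibrary(library_id, genotype, condition, replicate, unique)


def length_distribution(library: ReadLibrary) -> dict[int, tuple[int, int]]:
    """Histogram length -> (total read count, unique read count)."""
    hist: dict[int, list[int]] = {}
    for seq, count in library.unique_reads.items():
        entry = hist.setdefault(len(seq), [0, 0])
        entry[0] += count
        entry[1] += 1
    return {length: (t, u) for length, (t, u) in sorted(hist.items())}


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


@dataclass
class GffFeature:
    """One GFF3 feature with internal 0-based half-open coordinates."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    strand: str = "+"
    feature_type: str = "miRNA_primary_transcript"
    source: str = "chalkmir"
    score: str = "."
    attributes: dict[str, str] = field(default_factory=dict)

    @property
    def name(self) -> str:
        return self.attributes.get("Name", self.attributes.get("ID", ""))

    def overlaps(self, other: "GffFeature", stranded: bool = False) -> bool:
        """True if the intervals share >= 1 bp on the same chromosome."""
        if self.chrom != other.chrom:
            return False
        if stranded and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end


def read_gff3(path: str | Path) -> list[GffFeature]:
    """Parse a GFF3 file; 1-based inclusive on disk -> 0-based half-open."""
    feats: list[GffFeature] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(parts)}")
            chrom, source, ftype, start, end, score, strand, _phase, attrs = parts
            attributes: dict[str, str] = {}
            for item in attrs.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attributes[k.strip()] = v.strip()
            feats.append(
                GffFeature(
                    chrom=chrom,
                    start=int(start) - 1,
                    end=int(end),
                    strand=strand,
                    feature_type=ftype,
                    source=source,
                    score=score,
                    attributes=attributes,
                )
            )
    return feats


def write_gff3(path: str | Path, features: Iterable[GffFeature]) -> None:
    """Write features as GFF3 (converting back to 1-based inclusive)."""
    with open(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(f"{k}={v}" for k, v in f.attributes.items()) or "."
            fh.write(
                "\t".join(
                    [
                        f.chrom,
                        f.source,
                        f.feature_type,
                        str(f.start + 1),
                        str(f.end),
                        f.score,
                        f.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Vienna dot-bracket (.dbn)
# ---------------------------------------------------------------------------


def _check_structure(seq: str, structure: str, name: str = "") -> None:
    if len(seq) != len(structure):
        raise ValueError(
            f"structure length {len(structure)} != sequence length {len(seq)}"
            + (f" for {name}" if name else "")
        )
    depth = 0
    for ch in structure:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ValueError(f"unbalanced brackets in structure{' for ' + name if name else ''}")
        elif ch != ".":
            raise ValueError(f"invalid structure character {ch!r}")
    if depth != 0:
        raise ValueError(f"unbalanced brackets in structure{' for ' + name if name else ''}")


def read_dbn(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read a dot-bracket file: blocks of ``>name`` / sequence / structure.

    Returns name -> (sequence, structure); validates lengths and bracket
    balance.
    """
    out: dict[str, tuple[str, str]] = {}
    with _open_text(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise ValueError(f"expected '>' header at line {i + 1} of {path}")
        name = lines[i][1:].split()[0]
        if i + 2 >= len(lines):
            raise ValueError(f"truncated dot-bracket block for {name}")
        seq = normalize_seq(lines[i + 1])
        structure = lines[i + 2].split()[0]  # tolerate trailing energy annotation
        _check_structure(seq, structure, name)
        out[name] = (seq, structure)
        i += 3
    return out


def write_dbn(path: str | Path, records: Mapping[str, tuple[str, str]]) -> None:
    with open(path, "wt") as fh:
        for name, (seq, structure) in records.items():
            _check_structure(seq, structure, name)
            fh.write(f">{name}\n{seq}\n{structure}\n")


def iter_fastq_records(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (title, sequence) for every FASTQ record (sequence normalised)."""
    with _open_text(path) as fh:
        for title, seq, _qual in FastqGeneralIterator(fh):
            yield title, normalize_seq(seq)
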