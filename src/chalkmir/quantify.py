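"""Catalog construction, best-hit read attribution and CPM matrices.

A read is attributed to at most one catalog entry.  An entry is eligible
if the read aligns to it ungapped with at most 1 substitution and at most a
1-nt extension or truncation at each end; among eligible entries the best
hit minimises (mismatches, total end offset) lexicographically, with exact
ties broken by entry name.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hairpin import MirnaLocus, derive_star, fold_hairpin
from .io_formats import ReadLibrary, normalize_seq

__all__ = [
    "Catalog",
    "build_catalog",
    "score_read_vs_entry",
    "attribute_reads",
    "build_count_matrix",
    "cpm_normalize",
]

MIN_ENTRY_LEN = 18
MAX_ENTRY_LEN = 26


@dataclass
class Catalog:
    """Mature + star sequence catalog with redundancy merged.

    ``entries`` maps a (possibly combined) name to its sequence; names of
    identical sequences are joined with ``/`` in sorted order.
    """

    entries: dict[str, str] = field(default_factory=dict)

    @property
    def names(self) -> list[str]:
        return sorted(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def build_catalog(
    known: dict[str, str] | None = None,
    novel_loci: list[MirnaLocus] | None = None,
    hairpins: dict[str, str] | None = None,
) -> Catalog:
    """Assemble the quantification catalog.

    ``known`` maps name -> mature/star sequence (miRBase-style, 5p and 3p
    entries).  Known matures named ``<base>-5p``/``<base>-3p`` whose
    partner arm is absent get a star derived from ``hairpins[<base>]``
    (folded internally) with 2-nt 3' overhangs; entries without a hairpin
    are kept mature-only with a warning.  Novel loci contribute both arms
    directly.  Identical sequences are merged under a combined name.
    """
    raw: dict[str, str] = {}
    known = dict(known or {})
    for name, seq in known.items():
        raw[name] = normalize_seq(seq)

    # complete missing stars from fold-back structures
    bases: dict[str, set[str]] = {}
    for name in known:
        if name.endswith(("-5p", "-3p")):
            bases.setdefault(name[:-3], set()).add(name[-2:])
    for base, arms in sorted(bases.items()):
        if len(arms) == 2:
            continue
        present = next(iter(arms))
        missing = "3p" if present == "5p" else "5p"
        hairpin = (hairpins or {}).get(base)
        if hairpin is None:
            warnings.warn(
                f"no hairpin available to derive {base}-{missing}; keeping mature-only",
                stacklevel=2,
            )
            continue
        hairpin = normalize_seq(hairpin)
        mature = raw[f"{base}-{present}"]
        idx = hairpin.find(mature)
        if idx < 0:
            warnings.warn(
                f"mature {base}-{present} not found in its hairpin; keeping mature-only",
                stacklevel=2,
            )
            continue
        structure = fold_hairpin(hairpin)
        try:
            s0, s1 = derive_star(hairpin, structure, idx, idx + len(mature))
        except ValueError as exc:
            warnings.warn(f"star derivation failed for {base}: {exc}", stacklevel=2)
            continue
        raw[f"{base}-{missing}"] = hairpin[s0:s1]

    for locus in novel_loci or []:
        arm_m = locus.mature_arm
        arm_s = "3p" if arm_m == "5p" else "5p"
        raw[f"{locus.name}-{arm_m}"] = normalize_seq(locus.mature_seq)
        if locus.star_start >= 0:
            raw[f"{locus.name}-{arm_s}"] = normalize_seq(locus.star_seq)

    # merge redundant sequences under combined names
    by_seq: dict[str, list[str]] = {}
    for name in sorted(raw):
        by_seq.setdefault(raw[name], []).append(name)
    entries = {"/".join(names): seq for seq, names in by_seq.items()}
    for name, seq in entries.items():
        if not MIN_ENTRY_LEN <= len(seq) <= MAX_ENTRY_LEN:
            warnings.warn(
                f"catalog entry {name} length {len(seq)} outside "
                f"[{MIN_ENTRY_LEN},{MAX_ENTRY_LEN}]",
                stacklevel=2,
            )
    return Catalog(entries)


def score_read_vs_entry(
    read: str, entry: str, single_end_offset: bool = False
) -> tuple[int, int] | None:
    """Best (mismatches, total end offset) of read vs entry, or None.

    Alignments are ungapped; the read may extend or be truncated by at most
    1 nt at the 5' and at the 3' end (independently by default; with
    ``single_end_offset`` only one end may be offset).  Extended positions
    fall outside the entry and are not compared; at most 1 substitution is
    allowed in the overlap.
    """
    best: tuple[int, int] | None = None
    for d5 in (-1, 0, 1):  # read start relative to entry start (+1 = truncation)
        for d3 in (-1, 0, 1):  # read end relative to entry end (+1 = extension)
            if len(read) != len(entry) - d5 + d3:
                continue
            if single_end_offset and d5 != 0 and d3 != 0:
                continue
            # overlap in entry coordinates
            lo = max(0, d5)
            hi = min(len(entry), len(entry) + d3)
            if hi - lo < MIN_ENTRY_LEN - 2:
                continue
            mm = 0
            for pos in range(lo, hi):
                if entry[pos] != read[pos - d5]:
                    mm += 1
                    if mm > 1:
                        break
            if mm > 1:
                continue
            cand = (mm, abs(d5) + abs(d3))
            if best is None or cand < best:
                best = cand
    return best


def attribute_reads(
    library: ReadLibrary,
    catalog: Catalog,
    single_end_offset: bool = False,
) -> pd.Series:
    """Attribute each unique read to its single best catalog entry.

    Returns a count Series indexed by catalog entry name.  The full
    multiplicity of a read goes to the entry minimising (mismatches, total
    end offset); exact score ties break to the lexicographically smallest
    entry name.  Reads failing the rules against every entry stay
    unassigned.
    """
    by_seq = {seq: name for name, seq in catalog.entries.items()}
    names = catalog.names
    counts = {name: 0 for name in names}
    for read, count in library.unique_reads.items():
        exact = by_seq.get(read)
        if exact is not None:
            counts[exact] += count
            continue
        best_key: tuple[int, int, str] | None = None
        for name in names:
            score = score_read_vs_entry(read, catalog.entries[name], single_end_offset)
            if score is None:
                continue
            key = (*score, name)
            if best_key is None or key < best_key:
                best_key = key
        if best_key is not None:
            counts[best_key[2]] += count
    return pd.Series(counts, name=library.library_id).sort_index()


def build_count_matrix(
    libraries: list[ReadLibrary],
    catalog: Catalog,
    single_end_offset: bool = False,
) -> tuple[pd.DataFrame, pd.Series]:
    """Raw count matrix (entries x libraries) and clean-size vector."""
    columns = {
        lib.library_id: attribute_reads(lib, catalog, single_end_offset)
        for lib in libraries
    }
    counts = pd.DataFrame(columns)
    clean_sizes = pd.Series(
        {lib.library_id: lib.clean_size for lib in libraries}, name="clean_size"
    )
    return counts, clean_sizes


def cpm_normalize(counts: pd.DataFrame, clean_sizes: pd.Series) -> pd.DataFrame:
    """Counts Per Million clean reads: count * 1e6 / clean library size."""
    sizes = clean_sizes.reindex(counts.columns)
    if sizes.isna().any():
        missing = list(sizes.index[sizes.isna()])
        raise ValueError(f"missing clean sizes for libraries: {missing}")
    if (sizes <= 0).any():
        bad = list(sizes.index[sizes <= 0])
        raise ValueError(f"non-positive clean size for libraries: {bad}")
    return counts * 1e6 / sizes.astype(np.float64)
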