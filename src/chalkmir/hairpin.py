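"""Hairpin folding, miRNA* derivation and duplex-quality evaluation.

The built-in folder is a deterministic base-pair-maximising (Nussinov-style)
dynamic program over nested structures with Watson-Crick + G:U pairing and a
minimum hairpin loop of 3 nt.  It is a stand-in for a thermodynamic folder:
precomputed dot-bracket structures from any external tool are accepted
everywhere a structure is required.

Duplex acceptance follows plant MIRNA annotation practice: at most 5
unpaired (mismatched) nucleotides in the mature/miRNA* duplex region AND at
most 3 of them in asymmetric bulges.  Terminal 2-nt 3' overhangs are not
part of the duplex region and are never counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import normalize_seq, revcomp

__all__ = [
    "MirnaLocus",
    "DuplexReport",
    "fold_hairpin",
    "pairing_table",
    "derive_star",
    "check_duplex",
    "build_perfect_hairpin",
]

MIN_LOOP = 3  # minimum unpaired nucleotides enclosed by a base pair

_CAN_PAIR = {
    ("A", "T"),
    ("T", "A"),
    ("G", "C"),
    ("C", "G"),
    ("G", "T"),  # wobble counts as paired
    ("T", "G"),
}


def _can_pair(a: str, b: str) -> bool:
    return (a, b) in _CAN_PAIR


@dataclass
class MirnaLocus:
    """A genomic hairpin locus with designated mature and star arms.

    Offsets are hairpin-local, 0-based half-open.  ``mature_arm`` is
    ``"5p"`` or ``"3p"`` and designates which arm carries the (more
    abundant) mature miRNA; the other arm is the star.
    """

    name: str
    chrom: str
    start: int
    end: int
    strand: str
    hairpin: str
    structure: str = ""
    mature_start: int = -1
    mature_end: int = -1
    star_start: int = -1
    star_end: int = -1
    mature_arm: str = "5p"
    extra: dict = field(default_factory=dict)

    @property
    def mature_seq(self) -> str:
        return self.hairpin[self.mature_start : self.mature_end]

    @property
    def star_seq(self) -> str:
        return self.hairpin[self.star_start : self.star_end]

    def genomic_interval(self, local_start: int, local_end: int) -> tuple[int, int]:
        """Map a hairpin-local interval to genome coordinates.

        On the minus strand the hairpin sequence is the reverse complement
        of the genome slice, so local coordinates count from ``end``.
        """
        if self.strand == "+":
            return self.start + local_start, self.start + local_end
        return self.end - local_end, self.end - local_start


def fold_hairpin(sequence: str) -> str:
    """Fold a sequence into a nested dot-bracket structure.

    Maximises base pairs (Watson-Crick + G:U) with a minimum loop of 3 nt.
    Ties are broken deterministically by preferring pairings closer to the
    outer ends of the interval under consideration.
    """
    seq = normalize_seq(sequence)
    if any(c not in "ACGT" for c in seq):
        bad = sorted({c for c in seq if c not in "ACGT"})
        raise ValueError(f"non-ACGTU characters in sequence: {bad}")
    n = len(seq)
    if n == 0:
        return ""

    # best[i][j] = max pairs in seq[i..j]
    best = [[0] * n for _ in range(n)]
    for span in range(MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            b = best[i][j - 1]  # j unpaired
            for k in range(i, j - MIN_LOOP):
                if _can_pair(seq[k], seq[j]):
                    left = best[i][k - 1] if k > i else 0
                    inner = best[k + 1][j - 1]
                    cand = left + 1 + inner
                    if cand > b:
                        b = cand
            best[i][j] = b

    structure = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= MIN_LOOP or best[i][j] == 0:
            continue
        paired = False
        # outermost k first so ties resolve to pairings near the ends
        for k in range(i, j - MIN_LOOP):
            if _can_pair(seq[k], seq[j]):
                left = best[i][k - 1] if k > i else 0
                if left + 1 + best[k + 1][j - 1] == best[i][j]:
                    structure[k] = "("
                    structure[j] = ")"
                    if k > i:
                        stack.append((i, k - 1))
                    stack.append((k + 1, j - 1))
                    paired = True
                    break
        if not paired:
            stack.append((i, j - 1))
    return "".join(structure)


def pairing_table(structure: str) -> list[int]:
    """Partner index per position (-1 if unpaired) from dot-bracket."""
    table = [-1] * len(structure)
    stack: list[int] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced brackets in structure")
            j = stack.pop()
            table[i] = j
            table[j] = i
    if stack:
        raise ValueError("unbalanced brackets in structure")
    return table


def _nearest_paired(table: list[int], pos: int, step: int, lo: int, hi: int) -> tuple[int, int]:
    """First paired position at or after ``pos`` walking by ``step``.

    Returns (position, distance walked); raises if none inside [lo, hi].
    """
    p = pos
    while lo <= p <= hi:
        if table[p] >= 0:
            return p, abs(p - pos)
        p += step
    raise ValueError(f"no paired base found near position {pos} within the mature region")


def derive_star(
    hairpin: str,
    structure: str,
    mature_start: int,
    mature_end: int,
) -> tuple[int, int]:
    """Derive the miRNA* interval pairing the mature with 2-nt 3' overhangs.

    The star 5' end pairs with the base 2 nt inside the mature 3' end and
    the star 3' end extends 2 nt past the partner of the mature 5' end, so
    both duplex strands carry 2-nt 3' overhangs.  On a perfect stem this
    makes the star the reverse complement of the mature displaced by 2 nt.

    Parameters are hairpin-local 0-based half-open; returns the star
    interval in the same convention.
    """
    n = len(hairpin)
    if len(structure) != n:
        raise ValueError("structure/sequence length mismatch")
    if not (0 <= mature_start < mature_end <= n):
        raise ValueError(
            f"mature interval [{mature_start},{mature_end}) outside hairpin of length {n}"
        )
    table = pairing_table(structure)

    lo, hi = mature_start, mature_end - 1
    # partner of the base 2 nt inside the mature 3' end -> star 5' side
    q1, d1 = _nearest_paired(table, mature_end - 3, -1, lo, hi)
    # partner of the mature 5' end -> star 3' side (plus the 2-nt overhang)
    q2, d2 = _nearest_paired(table, mature_start, +1, lo, hi)
    p1, p2 = table[q1], table[q2]

    # Antiparallel pairing puts the partner of the mature's 3' side at the
    # low coordinate of the star on either arm: the star's 5' end sits at
    # p1 and its 3' end extends 2 nt past p2 (the mature 5' end's partner).
    star_start = p1 - d1
    star_end = p2 + d2 + 3
    if star_start < 0 or star_end > n:
        raise ValueError(
            f"derived star [{star_start},{star_end}) extends past hairpin bounds [0,{n})"
        )
    if not star_start < star_end:
        raise ValueError("degenerate star interval; mature arm may not be paired")
    return star_start, star_end


@dataclass
class DuplexReport:
    """Counts of duplex defects for a mature/star pair.

    ``n_unpaired`` is the number of mismatched (unpaired) nucleotides in
    the duplex region; ``n_asym_bulge_nt`` the subset sitting in asymmetric
    bulges (unpaired nucleotides on one strand opposite a 0-length gap).
    """

    n_unpaired: int
    n_asym_bulge_nt: int
    passes: bool

    MAX_UNPAIRED = 5
    MAX_ASYM_BULGE = 3


def check_duplex(
    hairpin: str,
    structure: str,
    mature: tuple[int, int],
    star: tuple[int, int],
    literal_or: bool = False,
) -> DuplexReport:
    """Evaluate the mature/miRNA* duplex against the annotation criteria.

    The duplex region is the union of the mature and star intervals with
    each strand's terminal 2-nt 3' overhang excluded.  A nucleotide counts
    as unpaired (mismatch) if it has no partner inside the opposite
    strand's duplex window; asymmetric-bulge nucleotides are the surplus of
    unpaired nucleotides between consecutive duplex pairs on one strand
    over the other.

    By default acceptance requires BOTH ``n_unpaired <= 5`` and
    ``n_asym_bulge_nt <= 3``; ``literal_or=True`` accepts if either cap
    holds.
    """
    if len(structure) != len(hairpin):
        raise ValueError("structure/sequence length mismatch")
    (m0, m1), (s0, s1) = mature, star
    if m1 - m0 < 3 or s1 - s0 < 3:
        raise ValueError("mature/star intervals too short")
    table = pairing_table(structure)

    # 3' ends: high coordinate on the 5' arm segment and on the 3' arm
    # segment alike (the hairpin is written 5'->3').  Trim 2 nt from each
    # segment's 3' (high-coordinate) side.
    m_window = range(m0, m1 - 2)
    s_window = range(s0, s1 - 2)
    m_set, s_set = set(m_window), set(s_window)

    def _paired_in(window, other) -> list[int]:
        return [i for i in window if table[i] >= 0 and table[i] in other]

    m_anchors = _paired_in(m_window, s_set)
    s_anchors = _paired_in(s_window, m_set)
    n_unpaired = (len(m_set) - len(m_anchors)) + (len(s_set) - len(s_anchors))

    # Walk the duplex between consecutive anchor pairs: the surplus of
    # unpaired nt on one side over the other is asymmetric-bulge material.
    n_asym = 0
    if m_anchors:
        anchors = sorted(m_anchors)
        boundaries_m = [min(m_window) - 1] + anchors + [max(m_window) + 1]
        partner = {i: table[i] for i in anchors}
        star_lo, star_hi = min(s_window), max(s_window)
        # mature ascends 5'->3' while its partners descend on the star, so
        # the segment before the first anchor faces the top of the star
        # window and the segment after the last anchor faces its bottom.
        for k in range(len(boundaries_m) - 1):
            a, b = boundaries_m[k], boundaries_m[k + 1]
            gap_m = b - a - 1
            if k == 0:
                gap_s = star_hi - partner[b]
            elif k == len(boundaries_m) - 2:
                gap_s = partner[a] - star_lo
            else:
                gap_s = partner[a] - partner[b] - 1
            n_asym += abs(gap_m - max(gap_s, 0))
    else:
        # no pairing at all: everything unpaired, fully asymmetric
        n_asym = n_unpaired

    ok_mm = n_unpaired <= DuplexReport.MAX_UNPAIRED
    ok_bulge = n_asym <= DuplexReport.MAX_ASYM_BULGE
    passes = (ok_mm or ok_bulge) if literal_or else (ok_mm and ok_bulge)
    return DuplexReport(n_unpaired=n_unpaired, n_asym_bulge_nt=n_asym, passes=passes)


def build_perfect_hairpin(mature: str, flank5: int = 6, stem_pad: int = 10, loop: str = "CACAACAA") -> tuple[str, int, int]:
    """Construct a perfect-stem hairpin containing ``mature`` on the 5p arm.

    Returns (hairpin, mature_start, mature_end).  Used by the simulator and
    by tests; the 3p arm is the exact reverse complement of the 5p arm so
    the duplex is defect-free by construction.
    """
    mature = normalize_seq(mature)
    arm5 = "GC" * (flank5 // 2) + mature + "GC" * (stem_pad // 2)
    hairpin = arm5 + loop + revcomp(arm5)
    m0 = flank5 // 2 * 2
    return hairpin, m0, m0 + len(mature)
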