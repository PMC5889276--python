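"""IUPAC-degenerate motif scanning and bipartite promoter search.

Restriction screens count distinct genomic sites: for IUPAC-palindromic
patterns the forward-strand matches enumerate every site; otherwise the
union of forward coordinates of matches on either strand is taken.

The promoter model is the classic sigma-70 bipartite consensus: a -35
hexamer and a -10 hexamer separated by an unconstrained spacer, with a
mismatch budget shared across both boxes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Sequence, Tuple

from .genome_io import GenomeRecord, reverse_complement

#: IUPAC letter -> set of concrete bases it stands for.
IUPAC_SETS: Dict[str, FrozenSet[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Restriction recognition patterns screened by default.
RESTRICTION_PATTERNS: Dict[str, str] = {
    "Gst1588I": "CYCGRG",
    "Gst1588II": "GATC",
    "GstI/GstGS18": "GGATCC",
    "Gst4109": "CGATCG",
    "GsaI": "CCCAGC",
    "BamHI": "GGATCC",
    "EcoRV": "GATATC",
    "HpaI": "GTTAAC",
    "KpnI": "GGTACC",
    "PstI": "CTGCAG",
    "SacI": "GAGCTC",
    "SalI": "GTCGAC",
    "SmaI": "CCCGGG",
}


class PatternError(ValueError):
    """Raised for patterns containing non-IUPAC letters."""


@dataclass(frozen=True)
class MotifHit:
    """A positioned match of a single degenerate pattern."""

    pattern_name: str
    position: int  # 1-based forward coordinate of the leftmost matched base
    strand: str
    mismatches: int
    length: int


@dataclass(frozen=True)
class PromoterHit:
    """A bipartite promoter placement; ``pos10 = pos35 + 6 + spacer``."""

    pos35: int
    pos10: int
    spacer: int
    mm35: int
    mm10: int
    strand: str

    @property
    def mm_total(self) -> int:
        return self.mm35 + self.mm10


class IupacMatcher:
    """Per-position compatibility matcher for one IUPAC pattern.

    Genome ambiguity letters are conservative by default: a non-ACGT base
    in the genome matches nothing. With ``permissive=True`` a genome
    ambiguity letter matches when its base set intersects the pattern
    letter's set.
    """

    def __init__(self, pattern: str, permissive: bool = False):
        pattern = pattern.upper()
        for i, c in enumerate(pattern):
            if c not in IUPAC_SETS:
                raise PatternError(f"illegal IUPAC letter {c!r} at position {i + 1}")
        self.pattern = pattern
        self.permissive = permissive
        self._sets = [IUPAC_SETS[c] for c in pattern]

    def __len__(self) -> int:
        return len(self.pattern)

    def mismatches(self, window: str) -> int:
        """IUPAC-aware Hamming distance between the pattern and a window."""
        if len(window) != len(self.pattern):
            raise PatternError(
                f"window length {len(window)} != pattern length {len(self.pattern)}"
            )
        mm = 0
        for base, allowed in zip(window.upper(), self._sets):
            if base in allowed:
                continue
            if self.permissive and base in IUPAC_SETS and IUPAC_SETS[base] & allowed:
                continue
            mm += 1
        return mm


def compile_iupac(pattern: str, permissive: bool = False) -> IupacMatcher:
    """Compile an IUPAC pattern into a reusable mismatch matcher."""
    return IupacMatcher(pattern, permissive=permissive)


def is_iupac_palindrome(pattern: str) -> bool:
    """Whether a pattern equals its IUPAC-aware reverse complement."""
    return pattern.upper() == reverse_complement(pattern)


def scan_pattern(
    genome: GenomeRecord,
    pattern: str,
    max_mismatch: int = 0,
    strands: str = "both",
    pattern_name: str = None,
    permissive: bool = False,
) -> List[MotifHit]:
    """All windows within ``max_mismatch`` of the pattern, both strands.

    Reverse-strand matches are reported at the forward coordinate of the
    leftmost base of the matched window. Overlapping hits are all reported.
    Hits are sorted by position, then strand.
    """
    if strands not in ("forward", "both"):
        raise PatternError(f"strands must be 'forward' or 'both', got {strands!r}")
    name = pattern_name if pattern_name is not None else pattern.upper()
    matchers = [(compile_iupac(pattern, permissive), "+")]
    if strands == "both":
        matchers.append((compile_iupac(reverse_complement(pattern), permissive), "-"))
    k = len(pattern)
    if k > genome.length:
        raise PatternError(f"pattern length {k} exceeds genome length {genome.length}")
    hits: List[MotifHit] = []
    seq = genome.seq
    for matcher, strand in matchers:
        for i in range(genome.length - k + 1):
            mm = matcher.mismatches(seq[i : i + k])
            if mm <= max_mismatch:
                hits.append(MotifHit(name, i + 1, strand, mm, k))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def count_recognition_sites(genome: GenomeRecord, pattern: str) -> int:
    """Number of distinct genomic recognition sites (exact matching).

    IUPAC-palindromic patterns are counted on the forward strand only
    (each site would otherwise be reported twice); non-palindromic
    patterns count the union of forward positions of matches on either
    strand.
    """
    if is_iupac_palindrome(pattern):
        hits = scan_pattern(genome, pattern, max_mismatch=0, strands="forward")
        return len(hits)
    hits = scan_pattern(genome, pattern, max_mismatch=0, strands="both")
    return len({h.position for h in hits})


def screen_patterns(
    genome: GenomeRecord, patterns: Dict[str, str] = None
) -> Dict[str, Tuple[str, int]]:
    """Site counts for a named pattern registry: name -> (pattern, count)."""
    if patterns is None:
        patterns = RESTRICTION_PATTERNS
    return {
        name: (pat, count_recognition_sites(genome, pat))
        for name, pat in patterns.items()
    }


def _promoters_one_strand(
    seq: str,
    m35: IupacMatcher,
    m10: IupacMatcher,
    spacer_range: Tuple[int, int],
    budget: int,
    strand: str,
) -> List[PromoterHit]:
    n = len(seq)
    k35, k10 = len(m35), len(m10)
    raw: List[PromoterHit] = []
    lo, hi = spacer_range
    for i in range(n - k35 + 1):  # 0-based pos35
        mm35 = m35.mismatches(seq[i : i + k35])
        if mm35 > budget:
            continue
        for spacer in range(lo, hi + 1):
            j = i + k35 + spacer
            if j + k10 > n:
                break
            mm10 = m10.mismatches(seq[j : j + k10])
            if mm35 + mm10 <= budget:
                raw.append(PromoterHit(i + 1, j + 1, spacer, mm35, mm10, strand))
    # One hit per -10 box: minimal total mismatches, then smallest spacer.
    best: Dict[int, PromoterHit] = {}
    for hit in raw:
        cur = best.get(hit.pos10)
        if cur is None or (hit.mm_total, hit.spacer) < (cur.mm_total, cur.spacer):
            best[hit.pos10] = hit
    return sorted(best.values(), key=lambda h: (h.pos35, h.pos10))


def find_promoters(
    genome: GenomeRecord,
    box35: str = "TTGACA",
    box10: str = "TATAAT",
    spacer_range: Tuple[int, int] = (15, 18),
    max_total_mismatch: int = 2,
    strand: str = "forward",
) -> List[PromoterHit]:
    """Spacer-constrained bipartite promoter search with a shared budget.

    All ``(pos35, spacer)`` placements with ``mm35 + mm10 <= budget`` are
    enumerated, deduplicated to one hit per -10 box (minimal total
    mismatches, ties to the smallest spacer), and sorted by pos35. The
    default scans the forward (coding) strand only; ``strand="both"`` adds
    reverse-strand hits whose box positions are reported on the scanned
    orientation's coordinates mapped to forward leftmost-base positions.
    """
    if strand not in ("forward", "both"):
        raise PatternError(f"strand must be 'forward' or 'both', got {strand!r}")
    m35, m10 = compile_iupac(box35), compile_iupac(box10)
    hits = _promoters_one_strand(genome.seq, m35, m10, tuple(spacer_range), max_total_mismatch, "+")
    if strand == "both":
        rc = reverse_complement(genome.seq)
        n = genome.length
        for h in _promoters_one_strand(rc, m35, m10, tuple(spacer_range), max_total_mismatch, "-"):
            hits.append(
                PromoterHit(
                    pos35=n - (h.pos35 + len(m35) - 1) + 1,
                    pos10=n - (h.pos10 + len(m10) - 1) + 1,
                    spacer=h.spacer,
                    mm35=h.mm35,
                    mm10=h.mm10,
                    strand="-",
                )
            )
        hits.sort(key=lambda h: (min(h.pos35, h.pos10), h.strand))
    return hits
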