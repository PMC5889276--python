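"""Intrinsic (rho-independent) terminator detection.

A candidate is an inverted-repeat hairpin followed by a T-rich tract on the
coding strand. Hairpins are found as maximal stems grown outward from every
(loop position, loop length) placement; stems may contain a bounded number
of non-paired positions, G.T (G.U in the transcript) counts as a weak pair,
and both the innermost and outermost stem positions must be paired.

Stem stability is a stem-only nearest-neighbor sum: each adjacent pair of
Watson-Crick-paired stem positions contributes the published unified RNA
stack free energy (kcal/mol, 37 C) keyed by the top-strand dinucleotide;
steps involving a wobble or mismatched position contribute nothing. There
is no helix-initiation or loop-entropy term, so reported values rank
hairpins rather than estimate full folding energies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .genome_io import GenomeRecord, reverse_complement

#: Unified RNA nearest-neighbor stack free energies (kcal/mol at 37 C),
#: keyed by the 5'->3' top-strand dinucleotide of two stacked WC pairs.
NN_STACK_DG = {
    "AA": -0.93, "UU": -0.93,
    "AU": -1.10,
    "UA": -1.33,
    "CU": -2.08, "AG": -2.08,
    "CA": -2.11, "UG": -2.11,
    "GU": -2.24, "AC": -2.24,
    "GA": -2.35, "UC": -2.35,
    "CG": -2.36,
    "GG": -3.26, "CC": -3.26,
    "GC": -3.42,
}

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

# Pair classes between top-strand base (row) and bottom-strand base (col),
# DNA notation: 2 = Watson-Crick, 1 = G.T weak pair, 0 = not paired.
_PAIR_CLASS = np.zeros((5, 5), dtype=np.int8)
for a, b in (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")):
    _PAIR_CLASS[_CODE[a], _CODE[b]] = 2
for a, b in (("G", "T"), ("T", "G")):
    _PAIR_CLASS[_CODE[a], _CODE[b]] = 1


@dataclass(frozen=True)
class Hairpin:
    """A maximal inverted repeat: arm1 | loop | arm2, 1-based inclusive."""

    start: int
    end: int
    stem_len: int
    loop_len: int
    n_mismatch: int
    strand: str = "+"


@dataclass(frozen=True)
class TerminatorCandidate:
    """An accepted terminator: hairpin plus its downstream tail window."""

    start: int
    end: int
    stem_len: int
    loop_len: int
    dg_stem: float
    u_score: float
    strand: str = "+"


def _encode(seq: str) -> np.ndarray:
    codes = np.full(len(seq), 4, dtype=np.int8)  # 4 = ambiguity, pairs with nothing
    for base, code in _CODE.items():
        codes[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = code
    return codes


def find_hairpins(
    genome: GenomeRecord,
    stem_range: Tuple[int, int] = (4, 30),
    loop_range: Tuple[int, int] = (3, 10),
    max_mismatch_in_stem: int = 1,
    allow_gu: bool = True,
) -> List[Hairpin]:
    """All maximal hairpins on the forward strand, sorted by start.

    For every loop placement the stem is the longest arm length ``a`` within
    ``stem_range`` such that all of the following hold: every stem position
    is inside the sequence; at most ``max_mismatch_in_stem`` positions are
    unpaired; the innermost and outermost positions are paired (weak G.T
    pairs count as paired when ``allow_gu``). One hairpin is reported per
    loop placement that admits any valid stem.
    """
    seq = genome.seq
    n = len(seq)
    if n < 2 * stem_range[0] + loop_range[0]:
        return []
    codes = _encode(seq)
    min_pair = 1 if allow_gu else 2
    stem_min, stem_max = stem_range
    out: List[Hairpin] = []

    for loop_len in range(loop_range[0], loop_range[1] + 1):
        # pair_class[d-1, p]: class of the depth-d pair for loop start p.
        depth = min(stem_max, (n - loop_len) // 2 + 1)
        if depth < stem_min:
            continue
        pair_class = np.zeros((depth, n), dtype=np.int8)
        for d in range(1, depth + 1):
            left = np.arange(n) - d
            right = np.arange(n) + loop_len + d - 1
            ok = (left >= 0) & (right < n)
            row = np.zeros(n, dtype=np.int8)
            row[ok] = _PAIR_CLASS[codes[left[ok]], codes[right[ok]]]
            oob = ~ok
            row[oob] = -1  # out of bounds: never paired, blocks extension
            pair_class[d - 1] = row

        paired = pair_class >= min_pair
        in_bounds = pair_class >= 0
        mism = in_bounds & ~paired
        cum_mism = np.cumsum(mism, axis=0)
        cum_oob = np.cumsum(~in_bounds, axis=0)
        valid = (
            paired
            & paired[0:1, :]
            & (cum_mism <= max_mismatch_in_stem)
            & (cum_oob == 0)
        )
        valid[: stem_min - 1, :] = False
        # a stem is maximal when it cannot be extended outward by one pair
        extendable = np.zeros_like(valid)
        extendable[:-1, :] = valid[1:, :]
        maximal = valid & ~extendable
        for d, p in zip(*np.nonzero(maximal)):
            a = int(d) + 1
            out.append(
                Hairpin(
                    start=int(p) - a + 1,
                    end=int(p) + loop_len + a,
                    stem_len=a,
                    loop_len=loop_len,
                    n_mismatch=int(cum_mism[d, p]),
                )
            )
    # identical spans (2a + loop constant) collapse to the longest stem
    by_span = {}
    for h in out:
        key = (h.start, h.end)
        cur = by_span.get(key)
        if cur is None or (h.stem_len, -h.n_mismatch) > (cur.stem_len, -cur.n_mismatch):
            by_span[key] = h
    result = sorted(by_span.values(), key=lambda h: (h.start, h.end))
    return result


def stem_dg(genome: GenomeRecord, hairpin: Hairpin) -> float:
    """Stem-only nearest-neighbor free-energy sum (kcal/mol) for a hairpin."""
    arm1 = genome.slice(hairpin.start, hairpin.start + hairpin.stem_len - 1)
    arm2 = genome.slice(hairpin.end - hairpin.stem_len + 1, hairpin.end)
    top = arm1.replace("T", "U")
    bottom = arm2[::-1]  # aligned with arm1: bottom[i] pairs top[i]
    wc = [
        _PAIR_CLASS[_CODE.get(a, 4) if a in _CODE else 4, _CODE.get(b, 4) if b in _CODE else 4] == 2
        for a, b in zip(arm1, bottom)
    ]
    dg = 0.0
    for i in range(len(top) - 1):
        if wc[i] and wc[i + 1]:
            dg += NN_STACK_DG[top[i : i + 2]]
    return dg


def evaluate_terminator(
    genome: GenomeRecord,
    hairpin: Hairpin,
    dg_threshold: float = -8.0,
    min_u_score: float = 0.5,
    tail_len: int = 8,
) -> Tuple[Optional[TerminatorCandidate], Optional[str]]:
    """Score a hairpin; return ``(candidate, None)`` or ``(None, reason)``."""
    tail_start = hairpin.end + 1
    tail_end = hairpin.end + tail_len
    if tail_end > genome.length:
        return None, "truncated tail"
    tail = genome.slice(tail_start, tail_end)
    u_score = tail.count("T") / tail_len
    dg = stem_dg(genome, hairpin)
    if dg > dg_threshold:
        return None, f"dg_stem {dg:.2f} above threshold {dg_threshold:.2f}"
    if u_score < min_u_score:
        return None, f"u_score {u_score:.3f} below {min_u_score:.3f}"
    return (
        TerminatorCandidate(
            start=hairpin.start,
            end=tail_end,
            stem_len=hairpin.stem_len,
            loop_len=hairpin.loop_len,
            dg_stem=dg,
            u_score=u_score,
            strand=hairpin.strand,
        ),
        None,
    )


def score_terminator(genome: GenomeRecord, hairpin: Hairpin, **kwargs) -> Optional[TerminatorCandidate]:
    """Accepted :class:`TerminatorCandidate` for a hairpin, or ``None``."""
    candidate, _ = evaluate_terminator(genome, hairpin, **kwargs)
    return candidate


def _collapse_overlaps(candidates: List[TerminatorCandidate]) -> List[TerminatorCandidate]:
    """Keep the lowest-dg candidate among mutually overlapping ones."""
    kept: List[TerminatorCandidate] = []
    for cand in sorted(candidates, key=lambda c: (c.dg_stem, c.start)):
        if all(cand.end < k.start or cand.start > k.end for k in kept):
            kept.append(cand)
    kept.sort(key=lambda c: (c.start, c.end))
    return kept


def find_terminators(
    genome: GenomeRecord,
    stem_range: Tuple[int, int] = (4, 30),
    loop_range: Tuple[int, int] = (3, 10),
    max_mismatch_in_stem: int = 1,
    allow_gu: bool = True,
    dg_threshold: float = -8.0,
    min_u_score: float = 0.5,
    tail_len: int = 8,
    strands: str = "forward",
) -> List[TerminatorCandidate]:
    """Hairpin search plus scoring, with overlap collapsing; sorted by start."""

    def one_strand(g: GenomeRecord) -> List[TerminatorCandidate]:
        hairpins = find_hairpins(g, stem_range, loop_range, max_mismatch_in_stem, allow_gu)
        scored = []
        for hp in hairpins:
            cand, _ = evaluate_terminator(g, hp, dg_threshold, min_u_score, tail_len)
            if cand is not None:
                scored.append(cand)
        return _collapse_overlaps(scored)

    candidates = one_strand(genome)
    if strands == "both":
        rc = GenomeRecord(id=genome.id, seq=reverse_complement(genome.seq))
        n = genome.length
        for c in one_strand(rc):
            candidates.append(
                TerminatorCandidate(
                    start=n - c.end + 1,
                    end=n - c.start + 1,
                    stem_len=c.stem_len,
                    loop_len=c.loop_len,
                    dg_stem=c.dg_stem,
                    u_score=c.u_score,
                    strand="-",
                )
            )
        candidates.sort(key=lambda c: (c.start, c.end))
    elif strands != "forward":
        raise ValueError(f"strands must be 'forward' or 'both', got {strands!r}")
    return candidates
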