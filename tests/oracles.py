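"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately written the dumb way — exhaustive
enumeration over all placements, with its own IUPAC table and its own
charge model — so agreement with the package is meaningful.
"""

from itertools import product

import numpy as np
from Bio.Seq import Seq
from Bio.SeqUtils import molecular_weight

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

STOPS = {"TAA", "TAG", "TGA"}


def mismatches(pattern: str, window: str) -> int:
    """Degenerate Hamming distance; ambiguous genome bases never match."""
    return sum(1 for p, b in zip(pattern, window) if b not in IUPAC[p])


def scan_oracle(seq: str, pattern: str, max_mm: int, strands: str = "both"):
    """All (position, strand, mm) with mm <= max_mm; positions 1-based."""
    hits = []
    k = len(pattern)
    rc_pattern = str(Seq(pattern).reverse_complement())
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        mm = mismatches(pattern, window)
        if mm <= max_mm:
            hits.append((i + 1, "+", mm))
        if strands == "both":
            mm = mismatches(rc_pattern, window)
            if mm <= max_mm:
                hits.append((i + 1, "-", mm))
    return sorted(hits)


def site_count_oracle(seq: str, pattern: str) -> int:
    """Distinct exact recognition-site positions, both strands unioned."""
    return len({pos for pos, _, _ in scan_oracle(seq, pattern, 0, "both")})


def promoter_oracle(seq, box35="TTGACA", box10="TATAAT", spacers=(15, 18), budget=2):
    """All placements, then one hit per pos10 (min mm, then min spacer)."""
    raw = []
    for i in range(len(seq) - len(box35) + 1):
        mm35 = mismatches(box35, seq[i : i + len(box35)])
        for spacer in range(spacers[0], spacers[1] + 1):
            j = i + len(box35) + spacer
            if j + len(box10) > len(seq):
                continue
            mm10 = mismatches(box10, seq[j : j + len(box10)])
            if mm35 + mm10 <= budget:
                raw.append((i + 1, j + 1, spacer, mm35, mm10))
    best = {}
    for pos35, pos10, spacer, mm35, mm10 in raw:
        key = pos10
        cand = (mm35 + mm10, spacer, pos35, mm35, mm10)
        if key not in best or cand < best[key]:
            best[key] = cand
    return sorted(
        (pos35, pos10, spacer, mm35, mm10)
        for pos10, (mm, spacer, pos35, mm35, mm10) in best.items()
    )


def _paired(a: str, b: str, allow_gu: bool) -> bool:
    if (a, b) in (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")):
        return True
    return allow_gu and (a, b) in (("G", "T"), ("T", "G"))


def hairpin_oracle(seq, stem_range=(4, 30), loop_range=(3, 10), max_mm=1, allow_gu=True):
    """All maximal (start, end, stem, loop) hairpins, span-deduplicated.

    A triple (s, a, l) is valid when every stem position is in bounds, the
    innermost and outermost positions are paired, and at most ``max_mm``
    positions are unpaired. It is maximal when (s-1, a+1, l) is not valid
    (including a == stem max). Identical spans keep the longest stem.
    """
    n = len(seq)

    def valid(s, a, l):
        if s < 0 or s + 2 * a + l > n:
            return False
        if not stem_range[0] <= a <= stem_range[1]:
            return False
        pairs = [
            _paired(seq[s + k], seq[s + 2 * a + l - 1 - k], allow_gu) for k in range(a)
        ]
        if not pairs[0] or not pairs[-1]:
            return False
        return pairs.count(False) <= max_mm

    by_span = {}
    for l in range(loop_range[0], loop_range[1] + 1):
        for a in range(stem_range[0], stem_range[1] + 1):
            for s in range(n - 2 * a - l + 1):
                if not valid(s, a, l):
                    continue
                if valid(s - 1, a + 1, l):
                    continue  # extendable, not maximal
                span = (s + 1, s + 2 * a + l)
                if span not in by_span or a > by_span[span][2]:
                    by_span[span] = (span[0], span[1], a, l)
    return sorted(by_span.values())


def orf_oracle(seq, min_mass_kda, starts=("ATG", "GTG", "TTG"), strands="both"):
    """All (start, end, strand) CDS intervals by exhaustive triple testing."""

    def forward_orfs(s):
        found = []
        for i in range(len(s) - 5):
            if s[i : i + 3] not in starts:
                continue
            for j in range(i + 5, len(s), 3):
                codon = s[j - 2 : j + 1]
                if (j - i + 1) % 3:
                    continue
                if codon in STOPS:
                    # most upstream start: no earlier in-frame start without
                    # an intervening stop
                    upstream_open = any(
                        s[k : k + 3] in starts
                        and all(
                            s[m : m + 3] not in STOPS for m in range(k, i, 3)
                        )
                        for k in range(i - 3, -1, -3)
                        if s[k : k + 3] not in STOPS
                    )
                    internal_stop = any(
                        s[m : m + 3] in STOPS for m in range(i, j - 2, 3)
                    )
                    if not internal_stop and not upstream_open:
                        protein = str(Seq(s[i + 3 : j - 2]).translate(table=11))
                        if "*" not in protein:
                            mass = (
                                molecular_weight("M" + protein, seq_type="protein")
                                / 1000.0
                            )
                            if mass >= min_mass_kda:
                                found.append((i + 1, j + 1))
                    break
        return found

    out = [(s, e, "+") for s, e in forward_orfs(seq)]
    if strands == "both":
        rc = str(Seq(seq).reverse_complement())
        n = len(seq)
        out += [(n - e + 1, n - s + 1, "-") for s, e in forward_orfs(rc)]
    return sorted(out)


def pi_grid_oracle(protein: str, pka) -> float:
    """pI from a 10^5-point grid scan of the net-charge function."""
    ph = np.linspace(0.0, 14.0, 100001)
    q = 1.0 / (1.0 + 10 ** (ph - pka.nterm_by_residue.get(protein[0], pka.nterm)))
    q -= 1.0 / (1.0 + 10 ** (pka.cterm_by_residue.get(protein[-1], pka.cterm) - ph))
    for aa, pk in pka.basic.items():
        q += protein.count(aa) / (1.0 + 10 ** (ph - pk))
    for aa, pk in pka.acidic.items():
        q -= protein.count(aa) / (1.0 + 10 ** (pk - ph))
    idx = int(np.argmin(np.abs(q)))
    return float(ph[idx])


def random_dna(seed: int, length: int, gc: float = 0.5) -> str:
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])
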