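"""ORF/CDS calling, translation (bacterial table 11) and packing statistics.

A CDS interval includes its stop codon, so for an in-frame CDS of ``L``
nucleotides the product has ``L/3 - 1`` residues. One ORF is reported per
stop codon per frame: the reading from the most upstream permitted start
codon (after the previous in-frame stop) to the stop. Candidates whose
product falls below the mass threshold are dropped.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Optional, Sequence, Set, Tuple

import pandas as pd
from Bio.Data import CodonTable

from .genome_io import GenomeRecord, reverse_complement
from .proteins import BJELLQVIST, average_mass, isoelectric_point

DEFAULT_START_CODONS = frozenset({"ATG", "GTG", "TTG"})


class CdsError(ValueError):
    """Raised for invalid CDS intervals or translation failures."""


@dataclass
class CdsFeature:
    """A called or imported CDS with its translated product properties."""

    label: str
    start: int
    end: int
    strand: str
    protein: Optional[str] = None
    product_mass: float = float("nan")  # kDa
    product_pi: float = float("nan")
    nt_length: int = -1
    aa_length: int = -1

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise CdsError(f"bad interval {self.start}..{self.end} for {self.label!r}")
        if self.strand not in ("+", "-"):
            raise CdsError(f"bad strand {self.strand!r} for {self.label!r}")
        if self.nt_length < 0:
            self.nt_length = self.end - self.start + 1
        if self.aa_length < 0:
            if self.protein is not None:
                self.aa_length = len(self.protein)
            else:
                self.aa_length = self.nt_length // 3 - 1

    @property
    def interval(self) -> Tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class IntergenicGap:
    """Nucleotides strictly between two start-sorted adjacent features.

    ``gap_nt = start(downstream) - end(upstream) - 1``; negative values are
    overlaps.
    """

    upstream_label: str
    downstream_label: str
    gap_nt: int


def _codon_tables(table: int) -> Tuple[Dict[str, str], Set[str]]:
    tbl = CodonTable.unambiguous_dna_by_id[table]
    return dict(tbl.forward_table), set(tbl.stop_codons)


def translate_cds(
    genome: GenomeRecord,
    start: int,
    end: int,
    strand: str = "+",
    translation_table: int = 11,
) -> str:
    """Translate a stop-inclusive CDS interval; the stop is dropped.

    The initiator codon is rendered as M whether it is ATG, GTG or TTG.
    Raises :class:`CdsError` if the length is not a codon multiple, on an
    internal stop (reporting the codon index), or if the final codon is not
    a stop.
    """
    nt = genome.slice(start, end)
    if strand == "-":
        nt = reverse_complement(nt)
    elif strand != "+":
        raise CdsError(f"bad strand {strand!r}")
    if len(nt) % 3:
        raise CdsError(f"CDS length {len(nt)} not divisible by 3")
    if len(nt) < 6:
        raise CdsError("CDS shorter than two codons")
    forward, stops = _codon_tables(translation_table)
    codons = [nt[i : i + 3] for i in range(0, len(nt), 3)]
    if codons[-1] not in stops:
        raise CdsError(f"final codon {codons[-1]} is not a stop codon")
    aas: List[str] = []
    for idx, codon in enumerate(codons[:-1]):
        if codon in stops:
            raise CdsError(f"internal stop codon at codon index {idx}")
        try:
            aas.append(forward[codon])
        except KeyError:
            raise CdsError(f"untranslatable codon {codon!r} at codon index {idx}") from None
    if codons[0] in ("ATG", "GTG", "TTG"):
        aas[0] = "M"
    return "".join(aas)


def _frame_orfs(
    seq: str,
    frame: int,
    start_codons: Set[str],
    stops: Set[str],
) -> List[Tuple[int, int]]:
    """0-based (start, end) intervals of one ORF per stop in one frame.

    ``end`` is the last base of the stop codon. The start is the most
    upstream start codon after the previous in-frame stop.
    """
    out: List[Tuple[int, int]] = []
    pending_start: Optional[int] = None
    for i in range(frame, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if codon in stops:
            if pending_start is not None:
                out.append((pending_start, i + 2))
            pending_start = None
        elif pending_start is None and codon in start_codons:
            pending_start = i
    return out


def find_orfs(
    genome: GenomeRecord,
    min_mass_kda: float = 4.0,
    start_codons: Sequence[str] = tuple(sorted(DEFAULT_START_CODONS)),
    strands: str = "both",
    translation_table: int = 11,
    pka=BJELLQVIST,
) -> List[CdsFeature]:
    """Call CDSs with a minimum-product-mass filter; sorted by start.

    ``strands`` is ``"forward"`` or ``"both"``. Reverse-strand ORFs are
    reported in forward coordinates with strand ``-``. Labels are
    zero-padded ordinals in start order.
    """
    if strands not in ("forward", "both"):
        raise CdsError(f"strands must be 'forward' or 'both', got {strands!r}")
    starts = set(s.upper() for s in start_codons)
    _, stops = _codon_tables(translation_table)
    n = genome.length

    intervals: List[Tuple[int, int, str]] = []  # 1-based inclusive, strand
    for frame in range(3):
        for s0, e0 in _frame_orfs(genome.seq, frame, starts, stops):
            intervals.append((s0 + 1, e0 + 1, "+"))
    if strands == "both":
        rc = reverse_complement(genome.seq)
        for frame in range(3):
            for s0, e0 in _frame_orfs(rc, frame, starts, stops):
                intervals.append((n - e0, n - s0, "-"))

    features: List[CdsFeature] = []
    for start, end, strand in intervals:
        protein = translate_cds(genome, start, end, strand, translation_table)
        mass = average_mass(protein)
        if mass < min_mass_kda:
            continue
        features.append(
            CdsFeature(
                label="",
                start=start,
                end=end,
                strand=strand,
                protein=protein,
                product_mass=mass,
                product_pi=isoelectric_point(protein, pka),
            )
        )
    features.sort(key=lambda f: (f.start, f.end, f.strand))
    width = max(2, len(str(len(features))))
    for i, f in enumerate(features, 1):
        f.label = f"CDS_{i:0{width}d}"
    return features


def packing_profile(features: Sequence[CdsFeature]):
    """Orientation counts, intergenic gaps/overlaps, and the largest gap.

    Gaps are computed between consecutive features of the start-sorted
    list; ``n_overlaps`` counts negative gaps; ``max_gap`` is the pair with
    the largest gap (ties broken toward the smaller start).
    """
    if not features:
        raise CdsError("packing_profile requires at least one feature")
    ordered = sorted(features, key=lambda f: (f.start, f.end))
    strand_counts = dict(Counter(f.strand for f in ordered))
    gaps: List[IntergenicGap] = []
    for up, down in zip(ordered, ordered[1:]):
        gaps.append(IntergenicGap(up.label, down.label, down.start - up.end - 1))
    n_overlaps = sum(1 for g in gaps if g.gap_nt < 0)
    max_gap = max(gaps, key=lambda g: g.gap_nt, default=None) if gaps else None
    return strand_counts, gaps, n_overlaps, max_gap


def read_cds_table(path, genome: Optional[GenomeRecord] = None) -> List[CdsFeature]:
    """Import a CDS table TSV (label, start, end, strand[, nt_length, ...]).

    If ``genome`` is given, every row is translated and its product mass
    and pI computed; otherwise the printed columns are carried through.
    A printed ``nt_length`` column is preserved even if it disagrees with
    the coordinate span (printed tables can carry typos); the discrepancy
    is exposed via ``coordinate_inconsistencies``.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"label", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise CdsError(f"CDS table missing columns: {sorted(missing)}")
    features: List[CdsFeature] = []
    for row in df.itertuples(index=False):
        kwargs = dict(
            label=str(row.label),
            start=int(row.start),
            end=int(row.end),
            strand=str(row.strand),
        )
        if hasattr(row, "nt_length"):
            kwargs["nt_length"] = int(row.nt_length)
        if hasattr(row, "aa_length"):
            kwargs["aa_length"] = int(row.aa_length)
        if hasattr(row, "mass_kda"):
            kwargs["product_mass"] = float(row.mass_kda)
        if hasattr(row, "pi"):
            kwargs["product_pi"] = float(row.pi)
        feat = CdsFeature(**kwargs)
        if genome is not None:
            feat.protein = translate_cds(genome, feat.start, feat.end, feat.strand)
            feat.product_mass = average_mass(feat.protein)
            feat.product_pi = isoelectric_point(feat.protein)
            feat.aa_length = len(feat.protein)
        features.append(feat)
    return features


def coordinate_inconsistencies(features: Sequence[CdsFeature]) -> List[str]:
    """Labels whose recorded nt_length differs from the coordinate span."""
    return [f.label for f in features if f.nt_length != f.end - f.start + 1]


def load_reference_cds_table(genome: Optional[GenomeRecord] = None) -> List[CdsFeature]:
    """The in-repo 81-row reference CDS table (transcribed printed values)."""
    ref = resources.files("phagekit.data") / "tp84_cds_table.tsv"
    with resources.as_file(ref) as path:
        return read_cds_table(path, genome=genome)
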