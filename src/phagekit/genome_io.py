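"""Genome sequence I/O with strict alphabet validation.

Coordinates are 1-based, inclusive at both ends, everywhere in this package;
the GFF3 writer therefore emits start/end columns verbatim.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import IO, Iterable, List, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

#: 15-letter IUPAC nucleotide alphabet (includes N).
IUPAC_LETTERS = frozenset("ACGTRYSWKMBDHVN")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class SequenceError(ValueError):
    """Raised for empty, malformed, or out-of-alphabet sequence input."""


@dataclass
class GenomeRecord:
    """A single nucleotide sequence with identity and topology.

    ``seq`` is an uppercase string over the IUPAC nucleotide alphabet.
    Ambiguity letters are permitted but recorded in ``ambiguous_positions``
    so downstream scanners can treat them conservatively.
    """

    id: str
    seq: str
    topology: str = "linear"
    ambiguous_positions: tuple = field(default_factory=tuple, repr=False)

    def __post_init__(self) -> None:
        if self.topology not in ("linear", "circular"):
            raise SequenceError(f"unknown topology {self.topology!r}")
        bad = [i for i, c in enumerate(self.seq) if c not in IUPAC_LETTERS]
        if bad:
            raise SequenceError(
                f"illegal character {self.seq[bad[0]]!r} at offset {bad[0]} in record {self.id!r}"
            )
        object.__setattr__(
            self,
            "ambiguous_positions",
            tuple(i + 1 for i, c in enumerate(self.seq) if c not in "ACGT"),
        )

    @property
    def length(self) -> int:
        return len(self.seq)

    def slice(self, start: int, end: int) -> str:
        """Subsequence for a 1-based inclusive interval."""
        if not (1 <= start <= end <= self.length):
            raise SequenceError(
                f"interval {start}..{end} outside [1, {self.length}] of record {self.id!r}"
            )
        return self.seq[start - 1 : end]


def _clean_sequence(raw: str, record_id: str) -> str:
    """Uppercase, strip whitespace/digits, map U->T, validate alphabet."""
    stripped = "".join(c for c in raw if not c.isspace() and not c.isdigit())
    seq = stripped.upper()
    if "U" in seq:
        logger.warning("record %r: RNA letter U mapped to T", record_id)
        seq = seq.replace("U", "T")
    for i, c in enumerate(seq):
        if c not in IUPAC_LETTERS:
            raise SequenceError(
                f"illegal character {c!r} at offset {i} in record {record_id!r}"
            )
    return seq


def read_fasta(path: Union[str, os.PathLike]) -> List[GenomeRecord]:
    """Read FASTA or bare sequence text into :class:`GenomeRecord` objects.

    Accepts standard (multi-)FASTA as well as the headerless dialect in
    which a file holds nothing but sequence characters, line breaks and
    digits; in that case a single record is synthesized with the file stem
    as its id.
    """
    path = os.fspath(path)
    with open(path) as handle:
        text = handle.read()
    if not text.strip():
        raise SequenceError(f"no sequence found in {path!r}")
    records: List[GenomeRecord] = []
    if text.lstrip().startswith(">"):
        with open(path) as handle:
            for rec in SeqIO.parse(handle, "fasta"):
                seq = _clean_sequence(str(rec.seq), rec.id)
                if not seq:
                    raise SequenceError(f"no sequence for record {rec.id!r} in {path!r}")
                records.append(GenomeRecord(id=rec.id, seq=seq))
    else:
        stem = os.path.splitext(os.path.basename(path))[0]
        seq = _clean_sequence(text, stem)
        if not seq:
            raise SequenceError(f"no sequence found in {path!r}")
        records.append(GenomeRecord(id=stem, seq=seq))
    if not records:
        raise SequenceError(f"no sequence found in {path!r}")
    return records


def read_genbank(path: Union[str, os.PathLike]) -> tuple:
    """Read a GenBank flat file: ORIGIN sequence plus CDS feature intervals.

    Returns ``(GenomeRecord, [(start, end, strand, label), ...])`` with
    1-based inclusive coordinates. Only simple (non-compound) CDS locations
    are imported; others are skipped with a warning.
    """
    rec = next(SeqIO.parse(os.fspath(path), "genbank"))
    genome = GenomeRecord(id=rec.id, seq=_clean_sequence(str(rec.seq), rec.id))
    cds = []
    for feat in rec.features:
        if feat.type != "CDS":
            continue
        loc = feat.location
        if len(getattr(loc, "parts", [loc])) > 1:
            logger.warning("skipping compound CDS location %s", loc)
            continue
        label = feat.qualifiers.get("locus_tag", feat.qualifiers.get("gene", ["?"]))[0]
        strand = "-" if loc.strand == -1 else "+"
        cds.append((int(loc.start) + 1, int(loc.end), strand, label))
    return genome, cds


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement (R<->Y, K<->M, B<->V, D<->H, N->N)."""
    up = seq.upper()
    for i, c in enumerate(up):
        if c not in IUPAC_LETTERS:
            raise SequenceError(f"illegal character {c!r} at offset {i}")
    return up.translate(_COMPLEMENT)[::-1]


# GFF3 type names and the tie-break ordering for features sharing a start.
_GFF_TYPE_ORDER = {"CDS": 0, "promoter": 1, "terminator": 2}


def _feature_gff_fields(feat) -> tuple:
    """(start, end, type, strand, score, attributes-extra) for any feature class."""
    cls = type(feat).__name__
    if cls == "CdsFeature":
        return feat.start, feat.end, "CDS", feat.strand, ".", f"label={feat.label}"
    if cls == "PromoterHit":
        start = min(feat.pos35, feat.pos10)
        end = max(feat.pos35 + 5, feat.pos10 + 5)
        return start, end, "promoter", feat.strand, str(feat.mm_total), (
            f"mm35={feat.mm35};mm10={feat.mm10};spacer={feat.spacer}"
        )
    if cls == "TerminatorCandidate":
        return feat.start, feat.end, "terminator", feat.strand, f"{feat.dg_stem:.2f}", (
            f"stem_len={feat.stem_len};loop_len={feat.loop_len};u_score={feat.u_score:.3f}"
        )
    if cls == "MotifHit":
        return (
            feat.position,
            feat.position + feat.length - 1,
            "restriction_site",
            feat.strand,
            str(feat.mismatches),
            f"pattern={feat.pattern_name}",
        )
    raise TypeError(f"cannot serialize feature of type {cls}")


def write_gff3(genome: GenomeRecord, features: Sequence, path: Union[str, os.PathLike, IO]) -> None:
    """Write features as GFF3 with deterministic ordering and stable IDs.

    Features are sorted by start, then by type (CDS < promoter <
    terminator < other), then by end. IDs are zero-padded ordinals in the
    genome id's namespace (e.g. ``g1_01``).
    """
    rows = []
    for feat in features:
        start, end, ftype, strand, score, extra = _feature_gff_fields(feat)
        if not (1 <= start <= end <= genome.length):
            raise SequenceError(
                f"feature {feat!r} interval {start}..{end} outside [1, {genome.length}]"
            )
        rows.append((start, _GFF_TYPE_ORDER.get(ftype, 99), end, ftype, strand, score, extra))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))

    width = max(2, len(str(len(rows))))
    lines = ["##gff-version 3", f"##sequence-region {genome.id} 1 {genome.length}"]
    for n, (start, _, end, ftype, strand, score, extra) in enumerate(rows, 1):
        attrs = f"ID={genome.id}_{n:0{width}d}"
        if extra:
            attrs += ";" + extra
        lines.append(
            "\t".join(
                [genome.id, "phagekit", ftype, str(start), str(end), score, strand, ".", attrs]
            )
        )
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(os.fspath(path), "w") as handle:
            handle.write(text)


def iupac_matches(pattern_char: str, base: str) -> bool:
    """Whether an IUPAC pattern letter is compatible with a concrete base."""
    from .motifs import IUPAC_SETS  # local import to avoid a cycle

    return base in IUPAC_SETS.get(pattern_char, frozenset())
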