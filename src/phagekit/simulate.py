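"""Seeded synthetic phage-genome generator with a planted-feature ledger.

Genomes are i.i.d. background at a target GC fraction with planted CDSs
(guarded by an in-frame stop immediately upstream so the caller recovers the
exact start), bipartite promoter motifs with known per-box mismatch counts,
stem-loop + T-tract terminators, and concrete restriction recognition
sites. With ``clean_background`` (the default) the generator then scrubs
the genome until the annotation pipeline reports planted features only:
accidental ORFs above the mass threshold, accidental promoter placements,
accidental terminator candidates and stray copies of planted restriction
patterns are destroyed by point edits that never touch planted motifs and
never introduce stops into planted reading frames. The ledger is therefore
exact truth for both sensitivity and precision on a clean spec.

Everything is deterministic per seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .genome_io import GenomeRecord, reverse_complement
from .motifs import IUPAC_SETS, MotifHit, PromoterHit, compile_iupac, find_promoters, scan_pattern
from .orfs import CdsFeature, find_orfs
from .terminators import find_terminators

STOPS = ("TAA", "TAG", "TGA")
REV_STOPS = ("TTA", "CTA", "TCA")  # sense triplets read as stops on the reverse strand
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOPS
]


class GenerationError(RuntimeError):
    """Raised when a spec cannot be realized (too dense, or scrub failed)."""


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic genome. ``seed`` fully determines output."""

    length: int
    target_gc: float = 0.5
    n_cds: int = 0
    cds_length_range: Tuple[int, int] = (300, 900)  # nt including the stop codon
    allow_overlap: bool = False
    strand_mode: str = "unidirectional"  # or "mixed"
    promoter_mismatches: Sequence[int] = ()
    promoter_spacers: Optional[Sequence[int]] = None
    n_terminators: int = 0
    terminator_stem_range: Tuple[int, int] = (8, 12)
    terminator_loop_range: Tuple[int, int] = (3, 8)
    restriction_sites: Mapping[str, int] = field(default_factory=dict)
    seed: int = 0
    clean_background: bool = True
    min_mass_kda: float = 4.0

    def __post_init__(self) -> None:
        if self.strand_mode not in ("unidirectional", "mixed"):
            raise GenerationError(f"unknown strand_mode {self.strand_mode!r}")
        if not 0.0 < self.target_gc < 1.0:
            raise GenerationError("target_gc must be in (0, 1)")
        for mm in self.promoter_mismatches:
            if not 0 <= mm <= 2:
                raise GenerationError("promoter mismatch counts must be 0-2")
        if self.promoter_spacers is not None and len(self.promoter_spacers) != len(
            self.promoter_mismatches
        ):
            raise GenerationError("promoter_spacers must match promoter_mismatches in length")


@dataclass(frozen=True)
class PlantedCds:
    start: int
    end: int
    strand: str
    seq: str


@dataclass(frozen=True)
class PlantedPromoter:
    pos35: int
    pos10: int
    spacer: int
    mm35: int
    mm10: int
    strand: str


@dataclass(frozen=True)
class PlantedTerminator:
    start: int  # hairpin start
    end: int  # end of the T-tract tail
    hairpin_end: int
    stem_len: int
    loop_len: int
    strand: str


@dataclass(frozen=True)
class PlantedSite:
    pattern: str
    position: int
    strand: str
    realized: str


@dataclass
class GroundTruth:
    """Ledger of every planted feature, verifiable by string inspection."""

    genome_id: str
    length: int
    seed: int
    cds: List[PlantedCds] = field(default_factory=list)
    promoters: List[PlantedPromoter] = field(default_factory=list)
    terminators: List[PlantedTerminator] = field(default_factory=list)
    sites: List[PlantedSite] = field(default_factory=list)

    def verify(self, genome: GenomeRecord) -> None:
        """Assert every planted feature is literally present at its coordinates."""
        if genome.id != self.genome_id or genome.length != self.length:
            raise GenerationError("ledger does not belong to this genome")
        for f in self.cds:
            if genome.slice(f.start, f.end) != f.seq:
                raise GenerationError(f"CDS at {f.start}..{f.end} does not match ledger")
        for p in self.promoters:
            box35 = genome.slice(p.pos35, p.pos35 + 5)
            box10 = genome.slice(p.pos10, p.pos10 + 5)
            if compile_iupac("TTGACA").mismatches(box35) != p.mm35:
                raise GenerationError(f"-35 box at {p.pos35} mismatch count changed")
            if compile_iupac("TATAAT").mismatches(box10) != p.mm10:
                raise GenerationError(f"-10 box at {p.pos10} mismatch count changed")
        for t in self.terminators:
            tail = genome.slice(t.hairpin_end + 1, t.end)
            if set(tail) != {"T"}:
                raise GenerationError(f"terminator tail at {t.hairpin_end + 1} not all T")
            arm1 = genome.slice(t.start, t.start + t.stem_len - 1)
            arm2 = genome.slice(t.hairpin_end - t.stem_len + 1, t.hairpin_end)
            if reverse_complement(arm1) != arm2:
                raise GenerationError(f"terminator stem at {t.start} no longer pairs")
        for s in self.sites:
            if genome.slice(s.position, s.position + len(s.realized) - 1) != s.realized:
                raise GenerationError(f"site {s.pattern} at {s.position} altered")

    def to_json(self, path) -> None:
        with open(path, "w") as handle:
            json.dump(asdict(self), handle, indent=1)


# ---------------------------------------------------------------------------
# block construction


def _random_codons(rng: np.random.Generator, n: int) -> List[str]:
    return [_SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), n)]


def _cds_string(rng: np.random.Generator, nt_length: int) -> str:
    """start codon + random sense codons + stop; ``nt_length`` includes the stop."""
    n_codons = nt_length // 3
    body = _random_codons(rng, n_codons - 2)
    return "ATG" + "".join(body) + STOPS[rng.integers(0, 3)]


def _mutate_box(rng: np.random.Generator, box: str, n_mut: int) -> str:
    """Introduce exactly ``n_mut`` mismatches into a concrete consensus box."""
    positions = rng.choice(len(box), size=n_mut, replace=False)
    out = list(box)
    for p in positions:
        choices = [b for b in "ACGT" if b != box[p]]
        out[p] = choices[rng.integers(0, 3)]
    return "".join(out)


def _realize_iupac(rng: np.random.Generator, pattern: str) -> str:
    out = []
    for c in pattern.upper():
        options = sorted(IUPAC_SETS[c])
        out.append(options[rng.integers(0, len(options))])
    return "".join(out)


def _terminator_block(rng: np.random.Generator, stem: int, loop: int) -> Tuple[str, int]:
    """Guard base + strong hairpin + T8 tail; returns (block, hairpin offset).

    Arms are GC-biased (not pure GC, to avoid planting accidental
    restriction-site matches inside a protected block) and resampled until
    the stem clears the default energy threshold with margin.
    """
    from .terminators import Hairpin, stem_dg

    for _ in range(50):
        arm = "".join(
            ("GC" if rng.random() < 0.8 else "AT")[rng.integers(0, 2)] for _ in range(stem)
        )
        loop_seq = "".join("ACT"[rng.integers(0, 3)] for _ in range(loop))
        hp = arm + loop_seq + reverse_complement(arm)
        rec = GenomeRecord(id="tmp", seq=hp)
        dg = stem_dg(rec, Hairpin(1, len(hp), stem, loop, 0))
        if dg <= -10.0:
            # guard 'C' cannot pair with the leading tail T, so the planted
            # stem is maximal
            return "C" + hp + "T" * 8, 1
    raise GenerationError(f"cannot build a stem-{stem} hairpin below -10 kcal/mol")


# ---------------------------------------------------------------------------
# generation


class _Workspace:
    """Mutable genome under construction, with protection bookkeeping."""

    def __init__(self, seq: List[str], spec: SyntheticSpec):
        self.seq = seq
        self.spec = spec
        self.hard: Set[int] = set()  # 0-based positions that must never change
        self.cds_frames: List[Tuple[int, int, str]] = []  # 0-based start,end, strand

    def record(self) -> GenomeRecord:
        return GenomeRecord(id=f"synthetic_seed{self.spec.seed}", seq="".join(self.seq))

    def _codon_at(self, cds: Tuple[int, int, str], pos0: int) -> Tuple[int, int]:
        s0, e0, strand = cds
        if strand == "+":
            k = (pos0 - s0) // 3
            return s0 + 3 * k, k
        k = (e0 - pos0) // 3
        return e0 - 3 * k - 2, k

    def safe_write(self, pos0: int, bases: str) -> bool:
        """Write ``bases`` at ``pos0`` unless a hard-protected position or a
        planted reading frame would be corrupted; returns success."""
        span = range(pos0, pos0 + len(bases))
        if span[-1] >= len(self.seq) or any(p in self.hard for p in span):
            return False
        trial = dict(zip(span, bases))
        for cds in self.cds_frames:
            s0, e0, strand = cds
            touched = [p for p in span if s0 <= p <= e0]
            if not touched:
                continue
            for p in touched:
                cstart, k = self._codon_at(cds, p)
                codon = "".join(
                    trial.get(q, self.seq[q]) for q in range(cstart, cstart + 3)
                )
                read = codon if strand == "+" else reverse_complement(codon)
                n_codons = (e0 - s0 + 1) // 3
                if k == n_codons - 1:
                    continue  # planted stop codon is hard-protected anyway
                if read in STOPS:
                    return False
                if k == 0 and read not in ("ATG",):
                    return False  # never touch the initiator
        for p, b in trial.items():
            self.seq[p] = b
        return True


def _layout_blocks(
    rng: np.random.Generator, blocks: List[Tuple[str, str, dict]], spec: SyntheticSpec
) -> List[Tuple[int, str, str, dict]]:
    """Assign non-overlapping 0-based offsets to blocks, left to right."""
    total = sum(len(b) for _, b, _ in blocks)
    if total > 0.7 * spec.length:
        raise GenerationError(
            f"planted span {total} exceeds 70% of genome length {spec.length}"
        )
    min_gap = 12
    slack = spec.length - total - min_gap * (len(blocks) + 1)
    if slack < 0:
        raise GenerationError("genome too short for requested features plus guard gaps")
    cuts = np.sort(rng.integers(0, slack + 1, size=len(blocks)))
    placed = []
    offset = 0
    prev_cut = 0
    for (kind, block, meta), cut in zip(blocks, cuts):
        offset += min_gap + int(cut - prev_cut)
        placed.append((offset, kind, block, meta))
        offset += len(block)
        prev_cut = int(cut)
    return placed


def generate_genome(spec: SyntheticSpec, max_attempts: int = 10) -> Tuple[GenomeRecord, GroundTruth]:
    """Generate a genome and its ground-truth ledger from a spec.

    Layout collisions that the background scrub cannot resolve (for
    example a screened restriction pattern occurring inside a planted
    motif) trigger a deterministic re-layout; after ``max_attempts`` the
    spec is declared unsatisfiable.
    """
    last_error: Optional[GenerationError] = None
    for attempt in range(max_attempts):
        try:
            return _generate_once(spec, attempt)
        except GenerationError as exc:
            last_error = exc
    raise GenerationError(
        f"spec unsatisfiable after {max_attempts} attempts (seed {spec.seed}): {last_error}"
    )


def _generate_once(spec: SyntheticSpec, attempt: int) -> Tuple[GenomeRecord, GroundTruth]:
    rng = np.random.default_rng((spec.seed, attempt))
    p_gc = spec.target_gc / 2.0
    p_at = (1.0 - spec.target_gc) / 2.0
    bases = np.array(list("ACGT"))
    seq = list(
        "".join(bases[rng.choice(4, size=spec.length, p=[p_at, p_gc, p_gc, p_at])])
    )

    # -- build blocks -------------------------------------------------------
    blocks: List[Tuple[str, str, dict]] = []
    lo, hi = spec.cds_length_range
    i = 0
    while i < spec.n_cds:
        nt = int(rng.integers(lo // 3, hi // 3 + 1)) * 3
        strand = "+"
        if spec.strand_mode == "mixed" and rng.random() < 0.5:
            strand = "-"
        pair_overlap = (
            spec.allow_overlap and strand == "+" and i + 1 < spec.n_cds and rng.random() < 0.5
        )
        if pair_overlap:
            nt2 = int(rng.integers(lo // 3, hi // 3 + 1)) * 3
            block, intervals = _overlap_pair_block(rng, nt, nt2)
            blocks.append(("cds_pair", block, {"intervals": intervals}))
            i += 2
        else:
            cds = _cds_string(rng, nt)
            if strand == "+":
                blocks.append(("cds", "TAA" + cds, {"strand": "+"}))
            else:
                blocks.append(("cds", reverse_complement(cds) + "TTA", {"strand": "-"}))
            i += 1
    for j, mm in enumerate(spec.promoter_mismatches):
        spacer = (
            int(spec.promoter_spacers[j])
            if spec.promoter_spacers is not None
            else int(rng.integers(15, 19))
        )
        mm35 = int(rng.integers(0, mm + 1))
        mm10 = mm - mm35
        box35 = _mutate_box(rng, "TTGACA", mm35)
        box10 = _mutate_box(rng, "TATAAT", mm10)
        spacer_seq = "".join(bases[rng.choice(4, size=spacer, p=[p_at, p_gc, p_gc, p_at])])
        blocks.append(
            (
                "promoter",
                box35 + spacer_seq + box10,
                {"spacer": spacer, "mm35": mm35, "mm10": mm10},
            )
        )
    for _ in range(spec.n_terminators):
        stem = int(rng.integers(spec.terminator_stem_range[0], spec.terminator_stem_range[1] + 1))
        loop = int(rng.integers(spec.terminator_loop_range[0], spec.terminator_loop_range[1] + 1))
        block, hp_off = _terminator_block(rng, stem, loop)
        blocks.append(("terminator", block, {"stem": stem, "loop": loop, "hp_off": hp_off}))
    for pattern, copies in spec.restriction_sites.items():
        for _ in range(copies):
            blocks.append(("site", _realize_iupac(rng, pattern), {"pattern": pattern}))

    order = rng.permutation(len(blocks))
    blocks = [blocks[k] for k in order]
    placed = _layout_blocks(rng, blocks, spec)

    # -- write blocks and build ledger -------------------------------------
    ws = _Workspace(seq, spec)
    truth = GroundTruth(genome_id=f"synthetic_seed{spec.seed}", length=spec.length, seed=spec.seed)
    for offset, kind, block, meta in placed:
        for k, b in enumerate(block):
            seq[offset + k] = b
        if kind == "cds":
            if meta["strand"] == "+":
                s0, e0 = offset + 3, offset + len(block) - 1
                ws.hard.update(range(offset, offset + 9))  # guard + start
                ws.hard.update(range(e0 - 2, e0 + 1))  # stop
            else:
                s0, e0 = offset, offset + len(block) - 4
                ws.hard.update(range(e0 - 5, e0 + 4))  # start + guard (rc layout)
                ws.hard.update(range(s0, s0 + 3))
            ws.cds_frames.append((s0, e0, meta["strand"]))
            truth.cds.append(PlantedCds(s0 + 1, e0 + 1, meta["strand"], "".join(seq[s0 : e0 + 1])))
        elif kind == "cds_pair":
            for s0, e0 in meta["intervals"]:
                s0, e0 = offset + s0, offset + e0
                ws.cds_frames.append((s0, e0, "+"))
                ws.hard.update(range(s0, s0 + 3))
                ws.hard.update(range(e0 - 2, e0 + 1))
                truth.cds.append(PlantedCds(s0 + 1, e0 + 1, "+", "".join(seq[s0 : e0 + 1])))
            ws.hard.update(range(offset, offset + 3))  # leading guard stop
        elif kind == "promoter":
            pos35 = offset + 1
            pos10 = offset + 6 + meta["spacer"] + 1
            ws.hard.update(range(offset, offset + 6))
            ws.hard.update(range(pos10 - 1, pos10 + 5))
            truth.promoters.append(
                PlantedPromoter(pos35, pos10, meta["spacer"], meta["mm35"], meta["mm10"], "+")
            )
        elif kind == "terminator":
            hp0 = offset + meta["hp_off"]
            hp_len = 2 * meta["stem"] + meta["loop"]
            ws.hard.update(range(offset, offset + len(block)))
            truth.terminators.append(
                PlantedTerminator(
                    start=hp0 + 1,
                    end=hp0 + hp_len + 8,
                    hairpin_end=hp0 + hp_len,
                    stem_len=meta["stem"],
                    loop_len=meta["loop"],
                    strand="+",
                )
            )
        elif kind == "site":
            ws.hard.update(range(offset, offset + len(block)))
            truth.sites.append(PlantedSite(meta["pattern"], offset + 1, "+", block))

    if spec.clean_background:
        _scrub(ws, truth, rng)

    genome = ws.record()
    # snapshot CDS sequences after scrubbing (interiors may have been edited)
    truth.cds = [
        PlantedCds(f.start, f.end, f.strand, genome.slice(f.start, f.end)) for f in truth.cds
    ]
    truth.verify(genome)
    return genome, truth


def _overlap_pair_block(
    rng: np.random.Generator, nt1: int, nt2: int
) -> Tuple[str, List[Tuple[int, int]]]:
    """Two '+' CDSs sharing 4 nt (``ATGA``: the first CDS's TGA stop overlaps
    the second's ATG start, gap -4), preceded by a guard stop. Returns the
    block string and the two block-relative 0-based CDS intervals."""
    n1 = nt1 // 3
    body1 = _random_codons(rng, n1 - 3)
    enders = [c for c in _SENSE_CODONS if c.endswith("A")]
    last_sense = enders[rng.integers(0, len(enders))]
    first = "ATG" + "".join(body1) + last_sense + "TGA"
    # second CDS: its ATG is first[-4:-1]; its 2nd codon begins with the
    # shared 'A' (a codon starting with A is never a stop).
    codon2 = "A" + "".join("ACGT"[rng.integers(0, 4)] for _ in range(2))
    mid = _random_codons(rng, nt2 // 3 - 3)
    second = "ATG" + codon2 + "".join(mid) + STOPS[rng.integers(0, 3)]
    s1, e1 = 3, 3 + nt1 - 1
    s2 = e1 - 3
    e2 = s2 + nt2 - 1
    # shared region is 4 bases: second[0:4] == "ATGA" == first[-4:]
    block = "TAA" + first + second[4:]
    return block, [(s1, e1), (s2, e2)]


def _scrub(ws: _Workspace, truth: GroundTruth, rng: np.random.Generator) -> None:
    """Iteratively destroy accidental features until only planted ones remain."""
    spec = ws.spec
    planted_cds = {(f.start, f.end, f.strand) for f in truth.cds}
    planted_pos10 = {p.pos10: p for p in truth.promoters}
    planted_term = [(t.start, t.end) for t in truth.terminators]
    site_patterns = set(spec.restriction_sites)
    planted_sites = {(s.pattern, s.position) for s in truth.sites}

    for _ in range(60):
        genome = ws.record()
        dirty = False

        # each class is scrubbed only when the spec plants it: a featureless
        # background stays untouched (its composition is the point)
        for orf in (
            find_orfs(genome, min_mass_kda=spec.min_mass_kda, strands="both")
            if truth.cds
            else []
        ):
            if (orf.start, orf.end, orf.strand) in planted_cds:
                continue
            if not _kill_orf(ws, orf, rng):
                raise GenerationError(
                    f"cannot scrub accidental ORF {orf.start}..{orf.end} ({orf.strand})"
                )
            dirty = True
        if dirty:
            continue

        for hit in find_promoters(genome) if truth.promoters else []:
            planted = planted_pos10.get(hit.pos10)
            if planted is not None and (hit.pos35, hit.mm35, hit.mm10) == (
                planted.pos35,
                planted.mm35,
                planted.mm10,
            ):
                continue
            if planted is not None:
                # a better-scoring alternative -35 pairing; degrade that box
                target = range(hit.pos35 - 1, hit.pos35 + 5)
            else:
                target = range(hit.pos10 - 1, hit.pos10 + 5)
            if not _degrade_window(ws, target, rng):
                # fall back to the other box
                other = (
                    range(hit.pos35 - 1, hit.pos35 + 5)
                    if planted is None
                    else range(hit.pos10 - 1, hit.pos10 + 5)
                )
                if not _degrade_window(ws, other, rng):
                    raise GenerationError(f"cannot scrub accidental promoter at {hit.pos10}")
            dirty = True
        if dirty:
            continue

        for cand in find_terminators(genome) if truth.terminators else []:
            if any(_overlap_frac(cand.start, cand.end, s, e) >= 0.5 for s, e in planted_term):
                continue
            window = range(cand.start - 1, cand.end - 8)
            if not _degrade_window(ws, window, rng):
                raise GenerationError(f"cannot scrub accidental terminator at {cand.start}")
            dirty = True
        if dirty:
            continue

        for pattern in sorted(site_patterns):
            for hit in scan_pattern(genome, pattern, 0, "both"):
                if (pattern, hit.position) in planted_sites:
                    continue
                if not _degrade_site(ws, hit, pattern, rng):
                    raise GenerationError(
                        f"cannot scrub accidental {pattern} site at {hit.position}"
                    )
                dirty = True
        if not dirty:
            return
    raise GenerationError("background scrub did not converge; try another seed")


def _overlap_frac(a1: int, a2: int, b1: int, b2: int) -> float:
    inter = min(a2, b2) - max(a1, b1) + 1
    return max(0, inter) / (b2 - b1 + 1)


def _kill_orf(ws: _Workspace, orf: CdsFeature, rng: np.random.Generator) -> bool:
    """Insert a stop codon into an accidental ORF's frame."""
    n_codons = (orf.end - orf.start + 1) // 3
    ks = list(range(1, n_codons - 1))
    rng.shuffle(ks)
    stops = STOPS if orf.strand == "+" else REV_STOPS
    for k in ks:
        if orf.strand == "+":
            pos0 = orf.start - 1 + 3 * k
        else:
            pos0 = orf.end - 1 - 3 * k - 2
        for stop in stops:
            if ws.safe_write(pos0, stop):
                return True
    return False


def _degrade_window(ws: _Workspace, window0, rng: np.random.Generator) -> bool:
    """Flip one base inside a 0-based window to any different base."""
    positions = list(window0)
    rng.shuffle(positions)
    for pos0 in positions:
        if pos0 < 0 or pos0 >= len(ws.seq):
            continue
        current = ws.seq[pos0]
        choices = [b for b in "ACGT" if b != current]
        rng.shuffle(choices)
        for b in choices:
            if ws.safe_write(pos0, b):
                return True
    return False


def _degrade_site(ws: _Workspace, hit: MotifHit, pattern: str, rng: np.random.Generator) -> bool:
    """Break one position of an accidental recognition-site match."""
    pat = pattern.upper() if hit.strand == "+" else reverse_complement(pattern)
    offsets = list(range(len(pat)))
    rng.shuffle(offsets)
    for off in offsets:
        pos0 = hit.position - 1 + off
        allowed = IUPAC_SETS[pat[off]]
        choices = [b for b in "ACGT" if b not in allowed]
        rng.shuffle(choices)
        for b in choices:
            if ws.safe_write(pos0, b):
                return True
    return False


# ---------------------------------------------------------------------------
# recovery scoring


def _match_counts(planted, called, is_match) -> Tuple[int, int]:
    matched_planted = sum(1 for p in planted if any(is_match(p, c) for c in called))
    matched_called = sum(1 for c in called if any(is_match(p, c) for p in planted))
    return matched_planted, matched_called


def recovery_report(outputs: Dict[str, Sequence], truth: GroundTruth) -> pd.DataFrame:
    """Sensitivity/precision per feature class against the planted ledger.

    ``outputs`` maps class name -> called features and must carry
    ``genome_id``. Matching: exact interval+strand for CDSs, exact positions
    for promoter boxes and restriction sites, >=50% overlap of the planted
    span for terminators.
    """
    if outputs.get("genome_id") != truth.genome_id:
        raise GenerationError(
            f"outputs for {outputs.get('genome_id')!r} scored against ledger "
            f"for {truth.genome_id!r}"
        )
    rows = []

    def add(name, planted, called, is_match):
        mp, mc = _match_counts(planted, called, is_match)
        rows.append(
            {
                "feature_class": name,
                "n_planted": len(planted),
                "n_called": len(called),
                "sensitivity": mp / len(planted) if planted else float("nan"),
                "precision": mc / len(called) if called else float("nan"),
            }
        )

    if "cds" in outputs:
        add(
            "cds",
            truth.cds,
            outputs["cds"],
            lambda p, c: (p.start, p.end, p.strand) == (c.start, c.end, c.strand),
        )
    if "promoters" in outputs:
        add(
            "promoters",
            truth.promoters,
            outputs["promoters"],
            lambda p, c: (p.pos35, p.pos10) == (c.pos35, c.pos10),
        )
    if "terminators" in outputs:
        add(
            "terminators",
            truth.terminators,
            outputs["terminators"],
            lambda p, c: _overlap_frac(c.start, c.end, p.start, p.end) >= 0.5,
        )
    if "sites" in outputs:
        add(
            "sites",
            truth.sites,
            outputs["sites"],
            lambda p, c: p.position == c.position,
        )
    return pd.DataFrame(rows)
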