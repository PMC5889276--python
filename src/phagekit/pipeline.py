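"""Full characterization run: every analysis stage plus a JSON summary.

Outputs are deterministic for a given genome and config: stable sort
orders, fixed float formats, and a config hash embedded in every file.
"""

from __future__ import annotations

import hashlib
import json
import os
import shutil
from dataclasses import asdict, dataclass, field
from typing import Dict, Optional, Tuple

import pandas as pd
import yaml

from . import __version__
from .composition import extreme_regions, global_gc, windowed_profile
from .genome_io import GenomeRecord, read_fasta, write_gff3
from .motifs import RESTRICTION_PATTERNS, find_promoters, screen_patterns
from .orfs import find_orfs, packing_profile
from .proteins import cds_table
from .terminators import find_terminators


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """All stage parameters with the published defaults."""

    min_mass_kda: float = 4.0
    start_codons: Tuple[str, ...] = ("ATG", "GTG", "TTG")
    orf_strands: str = "both"
    box35: str = "TTGACA"
    box10: str = "TATAAT"
    spacer_range: Tuple[int, int] = (15, 18)
    max_total_mismatch: int = 2
    promoter_strand: str = "forward"
    stem_range: Tuple[int, int] = (4, 30)
    loop_range: Tuple[int, int] = (3, 10)
    max_mismatch_in_stem: int = 1
    dg_threshold: float = -8.0
    min_u_score: float = 0.5
    tail_len: int = 8
    window: int = 500
    step: int = 100
    gc_high: float = 0.62
    gc_low: float = 0.28
    patterns: Dict[str, str] = field(default_factory=lambda: dict(RESTRICTION_PATTERNS))
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise PipelineError("config", f"unknown config keys: {sorted(unknown)}")
        for key in ("start_codons", "spacer_range", "stem_range", "loop_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: str, provenance: str) -> None:
    with open(path, "w") as handle:
        handle.write(provenance)
        df.to_csv(handle, sep="\t", index=False)


def run_pipeline(
    genome_path: str,
    out_dir: str,
    config: Optional[RunConfig] = None,
) -> Dict:
    """Run every stage on one genome; returns the summary dict.

    Emits genome.gff3, cds_table.tsv, restriction_counts.tsv, promoters.tsv,
    terminators.tsv, composition.tsv and summary.json into ``out_dir``.
    Any stage error removes partial outputs and raises
    :class:`PipelineError` naming the stage.
    """
    config = config or RunConfig()
    os.makedirs(out_dir, exist_ok=True)
    written = []
    provenance = f"# phagekit {__version__} config={config.digest()}\n"

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            for path in written:
                if os.path.exists(path):
                    os.remove(path)
            raise PipelineError(name, str(exc)) from exc

    genome = stage("read_genome", lambda: _single_record(genome_path))

    cds = stage(
        "orf_calling",
        lambda: find_orfs(
            genome,
            min_mass_kda=config.min_mass_kda,
            start_codons=config.start_codons,
            strands=config.orf_strands,
        ),
    )
    strand_counts, gaps, n_overlaps, max_gap = stage(
        "packing", lambda: packing_profile(cds) if cds else ({}, [], 0, None)
    )
    promoters = stage(
        "promoters",
        lambda: find_promoters(
            genome,
            box35=config.box35,
            box10=config.box10,
            spacer_range=config.spacer_range,
            max_total_mismatch=config.max_total_mismatch,
            strand=config.promoter_strand,
        ),
    )
    terminators = stage(
        "terminators",
        lambda: find_terminators(
            genome,
            stem_range=config.stem_range,
            loop_range=config.loop_range,
            max_mismatch_in_stem=config.max_mismatch_in_stem,
            dg_threshold=config.dg_threshold,
            min_u_score=config.min_u_score,
            tail_len=config.tail_len,
        ),
    )
    site_counts = stage("restriction", lambda: screen_patterns(genome, config.patterns))
    gc = stage("composition", lambda: global_gc(genome))
    profile = stage("composition", lambda: windowed_profile(genome, config.window, config.step))
    extremes = stage(
        "composition", lambda: extreme_regions(profile, config.gc_high, config.gc_low)
    )

    # -- serialize ----------------------------------------------------------
    def out(name):
        path = os.path.join(out_dir, name)
        written.append(path)
        return path

    table = cds_table(cds)
    _write_tsv(table, out("cds_table.tsv"), provenance)

    restr = pd.DataFrame(
        [
            {"name": name, "pattern": pat, "sites": count}
            for name, (pat, count) in sorted(site_counts.items())
        ]
    )
    _write_tsv(restr, out("restriction_counts.tsv"), provenance)

    prom = pd.DataFrame(
        [
            {
                "pos35": p.pos35,
                "pos10": p.pos10,
                "spacer": p.spacer,
                "mm35": p.mm35,
                "mm10": p.mm10,
                "mm_total": p.mm_total,
                "strand": p.strand,
            }
            for p in promoters
        ],
        columns=["pos35", "pos10", "spacer", "mm35", "mm10", "mm_total", "strand"],
    )
    _write_tsv(prom, out("promoters.tsv"), provenance)

    term = pd.DataFrame(
        [
            {
                "start": t.start,
                "end": t.end,
                "stem_len": t.stem_len,
                "loop_len": t.loop_len,
                "dg_stem": f"{t.dg_stem:.2f}",
                "u_score": f"{t.u_score:.3f}",
                "strand": t.strand,
            }
            for t in terminators
        ],
        columns=["start", "end", "stem_len", "loop_len", "dg_stem", "u_score", "strand"],
    )
    _write_tsv(term, out("terminators.tsv"), provenance)

    comp = profile.to_frame()
    comp["gc"] = comp["gc"].map(lambda v: f"{v:.4f}")
    comp["skew"] = comp["skew"].map(lambda v: f"{v:.4f}")
    _write_tsv(comp, out("composition.tsv"), provenance)

    stage(
        "gff3",
        lambda: write_gff3(genome, list(cds) + list(promoters) + list(terminators), out("genome.gff3")),
    )

    summary = {
        "tool": f"phagekit {__version__}",
        "config_hash": config.digest(),
        "genome_id": genome.id,
        "length_bp": genome.length,
        "gc_percent": round(gc * 100, 1),
        "n_cds": len(cds),
        "strand_counts": strand_counts,
        "n_overlaps": n_overlaps,
        "max_gap": (
            {
                "upstream": max_gap.upstream_label,
                "downstream": max_gap.downstream_label,
                "gap_nt": max_gap.gap_nt,
            }
            if max_gap
            else None
        ),
        "n_promoters": len(promoters),
        "n_terminators": len(terminators),
        "restriction_sites": {name: count for name, (_, count) in sorted(site_counts.items())},
        "gc_extreme_regions": [
            {"center": r.center, "kind": r.kind, "gc": round(r.gc, 4)} for r in extremes
        ],
    }
    with open(out("summary.json"), "w") as handle:
        json.dump(summary, handle, indent=1, sort_keys=True)
        handle.write("\n")
    return summary


def _single_record(path: str) -> GenomeRecord:
    records = read_fasta(path)
    if len(records) != 1:
        raise ValueError(f"expected exactly one sequence, found {len(records)}")
    return records[0]
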