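"""GC content, sliding-window profiles, GC skew, and extreme-region calls."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
import pandas as pd

from .genome_io import GenomeRecord

logger = logging.getLogger(__name__)


class CompositionError(ValueError):
    pass


@dataclass
class WindowProfile:
    """Per-window GC fraction and GC skew along a genome.

    ``centers`` are 1-based window centers (``floor((start+end)/2)``);
    windows with no G or C carry skew 0 and are listed in
    ``zero_gc_windows``.
    """

    window: int
    step: int
    centers: List[int]
    gc: List[float]
    skew: List[float]
    zero_gc_windows: List[int] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"center": self.centers, "gc": self.gc, "skew": self.skew})


@dataclass(frozen=True)
class ExtremeRegion:
    """A maximal run of windows beyond a GC threshold, at its extremal center."""

    center: int
    kind: str  # "high" | "low"
    gc: float


def _base_counts(seq: str) -> Tuple[int, int, int, int, int]:
    a, c, g, t = seq.count("A"), seq.count("C"), seq.count("G"), seq.count("T")
    return a, c, g, t, len(seq) - a - c - g - t


def global_gc(genome: GenomeRecord) -> float:
    """(G+C)/(A+C+G+T) over the whole sequence; ambiguity letters excluded."""
    a, c, g, t, amb = _base_counts(genome.seq)
    denom = a + c + g + t
    if denom == 0:
        raise CompositionError("sequence contains no unambiguous bases")
    if amb > 0.001 * genome.length:
        logger.warning(
            "%s: %d ambiguous positions (>0.1%%) excluded from GC", genome.id, amb
        )
    return (g + c) / denom


def windowed_profile(genome: GenomeRecord, window: int = 500, step: int = 100) -> WindowProfile:
    """Sliding-window GC and skew ``(G-C)/(G+C)`` on the forward strand."""
    if window < 1 or step < 1:
        raise CompositionError("window and step must be >= 1")
    if window > genome.length:
        raise CompositionError(
            f"window {window} exceeds genome length {genome.length}"
        )
    seq = np.frombuffer(genome.seq.encode(), dtype=np.uint8)
    is_g = (seq == ord("G")).astype(np.int64)
    is_c = (seq == ord("C")).astype(np.int64)
    is_acgt = np.isin(seq, [ord(b) for b in "ACGT"]).astype(np.int64)
    cg = np.concatenate([[0], np.cumsum(is_g)])
    cc = np.concatenate([[0], np.cumsum(is_c)])
    cn = np.concatenate([[0], np.cumsum(is_acgt)])

    centers, gc, skew, zero_windows = [], [], [], []
    for start0 in range(0, genome.length - window + 1, step):
        end0 = start0 + window  # exclusive
        g = int(cg[end0] - cg[start0])
        c = int(cc[end0] - cc[start0])
        n = int(cn[end0] - cn[start0])
        center = (start0 + 1 + end0) // 2  # 1-based floor((start+end)/2)
        centers.append(center)
        gc.append((g + c) / n if n else 0.0)
        if g + c == 0:
            skew.append(0.0)
            zero_windows.append(center)
        else:
            skew.append((g - c) / (g + c))
    return WindowProfile(window, step, centers, gc, skew, zero_windows)


def extreme_regions(profile: WindowProfile, high: float = 0.62, low: float = 0.28) -> List[ExtremeRegion]:
    """Collapse runs of beyond-threshold windows to single extreme regions.

    Consecutive windows with gc >= ``high`` (or <= ``low``) form one region
    reported at the center of the most extreme window in the run (ties to
    the earliest window). Sorted by center.
    """
    if not profile.centers:
        raise CompositionError("empty profile")
    regions: List[ExtremeRegion] = []
    for kind, beyond in (
        ("high", [v >= high for v in profile.gc]),
        ("low", [v <= low for v in profile.gc]),
    ):
        i = 0
        n = len(beyond)
        while i < n:
            if not beyond[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and beyond[j + 1]:
                j += 1
            run = range(i, j + 1)
            if kind == "high":
                best = max(run, key=lambda k: (profile.gc[k], -k))
            else:
                best = min(run, key=lambda k: (profile.gc[k], k))
            regions.append(ExtremeRegion(profile.centers[best], kind, profile.gc[best]))
            i = j + 1
    regions.sort(key=lambda r: r.center)
    return regions


def plot_profile(profile: WindowProfile, path: str, title: str = "") -> None:
    """Two-track GC / GC-skew plot (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(10, 5))
    ax1.plot(profile.centers, [v * 100 for v in profile.gc], lw=0.8, color="tab:blue")
    ax1.set_ylabel("GC (%)")
    ax2.plot(profile.centers, profile.skew, lw=0.8, color="tab:orange")
    ax2.set_ylabel("(G-C)/(G+C)")
    ax2.set_xlabel("position (bp)")
    if title:
        ax1.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
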