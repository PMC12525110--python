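"""Sliding-window CpG-island detection and island excision.

A CpG island here is a run of 1000 bp windows (500 bp step) with
G+C fraction >= 0.5 and CpG observed/expected ratio >= 0.6, where

    O/E = (N_CG * W) / (N_C * N_G)

(the Gardiner–Garden ratio; W = window length, N_CG the number of CG
dinucleotides fully inside the window).  Qualifying windows are merged
into maximal intervals.  Windows containing N are skipped; the final
partial window is evaluated at its actual length.

An optional BED exclusion mask lets callers drop intervals that overlap
externally annotated regions (e.g. short intra-genic fragments); no gene
annotation is bundled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._encoding import seq_to_codes, N_CODE, kmer_to_index
from .genome_io import GenomeSequence, GenomeSet, excise_intervals

DEFAULT_WINDOW = 1000
DEFAULT_STEP = 500
DEFAULT_GC_MIN = 0.5
DEFAULT_OE_MIN = 0.6

_C = kmer_to_index("C")
_G = kmer_to_index("G")


@dataclass
class WindowStats:
    start: int
    end: int
    gc_fraction: float
    oe_ratio: float


@dataclass
class IslandAnnotation:
    intervals: list[tuple[int, int]]
    params: dict = field(default_factory=dict)


def window_stats(g: GenomeSequence, window: int = DEFAULT_WINDOW,
                 step: int = DEFAULT_STEP) -> list[WindowStats]:
    """GC fraction and CpG O/E for each sliding window of the sequence."""
    if window < 2:
        raise ValueError("window must be >= 2")
    if step < 1:
        raise ValueError("step must be >= 1")
    codes = seq_to_codes(g.residues)
    L = len(codes)
    is_c = np.concatenate(([0], np.cumsum(codes == _C)))
    is_g = np.concatenate(([0], np.cumsum(codes == _G)))
    is_n = np.concatenate(([0], np.cumsum(codes == N_CODE)))
    cg = (codes[:-1] == _C) & (codes[1:] == _G) if L > 1 else np.zeros(0, bool)
    cg_cs = np.concatenate(([0], np.cumsum(cg)))
    out: list[WindowStats] = []
    for start in range(0, max(L - 1, 1), step):
        end = min(start + window, L)
        if end - start < 2:
            break
        if is_n[end] - is_n[start] > 0:
            continue
        w = end - start
        n_c = int(is_c[end] - is_c[start])
        n_g = int(is_g[end] - is_g[start])
        n_cg = int(cg_cs[end - 1] - cg_cs[start])   # CG starts in [start, end-1)
        gc = (n_c + n_g) / w
        oe = (n_cg * w) / (n_c * n_g) if n_c * n_g > 0 else 0.0
        out.append(WindowStats(start=start, end=end, gc_fraction=gc, oe_ratio=oe))
        if end == L:
            break
    return out


def call_islands(stats: list[WindowStats], gc_min: float = DEFAULT_GC_MIN,
                 oe_min: float = DEFAULT_OE_MIN,
                 exclude: list[tuple[int, int]] | None = None) -> IslandAnnotation:
    """Retain windows with gc >= gc_min and O/E >= oe_min (inclusive
    thresholds) and merge overlapping/adjacent windows into intervals.

    ``exclude`` drops any merged interval overlapping a masked span.
    """
    keep = [(w.start, w.end) for w in stats
            if w.gc_fraction >= gc_min and w.oe_ratio >= oe_min]
    merged: list[tuple[int, int]] = []
    for start, end in sorted(keep):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    if exclude:
        merged = [(s, e) for s, e in merged
                  if not any(s < me and ms < e for ms, me in exclude)]
    return IslandAnnotation(
        intervals=merged,
        params={"gc_min": gc_min, "oe_min": oe_min},
    )


def remove_islands(g: GenomeSequence, annotation: IslandAnnotation) -> GenomeSet:
    """Excise island intervals; complement segments stay separate so no
    k-mer window spans an excision junction."""
    return excise_intervals(g, annotation.intervals)
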