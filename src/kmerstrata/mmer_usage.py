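"""Genome-weighted relative frequency of m-mers inside 8-mer sets.

Each 8-mer contains 8 − m + 1 overlapping m-mer windows.  Weighting
each member 8-mer i by its genome occurrence count H_i, the relative
frequency of an m-mer over a set S is

    RF = 4^m / (8 − m + 1) · Σ_{i∈S} N_mi·H_i / Σ_{i∈S} H_i

where N_mi is the overlap-counted number of times the m-mer occurs
inside 8-mer i.  The 4^m scaling fixes the mean RF over all m-mers at
exactly 1 (Σ RF = 4^m), because every 8-mer contributes exactly
8 − m + 1 m-mer windows.  RF below 1 marks depleted sub-motifs (CG-rich
ones in real genomes), above 1 enriched ones (A/T runs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._encoding import index_to_kmer
from .kmer_spectrum import KmerCountTable
from .stratification import K, StratumSpec


@dataclass
class MmerRFProfile:
    """RF vector over all 4^m m-mers for one 8-mer set."""

    m: int
    rf: np.ndarray              # float64, length 4**m
    source: str                 # stratum label or "overall"

    def as_series(self):
        import pandas as pd
        return pd.Series(self.rf, index=[index_to_kmer(i, self.m)
                                         for i in range(4**self.m)])


@dataclass(frozen=True)
class UsagePair:
    """One m-mer's RF in the overall set (q) vs in a stratum (p)."""

    mmer: int
    q: float
    p: float


def _window_indices(members: np.ndarray, m: int) -> list[np.ndarray]:
    """m-mer index of each of the 8−m+1 windows of every member 8-mer."""
    mask = 4**m - 1
    return [
        (members >> (2 * (K - j - m))) & mask
        for j in range(K - m + 1)
    ]


def mmer_rf(table: KmerCountTable,
            stratum: StratumSpec | np.ndarray | list | None, m: int
            ) -> MmerRFProfile:
    """Evaluate the weighted m-mer relative frequency over a set of
    8-mers: a stratum, an explicit index array, or the full universe
    (``stratum=None``)."""
    if table.k != K:
        raise ValueError(f"m-mer usage is defined over 8-mers, table has k={table.k}")
    if not 1 <= m <= K - 1:
        raise ValueError(f"m must be in [1, {K - 1}], got {m}")
    if stratum is None:
        members = np.arange(4**K, dtype=np.int64)
        label = "overall"
    elif isinstance(stratum, StratumSpec):
        members = stratum.members
        label = stratum.label
    else:
        members = np.asarray(stratum, dtype=np.int64)
        label = "custom"
    weights = table.counts[members].astype(np.float64)
    total = weights.sum()
    if total <= 0:
        raise ValueError(f"set {label!r} has zero total genome weight")
    acc = np.zeros(4**m, dtype=np.float64)
    for win in _window_indices(members, m):
        acc += np.bincount(win, weights=weights, minlength=4**m)
    rf = (4**m / (K - m + 1)) * acc / total
    return MmerRFProfile(m=m, rf=rf, source=label)


def usage_pairs(overall: MmerRFProfile, stratum: MmerRFProfile) -> list[UsagePair]:
    """Index-aligned (q, p) scatter pairs for diagonal-deviation analysis."""
    if overall.m != stratum.m:
        raise ValueError(f"m mismatch: {overall.m} vs {stratum.m}")
    return [UsagePair(mmer=i, q=float(q), p=float(p))
            for i, (q, p) in enumerate(zip(overall.rf, stratum.rf))]
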