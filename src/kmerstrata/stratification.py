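"""Partition of the 8-mer universe by dinucleotide content.

Every 8-mer contains 7 overlapping dinucleotide windows.  For a chosen
dinucleotide XY the universe splits into three strata: motifs with no
occurrence of XY (0XY), exactly one (1XY), and two or more (2XY).
Occurrences are counted with overlap, so "AAA" holds two AA windows —
the convention under which the X = Y strata differ in size from the
X != Y ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from ._encoding import ALPHABET, all_kmer_base_matrix, index_to_kmer, kmer_to_index
from .kmer_spectrum import FASpectrum, KmerCountTable, fa_spectrum

K = 8
DINUCLEOTIDES = tuple(a + b for a in ALPHABET for b in ALPHABET)
OCCUPANCY_CLASSES = ("0", "1", "2+")


@dataclass(frozen=True)
class StratumSpec:
    """One occupancy class of one dinucleotide: a subset of the universe."""

    dinucleotide: str
    occupancy_class: str        # "0", "1" or "2+"
    members: np.ndarray         # sorted int64 8-mer indices

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def label(self) -> str:
        cls = self.occupancy_class.rstrip("+")
        return f"{cls}{self.dinucleotide}"


def _check_dinucleotide(xy: str) -> str:
    xy = xy.upper()
    if len(xy) != 2 or any(c not in ALPHABET for c in xy):
        raise ValueError(f"not a dinucleotide: {xy!r}")
    return xy


@lru_cache(maxsize=None)
def _occurrence_vector(xy: str) -> np.ndarray:
    """Overlap-counted occurrences of xy in every 8-mer (length 4^8)."""
    bases = all_kmer_base_matrix(K)
    x = kmer_to_index(xy[0])
    y = kmer_to_index(xy[1])
    occ = np.zeros(4**K, dtype=np.int8)
    for j in range(K - 1):
        occ += ((bases[:, j] == x) & (bases[:, j + 1] == y)).astype(np.int8)
    return occ


def dinucleotide_occurrences(motif: int | str, xy: str) -> int:
    """Number of overlapping occurrences of dinucleotide xy in an 8-mer."""
    xy = _check_dinucleotide(xy)
    if isinstance(motif, str):
        if len(motif) != K:
            raise ValueError(f"motif must be an 8-mer, got {motif!r}")
        motif = kmer_to_index(motif)
    if not 0 <= motif < 4**K:
        raise ValueError(f"8-mer index {motif} out of range")
    return int(_occurrence_vector(xy)[motif])


def build_strata(xy: str) -> tuple[StratumSpec, StratumSpec, StratumSpec]:
    """Exhaustive 0XY/1XY/2XY classification of all 65,536 8-mers."""
    xy = _check_dinucleotide(xy)
    occ = _occurrence_vector(xy)
    return (
        StratumSpec(xy, "0", np.flatnonzero(occ == 0).astype(np.int64)),
        StratumSpec(xy, "1", np.flatnonzero(occ == 1).astype(np.int64)),
        StratumSpec(xy, "2+", np.flatnonzero(occ >= 2).astype(np.int64)),
    )


def stratum_spectrum(table: KmerCountTable, stratum: StratumSpec) -> FASpectrum:
    """FA spectrum restricted to a stratum (denominator stays 4^8)."""
    if table.k != K:
        raise ValueError(f"stratification is defined for k={K}, table has k={table.k}")
    return fa_spectrum(table, universe=stratum.members)


def stratum_members_as_kmers(stratum: StratumSpec, limit: int | None = None) -> list[str]:
    idx = stratum.members if limit is None else stratum.members[:limit]
    return [index_to_kmer(int(i), K) for i in idx]
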