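"""k-mer occurrence counting and frequency-of-appearance (FA) spectra.

The FA spectrum of a genome answers, for every appearance count x, what
fraction of the 4^k motif universe occurs exactly x times:

    FA(x) = N_x / 4^k

where N_x is the number of k-mers whose genome-wide occurrence count is
exactly x.  Plotted against x this is the k-mer spectrum; the human
genome's spectrum at k = 8 is famously trimodal while yeast's is a
single positively skewed Poisson-like mode.

Counting is single-strand and strand-specific — complementary motifs are
separate universe members — and windows containing N are skipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._encoding import N_CODE, index_to_kmer, seq_to_codes
from .genome_io import GenomeSequence, GenomeSet


@dataclass
class KmerCountTable:
    """Occurrence count H for every k-mer index in [0, 4^k)."""

    k: int
    counts: np.ndarray          # int64, length 4**k
    windows_counted: int

    def __post_init__(self) -> None:
        if self.counts.shape != (4**self.k,):
            raise ValueError(f"counts must have length 4**{self.k}")

    @property
    def universe_size(self) -> int:
        return 4**self.k


@dataclass
class FASpectrum:
    """Eq-style FA distribution over appearance counts.

    ``n_x[x]`` is the number of universe members with count exactly x
    (x = 0 records nullomers/absent motifs); ``fa`` divides by the full
    4^k denominator regardless of the universe being a stratum.
    """

    k: int
    universe_size: int
    n_x: np.ndarray             # int64, index = appearance count x

    @property
    def denominator(self) -> int:
        return 4**self.k

    @property
    def fa(self) -> np.ndarray:
        return self.n_x / self.denominator

    @property
    def max_count(self) -> int:
        return len(self.n_x) - 1

    def dense_curve(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, FA) on the dense grid x = 1..max_count (nullomers excluded)."""
        x = np.arange(1, len(self.n_x))
        return x, self.fa[1:]


@dataclass
class SmoothedCurve:
    """Moving-average-smoothed spectrum (valid-window convention)."""

    x: np.ndarray
    y: np.ndarray
    window: int
    passes: int

    def config(self) -> tuple[int, int]:
        return (self.window, self.passes)


def _count_one(codes: np.ndarray, k: int, counts: np.ndarray) -> int:
    """Accumulate k-mer indices of one sequence into ``counts``; returns
    the number of valid (N-free) windows."""
    n = len(codes) - k + 1
    if n <= 0:
        return 0
    idx = np.zeros(n, dtype=np.int64)
    for j in range(k):
        idx += codes[j:j + n].astype(np.int64) << (2 * (k - 1 - j))
    is_n = (codes == N_CODE).astype(np.int64)
    cs = np.concatenate(([0], np.cumsum(is_n)))
    bad = (cs[k:] - cs[:-k]) > 0
    valid = idx[~bad]
    counts += np.bincount(valid, minlength=len(counts))
    return int(valid.size)


def count_kmers(genome: GenomeSet | GenomeSequence | str, k: int) -> KmerCountTable:
    """Count every N-free length-k window on the given strand.

    Multi-sequence inputs are counted per sequence and summed; windows
    never span sequence boundaries.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(genome, str):
        genome = GenomeSet([GenomeSequence(id="seq", residues=genome)])
    elif isinstance(genome, GenomeSequence):
        genome = GenomeSet([genome])
    if not len(genome):
        raise ValueError("empty genome")
    counts = np.zeros(4**k, dtype=np.int64)
    windows = 0
    for seq in genome:
        windows += _count_one(seq_to_codes(seq.residues), k, counts)
    if windows == 0:
        warnings.warn(f"k={k} exceeds every sequence length; empty count table")
    return KmerCountTable(k=k, counts=counts, windows_counted=windows)


def fa_spectrum(table: KmerCountTable,
                universe: np.ndarray | None = None) -> FASpectrum:
    """FA distribution of a k-mer universe (full set or a stratum).

    The denominator stays 4^k even when ``universe`` is a subset, so a
    stratum's FA values sum to |stratum|/4^k rather than 1.
    """
    if universe is None:
        members = table.counts
    else:
        universe = np.asarray(universe, dtype=np.int64)
        if universe.size == 0:
            raise ValueError("empty universe")
        members = table.counts[universe]
    n_x = np.bincount(members)
    return FASpectrum(k=table.k, universe_size=int(len(members)), n_x=n_x)


def smooth(spectrum: FASpectrum | SmoothedCurve, window: int = 10,
           passes: int = 1) -> SmoothedCurve:
    """Centered moving average on the dense x-grid, valid windows only.

    x = 0 (nullomers) is excluded before smoothing.  Each pass shortens
    the curve by window − 1 points and re-centers x; for even windows the
    center is taken just left of the half-integer midpoint so x stays on
    the integer grid.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if isinstance(spectrum, SmoothedCurve):
        x, y = spectrum.x, spectrum.y
        prior_passes = spectrum.passes
    else:
        x, y = spectrum.dense_curve()
        prior_passes = 0
    for _ in range(passes):
        if window > len(y):
            raise ValueError(f"window {window} exceeds curve length {len(y)}")
        if window > 1:
            y = np.convolve(y, np.full(window, 1.0 / window), mode="valid")
            lo = (window - 1) // 2
            x = x[lo:lo + len(y)]
    return SmoothedCurve(x=x, y=y, window=window, passes=prior_passes + passes)


def extreme_kmers(table: KmerCountTable, n_low: int, n_high: int
                  ) -> tuple[list[str], list[str], list[str]]:
    """Least- and most-frequent motifs, plus nullomers.

    Returns (lowest n_low motifs with count >= 1, highest n_high motifs,
    nullomer list); ties broken lexicographically (index order).
    """
    counts = table.counts
    nonzero = np.flatnonzero(counts)
    if nonzero.size == 0:
        raise ValueError("count table is empty")
    order_low = nonzero[np.argsort(counts[nonzero], kind="stable")]
    # descending count, ascending index on ties
    order_high = nonzero[np.lexsort((nonzero, -counts[nonzero]))]
    nullomers = np.flatnonzero(counts == 0)
    k = table.k
    low = [index_to_kmer(int(i), k) for i in order_low[:n_low]]
    high = [index_to_kmer(int(i), k) for i in order_high[:n_high]]
    nulls = [index_to_kmer(int(i), k) for i in nullomers]
    return low, high, nulls


def gc_fraction_of_kmers(kmers: list[str]) -> float:
    """Mean G+C fraction of a motif list (diagnostic for extreme motifs)."""
    if not kmers:
        raise ValueError("empty motif list")
    total = sum(m.count("G") + m.count("C") for m in kmers)
    return total / sum(len(m) for m in kmers)
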