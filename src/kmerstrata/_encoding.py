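"""2-bit nucleotide encoding shared across modules.

A = 0, C = 1, G = 2, T = 3; a k-mer index is the base-4 number whose
most-significant digit is the first base.  N (assembly gap) is carried as
the sentinel code 4 and windows containing it are skipped by counters.
"""

from __future__ import annotations

import numpy as np

ALPHABET = "ACGT"
N_CODE = 4

_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(ALPHABET):
    _CODE_LUT[ord(_b)] = _i
    _CODE_LUT[ord(_b.lower())] = _i
_CODE_LUT[ord("N")] = N_CODE
_CODE_LUT[ord("n")] = N_CODE

_CHAR_LUT = np.frombuffer(b"ACGTN", dtype=np.uint8)


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode a residue string to uint8 codes (A=0..T=3, N=4).

    Raises ValueError naming the first illegal character and its offset.
    """
    raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    codes = _CODE_LUT[raw]
    bad = np.flatnonzero(codes == 255)
    if bad.size:
        off = int(bad[0])
        raise ValueError(
            f"illegal residue {seq[off]!r} at offset {off} (expected A/C/G/T/N)"
        )
    return codes


def codes_to_seq(codes: np.ndarray) -> str:
    return _CHAR_LUT[codes].tobytes().decode("ascii")


def kmer_to_index(kmer: str) -> int:
    """Base-4 index of a k-mer, first base most significant."""
    idx = 0
    for ch in kmer.upper():
        pos = ALPHABET.find(ch)
        if pos < 0:
            raise ValueError(f"non-ACGT base {ch!r} in k-mer {kmer!r}")
        idx = (idx << 2) | pos
    return idx


def index_to_kmer(idx: int, k: int) -> str:
    if not 0 <= idx < 4**k:
        raise ValueError(f"index {idx} out of range for k={k}")
    out = []
    for shift in range(2 * (k - 1), -1, -2):
        out.append(ALPHABET[(idx >> shift) & 3])
    return "".join(out)


def all_kmer_base_matrix(k: int) -> np.ndarray:
    """(4**k, k) uint8 matrix of the base codes of every k-mer index."""
    idx = np.arange(4**k, dtype=np.int64)
    cols = [((idx >> (2 * (k - 1 - j))) & 3).astype(np.uint8) for j in range(k)]
    return np.stack(cols, axis=1)
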