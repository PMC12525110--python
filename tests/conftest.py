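import numpy as np
import pytest

import kmerstrata as ks
from kmerstrata.synthetic_data import base_probs_from_gc

# Study conditions for the qualitative synthetic checks: 10 Mb, yeast-like
# composition (GC 0.38), CpG odds 0.25, seed 1.
SUPPRESSED = dict(length=10_000_000, base_probs=base_probs_from_gc(0.38),
                  cg_odds=0.25, seed=1)


@pytest.fixture(scope="session")
def suppressed_genome():
    """10 Mb CpG-suppressed Markov genome (the stratified-spectrum fixture)."""
    return ks.gen_markov(ks.SyntheticGenomeSpec(**SUPPRESSED))


@pytest.fixture(scope="session")
def suppressed_table(suppressed_genome):
    return ks.count_kmers(suppressed_genome, 8)


@pytest.fixture(scope="session")
def uniform_10mb_table():
    """8-mer counts of a 10 Mb uniform i.i.d. genome (Poisson control)."""
    g = ks.gen_iid(ks.SyntheticGenomeSpec(length=10_000_000, seed=2))
    return ks.count_kmers(g, 8)


@pytest.fixture(scope="session")
def cg_strata():
    return ks.build_strata("CG")


def naive_kmer_counts(seq: str, k: int) -> dict[str, int]:
    """Brute-force sliding-window oracle: count every N-free window."""
    out: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        w = seq[i:i + k]
        if "N" not in w:
            out[w] = out.get(w, 0) + 1
    return out


def naive_overlap_count(s: str, sub: str) -> int:
    """Overlap-counted occurrences of ``sub`` in ``s``."""
    return sum(1 for i in range(len(s) - len(sub) + 1) if s[i:i + len(sub)] == sub)


def random_sequence(rng: np.random.Generator, length: int,
                    with_n: bool = False) -> str:
    bases = "ACGTN" if with_n else "ACGT"
    probs = [0.23, 0.23, 0.23, 0.23, 0.08] if with_n else None
    return "".join(rng.choice(list(bases), size=length, p=probs))
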