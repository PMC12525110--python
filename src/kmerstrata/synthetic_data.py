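"""Seeded synthetic genomes with controllable CpG statistics.

Three generators emulate the statistical structure the spectrum analysis
assumes about real genomes:

* ``gen_iid`` — i.i.d. draws from a base composition, the "random
  sequence with matched length and G+C content" control against which
  real spectra are compared;
* ``gen_markov`` — a first-order Markov chain equal to the i.i.d. chain
  except that the C→G transition probability is set to q_G·cg_odds, the
  removed mass redistributed proportionally over the other targets of
  the C row.  This models CpG suppression (deamination of methylated
  cytosine); the stationary CpG observed/expected ratio is
  cg_odds / (1 − π_C·(1 − cg_odds)), close to cg_odds for moderate
  compositions, and ``expected_cg_oe`` computes it exactly.
* ``embed_islands`` — replaces chosen spans with GC-rich, non-suppressed
  Markov material, returning ground-truth intervals for island-caller
  tests.

All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._encoding import codes_to_seq
from .genome_io import GenomeSequence

_A, _C, _G, _T = 0, 1, 2, 3


@dataclass(frozen=True)
class IslandSpec:
    """One embedded island: where it goes and how CG-rich it is."""

    position: int
    length: int
    island_gc: float = 0.65
    island_cg_odds: float = 1.0

    @property
    def span(self) -> tuple[int, int]:
        return (self.position, self.position + self.length)


@dataclass
class SyntheticGenomeSpec:
    length: int
    base_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    cg_odds: float = 1.0
    islands: list[IslandSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.base_probs, dtype=np.float64)
        if p.shape != (4,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("base_probs must be 4 non-negative values summing to 1")
        if self.cg_odds <= 0:
            raise ValueError("cg_odds must be positive")
        for isl in self.islands:
            if not (0 <= isl.position and isl.position + isl.length <= self.length):
                raise ValueError(f"island {isl} outside [0, {self.length})")


def base_probs_from_gc(gc: float) -> tuple[float, float, float, float]:
    """Symmetric composition (A=T, C=G) with the given G+C fraction."""
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    return ((1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2)


def transition_matrix(base_probs, cg_odds: float) -> np.ndarray:
    """Markov transition matrix: i.i.d. rows, C row CpG-adjusted.

    P(C→G) = q_G·cg_odds exactly; the other C-row entries are scaled by
    (1 − cg_odds·q_G)/(1 − q_G) so the row still sums to 1.
    """
    q = np.asarray(base_probs, dtype=np.float64)
    trans = np.tile(q, (4, 1))
    if cg_odds != 1.0:
        q_g = q[_G]
        if q_g >= 1.0:
            raise ValueError("degenerate composition: q_G = 1")
        scale = (1.0 - cg_odds * q_g) / (1.0 - q_g)
        trans[_C] = q * scale
        trans[_C, _G] = q_g * cg_odds
    rows = trans.sum(axis=1)
    if np.any(trans < 0) or not np.allclose(rows, 1.0):
        raise ValueError("degenerate transition row (check base_probs/cg_odds)")
    return trans


def stationary_distribution(trans: np.ndarray) -> np.ndarray:
    """Left eigenvector of the transition matrix with eigenvalue 1."""
    vals, vecs = np.linalg.eig(trans.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = pi / pi.sum()
    if np.any(pi < -1e-9):
        raise ValueError("no valid stationary distribution")
    return np.clip(pi, 0, None) / np.clip(pi, 0, None).sum()


def expected_cg_oe(base_probs, cg_odds: float) -> float:
    """Stationary CpG observed/expected ratio of the generated chain."""
    trans = transition_matrix(base_probs, cg_odds)
    pi = stationary_distribution(trans)
    return float(trans[_C, _G] / pi[_G])


def _sample_codes(length: int, trans: np.ndarray, start_probs: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    iid_rows = all(np.array_equal(trans[r], trans[0]) for r in range(4))
    if iid_rows:
        return rng.choice(4, size=length, p=trans[0]).astype(np.uint8)
    u = rng.random(length).tolist()
    cum = [tuple(np.cumsum(row)[:3]) for row in trans]
    start_cum = tuple(np.cumsum(start_probs)[:3])
    out = bytearray(length)
    c0, c1, c2 = start_cum
    x = u[0]
    state = 0 if x < c0 else 1 if x < c1 else 2 if x < c2 else 3
    out[0] = state
    for i in range(1, length):
        c0, c1, c2 = cum[state]
        x = u[i]
        state = 0 if x < c0 else 1 if x < c1 else 2 if x < c2 else 3
        out[i] = state
    return np.frombuffer(bytes(out), dtype=np.uint8)


def gen_iid(spec: SyntheticGenomeSpec, id: str = "synthetic_iid") -> GenomeSequence:
    """i.i.d. genome from the spec's base composition."""
    if spec.cg_odds != 1.0 or spec.islands:
        raise ValueError("gen_iid requires cg_odds = 1 and no islands")
    rng = np.random.default_rng(spec.seed)
    codes = rng.choice(4, size=spec.length,
                       p=np.asarray(spec.base_probs)).astype(np.uint8)
    return GenomeSequence(id=id, residues=codes_to_seq(codes))


def gen_markov(spec: SyntheticGenomeSpec, id: str = "synthetic_markov"
               ) -> GenomeSequence:
    """First-order Markov genome with the spec's CpG odds factor."""
    trans = transition_matrix(spec.base_probs, spec.cg_odds)
    rng = np.random.default_rng(spec.seed)
    start = stationary_distribution(trans)
    codes = _sample_codes(spec.length, trans, start, rng)
    return GenomeSequence(id=id, residues=codes_to_seq(codes))


def embed_islands(g: GenomeSequence, islands: list[IslandSpec], seed: int = 0
                  ) -> tuple[GenomeSequence, list[tuple[str, int, int]]]:
    """Replace island spans with CG-rich Markov material.

    Returns the modified sequence and the ground-truth intervals as BED
    tuples.  Island spans must be disjoint and inside the sequence.
    """
    spans = sorted(isl.span for isl in islands)
    for (s1_, e1), (s2_, _) in zip(spans, spans[1:]):
        if s2_ < e1:
            raise ValueError("island spans overlap")
    if spans and (spans[0][0] < 0 or spans[-1][1] > g.length):
        raise ValueError("island outside sequence")
    residues = list(g.residues)
    truth: list[tuple[str, int, int]] = []
    for i, isl in enumerate(sorted(islands, key=lambda x: x.position)):
        sub = SyntheticGenomeSpec(
            length=isl.length,
            base_probs=base_probs_from_gc(isl.island_gc),
            cg_odds=isl.island_cg_odds,
            seed=seed + i,
        )
        patch = gen_markov(sub).residues
        residues[isl.position:isl.position + isl.length] = patch
        truth.append((g.id, isl.position, isl.position + isl.length))
    return GenomeSequence(id=g.id, residues="".join(residues)), truth
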