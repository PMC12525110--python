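"""Divergence of a stratum's m-mer usage from the overall 8-mer set.

Three summaries of the (q_i, p_i) scatter (q = overall RF, p = stratum
RF):

* NSRE — a symmetric relative entropy between the two frequency vectors,

      NSRE(P||Q) = Σ_i [ p_i·log2(2p_i/(p_i+q_i)) + q_i·log2(2q_i/(p_i+q_i)) ]

  which for probability vectors equals twice the Jensen–Shannon
  divergence (base 2) and is bounded in [0, 2].
* S1 — distance deviation: RMS (n−1 denominator) of the signed
  perpendicular distances d_i = √(p_i²+q_i²)·sin α_i of each scatter
  point from the diagonal p = q.
* S2 — angular deviation: RMS of the angles α_i = π/4 − arctan(p_i/q_i)
  between each point's ray from the origin and the diagonal.

NSRE consumes probability-normalised vectors (zeros floored at half the
smallest non-zero entry, then rescaled to sum 1); S1/S2 consume the raw
RF pairs, matching the scatter-plot geometry they summarise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .mmer_usage import UsagePair


@dataclass
class NormalizedFrequencyVector:
    """Strictly positive probability vector after zero-replacement."""

    probs: np.ndarray
    floor_applied: float | None     # the substituted value, if any zeros

    def __post_init__(self) -> None:
        if self.probs.min() <= 0:
            raise ValueError("normalized vector must be strictly positive")


@dataclass
class DeviationComponents:
    """Per-m-mer diagonal distances and angles of the usage scatter."""

    d: np.ndarray               # signed perpendicular distances
    alpha: np.ndarray           # angles in radians, in (-pi/4, pi/4]
    n_dropped: int = 0          # (0,0) pairs excluded


@dataclass
class DivergenceScores:
    stratum: str
    m: int
    nsre: float
    s1: float
    s2: float


def normalize_for_nsre(raw: np.ndarray, rescale: bool = True
                       ) -> NormalizedFrequencyVector:
    """Floor zeros at half the smallest non-zero entry; optionally rescale
    to a probability vector (sum 1).

    ``rescale=False`` keeps the floored raw values divided by their
    original sum — the alternative reading of "normalization" for
    callers who want the floor applied before their own scaling.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if np.any(raw < 0):
        raise ValueError("negative frequencies")
    nonzero = raw[raw > 0]
    if nonzero.size == 0:
        raise ValueError("all-zero frequency vector")
    floor = None
    vec = raw.copy()
    if np.any(raw == 0):
        floor = float(nonzero.min() / 2.0)
        vec[vec == 0] = floor
    if rescale:
        vec = vec / vec.sum()
    else:
        vec = vec / raw.sum()
    return NormalizedFrequencyVector(probs=vec, floor_applied=floor)


def nsre(p: NormalizedFrequencyVector | np.ndarray,
         q: NormalizedFrequencyVector | np.ndarray) -> float:
    """Symmetric relative entropy in bits; 0 iff p = q, upper bound 2."""
    pv = p.probs if isinstance(p, NormalizedFrequencyVector) else np.asarray(p, float)
    qv = q.probs if isinstance(q, NormalizedFrequencyVector) else np.asarray(q, float)
    if pv.shape != qv.shape:
        raise ValueError(f"length mismatch: {pv.shape} vs {qv.shape}")
    mid = pv + qv
    return float(np.sum(pv * np.log2(2 * pv / mid) + qv * np.log2(2 * qv / mid)))


def deviation_components(pairs: list[UsagePair]) -> DeviationComponents:
    """Perpendicular distances and angles of (q, p) points vs the diagonal.

    The two-argument arctangent handles the axes: q = 0 maps to
    α = −π/4, p = 0 to α = +π/4.  A (0, 0) pair has no direction and is
    dropped with a warning.
    """
    q = np.array([pr.q for pr in pairs], dtype=np.float64)
    p = np.array([pr.p for pr in pairs], dtype=np.float64)
    if np.any(p < 0) or np.any(q < 0):
        raise ValueError("negative RF values")
    both_zero = (p == 0) & (q == 0)
    n_dropped = int(both_zero.sum())
    if n_dropped:
        warnings.warn(f"dropping {n_dropped} (0,0) usage pair(s): undefined direction")
        p, q = p[~both_zero], q[~both_zero]
    alpha = np.pi / 4 - np.arctan2(p, q)
    d = np.hypot(p, q) * np.sin(alpha)
    return DeviationComponents(d=d, alpha=alpha, n_dropped=n_dropped)


def _rms(values: np.ndarray) -> float:
    n = len(values)
    if n < 2:
        raise ValueError("need at least 2 components")
    return float(np.sqrt(np.sum(values**2) / (n - 1)))


def s1(components: DeviationComponents) -> float:
    """Distance deviation: RMS of diagonal distances (n−1 denominator)."""
    return _rms(components.d)


def s2(components: DeviationComponents) -> float:
    """Angular deviation: RMS of diagonal angles (n−1 denominator)."""
    return _rms(components.alpha)


def divergence_scores(overall_rf: np.ndarray, stratum_rf: np.ndarray,
                      stratum_label: str, m: int) -> DivergenceScores:
    """All three scores for one stratum-vs-overall comparison."""
    from .mmer_usage import UsagePair
    pairs = [UsagePair(mmer=i, q=float(q), p=float(p))
             for i, (q, p) in enumerate(zip(overall_rf, stratum_rf))]
    comp = deviation_components(pairs)
    p_norm = normalize_for_nsre(np.asarray(stratum_rf, float))
    q_norm = normalize_for_nsre(np.asarray(overall_rf, float))
    return DivergenceScores(
        stratum=stratum_label, m=m,
        nsre=nsre(p_norm, q_norm), s1=s1(comp), s2=s2(comp),
    )
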