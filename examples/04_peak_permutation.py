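"""Test whether two stratum spectra peak at different positions.

The observed peak distance D = |x0 - x2| is compared against a null
built by shuffling stratum labels over the pooled motifs (keeping
subset sizes), rebuilding both smoothed curves and re-taking peaks.
p = fraction of null distances >= observed.
"""

import kmerstrata as ks
from kmerstrata.synthetic_data import base_probs_from_gc

genome = ks.gen_markov(ks.SyntheticGenomeSpec(
    length=5_000_000, base_probs=base_probs_from_gc(0.38), cg_odds=0.25,
    seed=1))
table = ks.count_kmers(genome, k=8)
s0, s1, s2 = ks.build_strata("CG")

for a, b in ((s0, s1), (s0, s2), (s1, s2)):
    res = ks.permutation_test(table, a, b, B=1000, seed=7)
    print(f"D({a.label},{b.label}) = {res.d_obs:4d}   p = {res.p_display()}"
          f"   (B = {res.B})")
print("Large distances with p below 1/B: the CG strata occupy genuinely "
      "different count regimes, not a fluctuation of motif assignment.")
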