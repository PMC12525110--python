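# Methods

This note records the models, conventions and numerical choices behind
`kmerstrata`, in the order the pipeline applies them.

## Counting and spectra

8-mers are encoded in 2 bits per base (A=0, C=1, G=2, T=3; index =
base-4 number, first base most significant). Counting is
**single-strand**: complementary motifs (e.g. GCG and CGC) are distinct
universe members with distinct counts, which is required for sub-motif
tables where complementary m-mers carry different values. Windows
containing N are skipped; multi-sequence assemblies are counted per
sequence and summed, so no window spans a chromosome boundary or an
excision junction. Sequences are validated against {A,C,G,T,N} at
parse time.

The FA spectrum divides by the full 4⁸ denominator even for a stratum,
so stratum FA values sum to |stratum|/4⁸ rather than 1; peak positions
are unaffected, and heights remain comparable across strata. Nullomers
(x = 0) are recorded but excluded from the dense curve used for
smoothing and peak finding, which runs on bin size 1 from x = 1 to the
maximum observed count.

**Smoothing** is a centred moving average with the valid-window
(truncating) convention: each pass shortens the curve by window − 1
points and re-centres x; for even windows the centre is taken just left
of the half-integer midpoint so x stays integral. Default window 10,
1 pass; passes are configurable because multi-pass smoothing changes
peak positions by a few bins on sawtoothed spectra, and the
reproduction tests for published peak distances therefore sweep 1–5
passes.

## Stratification

Occurrences of a dinucleotide inside an 8-mer are **overlap-counted**
(AAA contains two AA). This is the only convention under which the
X = Y strata differ in size from the X ≠ Y strata: |0CG| = 40,545 but
|0AA| = 44,631. "2XY" means ≥ 2 occurrences. Strata are computed once
per dinucleotide from a vectorised scan of all 65,536 indices and
cached.

## m-mer relative frequency

RF is evaluated exactly as a weighted sum over the 8 − m + 1 m-mer
windows of every member 8-mer, accumulated with vectorised histogram
adds rather than string expansion (a string-expansion oracle backs it
in the tests). Because every 8-mer contributes exactly 8 − m + 1
windows, Σ RF = 4^m identically — asserted to 1e-9 on every computed
profile. The API accepts 1 ≤ m ≤ 7; analyses and tests use m = 3, 4.

## Divergence metrics

NSRE consumes probability vectors: zeros are replaced by **half the
smallest non-zero entry of the same vector**, then the vector is
rescaled to sum to 1. Rescaling is needed because raw RF values exceed
1 (AT-rich 4-mers reach ≈ 2.5–3.8) while the entropy form assumes
frequencies in [0,1]; a floor-without-rescale variant is available via
`normalize_for_nsre(..., rescale=False)` for sensitivity checks. NSRE
equals twice the Jensen–Shannon divergence (base 2); the test suite
verifies this against SciPy's independent implementation to 1e-12.

S₁ and S₂ consume **raw RF pairs**, because they summarise the geometry
of the RF-vs-RF scatter itself: S₂ depends only on the ratios p/q and
is scale-invariant, S₁ scales linearly with a common factor. Axis
points are handled by the two-argument arctangent (q = 0 → α = −π/4,
p = 0 → α = +π/4); a (0,0) pair has no direction and is dropped with a
warning rather than floored, since no zero-replacement rule applies to
the geometric scores. Both are RMS summaries with an n − 1 denominator
(n = 64 or 256).

## Peak inference and permutation test

The peak is the global argmax of the smoothed curve, ties resolved to
the smallest x. The permutation null **shuffles motif-level stratum
labels**: the member 8-mers of both strata are pooled with their genome
counts, reassigned to two pseudo-strata of the original sizes, and both
curves are rebuilt and smoothed with the observed configuration (the
engine enforces identical smoothing for observed and null curves). The
alternative reading — shuffling per-bin curve values — would destroy
the count-histogram structure the curves are built from; the
motif-label unit is isolated in one helper so it can be swapped. The
p-value uses the ≥ indicator, so identical peaks give p = 1, and a
Monte-Carlo p of exactly 0 is displayed as "< 1/B". B defaults to
10,000; the acceptance script uses B = 1,000 per pair.

Because peak distances are integers on a coarse grid, null p-values are
discrete and conservative (super-uniform) rather than exactly uniform.
The calibration test therefore checks validity of the raw p-values at
small α and exact uniformity of the tie-randomised rank p-value
(#{D♭ > D} + U·(1 + #{D♭ = D}))/(B + 1), which is uniform under
exchangeability by construction.

## CpG islands

O/E is the Gardiner–Garden ratio (N_CG·W)/(N_C·N_G). Thresholds
(GC ≥ 0.5, O/E ≥ 0.6) are inclusive; qualifying 1000 bp windows (step
500) are merged when overlapping or adjacent; the final partial window
is evaluated at its actual length; windows containing N are skipped,
and N_C·N_G = 0 defines O/E = 0. A third published filter (dropping
short intra-genic sequences) needs gene annotation the package does not
bundle; it is exposed as an optional user-supplied BED exclusion mask,
off by default. Excision returns the complement segments as separate
sequences, so island removal never creates chimeric k-mers.

## Synthetic genomes

The generator produces the conditions the analysis assumes:

- `gen_iid` — i.i.d. draws from a base composition. "Matched CG
  content" is read as matched mononucleotide composition (G+C
  fraction); matching the CpG *dinucleotide* frequency instead is
  available through `cg_odds`.
- `gen_markov` — a first-order chain whose rows equal the base
  composition except the C row: P(C→G) = q_G·cg_odds exactly, the
  removed mass redistributed proportionally over C→{A,C,T}. Under this
  construction the stationary CpG O/E is cg_odds/(1 − π_C(1 − cg_odds))
  — about 0.29 at cg_odds = 0.25 with GC 0.38 — and `expected_cg_oe`
  computes it in closed form for the tests. (Multiplying the C→G entry
  and renormalising the whole row would inflate P(C→G) back up and land
  the O/E near 1.35 × cg_odds, defeating the parameter's meaning.)
- `embed_islands` — replaces disjoint spans with GC-rich
  (island_gc = 0.65 by default), non-suppressed Markov material and
  returns ground-truth BED intervals.

All generators are bit-reproducible for a fixed seed.

Default study conditions, chosen once: 10 Mb genomes, yeast-like
GC = 0.38, cg_odds ∈ {1.0, 0.25}, seeds {1, 2, 3} — long enough that
stratum spectra have stable peaks (mean 8-mer count ≈ 153), small
enough to regenerate in seconds. The island fixture for excision
analyses uses an i.i.d. (cg_odds = 1) background with 150 × 2 kb
embedded islands in 3 Mb, i.e. islands are the *only* CG-rich
component; this isolates the direction of the excision effect (the 2CG
peak returns toward the island-free expectation). On a background that
is itself CpG-suppressed the same excision moves the 2CG peak further
left instead, which is worth remembering when interpreting real
genomes.

### What the generator does and does not emulate

It reproduces first-order composition, CpG suppression, and localized
CG-rich segments — the features the stratified-spectrum statistics
respond to. It has no repeats, isochores, chromosome-scale
heterogeneity or higher-order correlations. Consequently, passing
qualitative tests show that the *method* responds to CpG structure as
described, not that any particular real genome will show the same
effect sizes. One known divergence: under strong synthetic suppression
(cg_odds = 0.25) the 2CG stratum collapses into a narrow mode whose
smoothed FA height exceeds the broad 0CG mode, so the height ordering
FA2(p) < FA0(p) < FA1(p) seen in real (mildly suppressed,
heterogeneous) genomes does not hold on this fixture, and the
corresponding acceptance assertion fails by design rather than being
weakened. Peak-position ordering and divergence rankings are robust to
this.

## Problem sizes

Unit and property tests run on 200 bp–2 Mb sequences; the shared
qualitative fixture is one 10 Mb suppressed genome; permutation
calibration uses 60 independent 1.5 Mb genomes at B = 100; the
acceptance script uses the 10 Mb suppressed genome (B = 1,000 per
stratum pair) and the 3 Mb island fixture. Reproduction tests against
published yeast/nematode/human values require the corresponding
assemblies under `data/genomes/` and are the only tests that cannot run
self-contained.

## Known limitations

- In-memory counting only; genomes beyond ~4 Gb and k > 15 are out of
  scope.
- No reverse-complement collapsing (deliberate, see above) and no
  multiple-testing correction across stratum pairs or species.
- The island caller is the plain sliding-window criterion, not a
  hidden-Markov segmentation, and will quantise island boundaries to
  the step size.
- NSRE's zero-replacement makes scores for sets with many absent
  m-mers sensitive to the floor choice; the rescale/no-rescale switch
  exposes this.
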