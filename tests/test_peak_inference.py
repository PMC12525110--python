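import itertools

import numpy as np
import pytest

import kmerstrata as ks
from kmerstrata.kmer_spectrum import FASpectrum, SmoothedCurve
from kmerstrata.stratification import StratumSpec


def curve(y, x=None, window=10, passes=1):
    y = np.asarray(y, dtype=float)
    x = np.arange(1, len(y) + 1) if x is None else np.asarray(x)
    return SmoothedCurve(x=x, y=y, window=window, passes=passes)


def toy_table(members, counts):
    arr = np.zeros(4**8, dtype=np.int64)
    arr[np.asarray(members)] = counts
    return ks.KmerCountTable(k=8, counts=arr, windows_counted=int(arr.sum()))


def stratum(members, cls="0"):
    return StratumSpec("CG", cls, np.asarray(members, dtype=np.int64))


def oracle_peak(member_counts, window):
    """Independent peak finder: histogram, windowed means, linear scan."""
    n_x = np.bincount(member_counts)
    y = list(n_x[1:] / 4**8)
    sm = [sum(y[i:i + window]) / window for i in range(len(y) - window + 1)]
    xs = list(range(1, len(y) + 1))[(window - 1) // 2:][:len(sm)]
    best = max(range(len(sm)), key=lambda i: (sm[i], -xs[i]))
    return xs[best]


class TestFindPeak:
    def test_delta_curve(self):
        y = np.zeros(50)
        y[29] = 1.0
        assert ks.find_peak(curve(y)).x_hat == 30

    def test_plateau_tie_takes_smallest_x(self):
        y = np.zeros(20)
        y[[9, 10]] = 1.0
        assert ks.find_peak(curve(y)).x_hat == 10

    def test_matches_linear_scan_oracle(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(40, size=5000)
        spec = FASpectrum(k=8, universe_size=5000, n_x=np.bincount(counts))
        sm = ks.smooth(spec, window=10)
        assert ks.find_peak(sm).x_hat == oracle_peak(counts, 10)

    def test_all_zero_curve_errors(self):
        with pytest.raises(ValueError, match="no peak"):
            ks.find_peak(curve(np.zeros(5)))


class TestPeakDistance:
    def test_identical_curves(self):
        y = np.zeros(30)
        y[7] = 1.0
        a, b = ks.find_peak(curve(y)), ks.find_peak(curve(y))
        assert ks.peak_distance(a, b) == 0

    def test_absolute_difference(self):
        a = ks.PeakEstimate(x_hat=10, window=10, passes=1)
        b = ks.PeakEstimate(x_hat=30, window=10, passes=1)
        assert ks.peak_distance(a, b) == 20

    def test_mismatched_smoothing_rejected(self):
        a = ks.PeakEstimate(x_hat=10, window=10, passes=1)
        b = ks.PeakEstimate(x_hat=30, window=10, passes=2)
        with pytest.raises(ValueError, match="configs differ"):
            ks.peak_distance(a, b)


class TestPermutationTest:
    def test_identical_pooled_halves_give_p_one(self):
        t = toy_table(range(8), [3, 5, 7, 9, 3, 5, 7, 9])
        res = ks.permutation_test(t, stratum(range(4), "0"),
                                  stratum(range(4, 8), "1"),
                                  B=50, seed=1, window=2)
        assert res.d_obs == 0 and res.p_value == 1.0

    def test_overlapping_strata_rejected(self):
        t = toy_table(range(8), [1] * 8)
        with pytest.raises(ValueError, match="overlap"):
            ks.permutation_test(t, stratum(range(4)), stratum(range(3, 8)),
                                B=10, window=2)

    def test_agrees_with_exhaustive_enumeration(self):
        """8-motif toy pool split 4/4: Monte-Carlo p matches the exact
        p over all 70 label assignments within 3 standard errors."""
        pool = np.array([2, 3, 4, 5, 12, 13, 14, 15])
        window = 2
        t = toy_table(range(8), pool)
        s_i, s_j = stratum(range(4), "0"), stratum(range(4, 8), "1")
        res = ks.permutation_test(t, s_i, s_j, B=10_000, seed=3, window=window)
        d_obs = abs(oracle_peak(pool[:4], window) - oracle_peak(pool[4:], window))
        assert res.d_obs == d_obs
        null = []
        for picks in itertools.combinations(range(8), 4):
            rest = [i for i in range(8) if i not in picks]
            null.append(abs(oracle_peak(pool[list(picks)], window)
                            - oracle_peak(pool[rest], window)))
        p_exact = sum(d >= d_obs for d in null) / len(null)
        se = np.sqrt(max(p_exact * (1 - p_exact), 1e-9) / res.B)
        assert res.p_value == pytest.approx(p_exact, abs=3 * se)

    def test_bit_reproducible_for_fixed_seed(self):
        t = toy_table(range(10), [2, 4, 6, 8, 10, 3, 5, 7, 9, 11])
        kwargs = dict(B=200, seed=42, window=3)
        r1 = ks.permutation_test(t, stratum(range(5), "0"),
                                 stratum(range(5, 10), "1"), **kwargs)
        r2 = ks.permutation_test(t, stratum(range(5), "0"),
                                 stratum(range(5, 10), "1"), **kwargs)
        assert r1.d_obs == r2.d_obs and r1.p_value == r2.p_value
        assert np.array_equal(r1.null, r2.null)

    def test_p_non_increasing_in_observed_distance(self):
        """For a fixed null sample, larger observed distances can only
        lower the exceedance proportion."""
        t = toy_table(range(8), [2, 3, 4, 5, 12, 13, 14, 15])
        res = ks.permutation_test(t, stratum(range(4), "0"),
                                  stratum(range(4, 8), "1"), B=500, seed=9,
                                  window=2)
        ps = [np.mean(res.null >= d) for d in range(0, int(res.null.max()) + 2)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        assert ps[0] == 1.0

    def test_eq12_exceedance_count_oracle(self):
        t = toy_table(range(8), [2, 3, 4, 5, 12, 13, 14, 15])
        res = ks.permutation_test(t, stratum(range(4), "0"),
                                  stratum(range(4, 8), "1"), B=300, seed=11,
                                  window=2)
        assert res.p_value == sum(1 for d in res.null if d >= res.d_obs) / 300

    def test_p_display_reports_zero_as_bound(self):
        r = ks.PermutationResult(d_obs=5, null=np.zeros(200, dtype=int),
                                 p_value=0.0, B=200, seed=0)
        assert r.p_display() == "<0.005"


def test_null_p_values_uniform_under_exchangeability():
    """Strata drawn from the same distribution: raw permutation p-values
    are valid (super-uniform despite integer-distance ties) and the
    tie-randomized rank p-value is uniform by exchangeability."""
    from scipy.stats import kstest
    n_runs, B = 60, 100
    raw, randomized = [], []
    for run in range(n_runs):
        g = ks.gen_iid(ks.SyntheticGenomeSpec(length=1_500_000,
                                              seed=5000 + run))
        t = ks.count_kmers(g, 8)
        rng = np.random.default_rng(9000 + run)
        members = rng.choice(4**8, size=240, replace=False)
        res = ks.permutation_test(t, stratum(members[:120], "0"),
                                  stratum(members[120:], "1"),
                                  B=B, seed=run, window=5)
        raw.append(res.p_value)
        u = np.random.default_rng(70_000 + run).random()
        ties = int(np.sum(res.null == res.d_obs))
        randomized.append((np.sum(res.null > res.d_obs) + u * (1 + ties))
                          / (B + 1))
    raw = np.asarray(raw)
    # validity: exceedance of small alpha never exceeds alpha by > 3 SE
    for alpha in (0.05, 0.2):
        se = np.sqrt(alpha * (1 - alpha) / n_runs)
        assert np.mean(raw <= alpha) <= alpha + 3 * se
    assert kstest(np.asarray(randomized), "uniform").pvalue > 1e-3
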