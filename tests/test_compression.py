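"""Compression measures: FCM code lengths vs a brute-force oracle, NRC/NCD
behaviour on structured vs random data, serialization rules."""

import itertools
from math import log2

import numpy as np
import pytest
from scipy import stats

from ctgcompress import (
    FCMConfig,
    SymbolSequence,
    compression_ratio,
    fit_fcm,
    ncd,
    nrc,
    relative_code_length,
    serialize_segment,
)


def seq(symbols, A):
    return SymbolSequence(np.asarray(symbols, dtype=np.int64), A)


def oracle_code_length(x, y, k, d, A, alpha):
    """Independent re-implementation: literal dict counting over y and a
    symbol-by-symbol pass over x, summing -log2 smoothed probabilities."""
    counts, totals = {}, {}
    for i in range(k, len(y) - d + 1):
        ctx = tuple(y[i - k:i])
        blk = tuple(y[i:i + d])
        counts[(ctx, blk)] = counts.get((ctx, blk), 0) + 1
        totals[ctx] = totals.get(ctx, 0) + 1
    bits = k * log2(A)
    i = k
    while i + d <= len(x):
        ctx = tuple(x[i - k:i])
        blk = tuple(x[i:i + d])
        c = counts.get((ctx, blk), 0)
        t = totals.get(ctx, 0)
        p = (c + alpha) / (t + alpha * A**d)
        bits += min(-log2(p), d * log2(A))
        i += d
    bits += (len(x) - i) * log2(A)
    return bits


class TestFitFCM:
    def test_hand_counted_alternating_string(self):
        # "ABABAB", k=1, d=1: context A precedes B three times, B precedes A twice
        y = seq([0, 1, 0, 1, 0, 1], 2)
        model = fit_fcm(y, FCMConfig(k=1, d=1, alphabet_size=2, alpha=1.0))
        A_code, B_code = 0, 1
        blk_space = 2
        assert model.pair_counts[A_code * blk_space + B_code] == 3
        assert model.pair_counts[B_code * blk_space + A_code] == 2
        assert model.context_totals == {0: 3, 1: 2}

    def test_constant_sequence_single_pair(self):
        y = seq([2] * 30, 3)
        model = fit_fcm(y, FCMConfig(k=2, d=3, alphabet_size=3, alpha=1.0))
        assert len(model.pair_counts) == 1
        assert sum(model.pair_counts.values()) == 30 - 2 - 3 + 1

    def test_deterministic(self):
        y = seq(np.random.default_rng(0).integers(0, 3, 50), 3)
        cfg = FCMConfig(k=2, d=2, alphabet_size=3)
        m1, m2 = fit_fcm(y, cfg), fit_fcm(y, cfg)
        assert m1.pair_counts == m2.pair_counts
        assert m1.context_totals == m2.context_totals

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            fit_fcm(seq([0, 1], 2), FCMConfig(k=2, d=2, alphabet_size=2))

    def test_alphabet_mismatch_errors(self):
        model = fit_fcm(seq([0, 1] * 10, 2), FCMConfig(k=1, d=1, alphabet_size=2))
        with pytest.raises(ValueError):
            relative_code_length(seq([0, 1, 2] * 5, 3), model)


class TestOracleEquivalence:
    def test_exhaustive_binary_sequences(self):
        """relative_code_length equals the brute-force oracle to 1e-9 bits on
        every binary sequence up to length 10, all (k, d) in {1,2}^2."""
        for k, d in itertools.product((1, 2), (1, 2)):
            cfg = FCMConfig(k=k, d=d, alphabet_size=2, alpha=1.0)
            for n in range(k + d, 11):
                for bits in itertools.product((0, 1), repeat=n):
                    x = seq(bits, 2)
                    got = relative_code_length(x, fit_fcm(x, cfg)).bits
                    want = oracle_code_length(bits, bits, k, d, 2, 1.0)
                    assert got == pytest.approx(want, abs=1e-9)

    def test_random_ternary_pairs(self):
        rng = np.random.default_rng(2024)
        for _ in range(120):
            k = int(rng.integers(1, 3))
            d = int(rng.integers(1, 3))
            alpha = float(rng.choice([1.0, 0.25, 3 ** -d]))
            nx = int(rng.integers(k + d, 31))
            ny = int(rng.integers(k + d, 31))
            x = rng.integers(0, 3, nx)
            y = rng.integers(0, 3, ny)
            cfg = FCMConfig(k=k, d=d, alphabet_size=3, alpha=alpha)
            got = relative_code_length(seq(x, 3), fit_fcm(seq(y, 3), cfg)).bits
            want = oracle_code_length(x.tolist(), y.tolist(), k, d, 3, alpha)
            assert got == pytest.approx(want, abs=1e-9)


class TestCodeLength:
    def test_periodic_self_highly_compressible(self):
        y = seq([0, 1, 2, 3] * 600, 4)
        cfg = FCMConfig(k=2, d=2, alphabet_size=4)
        cl = relative_code_length(y, fit_fcm(y, cfg))
        assert cl.bits / cl.n_symbols < 0.2 * log2(4)

    def test_independent_uniform_incompressible(self):
        rng = np.random.default_rng(5)
        x = seq(rng.integers(0, 4, 3000), 4)
        y = seq(rng.integers(0, 4, 3000), 4)
        cfg = FCMConfig(k=1, d=1, alphabet_size=4)
        cl = relative_code_length(x, fit_fcm(y, cfg))
        assert cl.bits / cl.n_symbols == pytest.approx(2.0, rel=0.05)

    def test_cap_bounds_total_bits(self):
        rng = np.random.default_rng(6)
        x = seq(rng.integers(0, 20, 500), 20)
        y = seq(rng.integers(0, 20, 500), 20)
        cfg = FCMConfig()  # k=6, d=6, |A|=20
        cl = relative_code_length(x, fit_fcm(y, cfg))
        assert 0 <= cl.bits <= len(x) * log2(20) + 1e-9


class TestNRC:
    def test_range_and_extremes(self):
        rng = np.random.default_rng(8)
        periodic = seq([0, 1, 2] * 500, 4)
        assert nrc(periodic, periodic, FCMConfig(k=3, d=1, alphabet_size=4)) < 0.1
        x = seq(rng.integers(0, 4, 2000), 4)
        y = seq(rng.integers(0, 4, 2000), 4)
        v = nrc(x, y, FCMConfig(k=2, d=1, alphabet_size=4))
        assert 0.9 <= v <= 1.0

    def test_directionality(self):
        """NRC is not symmetric: a structured x vs its noisy copy differ by
        direction."""
        rng = np.random.default_rng(9)
        base = np.tile([0, 1, 2, 3], 400)
        noisy = base.copy()
        flip = rng.random(base.size) < 0.2
        noisy[flip] = rng.integers(0, 4, flip.sum())
        cfg = FCMConfig(k=3, d=1, alphabet_size=4)
        a = nrc(seq(base, 4), seq(noisy, 4), cfg)
        b = nrc(seq(noisy, 4), seq(base, 4), cfg)
        assert a != pytest.approx(b, abs=1e-6)

    def test_monotone_in_reference_noise(self):
        """NRC(x || y) grows as y degrades from a copy of x to pure noise
        (Spearman rho > 0.9 between noise level and NRC, averaged over seeds)."""
        cfg = FCMConfig(k=3, d=1, alphabet_size=4)
        noise_levels = np.linspace(0, 1, 8)
        rhos = []
        for s in range(20):
            rng = np.random.default_rng(100 + s)
            x_arr = np.tile([0, 1, 2, 3], 300)
            vals = []
            for nl in noise_levels:
                y = x_arr.copy()
                flip = rng.random(y.size) < nl
                y[flip] = rng.integers(0, 4, flip.sum())
                vals.append(nrc(seq(x_arr, 4), seq(y, 4), cfg))
            rhos.append(stats.spearmanr(noise_levels, vals).statistic)
        assert np.mean(rhos) > 0.9


class TestByteMeasures:
    def test_serialize_rounding_clamping_length(self):
        assert serialize_segment([140.4, 140.6]) == bytes([140, 141])
        assert serialize_segment([300.0]) == bytes([255])
        assert serialize_segment([-5.0]) == bytes([0])
        assert len(serialize_segment(np.arange(100.0))) == 100

    def test_constant_series_highly_compressible(self):
        assert compression_ratio(np.full(2400, 140.0)) > 10

    def test_random_bytes_incompressible(self, rng):
        x = rng.integers(0, 256, 2400).astype(float)
        assert 0.9 <= compression_ratio(x) <= 1.1

    def test_deterministic(self, rng):
        x = rng.normal(140, 5, 2400)
        assert compression_ratio(x) == compression_ratio(x.copy())
        with pytest.raises(ValueError):
            compression_ratio([])

    def test_ncd_self_small_for_structured(self):
        t = np.arange(2400) / 4.0
        x = 140 + 10 * np.sin(2 * np.pi * t / 300)
        assert ncd(x, x) <= 0.2

    def test_ncd_independent_random_near_one(self, rng):
        x = rng.integers(0, 256, 2400).astype(float)
        y = rng.integers(0, 256, 2400).astype(float)
        assert 0.8 <= ncd(x, y) <= 1.1
        with pytest.raises(ValueError):
            ncd([], [1.0])
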