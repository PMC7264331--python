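"""Non-linear markers against brute-force oracles and closed forms."""

import numpy as np
import pytest

from hrvnet.markers import (approximate_entropy, correlation_dimension,
                            dfa_alphas, poincare_markers, recurrence_markers,
                            sample_entropy)
from hrvnet.markers.nonlinear import _embed
from hrvnet.rr import RRSeries

from conftest import make_series


def brute_recurrence(x, m, tau, r, l_min):
    """Naive RQA: nested-loop recurrence matrix and diagonal-run census."""
    n = len(x) - (m - 1) * tau
    emb = [[x[i + k * tau] for k in range(m)] for i in range(n)]
    rec = [[np.sqrt(sum((a - b) ** 2 for a, b in zip(emb[i], emb[j]))) <= r
            for j in range(n)] for i in range(n)]
    pts = sum(rec[i][j] for i in range(n) for j in range(n) if i != j)
    lengths = []
    for off in range(1, n):
        run = 0
        for i in range(n - off):
            if rec[i][i + off]:
                run += 1
            else:
                if run >= l_min:
                    lengths.append(run)
                run = 0
        if run >= l_min:
            lengths.append(run)
    return pts, lengths


class TestPoincare:
    def test_constant_zero(self, constant_series):
        m = poincare_markers(constant_series)
        assert m[38] == 0 and m[39] == 0

    def test_sd1_is_rmssd_over_sqrt2(self, rng):
        rr = np.clip(0.8 + 0.05 * rng.normal(size=300), 0.2, 3.0)
        s = make_series(rr)
        d = np.diff(rr)
        rmssd = np.sqrt(np.mean(d**2))
        assert poincare_markers(s)[38] == pytest.approx(rmssd / np.sqrt(2), rel=1e-9)

    def test_alternating_series_closed_form(self):
        s = make_series([0.7, 0.9] * 50)
        m = poincare_markers(s)
        assert m[38] == pytest.approx(0.2 / np.sqrt(2), rel=1e-9)
        assert m[39] == pytest.approx(0.0, abs=1e-9)


class TestRecurrence:
    def test_periodic_series_fully_deterministic(self):
        x = np.tile([0.7, 0.8, 0.9, 0.8, 0.75], 10)  # period 5, L = 50
        s = make_series(x)
        m = recurrence_markers(s, m=3, tau=1)
        assert m[43] >= 99.0  # DET: recurrences sit on diagonals

    def test_matches_brute_force_on_random_series(self, rng):
        x = np.clip(0.8 + 0.1 * rng.normal(size=60), 0.2, 3.0)
        s = make_series(x)
        emb_m, tau, l_min = 3, 1, 2
        r = np.sqrt(emb_m) * np.std(x, ddof=1) * 0.3
        got = recurrence_markers(s, m=emb_m, tau=tau, r_factor=np.sqrt(emb_m) * 0.3,
                                 l_min=l_min)
        pts, lengths = brute_recurrence(x, emb_m, tau, r, l_min)
        n = len(x) - (emb_m - 1) * tau
        assert got[42] == pytest.approx(100.0 * pts / (n * n - n), rel=1e-9)
        if lengths:
            assert got[43] == pytest.approx(
                min(100.0, 100.0 * 2 * sum(lengths) / pts), rel=1e-9)
            assert got[40] == pytest.approx(np.mean(lengths), rel=1e-9)
            assert got[41] == max(lengths)

    def test_constant_series_recurs_everywhere(self):
        m = recurrence_markers(make_series([0.8] * 60), m=3)
        assert m[42] == pytest.approx(100.0)
        assert m[43] == pytest.approx(100.0, abs=0.5)

    def test_noise_with_tight_radius_barely_recurs(self, rng):
        x = np.clip(0.8 + 0.3 * rng.normal(size=100), 0.2, 3.0)
        m = recurrence_markers(make_series(x), m=3, r_factor=0.05)
        assert m[42] < 5.0


def brute_sampen(x, m, r):
    n = len(x)

    def matches(length):
        c = 0
        for i in range(n - m):
            for j in range(n - m):
                if i == j:
                    continue
                if max(abs(x[i + k] - x[j + k]) for k in range(length)) <= r:
                    c += 1
        return c

    b, a = matches(m), matches(m + 1)
    return -np.log(a / b) if a and b else float("nan")


class TestEntropies:
    def test_constant_series_zero(self, constant_series):
        assert approximate_entropy(constant_series) == pytest.approx(0.0, abs=1e-12)
        assert sample_entropy(constant_series) == pytest.approx(0.0, abs=1e-12)

    def test_periodic_alternation_sampen_zero(self):
        s = make_series([0.7, 0.9] * 40)
        assert sample_entropy(s, m=2) == pytest.approx(0.0, abs=1e-12)

    def test_sampen_matches_brute_force(self, rng):
        x = np.clip(0.8 + 0.05 * rng.normal(size=80), 0.2, 3.0)
        s = make_series(x)
        r = 0.2 * np.std(x, ddof=1)
        assert sample_entropy(s, m=2) == pytest.approx(brute_sampen(x, 2, r), rel=1e-9)

    def test_noise_exceeds_constant(self, rng):
        noisy = make_series(np.clip(0.8 + 0.2 * rng.uniform(size=200), 0.2, 3.0))
        assert sample_entropy(noisy) > 0.0

    def test_no_matches_warns_nan(self):
        # strictly monotone, huge spread: no Chebyshev template matches
        x = np.linspace(0.3, 2.9, 60)
        with pytest.warns(UserWarning):
            v = sample_entropy(make_series(x), m=2, r_factor=0.001)
        assert np.isnan(v)


class TestDFA:
    def test_white_noise_alpha_half(self):
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = np.clip(0.8 + 0.05 * rng.normal(size=10_000), 0.2, 3.0)
            vals.append(dfa_alphas(make_series(x))[47])
        assert abs(np.mean(vals) - 0.5) < 0.1

    def test_random_walk_alpha_three_halves(self):
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            x = np.clip(1.5 + 0.001 * np.cumsum(rng.normal(size=10_000)), 0.2, 3.0)
            vals.append(dfa_alphas(make_series(x))[48])
        assert abs(np.mean(vals) - 1.5) < 0.15

    def test_constant_series_undefined(self):
        m = dfa_alphas(make_series([0.8] * 300))
        assert np.isnan(m[47]) and np.isnan(m[48])

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            dfa_alphas(make_series([0.8] * 100))


class TestCorrelationDimension:
    @staticmethod
    def sinusoid(n=800, seed=0):
        # frequency incommensurate with the beat spacing, so the embedded
        # orbit fills the closed curve instead of 1/(f dt) discrete points
        rng = np.random.default_rng(seed)
        t = np.arange(n) * 0.8
        x = 0.8 + 0.1 * np.sin(2 * np.pi * 0.0537 * t) + 1e-5 * rng.normal(size=n)
        return make_series(np.clip(x, 0.2, 3.0))

    def test_curve_has_dimension_one(self):
        d2 = correlation_dimension(self.sinusoid())
        assert d2 == pytest.approx(1.0, abs=0.3)

    def test_affine_invariance(self):
        s = self.sinusoid()
        scaled = make_series(np.clip(0.4 + 0.5 * (s.intervals - 0.8), 0.2, 3.0))
        assert correlation_dimension(scaled) == pytest.approx(
            correlation_dimension(s), rel=0.05)

    def test_constant_series_undefined(self):
        assert np.isnan(correlation_dimension(make_series([0.8] * 600)))

    def test_embedding_shape(self):
        e = _embed(np.arange(10.0), m=3, tau=2)
        assert e.shape == (6, 3)
        assert e[0].tolist() == [0, 2, 4]
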