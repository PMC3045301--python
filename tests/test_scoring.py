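"""Three-region likelihood-ratio scoring against independent oracles."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import poisson

from nucleofind.background import BackgroundParams, BackgroundTrack
from nucleofind.scoring import (
    BindingGeometry,
    lrt_statistic,
    mle_estimates,
    region_counts,
    score_genome,
    truncated_support_estimates,
)


def numeric_lrt(x0, t0, x1, t1):
    """W from numeric likelihood maximization (independent oracle).

    In the (lam0, lam1) parametrization (lam1 = phi * lam0 * t1 / t0) the
    free model factorizes into two independent Poisson likelihoods, each
    maximized numerically; the equal-rates model constrains
    lam1 = lam0 * t1 / t0 and is maximized over the single remaining rate.
    """

    def pois_ll(lam, x):
        return -lam + (x * np.log(lam) if x else 0.0) - gammaln(x + 1)

    def maximize(f, hi):
        res = minimize_scalar(
            lambda lam: -f(lam),
            bounds=(1e-12, hi),
            method="bounded",
            options={"xatol": 1e-12},
        )
        return -res.fun

    hi = 10.0 * (x0 + x1) + 10.0
    l1 = maximize(lambda l: pois_ll(l, x0), hi) + maximize(
        lambda l: pois_ll(l, x1), hi
    )
    l0 = maximize(lambda l: pois_ll(l, x0) + pois_ll(l * t1 / t0, x1), hi)
    return 2.0 * (l1 - l0)


class TestMleEstimates:
    def test_rate_ratio(self):
        phi, lam0, pooled = mle_estimates(4, 2, 6, 3)
        assert phi == 1.0
        assert lam0 == 4.0
        assert pooled == 4.0  # 2 * 10 / 5

    def test_zero_x0_flags_ratio_undefined(self):
        phi, lam0, _ = mle_estimates(0, 2, 6, 3)
        assert np.isnan(phi)
        assert lam0 == 0.0

    def test_bad_window_length(self):
        with pytest.raises(ValueError):
            mle_estimates(1, 0, 1, 1)


class TestLrtStatistic:
    def test_equal_rates_give_zero(self):
        assert lrt_statistic(10, 100, 1, 10) == 0.0

    def test_worked_value(self):
        assert lrt_statistic(100, 2001, 10, 17) == pytest.approx(30.205, abs=1e-3)

    def test_zero_count_side(self):
        assert lrt_statistic(10, 10, 0, 10) == pytest.approx(20 * np.log(2))

    def test_both_zero_undefined(self):
        assert np.isnan(lrt_statistic(0, 10, 0, 10))

    def test_nonnegative_on_random_inputs(self, rng):
        x0 = rng.poisson(5, 500)
        x1 = rng.poisson(5, 500)
        w = lrt_statistic(x0, 7, x1, 13)
        ok = np.isfinite(w)
        assert np.all(w[ok] >= 0)

    def test_matches_numeric_maximization(self, rng):
        for _ in range(50):
            t0 = float(rng.integers(1, 3000))
            t1 = float(rng.integers(1, 200))
            x0 = int(rng.poisson(20))
            x1 = int(rng.poisson(5))
            if x0 + x1 == 0:
                continue
            w = float(lrt_statistic(x0, t0, x1, t1))
            assert w == pytest.approx(numeric_lrt(x0, t0, x1, t1), abs=1e-6)


class TestRegionCounts:
    geometry = BindingGeometry(b=10, s=3)

    def place(self, fwd_pos=(), rev_pos=(), n=100):
        fwd = np.zeros(n, dtype=np.int64)
        rev = np.zeros(n, dtype=np.int64)
        for p in fwd_pos:
            fwd[p] += 1
        for p in rev_pos:
            rev[p] += 1
        return region_counts(fwd, rev, self.geometry)

    def test_zero_reads(self):
        pos, xf, xb, xr = self.place()
        assert pos[0] == 3 and pos[-1] == 100 - 10 - 3
        assert not (xf.any() or xb.any() or xr.any())

    def test_forward_read_just_upstream_is_support(self):
        i = 50
        pos, xf, xb, xr = self.place(fwd_pos=[i - 1])
        k = np.searchsorted(pos, i)
        assert (xf[k], xb[k], xr[k]) == (1, 0, 0)

    def test_reverse_read_at_i_plus_b_is_support(self):
        i = 50
        pos, xf, xb, xr = self.place(rev_pos=[i + 10])
        k = np.searchsorted(pos, i)
        assert (xf[k], xb[k], xr[k]) == (0, 0, 1)

    def test_binding_region_pools_both_strands(self):
        i = 50
        pos, xf, xb, xr = self.place(fwd_pos=[i], rev_pos=[i + 9])
        k = np.searchsorted(pos, i)
        assert xb[k] == 2

    def test_short_chromosome_empty(self):
        fwd = np.zeros(10, dtype=np.int64)
        pos, *_ = region_counts(fwd, fwd, self.geometry)
        assert pos.size == 0


class TestTruncatedSupport:
    def test_cross_truncation_example(self):
        f, r = truncated_support_estimates([20], [10], 0.9)
        assert f[0] == 13

    def test_below_cap_unchanged(self):
        f, _ = truncated_support_estimates([5], [10], 0.9)
        assert f[0] == 5

    def test_zero_partner_invalidates(self):
        f, r = truncated_support_estimates([5], [0], 0.9)
        assert np.isnan(f[0])  # P[X <= j | lam=0] = 1 > gamma for all j
        assert np.isnan(r[0])  # and x_rev = 0 has empty feasible set

    def test_matches_brute_force_scan(self):
        def brute(x, partner, gamma):
            best = np.nan
            for j in range(1, int(x) + 1):
                if poisson.cdf(j, partner) <= gamma:
                    best = j
            return best

        xs = np.arange(0, 21)
        grid_x, grid_p = np.meshgrid(xs, xs)
        for gamma in (0.5, 0.9, 1.0):
            f, _ = truncated_support_estimates(
                grid_x.ravel(), grid_p.ravel(), gamma
            )
            expected = np.array(
                [
                    brute(x, p, gamma)
                    for x, p in zip(grid_x.ravel(), grid_p.ravel())
                ]
            )
            np.testing.assert_array_equal(f, expected)


def naive_score_genome(counts, bg, geometry, signed_root=True):
    """Position-by-position reference implementation of the genome scan."""
    chrom = counts.chromosomes()[0]
    fwd, rev = counts.fwd[chrom], counts.rev[chrom]
    b, s = geometry.b, geometry.s
    t_bg = 2 * bg.params.w_bg + 1
    pos_list, scores, valids = [], [], []
    for i in range(s, len(fwd) - b - s + 1):
        x_fwd = int(fwd[i - s : i].sum())
        x_bind = int(fwd[i : i + b].sum() + rev[i : i + b].sum())
        x_rev = int(rev[i + b : i + b + s].sum())
        bf = bg.lambda_tilde["+"][chrom][i]
        br = bg.lambda_tilde["-"][chrom][i]
        sf, sr = truncated_support_estimates([x_fwd], [x_rev], geometry.gamma_sup)
        sf, sr = float(sf[0]), float(sr[0])
        valid = (
            x_fwd >= 1
            and x_rev >= 1
            and bf > 0
            and br > 0
            and np.isfinite(sf)
            and np.isfinite(sr)
        )
        pos_list.append(i)
        valids.append(valid)
        if not valid:
            scores.append(np.nan)
            continue
        total = 0.0
        for x1, t1, x0, t0, flip in (
            (sf, s, bf, t_bg, False),
            (sr, s, br, t_bg, False),
            (x_bind, b, bf + br, 2 * t_bg, True),
        ):
            w = float(lrt_statistic(x0, t0, x1, t1))
            if np.isnan(w):
                w = 0.0
            mag = np.sqrt(w) if signed_root else w
            up = x1 / t1 > x0 / t0
            sign = (-1 if up else 1) if flip else (1 if up else -1)
            total += sign * mag
        scores.append(total)
    return np.array(pos_list), np.array(scores), np.array(valids)


class TestScoreGenome:
    def test_agrees_with_naive_implementation(self, toy_counts):
        geometry = BindingGeometry(b=20, s=5)
        bg = BackgroundTrack.from_counts(toy_counts, BackgroundParams(w_bg=100))
        track = score_genome(toy_counts, bg, geometry)
        pos, scores, valids = naive_score_genome(toy_counts, bg, geometry)
        np.testing.assert_array_equal(track.positions["chr1"], pos)
        np.testing.assert_array_equal(track.valid["chr1"], valids)
        np.testing.assert_allclose(
            track.score["chr1"][valids], scores[valids], rtol=0, atol=1e-10
        )

    def test_plain_w_mode_agrees_with_naive(self, toy_counts):
        geometry = BindingGeometry(b=20, s=5)
        bg = BackgroundTrack.from_counts(toy_counts, BackgroundParams(w_bg=100))
        track = score_genome(toy_counts, bg, geometry, signed_root=False)
        _, scores, valids = naive_score_genome(
            toy_counts, bg, geometry, signed_root=False
        )
        np.testing.assert_allclose(
            track.score["chr1"][valids], scores[valids], atol=1e-10
        )

    def test_empty_forward_support_invalidates_position(self, small_genome):
        from nucleofind.core_io import StrandCounts

        geometry = BindingGeometry(b=20, s=5)
        counts = StrandCounts(small_genome)
        i = 500
        counts.rev["chr1"][i + 20 : i + 23] = 1  # reverse support occupied
        counts.fwd["chr1"][450] = 2  # background on both strands, but
        counts.rev["chr1"][560] = 2  # nothing in [i - s, i - 1]
        bg = BackgroundTrack.from_counts(counts, BackgroundParams(w_bg=100))
        track = score_genome(counts, bg, geometry)
        k = np.searchsorted(track.positions["chr1"], i)
        assert not track.valid["chr1"][k]
        assert np.isnan(track.score["chr1"][k])

    def test_sum_decomposition_where_valid(self, toy_counts):
        geometry = BindingGeometry(b=20, s=5)
        bg = BackgroundTrack.from_counts(toy_counts, BackgroundParams(w_bg=100))
        track = score_genome(toy_counts, bg, geometry)
        v = track.valid["chr1"]
        total = (
            track.s_fwd["chr1"][v] + track.s_bind["chr1"][v] + track.s_rev["chr1"][v]
        )
        np.testing.assert_allclose(track.score["chr1"][v], total, atol=1e-12)

    def test_adding_forward_support_read_never_decreases_s_fwd(self):
        """Monotonicity of the forward support score in the support count."""
        t_bg, s_len, bg_count = 201.0, 5.0, 20.0
        prev = -np.inf
        for x in range(1, 30):
            sf, _ = truncated_support_estimates([x], [30], 0.9)
            w = float(lrt_statistic(bg_count, t_bg, float(sf[0]), s_len))
            sign = 1.0 if sf[0] / s_len > bg_count / t_bg else -1.0
            score = sign * np.sqrt(w)
            assert score >= prev - 1e-12
            prev = score
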