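"""Three-region likelihood-ratio scoring of candidate nucleosome positions.

A nucleosome whose bound DNA starts at position i leaves a characteristic
strand-specific footprint in read 5'-start counts: a peak of forward-strand
starts in the s-bp support region [i - s, i - 1], a depleted b-bp binding
region [i, i + b - 1] on both strands, and a peak of reverse-strand starts in
[i + b, i + b + s - 1]. Each region's count is compared to the local
background rate with a two-Poisson likelihood-ratio statistic W; the signed
square roots of the three W values (positive when the region deviates in the
expected direction) add up to the nucleosome score S(i).

Under the no-nucleosome null W is asymptotically chi-squared with one degree
of freedom, so each signed root is asymptotically standard normal — the
property the empirical null fit in :mod:`nucleofind.significance` builds on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np

from .background import BackgroundTrack, poisson_quantile_cap
from .core_io import StrandCounts


@dataclass(frozen=True)
class BindingGeometry:
    """Binding-region length b, support-region length s, support cut-off.

    Defaults b = 128, s = 17 target MNase mononucleosome data where only the
    most stable particles show the full 147 bp protected footprint; the
    preset ``BindingGeometry.canonical()`` restores b = 147, s = 10.
    """

    b: int = 128
    s: int = 17
    gamma_sup: float = 0.9

    def __post_init__(self) -> None:
        if self.b < 1 or self.s < 1:
            raise ValueError("region lengths must be >= 1")
        if not 0 < self.gamma_sup <= 1:
            raise ValueError(f"gamma_sup must be in (0, 1], got {self.gamma_sup}")

    @classmethod
    def canonical(cls) -> "BindingGeometry":
        return cls(b=147, s=10)

    @property
    def span(self) -> int:
        """Total model footprint s + b + s."""
        return self.b + 2 * self.s

    def dyad_offset(self) -> int:
        """Offset of the reported dyad from the binding-region start."""
        return self.b // 2


def region_counts(
    counts_fwd: np.ndarray, counts_rev: np.ndarray, geometry: BindingGeometry
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-candidate read counts in the three model regions.

    Candidate binding-region starts are i in [s, L - b - s]; returns
    (positions, x_fwd, x_bind, x_rev) as integer arrays. A chromosome
    shorter than b + 2s yields empty arrays.
    """
    b, s = geometry.b, geometry.s
    L = counts_fwd.size
    if L < geometry.span:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty.copy(), empty.copy(), empty.copy()
    pos = np.arange(s, L - b - s + 1, dtype=np.int64)
    cf = np.concatenate([[0], np.cumsum(counts_fwd)])
    cr = np.concatenate([[0], np.cumsum(counts_rev)])
    cb = cf + cr
    x_fwd = cf[pos] - cf[pos - s]
    x_bind = cb[pos + b] - cb[pos]
    x_rev = cr[pos + b + s] - cr[pos + b]
    return pos, x_fwd, x_bind, x_rev


def mle_estimates(x0, t0, x1, t1):
    """Maximum-likelihood estimates for the two-Poisson rate comparison.

    Given counts x0, x1 observed over windows of t0, t1 positions, returns
    (phi_hat, lambda0_hat, lambda_pooled): the rate ratio phi_hat =
    x1*t0 / (x0*t1) (NaN where x0 = 0), the free-model lambda0_hat = x0, and
    the equal-rate pooled estimate t0*(x0+x1)/(t0+t1).
    """
    x0 = np.asarray(x0, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    t0 = np.asarray(t0, dtype=float)
    t1 = np.asarray(t1, dtype=float)
    if np.any(t0 < 1) or np.any(t1 < 1):
        raise ValueError("window lengths must be >= 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_hat = np.where(x0 > 0, x1 * t0 / (x0 * t1), np.nan)
    lambda_pooled = t0 * (x0 + x1) / (t0 + t1)
    return phi_hat, x0, lambda_pooled


def _xlogx(x: np.ndarray) -> np.ndarray:
    """x * ln(x) with the convention 0 * ln 0 = 0."""
    from scipy.special import xlogy

    return xlogy(x, x)


def lrt_statistic(x0, t0, x1, t1):
    """Likelihood-ratio statistic W for equal per-position Poisson rates.

    W = 2{ x0 (ln x0 - ln t0) + x1 (ln x1 - ln t1)
           + (x0 + x1)(ln[t0 + t1] - ln[x0 + x1]) }

    with 0*ln 0 = 0. Vectorized; positions with x0 = x1 = 0 return NaN
    (the statistic is undefined there). Tiny negative rounding residues are
    clamped to zero.
    """
    x0 = np.asarray(x0, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    t0 = np.asarray(t0, dtype=float)
    t1 = np.asarray(t1, dtype=float)
    if np.any(t0 < 1) or np.any(t1 < 1):
        raise ValueError("window lengths must be >= 1")
    x0, x1, t0, t1 = np.broadcast_arrays(x0, x1, t0, t1)
    total = x0 + x1
    w = 2.0 * (
        _xlogx(x0)
        - x0 * np.log(t0)
        + _xlogx(x1)
        - x1 * np.log(t1)
        + total * np.log(t0 + t1)
        - _xlogx(total)
    )
    w = np.where(total > 0, w, np.nan)
    w = np.where((w < 0) & (w > -1e-9), 0.0, w)
    # equal estimated rates: the alternative collapses onto the null, W = 0
    # exactly (avoids 1e-15 rounding residue)
    w = np.where(x1 * t0 == x0 * t1, 0.0, w)
    return np.where(total > 0, w, np.nan)


def truncated_support_estimates(
    x_fwd, x_rev, gamma_sup: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Cross-truncated support-region count estimates.

    A genuine nucleosome produces comparable peaks on both strands, so each
    support count is capped at the gamma_sup Poisson quantile of its partner
    strand's count: lambda_tilde_fwd = max{ j : 0 < j <= x_fwd and
    P[X <= j | lambda = x_rev] <= gamma_sup }, and symmetrically. Where the
    feasible set is empty (x = 0, or the partner count is too small for any
    positive j to satisfy the bound) the estimate is NaN, marking the
    position invalid.
    """
    if not 0 < gamma_sup <= 1:
        raise ValueError(f"gamma_sup must be in (0, 1], got {gamma_sup}")
    x_fwd = np.asarray(x_fwd, dtype=float)
    x_rev = np.asarray(x_rev, dtype=float)

    def one_side(x, partner):
        cap = poisson_quantile_cap(partner, gamma_sup)
        est = np.minimum(x, cap)
        return np.where(est >= 1, est, np.nan)

    return one_side(x_fwd, x_rev), one_side(x_rev, x_fwd)


class ScoreTrack:
    """Per-chromosome nucleosome score arrays over candidate positions."""

    def __init__(self, geometry: BindingGeometry):
        self.geometry = geometry
        self.positions: Dict[str, np.ndarray] = {}
        self.s_fwd: Dict[str, np.ndarray] = {}
        self.s_bind: Dict[str, np.ndarray] = {}
        self.s_rev: Dict[str, np.ndarray] = {}
        self.score: Dict[str, np.ndarray] = {}
        self.valid: Dict[str, np.ndarray] = {}

    def valid_scores(self) -> np.ndarray:
        """All finite scores at valid positions, concatenated."""
        parts = [self.score[c][self.valid[c]] for c in self.score]
        return np.concatenate(parts) if parts else np.empty(0)


def _signed(w: np.ndarray, positive: np.ndarray, signed_root: bool) -> np.ndarray:
    mag = np.sqrt(w) if signed_root else w
    return np.where(positive, mag, -mag)


def score_genome(
    counts: StrandCounts,
    bg: BackgroundTrack,
    geometry: BindingGeometry,
    signed_root: bool = True,
) -> ScoreTrack:
    """Score every candidate nucleosome start on every chromosome.

    For each candidate i the three region statistics compare per-position
    rates against the robust local background (window centred at i):

    * support regions: x1 = truncated support estimate over t1 = s, against
      the same-strand background x0 = lambda_tilde_bg over t0 = 2*w_bg + 1;
      the score is +sqrt(W) when the support rate exceeds the background
      rate, else -sqrt(W);
    * binding region: x1 = both-strand count over t1 = b, against the pooled
      two-strand background over t0 = 2*(2*w_bg + 1); the sign is flipped —
      depletion is evidence for a nucleosome.

    A position is valid only if both support regions contain at least one
    read, both strand backgrounds are positive, and both truncated support
    estimates are defined. ``signed_root=False`` uses +/-W itself instead of
    its square root.
    """
    t_bg = float(bg.params.window)
    track = ScoreTrack(geometry)
    for chrom in counts.chromosomes():
        pos, x_fwd, x_bind, x_rev = region_counts(
            counts.fwd[chrom], counts.rev[chrom], geometry
        )
        n = pos.size
        track.positions[chrom] = pos
        if n == 0:
            for d in (track.s_fwd, track.s_bind, track.s_rev, track.score):
                d[chrom] = np.empty(0)
            track.valid[chrom] = np.empty(0, dtype=bool)
            continue
        bg_fwd = bg.lambda_tilde["+"][chrom][pos]
        bg_rev = bg.lambda_tilde["-"][chrom][pos]
        sup_fwd, sup_rev = truncated_support_estimates(
            x_fwd, x_rev, geometry.gamma_sup
        )
        valid = (
            (x_fwd >= 1)
            & (x_rev >= 1)
            & (bg_fwd > 0)
            & (bg_rev > 0)
            & np.isfinite(sup_fwd)
            & np.isfinite(sup_rev)
        )
        # Neutral fill-ins keep the vectorized arithmetic finite off-support.
        sf = np.where(valid, sup_fwd, 1.0)
        sr = np.where(valid, sup_rev, 1.0)
        bf = np.where(valid, bg_fwd, 1.0)
        br = np.where(valid, bg_rev, 1.0)
        s_len = float(geometry.s)
        b_len = float(geometry.b)

        w_fwd = lrt_statistic(bf, t_bg, sf, s_len)
        w_rev = lrt_statistic(br, t_bg, sr, s_len)
        bg_pool = bf + br
        w_bind = lrt_statistic(bg_pool, 2.0 * t_bg, x_bind.astype(float), b_len)
        w_bind = np.where(np.isnan(w_bind), 0.0, w_bind)

        s_fwd = _signed(w_fwd, sf / s_len > bf / t_bg, signed_root)
        s_rev = _signed(w_rev, sr / s_len > br / t_bg, signed_root)
        s_bind = _signed(
            w_bind, x_bind / b_len <= bg_pool / (2.0 * t_bg), signed_root
        )

        score = s_fwd + s_bind + s_rev
        track.s_fwd[chrom] = np.where(valid, s_fwd, np.nan)
        track.s_rev[chrom] = np.where(valid, s_rev, np.nan)
        track.s_bind[chrom] = np.where(valid, s_bind, np.nan)
        track.score[chrom] = np.where(valid, score, np.nan)
        track.valid[chrom] = valid
    return track
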