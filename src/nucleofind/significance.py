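"""Empirical null fitting, p/q-values, and discrete nucleosome calls.

Asymptotically each nucleosome score is a sum of three standard-normal
region scores, but truncation couples the support terms, so instead of
assuming N(0, 3) the null is fitted empirically: S ~ N(mu_bar, sigma) with
mu_bar the sample median of valid scores and sigma the maximum-likelihood
scale of a half-normal distribution fitted to the deviations mu_bar - S of
scores between the tau-th and 50th percentiles (truncated to that band).
Scores relating to real nucleosomes lie in the upper tail and never enter
the fit; tau guards against the extreme lower tail produced by positions
that pile unusually many reads into the binding region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .scoring import ScoreTrack


@dataclass(frozen=True)
class NullFit:
    """Fitted empirical null N(mu_bar, sigma), with truncation percentile tau."""

    mu_bar: float
    sigma: float
    tau: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def fit_null(scores: np.ndarray, tau: float = 5.0, min_scores: int = 1000) -> NullFit:
    """Fit the empirical null to the lower half of the score distribution.

    Parameters
    ----------
    scores
        Valid nucleosome scores.
    tau
        Lower truncation cut-off. Values in [1, 50) are percentiles: scores
        below the tau-th percentile are excluded as outliers before
        fitting. Values in (0, 1) use the retained-fraction convention
        (tau = 0.95 keeps 95%, i.e. cuts the lowest 5%); both readings of
        the cut-off are found in practice and map onto one another.
        tau = 0 disables the cut.
    min_scores
        Minimum number of valid scores required.
    """
    scores = np.asarray(scores, dtype=float)
    scores = scores[np.isfinite(scores)]
    if scores.size < min_scores:
        raise ValueError(
            f"need at least {min_scores} valid scores, got {scores.size}"
        )
    if 0 < tau < 1:
        tau = 100.0 * (1.0 - tau)
    if not 0 <= tau < 50:
        raise ValueError(f"tau must be in [0, 50) or (0, 1), got {tau}")
    mu_bar = float(np.median(scores))
    lo = float(np.percentile(scores, tau))
    band = scores[(scores >= lo) & (scores <= mu_bar)]
    dev = mu_bar - band  # deviations in [0, d_max]
    d_max = mu_bar - lo
    if d_max <= 0 or np.all(dev == dev[0]):
        raise ValueError("scores are (nearly) constant; null scale undefined")

    n = dev.size
    ss = float(np.sum(dev**2))

    def neg_loglik(sigma: float) -> float:
        # half-normal truncated to [0, d_max]; normalizer 2*Phi(d_max/sigma)-1
        z = d_max / sigma
        return (
            n * np.log(sigma)
            + ss / (2.0 * sigma**2)
            + n * np.log(2.0 * norm.cdf(z) - 1.0)
        )

    raw = np.sqrt(ss / n)  # untruncated half-normal MLE as a scale anchor
    res = minimize_scalar(
        neg_loglik,
        bounds=(raw * 1e-3, max(raw * 100.0, 1e-6)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return NullFit(mu_bar=mu_bar, sigma=float(res.x), tau=float(tau))


def score_pvalues(scores: np.ndarray, fit: NullFit) -> np.ndarray:
    """Upper-tail p-values under the fitted null; NaN scores stay NaN."""
    scores = np.asarray(scores, dtype=float)
    p = np.full(scores.shape, np.nan)
    ok = np.isfinite(scores)
    p[ok] = norm.sf(scores[ok], loc=fit.mu_bar, scale=fit.sigma)
    return p


def estimate_pi0(p: np.ndarray) -> float:
    """Proportion of true nulls, from the density of p-values above 1/2."""
    p = np.asarray(p, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        return 1.0
    return float(min(1.0, 2.0 * np.mean(p > 0.5)))


def adjust_fdr(p: np.ndarray, method: str = "BH") -> np.ndarray:
    """Benjamini-Hochberg q-values, optionally scaled by the estimated pi0.

    ``method`` is "BH" (step-up) or "adaptive" (BH multiplied by the
    estimated proportion of true null hypotheses, capped at 1). NaN entries
    pass through as NaN.
    """
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if not np.any(ok):
        return q
    _, q_bh, _, _ = multipletests(p[ok], method="fdr_bh")
    if method == "BH":
        q[ok] = q_bh
    elif method == "adaptive":
        q[ok] = np.minimum(1.0, estimate_pi0(p[ok]) * q_bh)
    else:
        raise ValueError(f"unknown FDR method {method!r}")
    return q


@dataclass(frozen=True)
class Prediction:
    chrom: str
    start: int  # binding-region start, 0-based
    dyad: int  # start + b // 2
    score: float
    p: float
    q: float


class PredictionSet:
    """Called nucleosomes, sorted by (chrom, start)."""

    def __init__(self, predictions: List[Prediction], b: int):
        self.predictions = sorted(predictions, key=lambda x: (x.chrom, x.start))
        self.b = b

    def __len__(self) -> int:
        return len(self.predictions)

    def __iter__(self):
        return iter(self.predictions)

    def dyads(self, chrom: Optional[str] = None) -> np.ndarray:
        return np.array(
            [x.dyad for x in self.predictions if chrom is None or x.chrom == chrom],
            dtype=np.int64,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (x.chrom, x.start, x.dyad, x.score, x.p, x.q)
                for x in self.predictions
            ],
            columns=["chrom", "start", "dyad", "score", "p", "q"],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_bed(self, path) -> None:
        """BED6: name = q-value, score = S linearly rescaled to 0-1000."""
        if self.predictions:
            smax = max(x.score for x in self.predictions)
            smin = min(x.score for x in self.predictions)
            rng = smax - smin or 1.0
        with open(path, "w") as fh:
            for x in self.predictions:
                scaled = int(round(1000 * (x.score - smin) / rng))
                fh.write(
                    f"{x.chrom}\t{x.start}\t{x.start + self.b}\t"
                    f"{x.q:.4g}\t{scaled}\t+\n"
                )


def call_nucleosomes(
    track: ScoreTrack,
    p: Dict[str, np.ndarray],
    q: Dict[str, np.ndarray],
    fdr: float = 0.05,
    min_sep: int = 5,
) -> PredictionSet:
    """Greedy selection of significant, locally maximal positions.

    Among candidate positions with q <= fdr, positions are taken in order of
    decreasing score (ties to the leftmost start) and accepted unless an
    already accepted start on the same chromosome lies within min_sep bp.
    The small default min_sep permits the overlapping predictions that
    cell-to-cell positional variation produces; min_sep = b enforces
    non-overlapping calls.
    """
    if not 0 < fdr < 1:
        raise ValueError(f"fdr must be in (0, 1), got {fdr}")
    if min_sep < 1:
        raise ValueError(f"min_sep must be >= 1, got {min_sep}")
    b = track.geometry.b
    dyad_off = track.geometry.dyad_offset()
    out: List[Prediction] = []
    for chrom, pos in track.positions.items():
        qc = q[chrom]
        pc = p[chrom]
        sc = track.score[chrom]
        sig = np.isfinite(qc) & (qc <= fdr)
        if not np.any(sig):
            continue
        idx = np.nonzero(sig)[0]
        # descending score, leftmost start on ties
        order = idx[np.lexsort((pos[idx], -sc[idx]))]
        taken = np.zeros(pos[-1] + min_sep + 1, dtype=bool)
        for i in order:
            start = int(pos[i])
            lo = max(start - min_sep + 1, 0)
            if taken[lo : start + min_sep].any():
                continue
            taken[start] = True
            out.append(
                Prediction(
                    chrom=chrom,
                    start=start,
                    dyad=start + dyad_off,
                    score=float(sc[i]),
                    p=float(pc[i]),
                    q=float(qc[i]),
                )
            )
    return PredictionSet(out, b=b)
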