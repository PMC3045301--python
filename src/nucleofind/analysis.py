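"""Downstream analyses of nucleosome predictions.

Dinucleotide periodicity around dyads, phasing relative to TSS/TES anchors,
adjacent-prediction distances, evaluation against a simulation truth table,
multi-sample repeatability via normalised total correlation, and
Pareto-optimal parameter selection from treatment/control prediction counts.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .core_io import AnchorSet
from .significance import PredictionSet

DINUCLEOTIDES = ["".join(p) for p in itertools.product("ACGT", repeat=2)]
_DINUC_INDEX = {d: j for j, d in enumerate(DINUCLEOTIDES)}


@dataclass
class DinucProfile:
    """Position-specific dinucleotide composition around predicted dyads.

    ``observed[i, j]`` counts dinucleotide j starting at offset
    ``offsets[i]`` from the dyad; ``expected[i, j]`` is the genome-based
    expectation; ``residuals`` are the standardized residuals
    (o - e) / sqrt(e) and ``chi2[i]`` their per-offset sum of squares, which
    is asymptotically chi-squared with 15 degrees of freedom when the
    sequences match genome composition.
    """

    offsets: np.ndarray
    observed: np.ndarray  # (n_offsets, 16)
    expected: np.ndarray
    residuals: np.ndarray
    chi2: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.observed, columns=DINUCLEOTIDES)
        df.insert(0, "offset", self.offsets)
        df["chi2"] = self.chi2
        return df


def genome_dinucleotide_freq(sequences: Iterable[str]) -> Dict[str, float]:
    """Relative dinucleotide abundance over the forward strand of sequences."""
    counts = np.zeros(16, dtype=np.int64)
    for seq in sequences:
        s = seq.upper()
        for a, b in zip(s, s[1:]):
            j = _DINUC_INDEX.get(a + b)
            if j is not None:
                counts[j] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no ACGT dinucleotides found")
    return {d: counts[j] / total for j, d in enumerate(DINUCLEOTIDES)}


def dinucleotide_profile(
    sequences: Sequence[str], genome_freq: Dict[str, float]
) -> DinucProfile:
    """Score position-specific dinucleotide enrichment around dyads.

    Sequences must be equal length and centred on predicted dyads; offset 0
    is the dyad (sequence midpoint), so length-2m sequences give offsets
    -m .. m-2 for fully contained pairs. Pairs containing non-ACGT
    characters are masked; the expectation at each offset scales with the
    number of unmasked sequences there. Raises if an observed dinucleotide
    has zero expected frequency.
    """
    if not sequences:
        raise ValueError("no sequences")
    length = len(sequences[0])
    if any(len(s) != length for s in sequences):
        raise ValueError("sequences must be equal length")
    if length < 2:
        raise ValueError("sequences must hold at least one dinucleotide")
    n_off = length - 1
    centre = length // 2
    # encode bases as 0..3 (ACGT), 0xff otherwise; dinucleotide = 4*first+second
    lut = np.full(256, 0xFF, dtype=np.uint8)
    for k, base in enumerate(b"ACGTacgt"):
        lut[base] = k % 4
    codes = lut[
        np.frombuffer("".join(sequences).encode("ascii"), dtype=np.uint8).reshape(
            len(sequences), length
        )
    ]
    first, second = codes[:, :-1], codes[:, 1:]
    masked = (first == 0xFF) | (second == 0xFF)
    idx = np.where(masked, 16, 4 * first.astype(np.int16) + second)
    observed = np.empty((n_off, 16), dtype=np.int64)
    for i in range(n_off):
        observed[i] = np.bincount(idx[:, i], minlength=17)[:16]
    n_valid = observed.sum(axis=1)
    freq = np.array([genome_freq[d] for d in DINUCLEOTIDES], dtype=float)
    expected = n_valid[:, None] * freq[None, :]
    if np.any((expected == 0) & (observed > 0)):
        raise ValueError("observed dinucleotide with zero expected frequency")
    with np.errstate(divide="ignore", invalid="ignore"):
        residuals = np.where(
            expected > 0, (observed - expected) / np.sqrt(expected), 0.0
        )
        # sum of squared residuals, but via (o-e)^2/e to avoid sqrt round-off
        chi2 = np.sum(
            np.where(expected > 0, (observed - expected) ** 2 / expected, 0.0),
            axis=1,
        )
    offsets = np.arange(n_off) - centre
    return DinucProfile(offsets, observed, expected, residuals, chi2)


@dataclass
class PhasingProfile:
    """Counts of prediction dyads per anchor-oriented offset."""

    offsets: np.ndarray
    counts: np.ndarray

    def smoothed(self, k: int = 3) -> np.ndarray:
        """k-point moving average (window truncated at the profile edges)."""
        if k < 1:
            raise ValueError("k must be >= 1")
        kernel = np.ones(k)
        sums = np.convolve(self.counts.astype(float), kernel, mode="same")
        norm = np.convolve(np.ones_like(self.counts, dtype=float), kernel, mode="same")
        return sums / norm

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.offsets, "count": self.counts, "smooth3": self.smoothed(3)}
        )


def phasing_profile(
    predictions: PredictionSet, anchors: AnchorSet, half_window: int = 1000
) -> PhasingProfile:
    """Accumulate prediction dyads around anchors, oriented by anchor strand.

    The offset of a dyad from a forward-strand anchor is dyad - anchor; for
    reverse-strand anchors the sign flips so that positive offsets always
    point downstream of the feature.
    """
    offsets = np.arange(-half_window, half_window + 1)
    counts = np.zeros(offsets.size, dtype=np.int64)
    dyads_by_chrom: Dict[str, np.ndarray] = {}
    for pred in predictions:
        dyads_by_chrom.setdefault(pred.chrom, [])
    for pred in predictions:
        dyads_by_chrom[pred.chrom].append(pred.dyad)
    dyads_by_chrom = {c: np.sort(np.array(v)) for c, v in dyads_by_chrom.items()}
    for anchor in anchors:
        dyads = dyads_by_chrom.get(anchor.chrom)
        if dyads is None or dyads.size == 0:
            continue
        lo = np.searchsorted(dyads, anchor.position - half_window, side="left")
        hi = np.searchsorted(dyads, anchor.position + half_window, side="right")
        for dyad in dyads[lo:hi]:
            off = int(dyad) - anchor.position
            if anchor.strand == "-":
                off = -off
            if -half_window <= off <= half_window:
                counts[off + half_window] += 1
    return PhasingProfile(offsets, counts)


def adjacent_distances(predictions: PredictionSet) -> List[int]:
    """Distances between consecutive prediction dyads, per chromosome."""
    out: List[int] = []
    frame = predictions.to_frame()
    for _, grp in frame.groupby("chrom"):
        dyads = np.sort(grp["dyad"].to_numpy())
        out.extend(np.diff(dyads).tolist())
    return out


@dataclass
class EvaluationResult:
    n_stable: int
    n_detected: int
    pct_stable: float  # percent of stable dyads detected
    distances: np.ndarray  # signed dyad - truth for detected stable dyads
    distance_sd: float
    detected: np.ndarray  # boolean per stable dyad


def evaluate_predictions(
    predictions: PredictionSet, truth, tol: int = 100
) -> EvaluationResult:
    """Match each stable truth dyad to its nearest prediction.

    A stable nucleosome counts as detected when some prediction dyad lies
    within ``tol`` bp of its planted dyad; the spatial resolution is the
    standard deviation of the signed distances of detected dyads.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    stable = np.sort(truth.stable_dyads())
    n_stable = stable.size
    pred_dyads = np.sort(predictions.dyads(getattr(truth, "chrom", None)))
    if pred_dyads.size == 0 or n_stable == 0:
        return EvaluationResult(
            n_stable, 0, 0.0, np.empty(0), float("nan"), np.zeros(n_stable, bool)
        )
    idx = np.searchsorted(pred_dyads, stable)
    left = np.clip(idx - 1, 0, pred_dyads.size - 1)
    right = np.clip(idx, 0, pred_dyads.size - 1)
    d_left = pred_dyads[left] - stable
    d_right = pred_dyads[right] - stable
    signed = np.where(np.abs(d_left) <= np.abs(d_right), d_left, d_right)
    detected = np.abs(signed) <= tol
    distances = signed[detected]
    sd = float(np.std(distances)) if distances.size else float("nan")
    pct = 100.0 * detected.sum() / n_stable
    return EvaluationResult(n_stable, int(detected.sum()), pct, distances, sd, detected)


def _entropy_bits(labels: np.ndarray) -> float:
    """Empirical Shannon entropy (bits) of a label sequence."""
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log2(p)))


def total_correlation(vectors: Sequence[np.ndarray]) -> float:
    """Multivariate mutual information: sum of marginal entropies minus the
    joint empirical entropy, in bits."""
    arr = np.asarray(vectors)
    if arr.ndim != 2:
        raise ValueError("need a 2-D stack of equal-length vectors")
    marginal = sum(_entropy_bits(row) for row in arr)
    # encode joint outcomes as row tuples
    joint = np.unique(arr.T, axis=0, return_counts=True)[1]
    p = joint / joint.sum()
    joint_h = float(-np.sum(p * np.log2(p)))
    return marginal - joint_h


def repeatability(detections: Sequence[np.ndarray]) -> float:
    """Normalised detection repeatability across k samples.

    ``detections`` holds k binary vectors indexed by the same stable
    nucleosomes. The total correlation C_tot measures information shared
    between samples; it is normalised by C_max, the total correlation after
    sorting each vector descending (aligning all detections), which is the
    detection-count-preserving rearrangement maximising repeated
    detections. Returns 0 when C_max = 0 (e.g. constant vectors).
    """
    arr = np.asarray(detections)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need >= 2 equal-length detection vectors")
    c_tot = total_correlation(arr)
    c_max = total_correlation(np.sort(arr, axis=1)[:, ::-1])
    if c_max <= 0:
        return 0.0
    return c_tot / c_max


@dataclass(frozen=True)
class ParetoPoint:
    """One parameter combination's prediction counts.

    M = predictions in the control sample (taken as false positives),
    m = predictions in the treatment sample.
    """

    params: tuple
    M: int
    m: int


def pareto_front(points: Sequence[ParetoPoint]) -> List[ParetoPoint]:
    """Staircase of non-dominated (M, m) points: for every control count
    level, the combination with the most treatment predictions among those
    with no more control predictions. Deduplicated on (M, m)."""
    if not points:
        raise ValueError("empty point list")
    ordered = sorted(points, key=lambda p: (p.M, -p.m))
    front: List[ParetoPoint] = []
    best_m = -math.inf
    for p in ordered:
        if p.m > best_m:
            front.append(p)
            best_m = p.m
    return front


def parameter_sweep(
    treatment,
    control,
    grid: Sequence[dict],
    runner,
) -> Tuple[List[ParetoPoint], List[ParetoPoint]]:
    """Run the full pipeline per parameter combination on both samples.

    ``grid`` is a sequence of keyword dicts (b, s, gamma_bg, gamma_sup,
    w_bg, ...) forwarded to ``runner(counts, **params) -> PredictionSet``;
    the default runner is :func:`nucleofind.cli.run_pipeline`. A failing
    combination is recorded as missing and the sweep continues. Returns
    (all points, Pareto front).
    """
    points: List[ParetoPoint] = []
    for combo in grid:
        key = tuple(sorted(combo.items()))
        try:
            m = len(runner(treatment, **combo))
            M = len(runner(control, **combo))
        except Exception:  # single-run failure: recorded as missing
            continue
        points.append(ParetoPoint(key, M=M, m=m))
    if not points:
        return [], []
    return points, pareto_front(points)
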