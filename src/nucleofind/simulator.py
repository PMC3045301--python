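"""Synthetic strand-specific read generator with chromatin feature structure.

Emulates an MNase mononucleosome sequencing experiment on a single synthetic
chromosome. The genome is tiled end-to-end with four kinds of chromatin
features — stable nucleosomes (fixed dyads, tiny positional spread), phased
arrays (regular spacing with jitter growing away from the array anchor),
fuzzy regions (delocalised dyads, large spread) and nucleosome-free regions
(no dyads). Reads are generated from a notional population of cells: each
signal read picks a dyad, jitters it by the feature's positional spread,
draws a ~150 bp fragment centred on the jittered dyad, and reports the 36 bp
read starting at one of the fragment's two 5' ends (fair coin). Background
reads start uniformly on a uniform strand.

All randomness flows from one integer-seeded generator; the same seed gives
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np

from .core_io import FORWARD, REVERSE, GenomeInfo, ReadAlignment

STABLE = "stable"
PHASED = "phased"
FUZZY = "fuzzy"
NFR = "nfr"

#: Default feature-count mix, proportional to the feature tallies of a
#: genome-scale Arabidopsis simulation (stable : phased : fuzzy : NFR).
DEFAULT_WEIGHTS = {STABLE: 0.288, PHASED: 0.342, FUZZY: 0.133, NFR: 0.237}

#: Region length per feature kind, bp. Stable features hold one nucleosome
#: in one spacing unit; phased/fuzzy arrays span several kilobases; NFRs are
#: short promoter-sized gaps.
REGION_LENGTHS = {PHASED: 5000, FUZZY: 5000, NFR: 150}


@dataclass(frozen=True)
class SimParams:
    """All tunable parameters of the read simulator.

    Spreads are standard deviations (bp) of the per-cell dyad jitter; the
    phased spread grows linearly with the nucleosome's index in its array up
    to ``phased_spread_max``, modelling loss of phase away from the anchor.
    """

    genome_length: int = 1_000_000
    chrom: str = "sim1"
    weights: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    footprint: int = 147
    spacing: int = 200
    stable_spread: float = 2.0
    phased_spread_min: float = 10.0
    phased_spread_max: float = 20.0
    phased_spread_step: float = 2.5
    fuzzy_spread: float = 40.0
    fragment_mean: float = 150.0
    fragment_sd: float = 10.0
    read_length: int = 36
    background_fraction: float = 0.2
    n_reads: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        w = self.weights
        if any(v < 0 for v in w.values()) or not np.isclose(sum(w.values()), 1.0):
            raise ValueError("feature weights must be >= 0 and sum to 1")
        if not 0 <= self.background_fraction <= 1:
            raise ValueError("background_fraction must be in [0, 1]")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if self.genome_length < 1:
            raise ValueError("genome_length must be >= 1")

    def genome(self) -> GenomeInfo:
        return GenomeInfo({self.chrom: self.genome_length})


@dataclass(frozen=True)
class TruthRecord:
    dyad: int
    kind: str  # feature kind
    spread: float  # per-cell positional jitter sd, bp

    @property
    def stable(self) -> bool:
        return self.kind == STABLE


class TruthTable:
    """Planted dyads with feature kind and stability label."""

    def __init__(self, records: List[TruthRecord], chrom: str):
        self.records = records
        self.chrom = chrom

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def dyads(self) -> np.ndarray:
        return np.array([r.dyad for r in self.records], dtype=np.int64)

    def stable_dyads(self) -> np.ndarray:
        return np.array([r.dyad for r in self.records if r.stable], dtype=np.int64)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tdyad\tkind\tstable\tspread\n")
            for r in self.records:
                fh.write(
                    f"{self.chrom}\t{r.dyad}\t{r.kind}\t"
                    f"{int(r.stable)}\t{r.spread:g}\n"
                )


def _feature_length(kind: str, params: SimParams) -> int:
    if kind == STABLE:
        return params.spacing
    return REGION_LENGTHS[kind]


def simulate_features(params: SimParams) -> Tuple[List[Tuple[str, int, int]], TruthTable]:
    """Tile the genome with features and plant truth dyads.

    Returns (feature map, truth table); the feature map lists
    (kind, region_start, region_end) half-open intervals laid end-to-end.
    Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    kinds = [k for k, w in params.weights.items() if w > 0]
    probs = np.array([params.weights[k] for k in kinds])
    probs = probs / probs.sum()
    if params.genome_length < min(_feature_length(k, params) for k in kinds):
        raise ValueError("genome shorter than the smallest feature")

    features: List[Tuple[str, int, int]] = []
    records: List[TruthRecord] = []
    cursor = 0
    while cursor < params.genome_length:
        kind = kinds[rng.choice(len(kinds), p=probs)]
        length = _feature_length(kind, params)
        end = min(cursor + length, params.genome_length)
        if end - cursor < params.footprint and kind != NFR:
            # trailing stub too short for a nucleosome; pad as free DNA
            kind = NFR
        features.append((kind, cursor, end))
        if kind == STABLE:
            records.append(
                TruthRecord((cursor + end) // 2, STABLE, params.stable_spread)
            )
        elif kind == PHASED:
            # regularly spaced dyads anchored at the region start, jitter sd
            # growing with the index in the array
            dyad = cursor + params.spacing // 2
            index = 0
            while dyad < end - params.footprint // 2:
                spread = min(
                    params.phased_spread_max,
                    params.phased_spread_min + index * params.phased_spread_step,
                )
                records.append(TruthRecord(dyad, PHASED, spread))
                dyad += params.spacing
                index += 1
        elif kind == FUZZY:
            dyad = cursor + params.spacing // 2
            while dyad < end - params.footprint // 2:
                records.append(TruthRecord(dyad, FUZZY, params.fuzzy_spread))
                dyad += params.spacing
        cursor = end
    return features, TruthTable(records, params.chrom)


@dataclass(frozen=True)
class SimRead:
    alignment: ReadAlignment
    source: int  # truth-record index, or -1 for background


class SimReads:
    def __init__(self, reads: List[SimRead], params: SimParams):
        self.reads = reads
        self.params = params

    def __len__(self) -> int:
        return len(self.reads)

    def alignments(self) -> List[ReadAlignment]:
        return [r.alignment for r in self.reads]

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, r in enumerate(self.reads):
                a = r.alignment
                fh.write(
                    f"{a.chrom}\t{a.start}\t{a.start + a.length}\t"
                    f"read{i}\t0\t{a.strand}\n"
                )


def fragment_bounds(centre: int, length: int) -> Tuple[int, int]:
    """Inclusive fragment interval centred on a dyad.

    The fragment covers [centre - ceil(L/2), centre + ceil(L/2) - 1]; for
    even L this is exactly centred ([c-75, c+74] at L=150), for odd L the
    extra base sits upstream.
    """
    left = centre - (length + 1) // 2
    return left, left + length - 1


def simulate_reads(
    truth: TruthTable, params: SimParams, rng: np.random.Generator | None = None
) -> SimReads:
    """Draw ``params.n_reads`` reads from planted dyads plus background.

    Each signal read: pick a truth dyad uniformly, jitter its position by a
    rounded Normal(0, spread), draw fragment length ~ Normal(150, 10)
    rounded, place the fragment centred on the jittered dyad, and emit the
    36 bp read at the forward (left) or reverse (right) fragment end with
    equal probability. Reads extending past either genome edge are redrawn.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed + 1)
    n = params.n_reads
    if n == 0:
        return SimReads([], params)
    if len(truth) == 0 and params.background_fraction < 1.0:
        raise ValueError("no truth dyads and background_fraction < 1")
    L = params.genome_length
    rl = params.read_length
    dyads = truth.dyads()
    spreads = np.array([r.spread for r in truth.records], dtype=float)
    reads: List[SimRead] = []
    while len(reads) < n:
        if rng.random() < params.background_fraction:
            # uniform 5' position on a uniform strand
            strand = FORWARD if rng.random() < 0.5 else REVERSE
            pos5 = int(rng.integers(0, L))
            start = pos5 if strand == FORWARD else pos5 - rl + 1
            if start < 0 or start + rl > L:
                continue
            reads.append(
                SimRead(ReadAlignment(params.chrom, strand, start, rl), -1)
            )
            continue
        i = int(rng.integers(0, len(dyads)))
        jitter = int(round(rng.normal(0.0, spreads[i]))) if spreads[i] > 0 else 0
        centre = int(dyads[i]) + jitter
        frag_len = max(int(round(rng.normal(params.fragment_mean, params.fragment_sd))), rl)
        left, right = fragment_bounds(centre, frag_len)
        if rng.random() < 0.5:
            strand, start = FORWARD, left
        else:
            strand, start = REVERSE, right - rl + 1
        if start < 0 or start + rl > L:
            continue
        reads.append(SimRead(ReadAlignment(params.chrom, strand, start, rl), i))
    return SimReads(reads, params)
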