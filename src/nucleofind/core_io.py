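"""Reading and writing of genomic formats and strand-specific read-start counts.

All internal coordinates are 0-based. BED input/output is 0-based half-open,
GFF3 input is 1-based inclusive and converted on read. The only read
coordinate the nucleosome model uses is the 5' end of each fragment on its
strand: the leftmost aligned base for forward-strand reads, the rightmost for
reverse-strand reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Tuple

import numpy as np

logger = logging.getLogger(__name__)

FORWARD = "+"
REVERSE = "-"


@dataclass(frozen=True)
class ReadAlignment:
    """A mapped single-end read: chromosome, strand, leftmost position, length."""

    chrom: str
    strand: str  # "+" or "-"
    start: int  # 0-based leftmost aligned position
    length: int  # aligned length in bp

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.length <= 0:
            raise ValueError(f"non-positive length {self.length}")
        if self.strand not in (FORWARD, REVERSE):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the read 5' end."""
        return self.start if self.strand == FORWARD else self.start + self.length - 1


class GenomeInfo:
    """Ordered mapping of chromosome name to length in bp."""

    def __init__(self, sizes: Dict[str, int] | Iterable[Tuple[str, int]]):
        items = sizes.items() if isinstance(sizes, dict) else list(sizes)
        self._sizes: Dict[str, int] = {}
        for name, length in items:
            if name in self._sizes:
                raise ValueError(f"duplicate chromosome {name}")
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length {length}")
            self._sizes[name] = int(length)

    def __contains__(self, name: str) -> bool:
        return name in self._sizes

    def __getitem__(self, name: str) -> int:
        return self._sizes[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def items(self):
        return self._sizes.items()

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenomeInfo":
        """Read a two-column chromosome-sizes table (name, length)."""
        pairs = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t") if "\t" in line else line.split()
                if len(fields) < 2:
                    raise ValueError(f"{path}:{lineno}: expected two columns")
                pairs.append((fields[0], int(fields[1])))
        return cls(pairs)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in self._sizes.items():
                fh.write(f"{name}\t{length}\n")


class StrandCounts:
    """Per-chromosome arrays of read 5'-start counts, one array per strand."""

    def __init__(self, genome: GenomeInfo):
        self.genome = genome
        self.fwd: Dict[str, np.ndarray] = {
            c: np.zeros(n, dtype=np.int64) for c, n in genome.items()
        }
        self.rev: Dict[str, np.ndarray] = {
            c: np.zeros(n, dtype=np.int64) for c, n in genome.items()
        }
        self.n_skipped = 0

    def total(self) -> int:
        return int(
            sum(a.sum() for a in self.fwd.values())
            + sum(a.sum() for a in self.rev.values())
        )

    def chromosomes(self) -> List[str]:
        return list(self.genome)


def load_alignments(
    path: str | Path, format: str | None = None
) -> Iterator[ReadAlignment]:
    """Stream alignments from a BED6 or BAM file.

    Only chromosome, strand, leftmost position and aligned length are kept.
    For BAM, unmapped and secondary/supplementary records are skipped.
    """
    path = Path(path)
    if format is None:
        format = "BAM" if path.suffix.lower() == ".bam" else "BED"
    format = format.upper()
    if format == "BED":
        yield from _load_bed(path)
    elif format == "BAM":
        yield from _load_bam(path)
    else:
        raise ValueError(f"unknown alignment format {format!r}")


def _load_bed(path: Path) -> Iterator[ReadAlignment]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 6:
                raise ValueError(
                    f"{path}:{lineno}: BED6 record required (strand missing)"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable coordinates") from exc
            strand = fields[5]
            if strand not in (FORWARD, REVERSE):
                raise ValueError(f"{path}:{lineno}: invalid strand {strand!r}")
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start")
            yield ReadAlignment(fields[0], strand, start, end - start)


def _load_bam(path: Path) -> Iterator[ReadAlignment]:
    import pysam

    with pysam.AlignmentFile(str(path), "rb") as bam:
        for rec in bam.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            length = rec.reference_length or rec.query_length
            if not length:
                continue
            yield ReadAlignment(
                rec.reference_name,
                REVERSE if rec.is_reverse else FORWARD,
                rec.reference_start,
                length,
            )


def read_starts(
    alignments: Iterable[ReadAlignment],
    genome: GenomeInfo,
    dedup: bool = False,
) -> StrandCounts:
    """Accumulate read 5'-end counts per strand.

    Forward reads contribute at their leftmost coordinate, reverse reads at
    start + length - 1 (their 5' end). Records on unknown chromosomes or with
    an out-of-bounds 5' position are skipped, logged, and counted in
    ``n_skipped``. With ``dedup`` identical (chrom, strand, 5') triples
    collapse to one count.
    """
    counts = StrandCounts(genome)
    seen = set() if dedup else None
    for aln in alignments:
        if aln.chrom not in genome:
            logger.warning("skipping read on unknown chromosome %s", aln.chrom)
            counts.n_skipped += 1
            continue
        pos = aln.five_prime
        if pos < 0 or pos >= genome[aln.chrom]:
            logger.warning(
                "skipping read with out-of-bounds 5' position %s:%d", aln.chrom, pos
            )
            counts.n_skipped += 1
            continue
        if seen is not None:
            key = (aln.chrom, aln.strand, pos)
            if key in seen:
                continue
            seen.add(key)
        target = counts.fwd if aln.strand == FORWARD else counts.rev
        target[aln.chrom][pos] += 1
    return counts


@dataclass(frozen=True)
class Anchor:
    chrom: str
    position: int  # 0-based
    strand: str
    kind: str  # "TSS" or "TES"


class AnchorSet:
    """TSS/TES anchor positions extracted from a gene annotation."""

    def __init__(self, anchors: Iterable[Anchor] = ()):
        self.anchors: List[Anchor] = list(anchors)

    def __len__(self) -> int:
        return len(self.anchors)

    def __iter__(self) -> Iterator[Anchor]:
        return iter(self.anchors)

    def of_kind(self, kind: str) -> "AnchorSet":
        return AnchorSet(a for a in self.anchors if a.kind == kind)


def load_anchors(
    path: str | Path, feature_types: Iterable[str] = ("gene",)
) -> AnchorSet:
    """Extract TSS/TES anchors from a GFF3 file.

    GFF coordinates are 1-based inclusive; the returned positions are 0-based.
    On the forward strand TSS = feature start and TES = feature end; on the
    reverse strand the roles swap.
    """
    wanted = set(feature_types)
    anchors: List[Anchor] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise ValueError(f"{path}:{lineno}: malformed GFF line")
            if fields[2] not in wanted:
                continue
            try:
                start1, end1 = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable coordinates") from exc
            strand = fields[6]
            if strand not in (FORWARD, REVERSE):
                raise ValueError(f"{path}:{lineno}: invalid strand {strand!r}")
            start0, end0 = start1 - 1, end1 - 1
            if strand == FORWARD:
                tss, tes = start0, end0
            else:
                tss, tes = end0, start0
            anchors.append(Anchor(fields[0], tss, strand, "TSS"))
            anchors.append(Anchor(fields[0], tes, strand, "TES"))
    return AnchorSet(anchors)


def write_reads_bed(
    counts: StrandCounts, path: str | Path, read_length: int = 36
) -> None:
    """Write one BED6 record per counted read 5' end (round-trip format)."""
    with open(path, "w") as fh:
        i = 0
        for chrom in counts.chromosomes():
            L = counts.genome[chrom]
            for pos in np.nonzero(counts.fwd[chrom])[0]:
                end = min(int(pos) + read_length, L)
                for _ in range(int(counts.fwd[chrom][pos])):
                    fh.write(f"{chrom}\t{pos}\t{end}\tread{i}\t0\t+\n")
                    i += 1
            for pos in np.nonzero(counts.rev[chrom])[0]:
                start = max(int(pos) - read_length + 1, 0)
                for _ in range(int(counts.rev[chrom][pos])):
                    fh.write(f"{chrom}\t{start}\t{int(pos) + 1}\tread{i}\t0\t-\n")
                    i += 1


def write_bedgraph(
    values: Dict[str, np.ndarray], path: str | Path, track_name: str = "track"
) -> None:
    """Export per-position values as bedGraph, merging runs of equal value."""
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{track_name}"\n')
        for chrom, arr in values.items():
            arr = np.asarray(arr, dtype=float)
            if arr.size == 0:
                continue
            change = np.nonzero(np.diff(arr))[0] + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [arr.size]])
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")
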