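"""ATAC-seq interval computations.

Coordinates are 0-based half-open throughout (BED convention).  The
module covers the bespoke pieces of the chromatin-accessibility analysis:
peak merge/intersect, ±flank TSS windows, Tn5 cut-site count matrices with
CPM normalization, and the genomic-feature enrichment statistic

    enrichment = (a/b) / (c/d),

where a is the number of peaks overlapping the feature (>= 1 bp), b the
total number of peaks, c the number of feature regions, and
d = G / (mean peak length + mean feature length) estimates how many
discrete slots of the genome (total length G) a peak and a feature could
co-occupy.  Under uniform random peak placement a/b approaches c/d, so the
statistic is calibrated to 1.

Merge and intersect are delegated to pyranges; the statistic itself and
the cut-site counting are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pyranges as pr

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "PeakSet",
    "FeatureSet",
    "EnrichmentResult",
    "CutCountMatrix",
    "merge_peaks",
    "intersect_peaks",
    "tss_windows",
    "feature_enrichment",
    "count_cut_sites",
    "cpm_normalize",
    "read_bed",
    "write_bed",
    "read_genome_tsv",
    "shift_cut_sites",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("empty chromosome name")
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"bad interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class IntervalSet:
    """A named, sorted set of intervals on a genome (chrom -> length)."""

    name: str
    intervals: list[GenomicInterval]
    genome: dict[str, int]

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals)
        for iv in self.intervals:
            if iv.chrom not in self.genome:
                raise ValueError(f"{self.name}: interval on unknown chromosome {iv.chrom}")
            if iv.end > self.genome[iv.chrom]:
                raise ValueError(
                    f"{self.name}: {iv.chrom}:{iv.start}-{iv.end} exceeds "
                    f"chromosome length {self.genome[iv.chrom]}"
                )

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def mean_length(self) -> float:
        if not self.intervals:
            raise ValueError(f"{self.name}: empty interval set")
        return float(np.mean([iv.length for iv in self.intervals]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Chromosome": [iv.chrom for iv in self.intervals],
                "Start": [iv.start for iv in self.intervals],
                "End": [iv.end for iv in self.intervals],
            }
        )

    @classmethod
    def from_frame(cls, name: str, df: pd.DataFrame, genome: dict[str, int]):
        ivs = [
            GenomicInterval(str(c), int(s), int(e))
            for c, s, e in zip(df["Chromosome"], df["Start"], df["End"])
        ]
        return cls(name=name, intervals=ivs, genome=genome)


PeakSet = IntervalSet
FeatureSet = IntervalSet


def _check_same_genome(sets: list[IntervalSet]) -> dict[str, int]:
    genome = sets[0].genome
    for s in sets[1:]:
        if s.genome != genome:
            raise ValueError(f"genome mismatch between {sets[0].name!r} and {s.name!r}")
    return genome


def merge_peaks(sets: list[IntervalSet], name: str = "merged") -> IntervalSet:
    """Union of interval sets with overlapping/bookended intervals coalesced."""
    if not sets:
        raise ValueError("no interval sets to merge")
    genome = _check_same_genome(sets)
    df = pd.concat([s.to_frame() for s in sets], ignore_index=True)
    if df.empty:
        return IntervalSet(name, [], genome)
    merged = pr.PyRanges(df).merge().df
    return IntervalSet.from_frame(name, merged, genome)


def intersect_peaks(a: IntervalSet, b: IntervalSet, name: str | None = None) -> IntervalSet:
    """Overlapping portions of *a* against *b*."""
    genome = _check_same_genome([a, b])
    name = name or f"{a.name}&{b.name}"
    if not a.intervals or not b.intervals:
        return IntervalSet(name, [], genome)
    out = pr.PyRanges(a.to_frame()).intersect(pr.PyRanges(b.to_frame())).df
    if out.empty:
        return IntervalSet(name, [], genome)
    return IntervalSet.from_frame(name, out, genome)


def tss_windows(
    tss: pd.DataFrame, genome: dict[str, int], flank: int = 1000, name: str = "TSS"
) -> FeatureSet:
    """±flank windows around transcription start sites.

    *tss* has columns chrom, pos (0-based), strand (unused for the window
    itself), and optionally gene_id; every row yields a window, so genes
    with multiple TSSs contribute multiple windows.  Windows are clipped
    to chromosome bounds.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    ivs = []
    for chrom, pos in zip(tss["chrom"], tss["pos"]):
        chrom = str(chrom)
        if chrom not in genome or not (0 <= pos < genome[chrom]):
            raise ValueError(f"TSS position {chrom}:{pos} outside genome")
        ivs.append(
            GenomicInterval(chrom, max(0, int(pos) - flank), min(genome[chrom], int(pos) + flank))
        )
    return FeatureSet(name, ivs, genome)


@dataclass(frozen=True)
class EnrichmentResult:
    feature: str
    a: int  # peaks overlapping the feature
    b: int  # total peaks
    c: int  # feature regions
    d: float  # estimated overlappable slots: G / (mean peak len + mean feature len)
    enrichment: float


def feature_enrichment(peaks: PeakSet, feature: FeatureSet) -> EnrichmentResult:
    """The (a/b)/(c/d) genomic-feature enrichment of a peak set."""
    if not peaks.intervals or not feature.intervals:
        raise ValueError("undefined enrichment: empty peak or feature set")
    genome = _check_same_genome([peaks, feature])
    b = len(peaks)
    c = len(feature)
    pf = peaks.to_frame()
    pf["PeakIndex"] = np.arange(len(pf))  # survives duplicate coordinates
    hits = pr.PyRanges(pf).overlap(pr.PyRanges(feature.to_frame())).df
    a = 0 if hits.empty else int(hits["PeakIndex"].nunique())
    G = float(sum(genome.values()))
    d = G / (peaks.mean_length + feature.mean_length)
    return EnrichmentResult(
        feature=feature.name, a=a, b=b, c=c, d=d, enrichment=(a / b) / (c / d)
    )


# ---------------------------------------------------------------------------
# cut-site counting


@dataclass
class CutCountMatrix:
    counts: pd.DataFrame  # rows: "chrom:start-end" peak labels, cols: samples
    skipped: dict[str, int] = field(default_factory=dict)  # QC: per-sample dropped cuts

    def column_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)


def shift_cut_sites(
    positions: np.ndarray, strands: np.ndarray, forward_shift: int = 4, reverse_shift: int = -5
) -> np.ndarray:
    """Tn5 transposition-center correction of read 5' ends (+4 / -5)."""
    shift = np.where(np.asarray(strands) == "+", forward_shift, reverse_shift)
    return np.asarray(positions) + shift


def count_cut_sites(
    cuts: dict[str, pd.DataFrame], peaks: PeakSet
) -> CutCountMatrix:
    """Count Tn5 cut positions per peak per sample.

    *cuts* maps sample name to a frame with columns chrom, pos (already
    shifted cut positions).  Positions on chromosomes absent from the peak
    genome are skipped and tallied in the QC counter.
    """
    labels = [f"{iv.chrom}:{iv.start}-{iv.end}" for iv in peaks.intervals]
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for i, iv in enumerate(peaks.intervals):
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, i))

    data = {}
    skipped: dict[str, int] = {}
    for sample, frame in cuts.items():
        col = np.zeros(len(labels), dtype=np.int64)
        dropped = 0
        for chrom, grp in frame.groupby("chrom"):
            chrom = str(chrom)
            if chrom not in peaks.genome:
                dropped += len(grp)
                continue
            pos = np.sort(grp["pos"].to_numpy())
            for start, end, i in by_chrom.get(chrom, []):
                col[i] += np.searchsorted(pos, end) - np.searchsorted(pos, start)
        data[sample] = col
        skipped[sample] = dropped
    counts = pd.DataFrame(data, index=labels)
    return CutCountMatrix(counts=counts, skipped=skipped)


def cpm_normalize(m: CutCountMatrix) -> pd.DataFrame:
    """Counts-per-million scaling per sample; all-zero samples stay zero."""
    totals = m.counts.sum(axis=0)
    safe = totals.replace(0, 1)
    return m.counts / safe * 1e6


# ---------------------------------------------------------------------------
# I/O


def read_genome_tsv(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return {str(c): int(l) for c, l in zip(df["chrom"], df["length"])}


def read_bed(path, genome: dict[str, int], name: str | None = None) -> IntervalSet:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :3]
    df.columns = ["Chromosome", "Start", "End"]
    return IntervalSet.from_frame(name or str(path), df, genome)


def write_bed(s: IntervalSet, path) -> None:
    s.to_frame().to_csv(path, sep="\t", header=False, index=False)
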