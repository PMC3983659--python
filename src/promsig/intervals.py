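"""Genomic coordinate algebra: intervals, transcript clusters, loci, promoters, CNEs.

All coordinates are 0-based, half-open (BED convention). A "locus" is the
territory assigned to a cluster of overlapping transcripts: the cluster span
plus the nearest half of each flanking intergenic gap, so that loci tile each
chromosome exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "GenomicInterval",
    "TranscriptRecord",
    "GeneCluster",
    "Locus",
    "PromoterRegion",
    "ConservedElement",
    "cluster_overlapping_transcripts",
    "define_loci",
    "define_promoter",
    "extract_cnes",
    "merge_overlapping",
    "distance_to_nearest_tss",
    "overlaps",
]

_STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def key(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    return a.overlaps(b)


@dataclass(frozen=True)
class TranscriptRecord:
    """A transcript with its strand-aware 5' transcription start site."""

    gene_symbol: str
    interval: GenomicInterval

    @property
    def tss(self) -> int:
        if self.interval.strand == "-":
            return self.interval.end - 1
        return self.interval.start


@dataclass
class GeneCluster:
    cluster_id: int
    span: GenomicInterval
    members: list[TranscriptRecord] = field(default_factory=list)


@dataclass(frozen=True)
class Locus:
    cluster_id: int
    span: GenomicInterval


@dataclass(frozen=True)
class PromoterRegion:
    gene_symbol: str
    interval: GenomicInterval
    tss: int


@dataclass
class ConservedElement:
    """A conserved non-coding element: interval, cross-species identity, sequence."""

    interval: GenomicInterval
    identity: float
    sequence: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError(f"identity {self.identity} outside [0, 1]")
        if self.sequence and len(self.sequence) != self.interval.length:
            raise ValueError("sequence length does not match interval length")


def cluster_overlapping_transcripts(
    transcripts: Sequence[TranscriptRecord],
) -> list[GeneCluster]:
    """Cluster transcripts connected by chains of >=1 bp overlap.

    Strand is ignored: any two transcripts on the same chromosome whose
    intervals intersect belong to the same cluster, transitively.
    """
    by_chrom: dict[str, list[TranscriptRecord]] = {}
    for t in transcripts:
        by_chrom.setdefault(t.interval.chrom, []).append(t)

    clusters: list[GeneCluster] = []
    cid = 0
    for chrom in sorted(by_chrom):
        recs = sorted(by_chrom[chrom], key=lambda t: (t.interval.start, t.interval.end))
        open_members: list[TranscriptRecord] = []
        span_start = span_end = -1
        for t in recs:
            if open_members and t.interval.start < span_end:
                open_members.append(t)
                span_end = max(span_end, t.interval.end)
            else:
                if open_members:
                    clusters.append(
                        GeneCluster(
                            cid,
                            GenomicInterval(chrom, span_start, span_end),
                            open_members,
                        )
                    )
                    cid += 1
                open_members = [t]
                span_start, span_end = t.interval.start, t.interval.end
        if open_members:
            clusters.append(
                GeneCluster(cid, GenomicInterval(chrom, span_start, span_end), open_members)
            )
            cid += 1
    return clusters


def define_loci(
    clusters: Sequence[GeneCluster], chrom_sizes: Mapping[str, int]
) -> list[Locus]:
    """Assign each cluster the nearest half of its flanking intergenic gaps.

    Each intergenic gap is split at its (integer-floor) midpoint; chromosome
    ends go to the terminal loci, so per-chromosome tiling is exact.
    """
    by_chrom: dict[str, list[GeneCluster]] = {}
    for c in clusters:
        size = chrom_sizes.get(c.span.chrom)
        if size is None:
            raise ValueError(f"unknown chromosome {c.span.chrom}")
        if c.span.end > size:
            raise ValueError(f"cluster {c.span.key()} outside chromosome bounds")
        by_chrom.setdefault(c.span.chrom, []).append(c)

    loci: list[Locus] = []
    for chrom, cs in by_chrom.items():
        cs = sorted(cs, key=lambda c: c.span.start)
        for prev, cur in zip(cs, cs[1:]):
            if prev.span.end > cur.span.start:
                raise ValueError("clusters overlap; cluster transcripts first")
        size = chrom_sizes[chrom]
        n = len(cs)
        for i, c in enumerate(cs):
            left = 0 if i == 0 else (cs[i - 1].span.end + c.span.start) // 2
            right = size if i == n - 1 else (c.span.end + cs[i + 1].span.start) // 2
            loci.append(Locus(c.cluster_id, GenomicInterval(chrom, left, right)))
    return loci


def define_promoter(
    gene_symbol: str,
    tss: int,
    strand: str,
    chrom: str,
    chrom_size: int,
    upstream: int = 2500,
    downstream: int = 500,
) -> PromoterRegion:
    """Strand-aware promoter window around the TSS, clipped to the chromosome.

    The default window spans 2.5 kb upstream and 0.5 kb downstream of the TSS
    (3 kb total), covering the core and proximal promoter.
    """
    if not (0 <= tss < chrom_size):
        raise ValueError(f"TSS {tss} outside chromosome of size {chrom_size}")
    if strand == "-":
        start, end = tss - downstream + 1, tss + upstream + 1
    else:
        start, end = tss - upstream, tss + downstream
    start, end = max(0, start), min(chrom_size, end)
    return PromoterRegion(
        gene_symbol, GenomicInterval(chrom, start, end, strand), tss
    )


def merge_overlapping(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Minimal set of disjoint intervals with the same base coverage."""
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def extract_cnes(
    identity_blocks: Sequence[tuple[GenomicInterval, float]],
    genome: Mapping[str, str] | None,
    min_identity: float = 0.70,
    min_length: int = 100,
) -> list[ConservedElement]:
    """Threshold alignment-identity blocks into conserved elements.

    Blocks with identity >= ``min_identity`` are kept, adjacent/overlapping
    surviving blocks are merged (identity of a merged run is the
    length-weighted mean), and runs shorter than ``min_length`` are dropped.
    Sequences are attached from ``genome`` when provided.
    """
    for iv, ident in identity_blocks:
        if not (0.0 <= ident <= 1.0):
            raise ValueError(f"identity {ident} outside [0, 1]")
        if genome is not None:
            seq = genome.get(iv.chrom)
            if seq is not None and iv.end > len(seq):
                raise ValueError(f"block {iv.key()} beyond chromosome end")

    kept = sorted(
        ((iv, ident) for iv, ident in identity_blocks if ident >= min_identity),
        key=lambda p: (p[0].chrom, p[0].start, p[0].end),
    )
    runs: list[tuple[str, int, int, float]] = []  # chrom, start, end, identity*bp
    for iv, ident in kept:
        if runs and runs[-1][0] == iv.chrom and iv.start <= runs[-1][2]:
            chrom, start, end, mass = runs[-1]
            new_end = max(end, iv.end)
            runs[-1] = (chrom, start, new_end, mass + ident * iv.length)
        else:
            runs.append((iv.chrom, iv.start, iv.end, ident * iv.length))

    out: list[ConservedElement] = []
    for chrom, start, end, mass in runs:
        if end - start < min_length:
            continue
        identity = min(1.0, mass / (end - start))
        seq = ""
        if genome is not None and chrom in genome:
            seq = str(genome[chrom][start:end]).upper()
        out.append(ConservedElement(GenomicInterval(chrom, start, end), identity, seq))
    return out


def distance_to_nearest_tss(
    interval: GenomicInterval, transcripts: Sequence[TranscriptRecord]
) -> int:
    """0 if a TSS lies inside the interval, else the gap to the closest TSS."""
    tsss = [t.tss for t in transcripts if t.interval.chrom == interval.chrom]
    if not tsss:
        raise ValueError(f"no transcript on chromosome {interval.chrom}")
    best = None
    for tss in tsss:
        if interval.start <= tss < interval.end:
            return 0
        d = interval.start - tss if tss < interval.start else tss - interval.end
        best = d if best is None else min(best, d)
    return best
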