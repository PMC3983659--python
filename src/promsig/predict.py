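"""Score distal sequences with a trained promoter model and call predictions.

Candidates are either conserved elements outside promoter exclusion zones or
fixed-size sliding windows (230 bp, shifted by 115 bp). A candidate is called
an enhancer prediction when its decision score exceeds s = min(0, delta),
where delta is the lowest score among the top 5% of candidates scanned in a
control locus set (the loci of the lowly expressed genes, by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .intervals import ConservedElement, GenomicInterval, Locus, PromoterRegion
from .motifs import PWM, BackgroundModel, DEFAULT_P_THRESHOLD, MotifScanner
from .svm import LinearModel, decision_score

__all__ = [
    "CandidateSequence",
    "PredictionSet",
    "select_conserved_candidates",
    "make_windows",
    "score_candidates",
    "compute_threshold",
    "call_predictions",
]

WINDOW_SIZE = 230
WINDOW_STEP = 115
TOP_FRACTION = 0.05


@dataclass
class CandidateSequence:
    interval: GenomicInterval
    origin: str  # "cne" or "window"
    locus_id: int | None = None
    sequence: str = ""
    features: np.ndarray | None = None
    score: float | None = None


@dataclass
class PredictionSet:
    candidates: list[CandidateSequence]
    threshold: float
    control_delta: float
    model_id: str = ""

    def __len__(self) -> int:
        return len(self.candidates)

    @property
    def intervals(self) -> list[GenomicInterval]:
        return [c.interval for c in self.candidates]

    def per_locus_counts(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for c in self.candidates:
            if c.locus_id is not None:
                out[c.locus_id] = out.get(c.locus_id, 0) + 1
        return out


class _LocusIndex:
    """Per-chromosome bisect lookup from interval to containing locus."""

    def __init__(self, loci: Sequence[Locus]) -> None:
        self._by_chrom: dict[str, tuple[list[int], list[tuple[int, int]]]] = {}
        for loc in sorted(loci, key=lambda l: (l.span.chrom, l.span.start)):
            starts, entries = self._by_chrom.setdefault(loc.span.chrom, ([], []))
            starts.append(loc.span.start)
            entries.append((loc.span.end, loc.cluster_id))

    def assign(self, interval: GenomicInterval) -> int | None:
        import bisect

        item = self._by_chrom.get(interval.chrom)
        if item is None:
            return None
        starts, entries = item
        i = bisect.bisect_right(starts, interval.start) - 1
        for j in (i, i + 1):
            if 0 <= j < len(starts):
                end, cid = entries[j]
                if starts[j] < interval.end and interval.start < end:
                    return cid
        return None


def select_conserved_candidates(
    cnes: Sequence[ConservedElement],
    promoters: Sequence[PromoterRegion],
    loci: Sequence[Locus] | None = None,
) -> list[CandidateSequence]:
    """Conserved elements clear of every promoter exclusion zone.

    A CNE overlapping any promoter window (the training -2.5 kb/+0.5 kb zone)
    by >= 1 bp is excluded; survivors carry their locus id when loci are
    given.
    """
    by_chrom: dict[str, list[PromoterRegion]] = {}
    for p in promoters:
        by_chrom.setdefault(p.interval.chrom, []).append(p)
    index = _LocusIndex(loci) if loci is not None else None
    out: list[CandidateSequence] = []
    for el in cnes:
        zone = by_chrom.get(el.interval.chrom, [])
        if any(el.interval.overlaps(p.interval) for p in zone):
            continue
        locus_id = index.assign(el.interval) if index is not None else None
        out.append(
            CandidateSequence(el.interval, "cne", locus_id, el.sequence)
        )
    return out


def make_windows(
    genome: Mapping[str, str],
    promoters: Sequence[PromoterRegion],
    size: int = WINDOW_SIZE,
    step: int = WINDOW_STEP,
    loci: Sequence[Locus] | None = None,
) -> list[CandidateSequence]:
    """Sliding windows tiling each chromosome, skipping promoter zones.

    Windows start at multiples of ``step``; a trailing partial window is
    dropped, and any window overlapping a promoter zone is excluded.
    """
    if not (1 <= step <= size):
        raise ValueError("need size >= step >= 1")
    by_chrom: dict[str, list[PromoterRegion]] = {}
    for p in promoters:
        by_chrom.setdefault(p.interval.chrom, []).append(p)
    import bisect

    from .intervals import merge_overlapping

    index = _LocusIndex(loci) if loci is not None else None
    out: list[CandidateSequence] = []
    for chrom in sorted(genome):
        seq = str(genome[chrom])
        zones = merge_overlapping(p.interval for p in by_chrom.get(chrom, []))
        zone_starts = [z.start for z in zones]
        for start in range(0, len(seq) - size + 1, step):
            iv = GenomicInterval(chrom, start, start + size)
            # merged zones are disjoint and sorted: only the nearest can overlap
            i = bisect.bisect_right(zone_starts, iv.start) - 1
            if (i >= 0 and zones[i].end > iv.start) or (
                i + 1 < len(zones) and zones[i + 1].start < iv.end
            ):
                continue
            locus_id = index.assign(iv) if index is not None else None
            out.append(
                CandidateSequence(iv, "window", locus_id, seq[start : start + size])
            )
    return out


def score_candidates(
    model: LinearModel,
    candidates: Sequence[CandidateSequence],
    library: list[PWM],
    bg: BackgroundModel | None = None,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    scanner: MotifScanner | None = None,
) -> list[CandidateSequence]:
    """Attach feature vectors and decision scores; pure function of inputs."""
    if scanner is None:
        scanner = MotifScanner(library, bg, p_threshold)
    if model.motif_ids is not None and model.motif_ids != scanner.motif_ids:
        raise ValueError("model and library motif ordering differ")
    for c in candidates:
        c.features = scanner.count_hits(c.sequence)
        c.score = float(decision_score(model, c.features))
    return list(candidates)


def compute_threshold(
    control_scores: Sequence[float], top_fraction: float = TOP_FRACTION
) -> tuple[float, float]:
    """Prediction threshold s = min(0, delta) from control-locus scores.

    delta is the k-th largest control score with k = max(1,
    floor(top_fraction * N)) - the lowest score of the top 5% by default.
    """
    scores = np.asarray(control_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("no control scores")
    k = max(1, math.floor(top_fraction * scores.size))
    delta = float(np.sort(scores)[::-1][k - 1])
    return min(0.0, delta), delta


def call_predictions(
    scored: Sequence[CandidateSequence],
    s: float,
    delta: float | None = None,
    model_id: str = "",
) -> PredictionSet:
    """Candidates with score strictly greater than the threshold s."""
    for c in scored:
        if c.score is None:
            raise ValueError(f"candidate {c.interval.key()} not scored")
    called = [c for c in scored if c.score > s]
    return PredictionSet(called, s, delta if delta is not None else s, model_id)
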