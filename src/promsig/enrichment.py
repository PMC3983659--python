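"""Locus-level and genome-level statistics for evaluating prediction sets.

Fold enrichments compare prediction densities between the loci of highly and
lowly expressed genes as ratios of proportions; significance comes from
Fisher's exact test (counts), the Wilcoxon rank-sum test (score shifts), and
randomization p-values against length-matched intervals placed uniformly in
allowed genomic space (mark overlaps).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .intervals import GenomicInterval, merge_overlapping
from .stats import rank_sum_test

__all__ = [
    "EnrichmentReport",
    "OverlapReport",
    "fold_enrichment_counts",
    "fisher_exact",
    "fold_loci_fraction",
    "score_shift_test",
    "overlap_count",
    "randomization_pvalue",
    "adjust_pvalues",
    "gc_log_ratio",
]


@dataclass
class EnrichmentReport:
    fold_predictions: float
    fisher_p: float
    fold_loci_fraction: float
    fraction_p: float
    score_shift_p: float
    counts: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "fold_predictions": self.fold_predictions,
            "fisher_p": self.fisher_p,
            "fold_loci_fraction": self.fold_loci_fraction,
            "fraction_p": self.fraction_p,
            "score_shift_p": self.score_shift_p,
            "counts": self.counts,
        }


@dataclass
class OverlapReport:
    observed_overlap: int
    randomized_overlaps: list[int]
    empirical_p: float
    fold: float


def fold_enrichment_counts(
    pred_high: int, scanned_high: int, pred_low: int, scanned_low: int
) -> float:
    """Ratio of prediction proportions: (pred/scanned) high over low."""
    if scanned_high <= 0 or scanned_low <= 0:
        raise ValueError("scanned counts must be positive")
    if pred_high == 0:
        return 0.0
    if pred_low == 0:
        warnings.warn("no predictions in control loci; fold is infinite", stacklevel=2)
        return float("inf")
    return (pred_high / scanned_high) / (pred_low / scanned_low)


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 count table."""
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a 2x2 table of non-negative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        warnings.warn("degenerate margin; p = 1", stacklevel=2)
        return 1.0
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def fold_loci_fraction(
    hit_high: int, tot_high: int, hit_low: int, tot_low: int
) -> float:
    """Ratio of loci fractions: (hit/total) high over low."""
    if tot_high <= 0 or tot_low <= 0:
        raise ValueError("totals must be positive")
    if hit_high > tot_high or hit_low > tot_low:
        raise ValueError("hits cannot exceed totals")
    if hit_high == 0:
        return 0.0
    if hit_low == 0:
        warnings.warn("no control loci hit; fold is infinite", stacklevel=2)
        return float("inf")
    return (hit_high / tot_high) / (hit_low / tot_low)


def score_shift_test(scores_high, scores_low) -> float:
    """Two-sided Wilcoxon rank-sum p comparing candidate score distributions."""
    return rank_sum_test(scores_high, scores_low)[1]


def overlap_count(
    queries: Sequence[GenomicInterval], marks: Sequence[GenomicInterval]
) -> int:
    """Number of query intervals intersecting >= 1 bp of the merged marks."""
    merged = merge_overlapping(marks)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {m.chrom for m in merged}:
        ms = [m for m in merged if m.chrom == chrom]
        by_chrom[chrom] = (
            np.array([m.start for m in ms]),
            np.array([m.end for m in ms]),
        )
    n = 0
    for q in queries:
        item = by_chrom.get(q.chrom)
        if item is None:
            continue
        starts, ends = item
        i = int(np.searchsorted(starts, q.end, side="left")) - 1
        if i >= 0 and ends[i] > q.start and starts[i] < q.end:
            n += 1
    return n


def randomization_pvalue(
    queries: Sequence[GenomicInterval],
    marks: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    excluded: Sequence[GenomicInterval] = (),
    n_rand: int = 1000,
    rng: np.random.Generator | None = None,
) -> OverlapReport:
    """Empirical overlap p-value against uniformly placed length-matched sets.

    Each randomization draws |queries| intervals with the original lengths,
    uniformly within the allowed space (chromosomes minus excluded regions;
    randomized intervals are not collision-checked against each other). The
    p-value uses add-one smoothing: (1 + #{rand >= observed}) / (n_rand + 1).
    """
    if rng is None:
        rng = np.random.default_rng()
    observed = overlap_count(queries, marks)

    # allowed placement segments per chromosome
    excl = merge_overlapping(excluded)
    segments: list[tuple[str, int, int]] = []
    for chrom, size in chrom_sizes.items():
        pos = 0
        for e in [x for x in excl if x.chrom == chrom]:
            if e.start > pos:
                segments.append((chrom, pos, e.start))
            pos = max(pos, e.end)
        if pos < size:
            segments.append((chrom, pos, size))

    lengths = [q.length for q in queries]
    max_len = max(lengths) if lengths else 0
    fits = [(c, s, e) for c, s, e in segments if e - s >= max_len]
    if not fits and lengths:
        raise ValueError("allowed space smaller than the longest query")

    cache: dict[int, tuple[list[tuple[str, int, int]], np.ndarray]] = {}
    for length in set(lengths):
        ok = [(c, s, e) for c, s, e in segments if e - s >= length]
        weights = np.array([e - s - length + 1 for _, s, e in ok], dtype=float)
        cache[length] = (ok, weights / weights.sum())

    rand_overlaps: list[int] = []
    for _ in range(n_rand):
        placed: list[GenomicInterval] = []
        for length in lengths:
            ok, probs = cache[length]
            seg = ok[int(rng.choice(len(ok), p=probs))]
            start = int(rng.integers(seg[1], seg[2] - length + 1))
            placed.append(GenomicInterval(seg[0], start, start + length))
        rand_overlaps.append(overlap_count(placed, marks))

    arr = np.array(rand_overlaps)
    p = float((1 + int((arr >= observed).sum())) / (n_rand + 1))
    if observed == 0 and np.all(arr == 0):
        p = 1.0
    mean_rand = float(arr.mean()) if n_rand else float("nan")
    fold = observed / mean_rand if mean_rand > 0 else float("inf" if observed else "nan")
    return OverlapReport(observed, rand_overlaps, p, fold)


def adjust_pvalues(pvalues, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment: 'bonferroni' or 'bh' (Benjamini-Hochberg)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    name = {"bh": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if name is None:
        raise ValueError(f"unknown method {method!r}")
    return multipletests(p, method=name)[1]


def gc_log_ratio(seqs_a, seqs_b, base: str | float = "e") -> float:
    """log(GC_a / GC_b) over concatenated bases; base 'e' (default) or 2."""

    def gc(seqs) -> float:
        g = at = 0
        for s in seqs:
            su = s.upper()
            g += su.count("G") + su.count("C")
            at += su.count("A") + su.count("T")
        tot = g + at
        if tot == 0:
            raise ValueError("no non-N bases")
        return g / tot

    gca, gcb = gc(seqs_a), gc(seqs_b)
    if gcb == 0:
        raise ValueError("GC content of denominator set is zero")
    if gca == 0:
        return float("-inf")
    ratio = gca / gcb
    if base in ("e", np.e):
        return float(np.log(ratio))
    if base == 2:
        return float(np.log2(ratio))
    return float(np.log(ratio) / np.log(float(base)))
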