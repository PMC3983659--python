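"""Synthetic genomes with planted tissue-specific regulatory structure.

The generator emulates the study design the package is built around: a
single-chromosome genome tiled by equal-sized gene loci; per tissue, 200
highly and 200 lowly expressed genes; promoters (-2.5 kb/+0.5 kb of the TSS)
containing on average 2.4 conserved elements of ~249 bp mean length; a set of
"planted" tissue-specific motifs embedded (with per-site probability
``p_plant``) into the conserved elements of highly expressed promoters and
into ``n_enh`` distal truth enhancers per highly expressed locus; and decoy
motifs that are never embedded. Conservation is a binary mask with identity
drawn Uniform(0.70, 0.95). Everything is reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import (
    GenomicInterval,
    Locus,
    PromoterRegion,
    TranscriptRecord,
    define_promoter,
)
from .motifs import PWM, BackgroundModel

__all__ = ["SyntheticSpec", "SyntheticBundle", "generate", "truth_eval"]

_DECODE = np.frombuffer("ACGT".encode(), dtype=np.uint8)


@dataclass
class SyntheticSpec:
    """Study-condition parameters of the synthetic genome."""

    n_high: int = 200
    n_low: int = 200
    n_other: int = 20
    locus_length: int = 60_000
    tx_length: int = 10_000
    promoter_upstream: int = 2_500
    promoter_downstream: int = 500
    cnes_per_promoter_mean: float = 2.4
    cne_length_mean: float = 249.0
    cne_min_length: int = 100
    distal_cnes_per_locus_mean: float = 4.0
    identity_range: tuple[float, float] = (0.70, 0.95)
    n_planted: int = 3
    p_plant: float = 0.8
    n_enh: int = 2
    decoy_motifs: int = 97
    motif_length: int = 10
    motif_sharpness: float = 0.85
    background: BackgroundModel = field(default_factory=BackgroundModel)
    chrom: str = "chr1"
    tissue: str = "tissue_a"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_high", "n_low", "n_other", "n_planted", "n_enh", "decoy_motifs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.p_plant <= 1.0):
            raise ValueError("p_plant must be in [0, 1]")
        needed = (
            self.promoter_upstream
            + self.promoter_downstream
            + self.tx_length
            + (self.n_enh + 4) * int(2 * self.cne_length_mean)
        )
        if self.locus_length < needed:
            raise ValueError(
                f"locus_length {self.locus_length} too short for the requested "
                f"elements (need >= {needed})"
            )


@dataclass
class SyntheticBundle:
    genome: dict[str, str]
    chrom_sizes: dict[str, int]
    transcripts: list[TranscriptRecord]
    identity_blocks: list[tuple[GenomicInterval, float]]
    expression: pd.DataFrame
    truth_enhancers: list[GenomicInterval]
    library: list[PWM]
    planted_motif_ids: list[str]
    high_genes: list[str]
    low_genes: list[str]
    loci: list[Locus]
    promoters: list[PromoterRegion]
    spec: SyntheticSpec


def _random_pwm(rng: np.random.Generator, motif_id: str, length: int, sharp: float) -> PWM:
    probs = np.full((length, 4), (1.0 - sharp) / 3.0)
    dominant = rng.integers(0, 4, size=length)
    probs[np.arange(length), dominant] = sharp
    return PWM(motif_id, probs, "synthetic")


def _sample_site(rng: np.random.Generator, pwm: PWM) -> np.ndarray:
    """Draw one binding-site instance (code array) from the PWM."""
    u = rng.random(len(pwm))
    cum = np.cumsum(pwm.probs, axis=1)
    return (u[:, None] < cum).argmax(axis=1).astype(np.uint8)


def _place_nonoverlapping(
    rng: np.random.Generator,
    lo: int,
    hi: int,
    lengths: Sequence[int],
    taken: list[tuple[int, int]],
    tries: int = 60,
) -> list[tuple[int, int]]:
    """Sample start positions in [lo, hi) avoiding ``taken``; skip on failure."""
    placed: list[tuple[int, int]] = []
    for length in lengths:
        if hi - lo < length:
            continue
        for _ in range(tries):
            start = int(rng.integers(lo, hi - length + 1))
            iv = (start, start + length)
            if all(iv[1] <= s or e <= iv[0] for s, e in taken):
                taken.append(iv)
                placed.append(iv)
                break
    return placed


def generate(spec: SyntheticSpec) -> SyntheticBundle:
    """Build a fully consistent synthetic bundle from the spec's seed."""
    rng = np.random.default_rng(spec.seed)
    n_genes = spec.n_high + spec.n_low + spec.n_other
    L = spec.locus_length
    total = n_genes * L
    codes = rng.integers(0, 4, size=total, dtype=np.uint8)
    # i.i.d. background with the spec's base composition
    bgf = spec.background.array
    if not np.allclose(bgf, 0.25):
        codes = rng.choice(4, size=total, p=bgf).astype(np.uint8)

    # motif library: planted motifs first, then decoys (order then shuffled)
    pwms = [
        _random_pwm(rng, f"PLANTED_{i:02d}", spec.motif_length, spec.motif_sharpness)
        for i in range(spec.n_planted)
    ]
    pwms += [
        _random_pwm(rng, f"DECOY_{i:03d}", spec.motif_length, spec.motif_sharpness)
        for i in range(spec.decoy_motifs)
    ]
    order = rng.permutation(len(pwms))
    library = [pwms[i] for i in order]
    planted_ids = [f"PLANTED_{i:02d}" for i in range(spec.n_planted)]
    planted = [p for p in library if p.motif_id in planted_ids]

    # gene classes shuffled along the chromosome
    classes = ["high"] * spec.n_high + ["low"] * spec.n_low + ["other"] * spec.n_other
    classes = [classes[i] for i in rng.permutation(n_genes)]

    transcripts: list[TranscriptRecord] = []
    promoters: list[PromoterRegion] = []
    loci: list[Locus] = []
    blocks: list[tuple[GenomicInterval, float]] = []
    truth: list[GenomicInterval] = []
    high_genes: list[str] = []
    low_genes: list[str] = []

    id_lo, id_hi = spec.identity_range

    def cne_length() -> int:
        extra_mean = max(1.0, spec.cne_length_mean - spec.cne_min_length)
        return spec.cne_min_length + int(rng.geometric(1.0 / extra_mean)) - 1

    def embed_planted(start: int, end: int) -> None:
        taken_sites: list[tuple[int, int]] = []
        for pwm in planted:
            if rng.random() >= spec.p_plant:
                continue
            site = _sample_site(rng, pwm)
            spots = _place_nonoverlapping(
                rng, start, end, [len(site)], taken_sites, tries=20
            )
            for s, e in spots:
                codes[s:e] = site

    for gi, cls in enumerate(classes):
        gene = f"gene_{gi:04d}"
        locus_start, locus_end = gi * L, (gi + 1) * L
        loci.append(Locus(gi, GenomicInterval(spec.chrom, locus_start, locus_end)))
        strand = "+" if rng.random() < 0.5 else "-"
        tss = locus_start + L // 2
        if strand == "+":
            tx = GenomicInterval(spec.chrom, tss, tss + spec.tx_length, "+")
        else:
            tx = GenomicInterval(spec.chrom, tss - spec.tx_length + 1, tss + 1, "-")
        transcripts.append(TranscriptRecord(gene, tx))
        promoter = define_promoter(
            gene, tss, strand, spec.chrom, total,
            spec.promoter_upstream, spec.promoter_downstream,
        )
        promoters.append(promoter)
        if cls == "high":
            high_genes.append(gene)
        elif cls == "low":
            low_genes.append(gene)

        taken: list[tuple[int, int]] = [
            (promoter.interval.start, promoter.interval.end)
        ]

        # promoter conserved elements (training material)
        if cls in ("high", "low"):
            n_cnes = int(rng.poisson(spec.cnes_per_promoter_mean))
            lengths = [cne_length() for _ in range(n_cnes)]
            placed = _place_nonoverlapping(
                rng,
                promoter.interval.start,
                promoter.interval.end,
                lengths,
                taken=[],
            )
            for s, e in placed:
                blocks.append(
                    (GenomicInterval(spec.chrom, s, e), float(rng.uniform(id_lo, id_hi)))
                )
                if cls == "high":
                    embed_planted(s, e)

        # distal truth enhancers in highly expressed loci
        if cls == "high" and spec.n_enh > 0:
            lengths = [cne_length() for _ in range(spec.n_enh)]
            placed = _place_nonoverlapping(rng, locus_start, locus_end, lengths, taken)
            for s, e in placed:
                blocks.append(
                    (GenomicInterval(spec.chrom, s, e), float(rng.uniform(id_lo, id_hi)))
                )
                truth.append(GenomicInterval(spec.chrom, s, e))
                embed_planted(s, e)

        # background distal conserved elements (no planted motifs)
        n_bg = int(rng.poisson(spec.distal_cnes_per_locus_mean))
        lengths = [cne_length() for _ in range(n_bg)]
        placed = _place_nonoverlapping(rng, locus_start, locus_end, lengths, taken)
        for s, e in placed:
            blocks.append(
                (GenomicInterval(spec.chrom, s, e), float(rng.uniform(id_lo, id_hi)))
            )

    # expression table: highs rank top, lows bottom, others in between
    genes = [t.gene_symbol for t in transcripts]
    focal = np.empty(n_genes)
    for i, cls in enumerate(classes):
        if cls == "high":
            focal[i] = 900.0 + rng.uniform(0, 100)
        elif cls == "low":
            focal[i] = rng.uniform(0, 100)
        else:
            focal[i] = 400.0 + rng.uniform(0, 100)
    other_tissue = focal[rng.permutation(n_genes)]
    expression = pd.DataFrame(
        {spec.tissue: focal, "tissue_b": other_tissue}, index=pd.Index(genes, name="gene")
    )

    genome = {spec.chrom: _DECODE[codes].tobytes().decode("ascii")}
    blocks.sort(key=lambda p: p[0].start)
    return SyntheticBundle(
        genome=genome,
        chrom_sizes={spec.chrom: total},
        transcripts=transcripts,
        identity_blocks=blocks,
        expression=expression,
        truth_enhancers=sorted(truth, key=lambda iv: iv.start),
        library=library,
        planted_motif_ids=planted_ids,
        high_genes=sorted(high_genes),
        low_genes=sorted(low_genes),
        loci=loci,
        promoters=promoters,
        spec=spec,
    )


def truth_eval(predictions, truth: Sequence[GenomicInterval]) -> tuple[float, float]:
    """Precision and recall of predictions against planted truth enhancers.

    A prediction is a true positive iff it overlaps a truth enhancer by >= 1
    bp; a truth enhancer is recovered iff >= 1 prediction overlaps it. With no
    predictions, precision is reported as 0.
    """
    pred_ivs = [
        c.interval if hasattr(c, "interval") else c
        for c in (predictions.candidates if hasattr(predictions, "candidates") else predictions)
    ]
    if not pred_ivs:
        return 0.0, 0.0
    tp = sum(1 for p in pred_ivs if any(p.overlaps(t) for t in truth))
    recovered = sum(1 for t in truth if any(p.overlaps(t) for p in pred_ivs))
    precision = tp / len(pred_ivs)
    recall = recovered / len(truth) if truth else 0.0
    return precision, recall
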