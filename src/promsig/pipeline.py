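"""End-to-end orchestration: train, scan, evaluate.

Connects the pieces: expression ranking selects the highly / lowly expressed
gene sets; promoters and conserved elements become a labeled feature matrix;
the double-loop cross-validation trains and assesses a tissue model; the
model then scores distal candidates locus-wide, with the prediction threshold
calibrated on the control (lowly expressed) loci; and locus-level enrichment
statistics evaluate the resulting prediction set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import (
    EnrichmentReport,
    OverlapReport,
    fisher_exact,
    fold_enrichment_counts,
    fold_loci_fraction,
    randomization_pvalue,
    score_shift_test,
)
from .features import FeatureMatrix, assemble_training_set
from .intervals import (
    ConservedElement,
    GenomicInterval,
    Locus,
    PromoterRegion,
    TranscriptRecord,
    cluster_overlapping_transcripts,
    define_loci,
    define_promoter,
    extract_cnes,
)
from .motifs import PWM, BackgroundModel, MotifScanner
from .predict import (
    CandidateSequence,
    PredictionSet,
    call_predictions,
    compute_threshold,
    make_windows,
    score_candidates,
    select_conserved_candidates,
)
from .svm import (
    CVReport,
    LinearModel,
    TrainConfig,
    build_consistent_positive_set,
    class_weight,
    double_loop_cv,
    estimate_C,
    is_reliable,
    train,
)

__all__ = ["Dataset", "RunConfig", "run_train", "run_scan", "run_evaluate"]


@dataclass
class RunConfig:
    """Per-tissue run parameters (mirrors the per-module defaults)."""

    tissue: str
    n_top: int = 200
    n_bottom: int = 200
    promoter_upstream: int = 2500
    promoter_downstream: int = 500
    min_identity: float = 0.70
    min_cne_length: int = 100
    p_threshold: float = 1e-4
    top_fraction: float = 0.05
    window_size: int = 230
    window_step: int = 115
    use_windows: bool = False
    use_cnes: bool = True
    seed: int = 0
    train: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self) -> None:
        if self.n_top < self.train.folds or self.n_bottom < self.train.folds:
            raise ValueError("gene set sizes must be >= the number of CV folds")


@dataclass
class Dataset:
    """In-memory inputs of one run (from files or a synthetic bundle)."""

    genome: Mapping[str, str]
    chrom_sizes: dict[str, int]
    transcripts: list[TranscriptRecord]
    identity_blocks: list[tuple[GenomicInterval, float]]
    expression: pd.DataFrame
    library: list[PWM]
    background: BackgroundModel = field(default_factory=BackgroundModel)

    @classmethod
    def from_bundle(cls, bundle) -> "Dataset":
        return cls(
            genome=bundle.genome,
            chrom_sizes=bundle.chrom_sizes,
            transcripts=bundle.transcripts,
            identity_blocks=bundle.identity_blocks,
            expression=bundle.expression,
            library=bundle.library,
            background=bundle.spec.background,
        )


@dataclass
class TrainResult:
    model: LinearModel
    report: CVReport
    matrix: FeatureMatrix
    high_genes: list[str]
    low_genes: list[str]
    promoters: list[PromoterRegion]  # promoters of all transcripts (exclusion zones)
    cnes: list[ConservedElement]
    loci: list[Locus]
    locus_genes: dict[int, frozenset[str]]

    @property
    def reliability(self) -> str:
        return is_reliable(self.report)


def select_gene_sets(
    expression: pd.DataFrame, tissue: str, n_top: int, n_bottom: int
) -> tuple[list[str], list[str]]:
    """Top and bottom genes by expression in the focal tissue."""
    if tissue not in expression.columns:
        raise ValueError(f"tissue {tissue!r} not in expression table")
    col = expression[tissue].dropna()
    if col.nunique() <= 1:
        raise ValueError("expression column is constant; cannot rank genes")
    if len(col) < n_top + n_bottom:
        raise ValueError(
            f"need >= {n_top + n_bottom} genes with expression, have {len(col)}"
        )
    ranked = col.sort_values(ascending=False, kind="mergesort")
    high = list(ranked.index[:n_top])
    low = list(ranked.index[-n_bottom:])
    return high, low


def _promoters_for(
    transcripts: Sequence[TranscriptRecord],
    genes: set[str] | None,
    chrom_sizes: Mapping[str, int],
    upstream: int,
    downstream: int,
) -> list[PromoterRegion]:
    out = []
    for t in transcripts:
        if genes is not None and t.gene_symbol not in genes:
            continue
        out.append(
            define_promoter(
                t.gene_symbol,
                t.tss,
                t.interval.strand,
                t.interval.chrom,
                chrom_sizes[t.interval.chrom],
                upstream,
                downstream,
            )
        )
    return out


def build_loci(
    transcripts: Sequence[TranscriptRecord], chrom_sizes: Mapping[str, int]
) -> tuple[list[Locus], dict[int, frozenset[str]]]:
    clusters = cluster_overlapping_transcripts(transcripts)
    loci = define_loci(clusters, chrom_sizes)
    genes = {
        c.cluster_id: frozenset(m.gene_symbol for m in c.members) for c in clusters
    }
    return loci, genes


def prepare_inputs(config: RunConfig, data: Dataset) -> TrainResult:
    """Gene sets, promoters, CNEs and loci without training (model unset).

    Used by the scan stage when a trained model is loaded from disk.
    """
    high, low = select_gene_sets(
        data.expression, config.tissue, config.n_top, config.n_bottom
    )
    all_promoters = _promoters_for(
        data.transcripts, None, data.chrom_sizes,
        config.promoter_upstream, config.promoter_downstream,
    )
    cnes = extract_cnes(
        data.identity_blocks, data.genome, config.min_identity, config.min_cne_length
    )
    loci, locus_genes = build_loci(data.transcripts, data.chrom_sizes)
    return TrainResult(
        model=None,  # type: ignore[arg-type]
        report=None,  # type: ignore[arg-type]
        matrix=None,  # type: ignore[arg-type]
        high_genes=high,
        low_genes=low,
        promoters=all_promoters,
        cnes=cnes,
        loci=loci,
        locus_genes=locus_genes,
    )


def run_train(config: RunConfig, data: Dataset) -> TrainResult:
    """Select gene sets, build features from promoter CNEs, train with CV."""
    high, low = select_gene_sets(
        data.expression, config.tissue, config.n_top, config.n_bottom
    )
    all_promoters = _promoters_for(
        data.transcripts, None, data.chrom_sizes,
        config.promoter_upstream, config.promoter_downstream,
    )
    high_promoters = [p for p in all_promoters if p.gene_symbol in set(high)]
    low_promoters = [p for p in all_promoters if p.gene_symbol in set(low)]
    cnes = extract_cnes(
        data.identity_blocks, data.genome, config.min_identity, config.min_cne_length
    )
    scanner = MotifScanner(data.library, data.background, config.p_threshold)
    matrix = assemble_training_set(
        high_promoters, low_promoters, cnes, data.library,
        scanner=scanner,
    )
    cfg = config.train
    report = double_loop_cv(matrix, cfg)

    # final model: consistent positive set over the full training data at the
    # chosen gamma, plus all negatives
    n_pos = int((matrix.y == 1).sum())
    n_neg = int((matrix.y == -1).sum())
    w1 = class_weight(n_pos, n_neg, report.chosen_gamma, cfg.flip_class_weight)
    C = cfg.C_override if cfg.C_override is not None else estimate_C(matrix)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(2,)))
    consistent = build_consistent_positive_set(
        matrix, C, w1, rng, cfg.per_promoter_pick
    )
    neg_rows = [i for i, lab in enumerate(matrix.y) if lab == -1]
    final_rows = sorted(set(consistent) | set(neg_rows))
    model = train(matrix.subset(final_rows), C=C, w1=w1)

    loci, locus_genes = build_loci(data.transcripts, data.chrom_sizes)
    return TrainResult(
        model=model,
        report=report,
        matrix=matrix,
        high_genes=high,
        low_genes=low,
        promoters=all_promoters,
        cnes=cnes,
        loci=loci,
        locus_genes=locus_genes,
    )


def _class_loci(
    locus_genes: dict[int, frozenset[str]], high: set[str], low: set[str]
) -> tuple[set[int], set[int]]:
    high_loci = {cid for cid, gs in locus_genes.items() if gs & high}
    low_loci = {cid for cid, gs in locus_genes.items() if gs & low}
    both = high_loci & low_loci
    if both:
        warnings.warn(
            f"{len(both)} loci contain both gene sets; excluded from both",
            stacklevel=2,
        )
        high_loci -= both
        low_loci -= both
    return high_loci, low_loci


@dataclass
class ScanResult:
    predictions: PredictionSet
    scored: list[CandidateSequence]
    threshold: float
    delta: float
    high_loci: set[int]
    low_loci: set[int]


def run_scan(config: RunConfig, data: Dataset, trained: TrainResult) -> ScanResult:
    """Score distal candidates and call predictions above min(0, delta).

    Candidates come from conserved elements (and/or sliding windows) in the
    loci of the highly and lowly expressed gene sets, excluding anything that
    touches a promoter zone; delta is calibrated per candidate class on the
    control (lowly expressed) loci.
    """
    scanner = MotifScanner(data.library, data.background, config.p_threshold)
    if trained.model.motif_ids != scanner.motif_ids:
        raise ValueError("model was trained on a different motif library")
    high_loci, low_loci = _class_loci(
        trained.locus_genes, set(trained.high_genes), set(trained.low_genes)
    )

    candidates: list[CandidateSequence] = []
    if config.use_cnes:
        candidates += select_conserved_candidates(
            trained.cnes, trained.promoters, trained.loci
        )
    if config.use_windows:
        candidates += make_windows(
            data.genome, trained.promoters, config.window_size,
            config.window_step, trained.loci,
        )
    in_scope = [
        c for c in candidates
        if c.locus_id is not None and c.locus_id in (high_loci | low_loci)
    ]
    scored = score_candidates(
        trained.model, in_scope, data.library, scanner=scanner
    )
    control_scores = [c.score for c in scored if c.locus_id in low_loci]
    if not control_scores:
        raise ValueError("no candidates in control loci; cannot set threshold")
    s, delta = compute_threshold(control_scores, config.top_fraction)
    predictions = call_predictions(scored, s, delta, model_id=config.tissue)
    return ScanResult(predictions, scored, s, delta, high_loci, low_loci)


def run_evaluate(
    config: RunConfig,
    scan: ScanResult,
    marks: Sequence[GenomicInterval] | None = None,
    chrom_sizes: Mapping[str, int] | None = None,
    excluded: Sequence[GenomicInterval] = (),
    n_rand: int = 1000,
) -> tuple[EnrichmentReport, OverlapReport | None]:
    """Locus-level enrichment statistics, plus optional mark-overlap report."""
    pred = scan.predictions.candidates
    pred_high = sum(1 for c in pred if c.locus_id in scan.high_loci)
    pred_low = sum(1 for c in pred if c.locus_id in scan.low_loci)
    scanned_high = sum(1 for c in scan.scored if c.locus_id in scan.high_loci)
    scanned_low = sum(1 for c in scan.scored if c.locus_id in scan.low_loci)

    fold = fold_enrichment_counts(pred_high, scanned_high, pred_low, scanned_low)
    fisher_p = fisher_exact(
        [[pred_high, scanned_high - pred_high], [pred_low, scanned_low - pred_low]]
    )

    hit_high = len({c.locus_id for c in pred if c.locus_id in scan.high_loci})
    hit_low = len({c.locus_id for c in pred if c.locus_id in scan.low_loci})
    tot_high = len({c.locus_id for c in scan.scored if c.locus_id in scan.high_loci})
    tot_low = len({c.locus_id for c in scan.scored if c.locus_id in scan.low_loci})
    frac_fold = fold_loci_fraction(hit_high, tot_high, hit_low, tot_low)
    frac_p = fisher_exact(
        [[hit_high, tot_high - hit_high], [hit_low, tot_low - hit_low]]
    )

    scores_high = [c.score for c in scan.scored if c.locus_id in scan.high_loci]
    scores_low = [c.score for c in scan.scored if c.locus_id in scan.low_loci]
    shift_p = score_shift_test(scores_high, scores_low)

    report = EnrichmentReport(
        fold_predictions=fold,
        fisher_p=fisher_p,
        fold_loci_fraction=frac_fold,
        fraction_p=frac_p,
        score_shift_p=shift_p,
        counts={
            "pred_high": pred_high,
            "scanned_high": scanned_high,
            "pred_low": pred_low,
            "scanned_low": scanned_low,
            "loci_hit_high": hit_high,
            "loci_total_high": tot_high,
            "loci_hit_low": hit_low,
            "loci_total_low": tot_low,
        },
    )

    overlap = None
    if marks is not None:
        if chrom_sizes is None:
            raise ValueError("chrom_sizes required for mark-overlap randomization")
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(3,)))
        overlap = randomization_pvalue(
            [c.interval for c in pred], marks, chrom_sizes, excluded, n_rand, rng
        )
    return report, overlap
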