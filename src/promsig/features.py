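"""Build labeled TF-binding-site feature matrices from conserved elements.

Each conserved element becomes a vector of per-motif hit counts over the
library. Elements intersecting promoters of the highly expressed gene set are
labeled +1, those in promoters of the lowly expressed set -1; elements shared
between several promoters appear once with the union of attributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .intervals import ConservedElement, GenomicInterval, PromoterRegion
from .motifs import PWM, BackgroundModel, DEFAULT_P_THRESHOLD, MotifScanner

__all__ = [
    "FeatureVector",
    "FeatureMatrix",
    "build_features",
    "deduplicate",
    "assemble_training_set",
]

UNLABELED = 0


@dataclass
class FeatureVector:
    element_id: str
    counts: np.ndarray
    promoter_of: frozenset[str] = frozenset()
    label: int = UNLABELED  # +1, -1, or 0 for unlabeled
    interval: GenomicInterval | None = None


@dataclass
class FeatureMatrix:
    """Rows of per-element motif-hit counts with a shared motif ordering."""

    rows: list[FeatureVector]
    motif_ids: list[str]

    def __post_init__(self) -> None:
        ids = [r.element_id for r in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("element ids must be unique; deduplicate first")
        for r in self.rows:
            if len(r.counts) != len(self.motif_ids):
                raise ValueError(f"{r.element_id}: count vector length mismatch")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def X(self) -> np.ndarray:
        if not self.rows:
            return np.zeros((0, len(self.motif_ids)))
        return np.vstack([r.counts for r in self.rows]).astype(float)

    @property
    def y(self) -> np.ndarray:
        return np.array([r.label for r in self.rows], dtype=int)

    def positive_promoters(self) -> dict[str, list[int]]:
        """Map positive-class promoter gene symbol -> row indices."""
        out: dict[str, list[int]] = {}
        for i, r in enumerate(self.rows):
            if r.label == 1:
                for g in r.promoter_of:
                    out.setdefault(g, []).append(i)
        return out

    def subset(self, indices) -> "FeatureMatrix":
        return FeatureMatrix([self.rows[i] for i in indices], self.motif_ids)

    def to_frame(self):
        import pandas as pd

        data = {
            "element_id": [r.element_id for r in self.rows],
            "label": [r.label for r in self.rows],
            "promoter_of": [",".join(sorted(r.promoter_of)) for r in self.rows],
        }
        df = pd.DataFrame(data)
        counts = self.X.astype(int)
        for j, mid in enumerate(self.motif_ids):
            df[mid] = counts[:, j] if len(self.rows) else []
        return df


def build_features(
    elements: Sequence[ConservedElement],
    library: list[PWM],
    bg: BackgroundModel | None = None,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    scanner: MotifScanner | None = None,
) -> FeatureMatrix:
    """One count vector per element, deterministic given inputs."""
    if scanner is None:
        scanner = MotifScanner(library, bg, p_threshold)
    rows = [
        FeatureVector(
            el.interval.key(), scanner.count_hits(el.sequence), interval=el.interval
        )
        for el in elements
    ]
    return FeatureMatrix(rows, scanner.motif_ids)


def deduplicate(
    rows: "Sequence[FeatureVector] | FeatureMatrix", motif_ids: list[str] | None = None
) -> FeatureMatrix:
    """Collapse rows with identical coordinates, merging promoter attributions.

    An element attributed both +1 and -1 raises: the caller must resolve (the
    training assembler drops such elements with a warning).
    """
    if isinstance(rows, FeatureMatrix):
        motif_ids = rows.motif_ids
        rows = rows.rows
    if motif_ids is None:
        raise ValueError("motif_ids required when passing raw rows")
    by_id: dict[str, FeatureVector] = {}
    for r in rows:
        prev = by_id.get(r.element_id)
        if prev is None:
            by_id[r.element_id] = replace(r, promoter_of=frozenset(r.promoter_of))
            continue
        if prev.label != r.label and UNLABELED not in (prev.label, r.label):
            raise ValueError(f"{r.element_id}: conflicting labels")
        label = prev.label if prev.label != UNLABELED else r.label
        by_id[r.element_id] = replace(
            prev, promoter_of=prev.promoter_of | r.promoter_of, label=label
        )
    return FeatureMatrix(list(by_id.values()), motif_ids)


def _element_promoters(
    el: ConservedElement,
    promoters: Sequence[PromoterRegion],
    min_overlap_fraction: float,
) -> frozenset[str]:
    hits = []
    for p in promoters:
        ov = el.interval.overlap_length(p.interval)
        if ov > 0 and ov >= min_overlap_fraction * el.interval.length:
            hits.append(p.gene_symbol)
    return frozenset(hits)


def assemble_training_set(
    high_promoters: Sequence[PromoterRegion],
    low_promoters: Sequence[PromoterRegion],
    cnes: Sequence[ConservedElement],
    library: list[PWM],
    bg: BackgroundModel | None = None,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    min_overlap_fraction: float = 0.0,
    scanner: MotifScanner | None = None,
) -> FeatureMatrix:
    """Label CNEs by the promoter set they intersect and build the matrix.

    CNEs intersecting a promoter of the highly expressed set get label +1,
    of the lowly expressed set -1; CNEs touching both sets are ambiguous and
    dropped with a warning; CNEs outside all promoters are excluded. The
    promoter-to-element attribution is retained for the consistent-positive-
    set construction.
    """
    high_genes = {p.gene_symbol for p in high_promoters}
    low_genes = {p.gene_symbol for p in low_promoters}
    shared = high_genes & low_genes
    if shared:
        raise ValueError(f"genes in both sets: {sorted(shared)[:5]}")
    if scanner is None:
        scanner = MotifScanner(library, bg, p_threshold)

    rows: list[FeatureVector] = []
    n_ambiguous = 0
    for el in cnes:
        hi = _element_promoters(el, high_promoters, min_overlap_fraction)
        lo = _element_promoters(el, low_promoters, min_overlap_fraction)
        if hi and lo:
            n_ambiguous += 1
            continue
        if not hi and not lo:
            continue
        label = 1 if hi else -1
        rows.append(
            FeatureVector(
                el.interval.key(),
                scanner.count_hits(el.sequence),
                promoter_of=hi or lo,
                label=label,
                interval=el.interval,
            )
        )
    if n_ambiguous:
        warnings.warn(
            f"dropped {n_ambiguous} elements overlapping both promoter sets",
            stacklevel=2,
        )
    return deduplicate(rows, scanner.motif_ids)
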