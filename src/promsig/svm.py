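"""Class-weighted linear SVM with consistent-positive-set double-loop CV.

The classifier solves the soft-margin primal

    min  1/2 w'w + C * sum_i c_i xi_i
    s.t. y_i (w'x_i + b) >= 1 - xi_i,  xi_i >= 0

with per-class error weights c_i = w1 for the positive class and 1 for the
negative class. The positive-class weight w1 = (n-/n+) * gamma balances the
classes up to a grid-searched factor gamma in {1/3, 2/3, 1, 4/3, 5/3}.

The double-loop cross-validation first distills, within each training fold,
a "consistent" positive set: for every positive-class promoter P, a model is
trained on the fold minus all elements of P, P's own elements are scored, and
up to two positive-scoring ones are kept at random. The final fold classifier
is trained on the consistent positives plus the fold negatives and evaluated
by AUC on the held-out fifth of both classes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from ._solver import solve_svm_dual
from .features import FeatureMatrix
from .stats import auc

__all__ = [
    "LinearModel",
    "TrainConfig",
    "CVReport",
    "ScaledWeightVector",
    "estimate_C",
    "train",
    "decision_score",
    "build_consistent_positive_set",
    "double_loop_cv",
    "auc",
    "scale_weights",
    "is_reliable",
]

DEFAULT_GAMMA_GRID = (1 / 3, 2 / 3, 1.0, 4 / 3, 5 / 3)
RELIABLE_AUC_CUTOFF = 0.6


@dataclass
class LinearModel:
    """Trained linear decision rule f(x) = w'x + b."""

    w: np.ndarray
    b: float
    C: float
    w1: float
    motif_ids: list[str] | None = None
    support_coefficients: np.ndarray | None = None  # alpha; not serialized

    def to_json(self) -> str:
        return json.dumps(
            {
                "motif_ids": self.motif_ids,
                "w": list(map(float, self.w)),
                "b": self.b,
                "C": self.C,
                "w1": self.w1,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "LinearModel":
        d = json.loads(text)
        return cls(np.asarray(d["w"], dtype=float), d["b"], d["C"], d["w1"], d["motif_ids"])


@dataclass
class TrainConfig:
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    C_override: float | None = None
    folds: int = 5
    repeats: int = 5
    per_promoter_pick: int = 2
    seed: int = 0
    flip_class_weight: bool = False  # use (n+/n-)*gamma instead of (n-/n+)*gamma
    literal_negative_holdout: bool = False

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not self.gamma_grid:
            raise ValueError("gamma_grid must be non-empty")


@dataclass
class CVReport:
    fold_aucs: list[float]
    chosen_gamma: float
    consistent_set_sizes: list[int]
    gamma_medians: dict[float, float] = field(default_factory=dict)

    @property
    def median_auc(self) -> float:
        return float(np.median(self.fold_aucs))


@dataclass
class ScaledWeightVector:
    scaled: np.ndarray
    wmin: float
    wmax: float


def estimate_C(matrix: FeatureMatrix | np.ndarray) -> float:
    """Scale-normalizing heuristic C = 1 / mean_i ||x_i||^2."""
    X = matrix.X if isinstance(matrix, FeatureMatrix) else np.asarray(matrix, float)
    norms = (X**2).sum(axis=1)
    mean = norms.mean() if norms.size else 0.0
    if mean == 0:
        raise ValueError("all-zero feature matrix; C heuristic undefined")
    return float(1.0 / mean)


def class_weight(n_pos: int, n_neg: int, gamma: float, flip: bool = False) -> float:
    """Positive-class error weight w1 = (n-/n+) * gamma (direction flippable)."""
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ratio = n_pos / n_neg if flip else n_neg / n_pos
    return ratio * gamma


def train(
    X: FeatureMatrix | np.ndarray,
    y: np.ndarray | None = None,
    C: float = 1.0,
    w1: float = 1.0,
    motif_ids: list[str] | None = None,
    alpha0: np.ndarray | None = None,
    eps: float = 1e-3,
    max_iter: int = 200_000,
) -> LinearModel:
    """Fit the class-weighted soft-margin linear SVM.

    Positive-class errors are penalized C*w1, negative-class errors C. The
    dual is solved to a projected-gradient violation below ``eps``;
    ``alpha0`` warm-starts the solver (used by the leave-one-promoter-out
    inner loop).
    """
    if isinstance(X, FeatureMatrix):
        motif_ids = X.motif_ids
        y = X.y
        X = X.X
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y length mismatch")
    classes = set(np.unique(y))
    if classes != {-1, 1}:
        raise ValueError(f"need both classes +1/-1, got {sorted(classes)}")
    w, b, alpha = solve_svm_dual(
        X, y, C_pos=C * w1, C_neg=C, alpha0=alpha0, eps=eps, max_iter=max_iter
    )
    return LinearModel(w, b, C, w1, motif_ids, support_coefficients=alpha)


def decision_score(model: LinearModel, x: np.ndarray) -> float | np.ndarray:
    """Raw decision value w'x + b (sign gives the hard call)."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != model.w.shape[0]:
        raise ValueError("dimension mismatch")
    return x @ model.w + model.b


def build_consistent_positive_set(
    fold_train: FeatureMatrix,
    C: float,
    w1: float,
    rng: np.random.Generator,
    per_promoter_pick: int = 2,
    inner_eps: float = 1e-2,
    inner_max_iter: int = 3000,
) -> list[int]:
    """Indices of a consistent positive subset of ``fold_train``.

    For each positive promoter P: train on the fold minus all of P's
    elements, score P's elements, and keep up to ``per_promoter_pick``
    positive-scoring ones chosen at random (all if fewer, none if none score
    above zero). The leave-one-promoter-out screening models only contribute
    score signs, so they are solved to a looser tolerance (``inner_eps``,
    ``inner_max_iter``) than the published models.
    """
    promoters = fold_train.positive_promoters()
    if not promoters:
        raise ValueError("no positive-promoter attribution in training fold")
    X = fold_train.X
    y = fold_train.y
    # warm-start each leave-one-promoter-out refit from the full-fold solution
    full = train(X, y, C=C, w1=w1)
    alpha_full = full.support_coefficients
    chosen: set[int] = set()
    for gene in sorted(promoters):
        rows = promoters[gene]
        mask = np.ones(len(y), dtype=bool)
        mask[rows] = False
        if len(set(y[mask])) < 2:
            continue  # removing P leaves one class empty; cannot score
        model = train(
            X[mask], y[mask], C=C, w1=w1, alpha0=alpha_full[mask],
            eps=inner_eps, max_iter=inner_max_iter,
        )
        scores = decision_score(model, X[rows])
        positive_rows = [r for r, s in zip(rows, scores) if s > 0]
        if len(positive_rows) > per_promoter_pick:
            positive_rows = sorted(
                int(r)
                for r in rng.choice(positive_rows, size=per_promoter_pick, replace=False)
            )
        chosen.update(int(r) for r in positive_rows)
    return sorted(chosen)


def _fold_auc(
    matrix: FeatureMatrix,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    gamma: float,
    cfg: TrainConfig,
    rng: np.random.Generator,
) -> tuple[float, int] | None:
    y = matrix.y
    if len(set(y[test_idx])) < 2 or len(set(y[train_idx])) < 2:
        return None
    fold_train = matrix.subset(train_idx)
    n_pos = int((fold_train.y == 1).sum())
    n_neg = int((fold_train.y == -1).sum())
    w1 = class_weight(n_pos, n_neg, gamma, cfg.flip_class_weight)
    C = cfg.C_override if cfg.C_override is not None else estimate_C(fold_train)
    consistent = build_consistent_positive_set(
        fold_train, C, w1, rng, cfg.per_promoter_pick
    )
    if not consistent:
        return None
    if cfg.literal_negative_holdout:
        neg_idx = [int(i) for i in test_idx if y[i] == -1]
    else:
        neg_idx = [int(i) for i in train_idx if y[i] == -1]
    final_rows = [int(train_idx[i]) for i in consistent] + neg_idx
    Xf = matrix.X[final_rows]
    yf = y[final_rows]
    if len(set(yf)) < 2:
        return None
    model = train(Xf, yf, C=C, w1=w1)
    test_scores = decision_score(model, matrix.X[test_idx])
    pos = test_scores[y[test_idx] == 1]
    neg = test_scores[y[test_idx] == -1]
    return auc(pos, neg), len(consistent)


def double_loop_cv(matrix: FeatureMatrix, cfg: TrainConfig) -> CVReport:
    """Grid-search gamma by repeated stratified CV with consistent positives.

    gamma is selected once (not per fold) to maximize the median held-out
    AUC over folds x repeats; ties break toward gamma = 1.
    """
    y = matrix.y
    if (y == 1).sum() < cfg.folds or (y == -1).sum() < cfg.folds:
        raise ValueError("each class needs at least `folds` members")

    # fold assignment and per-promoter picking each get their own substream,
    # all derived from cfg.seed
    ss = np.random.SeedSequence(cfg.seed)
    fold_seeds = ss.spawn(cfg.repeats)

    results: dict[float, list[float]] = {}
    sizes: dict[float, list[int]] = {}
    splits = []
    for r in range(cfg.repeats):
        skf = StratifiedKFold(
            n_splits=cfg.folds,
            shuffle=True,
            random_state=int(fold_seeds[r].generate_state(1)[0] % (2**31)),
        )
        splits.append(list(skf.split(matrix.X, y)))

    for gi, gamma in enumerate(cfg.gamma_grid):
        aucs: list[float] = []
        csizes: list[int] = []
        for r in range(cfg.repeats):
            for k, (train_idx, test_idx) in enumerate(splits[r]):
                rng = np.random.default_rng(
                    np.random.SeedSequence(
                        cfg.seed, spawn_key=(1, gi, r, k)
                    )
                )
                out = _fold_auc(matrix, train_idx, test_idx, gamma, cfg, rng)
                if out is None:
                    warnings.warn(
                        f"degenerate fold skipped (gamma={gamma:.3g}, repeat={r}, fold={k})",
                        stacklevel=2,
                    )
                    continue
                aucs.append(out[0])
                csizes.append(out[1])
        if not aucs:
            raise ValueError("all folds degenerate")
        results[gamma] = aucs
        sizes[gamma] = csizes

    def sort_key(g: float) -> tuple[float, float]:
        return (float(np.median(results[g])), -abs(g - 1.0))

    chosen = max(cfg.gamma_grid, key=sort_key)
    return CVReport(
        fold_aucs=results[chosen],
        chosen_gamma=chosen,
        consistent_set_sizes=sizes[chosen],
        gamma_medians={g: float(np.median(a)) for g, a in results.items()},
    )


def scale_weights(w: np.ndarray) -> ScaledWeightVector:
    """Map weights sign-preservingly into [-1, 1].

    Positive weights are divided by the largest positive weight; a negative
    weight w_j maps to -(1 - (w_j - w_min)/(-w_min)), which simplifies to
    w_j / |w_min| (the stable form used here). The extremes map to exactly
    +1 / -1 and zeros stay zero.
    """
    w = np.asarray(w, dtype=float)
    if not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite")
    wmin = float(w.min()) if w.size and w.min() < 0 else 0.0
    wmax = float(w.max()) if w.size and w.max() > 0 else 0.0
    scaled = np.zeros_like(w)
    neg = w < 0
    pos = w > 0
    if wmin < 0:
        scaled[neg] = w[neg] / (-wmin)
    if wmax > 0:
        scaled[pos] = w[pos] / wmax
    return ScaledWeightVector(scaled, wmin, wmax)


def is_reliable(report: CVReport, cutoff: float = RELIABLE_AUC_CUTOFF) -> str:
    """'reliable' iff the median cross-validation AUC reaches the cutoff."""
    return "reliable" if report.median_auc >= cutoff else "unreliable"
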