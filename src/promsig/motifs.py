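"""Motif library I/O and log-odds scanning with exact p-value calibration.

A PWM stores per-position nucleotide probabilities (rows = positions, columns
= A, C, G, T). Scanning converts the PWM to a log2-odds matrix against a
0-order background, discretizes the scores, and computes the exact null score
distribution of a random background k-mer by positionwise convolution. A
window is a hit when the exact tail probability of its score is at or below
the per-position p-value threshold (default 1e-4). Both strands are scanned
and overlapping hits are all counted; every choice is an argument.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import motifs as bio_motifs

from .intervals import GenomicInterval
from .stats import rank_sum_test

__all__ = [
    "PWM",
    "BackgroundModel",
    "ScoreDistribution",
    "MotifHit",
    "parse_motifs",
    "log_odds",
    "score_pvalue_distribution",
    "scan",
    "count_hits",
    "motif_gc",
    "permute_pwm",
    "motif_overrepresentation",
    "estimate_background",
]

ALPHABET = "ACGT"
#: Laplace pseudocount added per matrix cell when converting count matrices
PSEUDOCOUNT = 0.25
#: default per-position hit threshold (MAST's motif display default)
DEFAULT_P_THRESHOLD = 1e-4
#: default discretization bin for the null score distribution, in bits
DEFAULT_BIN_WIDTH = 1e-3

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate(ALPHABET):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Map a DNA string to codes 0..3 (A,C,G,T); anything else becomes -1."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class PWM:
    motif_id: str
    probs: np.ndarray  # L x 4, rows sum to 1
    source: str = "unknown"

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or self.probs.shape[0] < 1:
            raise ValueError(f"{self.motif_id}: PWM must be L x 4 with L >= 1")
        if np.any(self.probs < 0):
            raise ValueError(f"{self.motif_id}: negative probability")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"{self.motif_id}: rows must sum to 1")

    def __len__(self) -> int:
        return self.probs.shape[0]

    def reverse_complement(self) -> "PWM":
        return PWM(self.motif_id, self.probs[::-1, ::-1], self.source)

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=1))


@dataclass(frozen=True)
class BackgroundModel:
    """0-order background nucleotide frequencies (A, C, G, T)."""

    freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if f.shape != (4,) or np.any(f <= 0) or not np.isclose(f.sum(), 1.0):
            raise ValueError("background must be 4 positive frequencies summing to 1")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.freqs, dtype=float)


def estimate_background(sequences) -> BackgroundModel:
    """0-order background from observed base frequencies (uniform fallback)."""
    counts = np.zeros(4, dtype=float)
    for seq in sequences:
        codes = encode_sequence(seq)
        counts += np.bincount(codes[codes >= 0], minlength=4)
    if counts.sum() == 0:
        return BackgroundModel()
    counts += 1.0  # avoid zero frequencies
    return BackgroundModel(tuple(counts / counts.sum()))


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    interval: GenomicInterval
    strand: str
    score: float
    pvalue: float


def _counts_to_probs(counts: np.ndarray, pseudocount: float) -> np.ndarray:
    c = counts + pseudocount
    return c / c.sum(axis=1, keepdims=True)


def parse_motifs(path_or_handle, dialect: str, pseudocount: float = PSEUDOCOUNT) -> list[PWM]:
    """Read a motif library in JASPAR, TRANSFAC, or minimal-MEME format.

    Count matrices (JASPAR, TRANSFAC) receive a symmetric pseudocount per cell
    before normalization; MEME probability matrices are taken as printed.
    """
    if dialect not in {"jaspar", "transfac", "meme"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    if hasattr(path_or_handle, "read"):
        text = path_or_handle.read()
    else:
        with open(path_or_handle) as fh:
            text = fh.read()
    if not text.strip():
        return []

    pwms: list[PWM] = []
    if dialect == "meme":
        pwms = _parse_meme_minimal(text)
    else:
        fmt = {"jaspar": "jaspar", "transfac": "transfac"}[dialect]
        try:
            records = bio_motifs.parse(io.StringIO(text), fmt)
            parsed = list(records)
        except Exception as exc:  # pragma: no cover - malformed input path
            raise ValueError(f"malformed {dialect} motif file: {exc}") from exc
        for m in parsed:
            counts = np.array(
                [[m.counts[b][i] for b in ALPHABET] for i in range(m.length)],
                dtype=float,
            )
            name = m.matrix_id if getattr(m, "matrix_id", None) else m.name
            if not name:
                raise ValueError("motif record without identifier")
            pwms.append(PWM(name, _counts_to_probs(counts, pseudocount), dialect))

    seen: set[str] = set()
    for p in pwms:
        if p.motif_id in seen:
            raise ValueError(f"duplicate motif id {p.motif_id}")
        seen.add(p.motif_id)
    return pwms


def _parse_meme_minimal(text: str) -> list[PWM]:
    pwms: list[PWM] = []
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"malformed MOTIF line: {line!r}")
            name = parts[1]
            j = i + 1
            while j < len(lines) and "letter-probability" not in lines[j]:
                if lines[j].strip().startswith("MOTIF"):
                    raise ValueError(f"motif {name}: missing letter-probability matrix")
                j += 1
            if j >= len(lines):
                raise ValueError(f"motif {name}: missing letter-probability matrix")
            rows = []
            j += 1
            while j < len(lines):
                s = lines[j].strip()
                if not s or not s[0] in "0123456789.-":
                    break
                vals = s.split()
                if len(vals) != 4:
                    raise ValueError(f"motif {name}: bad probability row {s!r}")
                rows.append([float(v) for v in vals])
                j += 1
            if not rows:
                raise ValueError(f"motif {name}: empty probability matrix")
            pwms.append(PWM(name, np.array(rows), "meme"))
            i = j
        else:
            i += 1
    return pwms


def log_odds(pwm: PWM, bg: BackgroundModel) -> np.ndarray:
    """Per-position log2(prob / background) score matrix (bits)."""
    if np.any(pwm.probs == 0):
        raise ValueError(
            f"{pwm.motif_id}: zero probability; re-parse with a pseudocount"
        )
    return np.log2(pwm.probs / bg.array[None, :])


@dataclass
class ScoreDistribution:
    """Exact discretized null distribution of a motif's log-odds score.

    ``pmf[i]`` is the probability that a random background k-mer scores in
    bin ``min_bin + i``; scores are discretized as ``round(score/bin_width)``.
    """

    bin_width: float
    min_bin: int
    pmf: np.ndarray
    _sf: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not np.isclose(self.pmf.sum(), 1.0, atol=1e-9):
            raise ValueError("pmf must sum to 1")
        self._sf = np.cumsum(self.pmf[::-1])[::-1]

    def pvalue(self, score: float) -> float:
        """P(null score >= score), evaluated on the discretized grid."""
        idx = int(round(score / self.bin_width)) - self.min_bin
        if idx <= 0:
            return 1.0
        if idx >= len(self.pmf):
            return 0.0
        return float(self._sf[idx])

    def pvalue_binned(self, binned: np.ndarray) -> np.ndarray:
        idx = np.clip(binned - self.min_bin, 0, len(self.pmf))
        sf_ext = np.append(self._sf, 0.0)
        return sf_ext[idx]

    def score_threshold(self, p: float) -> float:
        """Smallest score whose tail probability is <= p (inf if none)."""
        ok = np.nonzero(self._sf <= p)[0]
        if ok.size == 0:
            return np.inf
        return (self.min_bin + int(ok[0])) * self.bin_width


def _binned_lom(lom: np.ndarray, bin_width: float) -> np.ndarray:
    return np.rint(lom / bin_width).astype(np.int64)


def score_pvalue_distribution(
    lom: np.ndarray, bg: BackgroundModel, bin_width: float = DEFAULT_BIN_WIDTH
) -> ScoreDistribution:
    """Exact null score distribution by positionwise convolution."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lom = np.asarray(lom, dtype=float)
    if not np.all(np.isfinite(lom)):
        raise ValueError("log-odds matrix must be finite")
    q = _binned_lom(lom, bin_width)
    bgf = bg.array
    cur = np.array([1.0])
    cur_lo = 0
    for row in q:
        new_lo = cur_lo + int(row.min())
        new_hi = cur_lo + len(cur) - 1 + int(row.max())
        new = np.zeros(new_hi - new_lo + 1)
        for b in range(4):
            off = cur_lo + int(row[b]) - new_lo
            new[off : off + len(cur)] += bgf[b] * cur
        cur, cur_lo = new, new_lo
    return ScoreDistribution(bin_width, cur_lo, cur / cur.sum())


def _window_scores(codes: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Binned window scores and validity mask (windows containing N invalid)."""
    L = q.shape[0]
    n = codes.size - L + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = np.all(win >= 0, axis=1)
    safe = np.where(win >= 0, win, 0)
    scores = q[np.arange(L)[None, :], safe].sum(axis=1)
    return scores.astype(np.int64), valid


def scan(
    sequence: str,
    pwm: PWM,
    bg: BackgroundModel | None = None,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    chrom: str = "seq",
    offset: int = 0,
    bin_width: float = DEFAULT_BIN_WIDTH,
    both_strands: bool = True,
) -> list[MotifHit]:
    """All positions (both strands) whose exact per-position p <= threshold.

    Windows containing non-ACGT characters are skipped. Sequences shorter than
    the motif yield an empty list.
    """
    if bg is None:
        bg = BackgroundModel()
    codes = encode_sequence(sequence)
    lom = log_odds(pwm, bg)
    dist = score_pvalue_distribution(lom, bg, bin_width)
    q = _binned_lom(lom, bin_width)
    hits: list[MotifHit] = []
    strands = [("+", q)]
    if both_strands:
        strands.append(("-", _binned_lom(log_odds(pwm.reverse_complement(), bg), bin_width)))
    L = len(pwm)
    for strand, qm in strands:
        scores, valid = _window_scores(codes, qm)
        if scores.size == 0:
            continue
        pvals = dist.pvalue_binned(scores)
        keep = valid & (pvals <= p_threshold)
        for i in np.nonzero(keep)[0]:
            hits.append(
                MotifHit(
                    pwm.motif_id,
                    GenomicInterval(chrom, offset + int(i), offset + int(i) + L),
                    strand,
                    float(scores[i] * bin_width),
                    float(pvals[i]),
                )
            )
    hits.sort(key=lambda h: (h.interval.start, h.strand))
    return hits


class MotifScanner:
    """Precompiled scanner for a motif library against a fixed background.

    Caches binned log-odds matrices and hit thresholds so that counting hits
    over many sequences does not recompute the null distributions.
    """

    def __init__(
        self,
        library: list[PWM],
        bg: BackgroundModel | None = None,
        p_threshold: float = DEFAULT_P_THRESHOLD,
        bin_width: float = DEFAULT_BIN_WIDTH,
        both_strands: bool = True,
    ) -> None:
        if not library:
            raise ValueError("empty motif library")
        self.library = list(library)
        self.bg = bg if bg is not None else BackgroundModel()
        self.p_threshold = p_threshold
        self.bin_width = bin_width
        self.both_strands = both_strands
        self.motif_ids = [p.motif_id for p in library]
        self._mats: list[list[tuple[np.ndarray, int]]] = []
        for pwm in library:
            lom = log_odds(pwm, self.bg)
            dist = score_pvalue_distribution(lom, self.bg, bin_width)
            thr = dist.score_threshold(p_threshold)
            thr_bin = np.inf if np.isinf(thr) else int(round(thr / bin_width))
            mats = [(_binned_lom(lom, bin_width), thr_bin)]
            if both_strands:
                rc = _binned_lom(log_odds(pwm.reverse_complement(), self.bg), bin_width)
                mats.append((rc, thr_bin))
            self._mats.append(mats)
        # batch motifs of equal length for vectorized counting
        groups: dict[int, list[tuple[int, np.ndarray, int]]] = {}
        for j, mats in enumerate(self._mats):
            for qm, thr_bin in mats:
                if np.isinf(thr_bin):
                    continue
                groups.setdefault(qm.shape[0], []).append((j, qm, thr_bin))
        self._groups: list[tuple[int, np.ndarray, np.ndarray, np.ndarray]] = []
        for L, items in sorted(groups.items()):
            idx = np.array([j for j, _, _ in items])
            stack = np.stack([q for _, q, _ in items]).astype(np.float64)
            thr = np.array([t for _, _, t in items], dtype=np.float64)
            self._groups.append((L, idx, stack, thr))

    def count_hits(self, sequence: str) -> np.ndarray:
        codes = encode_sequence(sequence)
        out = np.zeros(len(self.library), dtype=np.int64)
        for L, idx, stack, thr in self._groups:
            n = codes.size - L + 1
            if n <= 0:
                continue
            win = np.lib.stride_tricks.sliding_window_view(codes, L)
            valid = np.all(win >= 0, axis=1)
            safe = np.where(win >= 0, win, 0)
            onehot = (safe[:, :, None] == np.arange(4)).astype(np.float64)
            # binned scores are integers well below 2**53: float sums exact
            scores = np.einsum("mlj,nlj->mn", stack, onehot)
            hits = (scores >= thr[:, None]) & valid[None, :]
            np.add.at(out, idx, hits.sum(axis=1))
        return out


def count_hits(
    sequence: str,
    library: list[PWM],
    bg: BackgroundModel | None = None,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> np.ndarray:
    """Vector of per-motif hit counts (both strands, overlapping hits all counted)."""
    return MotifScanner(library, bg, p_threshold).count_hits(sequence)


def motif_gc(pwm: PWM) -> float:
    """Mean over positions of P(G) + P(C)."""
    return float((pwm.probs[:, 1] + pwm.probs[:, 2]).mean())


def permute_pwm(pwm: PWM, rng: np.random.Generator) -> PWM:
    """Permute the 4 nucleotide probabilities independently at each position."""
    probs = np.empty_like(pwm.probs)
    for i in range(pwm.probs.shape[0]):
        probs[i] = pwm.probs[i, rng.permutation(4)]
    return PWM(pwm.motif_id, probs, pwm.source)


def motif_overrepresentation(
    set_a,
    set_b,
    pwm: PWM,
    bg: BackgroundModel | None = None,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> tuple[float, float]:
    """Compare per-sequence hit counts of one motif between two sequence sets.

    Returns the standardized rank-sum statistic of set A and the two-sided
    Wilcoxon rank-sum p-value.
    """
    if not set_a or not set_b:
        raise ValueError("both sequence sets must be non-empty")
    scanner = MotifScanner([pwm], bg, p_threshold)
    counts_a = [scanner.count_hits(s)[0] for s in set_a]
    counts_b = [scanner.count_hits(s)[0] for s in set_b]
    return rank_sum_test(counts_a, counts_b)
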