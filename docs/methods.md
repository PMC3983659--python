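# Methods

## Overview

`promsig` implements a promoter-signature approach to tissue-specific
enhancer prediction. The premise: promoters of genes expressed highly in a
tissue carry transcription-factor binding-site (TFBS) signatures that
distinguish them from promoters of genes inhibited in that tissue, and the
same signatures mark distal enhancers active in that tissue. The pipeline
has three stages:

1. **Train.** Rank genes by expression in the focal tissue; take the top
   `n_top` (default 200) as the positive gene set and the bottom `n_bottom`
   (default 200) as the negative set. Within each gene's promoter
   (−2.5 kb…+0.5 kb of the TSS, strand-aware, clipped to the chromosome),
   collect conserved non-coding elements (CNEs; alignment-identity blocks
   ≥ 70%, merged, ≥ 100 bp). Each unique CNE becomes a vector of per-motif
   hit counts over the motif library, labeled by the promoter set it
   intersects. A class-weighted linear SVM is trained and assessed by
   double-loop cross-validation.
2. **Scan.** The trained model scores distal candidates — CNEs (or 230-bp
   windows stepped by 115 bp) that do not touch any promoter zone — in the
   loci of the positive and negative gene sets. A candidate is called an
   enhancer prediction when its decision score exceeds `s = min(0, δ)`,
   where δ is the lowest score among the top 5% of candidates in the
   control (negative-set) loci.
3. **Evaluate.** Locus-level statistics: the ratio of prediction proportions
   between positive and negative loci (with Fisher's exact test), the ratio
   of fractions of loci containing ≥ 1 prediction, a rank-sum test on the
   score distributions, and optional overlap of predictions with external
   mark intervals against 1,000 length-matched randomizations.

## Motif scanning

Motif libraries are read from JASPAR / TRANSFAC count matrices (converted to
probabilities with a symmetric pseudocount of 0.25 per cell) or minimal MEME
probability matrices (taken verbatim). Scanning uses log2-odds scores
against a 0-order background (uniform by default; optionally estimated from
the scanned sequences). The null score distribution of each motif is
computed exactly by positionwise convolution on a discretized grid
(bin width 10⁻³ bits), and a window is a hit when its exact tail probability
is ≤ 10⁻⁴ — the same per-position threshold MAST uses for motif display.
Both strands are scanned and overlapping hits all count; window scores are
accumulated on the discretized grid so scan p-values agree bit-for-bit with
the null distribution queries. Windows containing non-ACGT characters are
skipped.

## The classifier

Training solves the class-weighted soft-margin linear SVM primal

    min ½‖w‖² + C Σᵢ cᵢ ξᵢ,  s.t. yᵢ(w·xᵢ + b) ≥ 1 − ξᵢ, ξᵢ ≥ 0,

with cᵢ = w₁ for positive samples and 1 for negatives. Two printed formulas
in the source material for this family of models are typographically
ambiguous; the renderings used here are:

- `C = 1 / meanᵢ‖xᵢ‖²` — a scale-normalizing heuristic (overridable via
  `TrainConfig.C_override`);
- `w₁ = (n⁻/n⁺)·γ` — class balancing times a grid-searched factor
  γ ∈ {1/3, 2/3, 1, 4/3, 5/3} (direction flippable via
  `TrainConfig.flip_class_weight`).

The dual is solved by an in-package SMO solver (maximal-violating-pair
working-set selection, the libsvm strategy) with the bias handled exactly
through the equality constraint. The linear kernel lets the weight vector be
maintained directly, and warm starts from a previous solution make
leave-one-group-out refits converge in a handful of iterations — the reason
the solver is in-package: the consistent-set construction below performs
tens of thousands of such refits per tissue. Default stopping tolerance is a
KKT violation gap of 10⁻³ (libsvm's default); the test suite cross-checks
the solver against libsvm and against primal-feasibility probing.

### Consistent positive set and double-loop CV

Promoter sets are heterogeneous: not every CNE in a highly expressed
promoter carries the tissue signature. In each cross-validation fold, the
training four-fifths is distilled into a "consistent" positive set: for
every positive promoter P, a model is trained on the fold minus all of P's
elements, P's elements are scored, and up to two positive-scoring ones
(chosen uniformly at random) represent P. The final fold classifier is
trained on the consistent positives plus the fold's negatives and evaluated
by AUC on the held-out fifth of both classes. (A printed description of
this step pairs the consistent positives with the *held-out* negatives,
which would train on test data; the package trains on the training-fold
negatives by default and provides `literal_negative_holdout` to reproduce
the printed variant.) The whole procedure runs for 5 folds × 5 repeats; γ is
selected once per tissue to maximize the median held-out AUC, ties breaking
toward γ = 1 (the least-perturbed class weight). A model is labeled
*reliable* when its median AUC ≥ 0.6 (inclusive). The inner screening
models are solved to a looser tolerance (gap 10⁻², iteration cap 3,000)
than published models — they only contribute score signs.

All randomness (fold assignment, per-promoter picks) derives from a single
seed through named `SeedSequence` substreams.

### Weight interpretation

Motif relevance is read from the weight vector. For cross-model
comparability, weights are scaled sign-preservingly into [−1, 1]: positive
weights divide by the largest positive weight; negative weights divide by
|min weight| (the algebraic simplification of the printed piecewise
formula, used because it is numerically stable near zero).

## Prediction threshold

δ is the k-th largest control score with k = max(1, ⌊0.05·N⌋), and
predictions require score > min(0, δ) (strict). When δ < 0 — the typical
regime, since control candidates score predominantly negative — at most
~5% of control candidates pass their own threshold, which is what makes the
~5% false-positive-rate estimate meaningful. When δ > 0 the printed rule
relaxes the threshold to 0 and the control pass rate may exceed 5%; the
package implements the rule as printed and the evaluation reports the
realized control call rate. δ is computed separately per candidate class
(CNEs vs windows) over whichever class is being called.

## Synthetic study conditions

The generator (`promsig.simulate`) emulates the study design so that every
stage is testable without external data. Defaults are the study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_high`, `n_low` | 200, 200 | positive / negative gene-set sizes |
| `n_other` | 20 | background genes ranked mid-table |
| `locus_length` | 60 kb | per-gene locus, loci tiled end to end |
| `cnes_per_promoter_mean` | 2.4 | Poisson rate of promoter CNEs |
| `cne_length_mean` | 249 bp | shifted-geometric CNE length (min 100 bp) |
| `distal_cnes_per_locus_mean` | 4.0 | background distal CNEs per locus |
| `identity_range` | (0.70, 0.95) | uniform CNE identity |
| `n_planted` / `decoy_motifs` | 3 / 97 | planted vs never-embedded motifs |
| `p_plant` | 0.8 | per-site embedding probability |
| `n_enh` | 2 | planted distal enhancers per high locus |
| `motif_length` / `motif_sharpness` | 10 / 0.85 | random PWM shape |

Planted motifs are embedded into high-promoter CNEs and into the distal
truth enhancers by sampling instances from the PWM (not fixed consensus),
so the p-value-thresholded scanning is genuinely exercised. Low-expression
promoters and background CNEs receive no planted sites beyond chance.
Conservation is a binary mask (a second genome is not simulated).
The library holds 100 motifs (3 planted + 97 decoys): large enough that
"all planted motifs in the top 5% of scaled weights" is a meaningful
recovery criterion (top 5% = 5 motifs), while keeping a full pipeline run
around a minute on one CPU. The 60 kb locus and the 2 planted enhancers +
~4 background CNEs per locus keep candidate counts near 2,000 per run —
a deliberately scaled-down genome relative to a mammalian one.

What the generator does **not** emulate: CpG islands and TATA boxes,
realistic conservation-score distributions, overlapping genes and
alternative TSSs, GC isochores, or correlated motif co-occurrence. Passing
recovery tests therefore demonstrates that the pipeline's machinery is
correct and self-consistent, not that real tissues will reach the same
AUCs or fold enrichments.

## Statistics

- **Rank-sum test** (motif over-representation, score shifts): exact by
  enumeration of all rank splits for combined n ≤ 20 (valid under ties),
  otherwise normal approximation with tie and continuity correction;
  two-sided p = min(1, 2·min(tails)).
- **Fisher's exact test**: two-sided by hypergeometric enumeration (SciPy),
  degenerate margins give p = 1 with a warning.
- **AUC**: rank-based Mann–Whitney estimator, ties counted ½.
- **Randomization p-values**: length-matched intervals placed uniformly in
  allowed space (excluded regions removed; placements not collision-checked
  against each other), with add-one smoothing so p ≥ 1/(n_rand+1).
- **GC log-ratio** between locus sets: natural log by default; base 2
  available via the `base` argument.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open everywhere; 1-bp abutment is not
  overlap.
- Intergenic gaps split at the integer-floor midpoint, so locus tiling is
  exact.
- Merged identity blocks average identity weighted by block length.
- Elements touching both a high and a low promoter are ambiguous and
  dropped with a warning; a CNE serving several same-class promoters
  appears once with the union of attributions.
- Degenerate CV folds (a class absent, or an empty consistent set) are
  skipped with a warning; only if all folds degenerate does training fail.
- Score discretization means scan p-values are exact for the binned score,
  within one bin of the unbinned enumeration.
- `permute_pwm` permutes the four probabilities independently at each
  position, preserving per-position multisets and information content.

## Known limitations

- The SMO solver is dense and single-threaded; libraries with > 10⁵
  training vectors would need chunked or sparse handling.
- Candidate locus assignment takes the first overlapping locus; a candidate
  spanning a locus boundary is attributed to the left locus.
- The CLI's `scan` command recomputes CNEs and gene sets from the config
  rather than persisting them from `train`; with differing configs between
  the two commands the exclusion zones can differ.
- The rank-sum normal approximation is used above combined n = 20; for
  n barely above the cutoff with heavy ties, exact and approximate p-values
  can differ by a few percent.
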