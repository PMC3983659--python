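# promsig

Tissue-specific enhancer prediction from promoter sequence signatures.

## The problem

Enhancers drive most tissue-specific transcription, but unlike promoters
they are scattered across vast distances and carry no positional anchor.
`promsig` exploits the observation that promoters and enhancers active in
the same tissue share transcription-factor binding motifs: a classifier
trained only on *promoters* of genes highly vs. lowly expressed in a tissue
can be reused, unchanged, as a *genome-wide enhancer detector* for that
tissue. The package is for regulatory genomicists who have a genome, a
transcript annotation, an expression table, a motif library, and
cross-species conservation — and want tissue-specific enhancer candidates
plus honest statistics about them.

## The model

Each conserved non-coding element (CNE, ≥ 70% cross-species identity)
inside a promoter (−2.5 kb…+0.5 kb of the TSS) becomes a count vector
**x** over a motif library, where xⱼ is the number of hits of motif *j*
(log₂-odds scan, exact per-position p ≤ 10⁻⁴, both strands). A
class-weighted linear SVM

  min ½‖w‖² + C Σᵢ cᵢ ξᵢ  s.t. yᵢ(wᵀxᵢ + b) ≥ 1 − ξᵢ, ξᵢ ≥ 0

separates CNEs of highly expressed promoters (y = +1, error weight
c = w₁ = (n⁻/n⁺)γ) from those of lowly expressed promoters (y = −1,
c = 1), with C = 1/mean‖xᵢ‖² and γ grid-searched over
{⅓, ⅔, 1, 4/3, 5/3}. Accuracy is assessed by a double-loop five-fold CV
(×5 repeats) in which each training fold is first distilled into a
"consistent" positive set: per promoter, up to two elements that a model
trained *without* that promoter scores positive. Models with median
AUC ≥ 0.6 are *reliable*. Distal CNEs (or 230/115-bp sliding windows)
outside all promoter zones are then scored with f(x) = wᵀx + b, and a
candidate is a prediction when f(x) > min(0, δ), δ being the lowest score
of the top 5% of control-locus candidates. Locus-level enrichment (ratio
of prediction proportions, fraction-of-loci fold, rank-sum score shift,
randomized mark overlaps) evaluates each prediction set. See
`docs/methods.md` for the full account.

## Worked example

Everything below runs on a synthetic genome with planted ground truth —
30 highly and 30 lowly expressed genes in 60-kb loci, promoter CNEs at
2.4 per promoter, 3 planted tissue motifs among 97 decoys, and 2 planted
distal enhancers per high-expression locus:

```python
import numpy as np
import promsig as ps

spec = ps.SyntheticSpec(n_high=30, n_low=30, n_other=5, seed=1)
bundle = ps.generate(spec)
data = ps.Dataset.from_bundle(bundle)
cfg = ps.RunConfig(tissue="tissue_a", n_top=30, n_bottom=30,
                   train=ps.TrainConfig(repeats=2, seed=1))

trained = ps.run_train(cfg, data)
print(f"median AUC: {trained.report.median_auc:.3f} ({trained.reliability})")

scan = ps.run_scan(cfg, data, trained)
print(f"predictions: {len(scan.predictions)} (threshold s = {scan.threshold:.3f})")

report, _ = ps.run_evaluate(cfg, scan)
print(f"fold enrichment (high vs low loci): {report.fold_predictions:.2f}")

precision, recall = ps.truth_eval(scan.predictions, bundle.truth_enhancers)
print(f"truth precision/recall: {precision:.2f} / {recall:.2f}")

sw = ps.scale_weights(trained.model.w)
top = np.argsort(-sw.scaled)[:5]
print("top motifs:", [trained.model.motif_ids[j] for j in top])
```

Output:

```
median AUC: 0.891 (reliable)
predictions: 58 (threshold s = -0.819)
fold enrichment (high vs low loci): 9.31
truth precision/recall: 0.78 / 0.75
top motifs: ['PLANTED_01', 'PLANTED_00', 'DECOY_054', 'DECOY_002', 'DECOY_033']
```

Reading it: the promoter model separates held-out promoter CNEs with
median AUC 0.89; applied distally it calls 58 enhancer candidates, 9.3×
denser (per scanned sequence) in the loci of highly expressed genes than
in control loci; 78% of calls overlap a planted enhancer and 75% of
planted enhancers are recovered; and the motifs with the largest scaled
weights are dominated by the planted (truly tissue-specific) ones.

The same pipeline is available from the shell:

```bash
promsig simulate --out bundle/ --seed 1
promsig train    --config config.yaml --out run/
promsig scan     --config config.yaml --model run/model.json --out run/
promsig evaluate --config config.yaml --scored run/scored.tsv --out run/
```

where `config.yaml` names the five input files (`genome`, `transcripts`,
`conservation`, `expression`, `motifs`) and the tissue column.

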