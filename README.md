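# circboost

Prediction of circRNA-disease associations by multi-network data fusion
and gradient-boosted regression trees.

Circular RNAs (circRNAs) are covalently closed non-coding RNAs that act as
miRNA sponges and are increasingly used as disease biomarkers, but
experimentally validating a circRNA-disease link is slow and expensive.
`circboost` is for computational biologists who have a curated set of known
associations (e.g. a CircR2Disease-style export) plus heterogeneous side
data — circRNA sequences, GO annotations, expression profiles, disease gene
sets and a disease ontology — and want a ranked list of candidate novel
associations with a defensible cross-validated evaluation.

## Method

Let `A ∈ {0,1}^{|C|×|D|}` be the known association matrix over circRNAs C
and diseases D.

**circRNA similarity.** Three views are computed over C: `Seq_CS` from
global (Needleman-Wunsch) alignment with affine gaps, normalized by the
larger self-alignment score; `Fun_CS` from an information-content ratio of
GO annotation sets, `sim(i,j) = 2 ln P(i∩j) / (ln P(i) + ln P(j))` with
probabilities taken as term-set proportions of the GO universe; and `ES`
from the Pearson correlation of expression profiles (negative correlations
clamp to 0). The views are merged by similarity network fusion (SNF):
each view is row-normalized with half its mass on the diagonal, reduced to
a row-stochastic K-nearest-neighbor kernel `S`, and iterated with the
cross-diffusion update `P_v ← S_v · mean_{u≠v}(P_u) · S_vᵀ` (symmetrized
and renormalized each step) to a consensus matrix `P`.

**Disease similarity.** `DS = α·DFS + (1−α)·DSS` with `α = 0.5`, where
`DFS` is the Jaccard index of disease gene sets and `DSS` is the
Wang-method ontology similarity (semantic contribution decaying by 0.8 per
`is_a` edge).

**Pair features.** Each pair (c, d) gets
`F = [F1(c), F1(d), F2(c), F2(d), F3(c), F4(c,d)]`: association degree,
mean similarity and a 10-bin similarity histogram (F1); degree, top-10
similarities, neighbor-averaged F1 and betweenness/closeness/eigenvector
centrality in the mean-thresholded similarity graph (F2); GC content and
k-mer spectra, k = 2, 3, 4 (F3); truncated-SVD latent vectors of `A`,
degrees and bipartite-graph centralities (F4). An optional standardized
PCA reduces the vector. By default the association-derived blocks are
computed on *pair-conditional views* of `A` (the disease's column zeroed
for the circRNA side and vice versa), so no feature encodes the pair's own
label — see `docs/methods.md` for why this matters.

**Model.** Gradient boosting with squared-error loss, written from first
principles: `F_0 = mean(y)`, then 60 stages of depth-9 regression trees
fitted to residuals on an 80% row subsample, with per-node feature
subsampling (9 features), `min_samples_split = 24`, `min_samples_leaf =
11`, learning rate 0.1.

**Evaluation.** Balanced leave-one-out cross-validation: all positives
plus an equal number of uniformly sampled unknown cells; each sample is
held out in turn and the model retrained; held-out scores swept in
descending order yield the ROC/AUC, plus precision/recall/F-measure and
top-k hit counts, with a shuffled-label null for calibration.

A built-in synthetic generator emulates all input files with planted
functional blocks at the benchmark scale (132 circRNAs, 40 diseases, ~140
associations, 32 expression sites), so the whole pipeline is testable
without any downloads.

## Worked example

```python
from circboost import evaluate, gbdt, pipeline
from circboost.synthetic import SynthConfig, generate

bundle = generate(SynthConfig(n_circ=30, n_disease=12, n_blocks=3,
                              seq_len=(60, 100), n_sites=10,
                              within_block_assoc_prob=0.35,
                              between_block_assoc_prob=0.01, seed=7))
A, assembler = pipeline.build_assembler(bundle)
params = gbdt.GBDTParams(n_estimators=30, max_depth=4, min_samples_split=8,
                         min_samples_leaf=4, max_features=30)
report = evaluate.balanced_loocv(A, assembler, params, seed=0, n_folds=40)
null = evaluate.balanced_loocv(A, assembler, params, seed=0, n_folds=40,
                               shuffle_labels=True)
print(f"AUC {report.auc:.3f} vs null {null.auc:.3f}; F {report.f_measure:.3f}")
```

prints

```
AUC 0.909 vs null 0.552; F 0.778
```

AUC 0.909 says the held-out score of a true association beats that of a
sampled non-association 91% of the time; the shuffled-label null of 0.552
shows the same protocol on destroyed labels sits near chance, so the gap
is real planted signal. The `examples/` directory walks through each stage
(simulation, similarity and fusion, feature assembly, boosting,
cross-validation) with a short narrative script per capability, and the
`circboost` command line exposes `simulate`, `similarity`, `fuse`,
`featurize`, `train`, `predict`, `evaluate` and `tune` subcommands over
flat files.

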