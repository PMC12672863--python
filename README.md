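# charmark

Character-level Markov-chain biomarkers of cognitive decline from speech
transcripts.

Spontaneous speech changes early in dementia: more and longer pauses, more
repetition, less lexical variety. `charmark` looks for these signatures at
the lowest useful level of a transcript — the sequence of characters itself.
Each transcript, normalized to 26 lowercase letters plus the space symbol,
is modeled as its own first-order Markov chain with Laplace-smoothed
transition probabilities

```
P_ij = (n_ij + α) / Σ_u (n_iu + α),        α = 0.01 by default,
```

and summarized by the chain's stationary distribution π (the solution of
πP = π, Σπ_i = 1): a 27-dimensional, interpretable fingerprint of long-run
character usage in which the space entry acts as a structural proxy for
pausing and word-boundary rate. The package is aimed at researchers in
digital biomarkers and computational linguistics of ageing who want a
transparent, lightweight alternative to black-box text classifiers.

On top of feature extraction it provides:

* **Screening** — two-sample Kolmogorov–Smirnov tests per character with
  Bonferroni correction over the full 27-feature family;
* **Unsupervised structure** — k-means with silhouette-based selection of
  k, 2-D PCA projections, rolling mean/SD traces of single features;
* **Supervised validation** — L1-penalized (lasso) logistic regression
  under stratified 5-fold cross-validation with all of a participant's
  transcripts confined to one fold, reporting AUC, F1, precision,
  recall/sensitivity, specificity, accuracy (mean ± SD across folds), Brier
  score, expected calibration error, reliability bins, and thresholds
  optimized for Youden's J and maximal F1;
* **Ablations** — raw character frequencies, the space proportion alone,
  and a second-order (bigram-state, 729-state) chain variant;
* **A synthetic-corpus generator** — group-specific chains over the same
  alphabet, with tunable space-rate shifts, self-loop inflation, and
  transition-level letter effects, so the full pipeline is testable when
  real clinical corpora are access-gated;
* **Network export** — per-transcript transition graphs (DOT / GraphML /
  edge CSV) for visualizing rigid versus flexible production.

## Worked example

```python
import charmark as cm

spec = cm.GeneratorSpec(space_shift=0.03, seed=1)   # case group: +3pp space rate
corpus, _ = cm.generate_corpus(spec)                # 552 transcripts, 266 participants
fm = cm.build_feature_matrix(corpus, alpha=0.01)    # 552 x 27 stationary vectors

for r in cm.screen_features(fm)[:3]:
    print(r.feature_name, round(r.statistic, 3), r.significant)

plan = cm.make_folds(corpus, n_folds=5, seed=0)
rep = cm.evaluate_cv(corpus, plan, "charmark", seed=0)
print(round(rep.mean["auc"], 3), "+/-", round(rep.sd["auc"], 3))
```

prints

```
space 0.544 True
e 0.287 True
n 0.231 True
0.848 +/- 0.054
```

i.e. the space feature dominates the KS ranking (D = 0.544, significant
after Bonferroni), the letters pick up the indirect renormalization of the
space shift, and the cross-validated lasso separates the groups with mean
AUC 0.848 ± 0.054 while typically selecting a single feature per fold — the
space probability.

The `examples/` directory has one short script per capability (feature
extraction, screening, clustering/PCA, classification + calibration,
smoothing sweep + network export); each prints its numbers with a line on
what they mean. A thin CLI mirrors the same stages:

```bash
charmark simulate --out scratch/corpus --seed 1 --space-shift 0.03
charmark features --manifest scratch/corpus/manifest.csv --out scratch/features.csv
charmark screen --features-csv scratch/features.csv --out scratch/screen.csv
charmark classify --manifest scratch/corpus/manifest.csv --out scratch/cv --seed 0
charmark sweep-alpha --manifest scratch/corpus/manifest.csv --out scratch/sweep.csv
```

## Layout

```
src/charmark/      preprocess, markov, stats, unsupervised, classify,
                   synth, network, cli  (+ bundled English prose sample
                   used to give the generator realistic character statistics)
tests/             unit + property + end-to-end acceptance tests
examples/          narrative scripts, one per capability
docs/methods.md    modeling assumptions, parameter choices, limitations
```
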