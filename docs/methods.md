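# Methods

## Model

Each transcript is reduced to a symbol stream over a fixed 27-symbol
alphabet (a–z, then space) and modeled as its own first-order Markov chain:
the probability of the next character depends only on the current one.
Transition probabilities are Laplace-smoothed,

    P_ij = (n_ij + α) / Σ_u (n_iu + α),

which keeps every transition strictly positive for α > 0. Strict positivity
matters twice: it removes zero-probability transitions from short
transcripts, and by Perron–Frobenius it guarantees a unique strictly
positive stationary vector π with πP = π, Σπ = 1. That stationary vector —
the long-run occupancy of each character — is the transcript's feature
vector. Chains are fit per transcript, never pooled: pooling would erase
exactly the between-transcript variation the screening and classification
stages measure.

The space symbol is retained as a structural token marking word boundaries.
It is a proxy for pausing and fluency, not an acoustic measurement; the
interpretation of an elevated stationary space probability is "more
word-boundary events per character produced", which co-varies with hesitant,
fragmented speech.

### Second-order variant

The bigram-state ablation lifts the state space to character pairs:
27² = 729 states, with smoothing applied over the 27 emitted symbols per
bigram row (729 × 26 = 18,954 free parameters). The stationary vector lives
on the 729 bigram states of the induced chain in which (c₁,c₂) moves to
(c₂,c₃) with probability P[(c₁,c₂), c₃]. This lifting preserves the
free-parameter count and is the standard construction for bigram-to-bigram
transitions; the alternative of smoothing over 729 successor states would
assign mass to structurally impossible transitions.

## Parameters that matter

| parameter | default | units / range | why |
|---|---|---|---|
| α (smoothing) | 0.01 | pseudo-count per cell | small enough to preserve the sparsity of character transitions, large enough for positivity; a sweep over {0.001, 0.005, 0.01, 0.05, 0.1} is built in and the cross-validated AUC spread across it is reported |
| order | 1 | {1, 2} | first order balances stability and interpretability; order 2 multiplies parameters ×27 against the same data |
| C (lasso) | 1.0 | inverse penalty | sparse, interpretable coefficients with class-balanced weighting; features enter un-standardized since all 27 share the probability scale (an inner-CV selection of C would trade determinism for little gain at these dimensions) |
| n_folds | 5 | — | stratified, participant-grouped |
| ECE bins | 10 | equal-width | conventional default; empty bins skipped |
| k range (k-means) | 2–6 | — | silhouette comparison needs a range; ties go to smaller k |
| rolling window | 25 | transcripts | display-scale smoothing for single-feature traces |

## Numerical choices

* Stationary solve: dense left-eigendecomposition taking the eigenvalue
  nearest 1, real parts kept, numerically negative entries clipped at zero,
  renormalized; power iteration (tol 1e−12, ≤10,000 iterations) is the
  fallback and the primary path for the 729-state lifted chain (structured
  sparsity makes power iteration cheap, and α > 0 makes the lifted chain
  irreducible and aperiodic). The accepted residual is max|πP − π| ≤ 1e−8.
* α = 0 is allowed only when every observed row has mass; an all-zero row is
  an error rather than an arbitrary uniform fill.
* KS p-values are asymptotic by default — adequate at the ~100–300
  samples/group regime this screen targets; a seeded permutation mode exists
  for small samples. Ranking is by the D statistic, not p.
* Threshold optimization scans midpoints of sorted unique probabilities
  plus {0, 1}; ties go to the lower threshold.
* Fold construction is greedy: participants sorted by transcript count
  descending (seeded shuffle breaks ties), each placed in the fold with the
  lightest load of its own class, then the lightest total. This keeps
  per-fold class proportions within a few points of the global proportion
  while guaranteeing that no participant ever spans folds.
* Aggregate CV metrics are means ± SD of per-fold metrics; pooled
  out-of-fold metrics are reported alongside, and the AUC of the pooled
  predictions is checked against the normalized Mann–Whitney U statistic in
  the tests.
* PCA centers but does not variance-scale: the features are commensurable
  probabilities, and unit-variance scaling would inflate rare-letter noise.
  Component signs follow the largest-magnitude-loading-positive convention.
* Feature CSVs carry 12 significant digits; the space column is headed
  `space` and network exports render the space node as `␣`.

## What the synthetic generator emulates — and what it does not

The generator draws each participant's chain from a base chain estimated on
a bundled English prose sample (so letter statistics and word-length scale
are realistic), perturbs rows by Dirichlet resampling (concentration 500 by
default; lower = more participant heterogeneity), and applies case-group
effects: an additive tilt of every row's space-transition probability, a
multiplicative diagonal (self-loop) inflation, and/or a within-row transfer
of mass between two letter columns. The last leaves each row's space
probability untouched, providing a transition-level effect with matched
space usage for ablation studies. Default composition is 310 case
transcripts from 168 participants and 242 control transcripts from 98
participants, lengths uniform on [300, 1500] characters.

Synthetic transcripts are not language: there is no lexicon, no syntax, no
topic structure, and the group effects are homogeneous across rows rather
than concentrated in linguistically meaningful contexts. Passing tests
therefore demonstrate that the pipeline recovers distributional effects of
known size and direction under realistic character statistics and
participant grouping — they do not certify clinical performance on real
speech, which is access-gated and outside this package's reach. Effect
sizes (space shift 0.03–0.05) are free parameters chosen to give clearly
detectable but imperfect separation at the default corpus size; analyses of
calibration under the null use zero effects so the two groups are
exchangeable by construction.

Sampling post-processing (collapsing space runs, trimming boundary spaces)
re-imposes the transcript invariants; because the base chain's space
self-loop is negligible, the bias this introduces relative to the
generating chain's stationary vector is far below the recovery tolerances
used in testing.

## Problem sizes used in the checks

The end-to-end checks run at the default 552-transcript composition for
screening, clustering, classification and the smoothing sweep; null
calibration uses 80 participants × 120 transcripts with 200 label
permutations and 1,000 simulated 27-feature screens at 30 samples/group;
stationary recovery uses 5,000-character transcripts. At smaller corpus
sizes (≲200 transcripts) the class-balanced lasso at C = 1 can shrink to an
intercept-only model — a property of the penalty/sample-size trade-off
worth knowing when applying the pipeline to pilot-scale data.

## Known limitations

* The CHAT reader is a minimal dialect (participant tier only, annotation
  markup stripped); full CHAT/CLAN support is out of scope.
* Digits are treated as word boundaries, not verbalized; accented letters
  are ASCII-folded; apostrophes are deleted in place so contractions fuse.
  Inter-utterance boundaries are joined with a space.
* No covariate adjustment (age, education) and no post-hoc recalibration
  (Platt/isotonic); the calibration stage measures, it does not correct.
* Orders above 2, variable-length context models, and word-level baselines
  (TF–IDF, transformer fine-tuning) are deliberately excluded.
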