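# Methods

`qsaropt` implements a four-phase surrogate-assisted search for regions of
molecular-descriptor space that combine high predicted anti-breast-cancer
activity (ER-alpha inhibition, measured as pIC50) with acceptable ADMET
behavior. Descriptors are treated purely as precomputed numeric features;
no chemistry is performed and compound identifiers are opaque strings.

## 1. Descriptor screen

The raw table (by default 1,974 compounds x 729 descriptors, of which 225
are identically zero) is reduced in four nested stages:

1. **Constant-column removal.** A column is removed iff all of its values
   are exactly identical (the all-zero case is the common one). Exact
   equality, not a variance epsilon, so the rule is scale-free and
   reproducible.
2. **Min-max normalization.** x' = (x − x_min)/(x_max − x_min) per column;
   the (x_min, x_max) pairs are retained and reused to normalize test
   compounds and to de-normalize optimizer output. Test-set values may
   fall outside [0, 1]; they are not clipped.
3. **Grey relational analysis (GRA).** With reference sequence y(k) (pIC50,
   min-max normalized with the same formula so differences are
   commensurate) and candidate x_i(k), the relational coefficient at
   point k is (a + αb)/(|y(k) − x_i(k)| + αb), where a and b are the
   global min and max absolute difference over all candidates and points
   and α = 0.5 is the resolution coefficient. The relational degree is
   the per-candidate mean over points; the top 200 descriptors by degree
   are kept. GRA rewards similarity of curve *shape*, so it picks up
   monotone nonlinear associations that Pearson correlation would damp.
4. **Spearman redundancy filter.** Greedy scan in GRA-rank order; a
   candidate is kept iff its |rank correlation| with every already-kept
   descriptor is ≤ 0.85 (Pearson formula on average-tie ranks). Scanning
   in GRA order means the member of a correlated pair with the stronger
   activity association survives, making the reduction deterministic.
5. **Shapley ranking.** A seeded random forest is fit to pIC50 over the
   survivors and descriptors are ranked by mean |Shapley attribution|;
   the top 20 form the activity panel.

Ties anywhere break by descending score then ascending name, so every
report is bit-reproducible.

### Tree-Shapley attributions

Attributions are computed by an exact path-dependent tree-Shapley kernel
(`qsaropt._treeshap`, numba-compiled): the value of a feature coalition S
is the expectation of the tree output when splits on features outside S
are averaged over both children with training-cover weights and splits on
features in S follow the sample. The algorithm maintains an incrementally
extended/unwound path representation of subset proportions and is
O(leaves · depth²) per sample per tree. It satisfies local accuracy
(attributions sum to prediction minus baseline, verified to ~1e−15) and
matches a brute-force subset-enumeration Shapley oracle to ~3e−16 on
small trees.

The ranking forest uses 200 trees, depth ≤ 10 and sqrt feature
subsampling, with attributions computed on a seeded 100-row subsample.
These sizes were chosen because descriptor *ranking* stabilizes long
before forest predictions do; they keep the whole screen under ~10 s at
the 1974 × 729 scale while recovering 94% of planted signal descriptors
across ten seeded datasets (see §6).

## 2. Activity surrogate

Ten regression families (linear, ridge, lasso, elastic net, random
forest, LightGBM, XGBoost, gradient-boosted trees, SVR, decision tree;
library defaults, fixed seeds) are trained on the 20-descriptor panel
with a seeded 8:1:1 train/test/validation split (test and validation
sizes round to the nearest integer; the remainder trains). Families are
ranked by test-split R²; MAPE is excluded from ranking because pIC50
values near zero destabilize relative error. The top three are fused
three ways:

- **simple average**;
- **weighted average** with weights (0.5, 0.3, 0.2) assigned in
  descending base-model test R²;
- **stacking**: an intercept-free OLS meta-model fit on 5-fold
  out-of-fold base predictions over the training split (minimum-norm
  least squares, so collinear base predictions are harmless; identical
  base predictions are reproduced exactly).

All three fusion strategies are scored on the validation split, which no
training or weight-selection step ever touches; the configured strategy
(stacking by default) becomes the surrogate. Predictions convert between
scales by pIC50 = 9 − log10(IC50 in nM), i.e. −log10 of the molar IC50.

## 3. ADMET surrogates

For each endpoint (Caco-2 permeability, CYP3A4 metabolism, hERG
cardiotoxicity, HOB oral bioavailability, MN mutagenicity), recursive
feature elimination under a seeded 100-tree random forest — refit, drop
the single least impurity-important feature, repeat — reduces the
post-constant-removal table to 25 descriptors, using the training split
only. Eleven classifier families (logistic regression, Gaussian naive
Bayes, LDA, decision tree, random forest, AdaBoost, gradient boosting,
SVC with probability calibration, MLP, XGBoost, LightGBM) are trained on
those descriptors and compared on the test split by F1 (ties: higher
AUC, then family name). The winner becomes the endpoint's surrogate.

Scores are positive-class probabilities; the decision threshold is 0.5
with score-at-threshold mapping to label 1. F1 is defined as 0 when
precision + recall = 0. AUC is the trapezoid integral of the explicit
threshold-sweep ROC, which equals the Mann-Whitney pairwise-comparison
statistic (tested to 1e−9). No class reweighting is applied; prevalence
is logged so imbalance effects stay visible. A family that fails to fit
is recorded and skipped.

## 4. Constrained swarm search

The decision space is the first-occurrence-ordered union of the activity
panel and the five ADMET panels; for the published reference panels this
is 106 distinct descriptors with 39 duplicate occurrences. Search happens
in normalized [0, 1] coordinates; each surrogate reads exactly its own
feature sublist from a position by name, so descriptors outside a
surrogate's panel cannot affect it.

The scalar objective is

    value(x) = −pIC50_hat(x) + penalty · max(0, threshold − Reward(g(x)))
    Reward(g) = g1 + g2 + (1 − g3) + g4 + (1 − g5)

with favorable orientations (1, 1, 0, 1, 0) for (Caco-2, CYP3A4, hERG,
HOB, MN), threshold 3 and additive penalty coefficient 10 (configurable).
Exactly 16 of the 32 label combinations are feasible at threshold 3.

PSO uses the inertia-form update v ← w·v + c1·r1·(p_i − x) + c2·r2·(p_g − x)
with w = 0.8, c1 = c2 = 0.5, fresh uniform r1, r2 per particle per
dimension, velocities clamped to ±20% of the box range, and positions
clamped to the box with velocity zeroed on clamped dimensions. Defaults:
swarm 50, 80 iterations (30/30 in the small preset). Velocities start at
zero from a uniform initialization. The global-best trace is monotone
nonincreasing by construction. On benchmark functions the defaults reach
<1e−8 on the 2-D sphere (m=20, 100 iters) and <1e−6 on the 2-D
Rosenbrock (m=40, 300 iters).

Optimal per-descriptor ranges pool every feasible evaluated point, keep
the best 10% by objective value (configurable), take elementwise min/max
and de-normalize through the stored (x_min, x_max). With one feasible
point the range is degenerate; with none, range derivation raises and
suggests reviewing swarm size and penalty.

## 5. Synthetic data

The competition dataset has no public accession, so the generator
reproduces its shape and the statistical features each stage needs:

- **Shape**: 1,974 train / 50 test compounds, 729 descriptors, 225
  all-zero columns (all configurable).
- **Descriptors**: independent uniform or log-normal columns on
  heterogeneous scales (normalization has real work); planted signal
  columns are Uniform(0, 1).
- **Activity**: pIC50 = 5 + Σ c_i x_i + γ·x_a·x_b + N(0, noise_sd) over
  10 signal descriptors, c_i ~ U(0.2, 0.6), γ ~ U(1.5, 2.5) on the first
  two signals. The single product term is a smooth interaction linear
  models cannot represent exactly, giving tree ensembles an honest edge;
  the default noise_sd = 0.3 log-units is a typical assay
  reproducibility figure.
- **Collinearity**: a few non-signal columns are rank-jittered
  permutations of other columns' own values (|Spearman| > 0.9 with an
  identical marginal distribution), some shadowing signal columns, so
  the redundancy filter has activity-relevant work. The
  identical-marginal construction matters: additive noise would compress
  the shadow's normalized values toward the mid-range and systematically
  *raise* its grey-relational degree above its source's.
- **ADMET labels**: per endpoint, Bernoulli(sigmoid(b0 + w·z)) over six
  standardized columns (two signal + four other), coefficient scale 2
  with random signs drawn independently per endpoint; intercepts b0
  control prevalence (default 0 ⇒ ~50%).

All randomness flows from one integer seed through a single generator
stream; identical configurations are bit-identical.

What the generator does **not** emulate: real descriptor distributions
(heavy discreteness, counts, physical correlations among hundreds of
descriptors), structure–activity cliffs, label noise correlated across
ADMET endpoints, and any chemistry linking descriptors to realizable
molecules. Passing recovery tests therefore demonstrates that the
pipeline's machinery works — not that its accuracy figures transfer to
the real competition data.

## 6. Verification problem sizes

The recovery checks run at these scales (package choices, stated here so
reruns are interpretable): signal-recovery over ten seeds at the full
1974 × 729 default; stacking-surrogate recovery at n = 1,500 with
noise_sd = 0.1 (test R² ≥ 0.85); ADMET winner recovery at n = 600,
p = 120 with label coefficient scale 4 (F1 ≥ 0.8 per endpoint);
end-to-end swarm-vs-oracle at n = 300, p = 120 with permissive label
intercepts (±6 logits), comparing the swarm's best feasible predicted
pIC50 against the surrogate's maximum over 10⁵ uniform random points.

## 7. Known limitations

- Accuracy figures on real data cannot be validated without the
  original competition tables; only structural and recovery properties
  are tested.
- Path-dependent Shapley values use training-cover conditioning, which
  can spread attribution among correlated features; the Spearman filter
  upstream mitigates but does not eliminate this.
- The penalty formulation admits infeasible intermediate iterates by
  design; if no feasible point is ever evaluated, range derivation
  fails loudly rather than returning an unconstrained range.
- PSO with clamped velocities is a local-global hybrid with no
  convergence guarantee; defaults were chosen for the ~100-dimensional
  normalized box and validated on benchmark functions only.
- RFE refits one forest per eliminated feature; at the full 504-column
  scale this is the pipeline's dominant cost (~500 fits per endpoint).
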