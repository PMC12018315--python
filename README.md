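# qsaropt

Surrogate-assisted optimization of anti-breast-cancer drug candidates
over molecular-descriptor space.

Candidate compounds targeting estrogen receptor alpha (ERα) must balance
potency — IC50 against the receptor, usually reported as
pIC50 = −log10(IC50 in molar) = 9 − log10(IC50 in nM) — against five
binary ADMET liabilities: Caco-2 permeability, CYP3A4 metabolism, hERG
cardiotoxicity, HOB oral bioavailability and MN mutagenicity. `qsaropt`
builds data-driven surrogates for all six endpoints from tables of
precomputed molecular descriptors and then searches descriptor space for
regions that are simultaneously potent and ADMET-acceptable. It is aimed
at computational chemists and ML practitioners who have descriptor/assay
tables and want a reproducible screen-model-optimize pipeline; it does
no chemistry itself (descriptors in, descriptor ranges out).

The pipeline has four phases:

1. **Descriptor screen** — drop constant columns, min-max normalize,
   rank by grey relational degree against pIC50
   (ξ(k) = (a + αb)/(|y(k) − x_i(k)| + αb), degree = mean over k, α = 0.5),
   keep the top 200, remove redundancy by a greedy Spearman filter at
   |ρ| ≤ 0.85, then keep the top 20 by mean |Shapley attribution| under a
   seeded random forest (exact path-dependent tree-Shapley, implemented
   in `qsaropt._treeshap`).
2. **Activity surrogate** — train ten regression families on the panel
   (8:1:1 split), fuse the top three by simple average, 5:3:2 weighted
   average or stacking (intercept-free OLS on out-of-fold predictions);
   predictions convert between pIC50 and IC50 (nM).
3. **ADMET surrogates** — per endpoint, recursive feature elimination to
   25 descriptors under a random forest, then eleven classifier families
   compared by F1 (ties by AUC); the winner predicts binary labels at
   threshold 0.5.
4. **Constrained swarm search** — over the union of the six panels (106
   distinct descriptors for the published reference panels), maximize
   predicted pIC50 subject to the ADMET reward constraint

       Reward(g) = g1 + g2 + (1 − g3) + g4 + (1 − g5) ≥ 3,

   handled as an additive penalty and solved by particle swarm
   optimization (inertia w = 0.8, c1 = c2 = 0.5), then report
   per-descriptor optimal value ranges from the best feasible points.

Because the original competition tables have no public accession, the
package ships a seeded synthetic generator (`qsaropt.datasets`) that
reproduces their shape (1,974 × 729 descriptors with 225 all-zero
columns, 50 test compounds) and plants known activity/label structure,
so every stage is testable end to end without any download.

## Worked example

```sh
qsaropt run-all --scale small --seed 1 --out out/
```

runs the whole pipeline on a reduced synthetic problem (300 compounds,
120 descriptors of which 37 are zero, swarm 30 × 30 iterations) and
prints the per-stage summary. With seed 1 it reports, among other
things:

```
"selection":   {"n_removed_constant": 37, "n_after_gra": 60,
                "n_after_spearman": 55, "n_final": 20}
"activity":    {"base_families": ["xgboost", "random_forest", "lightgbm"],
                "fusion_strategy": "stacking",
                "fusion_r2_test": 0.8569, ...}
"admet":       {"Caco-2": {"best_family": "mlp", "best_f1": 0.9231}, ...}
"optimization":{"decision_dim": 70, "best_predicted_pic50": 8.942,
                "n_feasible_points": 910}
```

Reading: the screen removed the 37 constant columns, kept 60 descriptors
by grey relational rank, 55 after redundancy filtering, and 20 after
Shapley ranking; XGBoost, random forest and LightGBM were the three best
single models and their stacked fusion explains ~86% of held-out pIC50
variance; each ADMET endpoint got its own best classifier; and the swarm
found feasible descriptor settings with predicted pIC50 ≈ 8.9 (about
1.1 nM predicted IC50). `out/` then contains `ERα_activity_test.csv`
(predicted pIC50/IC50 for the 50 test compounds), `ADMET_test.csv`
(predicted binary labels), `results.csv` (per-descriptor optimal ranges),
`convergence_trace.csv`, selection/evaluation reports and a
`run_manifest.json` with content hashes — rerunning with the same seed
reproduces every file bit for bit.

The same stages are available as library calls (`generate_dataset`,
`run_selection`, `train_activity_model`, `train_admet_property`,
`assemble_decision_space`, `run_pso`, `derive_ranges`); see
`docs/methods.md` for the model details and design choices.

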