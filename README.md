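# sfcoupling

Region-wise **structure–function coupling** of brain connectomes, and its
use as a predictor of behavior.

Structural connectivity (white-matter streamline counts from probabilistic
tractography) and functional connectivity (correlated resting-state BOLD
fluctuations) describe the same brain through different lenses. How tightly
they agree — per region, per person — is itself a trait: a region whose
functional communication closely tracks its anatomical wiring is "coupled",
one whose activity has drifted from its wiring is not. This package
implements a complete, tested pipeline for asking whether that coupling
explains individual differences in a behavioral score (the motivating use
case is music perception measured by an averaged MBEA-style battery score),
and whether it explains them *better* than conventional unimodal features.

## What it computes

For a cohort of subjects with structural count matrices `S`, ROI volumes
`N`, and ROI time series:

1. **Connectome construction** — directed counts are symmetrized and
   normalized, `W_ij = (S_ij + S_ji) / (samples_per_voxel · (N_i + N_j))`;
   functional matrices are Fisher-z transformed Pearson correlations,
   `Z_ij = atanh(r_ij)`; edges whose weight is least consistent across
   subjects (top 30% coefficient of variation) are zeroed as tractography
   false positives.
2. **Per-ROI features** (subjects × ROIs tables):
   - *coupling* — Spearman ρ between a ROI's nonzero structural weights
     `{W_ij}` and the functional values `{Z_ij}` on those same edges;
   - *ALFF* — mean 0.01–0.1 Hz amplitude of the BOLD spectrum, z-scored
     across ROIs within subject;
   - *sDC*, *fDC* — structural/functional degree centrality (summed weights
     over the structurally present edge set);
   - *GMV* — gray matter volume per ROI.
3. **Prediction** — for each feature, an L2-regularized L2-loss linear SVR
   inside 10-fold cross-validation. In each training fold only: features
   are (optionally) residualized on covariates, filtered by Spearman
   correlation with the score at uncorrected p < 0.05, standardized, and
   fit; the held-out fold is scored with the training fold's parameters.
   Performance is the Spearman ρ (plus MAE/MSE) between actual and pooled
   out-of-fold predicted scores; significance comes from a permutation test
   that reshuffles the score and reruns the entire pipeline. ROIs selected
   by the filter in all folds are the *most predictive* set, reported with
   summed signed SVR weights.
4. **Mediation** — percentile-bootstrap simple mediation (X → M → Y) to
   test whether coupling mediates the effect of another feature on the
   score, reporting paths a, b, c, c′, the indirect effect a·b and its
   partially standardized form a·b / SD(Y).

A synthetic-cohort generator (`sfcoupling.synthetic`) produces data with
exactly the statistical structure this analysis assumes — a shared
structural backbone, FC that is a noisy monotone function of SC with
ROI-specific fidelity, and a score driven by the latent coupling of a
designated circuit — so the whole chain is testable without MRI data.

## Worked example

```python
import numpy as np
from sfcoupling import (SyntheticConfig, generate_cohort, build_connectome,
                        structure_function_coupling, drop_undefined_rois,
                        run_cv, permutation_test, CVConfig)

cfg = SyntheticConfig(n_subjects=106, n_rois=30, signal_rois=(3, 7),
                      effect_size=0.8, seed=1)
records = generate_cohort(cfg)
cc = build_connectome(records)             # symmetrize + Fisher-z + threshold
coupling, _ = drop_undefined_rois([structure_function_coupling(cc)])
scores = np.array([r.score for r in records])

res = run_cv(coupling[0], scores, config=CVConfig(n_folds=10, seed=1))
print("out-of-fold Spearman rho:", round(res.metrics["spearman_rho"], 3))
print("MAE:", round(res.metrics["mae"], 3), " MSE:", round(res.metrics["mse"], 3))
print("most predictive ROIs:", res.most_predictive)

perm = permutation_test(coupling[0], scores,
                        config=CVConfig(n_folds=10, n_permutations=999, seed=1),
                        observed=res)
print("permutation p:", perm.p_value)
```

Output:

```
out-of-fold Spearman rho: 0.414
MAE: 2.212  MSE: 7.476
most predictive ROIs: ['ROI003', 'ROI007']
permutation p: 0.001
```

The cohort was generated with a planted two-ROI circuit (ROIs 3 and 7)
whose latent coupling drives the score at standardized slope 0.8. The
pipeline recovers exactly those two regions as most predictive (selected by
the in-fold filter in 10/10 folds), predicts held-out scores at ρ ≈ 0.41
(MAE ≈ 2.2 points on a score scale with SD 3), and the permutation test
confirms the model beats its own null (p = 0.001 with 999 reshuffles).

## Command line

```bash
sfc simulate --subjects 106 --rois 30 --signal-rois 3,7 --effect-size 0.8 \
    --seed 1 --out cohort/
sfc predict  --cohort cohort/ --feature coupling --folds 10 \
    --permutations 999 --covariates age,sex,motion --seed 1 --out pred/
sfc mediate  --cohort cohort/ --x alff --m coupling --rois ROI003,ROI007 \
    --boot 5000 --seed 1 --out med/
sfc run      --config analysis.yaml     # the whole graph, one YAML
```

Exit codes: 0 ok, 2 configuration error, 3 data error.

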