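# tbmtools

Tensor-based morphometry (TBM) with voxel-wise allele-dose regression, on
synthetic brain-phantom cohorts with exactly known ground truth.

## The problem

Imaging-genetics studies ask whether carrying a risk allele is associated
with regional brain volume differences or faster atrophy.  The TBM recipe:
nonlinearly register every subject's scan to a common template, take the
Jacobian determinant of each deformation as a per-voxel measure of local
volume relative to the template, and fit, at every voxel,

    y = b0 + b_dose * dose + b_age * Age + b_sex * Sex + e

where `dose` counts risk alleles (0/1/2, the additive genetic model) and
`y` is the percent volume change at that voxel.  The dose coefficient map
is read as *percent brain tissue change per risk allele*; significance
maps are corrected across voxels with Benjamini-Hochberg FDR at q = 0.05,
reporting the *critical p-value* — the highest threshold at which only 5%
of surviving voxels are expected false positives.  Optional adjustment
sets (homocysteine, folate, ApoE4, dose-by-ApoE4 interaction) probe
confounding and mediation: an allele effect that works through plasma
homocysteine attenuates when homocysteine enters the model.

Real cohorts of this kind are access-controlled.  `tbmtools` therefore
ships a first-class phantom simulator: nested-ellipsoid brains with
Hardy-Weinberg genotypes, elderly-cohort covariates, a dose-dependent
homocysteine pathway with tunable mediation, and implanted periventricular
white-matter deficits whose per-voxel Jacobian is known in closed form —
so the whole chain (demons registration, minimal deformation templates,
Jacobian maps, voxel-wise GLM, FDR) can be validated against exact ground
truth.  It is aimed at methods developers and students who need a TBM
pipeline whose every stage is testable.

## Worked example

```python
from tbmtools import RunConfig, run_pipeline

cfg = RunConfig(seed=5, n=24, grid_shape=(32, 32, 32), out_dir="demo_run")
manifest = run_pipeline(cfg)
print(manifest.report["base"])
```

prints (seed 5):

```
{'dose_beta_region_mean': -4.914391099948902,
 'critical_p': 0.02579060759034958,
 'n_surviving': 4318,
 'peak_abs_beta': 9.317888240737714,
 'survivor_fraction_in_region': 0.9949050486336267,
 'n_complete_cases': 24}
```

Reading this: 24 phantom subjects carry an implanted −6 %/allele
white-matter deficit; after registration, Jacobian mapping, smoothing and
the voxel-wise dose regression, the mean dose coefficient over the
implanted region is −4.9 %/allele (regional means are biased toward zero
by registration regularization and smoothing — see `docs/methods.md`),
the FDR critical p-value is 0.026 at q = 0.05, and 99.5% of surviving
voxels fall inside the implanted region dilated by two voxels.  The same
report carries the post-hoc hemispheric white-matter volume regression
(`manifest.report["wm_volume_regression"]`), here with dose slopes
negative at p = 1.7e-4 (left) and 6.4e-6 (right).

The model/results layer is available directly: `VoxelwiseOLS(stack,
design, mask).fit()` returns a results object with `beta_map("dose")`,
`t_map`, `p_map`, `summary()`, and `fdr(q=0.05)`; `assemble_design`
builds the covariate-adjustment designs from subject records.

A command-line surface wraps the stages:

```sh
tbmtools simulate --n 24 --maf 0.31 --effect-percent -6 --seed 5 --out-dir sim
tbmtools run --seed 5 --out-dir demo_run        # full chain
tbmtools fdr --pvals pvals.txt --q 0.05
```

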