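# Methods

`tbmtools` implements a tensor-based morphometry (TBM) imaging-genetics
analysis and a synthetic brain-phantom cohort generator to exercise it end
to end.  This note records the models, the defaults and why they were
chosen, the numerical choices, and what the synthetic validation does and
does not demonstrate.

## The analysis chain

1. **Registration.** Each subject scan is aligned to a template (either a
   fixed phantom template or a minimal deformation template built from the
   group) by a diffusion-regularized demons scheme: at every iteration an
   intensity-difference update, scaled by the symmetrized image gradient
   and capped at `step_cap` voxels, is Gaussian-smoothed (`update_sigma`,
   fluid-like), added to the displacement field, and the field itself
   smoothed (`field_sigma`, diffusion-like), coarse-to-fine over a
   multiresolution pyramid.  The similarity is the sum of squared intensity
   differences — appropriate because phantom images share one intensity
   scale.  In symmetric mode the forward and backward fields are estimated
   jointly and periodically projected toward mutual inverses, yielding the
   inverse-consistent transforms used for baseline/follow-up pairs.

2. **Jacobian maps.** The per-voxel determinant of `I + grad(u)` measures
   local volume change of the template-to-subject transform (1 = no
   change).  Statistics run on percent maps, `(J - 1) * 100`, so the dose
   coefficient reads directly as percent tissue change per risk allele;
   log-Jacobian output is available behind a flag.  Longitudinal maps are
   the Jacobian of the baseline-to-follow-up transform, scaled to percent
   per year by each subject's actual scan interval and carried into
   template space through the baseline-to-template registration.

3. **Voxel-wise regression.** At every voxel inside the analysis mask an
   OLS model `y = b0 + b_dose*dose + b_age*age + b_sex*sex (+ adjustments)`
   is fitted across subjects, with dose the additive risk-allele count
   (0/1/2), age centered, and sex coded 0 = female / 1 = male.  Adjustment
   sets add ApoE4 allele count, homocysteine, folate, or a dose-by-ApoE4
   interaction; missing covariates are handled complete-case.  p-values
   come from the exact t distribution with n - k degrees of freedom, which
   matters at replication-cohort sizes (n ~ 50).  Voxels whose response is
   constant across subjects carry no information and are excluded from the
   valid-test count.

4. **FDR.** The dose p-values are thresholded by the plain
   Benjamini-Hochberg step-up rule at q = 0.05 over the valid tests in the
   analysis mask (brain tissue excluding the brainstem, plus the
   ventricle shell adjacent to white matter where partial-volume effects
   concentrate).  The reported *critical p-value* is the largest p(i) with
   p(i) <= i*q/m; ties share the rank of their last occurrence; survivors
   are all tests at or below it.  When nothing passes the critical p is 0.

5. **Scalar statistics.** Genotype percentages (rounded half away from
   zero to one decimal), Pearson chi-square without continuity correction
   for categorical comparisons, one-way fixed-effects ANOVA for continuous
   covariates, and a post-hoc OLS of hemispheric white-matter volume (cc)
   on dose, age and sex.  White-matter volumes in simulation are warped
   label-2 voxel counts times the voxel volume, standing in for a
   segmentation-based measure; output provenance records this.

## The phantom cohort

The template is a deterministic nested-ellipsoid "brain": a gray-matter
shell around a periventricular white-matter shell around a central
ventricle, with a small brainstem appendage.  Shell boundaries are level
sets of the normalized elliptical radius, so the implanted radial warp
aligns exactly with the tissue labels.  The intensity carries a smooth,
fixed texture inside each compartment (amplitude 0.10, correlation length
~2 voxels): without internal texture an intensity-driven registration has
no signal inside homogeneous compartments and dense Jacobian recovery
would be ill-posed in principle, not just hard.  Realism deliberately
stops there — no bias fields, motion, or multi-site effects — because the
downstream statistics consume only deformation fields.

**Implanted effect.** Each subject's scan is the template warped by an
analytic radial map whose Jacobian profile is prescribed directly: the
white-matter shell carries a uniform factor `1 + percent/100`, and the
displaced volume is released into the extra-cerebral CSF space just beyond
the brain surface — the brain shrinks within a fixed skull, the standard
picture of age-related atrophy.  Integrating the profile gives the radial
map in closed form, so the per-voxel ground-truth Jacobian is exact, the
warp conserves total volume, and it is identity far from the head.  The
compensation is placed outside the analysis mask deliberately: an earlier
design that vented the volume loss into narrow bands adjacent to the
measured shell produced large reactive expansion lobes (mass conservation
squeezed into two voxels) that any finite-resolution measurement smears
into the region of interest.  Follow-up scans compose an extra contraction
of `annual * dose * interval/12` percent multiplicatively on top of the
baseline warp, share the subject's anatomical nuisance warp, and draw
fresh intensity noise.

**Covariates.** Genotypes follow Hardy-Weinberg proportions at MAF 0.31
(the European frequency of the risk allele).  Ages are Normal(75, 7)
truncated to [55, 95]; the male fraction 0.643, the ApoE4 allele-count
distribution (0.48/0.40/0.12), and the homocysteine model
`10.2 + 0.75*dose + N(0, 2.4)` umol/L are calibrated to the published
cohort table (the slope reproduces the CC-to-TT spread 10.2 -> 11.7; the
within-group SD comes from SE 0.2 at group size ~149).  Folate is
independent of dose.  Follow-up intervals are drawn from the observed
frequency table: 10/12/13/14/15/16 months with weights 1/59/176/52/12/7.

**Mediation.** A `mediation_fraction` m routes part of the dose effect
through homocysteine: the implanted percent is
`percent*(1-m)*dose + (percent*m/hcy_per_allele)*(hcy - baseline)`,
calibrated so the expected effect per allele is `percent` at every m,
while at m = 1 the volume change is conditionally independent of dose
given homocysteine.  Note the forced consequence: a mediator that moves
only 0.75 umol/L per allele with SD 2.4 must carry a steep
volume-per-umol slope, so full mediation implies large between-subject
variance in the implanted effect.  That is a property of the scenario,
not an artifact.

**Randomness.** One named seed per run; per-subject streams are derived by
stable hashing (CRC-32) of the subject id, so cohorts are reproducible
subject-by-subject regardless of iteration order.

## Defaults that matter

| parameter | default | why |
|---|---|---|
| `percent_per_allele` | -6 %/allele | headline cross-sectional deficit |
| `annual_percent_per_allele` | -1.5 %/yr/allele | headline progression rate |
| `maf` | 0.31 | European risk-allele frequency |
| `hcy_per_allele`, `sigma_hcy` | 0.75, 2.4 umol/L | cohort-table calibration |
| `nuisance_warp_mm` | 0.5 | sub-voxel anatomical variability |
| `noise_sd` | 0.02 | ~2% of the intensity range |
| smoothing sigma | 1.5 voxels | stabilizes voxel-wise estimates |
| `update_sigma` / `field_sigma` | 1.0 / 0.8 voxels | fluid/diffusion balance; smaller field smoothing under-regularizes, larger biases Jacobians toward 1 |
| pyramid | 3 levels, (100, 80, 40) iterations | converges; the relative-improvement stop (1e-5) usually ends levels early |
| `step_cap` | 1.5 voxels | guards invertibility |
| q | 0.05 | conventional FDR level |
| Jacobian floor | 1e-3 | clamp with logged count; >1% clamped interior voxels rejects the field |

## Numerical choices

- Gradients by central differences, one-sided at faces; fields forced to
  zero on the outermost voxel shell; trilinear interpolation with
  background 0 outside the grid.
- Field inversion by fixed-point iteration `v = -u(x + v)`.
- Demons stops per level at the iteration cap or when the relative SSD
  improvement falls below `tol` (1e-5).
- The MDT loop registers all members to the evolving mean, averages the
  warped images, and composes with the inverse mean displacement so the
  template stays at the group's geometric center.
- Affine registration (9/12 dof) minimizes SSD by Powell's method,
  coarse-to-fine, initialized at the intensity center-of-mass offset.  It
  exists for generality; phantom cohorts are generated pre-aligned.
- Annualization divides by each subject's actual interval by default;
  treating every pair as 12 months is config-selectable, since published
  descriptions often leave this ambiguous.

## What the synthetic validation shows — and what it does not

Passing tests show the chain recovers implanted, analytically-known
volume effects at realistic cohort sizes, controls the FDR at its nominal
level, localizes survivors to the implanted region, and reproduces
printed cohort statistics from their count tables.  They do not show that
the registration handles real MR contrast, intensity nonuniformity,
anatomical topology, or segmentation error; the phantom's geometry is far
simpler than a brain, and its noise model is white.  Regional mean
estimates remain biased toward zero by 10-20% (registration
regularization plus map smoothing at boundaries) — visible here because
ground truth is exact, and worth remembering when reading effect sizes
from any TBM study.

Problem sizes used: parameter-recovery runs in the acceptance script use
the full study conditions (48^3 grid, n = 120 for the cross-sectional,
longitudinal and mediation cohorts); the pytest suite runs the same
checks at 40^3 / n = 40-60, which leaves the tolerances unchanged but
keeps the suite quick.  Full mediation deserves a note: because the
mediator moves only 0.75 umol/L per allele against a 2.4 umol/L spread,
routing the whole dose effect through homocysteine implies a subject-level
effect SD near 19%, so the *marginal* dose association in any one cohort
draw is noisy (SE ~2.6 %/allele at n = 120) even though the attenuation
on adjustment is structural.  The test-scale sizes are analysis choices
recorded here, not properties of the simulated population.

## Known limitations

- The demons registration assumes a shared intensity scale; it is not a
  substitute for mutual-information registration on real multi-contrast
  data.
- The white-matter "hemisphere" split is a mid-plane cut of the phantom,
  not an anatomical parcellation.
- Ventricular ex-vacuo expansion is not modeled; the implanted volume
  loss vents through the brain surface instead.
- The FDR step assumes exchangeable valid tests; spatial smoothing
  induces positive dependence, under which plain BH remains conservative
  in the weak sense but realized FDP varies more run to run.
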