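# Methods

`dmndyn` implements a four-state resting/task functional-connectivity
analysis of default-mode-network (DMN) reorganization, together with a
synthetic BOLD cohort generator that reproduces the statistical
structure the analysis assumes.  The experimental design has four
5-minute steady-state runs per subject — pre-task rest (R1), a relaxed
attentional task (T1), an intense attentional task (T2), and post-task
rest (R2) — 150 volumes each at TR = 2 s.

## The analysis model

**Per-run preprocessing.** The first 10 volumes are discarded, volumes
are smoothed with an 8 mm FWHM isotropic Gaussian (reflective
boundaries), band-passed to 0.008–0.08 Hz with a zero-phase 4th-order
Butterworth filter (forward–backward; the order is configurable), and
residualized against nine nuisance regressors: white-matter mean, CSF
mean, global (brain-mean) signal, and six rigid-body motion parameters,
plus an intercept.  Global-signal regression (GSR) is on by default and
can be disabled (`--no-gsr`); without it all connectivity values shift
positive, as expected when a shared global fluctuation is left in the
data.

**Motion censoring.** Framewise displacement is the Power convention:
sum of absolute translation differences plus 50 mm times the sum of
absolute rotation differences.  Frame-to-frame global-signal change is
measured in percent of the run-mean global signal, on the
post-smoothing, pre-band-pass data (band-passing removes the baseline
the percentage refers to).  A frame is flagged only when *both* metrics
reach their thresholds (0.5 mm and 0.5%); the flagged frame, the one
before and the two after are removed, overlapping windows merge, and a
run losing more than 60 frames excludes that subject's run.  Censoring
runs after filtering and regression; downstream correlations use
surviving frames only.

**Seed arm.** The seed is an 8 mm-radius sphere at the posterior
cingulate (MNI 0, −53, 26).  Per subject and state, every in-mask voxel
is correlated with the seed mean time course and Fisher-Z transformed
(|r| = 1 clipped at 1 − 1e-7).  Group maps are two-tailed one-sample
t-tests over subjects with Benjamini–Yekutieli FDR at q = 0.05 within
the brain mask; the state's network map is the significant positive-t
set (negative-t voxels are kept separately and do not enter the union).
Only subjects with all four usable states enter this arm.

**Region detection.** Within the union of the four network maps, a
one-way repeated-measures ANOVA (states within subjects, F with df
(3, 3(n−1)), no sphericity correction by default) finds state-dependent
voxels; FDR here and in all later test families is Benjamini–Hochberg
(the BY procedure is reserved for the voxelwise group maps, the one
place the study names it; BH is the field's default reading of "FDR
corrected").  Significant voxels are cluster-filtered (> 5 voxels,
26-connectivity by default) and classified by a retrospective paired
t-test of mean(T1, T2) against mean(R1, R2): significant decreases form
decreasing regions, increases increasing regions; ANOVA-significant but
retrospectively non-significant voxels are reported as unclassified and
dropped.  Stable regions are voxels significant in all four maps and
not ANOVA-significant, split into connected components; the same
> 5-voxel filter suppresses single-voxel noise components (the size
filter is described for "the detection" as a whole and tiny stable
islands are exactly the random noise it exists to remove).  The
component containing the seed is tagged.  Regions are auto-named by
peak coordinate — anatomical naming would need an atlas, which is out
of scope.

**System level.** Region mean time courses are correlated pairwise per
state.  The five aggregates — stable↔decreasing, stable↔increasing, and
the three within-system means — are averaged on the r scale (the scale
the group means are reported on), while paired t-tests between
consecutive states (R1→T1, T1→T2, T2→R2) and the R1-vs-R2 null check
run on the Fisher-Z scale, with BH-FDR across the whole family.

**Behavior arm.** dFC(pair, task) = meanFC(task) − meanFC(R1) per
subject (baseline is R1 alone; post-task rest is not involved, so an R2
dropout does not cost a subject here).  Each dFC is correlated with
mean RT and accuracy (Pearson r, two-tailed p from
t = r√((n−2)/(1−r²))), with a percentile bootstrap CI (1000 resamples
of subjects with replacement, 2.5/97.5 percentiles; degenerate
resamples are redrawn with a cap).  BCa was not used: only a "95%
bootstrap confidence interval" is specified, and the percentile method
is the simplest member of that family.  The FDR family pools the eight
headline tests with the within-system tests.

**ICA arm.** A simplified GIFT-style chain validates the seed arm:
per-subject temporal PCA, concatenation, group PCA, natural-gradient
infomax ICA with a logistic nonlinearity (small stochastic blocks,
annealed learning rate; standard, not extended, infomax), MDL order
selection from the eigenvalue spectrum (Wax–Kailath form; channels are
frames, samples are voxels; an optional subsampling correction halves
the effective sample count), DMN component selection by template
matching (mean z inside the template minus mean z outside, sign-flipped
to positive loading), and GICA back-projection (subject mixing =
subject PCA basis × group PCA block × pinv of the total unmixing;
subject maps are the pseudo-inverse projection of the subject's data).
On synthetic data the template is the planted stable-region mask.  The
back-reconstructed subject DMN maps feed the identical union/ANOVA/
paired-t region statistics as the seed arm.

## The synthetic cohort generator

**Geometry.** A 30×36×30 grid at 3 mm (MNI-like but desk-scale), an
ellipsoidal brain mask (~19k voxels), small WM and CSF cubes carrying
private nuisance signals, and fourteen planted regions: six stable (a
5³-voxel seed-bearing PCC plus MPFC, bilateral IPL, bilateral LTC),
four decreasing (precuneus, bilateral angular gyrus, vermis) and four
increasing (bilateral insula/IFC, ACC, MCC), each a 3³ cube, placed
with ≥ 5-voxel gaps so the 8 mm smoothing kernel cannot bridge regions.

**Signals.** Each region follows one latent signal.  Per state,
innovations are drawn from a multivariate Gaussian with the target
inter-region correlation matrix, passed through an identical AR(1)
filter (φ = 0.3) per channel and standardized — identical per-channel
filtering preserves the cross-correlations exactly.  Voxels carry
baseline 1000 + 2.0·latent + white noise (SD 1.0) + a global AR(1)
fluctuation (SD 2.0, shared by all brain voxels — the component GSR
exists to remove) + a slow sinusoidal drift (0.003 Hz, below the band).
Motion spikes are Poisson-placed (0.5 expected per run, ≥ 5 frames
apart) sustained steps that push both censoring metrics over threshold
simultaneously: ±1% global-signal step plus a 0.35 mm translation and
0.005 rad rotation step (FD 0.6 mm).

**Calibration targets.** The group correlation blocks are set to the
reported four-state trajectories: stable↔decreasing
(0.43, 0.35, 0.24, 0.45) and stable↔increasing (0.05, 0.30, 0.34, 0.03)
over (R1, T1, T2, R2).  Within-system and decreasing↔increasing blocks
are not reported numerically and were chosen once as field-realistic
values consistent with the qualitative description (stable cohesion
high and flat at 0.55; decreasing cohesion 0.50→0.30 under task;
increasing cohesion 0.10→0.36; cross-blocks near zero at rest).  All
four state matrices are verified positive definite (min eigenvalue
0.45).

Three deliberate "observation-scale" calibrations make the *measured*
statistics — not hidden latents — hit the reported values:

1. *tanh mean-matching.*  Between-subject deviates act on the Fisher-Z
   scale; the group Z-offsets are solved (Gauss–Hermite/Newton) so that
   the population mean on the r scale equals the target despite the
   tanh nonlinearity.
2. *Measurement compensation.*  The reported group means are
   post-pipeline observations: global-signal regression subtracts the
   network's own share of the brain mean from every voxel, deflating
   mutual correlations, and the bias is amplified for the regions the
   group statistics actually recover — each planted region plus its
   one-voxel smoothing halo, where the signal is diluted while the
   additive global residue is not.  The generator therefore plants the
   fixed point of a simulation-based calibration: block means are
   measured on the dilated planted masks through the default
   preprocessing and the planted correlations iterated (fixed seed,
   48 runs × 4 states × 3 rounds) until the measurement reproduces the
   targets.  The resulting table ships with the package
   (`data/default_calibration.json`, regenerated by
   `scripts/calibrate_scenario.py`), keyed by a scenario fingerprint;
   scenarios that do not match fall back to a first-order analytic GSR
   model (`predict_post_gsr`), which captures about two thirds of the
   effect.  The calibration never sees the region detector, so
   detection, classification and assembly remain genuinely tested.
   The region-level fast path (no images, no GSR) plants the raw
   targets.
3. *Coupling deattenuation.*  A 0.008–0.08 Hz band-passed 140-frame run
   has only ≈ 38 effective temporal samples (Bartlett dof of the
   filtered AR process), so any measured system-mean Fisher-Z carries
   sampling noise of ≈ 0.10 SD per state — present in the original
   measurements exactly as in ours.  The reported brain-behavior
   correlations are therefore correlations with *noisy* dFC estimates.
   The generator measures the latent→observed attenuation α once per
   scenario by a deterministic pilot simulation of its own latent
   process (the asymptotic Olkin–Siotani value is also implemented and
   agrees within ~15%, but underestimates the error at these sample
   sizes) and couples behavior to the latent dFC with slope
   ρ_obs·(1 + (1−ρ_obs²)/(2(n−1)))/α — the second factor undoes the
   small-sample bias of an n = 19 sample correlation.  Slopes are
   capped at 0.99; the reported effect sizes sit close to the
   information-theoretic ceiling these run lengths permit, which is
   itself an interesting consistency check on the study.

**Subject heterogeneity.** Each subject gets one Gaussian deviate per
(state, unordered system-block) on the Fisher-Z scale, with total SD
`subject_sd = 0.15`, decomposed into a trait-like offset shared by all
four states (SD ≈ 0.12) plus an independent state-specific part
(`state_sd = 0.09`).  Block-level (rather than per-pair) deviates are
what give *system means* a between-subject SD of exactly `subject_sd`:
the printed SEMs (0.028–0.047 at n = 16, i.e. SD 0.11–0.19) constrain
the block level, and per-pair deviates would average away over the ~24
pairs of a system mean.  The shared/state split is the generator's one
free variance knob: the state part must be large enough that the
behavior couplings are reachable (σ_latent-dFC = √2·state_sd ≥ the
value implied by r ≈ 0.6 against noisy estimates) yet small enough to
keep the repeated-measures error realistic.  The printed transition
p-values (e.g. R1→T1 at p = 0.02) and the printed behavior correlations
jointly over-determine this split and are not exactly compatible with
the ≈ 0.10 estimation noise floor; 0.09 favors the behavior couplings,
at the cost of R1→T1 transition significance being less reliable than
reported.  Perturbed matrices are clipped to (−1, 1) and PSD-repaired
by eigenvalue clipping when a deviate leaves the cone (~25% of draws,
with negligible (<0.01) mean shrinkage, verified by simulation).

**Behavior records.** RT and accuracy per task state are Gaussian with
the reported means and SDs (SEM·√19): T1 1864 ± 666 ms, T2 1310 ± 286
ms; accuracy 97.8 ± 2.0% and 94.5 ± 4.3%.  RT couples to the
standardized latent dFC(stable, decreasing), accuracy to
dFC(stable, increasing), of the same task state.  Accuracy is clipped
to [0, 100]; since ~10% of the Gaussian mass sits above 100, the
pre-clipping coupling is inflated analytically (censored-normal
moments) so the delivered, clipped values still carry the target
population correlation.

**What the generator does not emulate.**  No hemodynamic convolution of
trial events (the runs are steady-state by design), no scanner
artifacts beyond drift/AR noise/motion steps, no spatial
misregistration (data are born aligned; spatial normalization is out of
scope), no non-DMN background networks (background voxels are noise
only), and no anatomy — region names are conveniences.  Passing tests
therefore demonstrate that the *statistical* machinery recovers planted
structure through realistic temporal preprocessing; they do not
validate spatial preprocessing or physiological noise handling on real
scans.

## Problem sizes and numerical choices

Replicated validation uses 25 seeded 16-subject cohorts for the
full-pipeline recovery of the system means (the original design: 19
recruited, 3 lost to post-task-rest motion), 10 no-dynamics cohorts for
null specificity, and 200 region-level 19-subject cohorts for the
behavior statistics (the "cached connectome" mode: region time courses
are generated directly, band-passed and dropped exactly like the image
path, skipping the voxelwise detection stage that the calibration
experiment already exercises).

Numerical details: correlations are computed on centered float64
series; |r| = 1 is clipped at 1 − 1e-7 before atanh; zero-variance
voxels in group t-tests get p = 0 (mean ≠ 0) or 1 (mean = 0) with a
warning; rank-deficient nuisance designs drop dependent directions with
a warning; the band-pass is an exact reimplementation of
forward–backward SOS filtering (odd padding, steady-state initial
conditions) with a compiled kernel, verified against the scipy
reference to ~1e-10 and falling back to scipy when numba is absent;
cluster connectivity is 26 by default with 6/18 selectable; scrubbing
windows are clipped at run boundaries and merged when overlapping.

## Known limitations

* Detection of the decreasing system is power-limited by design
  realism: with ~38 effective samples per run, per-voxel ANOVA
  F-statistics for the (0.43, 0.35, 0.24, 0.45) contrast sit near the
  FDR threshold, and whole regions succeed or fail together because all
  voxels of a region share one latent and one seed realization.  Exact
  recovery of all eight planted changing regions is therefore not
  near-certain per cohort — the same physics would apply to any 5-minute
  acquisition at these effect sizes.
* The within-system behavior panel and the R1→T1 transition test
  inherit the same noise floor; their single-cohort significance is
  unreliable even though the planted effects are real.
* The GSR compensation is first-order: a residual bias of about −0.01
  to −0.02 on high-correlation blocks remains after compensation
  (second-order terms, nuisance-regression interactions).
* One pilot simulation (~8 s) runs per scenario to calibrate the
  behavior coupling; its α estimates carry Monte-Carlo error of ~±0.015.
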