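# dmndyn

Dynamic reorganization of the default-mode network (DMN) across a
four-state rest/task experiment: a tested, reusable re-implementation
of the full analysis pipeline — seed-based connectivity mapping,
data-driven classification of voxels into *stable*, *decreasing* and
*increasing* systems, system-level connectivity dynamics, a group-ICA
validation arm, and bootstrap brain–behavior correlation — together
with a synthetic BOLD cohort generator that emulates the study's
statistical structure, so every stage is testable without any scan
data.

It is written for researchers who want to reproduce, probe, or extend
this class of analysis: resting-state seed correlation with Fisher-Z
and FDR, motion scrubbing with framewise displacement, voxelwise
repeated-measures ANOVA, infomax group ICA with MDL order selection,
and percentile-bootstrap brain–behavior statistics.

## The analysis in one paragraph

Each subject completes four 5-minute runs — rest (R1), relaxed task
(T1), intense task (T2), rest (R2).  After temporal preprocessing
(first-10-volume drop, 8 mm smoothing, 0.008–0.08 Hz band-pass,
WM/CSF/global/motion regression, AND-rule frame censoring), every
brain voxel is correlated with an 8 mm posterior-cingulate seed sphere
(MNI 0, −53, 26), giving per-state Fisher-Z maps z = atanh(r).  Group
maps (one-sample t, Benjamini–Yekutieli FDR q < 0.05) are combined
into a four-state union mask, where a one-way repeated-measures ANOVA
(F = MS_state/MS_error, df (3, 3(n−1))) finds state-dependent voxels;
clusters > 5 voxels are classified by a retrospective paired t-test of
mean(T1, T2) vs mean(R1, R2) into decreasing (within-DMN
desynchronization) and increasing (salience-network integration)
regions, while voxels significant in all four maps with no ANOVA
change form the stable DMN core.  System-level mean FC is tracked
across states, and per-subject dFC = meanFC(task) − meanFC(R1) is
correlated with reaction time and accuracy
(t = r·√((n−2)/(1−r²)), 95% percentile-bootstrap CIs, FDR across the
panel).

## Worked example

```python
import dmndyn as dd

sc = dd.default_scenario(n_subjects=16, seed=3)   # packaged study design
cohort = dd.simulate_cohort(sc)                   # 16 subjects x 4 states
res = dd.analyze_cohort(cohort)                   # full seed-arm pipeline

for kind in ("stable", "decreasing", "increasing"):
    print(kind, sorted(r.size for r in res.regions.of_kind(kind)))
gm = res.group_means
sd = gm[(gm.system_a == "stable") & (gm.system_b == "decreasing")]
print(sd[["state", "mean", "sem"]].round(3).to_string(index=False))
```

prints (seed 3):

```
stable [84, 108, 130, 141, 144, 150, 381]
decreasing [58, 113, 120]
increasing [111, 118, 123, 125]
state  mean   sem
   R1 0.504 0.024
   R2 0.454 0.037
   T1 0.354 0.026
   T2 0.311 0.025
```

— seven stable components (the large one carries the seed), all four
increasing regions, and three of the four planted decreasing regions
(detection of the weaker decreasing contrast is power-limited at
5-minute run lengths; see `docs/methods.md`).  The stable↔decreasing
mean FC drops from ≈ 0.50 at rest toward ≈ 0.31–0.35 under task and
returns after it; single-cohort values scatter around the population
trajectory (0.43, 0.35, 0.24, 0.45) with cohort-level SD ≈ 0.04.  The
behavior stage then correlates each subject's connectivity change with
RT/accuracy:

```python
panel = dd.behavior_stage(res, cohort, n_boot=1000, rng=0)
sel = panel[(panel.system_a == "stable") & (panel.system_b == "decreasing")
            & (panel.behavior == "rt")]
print(sel[["task_state", "r", "p", "ci_low", "ci_high"]]
      .round(4).to_string(index=False))
```

```
task_state      r      p  ci_low  ci_high
        T1 0.5879 0.0166  0.1922   0.8172
        T2 0.6214 0.0102  0.1264   0.8343
```

— a positive dFC(stable, decreasing)–RT correlation in both task
states with bootstrap intervals excluding zero: subjects whose
within-network desynchronization is weaker (less negative dFC) respond
more slowly.

A command-line interface mirrors the stages
(`dmndyn synth | preprocess | seedfc | regions | systems | behavior |
ica`); `dmndyn synth --out DIR --seed 1` writes a NIfTI fixture cohort
any other tool can read.

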