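"""End-to-end orchestration of the four-state analysis.

``analyze_cohort`` runs the full seed arm on an in-memory cohort:
per-run temporal preprocessing and censoring, seed connectivity maps,
FDR group maps per state, union-mask region detection/classification,
subject connectomes over the detected regions and system-level
summaries.  The behavior stage and the ICA arm consume its outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import STATES, Cohort, ScrubReport
from . import preprocess as pp
from .seedfc import (
    ConnectivityMap,
    GroupStateMap,
    SeedSpec,
    connectivity_map,
    group_significance,
    seed_mask,
)
from .regions import RegionSet, UnionMask, detect_regions
from .systems import (
    SubjectConnectome,
    SystemSummary,
    connectome_from_series,
    group_system_means,
    pairwise_fc,
    state_transition_tests,
    system_means,
)
from .behavior import behavior_panel
from .simulate import RegionCohort


@dataclass
class PipelineConfig:
    """Tunable knobs of the seed-arm pipeline (defaults = study values)."""

    n_drop: int = 10
    fwhm_mm: float = 8.0
    low_hz: float = 0.008
    high_hz: float = 0.08
    global_signal: bool = True
    gs_thresh: float = 0.5
    disp_thresh: float = 0.5
    exclusion_n: int = 60
    q: float = 0.05
    #: FDR for the per-state group maps (the study cites BY there)
    fdr_method: str = "by"
    #: FDR for ANOVA / classification / transition / behavior families
    fdr_method_tests: str = "bh"
    connectivity: int = 26
    cluster_min: int = 5
    seed: SeedSpec = field(default_factory=SeedSpec)


@dataclass
class PipelineResult:
    group_maps: dict[str, GroupStateMap]
    union: UnionMask
    anova_sig: np.ndarray
    regions: RegionSet
    connectomes: list[SubjectConnectome]
    summaries: list[SystemSummary]
    group_means: pd.DataFrame
    transition_tests: pd.DataFrame
    scrub_reports: dict[tuple[str, str], ScrubReport]
    included_subjects: list[str]
    all_summaries: list[SystemSummary]  # R1/T1/T2 summaries for all subjects


def preprocess_series(run, motion, cfg: PipelineConfig
                      ) -> tuple[np.ndarray, ScrubReport]:
    """Array-level per-run preprocessing (same kernels as preprocess_run).

    Returns the cleaned in-(brain-)mask series (voxels x surviving
    frames) plus the scrub report; numerically identical to running the
    BoldRun-level chain and extracting the mask afterwards, but without
    rebuilding full volumes between steps.
    """
    from scipy import ndimage

    brain = run.brain_mask
    data = run.data[..., cfg.n_drop:]
    if run.n_frames <= cfg.n_drop:
        raise ValueError("run shorter than the initial drop")
    mot = motion.trimmed(cfg.n_drop)
    if cfg.fwhm_mm > 0:
        out = data.astype(np.float32, copy=True)
        for axis, v in enumerate(run.voxel_size):
            ndimage.gaussian_filter1d(
                out, pp.fwhm_to_sigma(cfg.fwhm_mm, v), axis=axis,
                mode="reflect", output=out,
            )
        data = out
    series = data[brain].astype(np.float64)
    gs = series.mean(axis=0)
    fd = pp.framewise_displacement(mot.params)
    gs_pct = np.concatenate([[0.0], np.abs(np.diff(gs)) / gs.mean() * 100.0])
    series = pp.bandpass_series(series, run.tr, cfg.low_hz, cfg.high_hz)
    wm_flat = run.wm_mask[brain] if run.wm_mask is not None else None
    csf_flat = run.csf_mask[brain] if run.csf_mask is not None else None
    cols = [np.ones(series.shape[1])]
    if wm_flat is not None and wm_flat.any():
        cols.append(series[wm_flat].mean(axis=0))
    if csf_flat is not None and csf_flat.any():
        cols.append(series[csf_flat].mean(axis=0))
    if cfg.global_signal:
        cols.append(series.mean(axis=0))
    cols.extend(mot.params[:, i] for i in range(6))
    series = pp.regress_series(series, np.column_stack(cols))
    flagged = np.where((fd >= cfg.disp_thresh) & (gs_pct >= cfg.gs_thresh))[0]
    removed = pp.scrub_windows(flagged, series.shape[1])
    keep = np.setdiff1d(np.arange(series.shape[1]), removed)
    report = ScrubReport(
        flagged=flagged, removed=removed, n_removed=len(removed),
        excluded=len(removed) > cfg.exclusion_n,
    )
    return series[:, keep].astype(np.float32), report


def _seed_correlation_z(series: np.ndarray, seed_flat: np.ndarray) -> np.ndarray:
    """Fisher-Z seed map from an in-mask series (seed = flat voxel mask)."""
    from .seedfc import fisher_z

    s = series[seed_flat].mean(axis=0, dtype=np.float64)
    x = series.astype(np.float64) - series.mean(axis=1, keepdims=True)
    s = s - s.mean()
    xn = np.sqrt((x**2).sum(axis=1))
    xn[xn == 0] = 1.0
    r = (x @ s) / (xn * np.sqrt((s**2).sum()))
    return fisher_z(np.clip(r, -1.0, 1.0))


def analyze_cohort(cohort: Cohort, config: PipelineConfig | None = None
                   ) -> PipelineResult:
    cfg = config or PipelineConfig()
    brain = cohort.subjects[0].runs["R1"].brain_mask
    smask_flat = seed_mask(
        cfg.seed, cohort.subjects[0].runs["R1"].affine, brain.shape, brain
    )[brain]
    processed: dict[tuple[str, str], np.ndarray] = {}
    reports: dict[tuple[str, str], ScrubReport] = {}
    z_maps_all: dict[str, dict[str, ConnectivityMap]] = {s: {} for s in STATES}
    for sub in cohort.subjects:
        for state in STATES:
            series, report = preprocess_series(
                sub.runs[state], sub.motion[state], cfg
            )
            reports[(sub.subject, state)] = report
            if report.excluded:
                continue
            processed[(sub.subject, state)] = series
            z_maps_all[state][sub.subject] = ConnectivityMap(
                subject=sub.subject, state=state,
                z=_seed_correlation_z(series, smask_flat), mask=brain,
            )

    # seed-arm group analysis uses subjects with all four usable states
    included = [
        s.subject for s in cohort.subjects
        if all(s.subject in z_maps_all[state] for state in STATES)
    ]
    if len(included) < 2:
        raise ValueError("fewer than 2 subjects with all four states")
    z_maps = {s: [z_maps_all[s][subj] for subj in included] for s in STATES}
    group_maps = {s: group_significance(z_maps[s], q=cfg.q,
                                        fdr_method=cfg.fdr_method)
                  for s in STATES}
    smask = seed_mask(cfg.seed, cohort.subjects[0].runs["R1"].affine,
                      brain.shape, brain)
    regset, union, anova_sig = detect_regions(
        z_maps, group_maps, smask, q=cfg.q, fdr_method=cfg.fdr_method_tests,
        connectivity=cfg.connectivity, min_size_exclusive=cfg.cluster_min,
    )

    # subject connectomes over the detected regions
    region_flat = [r.mask[brain] for r in regset.regions]
    names = [r.name for r in regset.regions]
    kinds = [r.kind for r in regset.regions]
    if not regset.regions:
        empty = pd.DataFrame()
        return PipelineResult(
            group_maps=group_maps, union=union, anova_sig=anova_sig,
            regions=regset, connectomes=[], summaries=[], group_means=empty,
            transition_tests=empty, scrub_reports=reports,
            included_subjects=included, all_summaries=[],
        )
    connectomes, summaries = [], []
    for subj in included:
        series_per_state = {
            state: np.stack(
                [processed[(subj, state)][flat].mean(axis=0, dtype=np.float64)
                 for flat in region_flat]
            )
            for state in STATES
        }
        conn = connectome_from_series(series_per_state, names, kinds, subj)
        connectomes.append(conn)
        summaries.append(system_means(conn))
    group_means = group_system_means(summaries)
    transitions = state_transition_tests(
        summaries, connectomes, q=cfg.q, fdr_method=cfg.fdr_method_tests
    )

    # behavior-arm summaries: any subject with usable R1 + both tasks
    all_summaries = []
    for sub in cohort.subjects:
        subj = sub.subject
        if subj in included:
            all_summaries.append(summaries[included.index(subj)])
            continue
        if all((subj, st) in processed for st in ("R1", "T1", "T2")):
            series_per_state = {
                st: np.stack(
                    [processed[(subj, st)][flat].mean(axis=0, dtype=np.float64)
                     for flat in region_flat]
                )
                for st in ("R1", "T1", "T2")
            }
            conn = connectome_from_series(series_per_state, names, kinds, subj)
            all_summaries.append(system_means(conn))

    return PipelineResult(
        group_maps=group_maps,
        union=union,
        anova_sig=anova_sig,
        regions=regset,
        connectomes=connectomes,
        summaries=summaries,
        group_means=group_means,
        transition_tests=transitions,
        scrub_reports=reports,
        included_subjects=included,
        all_summaries=all_summaries,
    )


def behavior_stage(result: PipelineResult, cohort: Cohort, n_boot: int = 1000,
                   rng=None, q: float = 0.05, fdr_method: str = "bh"
                   ) -> pd.DataFrame:
    """Brain-behavior panel on the pipeline's system summaries."""
    return behavior_panel(
        result.all_summaries, cohort.behavior, n_boot=n_boot, rng=rng,
        q=q, fdr_method=fdr_method,
    )


# ---------------------------------------------------------------------------
# region-level fast path (no images)
# ---------------------------------------------------------------------------

def region_cohort_summaries(
    rc: RegionCohort, n_drop: int = 10, low_hz: float = 0.008,
    high_hz: float = 0.08,
) -> list[SystemSummary]:
    """System summaries from a region-time-course cohort.

    Applies the temporal core of the pipeline (initial-frame drop,
    band-pass) to each planted region's series and estimates the
    connectome directly — the system-level stage with known regions.
    """
    sc = rc.scenario
    names = [r.name for r in sc.region_layout]
    kinds = [r.system for r in sc.region_layout]
    out = []
    for i, per_state in enumerate(rc.series):
        series_per_state = {}
        for state, x in per_state.items():
            x = x[:, n_drop:]
            series_per_state[state] = pp.bandpass_series(
                x, sc.tr, low_hz, high_hz
            )
        conn = connectome_from_series(
            series_per_state, names, kinds, f"sub-{i:02d}"
        )
        out.append(system_means(conn))
    return out
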