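"""Region- and system-level connectivity across the four states.

Per subject and state, region mean time courses are correlated pairwise
(Pearson r, with Fisher-Z alongside).  System summaries average r over
the stable-decreasing and stable-increasing pair blocks and within each
system; group comparisons (consecutive-state paired t-tests plus the
R1-vs-R2 null check) run on the Fisher-Z scale with FDR across the
family, while summary magnitudes are reported on the r scale — the
scale the published group means are printed on.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import STATES, BoldRun
from .regions import RegionSet
from .seedfc import fisher_z, fdr_correct

#: the five system-level aggregates of the analysis
SUMMARY_MEASURES = (
    ("stable", "decreasing"),
    ("stable", "increasing"),
    ("stable", "stable"),
    ("decreasing", "decreasing"),
    ("increasing", "increasing"),
)

TRANSITIONS = (("R1", "T1"), ("T1", "T2"), ("T2", "R2"), ("R1", "R2"))


@dataclass
class SubjectConnectome:
    """Per-state region-by-region correlation matrices for one subject."""

    subject: str
    region_names: list[str]
    region_kinds: list[str]
    r: dict[str, np.ndarray]
    z: dict[str, np.ndarray]


@dataclass
class SystemSummary:
    """Per-state mean FC for the five system aggregates (r scale)."""

    subject: str
    values: dict[tuple[str, str], dict[str, float]]  # (sysA, sysB) -> state -> r


def region_timecourse(run: BoldRun, region_mask: np.ndarray) -> np.ndarray:
    """Unweighted mean series over the region's voxels."""
    if not region_mask.any():
        raise ValueError("empty region")
    if (region_mask & ~run.brain_mask).any():
        raise ValueError("region extends outside the brain mask")
    return run.data[region_mask].mean(axis=0, dtype=np.float64)


def correlation_matrix(series: np.ndarray) -> np.ndarray:
    """Pearson correlations between rows, guarded for constant rows."""
    if series.shape[1] < 3:
        raise ValueError("need at least 3 surviving frames")
    x = series - series.mean(axis=1, keepdims=True)
    norm = np.sqrt((x**2).sum(axis=1))
    norm[norm == 0] = 1.0
    r = (x @ x.T) / np.outer(norm, norm)
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def pairwise_fc(
    runs: dict[str, BoldRun], regions: RegionSet, subject: str | None = None
) -> SubjectConnectome:
    """Region-pair Pearson r (and Fisher-Z) per state for one subject."""
    if not regions.regions:
        raise ValueError("empty region set")
    names = [r.name for r in regions.regions]
    kinds = [r.kind for r in regions.regions]
    r_mats, z_mats = {}, {}
    for state, run in runs.items():
        series = np.stack(
            [region_timecourse(run, reg.mask) for reg in regions.regions]
        )
        r = correlation_matrix(series)
        r_mats[state] = r
        z_mats[state] = fisher_z(r)
    return SubjectConnectome(
        subject=subject or next(iter(runs.values())).subject,
        region_names=names,
        region_kinds=kinds,
        r=r_mats,
        z=z_mats,
    )


def connectome_from_series(
    series_per_state: dict[str, np.ndarray],
    region_names: list[str],
    region_kinds: list[str],
    subject: str,
) -> SubjectConnectome:
    """Connectome directly from region time courses (fast generation mode)."""
    r_mats = {s: correlation_matrix(x) for s, x in series_per_state.items()}
    return SubjectConnectome(
        subject=subject,
        region_names=region_names,
        region_kinds=region_kinds,
        r=r_mats,
        z={s: fisher_z(r) for s, r in r_mats.items()},
    )


def _block_pairs(kinds: list[str], sys_a: str, sys_b: str) -> list[tuple[int, int]]:
    if sys_a == sys_b:
        idx = [i for i, k in enumerate(kinds) if k == sys_a]
        return list(combinations(idx, 2))
    ia = [i for i, k in enumerate(kinds) if k == sys_a]
    ib = [i for i, k in enumerate(kinds) if k == sys_b]
    return [(i, j) for i in ia for j in ib]


def system_means(connectome: SubjectConnectome) -> SystemSummary:
    """Average pairwise r within the five system aggregates.

    Between-system means average all (A-region, B-region) pairs; within-
    system means average unordered distinct pairs.  A system with fewer
    than 2 regions has no within-system mean (absent from the summary).
    """
    values: dict[tuple[str, str], dict[str, float]] = {}
    for sys_a, sys_b in SUMMARY_MEASURES:
        pairs = _block_pairs(connectome.region_kinds, sys_a, sys_b)
        if not pairs:
            continue
        values[(sys_a, sys_b)] = {
            state: float(np.mean([connectome.r[state][i, j] for i, j in pairs]))
            for state in connectome.r
        }
    return SystemSummary(subject=connectome.subject, values=values)


def summary_table(summaries: list[SystemSummary]) -> pd.DataFrame:
    """Long-format per-subject summary table."""
    rows = []
    for s in summaries:
        for (a, b), per_state in s.values.items():
            for state, val in per_state.items():
                rows.append(
                    {"subject": s.subject, "system_a": a, "system_b": b,
                     "state": state, "mean_fc": val}
                )
    return pd.DataFrame(rows)


def group_system_means(summaries: list[SystemSummary]) -> pd.DataFrame:
    """Group mean and SEM of each aggregate per state (r scale)."""
    df = summary_table(summaries)
    if df.empty:
        return pd.DataFrame(
            columns=["system_a", "system_b", "state", "mean", "sem", "count"]
        )
    g = df.groupby(["system_a", "system_b", "state"])["mean_fc"]
    return g.agg(["mean", "sem", "count"]).reset_index()


def state_transition_tests(
    summaries: list[SystemSummary],
    connectomes: list[SubjectConnectome] | None = None,
    q: float = 0.05,
    fdr_method: str = "bh",
) -> pd.DataFrame:
    """Paired t-tests between consecutive states (plus the R1-R2 check).

    Tests run on Fisher-Z values for each of the five system summaries
    and, when connectomes are supplied, for every stable-to-changing
    region pair; FDR is applied across the whole family.
    """
    if len(summaries) < 2:
        raise ValueError("need >= 2 subjects")
    rows = []
    # system-level measures, z scale
    for a, b in SUMMARY_MEASURES:
        if any((a, b) not in s.values for s in summaries):
            continue
        vals = {
            st: np.arctanh(np.clip(
                [s.values[(a, b)][st] for s in summaries], -1 + 1e-7, 1 - 1e-7
            ))
            for st in STATES
        }
        for s1, s2 in TRANSITIONS:
            t, p = _paired_t(vals[s1], vals[s2])
            rows.append(
                {"measure": f"meanFC({a},{b})", "level": "system",
                 "state_a": s1, "state_b": s2, "t": t, "p": p,
                 "mean_diff": float(np.mean(vals[s2] - vals[s1]))}
            )
    # region-pair level
    if connectomes:
        kinds = connectomes[0].region_kinds
        names = connectomes[0].region_names
        for sys_b in ("decreasing", "increasing"):
            for i, j in _block_pairs(kinds, "stable", sys_b):
                for s1, s2 in TRANSITIONS:
                    x = np.array([c.z[s1][i, j] for c in connectomes])
                    y = np.array([c.z[s2][i, j] for c in connectomes])
                    t, p = _paired_t(x, y)
                    rows.append(
                        {"measure": f"pair({names[i]},{names[j]})",
                         "level": "pair", "state_a": s1, "state_b": s2,
                         "t": t, "p": p, "mean_diff": float(np.mean(y - x))}
                    )
    if not rows:
        return pd.DataFrame(
            columns=["measure", "level", "state_a", "state_b", "t", "p",
                     "mean_diff", "significant"]
        )
    table = pd.DataFrame(rows)
    table["significant"] = fdr_correct(table["p"].to_numpy(), q=q,
                                       method=fdr_method)
    return table


def _paired_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    d = np.asarray(y, dtype=float) - np.asarray(x, dtype=float)
    sd = d.std(ddof=1)
    if sd == 0:
        return (0.0, 1.0) if d.mean() == 0 else (np.inf, 0.0)
    res = stats.ttest_rel(y, x)
    return float(res.statistic), float(res.pvalue)
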