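"""Brain-behavior correlation of task-dependent connectivity change.

Per subject, dFC(system pair, task state) is the system-level mean FC of
the task state minus that of the pre-task rest R1 (all subjects with R1
and the task state qualify, so an R2 dropout does not remove a subject
here).  Each dFC is correlated with mean RT and accuracy; confidence
intervals come from a percentile bootstrap over subjects, and
significance is FDR-controlled across the whole panel family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import TASK_STATES
from .seedfc import fdr_correct
from .systems import SystemSummary


@dataclass
class DfcResult:
    system_pair: tuple[str, str]
    task_state: str
    behavior_name: str
    n: int
    r: float
    r2: float
    p: float
    ci_low: float
    ci_high: float
    significant: bool = False


def compute_dfc(
    summaries: list[SystemSummary],
    task_state: str,
    system_pair: tuple[str, str] = ("stable", "decreasing"),
) -> np.ndarray:
    """Per-subject dFC = meanFC(task state) - meanFC(R1)."""
    if task_state not in TASK_STATES and task_state != "R1":
        raise ValueError(f"not a task state: {task_state}")
    out = []
    for s in summaries:
        if system_pair not in s.values:
            raise ValueError(f"summary lacks pair {system_pair}")
        per_state = s.values[system_pair]
        for st in ("R1", task_state):
            if st not in per_state:
                raise ValueError(f"subject {s.subject} missing state {st}")
        out.append(per_state[task_state] - per_state["R1"])
    return np.asarray(out)


def correlate_behavior(dfc: np.ndarray, behavior: np.ndarray
                       ) -> tuple[float, float, float]:
    """Pearson r, R^2, and the two-tailed p from t = r sqrt((n-2)/(1-r^2))."""
    x = np.asarray(dfc, dtype=float)
    y = np.asarray(behavior, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return r, r**2, 0.0
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, r**2, float(p)


def bootstrap_ci(
    x: np.ndarray,
    y: np.ndarray,
    n_boot: int = 1000,
    level: float = 0.95,
    rng=None,
    max_redraws: int = 100,
) -> tuple[float, float]:
    """Percentile bootstrap CI of Pearson r over subject resampling.

    Degenerate resamples (constant x or y) are redrawn up to a cap.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3")
    rng = np.random.default_rng(rng)
    # vectorized resampling; redraw degenerate rows
    idx = rng.integers(0, n, size=(n_boot, n))
    for _ in range(max_redraws):
        xs, ys = x[idx], y[idx]
        bad = (xs.std(axis=1) == 0) | (ys.std(axis=1) == 0)
        if not bad.any():
            break
        idx[bad] = rng.integers(0, n, size=(int(bad.sum()), n))
    else:
        raise RuntimeError("degenerate bootstrap resamples exceeded redraw cap")
    xs = xs - xs.mean(axis=1, keepdims=True)
    ys = ys - ys.mean(axis=1, keepdims=True)
    num = (xs * ys).sum(axis=1)
    den = np.sqrt((xs**2).sum(axis=1) * (ys**2).sum(axis=1))
    r = num / den
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(r, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def behavior_panel(
    summaries: list[SystemSummary],
    behavior_table: pd.DataFrame,
    n_boot: int = 1000,
    q: float = 0.05,
    fdr_method: str = "bh",
    rng=None,
    include_within_system: bool = True,
) -> pd.DataFrame:
    """The full dFC x behavior correlation grid with bootstrap CIs.

    Headline grid: {stable-decreasing, stable-increasing} x {RT,
    accuracy} x {T1, T2} (8 tests); optionally the within-system dFC
    tests join the same FDR family.
    """
    if len(summaries) < 2:
        raise ValueError("need >= 2 subjects")
    rng = np.random.default_rng(rng)
    subjects = [s.subject for s in summaries]
    beh = behavior_table.set_index(["subject", "state"])
    pairs = [("stable", "decreasing"), ("stable", "increasing")]
    if include_within_system:
        pairs += [("stable", "stable"), ("decreasing", "decreasing"),
                  ("increasing", "increasing")]
    rows = []
    for pair in pairs:
        if any(pair not in s.values for s in summaries):
            continue
        for task in TASK_STATES:
            dfc = compute_dfc(summaries, task, pair)
            for bname, col in (("rt", "rt_ms"), ("accuracy", "accuracy_pct")):
                try:
                    y = np.array(
                        [beh.loc[(s, task), col] for s in subjects], dtype=float
                    )
                except KeyError as e:
                    raise ValueError(f"behavior table misaligned: {e}") from e
                r, r2, p = correlate_behavior(dfc, y)
                lo, hi = bootstrap_ci(dfc, y, n_boot=n_boot, rng=rng)
                rows.append(
                    {"system_a": pair[0], "system_b": pair[1],
                     "task_state": task, "behavior": bname, "n": len(dfc),
                     "r": r, "r2": r2, "p": p, "ci_low": lo, "ci_high": hi}
                )
    if not rows:
        return pd.DataFrame(
            columns=["system_a", "system_b", "task_state", "behavior", "n",
                     "r", "r2", "p", "ci_low", "ci_high", "significant"]
        )
    table = pd.DataFrame(rows)
    table["significant"] = fdr_correct(table["p"].to_numpy(), q=q,
                                       method=fdr_method)
    return table
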