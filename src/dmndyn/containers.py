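"""Shared domain containers for the four-state DMN pipeline.

The experiment has four steady-state runs per subject: a pre-task rest
(R1), a relaxed task (T1), an intense task (T2) and a post-task rest
(R2).  Every downstream stage consumes :class:`BoldRun` objects (one
subject x state 4D time series on a common grid) plus their
:class:`MotionTrace`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: canonical state order used everywhere
STATES: tuple[str, ...] = ("R1", "T1", "T2", "R2")

#: states in which behavior (RT / accuracy) is recorded
TASK_STATES: tuple[str, ...] = ("T1", "T2")


@dataclass
class BoldRun:
    """One subject x state 4D BOLD run.

    ``data`` is an (x, y, z, t) array; masks are boolean volumes on the
    same grid.  ``history`` is the append-only list of preprocessing
    steps already applied, used to enforce the pipeline-order contract.
    """

    subject: str
    state: str
    data: np.ndarray
    tr: float
    affine: np.ndarray
    brain_mask: np.ndarray
    wm_mask: np.ndarray | None = None
    csf_mask: np.ndarray | None = None
    history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state label {self.state!r}")
        if self.data.ndim != 4 or self.data.shape[3] < 1:
            raise ValueError("BOLD data must be 4D with at least one frame")
        if self.brain_mask.shape != self.data.shape[:3]:
            raise ValueError("brain mask incongruent with grid")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_size(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def with_data(self, data: np.ndarray, step: str) -> "BoldRun":
        """Copy of this run with new voxel data and ``step`` appended."""
        if step in self.history:
            raise ValueError(f"step {step!r} already applied to this run")
        return BoldRun(
            subject=self.subject,
            state=self.state,
            data=data,
            tr=self.tr,
            affine=self.affine,
            brain_mask=self.brain_mask,
            wm_mask=self.wm_mask,
            csf_mask=self.csf_mask,
            history=self.history + [step],
        )


@dataclass
class MotionTrace:
    """Per-frame rigid-body parameters and derived censoring metrics.

    ``params`` has six columns: three translations (mm) and three
    rotations (radians).  ``fd`` (framewise displacement, mm) and
    ``gs_pct`` (frame-to-frame global-signal change, percent of run
    mean) are filled by ``preprocess.compute_frame_metrics``.
    """

    params: np.ndarray
    fd: np.ndarray | None = None
    gs_pct: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("motion parameters must have 6 columns")

    @property
    def n_frames(self) -> int:
        return self.params.shape[0]

    def trimmed(self, n: int) -> "MotionTrace":
        """Drop the first ``n`` frames (lockstep with drop_initial)."""
        return MotionTrace(
            params=self.params[n:],
            fd=None if self.fd is None else self.fd[n:],
            gs_pct=None if self.gs_pct is None else self.gs_pct[n:],
        )


@dataclass
class ScrubReport:
    """Outcome of the frame-censoring step for one run."""

    flagged: np.ndarray
    removed: np.ndarray
    n_removed: int
    excluded: bool

    def __post_init__(self) -> None:
        if not set(self.flagged).issubset(set(self.removed)):
            raise ValueError("removed frames must include all flagged frames")


@dataclass
class SubjectData:
    """All four runs of one simulated subject plus generator truth."""

    subject: str
    runs: dict[str, BoldRun]
    motion: dict[str, MotionTrace]
    #: per-state region-by-region correlation matrix actually planted
    #: for this subject (group matrix + subject deviates, PSD-repaired)
    true_corr: dict[str, np.ndarray]


@dataclass
class Cohort:
    """A full synthetic study: subjects, behavior table, and truth."""

    scenario: "object"
    subjects: list[SubjectData]
    behavior: "object"  # pandas.DataFrame: subject, state, rt_ms, accuracy_pct
    #: per-subject latent Fisher-Z dFC, keyed (system, task_state)
    latent_dfc: dict[tuple[str, str], np.ndarray]

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)
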