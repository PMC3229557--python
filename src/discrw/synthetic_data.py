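"""Synthetic stand-ins for the measured data: judgments, cohorts, and BOLD.

Judgments are independent Bernoulli draws with per-contrast accuracy
(defaults 0.9 high / 0.6 low, matching the nominal calibration).  BOLD time
series are generated as the design-matrix forward model plus slow cosine
drift inside the high-pass filter's stop band and AR(1) Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rw_models import BehavioralTrial
from .task_design import (
    DEFAULT_N_VOLUMES,
    DEFAULT_POST_DELIVERY_S,
    DEFAULT_TR,
    SessionDesign,
    design_to_frame,
    frame_to_design,
    generate_experimental_session,
    other_role,
)


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject behavioral parameters."""

    subject_id: int
    accuracy_high: float = 0.9
    accuracy_low: float = 0.6
    accuracy_maximal: float = 1.0
    counterbalance_flag: bool = False

    def __post_init__(self) -> None:
        if not 0.5 <= self.accuracy_low < self.accuracy_high <= 1.0:
            raise ValueError(
                "accuracies must satisfy 0.5 <= accuracy_low < accuracy_high <= 1, got "
                f"low={self.accuracy_low}, high={self.accuracy_high}"
            )

    def accuracy_for(self, contrast_level: str) -> float:
        return {
            "high": self.accuracy_high,
            "low": self.accuracy_low,
            "maximal": self.accuracy_maximal,
        }[contrast_level]


@dataclass(frozen=True)
class GroundTruth:
    """Parameters of the BOLD forward model."""

    generating_variant: str = "WITH"
    alpha: float = 0.05
    beta_true: tuple[float, ...] = (1.0, 1.0, 0.5, 1.0, 0.5)
    noise_sd: float = 0.5
    ar1_coef: float = 0.3
    drift_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.generating_variant not in ("WITH", "WITHOUT", "none"):
            raise ValueError(f"invalid generating_variant: {self.generating_variant!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not abs(self.ar1_coef) <= 0.95:
            raise ValueError("ar1_coef must satisfy |ar1_coef| <= 0.95")


@dataclass
class VoxelTimeSeries:
    """One synthetic voxel's signal over a session."""

    tr: float
    values: np.ndarray
    subject_id: int | None = None
    session_index: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")


def simulate_judgments(
    design: SessionDesign, profile: SubjectProfile, seed: int
) -> list[BehavioralTrial]:
    """Draw an orientation judgment for every trial of a session.

    Each judgment is correct independently with the profile's per-contrast
    accuracy; the outcome r is copied from the condition's liquid (classical
    conditioning: delivery never depends on the judgment).
    """
    rng = np.random.default_rng(seed)
    trials = []
    for spec in design.trials:
        accuracy = profile.accuracy_for(spec.condition.contrast_level)
        correct = bool(rng.random() < accuracy)
        role = spec.condition.orientation_role
        judged = role if correct else other_role(role)
        trials.append(
            BehavioralTrial(
                spec=spec,
                judged_role=judged,
                correct=correct,
                p=spec.condition.discriminability,
                r=1 if spec.condition.liquid == "juice" else 0,
            )
        )
    return trials


@dataclass
class SubjectSession:
    design: SessionDesign
    trials: list[BehavioralTrial]


@dataclass
class SubjectData:
    profile: SubjectProfile
    sessions: dict[int, SubjectSession]

    def all_trials(self) -> list[BehavioralTrial]:
        """Trials of all sessions concatenated in session order."""
        out: list[BehavioralTrial] = []
        for idx in sorted(self.sessions):
            out.extend(self.sessions[idx].trials)
        return out


@dataclass
class Cohort:
    subjects: list[SubjectData]
    master_seed: int

    def __len__(self) -> int:
        return len(self.subjects)


def simulate_cohort(
    n_subjects: int = 23,
    n_sessions: int = 4,
    master_seed: int = 0,
    *,
    accuracy_high: float = 0.9,
    accuracy_low: float = 0.6,
    tr: float = DEFAULT_TR,
    n_volumes: int = DEFAULT_N_VOLUMES,
    post_delivery_s: float = DEFAULT_POST_DELIVERY_S,
) -> Cohort:
    """Simulate independent subjects, each with its own session designs and judgments.

    Per-subject, per-session seeds are a deterministic table drawn once from
    ``master_seed``, so the cohort is bitwise reproducible.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if not 1 <= n_sessions <= 4:
        raise ValueError("n_sessions must be in 1..4")
    seed_rng = np.random.default_rng(master_seed)
    seed_table = seed_rng.integers(0, 2**31 - 1, size=(n_subjects, n_sessions, 2))
    subjects = []
    for s in range(n_subjects):
        profile = SubjectProfile(
            subject_id=s + 1,
            accuracy_high=accuracy_high,
            accuracy_low=accuracy_low,
            counterbalance_flag=bool(s % 2),
        )
        sessions: dict[int, SubjectSession] = {}
        for sess in range(1, n_sessions + 1):
            design_seed, judge_seed = (int(x) for x in seed_table[s, sess - 1])
            design = generate_experimental_session(
                sess,
                design_seed,
                tr=tr,
                n_volumes=n_volumes,
                post_delivery_s=post_delivery_s,
            )
            trials = simulate_judgments(design, profile, judge_seed)
            sessions[sess] = SubjectSession(design=design, trials=trials)
        subjects.append(SubjectData(profile=profile, sessions=sessions))
    return Cohort(subjects=subjects, master_seed=master_seed)


def ar1_noise(n: int, sd: float, coef: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) Gaussian noise with innovation sd ``sd``."""
    if sd == 0:
        return np.zeros(n)
    e = rng.standard_normal(n) * sd
    x = np.empty(n)
    x[0] = e[0] / np.sqrt(1.0 - coef**2) if abs(coef) < 1 else e[0]
    for t in range(1, n):
        x[t] = coef * x[t - 1] + e[t]
    return x


def synthesize_bold(design_matrix, truth: GroundTruth, seed: int) -> VoxelTimeSeries:
    """Forward model: task regressors x beta_true + slow drift + AR(1) noise.

    Drift is a random combination of the design's high-pass basis columns
    (periods at or above the cutoff), so the filter can remove it exactly.
    """
    rng = np.random.default_rng(seed)
    task = design_matrix.task_values
    beta = np.asarray(truth.beta_true, dtype=float)
    if beta.shape != (task.shape[1],):
        raise ValueError(
            f"beta_true has {beta.shape[0] if beta.ndim == 1 else beta.shape} entries, "
            f"design has {task.shape[1]} task regressors"
        )
    signal = task @ beta
    hp = design_matrix.highpass_values
    drift = np.zeros(task.shape[0])
    if hp.shape[1] > 0 and truth.drift_amplitude != 0:
        drift = hp @ (truth.drift_amplitude * rng.standard_normal(hp.shape[1]))
    noise = ar1_noise(task.shape[0], truth.noise_sd, truth.ar1_coef, rng)
    return VoxelTimeSeries(tr=design_matrix.tr, values=signal + drift + noise)


# ---------------------------------------------------------------------------
# TSV interchange
# ---------------------------------------------------------------------------

def behavior_to_frame(design: SessionDesign, trials: list[BehavioralTrial]) -> pd.DataFrame:
    frame = design_to_frame(design)
    frame["judged_role"] = [t.judged_role for t in trials]
    frame["correct"] = [int(t.correct) for t in trials]
    frame["r"] = [t.r for t in trials]
    return frame


def write_behavior_tsv(design: SessionDesign, trials: list[BehavioralTrial], path) -> None:
    behavior_to_frame(design, trials).to_csv(path, sep="\t", index=False, float_format="%.3f")


def read_behavior_tsv(
    path,
    *,
    tr: float = DEFAULT_TR,
    n_volumes: int = DEFAULT_N_VOLUMES,
    post_delivery_s: float = DEFAULT_POST_DELIVERY_S,
) -> tuple[SessionDesign, list[BehavioralTrial]]:
    frame = pd.read_csv(path, sep="\t")
    design = frame_to_design(
        frame, tr=tr, n_volumes=n_volumes, post_delivery_s=post_delivery_s
    )
    trials = [
        BehavioralTrial(
            spec=spec,
            judged_role=str(row["judged_role"]),
            correct=bool(row["correct"]),
            p=spec.condition.discriminability,
            r=int(row["r"]),
        )
        for spec, (_, row) in zip(design.trials, frame.iterrows())
    ]
    return design, trials


def timeseries_to_frame(ts: VoxelTimeSeries) -> pd.DataFrame:
    idx = np.arange(len(ts.values))
    return pd.DataFrame(
        {"volume_index": idx, "time_s": idx * ts.tr, "value": ts.values}
    )


def write_timeseries_tsv(ts: VoxelTimeSeries, path) -> None:
    timeseries_to_frame(ts).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_timeseries_tsv(path, *, tr: float = DEFAULT_TR) -> VoxelTimeSeries:
    frame = pd.read_csv(path, sep="\t")
    return VoxelTimeSeries(tr=tr, values=frame["value"].to_numpy())
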