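"""Trial schedules for the classical-conditioning reversal task.

The experimental session is a 2 (orientation role) x 2 (contrast) x 2 (liquid)
factorial with 5 replicates per cell (40 trials), half of which reverse the
conditioned orientation-liquid contingency ("prediction-error" trials).
Conditioning sessions use maximal-contrast stimuli with fully congruent
deliveries.  Timing: 500 ms stimulus, 4 s delay to delivery, a fixed
post-delivery (swallow) period, then an ITI of 2 s or 7 s.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

STIMULUS_DURATION_S = 0.5
DELIVERY_DELAY_S = 4.0
DEFAULT_POST_DELIVERY_S = 4.0
DEFAULT_ITI_VALUES = (2.0, 7.0)
DEFAULT_TR = 2.1
DEFAULT_N_VOLUMES = 250

N_TRIALS_PER_SESSION = 40

ORIENTATION_ROLES = ("reward_conditioned", "nonreward_conditioned")
LIQUIDS = ("juice", "saliva")
#: discriminability p attached to each contrast level
DISCRIMINABILITY = {"high": 0.9, "low": 0.6, "maximal": 1.0}


class SchedulingError(ValueError):
    """Raised when a trial schedule does not fit into the scan duration."""


def other_role(role: str) -> str:
    """The opposite orientation role."""
    if role not in ORIENTATION_ROLES:
        raise ValueError(f"unknown orientation role: {role!r}")
    return ORIENTATION_ROLES[1 - ORIENTATION_ROLES.index(role)]


@dataclass(frozen=True)
class Condition:
    """One cell of the factorial design."""

    orientation_role: str
    contrast_level: str
    liquid: str

    def __post_init__(self) -> None:
        if self.orientation_role not in ORIENTATION_ROLES:
            raise ValueError(f"invalid orientation_role: {self.orientation_role!r}")
        if self.contrast_level not in DISCRIMINABILITY:
            raise ValueError(f"invalid contrast_level: {self.contrast_level!r}")
        if self.liquid not in LIQUIDS:
            raise ValueError(f"invalid liquid: {self.liquid!r}")

    @property
    def discriminability(self) -> float:
        """p: probability of a correct orientation judgment at this contrast."""
        return DISCRIMINABILITY[self.contrast_level]

    @property
    def is_prediction_error(self) -> bool:
        """True when the delivered liquid contradicts the conditioned contingency."""
        return (self.orientation_role == "reward_conditioned") == (self.liquid == "saliva")


@dataclass(frozen=True)
class TrialSpec:
    """A single scheduled trial."""

    session_index: int
    trial_index: int
    condition: Condition
    stimulus_onset: float
    delivery_onset: float
    iti_after: float

    def __post_init__(self) -> None:
        expected = self.stimulus_onset + STIMULUS_DURATION_S + DELIVERY_DELAY_S
        if abs(self.delivery_onset - expected) > 1e-9:
            raise ValueError(
                "delivery_onset must equal stimulus_onset + "
                f"{STIMULUS_DURATION_S + DELIVERY_DELAY_S} s (got {self.delivery_onset})"
            )

    @property
    def is_prediction_error(self) -> bool:
        return self.condition.is_prediction_error


@dataclass(frozen=True)
class SessionDesign:
    """An ordered trial schedule plus the scan geometry it must fit into."""

    trials: tuple[TrialSpec, ...]
    tr: float = DEFAULT_TR
    n_volumes: int = DEFAULT_N_VOLUMES
    post_delivery_s: float = DEFAULT_POST_DELIVERY_S

    @property
    def session_index(self) -> int:
        return self.trials[0].session_index

    @property
    def total_duration(self) -> float:
        last = self.trials[-1]
        return last.delivery_onset + self.post_delivery_s + last.iti_after

    @property
    def scan_duration(self) -> float:
        return self.n_volumes * self.tr


def _experimental_conditions() -> list[Condition]:
    return [
        Condition(role, contrast, liquid)
        for role in ORIENTATION_ROLES
        for contrast in ("high", "low")
        for liquid in LIQUIDS
        for _ in range(5)
    ]


def _conditioning_conditions() -> list[Condition]:
    # Congruent by construction: juice with the reward-conditioned orientation.
    return [Condition("reward_conditioned", "maximal", "juice")] * 20 + [
        Condition("nonreward_conditioned", "maximal", "saliva")
    ] * 20


def _schedule(
    session_index: int,
    conditions: Sequence[Condition],
    itis: Sequence[float],
    *,
    tr: float,
    n_volumes: int,
    post_delivery_s: float,
) -> SessionDesign:
    trials = []
    onset = 0.0
    for i, (cond, iti) in enumerate(zip(conditions, itis), start=1):
        delivery = onset + STIMULUS_DURATION_S + DELIVERY_DELAY_S
        trials.append(
            TrialSpec(
                session_index=session_index,
                trial_index=i,
                condition=cond,
                stimulus_onset=onset,
                delivery_onset=delivery,
                iti_after=float(iti),
            )
        )
        onset = delivery + post_delivery_s + iti
    design = SessionDesign(
        trials=tuple(trials), tr=tr, n_volumes=n_volumes, post_delivery_s=post_delivery_s
    )
    if design.total_duration > design.scan_duration + 1e-9:
        raise SchedulingError(
            f"schedule of {design.total_duration:.1f} s exceeds scan duration "
            f"{design.scan_duration:.1f} s ({n_volumes} volumes x {tr} s)"
        )
    return design


def _draw_itis(rng: np.random.Generator, n_trials: int, iti_values: Sequence[float]) -> np.ndarray:
    # Balanced composition: equal counts of each ITI value, seeded permutation.
    reps = n_trials // len(iti_values)
    if reps * len(iti_values) != n_trials:
        raise ValueError("number of trials must be divisible by the number of ITI values")
    itis = np.repeat(np.asarray(iti_values, dtype=float), reps)
    return rng.permutation(itis)


def generate_experimental_session(
    session_index: int,
    seed: int,
    *,
    tr: float = DEFAULT_TR,
    n_volumes: int = DEFAULT_N_VOLUMES,
    post_delivery_s: float = DEFAULT_POST_DELIVERY_S,
    iti_values: Sequence[float] = DEFAULT_ITI_VALUES,
) -> SessionDesign:
    """Generate one 40-trial experimental session in pseudo-random order.

    The trial order is a seeded uniform permutation of the 40 condition
    instances (5 per factorial cell); ITIs are a seeded permutation of a
    balanced multiset of ``iti_values``.
    """
    if not 1 <= session_index <= 4:
        raise ValueError(f"session_index must be in 1..4, got {session_index}")
    rng = np.random.default_rng(seed)
    conditions = _experimental_conditions()
    order = rng.permutation(len(conditions))
    conditions = [conditions[i] for i in order]
    itis = _draw_itis(rng, len(conditions), iti_values)
    return _schedule(
        session_index,
        conditions,
        itis,
        tr=tr,
        n_volumes=n_volumes,
        post_delivery_s=post_delivery_s,
    )


def generate_conditioning_session(
    seed: int,
    *,
    tr: float = DEFAULT_TR,
    n_volumes: int = DEFAULT_N_VOLUMES,
    post_delivery_s: float = DEFAULT_POST_DELIVERY_S,
    iti_values: Sequence[float] = DEFAULT_ITI_VALUES,
) -> SessionDesign:
    """Generate one 40-trial conditioning session (20 juice, 20 saliva, maximal contrast)."""
    rng = np.random.default_rng(seed)
    conditions = _conditioning_conditions()
    order = rng.permutation(len(conditions))
    conditions = [conditions[i] for i in order]
    itis = _draw_itis(rng, len(conditions), iti_values)
    return _schedule(
        0, conditions, itis, tr=tr, n_volumes=n_volumes, post_delivery_s=post_delivery_s
    )


def count_prediction_error_trials(design: SessionDesign) -> tuple[int, float]:
    """Count trials whose delivery contradicts the conditioned contingency."""
    if len(design.trials) == 0:
        raise ValueError("design has no trials")
    count = sum(t.is_prediction_error for t in design.trials)
    return count, count / len(design.trials)


# ---------------------------------------------------------------------------
# Events TSV (BIDS-style) interchange
# ---------------------------------------------------------------------------

EVENTS_COLUMNS = [
    "onset",
    "duration",
    "trial_type",
    "session",
    "trial",
    "contrast_level",
    "discriminability",
    "liquid",
    "is_prediction_error",
    "iti_after",
]


def design_to_frame(design: SessionDesign) -> pd.DataFrame:
    rows = [
        {
            "onset": t.stimulus_onset,
            "duration": STIMULUS_DURATION_S,
            "trial_type": t.condition.orientation_role,
            "session": t.session_index,
            "trial": t.trial_index,
            "contrast_level": t.condition.contrast_level,
            "discriminability": t.condition.discriminability,
            "liquid": t.condition.liquid,
            "is_prediction_error": int(t.is_prediction_error),
            "iti_after": t.iti_after,
        }
        for t in design.trials
    ]
    return pd.DataFrame(rows, columns=EVENTS_COLUMNS)


def write_events_tsv(design: SessionDesign, path) -> None:
    design_to_frame(design).to_csv(path, sep="\t", index=False, float_format="%.3f")


def frame_to_design(
    frame: pd.DataFrame,
    *,
    tr: float = DEFAULT_TR,
    n_volumes: int = DEFAULT_N_VOLUMES,
    post_delivery_s: float = DEFAULT_POST_DELIVERY_S,
) -> SessionDesign:
    trials = []
    for _, row in frame.iterrows():
        onset = float(row["onset"])
        trials.append(
            TrialSpec(
                session_index=int(row["session"]),
                trial_index=int(row["trial"]),
                condition=Condition(
                    orientation_role=str(row["trial_type"]),
                    contrast_level=str(row["contrast_level"]),
                    liquid=str(row["liquid"]),
                ),
                stimulus_onset=onset,
                delivery_onset=onset + STIMULUS_DURATION_S + DELIVERY_DELAY_S,
                iti_after=float(row["iti_after"]),
            )
        )
    return SessionDesign(
        trials=tuple(trials), tr=tr, n_volumes=n_volumes, post_delivery_s=post_delivery_s
    )


def read_events_tsv(
    path,
    *,
    tr: float = DEFAULT_TR,
    n_volumes: int = DEFAULT_N_VOLUMES,
    post_delivery_s: float = DEFAULT_POST_DELIVERY_S,
) -> SessionDesign:
    frame = pd.read_csv(path, sep="\t")
    return frame_to_design(frame, tr=tr, n_volumes=n_volumes, post_delivery_s=post_delivery_s)
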