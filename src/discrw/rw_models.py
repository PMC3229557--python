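"""Trial-level Rescorla-Wagner value and prediction-error traces.

Two variants are computed over the same behavioral trial sequence:

* ``WITHOUT`` - the predicted value on a trial is the value of the judged
  orientation alone.
* ``WITH`` - the predicted value mixes the two orientation values by the
  stimulus discriminability p: p times the judged orientation's value plus
  (1 - p) times the other orientation's value.

Both variants track separate values for the reward-conditioned orientation
(vr, initialized at 1) and the nonreward-conditioned orientation (vn,
initialized at 0), always keyed on the orientation the subject *judged*,
never the orientation actually shown.  The prediction error is
delta = r - v with r = 1 for juice and 0 for saliva, and by default only the
judged orientation's value is updated by alpha * delta.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .task_design import TrialSpec, other_role, ORIENTATION_ROLES

logger = logging.getLogger(__name__)

VARIANTS = ("WITH", "WITHOUT")
UPDATE_MODES = ("judged_only", "weighted")

#: learning rates used throughout the analysis
ALPHA_GRID = (0.001, 0.005, 0.01, 0.025, 0.05, 0.1, 0.2, 0.4)

_CLIP_TOL = 1e-12


class ValueBoundError(ValueError):
    """A value update left [0, 1] by more than numerical tolerance."""


def alpha_grid() -> list[float]:
    """The fixed grid of learning rates, ascending."""
    return list(ALPHA_GRID)


@dataclass(frozen=True)
class ModelParams:
    variant: str
    learning_rate: float
    initial_vr: float = 1.0
    initial_vn: float = 0.0
    update_mode: str = "judged_only"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if not 0.0 < self.learning_rate <= 1.0:
            raise ValueError(f"learning_rate must be in (0, 1], got {self.learning_rate}")
        for name, v in (("initial_vr", self.initial_vr), ("initial_vn", self.initial_vn)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.update_mode not in UPDATE_MODES:
            raise ValueError(f"update_mode must be one of {UPDATE_MODES}")


@dataclass(frozen=True)
class BehavioralTrial:
    """A scheduled trial plus the subject's orientation judgment and outcome."""

    spec: TrialSpec
    judged_role: str
    correct: bool
    p: float
    r: int

    def __post_init__(self) -> None:
        if self.judged_role not in ORIENTATION_ROLES:
            raise ValueError(f"invalid judged_role: {self.judged_role!r}")
        expected_r = 1 if self.spec.condition.liquid == "juice" else 0
        if self.r != expected_r:
            raise ValueError(f"r must be {expected_r} for liquid {self.spec.condition.liquid}")
        if abs(self.p - self.spec.condition.discriminability) > 1e-9:
            raise ValueError(
                f"p {self.p} does not match the condition discriminability "
                f"{self.spec.condition.discriminability}"
            )
        if self.correct != (self.judged_role == self.spec.condition.orientation_role):
            raise ValueError("correct flag inconsistent with judged_role")


@dataclass
class ModelTrace:
    """Per-trial model quantities for one variant and learning rate."""

    params: ModelParams
    session_index: np.ndarray
    trial_index: np.ndarray
    judged_role: np.ndarray
    contrast_level: np.ndarray
    p: np.ndarray
    r: np.ndarray
    vr: np.ndarray
    vn: np.ndarray
    v: np.ndarray
    delta: np.ndarray
    n_saturated: int = 0

    def __len__(self) -> int:
        return len(self.delta)

    def for_session(self, session_index: int) -> "ModelTrace":
        """The sub-trace of one session (order preserved)."""
        mask = self.session_index == session_index
        if not mask.any():
            raise ValueError(f"trace contains no trials for session {session_index}")
        return ModelTrace(
            params=self.params,
            session_index=self.session_index[mask],
            trial_index=self.trial_index[mask],
            judged_role=self.judged_role[mask],
            contrast_level=self.contrast_level[mask],
            p=self.p[mask],
            r=self.r[mask],
            vr=self.vr[mask],
            vn=self.vn[mask],
            v=self.v[mask],
            delta=self.delta[mask],
            n_saturated=self.n_saturated,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "session": self.session_index,
                "trial": self.trial_index,
                "judged_role": self.judged_role,
                "contrast_level": self.contrast_level,
                "p": self.p,
                "r": self.r,
                "vr": self.vr,
                "vn": self.vn,
                "v": self.v,
                "delta": self.delta,
            }
        )


def predicted_value(vr: float, vn: float, judged_role: str, p: float, variant: str) -> float:
    """Predicted reward value for the judged orientation.

    WITHOUT: the judged orientation's value.  WITH: p times the judged
    orientation's value plus (1 - p) times the other orientation's value.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p must be in (0, 1], got {p}")
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")
    judged, other = (vr, vn) if judged_role == "reward_conditioned" else (vn, vr)
    if variant == "WITHOUT":
        return judged
    return p * judged + (1.0 - p) * other


def prediction_error(r: float, v: float) -> float:
    """delta = r - v."""
    return r - v


def _bound(value: float, saturating: bool) -> tuple[float, bool]:
    if 0.0 <= value <= 1.0:
        return value, False
    if -_CLIP_TOL <= value <= 1.0 + _CLIP_TOL:
        return min(max(value, 0.0), 1.0), False
    if saturating:
        return min(max(value, 0.0), 1.0), True
    raise ValueBoundError(f"value update produced {value!r}, outside [0, 1]")


def _update(
    vr: float, vn: float, judged_role: str, p: float, delta: float, params: ModelParams
) -> tuple[float, float, bool]:
    alpha = params.learning_rate
    if params.update_mode == "judged_only":
        d_judged, d_other = alpha * delta, 0.0
    else:
        d_judged, d_other = alpha * p * delta, alpha * (1.0 - p) * delta
    if judged_role == "reward_conditioned":
        new_vr, new_vn = vr + d_judged, vn + d_other
    else:
        new_vr, new_vn = vr + d_other, vn + d_judged
    saturating = params.variant == "WITH" or params.update_mode == "weighted"
    new_vr, sat_r = _bound(new_vr, saturating)
    new_vn, sat_n = _bound(new_vn, saturating)
    if sat_r or sat_n:
        logger.debug(
            "saturating value update at boundary (vr=%s, vn=%s, delta=%s)", vr, vn, delta
        )
    return new_vr, new_vn, sat_r or sat_n


def update_values(
    vr: float,
    vn: float,
    judged_role: str,
    p: float,
    delta: float,
    params: ModelParams,
) -> tuple[float, float]:
    """One learning step.

    ``judged_only`` (default): only the judged orientation's value moves, by
    alpha * delta.  ``weighted``: the judged orientation moves by
    alpha * p * delta and the other by alpha * (1 - p) * delta.

    Under the WITH variant (and under weighted updates) the step can push a
    value marginally past [0, 1] because the predicted value mixes both
    orientations; such updates saturate at the boundary.  Under
    WITHOUT/judged_only the update is a convex combination and an
    out-of-bounds result indicates invalid inputs, so it raises.
    """
    new_vr, new_vn, _ = _update(vr, vn, judged_role, p, delta, params)
    return new_vr, new_vn


def run_model(trials: list[BehavioralTrial], params: ModelParams) -> ModelTrace:
    """Iterate the model over an ordered trial sequence.

    State carries continuously across sessions; values start at
    (initial_vr, initial_vn) before the first trial.
    """
    if len(trials) == 0:
        raise ValueError("trial list is empty")
    n = len(trials)
    vr_arr = np.empty(n)
    vn_arr = np.empty(n)
    v_arr = np.empty(n)
    d_arr = np.empty(n)
    n_saturated = 0
    vr, vn = params.initial_vr, params.initial_vn
    for i, trial in enumerate(trials):
        v = predicted_value(vr, vn, trial.judged_role, trial.p, params.variant)
        delta = prediction_error(trial.r, v)
        vr_arr[i], vn_arr[i], v_arr[i], d_arr[i] = vr, vn, v, delta
        vr, vn, saturated = _update(vr, vn, trial.judged_role, trial.p, delta, params)
        n_saturated += saturated
    return ModelTrace(
        params=params,
        session_index=np.array([t.spec.session_index for t in trials]),
        trial_index=np.array([t.spec.trial_index for t in trials]),
        judged_role=np.array([t.judged_role for t in trials], dtype=object),
        contrast_level=np.array(
            [t.spec.condition.contrast_level for t in trials], dtype=object
        ),
        p=np.array([t.p for t in trials]),
        r=np.array([t.r for t in trials], dtype=float),
        vr=vr_arr,
        vn=vn_arr,
        v=v_arr,
        delta=d_arr,
        n_saturated=n_saturated,
    )


def summarize_vr_dominance(trace: ModelTrace) -> pd.Series:
    """Per-session proportion of trials with vr strictly greater than vn."""
    if len(trace) == 0:
        raise ValueError("trace is empty")
    frame = pd.DataFrame(
        {"session": trace.session_index, "dominant": trace.vr > trace.vn}
    )
    out = frame.groupby("session")["dominant"].mean()
    out.name = "vr_dominance"
    return out


def summarize_positive_pe(trace: ModelTrace) -> pd.DataFrame:
    """Mean delta on positive prediction-error trials per session x contrast.

    Positive prediction-error trials are those in which the subject judged
    the nonreward-conditioned orientation but juice was delivered.  Cells
    with no such trials are omitted (missing, not zero).
    """
    if len(trace) == 0:
        raise ValueError("trace is empty")
    mask = (trace.judged_role == "nonreward_conditioned") & (trace.r == 1)
    frame = pd.DataFrame(
        {
            "session": trace.session_index[mask],
            "contrast_level": trace.contrast_level[mask],
            "delta": trace.delta[mask],
        }
    )
    out = (
        frame.groupby(["session", "contrast_level"])["delta"]
        .agg(mean_delta="mean", n_trials="count")
        .reset_index()
    )
    return out
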