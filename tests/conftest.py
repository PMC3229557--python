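import numpy as np
import pytest

from discrw.rw_models import BehavioralTrial
from discrw.task_design import (
    Condition,
    SessionDesign,
    TrialSpec,
    generate_conditioning_session,
    generate_experimental_session,
    other_role,
)


@pytest.fixture
def exp_design() -> SessionDesign:
    return generate_experimental_session(1, seed=42)


@pytest.fixture
def cond_design() -> SessionDesign:
    return generate_conditioning_session(seed=7)


def make_trial_spec(
    i: int,
    role: str = "reward_conditioned",
    contrast: str = "high",
    liquid: str = "juice",
    session: int = 1,
) -> TrialSpec:
    onset = 13.0 * (i - 1)
    return TrialSpec(
        session_index=session,
        trial_index=i,
        condition=Condition(role, contrast, liquid),
        stimulus_onset=onset,
        delivery_onset=onset + 4.5,
        iti_after=2.0,
    )


def make_behavioral_trial(
    i: int,
    role: str = "reward_conditioned",
    contrast: str = "high",
    liquid: str = "juice",
    judged: str | None = None,
    session: int = 1,
) -> BehavioralTrial:
    spec = make_trial_spec(i, role, contrast, liquid, session)
    judged = judged or role
    return BehavioralTrial(
        spec=spec,
        judged_role=judged,
        correct=judged == role,
        p=spec.condition.discriminability,
        r=1 if liquid == "juice" else 0,
    )


def random_trial_sequence(rng: np.random.Generator, n: int, session: int = 1):
    """An arbitrary valid behavioral trial sequence (for property tests)."""
    roles = ("reward_conditioned", "nonreward_conditioned")
    trials = []
    for i in range(1, n + 1):
        role = roles[rng.integers(2)]
        contrast = ("high", "low", "maximal")[rng.integers(3)]
        liquid = ("juice", "saliva")[rng.integers(2)]
        judged = role if rng.random() < 0.7 else other_role(role)
        trials.append(make_behavioral_trial(i, role, contrast, liquid, judged, session))
    return trials
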