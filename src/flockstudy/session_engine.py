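"""Operant trial and session scheduling for two-alternative discrimination studies.

The protocol modelled here trains cohorts of four observers on daily sessions
of go-left/go-right choices about a displayed stimulus.  Correct choices on
*differential* trials are food-reinforced; incorrect ones trigger correction
trials (same stimulus, repeated until correct) that are excluded from scored
accuracy.  Test trials are *nondifferentially* reinforced — food regardless of
choice — so that testing cannot teach the tested stimuli.  Session
compositions follow the regimen of the histology experiment (24 training
exemplars, 144 training trials, 24 novel-test trials) or the mammogram
experiments (20 exemplars, 120 + 20 trials); a compression-testing phase
interleaves the full uncompressed set with 24 compressed probes per day over
6 four-day cycles.

All randomness is driven by ``numpy`` generators seeded from the experiment
config, so identical ``(config, day, seed)`` always yields an identical plan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Protocol, Sequence

import numpy as np
import pandas as pd

from .stimulus_prep import ORIENTATIONS

__all__ = [
    "PHASES",
    "EXPERIMENTS",
    "CHOICES",
    "COMPRESSION_RATIOS",
    "RECORD_COLUMNS",
    "ExperimentConfig",
    "TrialSpec",
    "SessionPlan",
    "ResponseRecord",
    "Agent",
    "counterbalance_cohort",
    "build_training_session",
    "build_testing_session",
    "compression_schedule",
    "run_trial",
    "run_session",
    "records_to_frame",
    "plan_to_frame",
    "adapt_observing_requirement",
]

PHASES = ("initial_0deg", "rotation", "novel_test", "compression_test", "full_set")
EXPERIMENTS = ("histology", "calcifications", "masses")
CHOICES = ("positive", "negative")
SIDES = ("left", "right")
REINFORCEMENTS = ("differential", "nondifferential")

#: Byte-size fractions of the two compressed probe sets (15:1 and 27:1).
COMPRESSION_RATIOS = (0.07, 0.04)

#: Per-experiment (training trials/day, test trials/day) defaults.
_TRIAL_COUNTS = {"histology": (144, 24), "calcifications": (120, 20), "masses": (120, 20)}

RECORD_COLUMNS = [
    "observer_id",
    "day",
    "trial_index",
    "attempt",
    "stimulus_id",
    "orientation",
    "true_label",
    "choice",
    "correct",
    "is_correction_trial",
    "reinforced",
    "reinforcement",
    "condition",
    "compression_ratio",
]


@dataclass
class ExperimentConfig:
    """Everything needed to schedule sessions for one observer.

    ``button_assignment`` maps each class to the side of its correct report
    button; assignments are counterbalanced within a cohort.  ``labels`` maps
    stimulus ids to their true class and is required for phases whose
    composition is class-balanced (compression testing) and for running
    trials.
    """

    experiment: str = "histology"
    training_set: tuple[str, ...] = ()
    testing_set: tuple[str, ...] = ()
    trials_per_training_session: int = 144
    test_trials_per_session: int = 24
    phase: str = "initial_0deg"
    button_assignment: Mapping[str, str] = field(
        default_factory=lambda: {"positive": "left", "negative": "right"}
    )
    seed: int = 0
    labels: Mapping[str, str] | None = None
    observer_id: str = "obs"

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        self.training_set = tuple(self.training_set)
        self.testing_set = tuple(self.testing_set)
        overlap = set(self.training_set) & set(self.testing_set)
        if overlap:
            raise ValueError(f"training and testing sets overlap: {sorted(overlap)}")
        if set(self.button_assignment) != set(CHOICES):
            raise ValueError("button_assignment must map both classes")
        if set(self.button_assignment.values()) != set(SIDES):
            raise ValueError("button_assignment must use both sides")


@dataclass(frozen=True)
class TrialSpec:
    """One scheduled trial."""

    index: int
    stimulus_id: str
    orientation: str = "r0"
    reinforcement: str = "differential"
    observing_requirement: int = 1
    condition: str = "training_familiar"
    compression_ratio: float = 1.0
    iti_s: float = 8.0

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.reinforcement not in REINFORCEMENTS:
            raise ValueError(f"unknown reinforcement {self.reinforcement!r}")
        if not (1 <= self.observing_requirement <= 10):
            raise ValueError("observing_requirement must be in [1, 10]")


@dataclass(frozen=True)
class SessionPlan:
    day: int
    trials: tuple[TrialSpec, ...]
    iti_range_s: tuple[float, float] = (6.0, 10.0)
    phase: str = "initial_0deg"


@dataclass(frozen=True)
class ResponseRecord:
    """One choice event.  Correction repeats share the trial_index of the
    failed first attempt and are flagged; they are never scored."""

    observer_id: str
    day: int
    trial_index: int
    attempt: int
    stimulus_id: str
    orientation: str
    true_label: str
    choice: str
    correct: bool
    is_correction_trial: bool
    reinforced: bool
    reinforcement: str
    condition: str
    compression_ratio: float = 1.0


class Agent(Protocol):
    """Minimal interface an observer must expose to run trials."""

    def choose(self, stimulus_id: str, orientation: str = "r0",
               compression_ratio: float = 1.0) -> str: ...


# ---------------------------------------------------------------------------
# Cohort counterbalancing
# ---------------------------------------------------------------------------


def counterbalance_cohort(
    observer_ids: Sequence[str],
    set_a: Sequence[str],
    set_b: Sequence[str],
    experiment: str = "histology",
    seed: int = 0,
    labels: Mapping[str, str] | None = None,
) -> dict[str, ExperimentConfig]:
    """Fully counterbalanced configs for a quartet of observers.

    The first two observers train on set A and are tested on set B; the last
    two the reverse.  Within each pair the left/right button assignments are
    mirrored, so every (training set, button mapping) combination occurs
    exactly once.
    """
    if len(observer_ids) != 4:
        raise ValueError(f"cohort must contain exactly 4 observers, got {len(observer_ids)}")
    if len(set(observer_ids)) != 4:
        raise ValueError("observer ids must be distinct")
    n_train, n_test = _TRIAL_COUNTS[experiment]
    buttons = (
        {"positive": "left", "negative": "right"},
        {"positive": "right", "negative": "left"},
    )
    configs = {}
    for i, oid in enumerate(observer_ids):
        train, test = (set_a, set_b) if i < 2 else (set_b, set_a)
        configs[oid] = ExperimentConfig(
            experiment=experiment,
            training_set=tuple(train),
            testing_set=tuple(test),
            trials_per_training_session=n_train,
            test_trials_per_session=n_test,
            button_assignment=dict(buttons[i % 2]),
            seed=seed,
            labels=labels,
            observer_id=oid,
        )
    return configs


# ---------------------------------------------------------------------------
# Session construction
# ---------------------------------------------------------------------------

_TAGS = {"train": 0, "test": 1, "cycle": 2}


def _rng(config: ExperimentConfig, day: int, tag: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, int(day), _TAGS[tag]])


def _finalize(
    config: ExperimentConfig,
    day: int,
    tag: str,
    protos: list[dict],
    observing_requirement: int,
) -> SessionPlan:
    """Seeded uniform permutation of the trial prototypes, then numbering."""
    rng = _rng(config, day, tag)
    order = rng.permutation(len(protos))
    itis = rng.uniform(6.0, 10.0, size=len(protos))
    trials = tuple(
        TrialSpec(
            index=i,
            observing_requirement=observing_requirement,
            iti_s=float(itis[i]),
            **protos[j],
        )
        for i, j in enumerate(order)
    )
    return SessionPlan(day=day, trials=trials, phase=config.phase)


def build_training_session(
    config: ExperimentConfig, day: int, observing_requirement: int = 1
) -> SessionPlan:
    """Plan one differentially reinforced training session.

    Phase contracts: ``initial_0deg`` shows each training exemplar
    ``trials_per_training_session / n_exemplars`` times in its unrotated
    view; ``rotation`` shows every exemplar once in each of the six views;
    ``full_set`` shows the union of training and testing exemplars equally
    often at 0 degrees.  Trial order is a seeded uniform permutation.
    """
    if config.phase not in ("initial_0deg", "rotation", "full_set"):
        raise ValueError(f"phase {config.phase!r} is not a training phase")
    if not config.training_set:
        raise ValueError("training set is empty")

    protos: list[dict] = []
    if config.phase == "initial_0deg":
        n = len(config.training_set)
        reps, rem = divmod(config.trials_per_training_session, n)
        if rem:
            raise ValueError(
                f"{config.trials_per_training_session} trials not divisible by "
                f"{n} exemplars"
            )
        for sid in config.training_set:
            protos += [
                dict(stimulus_id=sid, orientation="r0", condition="training_familiar")
            ] * reps
    elif config.phase == "rotation":
        for sid in config.training_set:
            for o in ORIENTATIONS:
                cond = "training_familiar" if o == "r0" else "training_rotated"
                protos.append(dict(stimulus_id=sid, orientation=o, condition=cond))
    else:  # full_set
        exemplars = tuple(config.training_set) + tuple(config.testing_set)
        reps, rem = divmod(config.trials_per_training_session, len(exemplars))
        if rem:
            raise ValueError(
                f"{config.trials_per_training_session} trials not divisible by "
                f"{len(exemplars)} exemplars"
            )
        for sid in exemplars:
            protos += [
                dict(stimulus_id=sid, orientation="r0", condition="training_familiar")
            ] * reps
    return _finalize(config, day, "train", protos, observing_requirement)


def build_testing_session(
    config: ExperimentConfig, day: int, observing_requirement: int = 1
) -> SessionPlan:
    """Plan one test session with interleaved training and probe trials.

    ``novel_test``: the full rotated training set (each exemplar once per
    view, differential) is interleaved with one nondifferential presentation
    of every novel exemplar — 144 + 24 trials for the histology regimen,
    120 + 20 for the mammogram regimens.

    ``compression_test``: 3 unrotated presentations of all exemplars
    (differential) plus 24 compressed probes (nondifferential): 6 per class
    at each of the two compression ratios.  ``day`` counts from 1 within the
    phase; consecutive blocks of 4 days form one cycle in which every
    (exemplar, ratio) pair appears exactly once.
    """
    if config.phase not in ("novel_test", "compression_test"):
        raise ValueError(f"phase {config.phase!r} is not a testing phase")

    protos: list[dict] = []
    if config.phase == "novel_test":
        if not config.testing_set:
            raise ValueError("testing set is empty")
        for sid in config.training_set:
            for o in ORIENTATIONS:
                protos.append(
                    dict(stimulus_id=sid, orientation=o, condition="training_familiar")
                )
        if len(protos) != config.trials_per_training_session:
            raise ValueError(
                f"rotated training set yields {len(protos)} trials, expected "
                f"{config.trials_per_training_session}"
            )
        for sid in config.testing_set:
            protos.append(
                dict(
                    stimulus_id=sid,
                    orientation="r0",
                    reinforcement="nondifferential",
                    condition="test_novel",
                )
            )
    else:  # compression_test
        if config.labels is None:
            raise ValueError("compression testing needs config.labels to balance classes")
        exemplars = tuple(config.training_set) + tuple(config.testing_set)
        reps, rem = divmod(config.trials_per_training_session, len(exemplars))
        if rem:
            raise ValueError(
                f"{config.trials_per_training_session} trials not divisible by "
                f"{len(exemplars)} exemplars"
            )
        for sid in exemplars:
            protos += [
                dict(stimulus_id=sid, orientation="r0", condition="uncompressed")
            ] * reps
        cycle, day_in_cycle = divmod(day - 1, 4)
        cond_by_ratio = {0.07: "compressed_15to1", 0.04: "compressed_27to1"}
        for ri, ratio in enumerate(COMPRESSION_RATIOS):
            for ci, cls in enumerate(CHOICES):
                ids = sorted(s for s in exemplars if config.labels[s] == cls)
                if len(ids) % 4:
                    raise ValueError(
                        f"class {cls!r} count {len(ids)} not divisible over a 4-day cycle"
                    )
                per_day = len(ids) // 4
                perm = np.random.default_rng(
                    [config.seed, _TAGS["cycle"], cycle, ri, ci]
                ).permutation(ids)
                chunk = perm[day_in_cycle * per_day : (day_in_cycle + 1) * per_day]
                for sid in chunk:
                    protos.append(
                        dict(
                            stimulus_id=str(sid),
                            orientation="r0",
                            reinforcement="nondifferential",
                            condition=cond_by_ratio[ratio],
                            compression_ratio=ratio,
                        )
                    )
    return _finalize(config, day, "test", protos, observing_requirement)


def compression_schedule(
    config: ExperimentConfig, n_cycles: int = 6, observing_requirement: int = 1
) -> list[SessionPlan]:
    """The full compression-testing phase: ``n_cycles`` cycles of 4 days."""
    cfg = replace(config, phase="compression_test")
    return [
        build_testing_session(cfg, day, observing_requirement)
        for day in range(1, 4 * n_cycles + 1)
    ]


# ---------------------------------------------------------------------------
# Trial execution
# ---------------------------------------------------------------------------


def run_trial(
    agent: Agent,
    trial: TrialSpec,
    true_label: str,
    observer_id: str = "obs",
    day: int = 1,
    max_corrections: int = 50,
) -> list[ResponseRecord]:
    """Execute one trial, including any correction repeats.

    On differential trials an incorrect choice triggers correction trials
    with the same stimulus until the correct response occurs (capped at
    ``max_corrections`` with a warning, a guard for non-learning agents).
    Only the first attempt is a scored trial.  Nondifferential trials always
    produce exactly one record and are reinforced regardless of choice; the
    correct/incorrect designation on them is for scoring only.  Reinforcement
    outcomes are reported to the agent (for learning updates) on differential
    trials only.
    """
    if true_label not in CHOICES:
        raise ValueError(f"invalid true label {true_label!r}")
    differential = trial.reinforcement == "differential"
    records: list[ResponseRecord] = []
    attempt = 0
    while True:
        choice = agent.choose(
            trial.stimulus_id, trial.orientation, trial.compression_ratio
        )
        if choice not in CHOICES:
            raise ValueError(f"agent returned invalid choice {choice!r}")
        correct = choice == true_label
        reinforced = correct if differential else True
        records.append(
            ResponseRecord(
                observer_id=observer_id,
                day=day,
                trial_index=trial.index,
                attempt=attempt,
                stimulus_id=trial.stimulus_id,
                orientation=trial.orientation,
                true_label=true_label,
                choice=choice,
                correct=correct,
                is_correction_trial=attempt > 0,
                reinforced=reinforced,
                reinforcement=trial.reinforcement,
                condition=trial.condition,
                compression_ratio=trial.compression_ratio,
            )
        )
        if differential and hasattr(agent, "observe_outcome"):
            agent.observe_outcome(trial.stimulus_id, choice, correct, reinforced)
        if not differential or correct:
            break
        attempt += 1
        if attempt > max_corrections:
            warnings.warn(
                f"correction loop for stimulus {trial.stimulus_id!r} capped at "
                f"{max_corrections} repeats",
                stacklevel=2,
            )
            break
    return records


def run_session(
    agent: Agent,
    plan: SessionPlan,
    labels: Mapping[str, str],
    observer_id: str = "obs",
    max_corrections: int = 50,
) -> list[ResponseRecord]:
    """Run every trial of a session plan against one agent."""
    records: list[ResponseRecord] = []
    for trial in plan.trials:
        records += run_trial(
            agent,
            trial,
            labels[trial.stimulus_id],
            observer_id=observer_id,
            day=plan.day,
            max_corrections=max_corrections,
        )
    return records


def records_to_frame(records: Iterable[ResponseRecord]) -> pd.DataFrame:
    """Response records as a tidy table with a fixed column order."""
    df = pd.DataFrame([vars(r) for r in records], columns=RECORD_COLUMNS)
    return df


def plan_to_frame(plan: SessionPlan) -> pd.DataFrame:
    """Session plan as a tidy table (one row per trial, in order)."""
    df = pd.DataFrame([vars(t) for t in plan.trials])
    df.insert(0, "day", plan.day)
    df.insert(1, "phase", plan.phase)
    return df


# ---------------------------------------------------------------------------
# Adaptive observing requirement
# ---------------------------------------------------------------------------


def adapt_observing_requirement(
    history: Sequence[float],
    current: int,
    window: int = 3,
    threshold: float = 0.65,
) -> int:
    """Raise the peck requirement when recent accuracy stalls below threshold.

    If the trailing ``window``-session mean accuracy is below ``threshold``
    the requirement increases by one peck (capped at 10); it never decreases.
    With an empty history the current requirement is returned unchanged.
    """
    if not (1 <= current <= 10):
        raise ValueError("current requirement must be in [1, 10]")
    if not history:
        return current
    trailing = list(history)[-window:]
    if float(np.mean(trailing)) < threshold:
        return min(current + 1, 10)
    return current
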