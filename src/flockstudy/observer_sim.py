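"""Synthetic observers for the trial engine.

No behavioural model is fitted to real animals here; the simulator exists so
that every downstream stage (scoring, flock pooling, ROC analysis) can be
exercised end-to-end on records with realistic statistical structure.  The
model is the minimal combination of three standard ingredients:

* a binormal signal-detection core — on session ``t`` a stimulus evokes
  evidence ``x ~ Normal(sign(label) * (d(t)/2 + offset), 1)`` and the observer
  reports "positive" when ``x`` exceeds its criterion;
* exponential learning — ``d(t) = dprime_max * (1 - exp(-t / learn_tau))``,
  so accuracy rises from chance toward an asymptote set by ``dprime_max``;
* an exemplar-memorization channel — reinforced exposures store the correct
  label with probability ``mem_rate`` per exposure, and at decision time the
  stored label is consulted with probability ``mem_weight``.  A pure
  memorizer (``mem_weight = 1``) discriminates trained stimuli but is at
  chance on novel ones, reproducing the signature of rote learning.

Per-stimulus difficulty enters through ``evidence_offset``: positive offsets
make a stimulus easier for every observer, negative offsets mark
counter-typical ("conflictive") exemplars.  Sharing offsets across a cohort
induces the between-observer agreement that makes vote pooling informative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import ndtr

from .session_engine import (
    CHOICES,
    SessionPlan,
    records_to_frame,
    run_session,
)

__all__ = [
    "ObserverParams",
    "LatentStimulus",
    "CohortSpec",
    "dprime_at",
    "feature_evidence",
    "SimulatedObserver",
    "make_latent_stimuli",
    "simulate_cohort",
    "simulate_detection_table",
    "fit_dprime_max",
    "feature_learner_params",
    "memorizer_params",
]

#: Default SD of per-stimulus evidence offsets.
DEFAULT_OFFSET_SD = 0.5


@dataclass(frozen=True)
class ObserverParams:
    """Tunable observer parameters.

    dprime_max
        Asymptotic class separation (in SD units of the evidence axis).
    learn_tau
        Sessions needed to reach ~63% of the asymptote.
    criterion
        Decision threshold on the evidence axis (response bias; 0 = neutral).
    lapse
        Probability of a uniformly random choice regardless of the stimulus.
    mem_weight
        Probability of consulting the exemplar memory instead of the feature
        channel (0 = pure feature generalizer, 1 = pure memorizer).
    mem_rate
        Per-reinforced-exposure probability of storing an exemplar's label.
    compression_attenuation
        Multiplicative attenuation of the evidence mean for stimuli shown at
        a given compression ratio (keys are ratios; 1.0 is implicit).
    """

    dprime_max: float = 2.2
    learn_tau: float = 4.0
    criterion: float = 0.0
    lapse: float = 0.05
    mem_weight: float = 0.0
    mem_rate: float = 0.1
    compression_attenuation: Mapping[float, float] = field(
        default_factory=lambda: {0.07: 0.5, 0.04: 0.4}
    )

    def __post_init__(self) -> None:
        if self.dprime_max < 0:
            raise ValueError("dprime_max must be >= 0")
        if self.learn_tau <= 0:
            raise ValueError("learn_tau must be > 0")
        if not (0.0 <= self.lapse <= 0.5):
            raise ValueError("lapse must be in [0, 0.5]")
        if not (0.0 <= self.mem_weight <= 1.0):
            raise ValueError("mem_weight must be in [0, 1]")
        if not (0.0 < self.mem_rate <= 1.0):
            raise ValueError("mem_rate must be in (0, 1]")


def feature_learner_params(**overrides) -> ObserverParams:
    """Preset for a feature-generalizing observer (novel ~= familiar)."""
    return ObserverParams(**{**dict(dprime_max=2.2, learn_tau=4.0, lapse=0.05,
                                    mem_weight=0.0), **overrides})


def memorizer_params(**overrides) -> ObserverParams:
    """Preset for a rote memorizer: trained stimuli above chance via the
    exemplar store, novel stimuli at chance (no usable feature channel)."""
    return ObserverParams(**{**dict(dprime_max=0.0, learn_tau=10.0, lapse=0.35,
                                    mem_weight=1.0, mem_rate=0.2), **overrides})


@dataclass(frozen=True)
class LatentStimulus:
    """Ground truth plus latent per-stimulus difficulty."""

    stimulus_id: str
    true_label: str
    evidence_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.true_label not in CHOICES:
            raise ValueError(f"invalid label {self.true_label!r}")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level simulation settings.

    With ``shared_difficulty`` the same per-stimulus offsets apply to every
    observer, inducing inter-observer correlation in errors; otherwise each
    observer receives independently resampled offsets of the same spread.
    """

    n_observers: int = 4
    shared_difficulty: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_observers < 1:
            raise ValueError("n_observers must be >= 1")


def dprime_at(params: ObserverParams, session_t: float) -> float:
    """Class separation after ``session_t`` sessions of training."""
    if session_t < 0:
        raise ValueError("session_t must be >= 0")
    return params.dprime_max * (1.0 - np.exp(-session_t / params.learn_tau))


def feature_evidence(
    stimulus: LatentStimulus,
    observer: ObserverParams,
    session_t: float,
    rng: np.random.Generator,
    attenuation: float = 1.0,
) -> float:
    """Draw one evidence sample for a stimulus from the binormal core.

    The positive class shifts evidence rightward.  The per-stimulus offset is
    signed by the true label, so positive offsets aid a correct response for
    either class.
    """
    sign = 1.0 if stimulus.true_label == "positive" else -1.0
    d = dprime_at(observer, session_t)
    mean = sign * attenuation * (d / 2.0 + stimulus.evidence_offset)
    return float(rng.normal(mean, 1.0))


class SimulatedObserver:
    """Stateful agent implementing the trial-engine protocol.

    The observer holds its parameters, a map of latent stimuli, a private
    random generator, the current session index (which drives the learning
    curve) and the exemplar memory populated by reinforced exposures.
    """

    def __init__(
        self,
        params: ObserverParams,
        latent: Mapping[str, LatentStimulus],
        rng: np.random.Generator,
        observer_id: str = "obs",
    ) -> None:
        self.params = params
        self.latent = dict(latent)
        self.rng = rng
        self.observer_id = observer_id
        self.session_t: float = 0.0
        self.memory: dict[str, str] = {}

    def begin_session(self, session_t: float) -> None:
        self.session_t = float(session_t)

    def choose(
        self, stimulus_id: str, orientation: str = "r0", compression_ratio: float = 1.0
    ) -> str:
        p = self.params
        if p.lapse > 0 and self.rng.random() < p.lapse:
            return CHOICES[self.rng.integers(2)]
        if p.mem_weight > 0 and self.rng.random() < p.mem_weight:
            stored = self.memory.get(stimulus_id)
            if stored is None:
                return CHOICES[self.rng.integers(2)]
            return stored
        stim = self.latent[stimulus_id]
        atten = 1.0
        if compression_ratio != 1.0:
            atten = p.compression_attenuation.get(compression_ratio, 1.0)
        x = feature_evidence(stim, p, self.session_t, self.rng, attenuation=atten)
        return "positive" if x > p.criterion else "negative"

    def observe_outcome(
        self, stimulus_id: str, choice: str, correct: bool, reinforced: bool
    ) -> None:
        """Learning update, called by the trial engine on differential trials.

        A reinforced (correct) exposure stores the exemplar's label with
        probability ``mem_rate``; reinforcement on differential trials only
        is what keeps nondifferential testing from teaching the test items.
        """
        if reinforced and stimulus_id not in self.memory:
            if self.rng.random() < self.params.mem_rate:
                self.memory[stimulus_id] = choice


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


def make_latent_stimuli(
    labels: Mapping[str, str],
    rng: np.random.Generator,
    offset_sd: float = DEFAULT_OFFSET_SD,
) -> list[LatentStimulus]:
    """Latent stimuli with offsets drawn Normal(0, offset_sd^2), in sorted
    id order for reproducibility."""
    ids = sorted(labels)
    offsets = rng.normal(0.0, offset_sd, size=len(ids))
    return [
        LatentStimulus(stimulus_id=i, true_label=labels[i], evidence_offset=float(o))
        for i, o in zip(ids, offsets)
    ]


def simulate_cohort(
    spec: CohortSpec,
    params: Sequence[ObserverParams],
    plans: Sequence[SessionPlan] | Mapping[str, Sequence[SessionPlan]],
    stimuli: Sequence[LatentStimulus],
    labels: Mapping[str, str] | None = None,
    observer_ids: Sequence[str] | None = None,
    offset_sd: float = DEFAULT_OFFSET_SD,
    session_t0: float = 0.0,
    max_corrections: int = 50,
) -> pd.DataFrame:
    """Run a cohort of simulated observers through a chronology of sessions.

    ``plans`` is either one shared list (every observer runs the same
    chronology, as in full-set phases) or a mapping from observer id to its
    own list (counterbalanced training).  The plan position, offset by
    ``session_t0``, drives each observer's learning clock.  All randomness
    descends from ``spec.seed``; rerunning reproduces every record.
    """
    if len(params) != spec.n_observers:
        raise ValueError(
            f"expected {spec.n_observers} parameter sets, got {len(params)}"
        )
    if observer_ids is None:
        observer_ids = [f"bird{i + 1}" for i in range(spec.n_observers)]
    if len(observer_ids) != spec.n_observers:
        raise ValueError("observer_ids length must match n_observers")

    if labels is None:
        labels = {s.stimulus_id: s.true_label for s in stimuli}
    shared = {s.stimulus_id: s for s in stimuli}

    children = np.random.SeedSequence(spec.seed).spawn(spec.n_observers)
    all_records = []
    for i, (oid, p) in enumerate(zip(observer_ids, params)):
        rng = np.random.default_rng(children[i])
        if spec.shared_difficulty:
            latent = shared
        else:
            resampled = make_latent_stimuli(labels, rng, offset_sd=offset_sd)
            latent = {s.stimulus_id: s for s in resampled}
        agent = SimulatedObserver(p, latent, rng, observer_id=oid)
        own_plans = plans[oid] if isinstance(plans, Mapping) else plans
        for t, plan in enumerate(own_plans):
            agent.begin_session(session_t0 + t)
            all_records += run_session(
                agent, plan, labels, observer_id=oid, max_corrections=max_corrections
            )
    return records_to_frame(all_records)


def simulate_detection_table(
    stimuli: Sequence[LatentStimulus],
    params: Sequence[ObserverParams],
    seed: int = 0,
    shared_difficulty: bool = True,
    session_t: float = 1000.0,
    offset_sd: float = DEFAULT_OFFSET_SD,
) -> pd.DataFrame:
    """One nondifferential response per (observer, stimulus) at a fixed point
    on the learning curve — the single-day table the flock score consumes."""
    from .session_engine import SessionPlan, TrialSpec

    trials = tuple(
        TrialSpec(
            index=i,
            stimulus_id=s.stimulus_id,
            reinforcement="nondifferential",
            condition="test_novel",
        )
        for i, s in enumerate(sorted(stimuli, key=lambda s: s.stimulus_id))
    )
    plan = SessionPlan(day=1, trials=trials, phase="novel_test")
    spec = CohortSpec(
        n_observers=len(params), shared_difficulty=shared_difficulty, seed=seed
    )
    return simulate_cohort(
        spec, params, [plan], stimuli, offset_sd=offset_sd, session_t0=session_t
    )


# ---------------------------------------------------------------------------
# Maximum-likelihood recovery of the learning asymptote
# ---------------------------------------------------------------------------


def fit_dprime_max(
    records: pd.DataFrame,
    learn_tau: float,
    lapse: float = 0.0,
    offset_sd: float = 0.0,
    bounds: tuple[float, float] = (0.0, 8.0),
) -> float:
    """Recover ``dprime_max`` from scored records by maximum likelihood.

    Scored (non-correction) trials are pooled by day; days are mapped in
    chronological order onto the session clock.  With a neutral criterion the
    per-trial success probability is

        p(t) = lapse/2 + (1 - lapse) * Phi( d(t) / (2 * sqrt(1 + offset_sd^2)) )

    where the offset variance term integrates the binormal core over the
    per-stimulus difficulty distribution.  The other observer parameters are
    assumed known (the fit is a one-dimensional likelihood problem).
    """
    scored = records[~records["is_correction_trial"]]
    if scored.empty:
        raise ValueError("no scored trials to fit")
    by_day = scored.groupby("day")["correct"].agg(["sum", "size"])
    by_day = by_day.sort_index()
    t = np.arange(len(by_day), dtype=float)
    k = by_day["sum"].to_numpy(dtype=float)
    n = by_day["size"].to_numpy(dtype=float)
    shrink = 2.0 * np.sqrt(1.0 + offset_sd**2)

    def nll(dmax: float) -> float:
        d = dmax * (1.0 - np.exp(-t / learn_tau))
        p = lapse / 2.0 + (1.0 - lapse) * ndtr(d / shrink)
        p = np.clip(p, 1e-12, 1.0 - 1e-12)
        return float(-(k * np.log(p) + (n - k) * np.log1p(-p)).sum())

    res = minimize_scalar(nll, bounds=bounds, method="bounded",
                          options={"xatol": 1e-6})
    return float(res.x)
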