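"""Synthetic learner cohorts: per-trial RT and accuracy for simulated subjects.

The experiment's dependent variables (response time, correctness, timeouts)
are generated from a small family of learner models crossed with a lognormal
response-time model:

* **static** — no learning; every prediction stays at chance.
* **sequential** — tracks first-order transitional regularities with an
  exponentially weighted estimate per left context (after a 0, after 11,
  after a single 1).  It acquires the First and Second Laws but treats the
  ambiguous single-1 context as exactly that: ambiguous.
* **structural** — the sequential learner plus hierarchy: once its
  First-Law estimate is confident, it segments the stream into [01] chunks
  on line, indexes the stranded 1s (k-points), and projects the next
  k-point from the {3, 5} gap metric and its succession rules (after a
  3-gap the next k is 5 away; after two 5-gaps it is 3 away).  Trials at a
  determinately projected k-slot receive an extra anticipation benefit.
  On a Skip stream the projections are no better than chance, so the
  benefit evaporates — which is what dissociates the grammars.

Response times are lognormal around a subject-specific base, slowed by a
congruency penalty and sped up by anticipation; draws beyond the 1000 ms
deadline are recorded as timeouts and counted as errors.  Correctness on
answered trials is Bernoulli with per-congruency probabilities.  Defaults
are calibrated so a 22-subject cohort reproduces the descriptive structure
of the study (block-1 first-law cell means near 504 / 699 ms, overall
accuracy near 91%).

Learner predictions depend only on the symbol stream, never on the RNG, so
a learner trace can be computed once per trial sequence and reused across
subjects and replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .trials import TrialRecord, ExperimentConfig, build_trials

__all__ = [
    "LearnerSpec",
    "RTParams",
    "LearnerTrace",
    "ParameterError",
    "predictive_probability",
    "learner_trace",
    "simulate_subject",
    "simulate_cohort",
    "COHORT_COLUMNS",
]

COHORT_COLUMNS = [
    "subject", "trial", "block", "grammar", "congruency",
    "a1", "a2", "a3", "is_k", "rt_ms", "timeout", "correct",
]

CONTEXTS = ("start", "after-0", "after-11", "after-single-1")


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class LearnerSpec:
    """Which learner to simulate and how strongly learning shapes RT.

    ``learning_rate`` is the exponential update weight λ of the
    transitional-probability estimates; ``anticipation_gain`` the maximal
    RT benefit (ms) for a confidently predicted symbol;
    ``confidence_threshold`` the predictive probability a context estimate
    must exceed before anticipation kicks in (no ambiguous context can
    reach it, so the benefit expresses acquired *laws*, not raw symbol
    frequencies); ``k_gain`` the extra benefit (ms) at a projected k-slot;
    ``first_law_threshold`` the First-Law confidence at which the
    structural learner switches k-tracking on.
    """

    kind: str = "structural"  # static | sequential | structural
    learning_rate: float = 0.02
    anticipation_gain: float = 70.0
    k_gain: float = 40.0
    first_law_threshold: float = 0.7
    confidence_threshold: float = 0.8

    def __post_init__(self) -> None:
        if self.kind not in ("static", "sequential", "structural"):
            raise ParameterError(f"unknown learner kind {self.kind!r}")
        if not 0 < self.learning_rate <= 1:
            raise ParameterError("learning_rate must be in (0, 1]")
        if self.anticipation_gain < 0 or self.k_gain < 0:
            raise ParameterError("gains must be >= 0")
        if not 0.5 < self.first_law_threshold < 1:
            raise ParameterError("first_law_threshold must be in (0.5, 1)")
        if not 0.5 < self.confidence_threshold < 1:
            raise ParameterError("confidence_threshold must be in (0.5, 1)")


@dataclass(frozen=True)
class RTParams:
    """Generative response-time and accuracy parameters (ms throughout)."""

    base_mean: float = 505.0
    subject_sd: float = 85.0
    congruency_penalty: float = 195.0
    practice_decay: float = 0.0  # proportional RT reduction per 100 trials
    noise_sd: float = 0.18      # SD of Gaussian noise on log-RT
    deadline: float = 1000.0
    accuracy: dict = field(
        default_factory=lambda: {"congruent": 0.96, "incongruent": 0.70}
    )

    def __post_init__(self) -> None:
        if self.base_mean <= 0:
            raise ParameterError("base_mean must be positive")
        if not 0 <= self.practice_decay < 1:
            raise ParameterError("practice_decay must be in [0, 1)")
        if self.subject_sd < 0 or self.noise_sd < 0:
            raise ParameterError("spreads must be >= 0")
        if self.deadline <= 0:
            raise ParameterError("deadline must be positive")
        for key in ("congruent", "incongruent"):
            p = self.accuracy[key]
            if not 0 <= p <= 1:
                raise ParameterError(f"accuracy[{key!r}] must be in [0, 1]")


@dataclass
class LearnerState:
    """Running state of a learner over a symbol stream."""

    spec: LearnerSpec
    # P(next symbol is 1 | context), exponentially updated, chance-initialised
    p_one: dict = field(
        default_factory=lambda: {c: 0.5 for c in CONTEXTS}
    )
    t: int = 0                       # 0-based index of the next symbol
    history: tuple = ()              # last two symbols
    last_k: int | None = None        # 0-based position of last stranded 1
    last_gap: int | None = None
    prev_gap: int | None = None
    projected_k: int | None = None   # determinate projection, 0-based


def _context(history: tuple) -> str:
    if not history:
        return "start"
    if history[-1] == "0":
        return "after-0"
    if len(history) >= 2 and history[-2] == "1":
        return "after-11"
    return "after-single-1"


def predictive_probability(
    state: LearnerState, observed: str
) -> tuple[dict, bool, LearnerState]:
    """Predict the next symbol, then update on the observed one.

    Returns ``(probs, predicted_k, state)`` where ``probs`` maps each
    alphabet symbol to its predicted probability *before* observing
    ``observed``, and ``predicted_k`` is True when the structural learner
    determinately projects a k-point at the current slot.  The state is
    mutated in place and returned for convenience.
    """
    spec = state.spec
    ctx = _context(state.history)
    if spec.kind == "static":
        p1 = 0.5
    else:
        p1 = state.p_one[ctx]
    predicted_k = (
        spec.kind == "structural"
        and state.projected_k is not None
        and state.t == state.projected_k
    )
    probs = {"0": 1.0 - p1, "1": p1}

    # --- update on the observation ---
    if spec.kind != "static" and ctx != "start":
        lam = spec.learning_rate
        state.p_one[ctx] = (1 - lam) * state.p_one[ctx] + lam * (observed == "1")

    if spec.kind == "structural":
        tracking = state.p_one["after-0"] >= spec.first_law_threshold
        is_stranded = observed == "1" and (
            state.t == 0 or (state.history and state.history[-1] == "1")
        )
        if is_stranded:
            if state.last_k is not None:
                gap = state.t - state.last_k
                state.prev_gap, state.last_gap = state.last_gap, gap
                if tracking:
                    if gap == 3:
                        state.projected_k = state.t + 5
                    elif gap == 5 and state.prev_gap == 5:
                        state.projected_k = state.t + 3
                    else:
                        state.projected_k = None
                else:
                    state.projected_k = None
            state.last_k = state.t

    state.history = (state.history + (observed,))[-2:]
    state.t += 1
    return probs, predicted_k, state


@dataclass(frozen=True)
class LearnerTrace:
    """Per-trial learner outputs along one symbol stream (deterministic)."""

    p_correct: np.ndarray      # probability assigned to the symbol shown
    predicted_k: np.ndarray    # bool, determinate k-slot projections
    benefit: np.ndarray        # anticipation benefit in ms per trial


def learner_trace(spec: LearnerSpec, symbols: str) -> LearnerTrace:
    """Run a learner over a symbol stream and derive per-trial RT benefits.

    The anticipation benefit ramps linearly from 0 at the confidence
    threshold θ to ``anticipation_gain`` at certainty:
    ``gain * max(0, (p - θ) / (1 - θ))``.  A determinately projected k-slot
    is fully predicted — the otherwise-ambiguous point becomes
    deterministic for the structural learner — so it earns the full
    ``anticipation_gain`` plus the structural ``k_gain``.
    """
    state = LearnerState(spec=spec)
    n = len(symbols)
    p_correct = np.empty(n)
    predicted_k = np.zeros(n, dtype=bool)
    for t, sym in enumerate(symbols):
        probs, pk, state = predictive_probability(state, sym)
        p_correct[t] = probs[sym]
        predicted_k[t] = pk
    theta = spec.confidence_threshold
    ramp = spec.anticipation_gain * np.clip(
        (p_correct - theta) / (1 - theta), 0.0, 1.0
    )
    benefit = np.where(
        predicted_k, spec.anticipation_gain + spec.k_gain, ramp
    )
    return LearnerTrace(p_correct=p_correct, predicted_k=predicted_k, benefit=benefit)


def _core_rt(
    trials_incongruent: np.ndarray,
    benefit: np.ndarray,
    intercept: float,
    rt: RTParams,
) -> np.ndarray:
    n = benefit.shape[0]
    t_idx = np.arange(n)
    core = (
        intercept * (1 - rt.practice_decay * t_idx / 100.0)
        + rt.congruency_penalty * trials_incongruent
        - benefit
    )
    return np.maximum(core, 50.0)  # floor: a response is never instantaneous


def simulate_subject(
    trials: list[TrialRecord],
    learner: LearnerSpec,
    rt: RTParams,
    seed,
    trace: LearnerTrace | None = None,
) -> pd.DataFrame:
    """Simulate one subject over a labelled trial sequence.

    Returns a frame with ``rt_ms`` (NaN on timeout), ``timeout`` and
    ``correct`` columns, one row per trial.  ``seed`` may be an int or a
    :class:`numpy.random.SeedSequence`; identical inputs give identical
    output.
    """
    rng = np.random.default_rng(seed)
    if trace is None:
        trace = learner_trace(learner, "".join(t.symbol for t in trials))
    incong = np.array([t.congruency == "incongruent" for t in trials], float)
    intercept = rt.base_mean + rng.normal(0.0, rt.subject_sd)
    intercept = max(intercept, 150.0)
    core = _core_rt(incong, trace.benefit, intercept, rt)
    draws = core * np.exp(rng.normal(0.0, rt.noise_sd, size=core.shape))
    timeout = draws >= rt.deadline
    p_acc = np.where(incong == 1.0, rt.accuracy["incongruent"], rt.accuracy["congruent"])
    correct = (rng.random(core.shape) < p_acc) & ~timeout
    rt_ms = np.where(timeout, np.nan, draws)
    return pd.DataFrame(
        {
            "trial": [t.index for t in trials],
            "block": [t.block for t in trials],
            "grammar": [t.grammar for t in trials],
            "congruency": [t.congruency for t in trials],
            "a1": [t.a1_target for t in trials],
            "a2": [t.a2_target for t in trials],
            "a3": [t.a3_target for t in trials],
            "is_k": [t.is_k for t in trials],
            "rt_ms": rt_ms,
            "timeout": timeout,
            "correct": correct,
        }
    )


def simulate_cohort(
    n_subjects: int = 22,
    learner: LearnerSpec | None = None,
    rt: RTParams | None = None,
    master_seed: int = 0,
    trials: list[TrialRecord] | None = None,
) -> pd.DataFrame:
    """Simulate a cohort; per-subject independent substreams from one seed."""
    if n_subjects < 2:
        raise ParameterError("need at least 2 subjects for a within-subject design")
    learner = learner or LearnerSpec()
    rt = rt or RTParams()
    if trials is None:
        trials = _default_trials()
    trace = learner_trace(learner, "".join(t.symbol for t in trials))
    streams = np.random.SeedSequence(master_seed).spawn(n_subjects)
    frames = []
    for s, stream in enumerate(streams, start=1):
        frame = simulate_subject(trials, learner, rt, stream, trace=trace)
        frame.insert(0, "subject", s)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)[COHORT_COLUMNS]


@lru_cache(maxsize=1)
def _default_trials() -> list[TrialRecord]:
    return build_trials(ExperimentConfig())
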