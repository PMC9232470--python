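"""Fixed-step n-down/1-up staircases in log coherence.

The staircase adjusts motion coherence on a log10 scale: one error moves the
level up (easier) by 0.1 log units, ``n`` consecutive correct responses move
it down (harder) by 0.074 log units.  With this 0.74 down/up step ratio a
two-down/one-up rule converges to the coherence where an observer is ~74%
correct, and a three-down/one-up rule to ~83% (the converged level is set by
the rule and step ratio, not by the observer's psychometric slope).

Runs start at a supra-threshold coherence of 31.6% and terminate after a fixed
number of reversals (default 10); the threshold is the mean of the coherences
at the last ``stop_reversals - 1`` reversals.  Two staircases (2-down and
3-down) can be run interleaved, alternating trial by trial, to yield a lower
(c_low) and a higher (c_high) coherence threshold for one observer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "StaircaseState",
    "LogisticObserver",
    "staircase_step",
    "run_staircase",
    "run_interleaved",
    "asymptotic_accuracy",
]

UP_STEP = 0.1
DOWN_STEP = 0.074
START_COHERENCE = 0.316


@dataclass(frozen=True)
class StaircaseState:
    """State of one n-down/1-up staircase in log10 coherence."""

    rule: int
    log10_coherence: float = field(default=math.log10(START_COHERENCE))
    up_step: float = UP_STEP
    down_step: float = DOWN_STEP
    consecutive_correct: int = 0
    last_move: str = "none"  # direction of the last level change
    reversal_levels: tuple[float, ...] = ()
    trial_count: int = 0

    def __post_init__(self) -> None:
        if self.rule < 1:
            raise ValueError("rule must be a positive integer (n-down/1-up)")
        if self.up_step <= 0 or self.down_step <= 0:
            raise ValueError("step sizes must be positive")

    @property
    def coherence(self) -> float:
        return 10.0 ** self.log10_coherence


@dataclass(frozen=True)
class LogisticObserver:
    """Logistic psychometric function in log10 coherence, zero lapse.

    ``P(correct | c) = 0.5 + 0.5 / (1 + exp(-slope * (log10 c - log10 c_mid)))``
    so ``c_mid`` is the coherence at 75% correct.  The default slope of 8 per
    log10 unit is typical of coherence psychometric functions and smooth on the
    scale of the staircase steps (0.074-0.1 log units).
    """

    c_mid: float = 0.12
    slope: float = 8.0

    def __post_init__(self) -> None:
        if not (0 < self.c_mid < 1):
            raise ValueError("c_mid must be a coherence in (0, 1)")
        if self.slope <= 0:
            raise ValueError("slope must be positive for a monotone observer")

    def p_correct(self, coherence: float | np.ndarray) -> float | np.ndarray:
        x = np.log10(coherence) - math.log10(self.c_mid)
        return 0.5 + 0.5 / (1.0 + np.exp(-self.slope * x))

    def __call__(self, coherence):
        return self.p_correct(coherence)


def staircase_step(state: StaircaseState, correct: bool) -> StaircaseState:
    """Advance the staircase by one trial outcome; returns the new state.

    An error moves the level up by ``up_step`` immediately; the ``rule``-th
    consecutive correct response moves it down by ``down_step``.  A reversal is
    recorded (at the pre-move level) whenever the direction of a level change
    differs from the previous change.  Coherence is clipped at 100%
    (log10 = 0), with the run counter reset on clipping.
    """
    log_c = state.log10_coherence
    reversals = state.reversal_levels
    move = None
    if correct:
        n_correct = state.consecutive_correct + 1
        if n_correct >= state.rule:
            move = "down"
            new_log_c = log_c - state.down_step
            n_correct = 0
        else:
            new_log_c = log_c
    else:
        n_correct = 0
        move = "up"
        new_log_c = log_c + state.up_step

    last_move = state.last_move
    if move is not None:
        if state.last_move != "none" and move != state.last_move:
            reversals = reversals + (10.0 ** log_c,)
        last_move = move
        if new_log_c > 0.0:  # ceiling: coherence cannot exceed 100%
            new_log_c = 0.0
            n_correct = 0
    else:
        new_log_c = log_c

    return replace(
        state,
        log10_coherence=new_log_c,
        consecutive_correct=n_correct,
        last_move=last_move,
        reversal_levels=reversals,
        trial_count=state.trial_count + 1,
    )


@dataclass(frozen=True)
class StaircaseRun:
    """Full record of one staircase run."""

    threshold: float
    final_state: StaircaseState
    coherences: np.ndarray  # level presented on each trial
    correct: np.ndarray
    reversal_trial: np.ndarray  # True where a reversal was recorded


def _check_observer(observer, coherence: float) -> float:
    p = float(observer(coherence))
    if not (0.5 <= p < 1.0):
        raise ValueError(
            f"observer returned P(correct)={p:.3f} outside [0.5, 1) at c={coherence:.4f}"
        )
    return p


def run_staircase(
    rule: int,
    observer,
    stop_reversals: int = 10,
    start_coherence: float = START_COHERENCE,
    rng: np.random.Generator | int | None = None,
    max_trials: int = 100_000,
) -> StaircaseRun:
    """Run one staircase against a simulated observer until ``stop_reversals``.

    The threshold is the mean of the coherences at the last
    ``stop_reversals - 1`` reversals.  ``observer`` maps coherence to
    P(correct) and must return values in [0.5, 1).
    """
    if stop_reversals < 2:
        raise ValueError("stop_reversals must be >= 2")
    rng = np.random.default_rng(rng)
    state = StaircaseState(rule=rule, log10_coherence=math.log10(start_coherence))
    coherences, corrects, flags = [], [], []
    while len(state.reversal_levels) < stop_reversals:
        if state.trial_count >= max_trials:
            raise RuntimeError("staircase failed to terminate within max_trials")
        c = state.coherence
        p = _check_observer(observer, c)
        correct = bool(rng.random() < p)
        n_rev = len(state.reversal_levels)
        state = staircase_step(state, correct)
        coherences.append(c)
        corrects.append(correct)
        flags.append(len(state.reversal_levels) > n_rev)
    levels = np.array(state.reversal_levels[-(stop_reversals - 1):])
    return StaircaseRun(
        threshold=float(levels.mean()),
        final_state=state,
        coherences=np.array(coherences),
        correct=np.array(corrects),
        reversal_trial=np.array(flags),
    )


def run_interleaved(
    observer,
    stop_reversals: int = 10,
    start_coherence: float = START_COHERENCE,
    rng: np.random.Generator | int | None = None,
    schedule: str = "alternate",
    max_trials: int = 200_000,
) -> tuple[float, float, dict]:
    """Run the 2-down and 3-down staircases interleaved on one observer.

    Returns ``(c_low, c_high, histories)`` where c_low is the 2-down/1-up
    threshold (~74% correct) and c_high the 3-down/1-up threshold (~83%).
    Scheduling is strict alternation by default; ``schedule='random'`` draws
    the next staircase at random.  Once one staircase has terminated the other
    continues alone.
    """
    if schedule not in ("alternate", "random"):
        raise ValueError("schedule must be 'alternate' or 'random'")
    rng = np.random.default_rng(rng)
    states = {
        2: StaircaseState(rule=2, log10_coherence=math.log10(start_coherence)),
        3: StaircaseState(rule=3, log10_coherence=math.log10(start_coherence)),
    }
    history: dict[int, dict[str, list]] = {
        r: {"coherence": [], "correct": [], "reversal": []} for r in (2, 3)
    }
    done = {2: False, 3: False}
    turn = 2
    total = 0
    while not all(done.values()):
        if total >= max_trials:
            raise RuntimeError("interleaved staircases failed to terminate")
        active = [r for r in (2, 3) if not done[r]]
        if len(active) == 1:
            r = active[0]
        elif schedule == "alternate":
            r = turn
            turn = 5 - turn  # swap 2 <-> 3
        else:
            r = int(rng.choice(active))
        state = states[r]
        c = state.coherence
        p = _check_observer(observer, c)
        correct = bool(rng.random() < p)
        n_rev = len(state.reversal_levels)
        state = staircase_step(state, correct)
        states[r] = state
        history[r]["coherence"].append(c)
        history[r]["correct"].append(correct)
        history[r]["reversal"].append(len(state.reversal_levels) > n_rev)
        if len(state.reversal_levels) >= stop_reversals:
            done[r] = True
        total += 1
    thresholds = {}
    for r in (2, 3):
        levels = np.array(states[r].reversal_levels[-(stop_reversals - 1):])
        thresholds[r] = float(levels.mean())
    return thresholds[2], thresholds[3], history


def asymptotic_accuracy(
    rule: int,
    observer,
    n_reversals: int = 200,
    rng: np.random.Generator | int | None = None,
    discard_frac: float = 0.5,
) -> float:
    """True observer accuracy at the staircase's converged level.

    Runs the staircase far past its usual 10-reversal termination
    (``n_reversals`` >= 200), averages the late reversal levels in log10
    coherence (the scale the staircase operates on, discarding the first
    ``discard_frac`` as transient), and returns the observer's true P(correct)
    at that level.  For the 0.074/0.1 step ratio this approaches ~0.74 for the
    2-down rule and ~0.83 for the 3-down rule, independent of observer slope.
    """
    if n_reversals < 200:
        raise ValueError("n_reversals must be >= 200 for a converged estimate")
    run = run_staircase(rule, observer, stop_reversals=n_reversals, rng=rng,
                        max_trials=2_000_000)
    levels = np.array(run.final_state.reversal_levels)
    late = levels[int(len(levels) * discard_frac):]
    c_star = 10.0 ** np.mean(np.log10(late))
    return float(observer(c_star))
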