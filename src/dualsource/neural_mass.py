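"""Extended two-population Wong-Wang reduced model for two motion sources.

Two competing neural populations (left / right accumulators) are described by
slow NMDA gating variables ``S_L, S_R``:

    dS/dt = -S / tau_s + (1 - S) * gamma * H(x)
    H(x)  = (a_H x - b_H) / (1 - exp(-d_H (a_H x - b_H)))

with total synaptic input ``x_L = J_self S_L - J_cross S_R + I_in,L + I_noise,L``
(and symmetrically for R).  The deterministic input currents extend the
single-source model to two coherence sources c1 (dominant, |c1| >= |c2|) and
c2:

    I_in,L = J_ext [ alpha mu (1 + c1) + (1 - alpha) mu (1 + c2) ] + beta I_0
    I_in,R = J_ext [ alpha mu (1 - c1) + (1 - alpha) mu (1 - c2) ] + beta I_0

``alpha`` splits the sensory weight between the two sources (alpha = 0.5 is
equal weighting; the two weights always sum to mu, the single-source weight),
and ``beta`` scales the non-selective background current.  ``beta`` is applied
only in the incongruent double-source condition; all other conditions run at
beta = 1.  Raising beta excites both populations non-selectively, which
destabilizes the undecided state and effectively lowers the decision
threshold: the model's speed-accuracy trade-off mechanism.

The first population whose firing rate H(x) crosses a threshold (default
15 Hz) renders the choice; a fixed non-decision offset is added to the
crossing time.  Noise currents are Ornstein-Uhlenbeck with a 2-ms time
constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
from numba import njit

__all__ = [
    "NMParams",
    "NMCondition",
    "ConditionPerformance",
    "PatternVerdict",
    "DeltaMaps",
    "standard_conditions",
    "input_currents",
    "simulate_nm_trial",
    "condition_performance",
    "qualitative_pattern",
    "sweep_alpha_beta",
]

CONDITIONS = ("CON", "CON_BSL", "INC", "INC_BSL")


@dataclass(frozen=True)
class NMParams:
    """Constants of the reduced two-variable model and its two extensions.

    The input-current constants (``j_ext``, ``i0``, ``mu``) follow the
    two-source extension; the reduced-model constants (transfer function,
    kinetics, couplings, noise) are the published defaults of the reduced
    two-variable attractor model.  All are configurable.
    """

    j_ext: float = 5.2e-4  # nA * Hz^-1, average synaptic coupling
    i0: float = 0.321      # nA, background current baseline
    mu: float = 35.0       # Hz, input-strength baseline
    alpha: float = 0.5     # weight of the dominant source, in [0, 1]
    beta: float = 1.0      # background scaling (applied to INC only)
    # reduced-model constants
    a_h: float = 270.0     # Hz/nA, transfer gain
    b_h: float = 108.0     # Hz, transfer threshold
    d_h: float = 0.154     # s, transfer curvature
    gamma: float = 0.641   # kinetic factor
    tau_s: float = 0.100   # s, NMDA gating time constant
    j_self: float = 0.2609   # nA, self-coupling
    j_cross: float = 0.0497  # nA, cross-coupling (inhibition)
    sigma_noise: float = 0.02  # nA, noise current amplitude
    tau_noise: float = 0.002   # s, noise time constant
    threshold: float = 15.0    # Hz, decision threshold on the population rate
    t_nondecision: float = 0.3  # s, fixed offset added to crossing time
    dt: float = 0.0005     # s, Euler step
    t_max: float = 4.0     # s, response window

    def __post_init__(self) -> None:
        for name in ("j_ext", "i0", "mu", "tau_s", "tau_noise", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        if self.dt > 0.001:
            raise ValueError("dt must be <= 1 ms")


@dataclass(frozen=True)
class NMCondition:
    """A stimulus condition: signed coherences of the two sources plus label."""

    c1: float
    c2: float
    label: str

    def __post_init__(self) -> None:
        if abs(self.c1) < abs(self.c2):
            raise ValueError("c1 must be the dominant source (|c1| >= |c2|)")
        if self.label not in CONDITIONS:
            raise ValueError(f"unknown condition label {self.label!r}")


def standard_conditions(
    c_high: float = 0.20, c_low: float = 0.15, direction: int = +1
) -> dict[str, NMCondition]:
    """The four experimental conditions at representative coherence levels.

    ``direction=+1`` encodes leftward net motion (positive coherences);
    -1 flips all signs.  Encodings (leftward): CON c1=c_low, c2=c_high-c_low;
    CON_BSL c1=c_high, c2=0; INC c1=c_high, c2=-(c_high-c_low);
    INC_BSL c1=c_low, c2=0.
    """
    if not (0 < c_low < c_high < 1):
        raise ValueError("need 0 < c_low < c_high < 1")
    d = float(direction)
    return {
        "CON": NMCondition(d * c_low, d * (c_high - c_low), "CON"),
        "CON_BSL": NMCondition(d * c_high, 0.0, "CON_BSL"),
        "INC": NMCondition(d * c_high, -d * (c_high - c_low), "INC"),
        "INC_BSL": NMCondition(d * c_low, 0.0, "INC_BSL"),
    }


def input_currents(p: NMParams, cond: NMCondition) -> tuple[float, float]:
    """Deterministic input currents (I_in,L, I_in,R) in nA.

    ``beta`` multiplies the background current only for the incongruent
    double-source condition (label INC); all other conditions use beta = 1.
    """
    beta = p.beta if cond.label == "INC" else 1.0
    sel_l = p.j_ext * (p.alpha * p.mu * (1 + cond.c1) + (1 - p.alpha) * p.mu * (1 + cond.c2))
    sel_r = p.j_ext * (p.alpha * p.mu * (1 - cond.c1) + (1 - p.alpha) * p.mu * (1 - cond.c2))
    bg = beta * p.i0
    return sel_l + bg, sel_r + bg


@njit(cache=True)
def _transfer(x, a_h, b_h, d_h):
    y = a_h * x - b_h
    z = d_h * y
    if abs(z) < 1e-9:
        return 1.0 / d_h
    return y / (1.0 - math.exp(-z))


@njit(cache=True)
def _nm_batch(
    n, i_l, i_r, a_h, b_h, d_h, gamma, tau_s, j_self, j_cross,
    sigma, tau_n, thresh, t0, dt, t_max, s_init, seed,
):
    """Simulate n trials; returns (choice, rt): choice 1=L, 0=R, -1=timeout."""
    np.random.seed(seed)
    choice = np.empty(n, dtype=np.int8)
    rts = np.full(n, np.nan)
    n_steps = int(t_max / dt)
    noise_scale = sigma * math.sqrt(dt / tau_n)
    for i in range(n):
        s_l = s_init
        s_r = s_init
        in_l = 0.0
        in_r = 0.0
        ch = np.int8(-1)
        for step in range(1, n_steps + 1):
            x_l = j_self * s_l - j_cross * s_r + i_l + in_l
            x_r = j_self * s_r - j_cross * s_l + i_r + in_r
            r_l = _transfer(x_l, a_h, b_h, d_h)
            r_r = _transfer(x_r, a_h, b_h, d_h)
            if r_l >= thresh or r_r >= thresh:
                if r_l > r_r:
                    ch = np.int8(1)
                elif r_r > r_l:
                    ch = np.int8(0)
                else:  # exact tie: break by the trial's random stream
                    ch = np.int8(1) if np.random.random() < 0.5 else np.int8(0)
                rts[i] = step * dt + t0
                break
            s_l += dt * (-s_l / tau_s + (1.0 - s_l) * gamma * r_l)
            s_r += dt * (-s_r / tau_s + (1.0 - s_r) * gamma * r_r)
            in_l += dt * (-in_l / tau_n) + noise_scale * np.random.normal()
            in_r += dt * (-in_r / tau_n) + noise_scale * np.random.normal()
        choice[i] = ch
    return choice, rts


S_INIT = 0.1  # symmetric initial gating


def _as_seed(rng: np.random.Generator | int | None) -> int:
    if rng is None:
        rng = np.random.default_rng()
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    return int(rng.integers(0, 2**31 - 1))


def simulate_nm_batch(
    p: NMParams, cond: NMCondition, n: int,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate ``n`` trials of one condition; returns (choice, rt) arrays.

    choice: 1 = left population wins, 0 = right, -1 = no crossing by t_max.
    """
    i_l, i_r = input_currents(p, cond)
    return _nm_batch(
        int(n), i_l, i_r, p.a_h, p.b_h, p.d_h, p.gamma, p.tau_s,
        p.j_self, p.j_cross, p.sigma_noise, p.tau_noise, p.threshold,
        p.t_nondecision, p.dt, p.t_max, S_INIT, _as_seed(rng),
    )


def simulate_nm_trial(
    p: NMParams, cond: NMCondition, rng: np.random.Generator | int | None = None
) -> tuple[str, float]:
    """Simulate one trial; returns (choice in {'L','R','none'}, rt in seconds)."""
    ch, rt = simulate_nm_batch(p, cond, 1, rng=rng)
    name = {1: "L", 0: "R", -1: "none"}[int(ch[0])]
    return name, float(rt[0])


@dataclass(frozen=True)
class ConditionPerformance:
    """Aggregate simulation outcome for one condition."""

    accuracy: float
    mean_rt: float
    timeout_rate: float
    n_completed: int
    rt_se: float = np.nan  # Monte-Carlo standard error of mean_rt


def condition_performance(
    p: NMParams, cond: NMCondition, n_trials: int = 5000,
    rng: np.random.Generator | int | None = None,
) -> ConditionPerformance:
    """Accuracy, mean RT and timeout rate over ``n_trials`` simulations.

    The correct response is the direction of the dominant source (sign of c1).
    Mean RT pools correct and error trials; timeouts are excluded from both
    accuracy and RT and reported separately.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    ch, rt = simulate_nm_batch(p, cond, n_trials, rng=rng)
    completed = ch >= 0
    n_comp = int(completed.sum())
    correct_choice = 1 if cond.c1 > 0 else 0
    if n_comp == 0:
        return ConditionPerformance(np.nan, np.nan, 1.0, 0)
    acc = float(np.mean(ch[completed] == correct_choice))
    rts = rt[completed]
    mean_rt = float(np.mean(rts))
    rt_se = float(np.std(rts) / math.sqrt(n_comp)) if n_comp > 1 else np.nan
    return ConditionPerformance(acc, mean_rt, 1.0 - n_comp / n_trials, n_comp, rt_se)


@dataclass(frozen=True)
class PatternVerdict:
    """Outcome of the qualitative behavioural-pattern test for one cell."""

    qualifies: bool
    indeterminate: bool
    margins: dict


def qualitative_pattern(
    perf: Mapping[str, ConditionPerformance],
    noise_guard_z: float = 1.645,
) -> PatternVerdict:
    """Check the four inequalities of the observed behavioural pattern.

    qualifies is True iff acc(CON) < acc(CON_BSL), rt(CON) > rt(CON_BSL),
    acc(INC) < acc(INC_BSL) and rt(INC) < rt(INC_BSL).  Margins smaller than
    ``noise_guard_z`` Monte-Carlo standard errors of the difference are
    flagged indeterminate (the cell's inequalities could be noise).  The
    default guard (1.645, one-sided 5% per margin) makes a fully null cell
    pass all four guards with probability ~6e-6.
    """
    missing = [c for c in CONDITIONS if c not in perf]
    if missing:
        raise ValueError(f"missing condition summaries: {missing}")

    def acc_se(s: ConditionPerformance) -> float:
        p_ = min(max(s.accuracy, 1e-6), 1 - 1e-6)
        return math.sqrt(p_ * (1 - p_) / max(s.n_completed, 1))

    margins = {
        "d_acc_con": perf["CON_BSL"].accuracy - perf["CON"].accuracy,
        "d_rt_con": perf["CON"].mean_rt - perf["CON_BSL"].mean_rt,
        "d_acc_inc": perf["INC_BSL"].accuracy - perf["INC"].accuracy,
        "d_rt_inc": perf["INC_BSL"].mean_rt - perf["INC"].mean_rt,
    }
    qualifies = all(v > 0 for v in margins.values())
    guards = {
        "d_acc_con": noise_guard_z * math.hypot(acc_se(perf["CON"]), acc_se(perf["CON_BSL"])),
        "d_acc_inc": noise_guard_z * math.hypot(acc_se(perf["INC"]), acc_se(perf["INC_BSL"])),
        "d_rt_con": noise_guard_z * math.hypot(perf["CON"].rt_se, perf["CON_BSL"].rt_se),
        "d_rt_inc": noise_guard_z * math.hypot(perf["INC"].rt_se, perf["INC_BSL"].rt_se),
    }
    indeterminate = any(abs(margins[k]) <= guards[k] for k in margins)
    return PatternVerdict(qualifies=qualifies, indeterminate=indeterminate, margins=margins)


@dataclass(frozen=True)
class DeltaMaps:
    """(alpha, beta) grid of baseline-minus-double performance differences."""

    alphas: np.ndarray
    betas: np.ndarray
    d_acc_con: np.ndarray  # acc(CON_BSL) - acc(CON), shape (n_alpha, n_beta)
    d_rt_con: np.ndarray   # rt(CON) - rt(CON_BSL)
    d_acc_inc: np.ndarray
    d_rt_inc: np.ndarray   # rt(INC_BSL) - rt(INC)
    qualifies: np.ndarray  # bool, pattern holds with margins above the guard
    indeterminate: np.ndarray

    def to_long_table(self):
        import pandas as pd

        rows = []
        for i, a in enumerate(self.alphas):
            for j, b in enumerate(self.betas):
                rows.append(
                    dict(
                        alpha=a, beta=b,
                        d_acc_con=self.d_acc_con[i, j], d_rt_con=self.d_rt_con[i, j],
                        d_acc_inc=self.d_acc_inc[i, j], d_rt_inc=self.d_rt_inc[i, j],
                        qualifies=bool(self.qualifies[i, j]),
                        indeterminate=bool(self.indeterminate[i, j]),
                    )
                )
        return pd.DataFrame(rows)


def sweep_alpha_beta(
    p_base: NMParams,
    grid_alpha: Iterable[float],
    grid_beta: Iterable[float],
    n_trials_per_cond: int = 5000,
    rng: np.random.Generator | int | None = None,
    c_high: float = 0.20,
    c_low: float = 0.15,
    noise_guard_z: float = 1.645,
) -> DeltaMaps:
    """Run the four conditions at every (alpha, beta) cell and map the deltas.

    ``beta`` affects only the INC condition (applied inside input_currents).
    Each cell is classified by :func:`qualitative_pattern` with a Monte-Carlo
    noise guard of ``noise_guard_z`` standard errors.
    """
    alphas = np.asarray(list(grid_alpha), dtype=float)
    betas = np.asarray(list(grid_beta), dtype=float)
    rng = np.random.default_rng(rng)
    conds = standard_conditions(c_high=c_high, c_low=c_low)
    shape = (len(alphas), len(betas))
    maps = {k: np.full(shape, np.nan) for k in ("d_acc_con", "d_rt_con", "d_acc_inc", "d_rt_inc")}
    qual = np.zeros(shape, dtype=bool)
    indet = np.zeros(shape, dtype=bool)
    for i, a in enumerate(alphas):
        for j, b in enumerate(betas):
            p = replace(p_base, alpha=float(a), beta=float(b))
            perf = {
                name: condition_performance(p, cond, n_trials_per_cond, rng=rng)
                for name, cond in conds.items()
            }
            verdict = qualitative_pattern(perf, noise_guard_z=noise_guard_z)
            maps["d_acc_con"][i, j] = verdict.margins["d_acc_con"]
            maps["d_rt_con"][i, j] = verdict.margins["d_rt_con"]
            maps["d_acc_inc"][i, j] = verdict.margins["d_acc_inc"]
            maps["d_rt_inc"][i, j] = verdict.margins["d_rt_inc"]
            qual[i, j] = verdict.qualifies and not verdict.indeterminate
            indet[i, j] = verdict.indeterminate
    return DeltaMaps(
        alphas=alphas, betas=betas,
        d_acc_con=maps["d_acc_con"], d_rt_con=maps["d_rt_con"],
        d_acc_inc=maps["d_acc_inc"], d_rt_inc=maps["d_rt_inc"],
        qualifies=qual, indeterminate=indet,
    )
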