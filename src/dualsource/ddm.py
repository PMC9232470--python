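"""Drift-diffusion trial simulation and the Wiener first-passage-time likelihood.

The model is the basic three-parameter drift-diffusion model (DDM) of
two-alternative forced choice: evidence ``x`` evolves as ``dx = v dt + dW``
(diffusion scale sigma = 1) from an unbiased start point ``a/2`` between
absorbing boundaries at 0 (error) and ``a`` (correct).  Response time is the
first-passage time plus a non-decision latency ``Ter``.

Closed-form results for the unbiased start (sigma = 1):

* probability of reaching the upper (correct) boundary
  ``P(upper) = 1 / (1 + exp(-v a))``
* mean decision time ``(a / 2v) tanh(v a / 2)`` (limit ``a**2 / 4`` at v = 0)

The first-passage density is evaluated with the small-time / large-time series
expansions, switching by the standard term-count criterion at a requested
truncation error (default 1e-7).  The data likelihood is a mixture in which a
fixed fraction of trials (default 5%) is attributed to a uniform outlier
process over both responses and the full response window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "DDMParams",
    "simulate_trial",
    "simulate_trials",
    "choice_probability",
    "mean_decision_time",
    "wfpt_density",
    "trial_loglik",
    "dataset_loglik",
]

DEFAULT_DT = 0.001
DEFAULT_T_MAX = 4.0
DEFAULT_OUTLIER_FRAC = 0.05
_WFPT_EPS = 1e-7


@dataclass(frozen=True)
class DDMParams:
    """Core DDM parameters: drift rate ``v``, threshold ``a``, non-decision ``ter``.

    The start point is fixed at ``a/2`` (unbiased) and the diffusion scale at
    sigma = 1, so ``v`` and ``a`` are in units where one second of accumulation
    has unit noise variance.
    """

    v: float
    a: float
    ter: float

    def __post_init__(self) -> None:
        if not (self.a > 0):
            raise ValueError(f"threshold a must be positive, got {self.a}")
        if self.ter < 0:
            raise ValueError(f"non-decision time must be >= 0, got {self.ter}")


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _fpt_norm_lower(tt: float, w: float, eps: float) -> float:
    """Density of the zero-drift, unit-boundary diffusion hitting the lower
    boundary at normalized time ``tt`` from relative start ``w``.

    Switches between the small-time and large-time series by comparing the
    number of terms each needs for truncation error ``eps``.
    """
    if tt <= 0.0:
        return 0.0
    # number of terms needed by the large-time expansion
    if math.pi * tt * eps < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * tt * eps) / (math.pi * math.pi * tt))
        kl = max(kl, 1.0 / (math.pi * math.sqrt(tt)))
    else:
        kl = 1.0 / (math.pi * math.sqrt(tt))
    # number of terms needed by the small-time expansion
    if 2.0 * math.sqrt(2.0 * math.pi * tt) * eps < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * tt * math.log(2.0 * math.sqrt(2.0 * math.pi * tt) * eps))
        ks = max(ks, math.sqrt(tt) + 1.0)
    else:
        ks = 2.0
    p = 0.0
    if ks < kl:
        K = int(math.ceil(ks))
        lo = -((K - 1) // 2)
        hi = (K - 1) - (K - 1) // 2
        for k in range(lo, hi + 1):
            wk = w + 2.0 * k
            p += wk * math.exp(-wk * wk / (2.0 * tt))
        p /= math.sqrt(2.0 * math.pi * tt * tt * tt)
    else:
        K = int(math.ceil(kl))
        for k in range(1, K + 1):
            p += k * math.exp(-(k * k) * (math.pi * math.pi) * tt / 2.0) * math.sin(k * math.pi * w)
        p *= math.pi
    return p if p > 0.0 else 0.0


@njit(cache=True)
def _wfpt_lower(t: float, v: float, a: float, w: float, eps: float) -> float:
    """First-passage density through the LOWER boundary at decision time ``t``."""
    if t <= 0.0:
        return 0.0
    tt = t / (a * a)
    p = _fpt_norm_lower(tt, w, eps)
    return p * math.exp(-v * a * w - v * v * t / 2.0) / (a * a)


@njit(cache=True)
def _wfpt(t: float, v: float, a: float, upper: bool, eps: float) -> float:
    """First-passage density at either boundary for the unbiased start w=0.5."""
    if upper:
        return _wfpt_lower(t, -v, a, 0.5, eps)
    return _wfpt_lower(t, v, a, 0.5, eps)


@njit(cache=True)
def _trial_loglik(
    rt: float, upper: bool, v: float, a: float, ter: float, q: float, t_max: float
) -> float:
    f = _wfpt(rt - ter, v, a, upper, _WFPT_EPS)
    dens = (1.0 - q) * f + q / (2.0 * t_max)
    if dens <= 0.0:
        return -np.inf
    return math.log(dens)


@njit(cache=True)
def _trials_loglik_sum(rt, upper, v, a, ter, q, t_max) -> float:
    total = 0.0
    for i in range(rt.shape[0]):
        total += _trial_loglik(rt[i], upper[i], v, a, ter, q, t_max)
    return total


@njit(cache=True)
def _simulate_ddm(n, v, a, ter, dt, t_max, seed):
    """Euler-Maruyama paths from a/2; returns (boundary, rt) arrays.

    Within-step boundary crossings are detected with the Brownian-bridge
    crossing probabilities exp(-2(a-x0)(a-x1)/dt) and exp(-2 x0 x1 / dt),
    which removes the O(sqrt(dt)) first-passage bias of the naive scheme.
    boundary: 1 upper, 0 lower, -1 no crossing before t_max - ter.
    """
    np.random.seed(seed)
    boundary = np.empty(n, dtype=np.int8)
    rts = np.full(n, np.nan)
    sdt = math.sqrt(dt)
    # the step budget is ter-independent so that equal seeds yield identical
    # diffusion paths for any non-decision time; crossings later than
    # t_max - ter still count as non-responses
    max_steps = int(math.floor(t_max / dt))
    cutoff = t_max - ter
    for i in range(n):
        x = a / 2.0
        b = np.int8(-1)
        for s in range(1, max_steps + 1):
            x_new = x + v * dt + sdt * np.random.normal()
            crossed = np.int8(-1)
            if x_new >= a:
                crossed = np.int8(1)
            elif x_new <= 0.0:
                crossed = np.int8(0)
            else:
                # bridge crossing probabilities within the step
                p_up = math.exp(-2.0 * (a - x) * (a - x_new) / dt)
                p_dn = math.exp(-2.0 * x * x_new / dt)
                u = np.random.random()
                if u < p_up:
                    crossed = np.int8(1)
                elif u < p_up + p_dn:
                    crossed = np.int8(0)
            if crossed >= 0:
                if s * dt <= cutoff:
                    b = crossed
                    rts[i] = s * dt + ter
                break
            x = x_new
        boundary[i] = b
    return boundary, rts


@njit(cache=True)
def _wfpt_vec(t, v, a, upper, eps):
    out = np.empty(t.shape[0])
    for i in range(t.shape[0]):
        out[i] = _wfpt(t[i], v, a, upper, eps)
    return out


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def _as_seed(rng: np.random.Generator | int | None) -> int:
    """Derive a 32-bit seed for the numba kernels from a Generator or int."""
    if rng is None:
        rng = np.random.default_rng()
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    return int(rng.integers(0, 2**31 - 1))


def simulate_trials(
    params: DDMParams,
    n: int,
    dt: float = DEFAULT_DT,
    t_max: float = DEFAULT_T_MAX,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate ``n`` independent DDM trials.

    Returns ``(boundary, rt)`` where boundary is 1 (upper/correct),
    0 (lower/error) or -1 (no crossing by ``t_max``; rt is NaN there).
    Reported rt includes the non-decision time.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt > 0.005:
        raise ValueError("dt must be <= 0.005 s for acceptable discretization bias")
    if t_max <= params.ter:
        raise ValueError("t_max must exceed the non-decision time")
    return _simulate_ddm(int(n), params.v, params.a, params.ter, dt, t_max, _as_seed(rng))


def simulate_trial(
    params: DDMParams,
    dt: float = DEFAULT_DT,
    t_max: float = DEFAULT_T_MAX,
    rng: np.random.Generator | int | None = None,
) -> tuple[str, float]:
    """Simulate one trial; returns (boundary in {'upper','lower','none'}, rt)."""
    b, rt = simulate_trials(params, 1, dt=dt, t_max=t_max, rng=rng)
    name = {1: "upper", 0: "lower", -1: "none"}[int(b[0])]
    return name, float(rt[0])


def choice_probability(params: DDMParams) -> float:
    """Probability of absorbing at the upper (correct) boundary.

    Closed form for start a/2, sigma = 1: ``1 / (1 + exp(-v a))``; depends on
    the product ``v * a`` only.  Continuous at v = 0 (value 0.5).
    """
    return float(1.0 / (1.0 + np.exp(-params.v * params.a)))


def mean_decision_time(params: DDMParams) -> float:
    """Expected decision time (excluding Ter) for start a/2, sigma = 1."""
    v, a = params.v, params.a
    if v == 0.0:
        return a * a / 4.0
    return float((a / (2.0 * v)) * np.tanh(v * a / 2.0))


def wfpt_density(
    t: float | np.ndarray,
    params: DDMParams,
    boundary: str = "upper",
    eps: float = _WFPT_EPS,
) -> float | np.ndarray:
    """Wiener first-passage-time density at the given boundary.

    ``t`` is decision time (response time minus Ter); t <= 0 yields density 0.
    """
    if boundary not in ("upper", "lower"):
        raise ValueError("boundary must be 'upper' or 'lower'")
    upper = boundary == "upper"
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    out = _wfpt_vec(t_arr, params.v, params.a, upper, eps)
    if np.isscalar(t) or np.asarray(t).ndim == 0:
        return float(out[0])
    return out


def trial_loglik(
    choice: str | bool,
    rt: float,
    params: DDMParams,
    outlier_frac: float = DEFAULT_OUTLIER_FRAC,
    t_max: float = DEFAULT_T_MAX,
) -> float:
    """Log-likelihood of one (choice, rt) datum under the DDM-outlier mixture.

    A fraction ``outlier_frac`` of trials is modelled as uniform over both
    responses and the interval (0, t_max], contributing density
    ``outlier_frac / (2 t_max)``; responses faster than Ter can only arise from
    the outlier process.
    """
    if not (0.0 <= outlier_frac < 1.0):
        raise ValueError("outlier_frac must be in [0, 1)")
    if rt > t_max:
        raise ValueError("rt exceeds the response window t_max")
    if isinstance(choice, str):
        if choice not in ("upper", "lower"):
            raise ValueError("choice must be 'upper' or 'lower'")
        upper = choice == "upper"
    else:
        upper = bool(choice)
    return float(
        _trial_loglik(rt, upper, params.v, params.a, params.ter, outlier_frac, t_max)
    )


def dataset_loglik(
    rts: np.ndarray,
    upper: np.ndarray,
    params: DDMParams,
    outlier_frac: float = DEFAULT_OUTLIER_FRAC,
    t_max: float = DEFAULT_T_MAX,
) -> float:
    """Summed log-likelihood of a response-time dataset under one parameter set."""
    rts = np.ascontiguousarray(rts, dtype=float)
    upper = np.ascontiguousarray(upper, dtype=np.bool_)
    return float(
        _trials_loglik_sum(rts, upper, params.v, params.a, params.ter, outlier_frac, t_max)
    )
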