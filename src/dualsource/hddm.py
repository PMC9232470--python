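"""Hierarchical Bayesian estimation of four DDM variants.

Model.  Each subject ``s`` has DDM parameters (drift ``v``, threshold ``a``,
non-decision ``ter``); a parameter kind either varies by condition (one value
per condition) or is shared across the four conditions, according to the
variant.  Subject-level parameters are drawn from group-level normal
distributions, one (mean, SD) pair per condition-specific parameter, with
``a`` truncated above 0.1 and ``ter`` to [0.05, 1].  Trial likelihood is the
Wiener first-passage density mixed with a 5% uniform outlier component.

The four variants let two or all three of (v, a, ter) vary between
conditions: ``v+a``, ``v+ter``, ``a+ter``, ``v+a+ter``.

Priors (weakly informative, spanning typical 2AFC fits): group means
v ~ N(2, 3); a ~ N(1.5, 1) truncated > 0.1; ter ~ N(0.3, 0.25) truncated to
[0.05, 1]; group SDs half-normal(1).

Sampler.  Component-wise random-walk Metropolis: subject-level parameters are
updated per (kind, condition) block, vectorized across subjects (the
components are conditionally independent given the group level); group means
and SDs are updated by scalar random walks.  Proposal scales adapt during
burn-in only, preserving detailed balance afterwards.  Chains are
deterministic under a fixed seed.

Model comparison uses the deviance information criterion
``DIC = mean deviance + p_D`` with ``p_D = mean deviance - deviance at the
posterior mean`` of the subject-level parameters, and convergence is checked
with the Gelman-Rubin potential-scale-reduction statistic on group-level
parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import log_ndtr, ndtr

from .ddm import _trial_loglik
from .synthetic_data import TASK_CONDITIONS

__all__ = [
    "VariantSpec",
    "VARIANTS",
    "PreparedData",
    "PosteriorSamples",
    "FitReport",
    "prepare_data",
    "sample_posterior",
    "gelman_rubin",
    "dic",
    "posterior_prob_greater",
    "posterior_predict",
    "fit_report",
]

KINDS = ("v", "a", "ter")
N_COND = len(TASK_CONDITIONS)

# subject-level truncation bounds per kind
_BOUNDS = {"v": (-np.inf, np.inf), "a": (0.10, np.inf), "ter": (0.05, 1.0)}
# group-mean priors: (mean, sd, lo, hi)
_MEAN_PRIOR = {
    "v": (2.0, 3.0, -np.inf, np.inf),
    "a": (1.5, 1.0, 0.10, np.inf),
    "ter": (0.3, 0.25, 0.05, 1.0),
}
_SD_PRIOR_SCALE = 1.0  # half-normal scale for group SDs
_INIT_SCALES = {"v": 0.4, "a": 0.15, "ter": 0.04}


@dataclass(frozen=True)
class VariantSpec:
    """Which DDM parameters vary between conditions in this variant."""

    varies_by_condition: frozenset

    def __post_init__(self) -> None:
        v = frozenset(self.varies_by_condition)
        object.__setattr__(self, "varies_by_condition", v)
        if not v <= set(KINDS):
            raise ValueError(f"unknown parameter kinds: {sorted(v - set(KINDS))}")
        if len(v) not in (2, 3):
            raise ValueError("a variant lets two or all three parameters vary")

    @property
    def name(self) -> str:
        return "+".join(k for k in KINDS if k in self.varies_by_condition)

    def levels(self, kind: str) -> tuple[str, ...]:
        return TASK_CONDITIONS if kind in self.varies_by_condition else ("shared",)

    def n_levels(self, kind: str) -> int:
        return N_COND if kind in self.varies_by_condition else 1


VARIANTS: dict[str, VariantSpec] = {
    "v+a": VariantSpec(frozenset({"v", "a"})),
    "v+ter": VariantSpec(frozenset({"v", "ter"})),
    "a+ter": VariantSpec(frozenset({"a", "ter"})),
    "v+a+ter": VariantSpec(frozenset({"v", "a", "ter"})),
}


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PreparedData:
    """Trial arrays sorted so every (subject, condition) cell is contiguous."""

    rt: np.ndarray
    upper: np.ndarray  # response at the correct (upper) boundary
    cell_start: np.ndarray  # (n_subjects * 4,)
    cell_end: np.ndarray
    subject_ids: tuple
    t_max: float

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_trials(self) -> int:
        return len(self.rt)

    def cell(self, s: int, c: int) -> int:
        return s * N_COND + c


def prepare_data(trials: pd.DataFrame, t_max: float = 4.0) -> PreparedData:
    """Index a preprocessed trial table for the sampler.

    Expects valid, responded task trials (see behavior_stats.preprocess);
    every subject must have trials in all four conditions.
    """
    task = trials[trials["condition"].isin(TASK_CONDITIONS)]
    task = task[task["choice"].isin(["left", "right"]) & task["rt"].notna()]
    if task["rt"].max() > t_max:
        raise ValueError("trial RT exceeds the response window t_max")
    subject_ids = tuple(sorted(task["subject_id"].unique()))
    if len(subject_ids) == 1:
        warnings.warn("single-subject data: group SDs will be prior-dominated")
    cond_index = {c: i for i, c in enumerate(TASK_CONDITIONS)}
    sidx = task["subject_id"].map({s: i for i, s in enumerate(subject_ids)}).to_numpy()
    cidx = task["condition"].map(cond_index).to_numpy()
    order = np.lexsort((cidx, sidx))
    rt = task["rt"].to_numpy()[order]
    upper = (task["choice"] == task["direction"]).to_numpy()[order]
    cell = sidx[order] * N_COND + cidx[order]
    n_cells = len(subject_ids) * N_COND
    counts = np.bincount(cell, minlength=n_cells)
    if (counts == 0).any():
        bad = np.nonzero(counts == 0)[0]
        raise ValueError(
            f"subjects missing conditions: cells {bad.tolist()} are empty"
        )
    end = np.cumsum(counts)
    start = end - counts
    return PreparedData(
        rt=np.ascontiguousarray(rt, dtype=float),
        upper=np.ascontiguousarray(upper, dtype=np.bool_),
        cell_start=start.astype(np.int64), cell_end=end.astype(np.int64),
        subject_ids=subject_ids, t_max=float(t_max),
    )


# ---------------------------------------------------------------------------
# likelihood kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _cells_loglik(rt, upper, cell_start, cell_end, cells, v_cell, a_cell, ter_cell, q, t_max):
    out = np.empty(cells.shape[0])
    for k in range(cells.shape[0]):
        cid = cells[k]
        tot = 0.0
        for i in range(cell_start[cid], cell_end[cid]):
            tot += _trial_loglik(rt[i], upper[i], v_cell[k], a_cell[k], ter_cell[k], q, t_max)
        out[k] = tot
    return out


# ---------------------------------------------------------------------------
# posterior container
# ---------------------------------------------------------------------------


@dataclass
class PosteriorSamples:
    """Post-burn-in MCMC draws for one model variant.

    Group-level arrays have shape (n_chains, n_kept, n_levels); subject-level
    arrays (n_chains, n_kept, n_subjects, n_levels).  ``loglik`` is the data
    log-likelihood at the subject-level parameters of each iteration.
    """

    variant: VariantSpec
    group_mean: dict
    group_sd: dict
    subject: dict
    loglik: np.ndarray
    subject_ids: tuple
    outlier_frac: float
    t_max: float
    n_burn: int
    prior_dominated_sds: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.loglik.shape[0]

    @property
    def n_kept(self) -> int:
        return self.loglik.shape[1]

    def level_labels(self, kind: str) -> tuple[str, ...]:
        return self.variant.levels(kind)

    def group_mean_draws(self, kind: str, level: str) -> np.ndarray:
        """Paired draws (n_chains, n_kept) of one group-level mean."""
        labels = self.level_labels(kind)
        if level not in labels:
            raise KeyError(f"{kind} has levels {labels}, not {level!r}")
        return self.group_mean[kind][:, :, labels.index(level)]

    def to_frame(self) -> pd.DataFrame:
        """Long-format group-level draws with chain/iteration indices."""
        rows = []
        for kind in KINDS:
            for li, level in enumerate(self.level_labels(kind)):
                for arr, what in ((self.group_mean, "mean"), (self.group_sd, "sd")):
                    a = arr[kind][:, :, li]
                    for ch in range(a.shape[0]):
                        rows.append(pd.DataFrame({
                            "param": f"{kind}[{level}]", "stat": what, "chain": ch,
                            "iteration": np.arange(a.shape[1]), "value": a[ch],
                        }))
        return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------


def _trunc_norm_logpdf(x, mu, sd, lo, hi):
    """Log density of a normal truncated to [lo, hi], vectorized."""
    z = (x - mu) / sd
    base = -0.5 * z * z - np.log(sd) - 0.5 * np.log(2 * np.pi)
    if np.isneginf(lo) and np.isposinf(hi):
        return base
    if np.isposinf(hi):
        log_z = log_ndtr((mu - lo) / sd)
    else:
        mass = ndtr((hi - mu) / sd) - ndtr((lo - mu) / sd)
        log_z = np.log(np.maximum(mass, 1e-300))
    return base - log_z


def _expand(theta: dict, variant: VariantSpec) -> dict:
    """Per-cell (S, 4) parameter matrices from per-level storage."""
    out = {}
    for kind in KINDS:
        t = theta[kind]
        out[kind] = t if variant.n_levels(kind) == N_COND else np.repeat(t, N_COND, axis=1)
    return out


def _chain(data: PreparedData, variant: VariantSpec, n_samples, n_burn, q, rng,
           init_retry=100):
    S = data.n_subjects
    all_cells = np.arange(S * N_COND, dtype=np.int64)

    # --- initialization from priors, retried until the likelihood is finite
    for attempt in range(init_retry):
        mu, sd, theta = {}, {}, {}
        for kind in KINDS:
            L = variant.n_levels(kind)
            pm, psd, lo, hi = _MEAN_PRIOR[kind]
            m = np.clip(rng.normal(pm, psd * 0.25, size=L), lo if np.isfinite(lo) else None,
                        hi if np.isfinite(hi) else None)
            s = np.abs(rng.normal(0.0, 0.3, size=L)) + 0.05
            blo, bhi = _BOUNDS[kind]
            t = np.clip(m[None, :] + rng.normal(0, s, size=(S, L)),
                        blo if np.isfinite(blo) else None,
                        bhi if np.isfinite(bhi) else None)
            mu[kind], sd[kind], theta[kind] = m, s, t
        cellp = _expand(theta, variant)
        ll = _cells_loglik(data.rt, data.upper, data.cell_start, data.cell_end,
                           all_cells, cellp["v"].ravel(), cellp["a"].ravel(),
                           cellp["ter"].ravel(), q, data.t_max)
        if np.isfinite(ll).all():
            L_cells = ll.reshape(S, N_COND)
            break
    else:
        raise RuntimeError("failed to initialize chain at finite likelihood")

    # proposal scales: per (kind, level) vectors over subjects + scalars for groups
    scales = {k: np.full((variant.n_levels(k), S), _INIT_SCALES[k]) for k in KINDS}
    mu_step = {k: np.full(variant.n_levels(k), 0.2 * _INIT_SCALES[k] / _INIT_SCALES["v"] + 0.05)
               for k in KINDS}
    sd_step = {k: np.full(variant.n_levels(k), 0.1) for k in KINDS}
    acc = {k: np.zeros((variant.n_levels(k), S)) for k in KINDS}
    mu_acc = {k: np.zeros(variant.n_levels(k)) for k in KINDS}
    sd_acc = {k: np.zeros(variant.n_levels(k)) for k in KINDS}
    ADAPT_EVERY = 50

    n_kept = n_samples - n_burn
    out_mu = {k: np.empty((n_kept, variant.n_levels(k))) for k in KINDS}
    out_sd = {k: np.empty((n_kept, variant.n_levels(k))) for k in KINDS}
    out_theta = {k: np.empty((n_kept, S, variant.n_levels(k))) for k in KINDS}
    out_ll = np.empty(n_kept)

    for it in range(n_samples):
        # ---- subject-level blocks
        for kind in KINDS:
            L = variant.n_levels(kind)
            blo, bhi = _BOUNDS[kind]
            varies = L == N_COND
            for l in range(L):
                cur = theta[kind][:, l]
                prop = cur + scales[kind][l] * rng.normal(size=S)
                ok = (prop > blo) & (prop < bhi)
                conds = [l] if varies else list(range(N_COND))
                cells = np.concatenate([s0 * N_COND + np.array(conds) for s0 in range(S)]) \
                    if len(conds) > 1 else np.arange(S) * N_COND + l
                # per-cell parameter vectors under the proposal
                cellp = _expand(theta, variant)
                vals = {k2: cellp[k2][:, conds].ravel() for k2 in KINDS}
                vals[kind] = np.repeat(prop, len(conds))
                new_ll = _cells_loglik(
                    data.rt, data.upper, data.cell_start, data.cell_end,
                    cells.astype(np.int64), vals["v"], vals["a"], vals["ter"],
                    q, data.t_max)
                new_ll = new_ll.reshape(S, len(conds))
                old_ll = L_cells[:, conds]
                # prior under the group distribution (truncation constant cancels)
                d_prior = (-0.5 * ((prop - mu[kind][l]) / sd[kind][l]) ** 2
                           + 0.5 * ((cur - mu[kind][l]) / sd[kind][l]) ** 2)
                delta = new_ll.sum(axis=1) - old_ll.sum(axis=1) + d_prior
                accept = ok & (np.log(rng.random(S)) < delta)
                theta[kind][accept, l] = prop[accept]
                L_cells[np.ix_(accept, conds)] = new_ll[accept]
                acc[kind][l] += accept

        # ---- group-level updates
        for kind in KINDS:
            pm, psd, plo, phi = _MEAN_PRIOR[kind]
            blo, bhi = _BOUNDS[kind]
            for l in range(variant.n_levels(kind)):
                t = theta[kind][:, l]
                # mean
                cur, step = mu[kind][l], mu_step[kind][l]
                prop = cur + step * rng.normal()
                if plo < prop < phi:
                    d = (_trunc_norm_logpdf(t, prop, sd[kind][l], blo, bhi).sum()
                         - _trunc_norm_logpdf(t, cur, sd[kind][l], blo, bhi).sum()
                         - 0.5 * ((prop - pm) / psd) ** 2 + 0.5 * ((cur - pm) / psd) ** 2)
                    if np.log(rng.random()) < d:
                        mu[kind][l] = prop
                        mu_acc[kind][l] += 1
                # sd
                cur, step = sd[kind][l], sd_step[kind][l]
                prop = cur + step * rng.normal()
                if prop > 1e-3:
                    d = (_trunc_norm_logpdf(t, mu[kind][l], prop, blo, bhi).sum()
                         - _trunc_norm_logpdf(t, mu[kind][l], cur, blo, bhi).sum()
                         - 0.5 * (prop / _SD_PRIOR_SCALE) ** 2
                         + 0.5 * (cur / _SD_PRIOR_SCALE) ** 2)
                    if np.log(rng.random()) < d:
                        sd[kind][l] = prop
                        sd_acc[kind][l] += 1

        # ---- adaptation (burn-in only; frozen afterwards)
        if it < n_burn and (it + 1) % ADAPT_EVERY == 0:
            for kind in KINDS:
                rate = acc[kind] / ADAPT_EVERY
                scales[kind] *= np.exp(0.7 * (rate - 0.44))
                acc[kind][:] = 0
                mrate = mu_acc[kind] / ADAPT_EVERY
                mu_step[kind] *= np.exp(0.7 * (mrate - 0.44))
                mu_acc[kind][:] = 0
                srate = sd_acc[kind] / ADAPT_EVERY
                sd_step[kind] *= np.exp(0.7 * (srate - 0.44))
                sd_acc[kind][:] = 0

        if it >= n_burn:
            j = it - n_burn
            for kind in KINDS:
                out_mu[kind][j] = mu[kind]
                out_sd[kind][j] = sd[kind]
                out_theta[kind][j] = theta[kind]
            out_ll[j] = L_cells.sum()

    return out_mu, out_sd, out_theta, out_ll


def sample_posterior(
    data: PreparedData | pd.DataFrame,
    variant: VariantSpec | str,
    n_samples: int = 20_000,
    n_burn: int = 4_000,
    n_chains: int = 5,
    outlier_frac: float = 0.05,
    seed: int = 0,
    t_max: float = 4.0,
) -> PosteriorSamples:
    """Draw from the joint posterior of one hierarchical DDM variant.

    Defaults mirror the full estimation protocol (20,000 samples per chain
    with the first 4,000 discarded, five chains, 5% outlier mixture); smaller
    budgets are appropriate for desk-scale recovery studies.  Deterministic
    under a fixed ``seed``.
    """
    if isinstance(variant, str):
        variant = VARIANTS[variant]
    if isinstance(data, pd.DataFrame):
        data = prepare_data(data, t_max=t_max)
    if n_burn >= n_samples:
        raise ValueError("n_burn must be smaller than n_samples")
    if n_chains < 2:
        raise ValueError("at least two chains are required for diagnostics")
    ss = np.random.SeedSequence(seed)
    chains = [np.random.default_rng(s) for s in ss.spawn(n_chains)]
    mus, sds, thetas, lls = [], [], [], []
    for rng in chains:
        m, s, t, ll = _chain(data, variant, n_samples, n_burn, outlier_frac, rng)
        mus.append(m); sds.append(s); thetas.append(t); lls.append(ll)
    stack = lambda seq, k: np.stack([x[k] for x in seq])
    return PosteriorSamples(
        variant=variant,
        group_mean={k: stack(mus, k) for k in KINDS},
        group_sd={k: stack(sds, k) for k in KINDS},
        subject={k: stack(thetas, k) for k in KINDS},
        loglik=np.stack(lls),
        subject_ids=data.subject_ids,
        outlier_frac=outlier_frac,
        t_max=data.t_max,
        n_burn=n_burn,
        prior_dominated_sds=data.n_subjects < 2 or data.n_subjects == 1,
        meta={"n_samples": n_samples, "n_chains": n_chains, "seed": seed,
              "n_subjects": data.n_subjects},
    )


# ---------------------------------------------------------------------------
# diagnostics and comparison
# ---------------------------------------------------------------------------


def gelman_rubin(samples: PosteriorSamples) -> dict[str, float]:
    """Potential scale reduction R-hat for every group-level parameter.

    Classic between/within-chain variance ratio; values near 1 indicate
    convergence (< 1.1 by the usual criterion).  Requires >= 2 chains.
    """
    if samples.n_chains < 2:
        raise ValueError("R-hat requires at least two chains")
    out = {}
    for kind in KINDS:
        labels = samples.level_labels(kind)
        for li, level in enumerate(labels):
            for arr, what in ((samples.group_mean, "mean"), (samples.group_sd, "sd")):
                chains = arr[kind][:, :, li]  # (m, n)
                out[f"{what}_{kind}[{level}]"] = _rhat(chains)
    return out


def _rhat(chains: np.ndarray) -> float:
    m, n = chains.shape
    means = chains.mean(axis=1)
    w = chains.var(axis=1, ddof=1).mean()
    b_over_n = means.var(ddof=1)
    v_hat = (n - 1) / n * w + (1.0 + 1.0 / m) * b_over_n
    if w <= 0:
        return 1.0
    return float(np.sqrt(v_hat / w))


def dic(samples: PosteriorSamples, data: PreparedData | pd.DataFrame) -> float:
    """Deviance information criterion of a fitted variant.

    ``DIC = Dbar + pD`` with ``Dbar`` the posterior mean deviance and
    ``pD = Dbar - D(theta_bar)`` the effective number of parameters, both at
    the subject-level parameters.
    """
    if isinstance(data, pd.DataFrame):
        data = prepare_data(data, t_max=samples.t_max)
    d_bar = float(np.mean(-2.0 * samples.loglik))
    theta_bar = {k: samples.subject[k].mean(axis=(0, 1)) for k in KINDS}
    cellp = _expand(theta_bar, samples.variant)
    S = data.n_subjects
    all_cells = np.arange(S * N_COND, dtype=np.int64)
    ll_hat = _cells_loglik(
        data.rt, data.upper, data.cell_start, data.cell_end, all_cells,
        cellp["v"].ravel(), cellp["a"].ravel(), cellp["ter"].ravel(),
        samples.outlier_frac, data.t_max).sum()
    d_hat = -2.0 * float(ll_hat)
    p_d = d_bar - d_hat
    return d_bar + p_d


def posterior_prob_greater(
    samples: PosteriorSamples,
    param_a: tuple[str, str],
    param_b: tuple[str, str],
    method: str = "paired",
    rng: np.random.Generator | int | None = None,
) -> float:
    """Posterior probability P(a > b) for two condition-specific group means.

    ``method='paired'`` (default) compares draws from the same chain and
    iteration, the sample-wise operationalization of posterior non-overlap;
    identical parameters then give exactly 0 under the strict inequality.
    ``method='permuted'`` compares independently permuted draws, so two
    identically distributed parameters give ~0.5.
    """
    a = samples.group_mean_draws(*param_a).ravel()
    b = samples.group_mean_draws(*param_b).ravel()
    if method == "paired":
        return float(np.mean(a > b))
    if method == "permuted":
        rng = np.random.default_rng(rng)
        return float(np.mean(rng.permutation(a) > b))
    raise ValueError("method must be 'paired' or 'permuted'")


def posterior_predict(
    samples: PosteriorSamples,
    data: PreparedData | pd.DataFrame,
    n_sims: int = 50,
    rng: np.random.Generator | int | None = None,
    dt: float = 0.001,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Posterior-predictive datasets and per-condition summaries.

    Draws ``n_sims`` posterior iterations at random, simulates each subject's
    observed number of trials per condition from that iteration's
    subject-level parameters, and aggregates accuracy and RT quantiles (q10 /
    q50 / q90) per condition across simulations.  Returns
    ``(example_dataset, summary)``; the example dataset is the first
    simulation in the trial-table schema (without stimulus columns).
    """
    from .ddm import _simulate_ddm

    if isinstance(data, pd.DataFrame):
        data = prepare_data(data, t_max=samples.t_max)
    rng = np.random.default_rng(rng)
    n_chains, n_kept = samples.loglik.shape
    S = data.n_subjects
    summaries = []
    example = None
    for sim in range(n_sims):
        ch = int(rng.integers(n_chains))
        it = int(rng.integers(n_kept))
        theta = {k: samples.subject[k][ch, it] for k in KINDS}
        cellp = _expand(theta, samples.variant)
        rows = []
        for s in range(S):
            for c, cond in enumerate(TASK_CONDITIONS):
                cid = data.cell(s, c)
                n_tr = int(data.cell_end[cid] - data.cell_start[cid])
                seed = int(rng.integers(0, 2**31 - 1))
                b, rt = _simulate_ddm(n_tr, cellp["v"][s, c], cellp["a"][s, c],
                                      cellp["ter"][s, c], dt, samples.t_max, seed)
                for bi, ri in zip(b, rt):
                    rows.append((samples.subject_ids[s], cond, int(bi), ri))
        df = pd.DataFrame(rows, columns=["subject_id", "condition", "boundary", "rt"])
        if example is None:
            example = df.copy()
        done = df[df["boundary"] >= 0]
        for cond, sub in done.groupby("condition"):
            q10, q50, q90 = np.quantile(sub["rt"], [0.1, 0.5, 0.9])
            summaries.append(dict(sim=sim, condition=cond,
                                  accuracy=float((sub["boundary"] == 1).mean()),
                                  rt_q10=q10, rt_q50=q50, rt_q90=q90))
    summary = (pd.DataFrame(summaries)
               .groupby("condition")[["accuracy", "rt_q10", "rt_q50", "rt_q90"]]
               .mean().reset_index())
    return example, summary


@dataclass(frozen=True)
class FitReport:
    """Summary of one fitted variant: DIC, worst R-hat, posterior means."""

    variant: str
    dic: float
    max_rhat: float
    rhat: dict
    posterior_means: dict


def fit_report(samples: PosteriorSamples, data: PreparedData | pd.DataFrame) -> FitReport:
    rhat = gelman_rubin(samples)
    means = {}
    for kind in KINDS:
        for li, level in enumerate(samples.level_labels(kind)):
            means[f"{kind}[{level}]"] = float(samples.group_mean[kind][:, :, li].mean())
    return FitReport(
        variant=samples.variant.name,
        dic=float(dic(samples, data)),
        max_rhat=float(max(rhat.values())),
        rhat=rhat,
        posterior_means=means,
    )
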