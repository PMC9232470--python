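"""Preprocessing filters, condition summaries, contrasts and power.

Preprocessing mirrors the experiment's rules: trials faster than 250 ms or
without a valid response are removed; a subject whose accuracy over any two
consecutive blocks falls below 60% is excluded wholesale; easy control trials
are dropped from the analysis set.  Summaries are per subject x condition
accuracy and mean RT (correct and error trials pooled).

The group-level tests are the classical 2 (sources) x 2 (coherence) mixed
ANOVA with aperture-angle group as the between factor, computed via
per-subject contrast scores (every factor has two levels, so each effect has
one numerator degree of freedom and reduces to an OLS on contrast scores with
effect-coded group), plus paired t contrasts between matched conditions and
the exact noncentral-t power of a paired t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import CONDITIONS, TASK_CONDITIONS

__all__ = [
    "preprocess",
    "condition_summary",
    "mixed_anova",
    "paired_contrast",
    "power_paired_t",
    "ExclusionReport",
    "PairedContrast",
]

MIN_RT = 0.250
MIN_BLOCK_PAIR_ACCURACY = 0.60


@dataclass(frozen=True)
class ExclusionReport:
    """What preprocessing removed and why."""

    n_input_trials: int
    n_fast: int
    n_no_response: int
    removed_fraction: float  # fast + no-response, among all input trials
    excluded_subjects: tuple[int, ...]
    n_control_dropped: int


def preprocess(trials: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the trial and subject filters; returns (analysis set, report).

    Removes RT < 250 ms and non-responses; excludes subjects whose accuracy on
    task trials over any two consecutive blocks is below 60% (the premature-
    termination rule applied retrospectively); drops control trials from the
    analysis set.  Idempotent: a second application removes nothing.
    """
    unknown = set(trials["condition"].unique()) - set(CONDITIONS)
    if unknown:
        raise ValueError(f"unknown condition labels: {sorted(unknown)}")
    n_input = len(trials)
    responded = trials["choice"].isin(["left", "right"]) & trials["rt"].notna()
    fast = responded & (trials["rt"] < MIN_RT)
    n_no_response = int((~responded).sum())
    n_fast = int(fast.sum())
    kept = trials[responded & ~fast].copy()

    # subject-level exclusion: sliding pairs of consecutive blocks, task trials
    excluded = []
    task = kept[kept["condition"] != "CONTROL"]
    correct = task["choice"] == task["direction"]
    for sid, sub in task.assign(correct=correct).groupby("subject_id"):
        blocks = sorted(sub["block"].unique())
        for b0, b1 in zip(blocks[:-1], blocks[1:]):
            if b1 != b0 + 1:
                continue
            pair = sub[sub["block"].isin([b0, b1])]
            if len(pair) and pair["correct"].mean() < MIN_BLOCK_PAIR_ACCURACY:
                excluded.append(int(sid))
                break
    kept = kept[~kept["subject_id"].isin(excluded)]

    n_control = int((kept["condition"] == "CONTROL").sum())
    kept = kept[kept["condition"] != "CONTROL"].reset_index(drop=True)
    report = ExclusionReport(
        n_input_trials=n_input,
        n_fast=n_fast,
        n_no_response=n_no_response,
        removed_fraction=(n_fast + n_no_response) / n_input if n_input else 0.0,
        excluded_subjects=tuple(sorted(set(excluded))),
        n_control_dropped=n_control,
    )
    return kept, report


def condition_summary(trials: pd.DataFrame, split_by_accuracy: bool = False) -> pd.DataFrame:
    """Per subject x condition accuracy and mean RT over valid task trials.

    RT pools correct and error trials by default; ``split_by_accuracy`` adds
    separate correct/error RT columns.  Empty cells yield NaN with a warning.
    """
    import warnings

    task = trials[trials["condition"].isin(TASK_CONDITIONS)].copy()
    task["correct"] = task["choice"] == task["direction"]
    rows = []
    for (sid, angle), sub in task.groupby(["subject_id", "group_angle"]):
        for cond in TASK_CONDITIONS:
            cell = sub[sub["condition"] == cond]
            if len(cell) == 0:
                warnings.warn(f"subject {sid} has no {cond} trials; summary is NaN")
                row = dict(subject_id=sid, group_angle=angle, condition=cond,
                           accuracy=np.nan, mean_rt=np.nan, n_trials=0)
            else:
                row = dict(
                    subject_id=sid, group_angle=angle, condition=cond,
                    accuracy=float(cell["correct"].mean()),
                    mean_rt=float(cell["rt"].mean()),
                    n_trials=len(cell),
                )
                if split_by_accuracy:
                    row["mean_rt_correct"] = float(cell.loc[cell["correct"], "rt"].mean())
                    row["mean_rt_error"] = float(cell.loc[~cell["correct"], "rt"].mean())
            rows.append(row)
    return pd.DataFrame(rows)


# contrast weights over (CON, CON_BSL, INC, INC_BSL)
_CONTRASTS = {
    # double minus single sources, averaged over coherence
    "source": {"CON": 0.5, "CON_BSL": -0.5, "INC": 0.5, "INC_BSL": -0.5},
    # high minus low combined coherence, averaged over sources
    "coherence": {"CON": 0.5, "CON_BSL": 0.5, "INC": -0.5, "INC_BSL": -0.5},
    "source_x_coherence": {"CON": 1.0, "CON_BSL": -1.0, "INC": -1.0, "INC_BSL": 1.0},
}


def _anova_row(effect: str, scores: np.ndarray, groups: np.ndarray, which: str) -> dict:
    """F test on per-subject contrast scores with effect-coded group.

    ``which='intercept'`` tests the within-subject effect (unweighted grand
    mean of group means, i.e. Type III); ``which='group'`` tests the
    group x within interaction (or the between main effect when the scores
    are subject means).
    """
    g = np.unique(groups)
    if len(g) != 2:
        raise ValueError("exactly two between-subject groups required")
    x = np.where(groups == g[0], 1.0, -1.0)
    n = len(scores)
    # OLS y = b0 + b1 * x with effect coding
    m1, m2 = scores[x > 0].mean(), scores[x < 0].mean()
    b0, b1 = (m1 + m2) / 2.0, (m1 - m2) / 2.0
    resid = scores - (b0 + b1 * x)
    df_err = n - 2
    mse = float(resid @ resid) / df_err
    n1, n2 = int((x > 0).sum()), int((x < 0).sum())
    # variances of b0 and b1 under effect coding with unbalanced groups
    var_b = mse * (1.0 / n1 + 1.0 / n2) / 4.0
    b = b0 if which == "intercept" else b1
    f = b * b / var_b
    p = float(stats.f.sf(f, 1, df_err))
    ss_eff = b * b / ((1.0 / n1 + 1.0 / n2) / 4.0)
    eta_p = ss_eff / (ss_eff + mse * df_err)
    return dict(effect=effect, F=float(f), df1=1, df2=df_err, p=p,
                partial_eta_sq=float(eta_p))


def mixed_anova(summary: pd.DataFrame, dependent: str = "accuracy") -> pd.DataFrame:
    """2 x 2 repeated-measures ANOVA with group as the between factor.

    Returns one row per effect: sources and coherence main effects, their
    interaction, the group main effect, and every group interaction; columns
    F, df1, df2, p, partial_eta_sq.  Subjects missing any of the four cells
    are dropped with a warning.
    """
    import warnings

    if dependent not in ("accuracy", "mean_rt", "rt"):
        raise ValueError("dependent must be 'accuracy' or 'rt'")
    col = "mean_rt" if dependent in ("rt", "mean_rt") else "accuracy"
    wide = summary.pivot_table(index=["subject_id", "group_angle"],
                               columns="condition", values=col)
    complete = wide.dropna()
    dropped = len(wide) - len(complete)
    if dropped:
        warnings.warn(f"dropping {dropped} subject(s) with incomplete condition cells")
    if len(complete) < 4:
        raise ValueError("too few complete subjects for the mixed ANOVA")
    groups = complete.index.get_level_values("group_angle").to_numpy()
    rows = []
    for name, w in _CONTRASTS.items():
        scores = sum(complete[c] * w[c] for c in TASK_CONDITIONS).to_numpy()
        rows.append(_anova_row(name, scores, groups, "intercept"))
        rows.append(_anova_row(f"group_x_{name}", scores, groups, "group"))
    subj_mean = complete[list(TASK_CONDITIONS)].mean(axis=1).to_numpy()
    rows.append(_anova_row("group", subj_mean, groups, "group"))
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PairedContrast:
    mean_diff: float
    t: float
    df: int
    p: float
    degenerate: bool = False


def paired_contrast(
    summary: pd.DataFrame, cond_a: str, cond_b: str, dependent: str = "accuracy"
) -> PairedContrast:
    """Classical paired t-test of condition A minus condition B per subject."""
    col = "mean_rt" if dependent in ("rt", "mean_rt") else "accuracy"
    wide = summary.pivot_table(index="subject_id", columns="condition", values=col)
    for c in (cond_a, cond_b):
        if c not in wide.columns:
            raise ValueError(f"condition {c!r} absent from summary")
    diff = (wide[cond_a] - wide[cond_b]).dropna().to_numpy()
    n = len(diff)
    if n < 2:
        raise ValueError("paired contrast needs at least 2 subjects")
    md = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if sd == 0.0:
        if md == 0.0:
            return PairedContrast(0.0, 0.0, n - 1, 1.0, degenerate=True)
        t = np.inf if md > 0 else -np.inf
        return PairedContrast(md, float(t), n - 1, 0.0, degenerate=True)
    t = md / (sd / np.sqrt(n))
    p = float(2.0 * stats.t.sf(abs(t), n - 1))
    return PairedContrast(md, float(t), n - 1, p, degenerate=False)


def power_paired_t(n: int, d: float, alpha: float = 0.05) -> float:
    """Exact power of a two-sided one-sample/paired t-test.

    Noncentrality ``d * sqrt(n)``, df ``n - 1``; at d = 0 the power equals
    ``alpha`` and power is strictly increasing in n for d > 0.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    df = n - 1
    nc = d * np.sqrt(n)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))
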