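"""Synthetic trial-level datasets with the two-aperture experiment's structure.

The design emulates the main experiment: 432 trials per subject in 6 blocks of
72, each block holding 16 trials of each of four task conditions plus 8 easy
control trials, with left/right motion balanced within every block.  Condition
coding (signed coherence, positive = leftward, c1 is the dominant source):

================  =================  ==========================  ============
condition         sources            (|c1|, c2) assignment        net evidence
================  =================  ==========================  ============
CON (congruent)   double, same dir   c_low, c_high - c_low        c_high
CON_BSL           single             c_high, 0                    c_high
INC (incongru.)   double, opposed    c_high, -(c_high - c_low)    c_low
INC_BSL           single             c_low, 0                     c_low
CONTROL           single, easy       0.60, 0                      0.60
================  =================  ==========================  ============

Responses are generated by a drift-diffusion process per condition; a cohort
generator draws subject-level DDM parameters from group-level normal
distributions (truncated to positivity for threshold and non-decision time),
returning the ground truth alongside for parameter-recovery studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .ddm import DDMParams, _simulate_ddm

__all__ = [
    "TASK_CONDITIONS",
    "CONDITIONS",
    "CohortSpec",
    "generate_design",
    "sample_behavior",
    "generate_cohort",
    "net_evidence",
    "write_trials_csv",
    "read_trials_csv",
    "load_cohort_spec",
    "save_cohort_spec",
]

TASK_CONDITIONS = ("CON", "CON_BSL", "INC", "INC_BSL")
CONDITIONS = TASK_CONDITIONS + ("CONTROL",)

N_BLOCKS = 6
TRIALS_PER_TASK_CONDITION = 16  # per block
CONTROL_PER_BLOCK = 8
CONTROL_COHERENCE = 0.60

TRIAL_COLUMNS = [
    "subject_id", "group_angle", "block", "condition",
    "c1", "c2", "direction", "choice", "rt", "is_valid",
]


def _condition_coherences(condition: str, c_low: float, c_high: float) -> tuple[float, float]:
    """Unsigned (|c1|, c2-magnitude-with-sign) for one condition, c1 dominant."""
    if condition == "CON":
        hi, lo = sorted((c_low, c_high - c_low), reverse=True)
        return hi, lo
    if condition == "CON_BSL":
        return c_high, 0.0
    if condition == "INC":
        return c_high, -(c_high - c_low)
    if condition == "INC_BSL":
        return c_low, 0.0
    if condition == "CONTROL":
        return CONTROL_COHERENCE, 0.0
    raise ValueError(f"unknown condition {condition!r}")


def net_evidence(condition: str, c_low: float, c_high: float) -> float:
    """Unsigned net motion coherence (|c1| + c2 with c2's sign) for a condition."""
    m1, m2 = _condition_coherences(condition, c_low, c_high)
    return m1 + m2


def generate_design(
    group_angle: int,
    c_low: float,
    c_high: float,
    rng: np.random.Generator | int | None = None,
    subject_id: int = 0,
) -> pd.DataFrame:
    """Ordered trial stubs (no responses) for one subject.

    432 trials in 6 blocks of 72; per block 16 trials of each task condition
    plus 8 control trials, half leftward and half rightward within every
    condition of every block; trial order shuffled within block.
    """
    if group_angle not in (20, 45):
        raise ValueError("group_angle must be 20 or 45 degrees")
    if not (0.0 < c_low < c_high < 1.0):
        raise ValueError("need 0 < c_low < c_high < 1")
    rng = np.random.default_rng(rng)
    rows = []
    for block in range(1, N_BLOCKS + 1):
        block_rows = []
        for cond in CONDITIONS:
            n = CONTROL_PER_BLOCK if cond == "CONTROL" else TRIALS_PER_TASK_CONDITION
            m1, m2 = _condition_coherences(cond, c_low, c_high)
            for k in range(n):
                direction = "left" if k < n // 2 else "right"
                sign = 1.0 if direction == "left" else -1.0
                block_rows.append(
                    dict(
                        subject_id=subject_id, group_angle=group_angle, block=block,
                        condition=cond, c1=sign * m1, c2=sign * m2,
                        direction=direction, choice="none", rt=np.nan, is_valid=False,
                    )
                )
        order = rng.permutation(len(block_rows))
        rows.extend(block_rows[i] for i in order)
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def sample_behavior(
    design: pd.DataFrame,
    params_by_condition: Mapping[str, DDMParams],
    t_max: float = 4.0,
    dt: float = 0.001,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Fill a design's trials with DDM-generated (choice, rt).

    One DDMParams per condition present in the design; the drift points toward
    the correct (upper) boundary, so an upper crossing yields ``choice ==
    direction``.  Trials with no crossing by ``t_max`` get choice 'none',
    NaN rt and ``is_valid = False``.
    """
    rng = np.random.default_rng(rng)
    out = design.copy()
    choices = np.empty(len(out), dtype=object)
    rts = np.full(len(out), np.nan)
    valid = np.zeros(len(out), dtype=bool)
    for cond, sub in out.groupby("condition", sort=True):
        if cond not in params_by_condition:
            raise KeyError(f"no DDM parameters supplied for condition {cond!r}")
        p = params_by_condition[cond]
        if p.a <= 0 or p.ter <= 0:
            raise ValueError("threshold and non-decision time must be positive")
        seed = int(rng.integers(0, 2**31 - 1))
        b, rt = _simulate_ddm(len(sub), p.v, p.a, p.ter, dt, t_max, seed)
        idx = sub.index.to_numpy()
        directions = sub["direction"].to_numpy()
        opposite = np.where(directions == "left", "right", "left")
        choices[idx] = np.select([b == 1, b == 0], [directions, opposite], default="none")
        rts[idx] = rt
        valid[idx] = b >= 0
    out["choice"] = choices
    out["rt"] = rts
    out["is_valid"] = valid
    return out


def _default_means() -> dict[str, dict[str, float]]:
    """Group-level generative means emulating the observed condition effects:

    a reduced drift in the congruent double-source condition and a reduced
    threshold in the incongruent double-source condition; non-decision time
    constant across conditions.
    """
    return {
        "v": {"CON": 0.85, "CON_BSL": 1.05, "INC": 0.70, "INC_BSL": 0.70},
        "a": {"CON": 1.60, "CON_BSL": 1.60, "INC": 1.45, "INC_BSL": 1.60},
        "ter": {"CON": 0.35, "CON_BSL": 0.35, "INC": 0.35, "INC_BSL": 0.35},
    }


@dataclass
class CohortSpec:
    """Generative specification for a synthetic cohort.

    ``group_means[param][condition]`` are the group-level means of the
    subject-level DDM parameters; SDs are shared across conditions per
    parameter.  ``drift_gain`` maps the 60% control coherence to a control
    drift rate (v = drift_gain * coherence); with the default threshold the
    same map puts c_high = 0.20 near 83% accuracy, its staircase calibration
    target.
    """

    n_per_group: int = 20
    group_angles: tuple[int, ...] = (20, 45)
    c_low: float = 0.15
    c_high: float = 0.20
    group_means: dict = field(default_factory=_default_means)
    group_sds: dict = field(default_factory=lambda: {"v": 0.30, "a": 0.20, "ter": 0.05})
    drift_gain: float = 5.0
    t_max: float = 4.0
    dt: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2 (group SD unidentifiable below)")
        if not (0.0 < self.c_low < self.c_high < 1.0):
            raise ValueError("need 0 < c_low < c_high < 1")
        for k, sd in self.group_sds.items():
            if sd <= 0:
                raise ValueError(f"group SD for {k} must be positive")


_TRUNC_LO = {"v": -np.inf, "a": 0.10, "ter": 0.05}


def _draw_truncated(rng, mean, sd, lo, max_tries=1000):
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if x > lo:
            return float(x)
    raise RuntimeError("truncated draw failed; check group means/SDs")


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a full cohort; returns (trials, ground_truth).

    ``ground_truth`` holds one row per subject x condition with the true
    subject-level parameters, for parameter-recovery studies.  Datasets are
    byte-identical for equal specs (all randomness flows from ``spec.seed``).
    Cohorts with fewer than 5 subjects per group are flagged low-information
    in ``trials.attrs``.
    """
    rng = np.random.default_rng(spec.seed)
    all_trials, truth_rows = [], []
    subject_id = 0
    for angle in spec.group_angles:
        for _ in range(spec.n_per_group):
            params: dict[str, DDMParams] = {}
            for cond in TASK_CONDITIONS:
                vals = {}
                for kind in ("v", "a", "ter"):
                    m = spec.group_means[kind][cond]
                    sd = spec.group_sds[kind]
                    vals[kind] = (
                        float(rng.normal(m, sd)) if kind == "v"
                        else _draw_truncated(rng, m, sd, _TRUNC_LO[kind])
                    )
                params[cond] = DDMParams(vals["v"], vals["a"], vals["ter"])
                truth_rows.append(
                    dict(subject_id=subject_id, group_angle=angle, condition=cond, **vals)
                )
            # control trials: high drift via the linear coherence->drift map,
            # with the subject's average threshold and non-decision time
            a_bar = float(np.mean([params[c].a for c in TASK_CONDITIONS]))
            ter_bar = float(np.mean([params[c].ter for c in TASK_CONDITIONS]))
            params["CONTROL"] = DDMParams(spec.drift_gain * CONTROL_COHERENCE, a_bar, ter_bar)
            design = generate_design(angle, spec.c_low, spec.c_high, rng=rng,
                                     subject_id=subject_id)
            trials = sample_behavior(design, params, t_max=spec.t_max, dt=spec.dt, rng=rng)
            all_trials.append(trials)
            subject_id += 1
    trials = pd.concat(all_trials, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    trials.attrs["low_information"] = spec.n_per_group < 5
    return trials, truth


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_trials_csv(trials: pd.DataFrame, path: str | Path) -> None:
    """Write trials as CSV with the canonical column order, RT to 6 dp."""
    out = trials[TRIAL_COLUMNS].copy()
    out.to_csv(path, index=False, float_format="%.6f")


def read_trials_csv(path: str | Path) -> pd.DataFrame:
    trials = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    trials["is_valid"] = trials["is_valid"].astype(bool)
    return trials


def load_cohort_spec(path: str | Path) -> CohortSpec:
    """Read a CohortSpec from a YAML mapping of constructor fields."""
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    if "group_angles" in payload:
        payload["group_angles"] = tuple(payload["group_angles"])
    return CohortSpec(**payload)


def save_cohort_spec(spec: CohortSpec, path: str | Path) -> None:
    payload = {
        "n_per_group": spec.n_per_group,
        "group_angles": list(spec.group_angles),
        "c_low": spec.c_low, "c_high": spec.c_high,
        "group_means": spec.group_means, "group_sds": spec.group_sds,
        "drift_gain": spec.drift_gain, "t_max": spec.t_max, "dt": spec.dt,
        "seed": spec.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
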