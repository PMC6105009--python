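"""Raw reaction-time analyses of the Implicit Salience Paradigm.

Three paradigm-defined quantities are implemented natively: the
expected/unexpected contrast on the relevant cue feature, condition x
time-bin learning curves following each contingency reversal, and the
ground-truth aberrant salience score — the absolute reaction-time difference
(in milliseconds) between the two manifestations of the currently
*irrelevant* feature, averaged over the two test halves. Routine group
comparisons (Welch tests, one-sample t, Spearman correlations) are thin
wrappers over scipy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

#: inclusive validity bounds on raw reaction times (ms)
RT_MIN_MS = 150.0
RT_MAX_MS = 1500.0


def preprocess_rts(behavior: pd.DataFrame) -> pd.DataFrame:
    """Mark valid trials and add natural-log reaction times.

    A trial is valid when a response was given and 150 ms <= rt <= 1500 ms;
    faster or slower responses are excluded as anticipations/lapses.
    Negative reaction times are rejected as malformed input.
    """
    out = behavior.copy()
    rt = out["rt_ms"].to_numpy(dtype=float)
    if np.any(rt[np.isfinite(rt)] < 0):
        raise ValueError("negative reaction times are malformed input")
    responded = out["responded"].to_numpy(dtype=bool)
    valid = responded & np.isfinite(rt) & (rt >= RT_MIN_MS) & (rt <= RT_MAX_MS)
    out["valid"] = valid
    log_rt = np.full(len(out), np.nan)
    log_rt[valid] = np.log(rt[valid])
    out["log_rt"] = log_rt
    return out


def _merged(behavior: pd.DataFrame, task) -> pd.DataFrame:
    if "valid" not in behavior.columns:
        behavior = preprocess_rts(behavior)
    df = task.trials.merge(behavior, on="trial", validate="one_to_one")
    return df


def expectedness_analysis(behavior: pd.DataFrame, task) -> tuple[float, float]:
    """Mean log RT for expected vs. unexpected events of the relevant feature.

    Expected: rewarded manifestation followed by coin, or non-rewarded by
    circle; unexpected: the reverse. Classification uses only the relevant
    dimension's ground truth. Raises if either cell has no valid trials.
    """
    df = _merged(behavior, task)
    df = df[df["valid"]]
    means = {}
    for label in ("expected", "unexpected"):
        cell = df.loc[df["expected"] == label, "log_rt"]
        if len(cell) == 0:
            raise ValueError(f"no valid trials in the {label} cell")
        means[label] = float(cell.mean())
    return means["expected"], means["unexpected"]


def timebin_means(behavior: pd.DataFrame, task) -> pd.DataFrame:
    """Condition x time-bin mean log RTs of expected events.

    Within every block the expected events are split by outcome condition
    (coin vs. circle), each condition's trials are grouped in block order
    into 4 bins of 2 consecutive trials, and bin means are averaged across
    blocks. Returns a 2 x 4 DataFrame (rows coin/circle, columns bins 1-4);
    bins with no valid trial anywhere are NaN.
    """
    cfg = task.config
    df = _merged(behavior, task)
    df = df[df["expected"] == "expected"].copy()
    df["block"] = (df["trial"] - 1) // cfg.block_length
    cells: dict[tuple[str, int], list[float]] = {}
    for (_, outcome), grp in df.groupby(["block", "outcome"], sort=True):
        grp = grp.sort_values("trial")
        n_bins = 4
        per_bin = max(1, len(grp) // n_bins)
        for pos, (_, row) in enumerate(grp.iterrows()):
            b = min(pos // per_bin, n_bins - 1)
            if row["valid"]:
                cells.setdefault((outcome, b), []).append(row["log_rt"])
    out = pd.DataFrame(
        index=pd.Index(["coin", "circle"], name="condition"),
        columns=[f"bin{i + 1}" for i in range(4)],
        dtype=float,
    )
    for (outcome, b), vals in cells.items():
        out.loc[outcome, f"bin{b + 1}"] = float(np.mean(vals))
    return out


def aberrant_salience_raw(behavior: pd.DataFrame, task) -> float:
    """Ground-truth aberrant salience score in milliseconds.

    Per test half, the mean raw RT (valid trials, untransformed ms) is
    computed for each manifestation of the currently irrelevant feature and
    the half's score is the absolute difference; the session score is the
    mean of the two half scores. Non-negative by construction and invariant
    to relabeling manifestations within a feature.
    """
    from relsal.task import _manifestations

    df = _merged(behavior, task)
    df = df[df["valid"]]
    cfg = task.config
    half_scores = []
    for half in (0, 1):
        lo = 0 if half == 0 else cfg.switch_trial
        hi = cfg.switch_trial if half == 0 else cfg.n_trials
        sub = df[(df["trial"] > lo) & (df["trial"] <= hi)]
        if len(sub) == 0:
            raise ValueError(f"no valid trials in test half {half + 1}")
        rel_dim = sub["relevant_dimension"].iloc[0]
        irr_dim = "shape" if rel_dim == "color" else "color"
        means = []
        for manif in _manifestations(irr_dim):
            cell = sub.loc[sub[irr_dim] == manif, "rt_ms"]
            if len(cell) == 0:
                raise ValueError(
                    f"no valid presentations of {manif!r} in test half {half + 1}"
                )
            means.append(float(cell.mean()))
        half_scores.append(abs(means[0] - means[1]))
    return float(np.mean(half_scores))


@dataclass(frozen=True)
class TestResult:
    statistic: float
    dof: tuple
    p: float
    kind: str


def group_compare(values_a, values_b=None, kind: str = "welch", one_tailed: bool = False):
    """Group comparisons used in the study's behavioral reports.

    ``welch``: Welch's unequal-variance test of two independent groups,
    reported as F on (1, Welch-Satterthwaite) degrees of freedom (F = t^2).
    ``one_sample_t``: t test of ``values_a`` against zero.
    ``spearman``: rank correlation of the paired vectors.
    One-tailed p halves the two-tailed value.
    """
    a = np.asarray(values_a, dtype=float)
    if kind == "welch":
        b = np.asarray(values_b, dtype=float)
        if a.size < 2 or b.size < 2:
            raise ValueError("welch requires >= 2 values per group")
        if np.var(a) == 0 and np.var(b) == 0:
            raise ValueError("degenerate zero-variance inputs")
        t, p = sps.ttest_ind(a, b, equal_var=False)
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        dof = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
        p = float(p)
        return TestResult(float(t * t), (1.0, float(dof)), p / 2 if one_tailed else p, "welch")
    if kind == "one_sample_t":
        if a.size < 2 or np.var(a) == 0:
            raise ValueError("one-sample t undefined for zero-variance input")
        t, p = sps.ttest_1samp(a, 0.0)
        p = float(p)
        return TestResult(float(t), (float(a.size - 1),), p / 2 if one_tailed else p, "one_sample_t")
    if kind == "spearman":
        b = np.asarray(values_b, dtype=float)
        if a.size < 3 or a.size != b.size:
            raise ValueError("spearman requires >= 3 paired values")
        rho, p = sps.spearmanr(a, b)
        p = float(p)
        return TestResult(float(rho), (float(a.size - 2),), p / 2 if one_tailed else p, "spearman")
    raise ValueError(f"unknown test kind {kind!r}")


def subject_summary(behavior: pd.DataFrame, task, group: str = "") -> dict:
    """Per-subject summary: expectedness means, time-bin means, AS score."""
    exp_m, unexp_m = expectedness_analysis(behavior, task)
    bins = timebin_means(behavior, task)
    summary = {
        "mean_logrt_expected": exp_m,
        "mean_logrt_unexpected": unexp_m,
        "as_score_ms": aberrant_salience_raw(behavior, task),
        "group": group,
    }
    for cond in ("coin", "circle"):
        for b in range(4):
            summary[f"{cond}_bin{b + 1}"] = float(bins.loc[cond, f"bin{b + 1}"])
    return summary
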