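"""Implicit Salience Paradigm (ISP) task generation and behavior simulation.

The ISP is an outcome-detection task: on each trial a cue with two binary
features (color: colorful/grey; shape: square/triangle) precedes a binary
outcome (a 10-cent coin or a neutral circle) which the participant classifies
by button press. One feature is *relevant*: one of its manifestations is
followed by the coin with probability ``contingency`` (default 0.8), the
other by the circle, and the rewarded manifestation reverses every block of
20 trials. The other feature is *irrelevant* (coin/circle at 50% each). After
half of the session the relevant dimension itself switches. Learning is
incidental — participants are never told about the contingencies.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

COLOR_MANIFESTATIONS = ("colorful", "grey")
SHAPE_MANIFESTATIONS = ("square", "triangle")
OUTCOMES = ("coin", "circle")
DIMENSIONS = ("color", "shape")

#: columns of the tidy per-trial table
TRIAL_COLUMNS = [
    "trial",
    "color",
    "shape",
    "outcome",
    "relevant_dimension",
    "rewarded_manifestation",
    "expected",
]

BEHAVIOR_COLUMNS = ["trial", "rt_ms", "responded"]


@dataclass(frozen=True)
class TaskConfig:
    """Design parameters of one ISP session.

    With the defaults (160 trials, 20-trial blocks, 0.8 contingency, switch
    after 80 trials) the session pays out 80 coins x 0.10 EUR = 8 EUR.
    """

    n_trials: int = 160
    block_length: int = 20
    contingency: float = 0.8
    switch_trial: int = 80
    first_relevant_dimension: str = "color"
    coin_value: float = 0.10
    exact_counts: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials <= 0 or self.n_trials % self.block_length != 0:
            raise ValueError(
                f"n_trials ({self.n_trials}) must be a positive multiple of "
                f"block_length ({self.block_length})"
            )
        if not (0.5 < self.contingency <= 1.0):
            raise ValueError(f"contingency must lie in (0.5, 1], got {self.contingency}")
        if self.switch_trial % self.block_length != 0 or not (
            0 < self.switch_trial <= self.n_trials
        ):
            raise ValueError(
                "switch_trial must be a positive multiple of block_length "
                "no larger than n_trials"
            )
        if self.first_relevant_dimension not in DIMENSIONS:
            raise ValueError(f"unknown dimension {self.first_relevant_dimension!r}")
        if self.block_length % 4 != 0:
            raise ValueError("block_length must be divisible by 4")


@dataclass
class TaskSequence:
    """A generated ISP session: trial table plus the ground-truth schedule.

    ``trials`` is a tidy DataFrame with one row per trial (columns
    ``TRIAL_COLUMNS``); ``schedule`` holds one row per block with the
    relevant dimension and currently rewarded manifestation.
    """

    config: TaskConfig
    trials: pd.DataFrame
    schedule: pd.DataFrame

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def total_coin_value(self) -> float:
        """Monetary payout: number of coin outcomes times the coin value (EUR)."""
        return float((self.trials["outcome"] == "coin").sum()) * self.config.coin_value

    def half_of_trial(self, trial: int) -> int:
        """Test half (0 or 1) of a 1-based trial index."""
        return 0 if trial <= self.config.switch_trial else 1

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TaskSequence):
            return NotImplemented
        return (
            self.config == other.config
            and self.trials.reset_index(drop=True).equals(other.trials.reset_index(drop=True))
            and self.schedule.reset_index(drop=True).equals(
                other.schedule.reset_index(drop=True)
            )
        )


def _manifestations(dimension: str) -> tuple[str, str]:
    return COLOR_MANIFESTATIONS if dimension == "color" else SHAPE_MANIFESTATIONS


def generate_task(config: TaskConfig | None = None) -> TaskSequence:
    """Generate one ISP session with the ground-truth contingency structure.

    In ``exact_counts`` mode (default) every block realizes the design
    frequencies exactly: with a 0.8 contingency and 20-trial blocks, the
    rewarded relevant manifestation is followed by the coin on 8 of its 10
    presentations, the non-rewarded one on 2 of its 10, each block contains
    exactly 10 coins and 10 circles, and each irrelevant manifestation is
    followed by the coin on exactly half of its presentations. Trial order
    within a block is a seeded permutation. With ``exact_counts`` off,
    cue manifestations and outcomes are drawn independently per trial with
    the scheduled probabilities.

    The rewarded manifestation alternates deterministically from block to
    block (if colorful is rewarded in one block, grey is rewarded in the
    next); the relevant dimension flips at ``switch_trial``.
    """
    cfg = config if config is not None else TaskConfig()
    rng = np.random.default_rng(cfg.seed)
    n_blocks = cfg.n_trials // cfg.block_length

    other_dim = "shape" if cfg.first_relevant_dimension == "color" else "color"
    rows: list[dict] = []
    schedule_rows: list[dict] = []
    for b in range(n_blocks):
        block_start = b * cfg.block_length  # 0-based
        rel_dim = cfg.first_relevant_dimension if block_start < cfg.switch_trial else other_dim
        irr_dim = "shape" if rel_dim == "color" else "color"
        rel_manifs = _manifestations(rel_dim)
        irr_manifs = _manifestations(irr_dim)
        rewarded = rel_manifs[b % 2]
        unrewarded = rel_manifs[(b + 1) % 2]
        schedule_rows.append(
            {
                "block": b + 1,
                "first_trial": block_start + 1,
                "relevant_dimension": rel_dim,
                "rewarded_manifestation": rewarded,
            }
        )
        if cfg.exact_counts:
            rows.extend(
                _exact_block(rng, cfg, rewarded, unrewarded, irr_manifs, rel_dim, block_start)
            )
        else:
            rows.extend(
                _bernoulli_block(rng, cfg, rewarded, unrewarded, irr_manifs, rel_dim, block_start)
            )

    trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    rel_manif = np.where(
        trials["relevant_dimension"].to_numpy() == "color",
        trials["color"].to_numpy(),
        trials["shape"].to_numpy(),
    )
    is_rewarded = rel_manif == trials["rewarded_manifestation"].to_numpy()
    is_coin = (trials["outcome"] == "coin").to_numpy()
    trials["expected"] = np.where(is_rewarded == is_coin, "expected", "unexpected")
    return TaskSequence(config=cfg, trials=trials, schedule=pd.DataFrame(schedule_rows))


def _block_rows(cfg, pairs, rel_dim, block_start):
    irr_dim = "shape" if rel_dim == "color" else "color"
    rows = []
    for i, (rel_m, irr_m, outcome, rewarded) in enumerate(pairs):
        rows.append(
            {
                "trial": block_start + i + 1,
                rel_dim: rel_m,
                irr_dim: irr_m,
                "outcome": outcome,
                "relevant_dimension": rel_dim,
                "rewarded_manifestation": rewarded,
                "expected": "",  # filled in afterwards
            }
        )
    return rows


def _exact_block(rng, cfg, rewarded, unrewarded, irr_manifs, rel_dim, block_start):
    half = cfg.block_length // 2  # presentations per relevant manifestation
    n_rew_coin = cfg.contingency * half
    if abs(n_rew_coin - round(n_rew_coin)) > 1e-9:
        raise ValueError(
            "exact_counts requires contingency * block_length / 2 to be an integer"
        )
    k = int(round(n_rew_coin))
    pairs = (
        [(rewarded, "coin")] * k
        + [(rewarded, "circle")] * (half - k)
        + [(unrewarded, "coin")] * (half - k)
        + [(unrewarded, "circle")] * k
    )
    # balance the irrelevant manifestation 50/50 within each outcome type
    full = []
    for outcome in OUTCOMES:
        sub = [p for p in pairs if p[1] == outcome]
        n = len(sub)
        irr = np.array([irr_manifs[0]] * (n // 2) + [irr_manifs[1]] * (n - n // 2))
        rng.shuffle(irr)
        full.extend((rel_m, irr_m, outc, rewarded) for (rel_m, outc), irr_m in zip(sub, irr))
    order = rng.permutation(len(full))
    return _block_rows(cfg, [full[i] for i in order], rel_dim, block_start)


def _bernoulli_block(rng, cfg, rewarded, unrewarded, irr_manifs, rel_dim, block_start):
    pairs = []
    for _ in range(cfg.block_length):
        rel_m = rewarded if rng.random() < 0.5 else unrewarded
        irr_m = irr_manifs[0] if rng.random() < 0.5 else irr_manifs[1]
        p_coin = cfg.contingency if rel_m == rewarded else 1.0 - cfg.contingency
        outcome = "coin" if rng.random() < p_coin else "circle"
        pairs.append((rel_m, irr_m, outcome, rewarded))
    return _block_rows(cfg, pairs, rel_dim, block_start)


def simulate_subject(
    task: TaskSequence,
    model_id,
    learn_params,
    resp_params,
    seed: int = 0,
    miss_rate: float = 0.0,
) -> pd.DataFrame:
    """Simulate one synthetic subject's reaction times on a task session.

    Runs the learning model over the trial sequence, computes each trial's
    predicted mean log reaction time under the response model, adds zero-mean
    Gaussian noise with variance ``zeta``, and exponentiates to milliseconds.
    All trials are marked responded unless ``miss_rate`` > 0, in which case a
    seeded Bernoulli draw marks trials as missed (rt set to NaN).

    ``model_id`` may be a ``ModelSpec`` or None; if given, it must agree with
    the variants carried by the parameter objects.
    """
    from relsal.hgf import run_two_branch
    from relsal.response import predict_logrt

    if model_id is not None:
        if getattr(model_id, "learning", None) != learn_params.variant:
            raise ValueError(
                f"model {model_id} does not match learning variant {learn_params.variant!r}"
            )
        if getattr(model_id, "response", None) != resp_params.variant:
            raise ValueError(
                f"model {model_id} does not match response variant {resp_params.variant!r}"
            )
    if resp_params.zeta < 0:
        raise ValueError(f"noise variance zeta must be >= 0, got {resp_params.zeta}")
    if not (0.0 <= miss_rate < 1.0):
        raise ValueError("miss_rate must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    traj = run_two_branch(task, learn_params)
    mean_logrt = predict_logrt(traj, task, resp_params)
    noise = (
        rng.normal(0.0, np.sqrt(resp_params.zeta), size=task.n_trials)
        if resp_params.zeta > 0
        else np.zeros(task.n_trials)
    )
    rt_ms = np.exp(mean_logrt + noise)
    responded = np.ones(task.n_trials, dtype=bool)
    if miss_rate > 0:
        responded = rng.random(task.n_trials) >= miss_rate
        rt_ms = np.where(responded, rt_ms, np.nan)
    return pd.DataFrame(
        {
            "trial": task.trials["trial"].to_numpy(),
            "rt_ms": rt_ms,
            "responded": responded,
        }
    )


def write_session(
    task: TaskSequence, behavior: pd.DataFrame | None, path, subject_id: str = "s01"
) -> None:
    """Serialize a session (trials plus optional behavior) to one tidy TSV."""
    import json

    df = task.trials.copy()
    df.insert(0, "subject_id", subject_id)
    if behavior is not None:
        merged = behavior.set_index("trial")
        df["rt_ms"] = merged["rt_ms"].reindex(df["trial"]).to_numpy()
        df["responded"] = merged["responded"].reindex(df["trial"]).to_numpy()
    else:
        df["rt_ms"] = np.nan
        df["responded"] = False
    with open(path, "w") as fh:
        fh.write("# config: " + json.dumps(dataclasses.asdict(task.config)) + "\n")
        df.to_csv(fh, sep="\t", index=False)
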