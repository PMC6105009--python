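"""Two-branch binary hierarchical Gaussian filter (HGF) with precision-based relevance.

Each cue feature (color, shape) is learned by its own binary HGF branch: a
level-2 Gaussian random walk over the tendency ``mu2`` whose logistic
transform is the outcome prediction ``mu1hat``, optionally topped by a
level-3 volatility state. The first-level precision

    pi1hat = 1 / (mu1hat * (1 - mu1hat))

is the model's definition of a feature's subjective *relevance*: it has a
minimum of 4 at ``mu1hat = 0.5`` (a maximally uninformative feature) and
grows without bound as the prediction becomes confident. Relevance weights
normalize the two branches' first-level precisions to sum to one; a
feature's irrelevance weight is the other feature's relevance weight.

Branch inputs are binary recodings of (manifestation, outcome) pairs. The
direction of this coding is arbitrary (beliefs track association strength,
not reward value); the fixed reference pairing is: u_color = 1 iff
(colorful AND coin) or (grey AND circle); u_shape = 1 iff (triangle AND
coin) or (square AND circle).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

LEARNING_VARIANTS = ("2HGF", "2HGFprecfb", "3HGF", "3HGFprecfb")

#: logistic argument clamp and level-2 variance floor (numerical guards)
MU2_CLAMP = 36.0
SIGMA2_FLOOR = 1e-12


@dataclass(frozen=True)
class LearnParams:
    """Learning-model parameters shared by the two branches.

    ``omega`` is the log-volatility of the level-2 random walk and
    ``sigma2_0`` the initial level-2 variance; these are the free parameters.
    The level-2 initial mean is fixed at 0 (agnostic prior, prediction 0.5).
    For the 3-level variants the level-2/3 coupling ``kappa``, the level-3
    log step variance ``omega3``, and the level-3 initial state are fixed
    structural constants (configurable here, not fitted).
    """

    omega: float = -3.0
    sigma2_0: float = 0.05
    mu2_0: float = 0.0
    kappa: float = 1.0
    omega3: float = -6.0
    mu3_0: float = 1.0
    sigma3_0: float = 0.1
    variant: str = "2HGF"

    def __post_init__(self) -> None:
        if self.variant not in LEARNING_VARIANTS:
            raise ValueError(f"unknown learning variant {self.variant!r}")
        if not self.sigma2_0 > 0:
            raise ValueError(f"sigma2_0 must be > 0, got {self.sigma2_0}")
        if self.three_level and not self.kappa > 0:
            raise ValueError("kappa must be > 0 for 3-level variants")

    @property
    def three_level(self) -> bool:
        return self.variant.startswith("3")

    @property
    def precision_feedback(self) -> bool:
        return self.variant.endswith("precfb")


@dataclass
class BranchState:
    """Posterior state of one branch after (or before) a trial."""

    mu2: float
    sigma2: float
    mu3: float = 1.0
    sigma3: float = 0.1
    mu1hat: float = float("nan")
    pi1hat: float = float("nan")
    delta1: float = float("nan")


@dataclass
class Trajectories:
    """Per-trial belief trajectories of both branches.

    All arrays have length ``n_trials``. Quantities indexed by trial k are
    prediction-time values for mu1hat/pi1hat/relevance (computed before the
    trial's outcome) and update-time for delta1 (requires the outcome).
    """

    u_color: np.ndarray
    u_shape: np.ndarray
    mu1hat_color: np.ndarray
    mu1hat_shape: np.ndarray
    pi1hat_color: np.ndarray
    pi1hat_shape: np.ndarray
    delta1_color: np.ndarray
    delta1_shape: np.ndarray
    rel_color: np.ndarray
    rel_shape: np.ndarray
    mu2_color: np.ndarray
    mu2_shape: np.ndarray
    valid: bool = True
    n_clamped: int = 0
    n_floored: int = 0

    @property
    def n_trials(self) -> int:
        return len(self.u_color)

    def to_frame(self, subject_id: str = "s01"):
        """Tidy long-format table (subject, trial, branch, ...) for export."""
        import pandas as pd

        n = self.n_trials
        frames = []
        for branch, u, mu, pi, d in (
            ("color", self.u_color, self.mu1hat_color, self.pi1hat_color, self.delta1_color),
            ("shape", self.u_shape, self.mu1hat_shape, self.pi1hat_shape, self.delta1_shape),
        ):
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": subject_id,
                        "trial": np.arange(1, n + 1),
                        "branch": branch,
                        "u": u,
                        "mu1hat": mu,
                        "pi1hat": pi,
                        "delta1": d,
                        "rel_color": self.rel_color,
                        "rel_shape": self.rel_shape,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def precision_of_prediction(mu1hat: float) -> float:
    """First-level precision 1/(mu1hat*(1-mu1hat)) — the relevance measure.

    Minimum 4 at ``mu1hat = 0.5``; symmetric; diverges toward 0 and 1.
    """
    mu1hat = float(mu1hat)
    if not 0.0 < mu1hat < 1.0:
        raise ValueError(f"mu1hat must lie strictly in (0, 1), got {mu1hat}")
    return 1.0 / (mu1hat * (1.0 - mu1hat))


def relevance_weights(pi1hat_color: float, pi1hat_shape: float) -> tuple[float, float]:
    """Normalize the two branches' first-level precisions to relevance weights.

    Returns ``(rel_color, rel_shape)`` summing to one. A feature's
    irrelevance weight is by definition the other feature's relevance weight.
    """
    if pi1hat_color < 4.0 - 1e-9 or pi1hat_shape < 4.0 - 1e-9:
        raise ValueError("first-level precisions must be >= 4")
    total = pi1hat_color + pi1hat_shape
    rel_color = pi1hat_color / total
    return rel_color, 1.0 - rel_color


def encode_branch_inputs(task) -> tuple[np.ndarray, np.ndarray]:
    """Binary branch inputs under the fixed reference pairing (see module docstring)."""
    color = task.trials["color"].to_numpy()
    shape = task.trials["shape"].to_numpy()
    coin = (task.trials["outcome"] == "coin").to_numpy()
    u_color = ((color == "colorful") & coin) | ((color == "grey") & ~coin)
    u_shape = ((shape == "triangle") & coin) | ((shape == "square") & ~coin)
    return u_color.astype(np.float64), u_shape.astype(np.float64)


def branch_step(
    state: BranchState,
    u: float,
    params: LearnParams,
    rel_weight: float | None = None,
) -> BranchState:
    """One trial's belief update for a single branch (reference implementation).

    The prediction is ``mu1hat = logistic(mu2)``; the first-level prediction
    error ``delta1 = u - mu1hat`` moves the level-2 mean by
    ``delta1 / pi2`` where ``pi2`` is the updated level-2 precision. In
    3-level variants the level-3 volatility state modulates the level-2 step
    size and is itself updated from the level-2 volatility prediction error.

    Precision-feedback variants scale ``delta1`` in the level-2 mean update
    by ``2 * rel_weight`` — the branch's relevance weight relative to
    indifference (0.5), so a branch believed relevant updates up to twice as
    fast, an irrelevant one down to not at all, and at equal relevance the
    update reduces exactly to the standard one.
    """
    if u not in (0.0, 1.0):
        raise ValueError(f"branch input must be binary, got {u}")
    if params.precision_feedback and rel_weight is None:
        raise ValueError("precision-feedback variants require a relevance weight")
    w = 1.0 if rel_weight is None else 2.0 * float(rel_weight)
    out = _step(
        state.mu2,
        state.sigma2,
        state.mu3,
        state.sigma3,
        float(u),
        w,
        params.omega,
        params.three_level,
        params.kappa,
        params.omega3,
    )
    (mu1hat, pi1hat, delta1, mu2, sigma2, mu3, sigma3, ok, clamped, floored) = out
    if not ok:
        raise FloatingPointError("level-3 precision became non-positive")
    if sigma2 <= 0:
        raise FloatingPointError("level-2 variance became non-positive")
    return BranchState(
        mu2=mu2,
        sigma2=sigma2,
        mu3=mu3,
        sigma3=sigma3,
        mu1hat=mu1hat,
        pi1hat=pi1hat,
        delta1=delta1,
    )


@njit(cache=True)
def _step(mu2, sigma2, mu3, sigma3, u, rel_w, omega, three_level, kappa, omega3):
    """Single-branch binary HGF update (shared by the python and array paths)."""
    clamped = 0
    floored = 0
    a = mu2
    if a > MU2_CLAMP:
        a = MU2_CLAMP
        clamped = 1
    elif a < -MU2_CLAMP:
        a = -MU2_CLAMP
        clamped = 1
    mu1hat = 1.0 / (1.0 + np.exp(-a))
    pi1hat = 1.0 / (mu1hat * (1.0 - mu1hat))
    delta1 = u - mu1hat
    if three_level:
        ehat = np.exp(kappa * mu3 + omega)
    else:
        ehat = np.exp(omega)
    sigma2hat = sigma2 + ehat
    pi2 = 1.0 / sigma2hat + mu1hat * (1.0 - mu1hat)
    sigma2_new = 1.0 / pi2
    if sigma2_new < SIGMA2_FLOOR:
        sigma2_new = SIGMA2_FLOOR
        floored = 1
    mu2_new = mu2 + sigma2_new * (rel_w * delta1)
    ok = True
    mu3_new = mu3
    sigma3_new = sigma3
    if three_level:
        sigma3hat = sigma3 + np.exp(omega3)
        pi3hat = 1.0 / sigma3hat
        w2 = ehat / sigma2hat
        delta2 = (sigma2_new + (mu2_new - mu2) ** 2) / sigma2hat - 1.0
        pi3 = pi3hat + (kappa * kappa / 2.0) * w2 * (w2 + (2.0 * w2 - 1.0) * delta2)
        if pi3 <= 0.0:
            ok = False
        else:
            sigma3_new = 1.0 / pi3
            mu3_new = mu3 + (kappa / 2.0) * sigma3_new * w2 * delta2
    return (mu1hat, pi1hat, delta1, mu2_new, sigma2_new, mu3_new, sigma3_new, ok, clamped, floored)


@njit(cache=True)
def _run_branches(
    u_c, u_s, omega, sigma2_0, mu2_0, three_level, kappa, omega3, mu3_0, sigma3_0, precfb
):
    n = u_c.shape[0]
    mu1hat_c = np.empty(n)
    mu1hat_s = np.empty(n)
    pi1hat_c = np.empty(n)
    pi1hat_s = np.empty(n)
    delta1_c = np.empty(n)
    delta1_s = np.empty(n)
    rel_c_arr = np.empty(n)
    rel_s_arr = np.empty(n)
    mu2_c_arr = np.empty(n)
    mu2_s_arr = np.empty(n)
    mu2_c, s2_c, mu3_c, s3_c = mu2_0, sigma2_0, mu3_0, sigma3_0
    mu2_s, s2_s, mu3_s, s3_s = mu2_0, sigma2_0, mu3_0, sigma3_0
    rel_prev_c = 0.5
    rel_prev_s = 0.5
    ok = True
    n_clamped = 0
    n_floored = 0
    for k in range(n):
        wc = 2.0 * rel_prev_c if precfb else 1.0
        ws = 2.0 * rel_prev_s if precfb else 1.0
        rc = _step(mu2_c, s2_c, mu3_c, s3_c, u_c[k], wc, omega, three_level, kappa, omega3)
        rs = _step(mu2_s, s2_s, mu3_s, s3_s, u_s[k], ws, omega, three_level, kappa, omega3)
        if not (rc[7] and rs[7]):
            ok = False
            break
        mu1hat_c[k], pi1hat_c[k], delta1_c[k] = rc[0], rc[1], rc[2]
        mu1hat_s[k], pi1hat_s[k], delta1_s[k] = rs[0], rs[1], rs[2]
        mu2_c_arr[k], mu2_s_arr[k] = mu2_c, mu2_s
        total = rc[1] + rs[1]
        rel_c_arr[k] = rc[1] / total
        rel_s_arr[k] = rs[1] / total
        mu2_c, s2_c, mu3_c, s3_c = rc[3], rc[4], rc[5], rc[6]
        mu2_s, s2_s, mu3_s, s3_s = rs[3], rs[4], rs[5], rs[6]
        rel_prev_c = rel_c_arr[k]
        rel_prev_s = rel_s_arr[k]
        n_clamped += rc[8] + rs[8]
        n_floored += rc[9] + rs[9]
    return (
        mu1hat_c,
        mu1hat_s,
        pi1hat_c,
        pi1hat_s,
        delta1_c,
        delta1_s,
        rel_c_arr,
        rel_s_arr,
        mu2_c_arr,
        mu2_s_arr,
        ok,
        n_clamped,
        n_floored,
    )


def run_two_branch(task, params: LearnParams) -> Trajectories:
    """Run both HGF branches over a task sequence.

    The branches share one (omega, sigma2_0) parameter pair. In
    precision-feedback variants the branches are coupled: trial k's level-2
    mean update is scaled by the branch's relevance weight computed from
    trial k-1's predictions (0.5/0.5 on the first trial), so that beliefs
    about an irrelevant feature are updated less.
    """
    u_c, u_s = encode_branch_inputs(task)
    out = _run_branches(
        u_c,
        u_s,
        params.omega,
        params.sigma2_0,
        params.mu2_0,
        params.three_level,
        params.kappa,
        params.omega3,
        params.mu3_0,
        params.sigma3_0,
        params.precision_feedback,
    )
    traj = Trajectories(
        u_color=u_c,
        u_shape=u_s,
        mu1hat_color=out[0],
        mu1hat_shape=out[1],
        pi1hat_color=out[2],
        pi1hat_shape=out[3],
        delta1_color=out[4],
        delta1_shape=out[5],
        rel_color=out[6],
        rel_shape=out[7],
        mu2_color=out[8],
        mu2_shape=out[9],
        valid=bool(out[10]),
        n_clamped=int(out[11]),
        n_floored=int(out[12]),
    )
    return traj
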