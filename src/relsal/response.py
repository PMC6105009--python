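"""Response models: from belief trajectories to mean log reaction times.

All four variants share the linear form

    log(rt_k) = beta0 + beta1 * PE_k
                - w_color_k * (beta2 * m_colorful + beta3 * m_grey)
                - w_shape_k * (beta4 * m_square + beta5 * m_triangle)
                + beta6 * outcome_k          (circle = 1, coin = 0)
                + Gaussian noise, variance zeta

where PE_k is the mean of the two branches' unsigned first-level prediction
errors. The variants differ in two switches: RelPE weights each branch's
|delta1| by its relevance weight inside the mean, and IrrelBias scales the
constant manifestation-bias terms by the feature's irrelevance weight (a
bias toward one manifestation matters most when its feature is believed to
be uninformative). The full model (RelPE+IrrelBias) applies both.

The composite parameter beta_irrelevance — the mean of the absolute
within-feature coefficient differences — summarizes an individual's
idiosyncratic bias toward one of two equally irrelevant manifestations and
is the model-based analogue of the raw aberrant salience score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

RESPONSE_VARIANTS = ("BL", "RelPE", "IrrelBias", "RelPE+IrrelBias")

BETA_NAMES = ("beta0", "beta1", "beta2", "beta3", "beta4", "beta5", "beta6")


@dataclass(frozen=True)
class RespParams:
    beta0: float = 6.2
    beta1: float = 0.2
    beta2: float = 0.0
    beta3: float = 0.0
    beta4: float = 0.0
    beta5: float = 0.0
    beta6: float = 0.07
    zeta: float = 0.04
    variant: str = "BL"

    def __post_init__(self) -> None:
        if self.variant not in RESPONSE_VARIANTS:
            raise ValueError(f"unknown response variant {self.variant!r}")
        if self.zeta < 0:
            raise ValueError(f"zeta must be >= 0, got {self.zeta}")

    @property
    def betas(self) -> np.ndarray:
        return np.array([getattr(self, b) for b in BETA_NAMES])


def manifestation_vectors(task) -> dict[str, np.ndarray]:
    """Per-trial 0/1 indicators of the four cue manifestations."""
    color = task.trials["color"].to_numpy()
    shape = task.trials["shape"].to_numpy()
    return {
        "m_colorful": (color == "colorful").astype(float),
        "m_grey": (color == "grey").astype(float),
        "m_square": (shape == "square").astype(float),
        "m_triangle": (shape == "triangle").astype(float),
    }


def design_matrix(traj, task, variant: str) -> np.ndarray:
    """(n_trials, 7) design matrix; column j multiplies beta_j.

    Columns: intercept, (relevance-weighted) mean unsigned PE, the four
    negated manifestation indicators (scaled by irrelevance weights under
    IrrelBias variants), and the outcome code (circle = 1, coin = 0).
    """
    if variant not in RESPONSE_VARIANTS:
        raise ValueError(f"unknown response variant {variant!r}")
    n = traj.n_trials
    m = manifestation_vectors(task)
    abs_dc = np.abs(traj.delta1_color)
    abs_ds = np.abs(traj.delta1_shape)
    if "RelPE" in variant:
        pe = (traj.rel_color * abs_dc + traj.rel_shape * abs_ds) / 2.0
    else:
        pe = (abs_dc + abs_ds) / 2.0
    if "IrrelBias" in variant:
        # irrelevance of a feature = relevance weight of the other feature
        w_color = traj.rel_shape
        w_shape = traj.rel_color
    else:
        w_color = np.ones(n)
        w_shape = np.ones(n)
    outcome = (task.trials["outcome"] == "circle").to_numpy().astype(float)
    X = np.column_stack(
        [
            np.ones(n),
            pe,
            -w_color * m["m_colorful"],
            -w_color * m["m_grey"],
            -w_shape * m["m_square"],
            -w_shape * m["m_triangle"],
            outcome,
        ]
    )
    return X


def predict_logrt(traj, task, params: RespParams) -> np.ndarray:
    """Predicted mean log reaction time per trial under the given variant."""
    return design_matrix(traj, task, params.variant) @ params.betas


def response_loglik(
    log_rt: np.ndarray,
    predictions: np.ndarray,
    zeta: float,
    valid: np.ndarray | None = None,
) -> float:
    """Gaussian log-likelihood of observed log RTs at the predicted means.

    Sums the log-density with variance ``zeta`` over valid trials only;
    invalid/missing trials contribute nothing.
    """
    log_rt = np.asarray(log_rt, dtype=float)
    predictions = np.asarray(predictions, dtype=float)
    if log_rt.shape != predictions.shape:
        raise ValueError(
            f"length mismatch: {log_rt.shape} observations vs {predictions.shape} predictions"
        )
    if zeta <= 0:
        raise ValueError(f"zeta must be > 0, got {zeta}")
    if valid is not None:
        log_rt = log_rt[valid]
        predictions = predictions[valid]
    r = log_rt - predictions
    n = r.size
    return float(-0.5 * n * np.log(2.0 * np.pi * zeta) - 0.5 * np.sum(r * r) / zeta)


def composite_beta_irrelevance(beta2: float, beta3: float, beta4: float, beta5: float) -> float:
    """Mean of the absolute within-feature manifestation-bias differences.

    (|beta2 - beta3| + |beta4 - beta5|) / 2 — zero iff the subject is
    unbiased within both features, and invariant to relabeling the
    manifestations within a feature.
    """
    return 0.5 * (abs(beta2 - beta3) + abs(beta4 - beta5))
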