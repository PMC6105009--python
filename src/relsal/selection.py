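"""Random-effects Bayesian model selection (RFX-BMS) over the model space.

Model identity is treated as a random effect in the population: model
frequencies r follow a Dirichlet prior, each subject's model assignment a
multinomial draw, and each subject's data enter through the approximate log
model evidences. A variational fixed-point iteration yields the Dirichlet
posterior concentrations alpha; the expected frequencies alpha / sum(alpha)
are the posterior model probabilities (PP). Exceedance probabilities (XP)
are Monte-Carlo estimates of each model's frequency being the largest.
The Bayesian omnibus risk (BOR) is the posterior probability of the
equal-frequency null hypothesis, and the protected exceedance probability
(PXP) shrinks the XP toward uniform by that risk:

    PXP_k = (1 - BOR) * XP_k + BOR / K
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betainc, digamma, gammaln, logsumexp

from relsal.inference import MODEL_SPACE

#: family partitions used in the study's model comparison
DEFAULT_FAMILIES = {
    "learning_feedback": {
        "HGF": [m.id for m in MODEL_SPACE if not m.learning.endswith("precfb")],
        "HGFprecfb": [m.id for m in MODEL_SPACE if m.learning.endswith("precfb")],
    },
    "levels": {
        "2HGF": [m.id for m in MODEL_SPACE if m.learning.startswith("2")],
        "3HGF": [m.id for m in MODEL_SPACE if m.learning.startswith("3")],
    },
    "response": {
        r: [m.id for m in MODEL_SPACE if m.response == r]
        for r in ("BL", "RelPE", "IrrelBias", "RelPE+IrrelBias")
    },
}


@dataclass
class FamilyResult:
    names: tuple[str, ...]
    pp: np.ndarray
    xp: np.ndarray


@dataclass
class BMSResult:
    model_ids: tuple[str, ...]
    alpha: np.ndarray
    pp: np.ndarray
    xp: np.ndarray
    bor: float
    pxp: np.ndarray
    family_results: dict[str, FamilyResult] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"model": self.model_ids, "alpha": self.alpha, "pp": self.pp, "xp": self.xp,
             "pxp": self.pxp}
        )


def _as_matrix(L) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(L, pd.DataFrame):
        return L.to_numpy(dtype=float), tuple(L.columns)
    L = np.asarray(L, dtype=float)
    return L, tuple(f"m{j + 1}" for j in range(L.shape[1]))


def _vb_fixed_point(L: np.ndarray, alpha0: np.ndarray, max_iter: int, tol: float):
    """Variational Dirichlet-multinomial iteration; returns (alpha, g)."""
    n, K = L.shape
    alpha = alpha0.copy()
    g = np.full((n, K), 1.0 / K)
    for _ in range(max_iter):
        logu = L + digamma(alpha)[None, :] - digamma(alpha.sum())
        g = np.exp(logu - logsumexp(logu, axis=1, keepdims=True))
        alpha_new = alpha0 + g.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    else:
        raise RuntimeError(f"RFX-BMS fixed point did not converge in {max_iter} iterations")
    return alpha, g


def rfx_bms(L, alpha0: float | np.ndarray = 1.0, max_iter: int = 10_000, tol: float = 1e-8):
    """Variational RFX-BMS; returns (alpha, pp).

    ``L`` is the subjects x models matrix of approximate log model evidences
    (rows may be shifted by any per-subject constant without effect).
    """
    Lm, _ = _as_matrix(L)
    if Lm.ndim != 2 or Lm.shape[0] < 1 or Lm.shape[1] < 2:
        raise ValueError("need a 2-D evidence matrix with >= 1 subject and >= 2 models")
    if not np.all(np.isfinite(Lm)):
        raise ValueError("evidence matrix contains non-finite values")
    K = Lm.shape[1]
    alpha0 = np.broadcast_to(np.asarray(alpha0, dtype=float), (K,)).copy()
    if np.any(alpha0 <= 0):
        raise ValueError("alpha0 must be positive")
    alpha, _ = _vb_fixed_point(Lm, alpha0, max_iter, tol)
    return alpha, alpha / alpha.sum()


def _dirichlet_free_energy(L, alpha0, alpha, g) -> float:
    """Variational free energy of the alternative (frequencies-differ) model."""
    a_s = alpha.sum()
    psi = digamma(alpha) - digamma(a_s)
    e_loglik = float(np.sum(g * L))
    e_logpz = float(np.sum(g * psi[None, :]))
    ent_z = -float(np.sum(g[g > 0] * np.log(g[g > 0])))
    e_logpr = float(
        gammaln(alpha0.sum()) - gammaln(alpha0).sum() + np.sum((alpha0 - 1.0) * psi)
    )
    ent_r = -float(gammaln(a_s) - gammaln(alpha).sum() + np.sum((alpha - 1.0) * psi))
    return e_loglik + e_logpz + e_logpr + ent_z + ent_r


def _null_free_energy(L: np.ndarray) -> float:
    """Log evidence of the null: every subject's model drawn uniformly."""
    n, K = L.shape
    return float(np.sum(logsumexp(L, axis=1) - np.log(K)))


def exceedance_and_protected(
    L,
    alpha: np.ndarray,
    n_samples: int = 1_000_000,
    seed: int = 0,
    alpha0: float | np.ndarray = 1.0,
):
    """Monte-Carlo exceedance probabilities, omnibus risk, and PXP.

    ``alpha`` must come from :func:`rfx_bms` on the same evidence matrix
    (the assignment responsibilities are re-derived from it). Sampling is
    seeded; ``n_samples`` below 1e4 is rejected as too coarse.
    """
    if n_samples < 10_000:
        raise ValueError("n_samples must be >= 1e4")
    Lm, _ = _as_matrix(L)
    K = Lm.shape[1]
    alpha = np.asarray(alpha, dtype=float)
    alpha0 = np.broadcast_to(np.asarray(alpha0, dtype=float), (K,)).copy()
    rng = np.random.default_rng(seed)
    xp = _sample_max_probability(alpha, n_samples, rng)
    # responsibilities at the fixed point are a function of (L, alpha)
    logu = Lm + digamma(alpha)[None, :] - digamma(alpha.sum())
    g = np.exp(logu - logsumexp(logu, axis=1, keepdims=True))
    f1 = _dirichlet_free_energy(Lm, alpha0, alpha, g)
    f0 = _null_free_energy(Lm)
    bor = float(1.0 / (1.0 + np.exp(f1 - f0)))
    pxp = (1.0 - bor) * xp + bor / K
    return xp, bor, pxp


def _sample_max_probability(alpha: np.ndarray, n_samples: int, rng) -> np.ndarray:
    """P(r_k is the largest frequency) under Dirichlet(alpha), by sampling."""
    K = alpha.size
    counts = np.zeros(K)
    chunk = 200_000
    left = int(n_samples)
    while left > 0:
        m = min(chunk, left)
        gam = rng.standard_gamma(alpha, size=(m, K))
        counts += np.bincount(np.argmax(gam, axis=1), minlength=K)
        left -= m
    return counts / n_samples


def xp_closed_form_2(alpha: np.ndarray) -> np.ndarray:
    """Exact exceedance probabilities for K = 2 via the regularized beta."""
    if alpha.size != 2:
        raise ValueError("closed form only for K = 2")
    # P(r1 > 0.5) = P(r2 < 0.5) = I_0.5(alpha2, alpha1)
    p1 = betainc(alpha[1], alpha[0], 0.5)
    return np.array([p1, 1.0 - p1])


def family_bms(
    L,
    partition: dict[str, list],
    alpha0: float = 1.0,
    seed: int = 0,
    n_samples: int = 1_000_000,
) -> FamilyResult:
    """Family-level inference by summing sampled Dirichlet frequencies.

    The model-level prior mass is re-divided so each family carries equal
    prior mass (``alpha0`` per-model total preserved: total mass K * alpha0
    split evenly across families, then evenly within each family). Family
    PP is the summed expected frequency of its members; family XP the
    Monte-Carlo probability that the summed frequency is the largest.
    """
    Lm, ids = _as_matrix(L)
    K = Lm.shape[1]
    id_index = {m: j for j, m in enumerate(ids)}
    seen: list[int] = []
    idx_lists = []
    for fam, members in partition.items():
        idx = [id_index[m] if m in id_index else int(m) for m in members]
        if any(i in seen for i in idx):
            raise ValueError("overlapping family partition")
        seen.extend(idx)
        idx_lists.append(idx)
    if sorted(seen) != list(range(K)):
        raise ValueError("family partition must cover every model exactly once")
    n_fam = len(partition)
    a0 = np.empty(K)
    for idx in idx_lists:
        a0[idx] = (K * alpha0 / n_fam) / len(idx)
    alpha, _ = rfx_bms(Lm, alpha0=a0)
    fam_pp = np.array([alpha[idx].sum() for idx in idx_lists]) / alpha.sum()
    rng = np.random.default_rng(seed)
    counts = np.zeros(n_fam)
    left = int(n_samples)
    while left > 0:
        m = min(200_000, left)
        gam = rng.standard_gamma(alpha, size=(m, K))
        sums = np.column_stack([gam[:, idx].sum(axis=1) for idx in idx_lists])
        counts += np.bincount(np.argmax(sums, axis=1), minlength=n_fam)
        left -= m
    return FamilyResult(names=tuple(partition), pp=fam_pp, xp=counts / n_samples)


def run_bms(
    L,
    alpha0: float = 1.0,
    n_samples: int = 1_000_000,
    seed: int = 0,
    families: dict[str, dict[str, list]] | None = None,
) -> BMSResult:
    """Full model comparison report: PP, XP, BOR, PXP, and family analyses."""
    Lm, ids = _as_matrix(L)
    alpha, pp = rfx_bms(Lm, alpha0=alpha0)
    xp, bor, pxp = exceedance_and_protected(
        Lm, alpha, n_samples=n_samples, seed=seed, alpha0=alpha0
    )
    fams = {}
    if families is None and set(ids) == {m.id for m in MODEL_SPACE}:
        families = DEFAULT_FAMILIES
    if families:
        for name, part in families.items():
            fams[name] = family_bms(
                pd.DataFrame(Lm, columns=ids), part, alpha0=alpha0, seed=seed,
                n_samples=n_samples,
            )
    return BMSResult(
        model_ids=ids, alpha=alpha, pp=pp, xp=xp, bor=bor, pxp=pxp, family_results=fams
    )
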