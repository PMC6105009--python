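"""MAP fitting and Laplace-approximate log model evidence.

Each model in the 16-model space is the combination of a learning variant
(2HGF, 2HGFprecfb, 3HGF, 3HGFprecfb — see :mod:`relsal.hgf`) with a response
variant (BL, RelPE, IrrelBias, RelPE+IrrelBias — see :mod:`relsal.response`).
Free parameters per model: the learning parameters omega and sigma2_0, the
seven response coefficients beta0..beta6, and the log-RT noise variance zeta.

Parameters are estimated in an unconstrained *estimation space* (identity,
log, or logit transform per parameter) with independent Gaussian priors
specified in that space. The MAP is found by quasi-Newton (L-BFGS-B)
optimization started from the prior mean plus seeded perturbed restarts.
Because the log-joint is exactly quadratic in the response coefficients at
fixed (omega, sigma2_0, zeta), the optimizer works on the three-dimensional
profile objective in which the betas are solved in closed form (ridge
regression against their Gaussian priors); this changes nothing about the
optimum, only the route to it.

The approximate log model evidence is the negative free energy from the
Laplace approximation at the MAP:

    F = log p(y, theta_hat) + (d/2) log(2 pi) - (1/2) log det H

with H the Hessian of the negative log-joint at the optimum and d the number
of free parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from relsal.hgf import LEARNING_VARIANTS, LearnParams
from relsal.response import BETA_NAMES, RESPONSE_VARIANTS, response_loglik

PARAM_NAMES = ("omega", "sigma2_0") + BETA_NAMES + ("zeta",)

_BIG = 1e12  # objective value standing in for an invalid trajectory


@dataclass(frozen=True)
class ModelSpec:
    """One cell of the learning x response model space."""

    learning: str
    response: str

    def __post_init__(self) -> None:
        if self.learning not in LEARNING_VARIANTS:
            raise ValueError(f"unknown learning variant {self.learning!r}")
        if self.response not in RESPONSE_VARIANTS:
            raise ValueError(f"unknown response variant {self.response!r}")

    @property
    def id(self) -> str:
        return f"{self.learning}-{self.response}"

    def __str__(self) -> str:
        return self.id


#: the full 16-model space, learning variant major
MODEL_SPACE = tuple(
    ModelSpec(l, r) for l in LEARNING_VARIANTS for r in RESPONSE_VARIANTS
)


def model_by_id(model_id: str) -> ModelSpec:
    for m in MODEL_SPACE:
        if m.id == model_id:
            return m
    raise KeyError(f"unknown model id {model_id!r}")


@dataclass(frozen=True)
class ParamPrior:
    """Gaussian prior on one parameter in its estimation space.

    ``transform`` maps estimation space to native space (identity, log, or
    logit). A prior variance of exactly 0 pins the parameter at the native
    value corresponding to the prior mean (it is then not estimated).
    """

    transform: str
    mean: float
    var: float

    def __post_init__(self) -> None:
        if self.transform not in ("identity", "log", "logit"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.var < 0:
            raise ValueError("prior variance must be >= 0")

    def to_native(self, x: float) -> float:
        if self.transform == "log":
            # overflow-safe: the objective rejects non-finite natives
            return math.exp(x) if x < 700.0 else math.inf
        if self.transform == "logit":
            return 1.0 / (1.0 + math.exp(-min(max(x, -700.0), 700.0)))
        return x

    def from_native(self, v: float) -> float:
        if self.transform == "log":
            return math.log(v)
        if self.transform == "logit":
            return math.log(v / (1.0 - v))
        return v

    def logpdf(self, x: float) -> float:
        return -0.5 * math.log(2.0 * math.pi * self.var) - 0.5 * (x - self.mean) ** 2 / self.var


def default_priors() -> dict[str, ParamPrior]:
    """Weakly informative priors on the magnitudes typical for log-RT data.

    omega ~ N(-3, 16); log sigma2_0 ~ N(ln 0.05, 1); beta0 ~ N(6, 4)
    (log RTs of a few hundred ms sit near 6); beta1..beta6 ~ N(0, 1)
    (zero-centered shrinkage also resolves the intercept/manifestation
    trade-off); log zeta ~ N(ln 0.01, 4).
    """
    pri = {
        "omega": ParamPrior("identity", -3.0, 16.0),
        "sigma2_0": ParamPrior("log", math.log(0.05), 1.0),
        "beta0": ParamPrior("identity", 6.0, 4.0),
        "zeta": ParamPrior("log", math.log(0.01), 4.0),
    }
    for b in BETA_NAMES[1:]:
        pri[b] = ParamPrior("identity", 0.0, 1.0)
    return pri


@dataclass
class FitOptions:
    n_starts: int = 5
    seed: int = 0
    perturb_scale: float = 1.0  # in prior standard deviations
    grad_tol: float = 1e-5
    maxiter: int = 200
    hessian_step: float = 1e-3


@dataclass
class FitResult:
    """MAP estimate, curvature, and approximate evidence for one subject x model."""

    model_id: str
    map_params: dict[str, float]  # native space, all parameters incl. fixed
    free_names: tuple[str, ...]
    map_est: np.ndarray  # estimation-space vector over free_names
    hessian: np.ndarray  # of the negative log-joint at the optimum
    log_joint: float
    neg_free_energy: float
    n_valid_trials: int
    diagnostics: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)


def _ensure_preprocessed(behavior: pd.DataFrame) -> pd.DataFrame:
    if "valid" not in behavior.columns or "log_rt" not in behavior.columns:
        from relsal.stats import preprocess_rts

        return preprocess_rts(behavior)
    return behavior


class _Objective:
    """Negative log-joint for one subject x model, with trajectory caching.

    The belief trajectories depend only on (omega, sigma2_0); evaluations
    that perturb response parameters reuse the cached trajectory/design.
    """

    def __init__(self, behavior, task, model: ModelSpec, priors):
        from relsal.hgf import encode_branch_inputs
        from relsal.response import manifestation_vectors

        behavior = _ensure_preprocessed(behavior)
        self.task = task
        self.model = model
        self.priors = priors
        self.valid = behavior["valid"].to_numpy()
        self.y = behavior["log_rt"].to_numpy()[self.valid]
        if self.y.size < 1:
            raise ValueError("at least one valid trial is required")
        # static per-trial regressor ingredients (hot path avoids pandas)
        self._u_c, self._u_s = encode_branch_inputs(task)
        m = manifestation_vectors(task)
        self._m = (m["m_colorful"], m["m_grey"], m["m_square"], m["m_triangle"])
        self._outcome = (task.trials["outcome"] == "circle").to_numpy().astype(float)
        self._ones = np.ones(len(self._u_c))
        self._lp_base = LearnParams(variant=model.learning)
        self.free = tuple(n for n in PARAM_NAMES if priors[n].var > 0)
        self.fixed_native = {
            n: priors[n].to_native(priors[n].mean) for n in PARAM_NAMES if priors[n].var == 0
        }
        self.free_betas = tuple(n for n in self.free if n in BETA_NAMES)
        self.outer = tuple(n for n in self.free if n not in BETA_NAMES)
        self.profile_ok = all(priors[n].transform == "identity" for n in self.free_betas)
        self._beta_idx = {n: BETA_NAMES.index(n) for n in BETA_NAMES}
        self._cache: dict[tuple[float, float], np.ndarray | None] = {}
        self.invalid_count = 0

    # -- trajectory/design cache -------------------------------------------
    def design(self, omega: float, sigma2_0: float):
        key = (omega, sigma2_0)
        if key not in self._cache:
            if len(self._cache) > 4096:
                self._cache.clear()
            self._cache[key] = self._build_design(omega, sigma2_0)
        return self._cache[key]

    def _build_design(self, omega: float, sigma2_0: float):
        from relsal.hgf import _run_branches

        if not (np.isfinite(omega) and np.isfinite(sigma2_0) and sigma2_0 > 0):
            return None
        b = self._lp_base
        out = _run_branches(
            self._u_c, self._u_s, omega, sigma2_0, b.mu2_0, b.three_level, b.kappa,
            b.omega3, b.mu3_0, b.sigma3_0, b.precision_feedback,
        )
        if not out[10]:
            return None
        delta_c, delta_s, rel_c, rel_s = out[4], out[5], out[6], out[7]
        variant = self.model.response
        abs_dc = np.abs(delta_c)
        abs_ds = np.abs(delta_s)
        if "RelPE" in variant:
            pe = (rel_c * abs_dc + rel_s * abs_ds) / 2.0
        else:
            pe = (abs_dc + abs_ds) / 2.0
        if "IrrelBias" in variant:
            w_color, w_shape = rel_s, rel_c
        else:
            w_color = w_shape = self._ones
        mc, mg, ms, mt = self._m
        X = np.column_stack(
            [
                self._ones,
                pe,
                -w_color * mc,
                -w_color * mg,
                -w_shape * ms,
                -w_shape * mt,
                self._outcome,
            ]
        )
        return X[self.valid]

    def _native(self, est: dict[str, float]) -> dict[str, float]:
        nat = dict(self.fixed_native)
        for n, x in est.items():
            nat[n] = self.priors[n].to_native(x)
        return nat

    # -- full negative log-joint over the free estimation-space vector -----
    def neg_log_joint(self, x: np.ndarray) -> float:
        est = dict(zip(self.free, x))
        nat = self._native(est)
        X = self.design(nat["omega"], nat["sigma2_0"])
        if X is None or nat["zeta"] <= 0 or not np.isfinite(nat["zeta"]):
            self.invalid_count += 1
            return _BIG
        beta = np.array([nat[b] for b in BETA_NAMES])
        ll = response_loglik(self.y, X @ beta, nat["zeta"])
        lp = sum(self.priors[n].logpdf(est[n]) for n in self.free)
        val = ll + lp
        if not np.isfinite(val):
            self.invalid_count += 1
            return _BIG
        return -val

    # -- profile objective over the non-beta parameters ---------------------
    def profile(self, outer_x: np.ndarray):
        """Return (neg log-joint, free-beta solution) at the inner optimum."""
        est = dict(zip(self.outer, outer_x))
        nat = self._native(est)
        zeta = nat["zeta"]
        X = self.design(nat["omega"], nat["sigma2_0"])
        if X is None or zeta <= 0 or not np.isfinite(zeta):
            self.invalid_count += 1
            return _BIG, None
        fixed_idx = [self._beta_idx[b] for b in BETA_NAMES if b not in self.free_betas]
        free_idx = [self._beta_idx[b] for b in self.free_betas]
        offset = 0.0
        if fixed_idx:
            fixed_vals = np.array([self.fixed_native[BETA_NAMES[i]] for i in fixed_idx])
            offset = X[:, fixed_idx] @ fixed_vals
        y_eff = self.y - offset
        beta_full = np.array([self.fixed_native.get(b, 0.0) for b in BETA_NAMES])
        if free_idx:
            Xf = X[:, free_idx]
            pm = np.array([self.priors[b].mean for b in self.free_betas])
            pv = np.array([self.priors[b].var for b in self.free_betas])
            A = Xf.T @ Xf / zeta + np.diag(1.0 / pv)
            b = Xf.T @ y_eff / zeta + pm / pv
            try:
                beta_f = np.linalg.solve(A, b)
            except np.linalg.LinAlgError:
                self.invalid_count += 1
                return _BIG, None
            beta_full[free_idx] = beta_f
        else:
            beta_f = np.array([])
        ll = response_loglik(self.y, X @ beta_full, zeta)
        lp = sum(self.priors[n].logpdf(est[n]) for n in self.outer)
        lp += sum(self.priors[b].logpdf(v) for b, v in zip(self.free_betas, beta_f))
        val = ll + lp
        if not np.isfinite(val):
            self.invalid_count += 1
            return _BIG, None
        return -val, beta_f


def log_joint(
    params_est: dict[str, float],
    behavior: pd.DataFrame,
    task,
    model: ModelSpec,
    priors: dict[str, ParamPrior] | None = None,
) -> float:
    """Log-joint density: response log-likelihood plus estimation-space log-priors.

    ``params_est`` maps free parameter names to estimation-space values;
    parameters with zero prior variance are pinned at their prior value.
    Returns ``-inf`` for numerically invalid trajectories.
    """
    priors = priors if priors is not None else default_priors()
    obj = _Objective(behavior, task, model, priors)
    if set(params_est) != set(obj.free):
        missing = set(obj.free) - set(params_est)
        extra = set(params_est) - set(obj.free)
        raise ValueError(f"parameter mismatch: missing {missing or '{}'}, extra {extra or '{}'}")
    val = obj.neg_log_joint(np.array([params_est[n] for n in obj.free]))
    return -math.inf if val >= _BIG else -val


def _numeric_hessian(f, x: np.ndarray, rel_step: float) -> np.ndarray:
    d = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((d, d))
    f0 = f(x)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return 0.5 * (H + H.T)


def laplace_evidence(
    log_joint_at_map: float, hessian: np.ndarray, eig_floor: float = 1e-6
) -> tuple[float, bool]:
    """Laplace approximation to the log model evidence.

    ``log p(y) ~= log p(y, theta_hat) + (d/2) log 2pi - (1/2) log det H``.
    Non-positive Hessian eigenvalues are clipped at ``eig_floor`` and a
    warning flag returned.
    """
    d = hessian.shape[0]
    if d == 0:
        return log_joint_at_map, False
    eig = np.linalg.eigvalsh(0.5 * (hessian + hessian.T))
    warned = bool(np.any(eig < eig_floor))
    eig = np.maximum(eig, eig_floor)
    return (
        log_joint_at_map + 0.5 * d * math.log(2.0 * math.pi) - 0.5 * float(np.sum(np.log(eig))),
        warned,
    )


def map_fit(
    behavior: pd.DataFrame,
    task,
    model: ModelSpec,
    priors: dict[str, ParamPrior] | None = None,
    options: FitOptions | None = None,
) -> FitResult:
    """MAP fit of one model to one subject's behavior, with Laplace evidence.

    Quasi-Newton optimization in estimation space from the prior mean plus
    ``n_starts - 1`` seeded perturbed starts; deterministic for a fixed seed.
    """
    priors = priors if priors is not None else default_priors()
    options = options if options is not None else FitOptions()
    obj = _Objective(behavior, task, model, priors)
    rng = np.random.default_rng(options.seed)

    warnings: list[str] = []
    use_profile = obj.profile_ok
    if use_profile:
        var_names = obj.outer
        inner = lambda x: obj.profile(x)[0]
    else:
        var_names = obj.free
        inner = obj.neg_log_joint

    x0 = np.array([priors[n].mean for n in var_names])
    sds = np.array([math.sqrt(priors[n].var) for n in var_names])
    starts = [x0]
    for _ in range(max(0, options.n_starts - 1)):
        starts.append(x0 + options.perturb_scale * sds * rng.standard_normal(len(var_names)))

    best = None
    funs = []
    grad_norms = []
    if len(var_names) == 0:
        funs.append(inner(np.array([])))
        best = (funs[0], np.array([]))
        grad_norms.append(0.0)
    else:
        for s in starts:
            res = minimize(
                inner,
                s,
                method="L-BFGS-B",
                options={"maxiter": options.maxiter, "ftol": 1e-12, "gtol": options.grad_tol},
            )
            funs.append(res.fun)
            grad_norms.append(float(np.linalg.norm(np.atleast_1d(res.jac))))
            if best is None or res.fun < best[0]:
                best = (res.fun, np.asarray(res.x, dtype=float))
    if best is None or best[0] >= _BIG:
        raise RuntimeError(f"all optimization starts invalid for model {model.id}")

    # assemble the full free estimation-space vector
    est = dict(zip(var_names, best[1]))
    if use_profile:
        _, beta_f = obj.profile(best[1])
        for name, v in zip(obj.free_betas, beta_f):
            est[name] = priors[name].from_native(v)  # identity transform by construction
    x_full = np.array([est[n] for n in obj.free])

    lj = -obj.neg_log_joint(x_full)
    H = _numeric_hessian(obj.neg_log_joint, x_full, options.hessian_step)
    nfe, eig_warned = laplace_evidence(lj, H)
    if eig_warned:
        warnings.append("hessian eigenvalues clipped at floor")
    converged = min(grad_norms) if grad_norms else 0.0
    if grad_norms and min(grad_norms) > max(options.grad_tol * 100, 1e-2):
        warnings.append(f"large gradient norm at optimum: {min(grad_norms):.2e}")

    nat = {n: priors[n].to_native(v) for n, v in est.items()}
    nat.update(obj.fixed_native)
    return FitResult(
        model_id=model.id,
        map_params=nat,
        free_names=obj.free,
        map_est=x_full,
        hessian=H,
        log_joint=float(lj),
        neg_free_energy=float(nfe),
        n_valid_trials=int(obj.y.size),
        diagnostics={
            "multistart_funs": funs,
            "multistart_spread": float(np.max(funs) - np.min(funs)) if funs else 0.0,
            "grad_norm": float(min(grad_norms)) if grad_norms else 0.0,
            "invalid_evals": obj.invalid_count,
            "profiled": use_profile,
        },
        warnings=warnings,
    )


def neg_free_energy(fit: FitResult) -> float:
    """Laplace-approximate log model evidence of a completed fit."""
    val, _ = laplace_evidence(fit.log_joint, fit.hessian)
    return val


@dataclass
class CohortFit:
    """Evidence matrix (subjects x models) plus the per-cell fit results."""

    evidence: pd.DataFrame
    fits: dict
    failures: list


def fit_cohort(
    behaviors: list[pd.DataFrame],
    tasks,
    model_space=None,
    priors: dict[str, ParamPrior] | None = None,
    options: FitOptions | None = None,
    subject_ids: list[str] | None = None,
    progress: bool = False,
) -> CohortFit:
    """Fit every model to every subject; collect the log-evidence matrix.

    ``tasks`` may be a single TaskSequence (shared design) or one per
    subject. Per-cell failures are recorded (NaN in the matrix), not fatal.
    """
    models = tuple(model_space) if model_space is not None else MODEL_SPACE
    n = len(behaviors)
    if not isinstance(tasks, (list, tuple)):
        tasks = [tasks] * n
    if len(tasks) != n:
        raise ValueError("need one task (or one per subject)")
    ids = subject_ids if subject_ids is not None else [f"s{i + 1:03d}" for i in range(n)]
    L = np.full((n, len(models)), np.nan)
    fits = {}
    failures = []
    it = enumerate(zip(ids, behaviors, tasks))
    for i, (sid, beh, task) in it:
        for j, m in enumerate(models):
            try:
                fit = map_fit(beh, task, m, priors=priors, options=options)
                L[i, j] = fit.neg_free_energy
                fits[(sid, m.id)] = fit
            except Exception as exc:  # noqa: BLE001 - per-cell failures are data
                failures.append((sid, m.id, repr(exc)))
        if progress:
            print(f"fit subject {sid} ({i + 1}/{n})", flush=True)
    ev = pd.DataFrame(L, index=ids, columns=[m.id for m in models])
    return CohortFit(evidence=ev, fits=fits, failures=failures)
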