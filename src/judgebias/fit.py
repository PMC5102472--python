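"""Hierarchical (empirical-Bayes) fitting of the decision model.

Subject-level parameter vectors h_i (inference space) are modelled as draws
from a diagonal Gaussian population prior theta = (mu, Sigma).  The prior
is estimated by Type-II maximum likelihood — maximizing the data likelihood
with the subject-level parameters integrated out — using an approximate EM
scheme:

  E-step: for each subject, a Laplace approximation of the posterior
          p(h | D_i, theta): the MAP m_i of log p(D_i|h) + log p(h|theta)
          and the covariance Phi_i from the inverse Hessian at m_i.
  M-step: moment updates
          mu     <- mean_i(m_i)
          Sigma  <- diag( mean_i(m_i m_i' + Phi_i) - mu mu' )

iterated to convergence of mu and log Sigma.  Per-subject MAP estimates
under the final prior are returned alongside the prior and a per-iteration
trace.

Numerical choices: the subject objective is maximized by L-BFGS-B with an
analytic gradient (finite differences only cross-check it in tests);
failures trigger up to ``n_restarts`` seeded restarts from prior draws.
The Hessian is a central finite difference of the gradient; if it is not
positive definite, escalating jitter is added and the subject flagged.
Population variances are floored at ``var_floor`` and flooring is counted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, ndtr, ndtri

from .model import ModelSpec, PROB_CLIP, SubjectData, trial_arrays
from .transforms import GroupPrior, from_inference_space, to_inference_space

__all__ = [
    "FitSettings",
    "SubjectPosterior",
    "FitResult",
    "map_estimate",
    "em_fit",
    "m_step",
    "subject_log_posterior",
]

_SQRT_2PI = np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class FitSettings:
    """Tolerances, caps and seeds for the EM fit."""

    max_iter: int = 200
    mu_tol: float = 1e-3          # convergence: max |delta mu|
    log_var_tol: float = 1e-2     # convergence: max |delta log Sigma_jj|
    var_floor: float = 1e-6       # floor on population variances
    n_restarts: int = 5           # seeded optimizer restarts on failure
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "FitSettings":
        """Load settings from a JSON or YAML mapping."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)


@dataclass
class SubjectPosterior:
    """Laplace approximation of one subject's parameter posterior."""

    subject_id: str
    map_estimate: np.ndarray          # m_i, inference space
    covariance: np.ndarray            # Phi_i, symmetric positive definite
    log_posterior_at_map: float
    hessian_jittered: bool = False    # True if PD required added jitter

    def sd(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))


@dataclass
class FitResult:
    """Estimated population prior plus per-subject Laplace posteriors."""

    spec: ModelSpec
    prior: GroupPrior
    subjects: list[SubjectPosterior]
    n_iterations: int
    converged: bool
    trace: list[dict]                 # per-iteration {"mean": [...], "variance": [...]}
    n_floored: int = 0                # variance-floor activations across iterations

    def prior_mean_se(self) -> np.ndarray:
        """Standard error of the estimated population means (per coordinate).

        Each subject informs the population mean through its marginal
        variance Sigma_jj + d_ij, where d_ij is the subject's data-only
        posterior variance recovered from the Laplace covariance by
        removing the prior precision (1/d = 1/Phi - 1/Sigma).  A subject
        whose posterior is as wide as the prior carries no information
        about that coordinate.  This reduces to sqrt(Sigma/N) when every
        subject is well identified, and inflates appropriately for weakly
        identified coordinates.
        """
        sigma = np.diag(self.prior.variance)
        sigma_inv = np.diag(1.0 / self.prior.variance)
        d = len(self.prior.variance)
        info = np.zeros((d, d))
        for sp in self.subjects:
            data_prec = np.linalg.inv(sp.covariance) - sigma_inv
            # floor the data precision: directions the data do not constrain
            # contribute (numerically) unbounded marginal variance
            vals, vecs = np.linalg.eigh(0.5 * (data_prec + data_prec.T))
            vals = np.maximum(vals, 1e-10)
            data_cov = (vecs / vals) @ vecs.T
            info += np.linalg.inv(sigma + data_cov)
        return np.sqrt(np.diag(np.linalg.inv(info)))

    def map_params(self) -> dict[str, "np.ndarray"]:
        """Per-subject MAPs mapped back to natural space."""
        return {
            sp.subject_id: from_inference_space(sp.map_estimate, self.spec)
            for sp in self.subjects
        }

    def to_dict(self) -> dict:
        return {
            "spec": {"free": list(self.spec.free), "fixed_values": self.spec.fixed_values},
            "prior": {
                "mean": self.prior.mean.tolist(),
                "variance": self.prior.variance.tolist(),
            },
            "subjects": [
                {
                    "subject_id": sp.subject_id,
                    "map_inference": sp.map_estimate.tolist(),
                    "map_natural": from_inference_space(sp.map_estimate, self.spec).as_dict(),
                    "covariance": sp.covariance.tolist(),
                    "log_posterior_at_map": sp.log_posterior_at_map,
                    "hessian_jittered": sp.hessian_jittered,
                }
                for sp in self.subjects
            ],
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "n_floored": self.n_floored,
            "trace": self.trace,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "FitResult":
        spec = ModelSpec(free=tuple(data["spec"]["free"]),
                         fixed_values=dict(data["spec"]["fixed_values"]))
        prior = GroupPrior(mean=np.array(data["prior"]["mean"]),
                           variance=np.array(data["prior"]["variance"]))
        subjects = [
            SubjectPosterior(
                subject_id=s["subject_id"],
                map_estimate=np.array(s["map_inference"]),
                covariance=np.array(s["covariance"]),
                log_posterior_at_map=s["log_posterior_at_map"],
                hessian_jittered=s["hessian_jittered"],
            )
            for s in data["subjects"]
        ]
        return cls(spec=spec, prior=prior, subjects=subjects,
                   n_iterations=data["n_iterations"], converged=data["converged"],
                   trace=data["trace"], n_floored=data.get("n_floored", 0))


# ---------------------------------------------------------------------------
# Likelihood in inference space, with analytic gradient
# ---------------------------------------------------------------------------

def _decode(h: np.ndarray, spec: ModelSpec) -> dict[str, float]:
    params = from_inference_space(h, spec)
    return params.as_dict()


def loglik_grad(h: np.ndarray, spec: ModelSpec, s, w, l, y):
    """Choice log-likelihood and its gradient w.r.t. inference coordinates.

    ``(s, w, l, y)`` are the trial arrays (lean, win, loss, choice as 0/1).
    Gradient coordinates follow ``spec.free``.  Degenerate-stakes trials
    (alpha exactly 0 or 1) contribute saturated probabilities and zero
    gradient in the curve parameters.
    """
    p = _decode(h, spec)
    sigma, delta, c_loss, lapse = p["sigma"], p["delta"], p["c_loss"], p["p_lapse"]

    a = w / (w + c_loss * l)
    degenerate = (a <= 0.0) | (a >= 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = ndtri(np.clip(a, 1e-300, 1.0 - 1e-16))
    t = (s + delta) / sigma
    z = np.where(degenerate, np.where(a >= 1.0, np.inf, -np.inf), t + q)
    p_phi = ndtr(z)
    prob = (1.0 - lapse) * p_phi + lapse / 2.0
    prob_c = np.clip(prob, PROB_CLIP, 1.0 - PROB_CLIP)
    ll = float(np.sum(np.where(y == 1, np.log(prob_c), np.log1p(-prob_c))))

    # dL/dp; then chain through each inference coordinate
    weight = np.where(y == 1, 1.0 / prob_c, -1.0 / (1.0 - prob_c))
    with np.errstate(over="ignore", under="ignore"):
        phi_z = np.where(np.isfinite(z), np.exp(-0.5 * np.minimum(z, 1e150) ** 2) / _SQRT_2PI, 0.0)
    common = weight * (1.0 - lapse) * phi_z

    grad = np.empty(spec.n_free)
    for i, name in enumerate(spec.free):
        if name == "sigma":          # h = log sigma; dz/dh = -(s+delta)/sigma
            grad[i] = np.sum(common * (-t))
        elif name == "delta":        # dz/ddelta = 1/sigma
            grad[i] = np.sum(common / sigma)
        elif name == "c_loss":       # h = log c_loss; dq/dh = -a(1-a)/phi(q)
            with np.errstate(over="ignore", under="ignore", divide="ignore",
                             invalid="ignore"):
                phi_q = np.exp(-0.5 * q**2) / _SQRT_2PI
                ratio = np.where(degenerate | (phi_q == 0.0), 0.0,
                                 a * (1.0 - a) / np.where(phi_q == 0.0, 1.0, phi_q))
            grad[i] = np.sum(common * (-ratio))
        else:                        # p_lapse: h = logit; dp/dh = (1/2-Phi)l(1-l)
            grad[i] = np.sum(weight * (0.5 - p_phi) * lapse * (1.0 - lapse))
    return ll, grad


def loglik_many(H: np.ndarray, spec: ModelSpec, s, w, l, y,
                block: int = 2000) -> np.ndarray:
    """Log-likelihood of one subject's choices at many parameter vectors.

    ``H`` has shape (K, n_free); returns a length-K vector.  Used by the
    Monte-Carlo marginal-likelihood estimator; evaluated in blocks to bound
    memory.
    """
    H = np.asarray(H, dtype=float)
    K = H.shape[0]
    out = np.empty(K)
    idx = {name: i for i, name in enumerate(spec.free)}

    def col(name, default):
        if name in idx:
            return H[:, idx[name]]
        return np.full(K, default)

    sigma = np.exp(col("sigma", np.log(1.0)))
    if "sigma" not in idx:
        raise ValueError("sigma must be a free parameter")  # all specs free it
    delta = col("delta", 0.0)
    c_loss = np.exp(col("c_loss", np.log(spec.fixed_values.get("c_loss", 1.0))))
    lapse = (expit(col("p_lapse", 0.0)) if "p_lapse" in idx
             else np.full(K, spec.fixed_values.get("p_lapse", 0.0)))

    y_is_rew = (y == 1)
    for start in range(0, K, block):
        sl = slice(start, min(start + block, K))
        a = w[None, :] / (w[None, :] + c_loss[sl, None] * l[None, :])
        degen_hi = a >= 1.0
        degen_lo = a <= 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            q = ndtri(np.clip(a, 1e-300, 1.0 - 1e-16))
        z = (s[None, :] + delta[sl, None]) / sigma[sl, None] + q
        z = np.where(degen_hi, np.inf, np.where(degen_lo, -np.inf, z))
        prob = (1.0 - lapse[sl, None]) * ndtr(z) + lapse[sl, None] / 2.0
        prob = np.clip(prob, PROB_CLIP, 1.0 - PROB_CLIP)
        out[sl] = np.sum(np.where(y_is_rew[None, :], np.log(prob), np.log1p(-prob)),
                         axis=1)
    return out


def subject_log_posterior(h: np.ndarray, subject_arrays, spec: ModelSpec,
                          prior: GroupPrior):
    """log p(D_i|h) + log p(h|theta) and its gradient."""
    s, w, l, y = subject_arrays
    ll, grad = loglik_grad(h, spec, s, w, l, y)
    resid = h - prior.mean
    lp = -0.5 * np.sum(resid**2 / prior.variance
                       + np.log(2 * np.pi * prior.variance))
    return ll + lp, grad - resid / prior.variance


# ---------------------------------------------------------------------------
# Laplace E-step
# ---------------------------------------------------------------------------

class MapConvergenceError(RuntimeError):
    """Raised when a subject's MAP optimization fails after all restarts."""

    def __init__(self, subject_id: str, diagnostics: dict):
        self.subject_id = subject_id
        self.diagnostics = diagnostics
        super().__init__(f"MAP optimization failed for subject {subject_id}: "
                         f"{diagnostics}")


def _hessian_of_objective(grad_fn, x: np.ndarray, step_scale: float = 1e-4):
    """Central finite difference of an analytic gradient; symmetrized."""
    d = len(x)
    H = np.empty((d, d))
    for i in range(d):
        step = step_scale * (1.0 + abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += step
        xm[i] -= step
        H[i] = (grad_fn(xp) - grad_fn(xm)) / (2.0 * step)
    return 0.5 * (H + H.T)


def _regularize_pd(H: np.ndarray):
    """Jitter a matrix to positive definiteness; returns (H_pd, jittered)."""
    try:
        np.linalg.cholesky(H)
        return H, False
    except np.linalg.LinAlgError:
        pass
    jitter = 1e-6 * (1.0 + np.abs(np.diag(H)))
    for _ in range(3):
        cand = H + np.diag(jitter)
        try:
            np.linalg.cholesky(cand)
            return cand, True
        except np.linalg.LinAlgError:
            jitter *= 10.0
    # last resort: eigenvalue clipping, still flagged
    vals, vecs = np.linalg.eigh(H)
    vals = np.maximum(vals, 1e-6)
    return (vecs * vals) @ vecs.T, True


def map_estimate(subject: SubjectData, prior: GroupPrior, spec: ModelSpec,
                 x0: np.ndarray | None = None,
                 n_restarts: int = 5, seed: int = 0) -> SubjectPosterior:
    """MAP estimate and Laplace covariance for one subject.

    Maximizes log p(D_i|h) + log p(h|theta) from ``x0`` (default: the prior
    mean); on optimizer failure, retries from up to ``n_restarts`` seeded
    prior draws and keeps the best solution found.  A subject with no
    trials carries no information: the posterior is the prior itself.
    """
    if np.any(prior.variance <= 0):
        raise ValueError("map_estimate requires strictly positive prior variances")
    if not subject.trials:
        return SubjectPosterior(
            subject_id=subject.subject_id,
            map_estimate=prior.mean.copy(),
            covariance=np.diag(prior.variance),
            log_posterior_at_map=prior.log_pdf(prior.mean),
        )
    subject.require_choices()
    arrays = trial_arrays(subject.trials)

    def neg(h):
        lp, g = subject_log_posterior(h, arrays, spec, prior)
        return -lp, -g

    starts = [prior.mean.copy() if x0 is None else np.asarray(x0, dtype=float)]
    rng = np.random.default_rng(seed)
    best = None
    failures = []
    for attempt, start in enumerate(starts):
        res = minimize(neg, start, jac=True, method="L-BFGS-B")
        ok = res.success and np.all(np.isfinite(res.x)) and np.isfinite(res.fun)
        if ok and (best is None or res.fun < best.fun):
            best = res
        if not ok:
            failures.append({"attempt": attempt, "message": str(res.message)})
        if best is None and len(starts) - 1 == attempt and len(starts) <= n_restarts:
            starts.append(prior.sample(rng, 1)[0])
    if best is None:
        raise MapConvergenceError(subject.subject_id, {"failures": failures})

    m = best.x
    H = _hessian_of_objective(lambda h: neg(h)[1], m)
    H_pd, jittered = _regularize_pd(H)
    cov = np.linalg.inv(H_pd)
    cov = 0.5 * (cov + cov.T)
    return SubjectPosterior(
        subject_id=subject.subject_id,
        map_estimate=m,
        covariance=cov,
        log_posterior_at_map=-float(best.fun),
        hessian_jittered=jittered,
    )


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------

def m_step(maps: np.ndarray, covariances: np.ndarray,
           var_floor: float = 1e-6):
    """Moment-matching prior update from subject MAPs and Laplace covariances.

    mu     = mean of the m_i
    Sigma  = diag( mean(m_i m_i' + Phi_i) - mu mu' ), floored at var_floor.

    Returns (GroupPrior, n_floored).  With all Phi_i = 0 the variance is the
    population (1/N) variance of the MAPs.
    """
    maps = np.asarray(maps, dtype=float)
    covariances = np.asarray(covariances, dtype=float)
    mu = maps.mean(axis=0)
    second = (maps**2 + np.diagonal(covariances, axis1=1, axis2=2)).mean(axis=0)
    var = second - mu**2
    n_floored = int(np.sum(var < var_floor))
    var = np.maximum(var, var_floor)
    return GroupPrior(mean=mu, variance=var), n_floored


def _default_init(spec: ModelSpec) -> GroupPrior:
    # weakly informative start centred on the model-agnostic indifference point
    from .model import Params

    anchor = {"sigma": 0.5, "delta": 0.0, "c_loss": 1.0, "p_lapse": 0.05}
    mean = to_inference_space(Params(**anchor), spec)
    return GroupPrior(mean=mean, variance=np.ones(spec.n_free))


def em_fit(subjects: list[SubjectData], spec: ModelSpec,
           settings: FitSettings = FitSettings(),
           init: GroupPrior | None = None) -> FitResult:
    """Estimate the population prior by approximate EM with Laplace E-steps.

    Requires at least two subjects (the population variance is otherwise
    not estimable).  E-steps warm-start each subject's optimizer from its
    previous MAP; a final E-step under the converged prior produces the
    reported per-subject MAPs.
    """
    if len(subjects) < 2:
        raise ValueError("em_fit needs at least 2 subjects")
    for subj in subjects:
        subj.require_choices()

    prior = _default_init(spec) if init is None else init
    trace: list[dict] = []
    warm: list[np.ndarray | None] = [None] * len(subjects)
    n_floored_total = 0
    converged = False
    iteration = 0
    for iteration in range(1, settings.max_iter + 1):
        posteriors = [
            map_estimate(subj, prior, spec, x0=warm[i],
                         n_restarts=settings.n_restarts,
                         seed=settings.seed + 1000 * i)
            for i, subj in enumerate(subjects)
        ]
        warm = [sp.map_estimate for sp in posteriors]
        maps = np.stack([sp.map_estimate for sp in posteriors])
        covs = np.stack([sp.covariance for sp in posteriors])
        new_prior, n_floored = m_step(maps, covs, settings.var_floor)
        n_floored_total += n_floored
        trace.append({"mean": new_prior.mean.tolist(),
                      "variance": new_prior.variance.tolist()})
        d_mu = np.max(np.abs(new_prior.mean - prior.mean))
        d_logvar = np.max(np.abs(np.log(new_prior.variance) - np.log(prior.variance)))
        prior = new_prior
        if d_mu < settings.mu_tol and d_logvar < settings.log_var_tol:
            converged = True
            break

    # MAPs under the final (maximum-likelihood) prior
    final = [
        map_estimate(subj, prior, spec, x0=warm[i],
                     n_restarts=settings.n_restarts,
                     seed=settings.seed + 1000 * i)
        for i, subj in enumerate(subjects)
    ]
    return FitResult(spec=spec, prior=prior, subjects=final,
                     n_iterations=iteration, converged=converged,
                     trace=trace, n_floored=n_floored_total)
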