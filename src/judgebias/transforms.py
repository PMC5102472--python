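"""Unconstrained parameter coordinates and the Gaussian population prior.

The hierarchical model assumes subject-level parameters are a random sample
from a diagonal Gaussian in a transformed "inference" space where every
coordinate is unconstrained:

    h = (log sigma, delta, log c_loss, logit p_lapse)

restricted to the free parameters of the model spec, in canonical order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

from .model import ModelSpec, PARAM_NAMES, Params

__all__ = ["GroupPrior", "to_inference_space", "from_inference_space"]

_FORWARD = {
    "sigma": np.log,
    "delta": lambda v: v,
    "c_loss": np.log,
    "p_lapse": logit,
}
_INVERSE = {
    "sigma": np.exp,
    "delta": lambda v: v,
    "c_loss": np.exp,
    "p_lapse": expit,
}


def to_inference_space(params: Params, spec: ModelSpec) -> np.ndarray:
    """Free parameters of ``params`` as an unconstrained vector.

    Boundary values (sigma = 0, p_lapse exactly 0 or 1) have no finite
    image and raise; pin such parameters in the model spec instead of estimating
    them at a boundary.
    """
    out = np.empty(spec.n_free)
    for i, name in enumerate(spec.free):
        value = getattr(params, name)
        if name == "p_lapse" and not 0.0 < value < 1.0:
            raise ValueError("p_lapse on the boundary has no inference-space image")
        out[i] = _FORWARD[name](value)
        if not np.isfinite(out[i]):
            raise ValueError(f"{name}={value} maps outside inference space")
    return out


def from_inference_space(h: np.ndarray, spec: ModelSpec) -> Params:
    """Inverse of :func:`to_inference_space` (free coords -> full Params)."""
    h = np.asarray(h, dtype=float)
    if h.shape != (spec.n_free,):
        raise ValueError(f"expected {spec.n_free} coordinates, got shape {h.shape}")
    if not np.all(np.isfinite(h)):
        raise ValueError("inference-space vector must be finite")
    values = {name: float(_INVERSE[name](h[i])) for i, name in enumerate(spec.free)}
    return spec.build_params(values)


@dataclass(frozen=True)
class GroupPrior:
    """Diagonal Gaussian population distribution in inference space."""

    mean: np.ndarray
    variance: np.ndarray

    def __post_init__(self) -> None:
        mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        var = np.atleast_1d(np.asarray(self.variance, dtype=float))
        if mean.shape != var.shape or mean.ndim != 1:
            raise ValueError("mean and variance must be 1-D and equal length")
        if np.any(var < 0) or not np.all(np.isfinite(var)) or not np.all(np.isfinite(mean)):
            raise ValueError("variances must be finite and non-negative")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "variance", var)

    @property
    def sd(self) -> np.ndarray:
        return np.sqrt(self.variance)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw ``n`` subject-level vectors, shape (n, d)."""
        return self.mean + self.sd * rng.standard_normal((n, len(self.mean)))

    def log_pdf(self, h: np.ndarray) -> float:
        """Log density at a single inference-space vector (needs variance > 0)."""
        var = self.variance
        if np.any(var == 0):
            raise ValueError("log_pdf undefined for zero variance coordinates")
        resid = np.asarray(h, dtype=float) - self.mean
        return float(-0.5 * np.sum(resid**2 / var + np.log(2 * np.pi * var)))

    @classmethod
    def from_natural(cls, spec: ModelSpec, sd: np.ndarray | list[float],
                     **natural_means: float) -> "GroupPrior":
        """Build a prior from natural-space means and inference-space SDs.

        Convenience for simulation configs, e.g.
        ``GroupPrior.from_natural(spec, sd=[0.3, 0.1], sigma=0.5, delta=-0.1)``.
        """
        defaults = {"sigma": 0.5, "delta": 0.0, "c_loss": 1.0, "p_lapse": 0.05}
        defaults.update(natural_means)
        mean = to_inference_space(Params(**{n: defaults[n] for n in PARAM_NAMES
                                            if n in defaults}), spec)
        sd = np.asarray(sd, dtype=float)
        return cls(mean=mean, variance=sd**2)
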