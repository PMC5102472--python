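"""Bayesian perceptual decision model for the judgement-bias task.

A subject views a stimulus whose true lean ``s`` lies in [-1, 1] (+1 =
maximal lean toward the WIN side, 0 = fully ambiguous) and receives a noisy
percept ``x ~ N(s, sigma^2)``.  Choosing the risky REW key wins ``R+`` pence
if the stimulus leant toward WIN and loses ``R-`` pence otherwise; the SAFE
key always yields 0.  With a flat prior over the lean, the expected
subjective value of the risky choice is positive exactly when the percept
exceeds a threshold set by

    alpha = R+ / (R+ + C_loss * R-),

where ``C_loss`` is the relative subjective weight of losses to wins.  The
probability of a risky choice given the true lean, allowing for an additive
decision bias ``delta`` (negative = toward SAFE) and a lapse rate
``P_lapse`` (probability of an uninformed coin-flip choice), is

    P(REW | s) = (1 - P_lapse) * Phi((s + sigma*Phi^-1(alpha) + delta) / sigma)
                 + P_lapse / 2.

This module provides the closed-form choice probability, the Bernoulli
log-likelihood of a subject's choice sequence, and a seeded choice
simulator; everything downstream (cohort simulation, hierarchical fitting,
model comparison) builds on these primitives.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr, ndtri

__all__ = [
    "Choice",
    "TrialRecord",
    "Params",
    "ModelSpec",
    "SubjectData",
    "PARAM_NAMES",
    "alpha",
    "decision_threshold",
    "p_rew",
    "p_rew_session1",
    "log_likelihood",
    "simulate_choices",
]

#: Canonical parameter order used throughout the package.
PARAM_NAMES = ("sigma", "delta", "c_loss", "p_lapse")

#: Per-trial probabilities are clipped to this range before taking logs so
#: that lapse-free models never produce -inf likelihoods.
PROB_CLIP = 1e-9


class Choice(str, enum.Enum):
    """The two response keys: risky REW and risk-free SAFE."""

    REW = "REW"
    SAFE = "SAFE"


@dataclass(frozen=True)
class TrialRecord:
    """One task trial: stimulus lean, stakes, and (optionally) the response.

    ``choice`` may be None for design-only trials (e.g. a generated session
    layout that has not yet been simulated or run).
    """

    ambiguity: float
    win_pence: int
    loss_pence: int
    choice: Choice | None = None
    rt_ms: float | None = None

    def __post_init__(self) -> None:
        if not -1.0 <= self.ambiguity <= 1.0:
            raise ValueError(f"ambiguity {self.ambiguity} outside [-1, 1]")
        if not 0 <= self.win_pence <= 100:
            raise ValueError(f"win_pence {self.win_pence} outside [0, 100]")
        if not 0 <= self.loss_pence <= 100:
            raise ValueError(f"loss_pence {self.loss_pence} outside [0, 100]")
        if self.rt_ms is not None and self.rt_ms <= 0:
            raise ValueError("rt_ms must be positive when present")


@dataclass(frozen=True)
class Params:
    """Subject-level model parameters in natural space.

    sigma    perceptual noise SD, in ambiguity units (> 0)
    delta    additive decision bias, ambiguity units (negative = toward SAFE)
    c_loss   relative subjective weight of losses to wins, c-/c+ (> 0);
             only this ratio is identifiable, c+ is fixed to 1
    p_lapse  probability of an uninformed 50/50 choice, in [0, 1]
    """

    sigma: float
    delta: float
    c_loss: float = 1.0
    p_lapse: float = 0.0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")
        if not self.c_loss > 0:
            raise ValueError("c_loss must be > 0")
        if not 0.0 <= self.p_lapse <= 1.0:
            raise ValueError("p_lapse must lie in [0, 1]")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAM_NAMES}


@dataclass(frozen=True)
class ModelSpec:
    """Which parameters are estimated and which are pinned.

    ``free`` lists estimated parameters in canonical order; the complement
    takes the values in ``fixed_values`` (defaults: c_loss = 1, p_lapse = 0).
    The reduced two-parameter model frees (sigma, delta) with a symmetric
    threshold and no lapses, matching the fixed 50p/50p session; the full
    model frees all four.
    """

    free: tuple[str, ...]
    fixed_values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.free:
            raise ValueError("free parameter set must be non-empty")
        unknown = set(self.free) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter names: {sorted(unknown)}")
        # normalize order and freeze defaults for the fixed complement
        ordered = tuple(n for n in PARAM_NAMES if n in self.free)
        object.__setattr__(self, "free", ordered)
        fixed = {"c_loss": 1.0, "p_lapse": 0.0}
        fixed.update(self.fixed_values)
        fixed = {k: v for k, v in fixed.items() if k not in ordered}
        missing = set(PARAM_NAMES) - set(ordered) - set(fixed)
        if missing:
            raise ValueError(f"no fixed value for non-free parameters {sorted(missing)}")
        object.__setattr__(self, "fixed_values", fixed)
        # fixed values must themselves be valid
        probe = dict(fixed)
        probe.setdefault("sigma", 1.0)
        probe.setdefault("delta", 0.0)
        Params(**probe)

    @property
    def n_free(self) -> int:
        return len(self.free)

    def build_params(self, free_values: dict[str, float] | np.ndarray) -> Params:
        """Combine free values (dict or vector in canonical order) with the
        fixed complement into a full Params."""
        if isinstance(free_values, dict):
            vals = dict(free_values)
        else:
            arr = np.asarray(free_values, dtype=float)
            if arr.shape != (self.n_free,):
                raise ValueError(f"expected {self.n_free} free values, got {arr.shape}")
            vals = dict(zip(self.free, arr))
        vals.update(self.fixed_values)
        return Params(**vals)

    def check_consistent(self, params: Params) -> None:
        """Raise if ``params`` disagrees with this spec's fixed values."""
        for name, value in self.fixed_values.items():
            if getattr(params, name) != value:
                raise ValueError(
                    f"params.{name}={getattr(params, name)} conflicts with "
                    f"fixed value {value}"
                )

    # Named model families used in the analyses -----------------------------
    @classmethod
    def session1(cls) -> "ModelSpec":
        """Two-parameter model: learn (sigma, delta), set c_loss=1, p_lapse=0."""
        return cls(free=("sigma", "delta"))

    @classmethod
    def session1_lapse(cls) -> "ModelSpec":
        """Three-parameter model: learn (sigma, delta, p_lapse), set c_loss=1."""
        return cls(free=("sigma", "delta", "p_lapse"))

    @classmethod
    def session3_no_lapse(cls) -> "ModelSpec":
        """Three-parameter model: learn (sigma, delta, c_loss), set p_lapse=0."""
        return cls(free=("sigma", "delta", "c_loss"))

    @classmethod
    def session3_full(cls) -> "ModelSpec":
        """Full four-parameter model."""
        return cls(free=PARAM_NAMES)

    @classmethod
    def named(cls, name: str) -> "ModelSpec":
        table = {
            "session1": cls.session1,
            "session1_lapse": cls.session1_lapse,
            "session3_no_lapse": cls.session3_no_lapse,
            "session3_full": cls.session3_full,
        }
        try:
            return table[name]()
        except KeyError:
            raise ValueError(
                f"unknown model spec {name!r}; choose from {sorted(table)}"
            ) from None


@dataclass
class SubjectData:
    """One subject's labelled trial sequence."""

    subject_id: str
    group: str
    trials: list[TrialRecord]

    def n_choices(self) -> int:
        return sum(1 for t in self.trials if t.choice is not None)

    def require_choices(self) -> None:
        if not self.trials:
            raise ValueError(f"subject {self.subject_id} has no trials")
        if any(t.choice is None for t in self.trials):
            raise ValueError(
                f"subject {self.subject_id} has trials without recorded choices"
            )


# ---------------------------------------------------------------------------
# Core computations
# ---------------------------------------------------------------------------

def alpha(win_pence, loss_pence, c_loss):
    """Risky-choice posterior threshold alpha = R+ / (R+ + C_loss * R-).

    The risky key is subjectively worthwhile when the posterior probability
    of the WIN side exceeds 1 - alpha ... equivalently when the percept
    exceeds the threshold of :func:`decision_threshold`.  Accepts scalars or
    arrays; a trial with both stakes zero has no defined trade-off and is
    rejected.
    """
    w = np.asarray(win_pence, dtype=float)
    l = np.asarray(loss_pence, dtype=float)
    if np.any(w < 0) or np.any(l < 0):
        raise ValueError("stakes must be non-negative")
    if not c_loss > 0:
        raise ValueError("c_loss must be > 0")
    denom = w + c_loss * l
    if np.any(denom == 0):
        raise ValueError("trial with win_pence = loss_pence = 0: trade-off undefined")
    out = w / denom
    return float(out) if out.ndim == 0 else out


def decision_threshold(alpha_val: float, sigma: float, delta: float) -> float:
    """Percept threshold x* = -sigma * Phi^-1(alpha) - delta.

    The agent presses REW iff its percept exceeds x*.  Decreasing in alpha;
    a negative bias delta raises the threshold (more SAFE choices).  For the
    degenerate stakes alpha = 0 or 1 the threshold is +inf / -inf (the risky
    choice is never / always worthwhile); callers that cannot handle
    infinities should guard on alpha first.
    """
    if not 0.0 <= alpha_val <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if not sigma > 0:
        raise ValueError("sigma must be > 0")
    if alpha_val == 0.0:
        return np.inf
    if alpha_val == 1.0:
        return -np.inf
    return float(-sigma * ndtri(alpha_val) - delta)


def p_rew(s, params: Params, win_pence, loss_pence):
    """Closed-form probability of the risky choice given the true lean.

    Implements (1 - P_lapse) * Phi((s + sigma*Phi^-1(alpha) + delta)/sigma)
    + P_lapse/2, vectorized over ``s`` and the stakes.  Degenerate stakes
    (alpha exactly 0 or 1) saturate at the lapse-bounded extremes.
    """
    a = alpha(win_pence, loss_pence, params.c_loss)
    return _p_rew_from_alpha(np.asarray(s, dtype=float), a,
                             params.sigma, params.delta, params.p_lapse)


def _p_rew_from_alpha(s, a, sigma, delta, p_lapse):
    a = np.asarray(a, dtype=float)
    s = np.asarray(s, dtype=float)
    # ndtri(0/1) = -/+inf; (s+delta)/sigma + ndtri(a) then saturates Phi.
    with np.errstate(invalid="ignore"):
        z = (s + delta) / sigma + ndtri(a)
    z = np.where(a == 1.0, np.inf, np.where(a == 0.0, -np.inf, z))
    out = (1.0 - p_lapse) * ndtr(z) + p_lapse / 2.0
    return float(out) if out.ndim == 0 else out


def p_rew_session1(s, sigma: float, delta: float):
    """Reduced fixed-stakes model: P(REW|s) = Phi((s + delta)/sigma).

    Equal stakes with equal subjective weights give alpha = 1/2, and the
    lapse rate is pinned at 0, so only the noise and the bias remain.
    """
    if not sigma > 0:
        raise ValueError("sigma must be > 0")
    out = ndtr((np.asarray(s, dtype=float) + delta) / sigma)
    return float(out) if out.ndim == 0 else out


def trial_arrays(trials: list[TrialRecord]):
    """Column arrays (s, win, loss, y) for a trial list; y = 1 for REW.

    Trials without choices get y = -1 (callers fitting data should have
    validated with :meth:`SubjectData.require_choices`).
    """
    s = np.array([t.ambiguity for t in trials], dtype=float)
    w = np.array([t.win_pence for t in trials], dtype=float)
    l = np.array([t.loss_pence for t in trials], dtype=float)
    y = np.array(
        [-1 if t.choice is None else int(t.choice is Choice.REW) for t in trials],
        dtype=int,
    )
    return s, w, l, y


def log_likelihood(subject: SubjectData, params: Params,
                   spec: ModelSpec | None = None) -> float:
    """Bernoulli log-likelihood of a subject's choice sequence.

    Sums log P(REW|s) over REW choices and log(1 - P(REW|s)) over SAFE
    choices, with per-trial probabilities clipped to [1e-9, 1 - 1e-9] so
    that lapse-free models stay finite.  If ``spec`` is given, ``params``
    must agree with its pinned values.
    """
    subject.require_choices()
    if spec is not None:
        spec.check_consistent(params)
    s, w, l, y = trial_arrays(subject.trials)
    p = p_rew(s, params, w, l)
    p = np.clip(p, PROB_CLIP, 1.0 - PROB_CLIP)
    return float(np.sum(np.where(y == 1, np.log(p), np.log1p(-p))))


def simulate_choices(design: list[TrialRecord], params: Params,
                     seed: int | np.random.Generator) -> list[Choice]:
    """Draw one choice per design trial from Bernoulli(P(REW|s)).

    Deterministic given the seed; design trials need no recorded choices.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    s, w, l, _ = trial_arrays(design)
    p = np.atleast_1d(p_rew(s, params, w, l))
    draws = rng.random(len(design)) < p
    return [Choice.REW if d else Choice.SAFE for d in draws]
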