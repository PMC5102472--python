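"""Task-design generation and cohort simulation.

The judgement-bias task probes decisions under ambiguity in two analysed
sessions.  The fixed-stakes session presents 70 trials at five lean levels
{-1, -0.25, 0, 0.25, 1} with 50p at stake on both sides — the design most
comparable to animal variants of the task.  The varying-stakes session
presents 250 trials whose (WIN, LOSE) amounts are drawn from the four
quadrants of the cost plane (0-50p crossed with 60-100p), each cost pair
shown twice with mirrored leans +x and -x, and with 70% of stimuli in the
hard-to-classify band |s| <= 0.25.

Cohorts are simulated hierarchically: each subject's parameters are drawn
from a diagonal Gaussian population prior in the unconstrained inference
space (log sigma, delta, log c_loss, logit p_lapse), transformed to natural
space, and choices are simulated trial by trial from the decision model.
The drawn ground-truth parameters are returned alongside the data so that
every downstream fit can be validated by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import Choice, ModelSpec, Params, SubjectData, TrialRecord, simulate_choices
from .transforms import GroupPrior, from_inference_space

__all__ = [
    "DesignConfig",
    "CohortConfig",
    "SESSION1_LEVELS",
    "MAX_TILT_DEGREES",
    "generate_session1_design",
    "generate_session3_design",
    "generate_design",
    "ambiguity_to_degrees",
    "sample_cohort",
]

SESSION1_LEVELS = (-1.0, -0.25, 0.0, 0.25, 1.0)

#: The stimulus tilts at most this many degrees from vertical; the signed
#: lean s in [-1, 1] maps linearly onto degrees.
MAX_TILT_DEGREES = 1.4

# Varying-stakes design constants.  70% ambiguous is not attainable exactly
# with mirrored pairs (87.5 pairs), so the design uses 88 ambiguous pairs
# (176 trials, 70.4%) and 37 clear pairs.
_S3_N_AMBIG_PAIRS = 88
_S3_N_CLEAR_PAIRS = 37
_S3_QUADRANTS = (
    ((0, 50), (0, 50)),
    ((0, 50), (60, 100)),
    ((60, 100), (0, 50)),
    ((60, 100), (60, 100)),
)
# near-equal pair allocation over quadrants: 31 + 31 + 31 + 32 = 125 pairs
_S3_QUADRANT_PAIRS = (31, 31, 31, 32)


@dataclass(frozen=True)
class DesignConfig:
    """Which session layout to generate."""

    session: str  # "S1" or "S3"
    n_trials: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.session not in ("S1", "S3"):
            raise ValueError("session must be 'S1' or 'S3'")
        n = self.resolved_n_trials
        if n <= 0:
            raise ValueError("n_trials must be positive")
        if self.session == "S3" and n % 2:
            raise ValueError("varying-stakes designs need an even trial count (mirrored pairs)")

    @property
    def resolved_n_trials(self) -> int:
        if self.n_trials is not None:
            return self.n_trials
        return 70 if self.session == "S1" else 250


@dataclass(frozen=True)
class CohortConfig:
    """Ground-truth population priors and design for a simulated cohort."""

    n_subjects_per_group: int
    group_priors: dict[str, GroupPrior]
    spec: ModelSpec
    design: DesignConfig
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects_per_group <= 0:
            raise ValueError("n_subjects_per_group must be positive")
        for name, prior in self.group_priors.items():
            if len(prior.mean) != self.spec.n_free:
                raise ValueError(
                    f"prior for group {name!r} has {len(prior.mean)} coordinates, "
                    f"spec has {self.spec.n_free} free parameters"
                )


def ambiguity_to_degrees(s: float) -> float:
    """Map the signed lean s in [-1, 1] to degrees of tilt from vertical."""
    if not -1.0 <= s <= 1.0:
        raise ValueError(f"ambiguity {s} outside [-1, 1]")
    return MAX_TILT_DEGREES * s


def generate_session1_design(seed: int, n_trials: int = 70) -> list[TrialRecord]:
    """Fixed-stakes session: equal counts at each of the five lean levels.

    All trials offer WIN 50p / LOSE 50p.  Per-level counts are not reported
    for the original task; a balanced split (n_trials / 5 per level) is used
    because it maximizes identifiability of the psychometric curve.  Order
    is shuffled by the seed.
    """
    if n_trials % len(SESSION1_LEVELS):
        raise ValueError(f"n_trials must be a multiple of {len(SESSION1_LEVELS)}")
    rng = np.random.default_rng(seed)
    per_level = n_trials // len(SESSION1_LEVELS)
    leans = np.repeat(SESSION1_LEVELS, per_level)
    rng.shuffle(leans)
    return [TrialRecord(ambiguity=float(s), win_pence=50, loss_pence=50) for s in leans]


def generate_session3_design(seed: int, n_trials: int = 250) -> list[TrialRecord]:
    """Varying-stakes session: mirrored cost pairs over the four cost quadrants.

    ``n_trials``/2 unique (WIN, LOSE) pairs are drawn — integer pence,
    uniform over each quadrant's ranges, the joint (0, 0) pair resampled —
    allocated near-equally over the quadrants.  Each pair appears twice,
    once at lean +x and once at -x.  70.4% of pairs take x uniform on
    (0, 0.25] (the ambiguous band) and the rest x uniform on (0.25, 1].
    """
    rng = np.random.default_rng(seed)
    n_pairs = n_trials // 2
    # scale the canonical 88/37 ambiguous/clear pair split to other sizes
    n_ambig = round(n_pairs * _S3_N_AMBIG_PAIRS / (_S3_N_AMBIG_PAIRS + _S3_N_CLEAR_PAIRS))
    # near-equal quadrant allocation, remainder spread deterministically
    base, extra = divmod(n_pairs, len(_S3_QUADRANTS))
    quad_counts = [base + (1 if i < extra else 0) for i in range(len(_S3_QUADRANTS))]

    costs: list[tuple[int, int]] = []
    for (wlo, whi), (llo, lhi), count in zip(
        (q[0] for q in _S3_QUADRANTS), (q[1] for q in _S3_QUADRANTS), quad_counts
    ):
        for _ in range(count):
            while True:
                w = int(rng.integers(wlo, whi + 1))
                l = int(rng.integers(llo, lhi + 1))
                if (w, l) != (0, 0):
                    break
            costs.append((w, l))
    # seed-shuffled assignment of cost pairs to ambiguous vs clear leans;
    # 1 - random() is uniform on (0, 1], keeping x strictly positive so a
    # mirrored pair is genuinely two distinct stimuli
    order = rng.permutation(n_pairs)
    xs = np.empty(n_pairs)
    xs[order[:n_ambig]] = 0.25 * (1.0 - rng.random(n_ambig))
    xs[order[n_ambig:]] = 0.25 + 0.75 * (1.0 - rng.random(n_pairs - n_ambig))

    trials = [
        TrialRecord(ambiguity=float(sx * x), win_pence=w, loss_pence=l)
        for (w, l), x in zip(costs, xs)
        for sx in (1.0, -1.0)
    ]
    perm = rng.permutation(len(trials))
    return [trials[i] for i in perm]


def generate_design(config: DesignConfig) -> list[TrialRecord]:
    if config.session == "S1":
        return generate_session1_design(config.seed, config.resolved_n_trials)
    return generate_session3_design(config.seed, config.resolved_n_trials)


def sample_cohort(config: CohortConfig):
    """Simulate a cohort: draw subjects from each group's prior, simulate choices.

    Returns ``(subjects_by_group, truth)`` where ``truth`` maps subject_id to
    the ground-truth :class:`Params` actually used for simulation.  The same
    seeded design is shared by every subject (as in the task, where all
    subjects received the same stimulus sequence); parameter draws and
    choice simulation consume independent seeded streams, so the whole
    cohort is reproducible from ``config.seed``.
    """
    design = generate_design(config.design)
    rng = np.random.default_rng(config.seed)
    subjects_by_group: dict[str, list[SubjectData]] = {}
    truth: dict[str, Params] = {}
    for group in sorted(config.group_priors):
        prior = config.group_priors[group]
        members: list[SubjectData] = []
        draws = prior.sample(rng, config.n_subjects_per_group)
        for j in range(config.n_subjects_per_group):
            params = from_inference_space(draws[j], config.spec)
            subject_id = f"{group}_{j:03d}"
            choices = simulate_choices(design, params, rng)
            trials = [
                TrialRecord(t.ambiguity, t.win_pence, t.loss_pence, choice=c)
                for t, c in zip(design, choices)
            ]
            members.append(SubjectData(subject_id=subject_id, group=group, trials=trials))
            truth[subject_id] = params
        subjects_by_group[group] = members
    return subjects_by_group, truth
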