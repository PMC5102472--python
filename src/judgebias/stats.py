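"""Model-agnostic choice analyses and permutation tests.

Everything here works directly on choice data or on fitted parameter
values, with no dependence on the decision model's correctness: choice
curves (risky-choice probability by stimulus-lean bin), the risk-aversion
test at the fully ambiguous stimulus, label-shuffling permutation tests for
group differences, and posterior-predictive simulation of fitted cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .fit import FitResult
from .model import Choice, Params, SubjectData, TrialRecord, p_rew, simulate_choices, trial_arrays

__all__ = [
    "ChoiceCurve",
    "PermResult",
    "RiskAversionReport",
    "choice_curve",
    "risk_aversion_test",
    "permutation_test",
    "simulate_fitted_cohort",
]

#: Bin width used for continuously varying stimulus leans.
DEFAULT_BIN_WIDTH = 0.2


@dataclass
class ChoiceCurve:
    """Across-subject mean risky-choice probability per ambiguity bin."""

    bin_centers: np.ndarray
    mean_p_rew: np.ndarray
    sem: np.ndarray            # NaN where undefined (single subject)
    n_subjects: int
    bin_width: float           # 0.0 when exact discrete levels were used

    def __post_init__(self) -> None:
        if not (len(self.bin_centers) == len(self.mean_p_rew) == len(self.sem)):
            raise ValueError("curve vectors must have equal length")
        if np.any(self.mean_p_rew < 0) or np.any(self.mean_p_rew > 1):
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class PermResult:
    """Outcome of a two-sided label-shuffling permutation test."""

    observed: float
    p_value: float
    n_permutations: int
    seed: int
    statistic_name: str

    def __post_init__(self) -> None:
        if not 1.0 / (self.n_permutations + 1) <= self.p_value <= 1.0:
            raise ValueError("p_value outside its attainable range")


@dataclass(frozen=True)
class RiskAversionReport:
    """Group-level preference for SAFE at the fully ambiguous stimulus."""

    mean_p_safe: float
    t_statistic: float
    t_p_value: float
    t_df: int
    sign_test_p_value: float
    n_subjects: int
    n_above: int               # subjects with P(SAFE|s=0) > 0.5
    n_below: int


def _subject_bin_means(subject: SubjectData, edges: np.ndarray | None,
                       levels: np.ndarray | None):
    s, _, _, y = trial_arrays(subject.trials)
    if np.any(y < 0):
        raise ValueError(f"subject {subject.subject_id} has trials without choices")
    if levels is not None:
        keys = np.searchsorted(levels, s)
        n_bins = len(levels)
    else:
        # right-closed bins on [-1, 1]
        keys = np.clip(np.ceil((s - edges[0]) / (edges[1] - edges[0])).astype(int) - 1,
                       0, len(edges) - 2)
        n_bins = len(edges) - 1
    sums = np.bincount(keys, weights=y, minlength=n_bins)
    counts = np.bincount(keys, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def choice_curve(subjects: list[SubjectData],
                 bin_width: float = DEFAULT_BIN_WIDTH) -> ChoiceCurve:
    """Mean and SEM of per-subject risky-choice probability by lean bin.

    If the data use a small set of exact lean levels (a fixed-stakes
    session), those levels are used directly and ``bin_width`` is ignored;
    otherwise leans are binned right-closed with the given width on
    [-1, 1] (centers at -1 + w/2, ...).  Bins with no trials for any
    subject are omitted with a warning.
    """
    if not subjects:
        raise ValueError("no subjects")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    all_s = np.concatenate([trial_arrays(s.trials)[0] for s in subjects])
    uniq = np.unique(all_s)
    if len(uniq) <= 10:
        levels, edges = uniq, None
        centers = uniq
        width_out = 0.0
    else:
        levels = None
        n_bins = int(round(2.0 / bin_width))
        edges = np.linspace(-1.0, 1.0, n_bins + 1)
        centers = 0.5 * (edges[:-1] + edges[1:])
        width_out = bin_width
    per_subject = np.vstack([_subject_bin_means(s, edges, levels) for s in subjects])

    keep = ~np.all(np.isnan(per_subject), axis=0)
    if not np.all(keep):
        warnings.warn(f"omitting {np.sum(~keep)} empty ambiguity bin(s)")
    per_subject = per_subject[:, keep]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(per_subject, axis=0)
        n_eff = np.sum(~np.isnan(per_subject), axis=0)
        sd = np.nanstd(per_subject, axis=0, ddof=1)
    sem = np.where(n_eff > 1, sd / np.sqrt(n_eff), np.nan)
    return ChoiceCurve(bin_centers=centers[keep], mean_p_rew=mean, sem=sem,
                       n_subjects=len(subjects), bin_width=width_out)


def risk_aversion_test(subjects: list[SubjectData]) -> RiskAversionReport:
    """Do subjects prefer SAFE at the fully ambiguous stimulus (s = 0)?

    Computes each subject's P(SAFE | s = 0), then a one-sample two-sided
    t-test of those proportions against 0.5 and an exact two-sided binomial
    sign test (subjects above vs below 0.5, ties dropped).  If every
    subject shares the same proportion != 0.5, the t statistic is reported
    as signed infinity with p = 0 (maximal evidence).
    """
    p_safe = []
    for subject in subjects:
        s, _, _, y = trial_arrays(subject.trials)
        at_zero = s == 0.0
        if not np.any(at_zero):
            raise ValueError(f"subject {subject.subject_id} has no trials at s = 0")
        if np.any(y[at_zero] < 0):
            raise ValueError(f"subject {subject.subject_id} has unchosen s = 0 trials")
        p_safe.append(1.0 - y[at_zero].mean())
    p_safe = np.asarray(p_safe)
    n = len(p_safe)

    if np.ptp(p_safe) == 0.0:
        if p_safe[0] == 0.5:
            t_stat, t_p = 0.0, 1.0
        else:
            t_stat = np.inf if p_safe[0] > 0.5 else -np.inf
            t_p = 0.0
    else:
        t_stat, t_p = sps.ttest_1samp(p_safe, 0.5)
    above = int(np.sum(p_safe > 0.5))
    below = int(np.sum(p_safe < 0.5))
    if above + below == 0:
        sign_p = 1.0
    else:
        sign_p = float(sps.binomtest(above, above + below, 0.5,
                                     alternative="two-sided").pvalue)
    return RiskAversionReport(
        mean_p_safe=float(p_safe.mean()),
        t_statistic=float(t_stat),
        t_p_value=float(t_p),
        t_df=n - 1,
        sign_test_p_value=sign_p,
        n_subjects=n,
        n_above=above,
        n_below=below,
    )


_STATISTICS = {
    "mean_diff": lambda a, b: np.mean(a) - np.mean(b),
    "var_diff": lambda a, b: np.var(a, ddof=1) - np.var(b, ddof=1),
}


def permutation_test(values_a, values_b, statistic: str = "mean_diff",
                     n_perm: int = 10_000, seed: int = 0) -> PermResult:
    """Two-sided permutation test of a group-difference statistic.

    Subject labels are shuffled ``n_perm`` times; the p-value uses the
    add-one rule p = (1 + #{|stat*| >= |observed|}) / (n_perm + 1), which is
    valid (never zero) under the null.  ``statistic`` is the difference of
    group means or of unbiased group variances.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both value vectors must be non-empty")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    stat_fn = _STATISTICS[statistic]
    observed = float(stat_fn(a, b))
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(stat_fn(perm[: a.size], perm[a.size:])) >= abs(observed):
            count += 1
    return PermResult(
        observed=observed,
        p_value=(1 + count) / (n_perm + 1),
        n_permutations=n_perm,
        seed=seed,
        statistic_name=statistic,
    )


def simulate_fitted_cohort(fit: FitResult, design: list[TrialRecord],
                           reps: int = 500, seed: int = 0):
    """Posterior-predictive simulation of a fitted cohort.

    Each subject's MAP parameters (natural space) are run through the
    choice simulator ``reps`` times on the given design (default 500
    repetitions per subject).  Returns ``(simulated, group_mean_curve)``:
    ``simulated`` maps subject_id to a (reps, n_trials) boolean array of
    risky choices; ``group_mean_curve`` is the closed-form risky-choice
    probability per design trial at the population-mean parameters.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    params_by_subject = fit.map_params()
    simulated: dict[str, np.ndarray] = {}
    for sp in fit.subjects:
        params = params_by_subject[sp.subject_id]
        out = np.empty((reps, len(design)), dtype=bool)
        for r in range(reps):
            choices = simulate_choices(design, params, rng)
            out[r] = [c is Choice.REW for c in choices]
        simulated[sp.subject_id] = out

    from .transforms import from_inference_space

    mean_params = from_inference_space(fit.prior.mean, fit.spec)
    s, w, l, _ = trial_arrays(design)
    group_mean_curve = np.atleast_1d(p_rew(s, mean_params, w, l))
    return simulated, group_mean_curve
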