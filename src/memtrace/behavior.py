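"""Behavioral and meta-memory analysis.

Association task: accuracy against a 12.5% guessing baseline (eight
response options), block-wise learning curves (one-way ANOVA with Tukey
HSD), and meta-memory d'/criterion computed from confidence-conditional
rates.  Localizer: signal-detection trial typing (hit / miss / correct
rejection / false alarm) and the 2-SD low-performance exclusion rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MetaMemory",
    "LocalizerPerformance",
    "score_learning",
    "meta_memory",
    "sdt_trial_types",
    "score_localizer",
    "localizer_performance_scalar",
    "UndefinedMetricError",
    "DegenerateAnovaError",
]


class UndefinedMetricError(ValueError):
    """Meta-memory rates are undefined (no correct or no error trials)."""


class DegenerateAnovaError(ValueError):
    """Too few observations in a block for the learning ANOVA."""


@dataclass
class MetaMemory:
    d_prime: float
    d_bias: float       # criterion c
    hit_rate: float     # P(high confidence | correct), after adjustment
    fa_rate: float      # P(high confidence | error), after adjustment
    n_correct: int
    n_error: int


@dataclass
class LocalizerPerformance:
    hits: int
    misses: int
    correct_rejections: int
    false_alarms: int
    hit_rate: float
    cr_rate: float
    excluded: bool


def score_learning(trials: pd.DataFrame, chance: float = 1.0 / 8.0) -> dict:
    """Accuracy summary for the association task.

    Returns overall accuracy (%), per-block (presentation-number) means, a
    one-sample t test of per-trial accuracy against ``chance``, and a
    one-way ANOVA across blocks with Tukey HSD post-hoc comparisons.
    When a ``participant_id`` column is present, tests run on per-
    participant summary scores (the convention for group-level inference);
    otherwise trials are treated as one participant's observations.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    if "participant_id" in trials.columns and trials["participant_id"].nunique() > 1:
        scores = trials.groupby("participant_id")["accuracy"].mean().to_numpy()
        block = (trials.groupby(["participant_id", "presentation"])["accuracy"]
                 .mean().reset_index())
    else:
        scores = trials["accuracy"].to_numpy(float)
        block = trials[["presentation", "accuracy"]].copy()
    n = len(scores)
    se = scores.std(ddof=1) / np.sqrt(n)
    if se == 0:  # degenerate zero-variance sample: cap rather than return inf
        t_stat = np.sign(scores.mean() - chance) * 1e6
        p_val = 0.0 if t_stat != 0 else 1.0
        ci = (scores.mean(), scores.mean())
    else:
        t_stat, p_val = stats.ttest_1samp(scores, chance)
        ci = stats.t.interval(0.95, n - 1, loc=scores.mean(), scale=se)

    groups = [g["accuracy"].to_numpy(float)
              for _, g in block.groupby("presentation")]
    if any(len(g) < 2 for g in groups):
        raise DegenerateAnovaError(
            "every presentation block needs at least 2 observations")
    f_stat, f_p = stats.f_oneway(*groups)
    tukey = pairwise_tukeyhsd(block["accuracy"].to_numpy(float),
                              block["presentation"].to_numpy())
    block_means = block.groupby("presentation")["accuracy"].mean()
    return {
        "overall_accuracy_pct": 100.0 * trials["accuracy"].mean(),
        "block_means_pct": (100.0 * block_means).to_dict(),
        "chance_pct": 100.0 * chance,
        "t_stat": float(t_stat),
        "t_p": float(p_val),
        "ci95_pct": (100.0 * ci[0], 100.0 * ci[1]),
        "anova_f": float(f_stat),
        "anova_p": float(f_p),
        "tukey": pd.DataFrame(tukey.summary().data[1:],
                              columns=tukey.summary().data[0]),
    }


def _adjust_rate(k: int, n: int) -> float:
    """Confidence-rate with the one-trial adjustment for infinite z values.

    A rate of exactly 1 becomes ``1 - 1/n`` and a rate of exactly 0 becomes
    ``1/n`` (the proportion of a single trial); rates strictly inside (0, 1)
    are returned unchanged.
    """
    rate = k / n
    if rate >= 1.0:
        return 1.0 - 1.0 / n
    if rate <= 0.0:
        return 1.0 / n
    return rate


def meta_memory(trials: pd.DataFrame) -> MetaMemory:
    """Meta-memory sensitivity (d') and criterion (c, reported as d_bias).

    A "hit" is a high-confidence report on a correct recall; a "false
    alarm" is a high-confidence report on an error.  d' = z(hit) - z(fa),
    c = -(z(hit) + z(fa))/2, with boundary rates adjusted by one trial's
    proportion so both z values stay finite.
    """
    correct = trials[trials["accuracy"] == 1]
    error = trials[trials["accuracy"] == 0]
    if len(correct) == 0 or len(error) == 0:
        raise UndefinedMetricError(
            "meta-memory needs at least one correct and one error trial")
    hit = _adjust_rate(int((correct["confidence"] == "high").sum()), len(correct))
    fa = _adjust_rate(int((error["confidence"] == "high").sum()), len(error))
    zh, zf = stats.norm.ppf(hit), stats.norm.ppf(fa)
    return MetaMemory(
        d_prime=float(zh - zf), d_bias=float(-(zh + zf) / 2.0),
        hit_rate=hit, fa_rate=fa,
        n_correct=len(correct), n_error=len(error),
    )


def sdt_trial_types(trials: pd.DataFrame) -> pd.Series:
    """Signal-detection trial type per localizer trial.

    Repetition trials are targets (press -> hit, no press -> miss);
    non-repetitions are lures (no press -> correct rejection, press ->
    false alarm).  Trials without a recorded press column count as
    non-presses.
    """
    rep = trials["is_repetition"].to_numpy(bool)
    pressed = (trials["pressed"].to_numpy(bool) if "pressed" in trials.columns
               else np.zeros(len(trials), bool))
    out = np.where(rep, np.where(pressed, "hit", "miss"),
                   np.where(pressed, "falsealarm", "correctrejection"))
    return pd.Series(out, index=trials.index)


def localizer_performance_scalar(hit_rate: float, cr_rate: float) -> float:
    """Scalar task-performance summary: mean of hit and CR rates."""
    return 0.5 * (hit_rate + cr_rate)


def score_localizer(trials: pd.DataFrame,
                    cohort_performances: list[float] | None = None,
                    ) -> LocalizerPerformance:
    """SDT counts for one participant plus the 2-SD exclusion decision.

    ``cohort_performances`` holds every cohort member's scalar performance
    (mean of hit and CR rates, including this participant's); a participant
    is excluded when their performance is *strictly* below
    ``mean - 2*SD`` of the cohort.  With a cohort smaller than 2 the rule
    is undefined and the participant is kept with a warning.
    """
    sdt = sdt_trial_types(trials)
    hits = int((sdt == "hit").sum())
    misses = int((sdt == "miss").sum())
    crs = int((sdt == "correctrejection").sum())
    fas = int((sdt == "falsealarm").sum())
    n_rep = hits + misses
    n_lure = crs + fas
    hit_rate = hits / n_rep if n_rep else np.nan
    cr_rate = crs / n_lure if n_lure else np.nan
    excluded = False
    if cohort_performances is None or len(cohort_performances) < 2:
        warnings.warn("cohort too small for the 2-SD exclusion rule; "
                      "participant kept")
    else:
        cohort = np.asarray(cohort_performances, float)
        cutoff = cohort.mean() - 2.0 * cohort.std(ddof=1)
        excluded = bool(localizer_performance_scalar(hit_rate, cr_rate) < cutoff)
    return LocalizerPerformance(
        hits=hits, misses=misses, correct_rejections=crs, false_alarms=fas,
        hit_rate=hit_rate, cr_rate=cr_rate, excluded=excluded,
    )
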