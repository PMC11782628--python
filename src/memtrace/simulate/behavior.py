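"""Simulated behavior: feedback-based association learning and 1-back responses.

Recall accuracy follows a logistic learning curve in presentation number:
the log-odds of a correct recall start at ``logit(guess_prob)`` on the
first exposure (a pure guess among eight orientations) and increase by
``learning_rate`` with each additional exposure.  Confidence reports track
accuracy with tunable meta-memory: a correct recall draws a high-confidence
report with probability ``conf_sensitivity`` and an error draws a
low-confidence report with probability ``conf_specificity``.

The defaults are calibrated to the behavioral regime the pipeline is meant
to emulate: chance = 1/8 on first exposures, a mean accuracy of 59.35%
across the four presentation blocks (``learning_rate = 1.7622`` solves this
exactly for the logistic curve), and confidence-accuracy coupling of
80.14% / 76.22%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "BehaviorParams",
    "simulate_behavior",
    "simulate_localizer_behavior",
    "simulate_evidence_table",
]


@dataclass(frozen=True)
class BehaviorParams:
    learning_rate: float = 1.7622   # log-odds increment per exposure
    guess_prob: float = 1.0 / 8.0   # eight response options
    conf_sensitivity: float = 0.8014  # P(high confidence | correct)
    conf_specificity: float = 0.7622  # P(low confidence | error)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("guess_prob", "conf_sensitivity", "conf_specificity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    def p_correct(self, presentation: np.ndarray) -> np.ndarray:
        """Probability of correct recall at a given presentation number (1-based)."""
        pres = np.asarray(presentation)
        return expit(logit(self.guess_prob) + self.learning_rate * (pres - 1))


def simulate_behavior(schedule: pd.DataFrame, params: BehaviorParams) -> pd.DataFrame:
    """Add ``accuracy`` (0/1) and ``confidence`` ('low'/'high') to a schedule.

    Deterministic given ``params.seed``; the input schedule is not modified.
    """
    rng = np.random.default_rng(params.seed)
    out = schedule.copy()
    p = params.p_correct(out["presentation"].to_numpy())
    acc = (rng.random(len(out)) < p).astype(int)
    u = rng.random(len(out))
    high = np.where(acc == 1, u < params.conf_sensitivity, u >= params.conf_specificity)
    out["accuracy"] = acc
    out["confidence"] = np.where(high, "high", "low")
    return out


def simulate_localizer_behavior(schedule: pd.DataFrame, p_hit: float = 1.0,
                                p_false_alarm: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Add a ``pressed`` column to a localizer schedule.

    Defaults emulate optimal performance (press on every direct repetition,
    never otherwise); lower ``p_hit`` / higher ``p_false_alarm`` produce
    imperfect participants for exclusion testing.
    """
    rng = np.random.default_rng(seed)
    out = schedule.copy()
    rep = out["is_repetition"].to_numpy(bool)
    u = rng.random(len(out))
    out["pressed"] = np.where(rep, u < p_hit, u < p_false_alarm)
    return out


def simulate_evidence_table(schedules: list[pd.DataFrame],
                            demand_effect: float = 0.04,
                            success_effect: float = 0.015,
                            intercept: float = 0.35,
                            participant_sd: float = 0.05,
                            noise_sd: float = 0.15,
                            epoch: str = "encoding",
                            seed: int = 0) -> pd.DataFrame:
    """Simulate decoded face-evidence directly on the probability scale.

    For each participant's schedule (which must already carry behavioral
    factor codes ``demand``, ``success`` and ``included`` — see
    :func:`memtrace.linking.code_factors`), trial evidence is

        ``intercept + u_participant + demand_effect*demand
        + success_effect*success + noise``

    with a Gaussian participant intercept and Gaussian trial noise, clipped
    to [0, 1].  The defaults inject probability-scale increments of 0.04
    (demand) and 0.015 (success), the magnitudes the full pipeline is
    designed to recover.  This generator bypasses the imaging stages and is
    the ground-truth source for mixed-model parameter-recovery checks.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for pid, sched in enumerate(schedules, start=1):
        sub = sched.loc[sched["included"]].copy()
        u = rng.normal(0.0, participant_sd)
        ev = (intercept + u
              + demand_effect * sub["demand"].to_numpy(float)
              + success_effect * sub["success"].to_numpy(float)
              + rng.normal(0.0, noise_sd, size=len(sub)))
        sub["face_probability"] = np.clip(ev, 0.0, 1.0)
        sub["epoch"] = epoch
        sub["participant_id"] = pid
        frames.append(sub)
    return pd.concat(frames, ignore_index=True)
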