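"""Task designs and trial schedules for the association-learning and 1-back localizer tasks.

The association task presents faces that must be linked to one of eight
gabor-patch orientations over repeated exposures; the localizer presents
faces and houses in a 1-back repetition-detection task.  Schedules are
generated under the same trial-economy constraints as the scanner tasks:
jittered inter-trial intervals and bounded gaps between re-presentations
of the same face.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TaskDesign",
    "ScheduleInfeasibleError",
    "generate_association_schedule",
    "generate_localizer_schedule",
    "events_long",
    "ASSOCIATION_EPOCHS",
]

#: epochs of one association-task trial, in presentation order
ASSOCIATION_EPOCHS = ("recall", "confidence", "feedback", "encoding")


class ScheduleInfeasibleError(RuntimeError):
    """Raised when no trial ordering satisfies the schedule constraints."""


@dataclass(frozen=True)
class TaskDesign:
    """Parameters of the trial economy shared by both tasks.

    Durations are in seconds.  ``event_durations`` covers the four epochs
    of an association trial; the localizer uses ``event_durations['encoding']``
    (1.5 s) for its single stimulus epoch, matching the encoding display.
    ``min_gap``/``max_gap`` bound the number of trials between consecutive
    presentations of the same face (index difference, so ``min_gap=2``
    forbids back-to-back repeats of a face).
    """

    n_runs: int = 5
    faces_per_run: int = 8
    presentations_per_face: int = 4
    iti_range: tuple[float, float] = (2.5, 6.0)
    event_durations: Mapping[str, float] = field(
        default_factory=lambda: {
            "recall": 2.5,
            "confidence": 1.0,
            "feedback": 0.8,
            "encoding": 1.5,
        }
    )
    feedback_delay: float = 0.2  # gap between confidence choice and feedback
    min_gap: int = 2
    max_gap: int = 15
    repetition_rate: float = 2.0 / 16.0  # localizer 1-back repetitions
    tr: float = 2.0

    def __post_init__(self) -> None:
        if self.iti_range[0] > self.iti_range[1]:
            raise ValueError("iti_range min must be <= max")
        if self.min_gap < 1 or self.max_gap < self.min_gap:
            raise ValueError("require 1 <= min_gap <= max_gap")
        for name in ASSOCIATION_EPOCHS:
            if name not in self.event_durations:
                raise ValueError(f"event_durations missing epoch {name!r}")

    @property
    def n_trials(self) -> int:
        return self.n_runs * self.faces_per_run * self.presentations_per_face

    @property
    def trials_per_run(self) -> int:
        return self.faces_per_run * self.presentations_per_face

    def replace(self, **kwargs) -> "TaskDesign":
        return dataclasses.replace(self, **kwargs)


def _order_one_run(design: TaskDesign, rng: np.random.Generator,
                   max_restarts: int = 2000) -> np.ndarray:
    """Randomized greedy ordering of face presentations for one run.

    Builds the sequence position by position; a face is eligible if it has
    presentations left and its previous occurrence is at least ``min_gap``
    positions back.  A face whose deadline (previous occurrence +
    ``max_gap``) has arrived must be scheduled immediately; two simultaneous
    deadlines force a restart.
    """
    n_faces = design.faces_per_run
    n_rep = design.presentations_per_face
    n_pos = n_faces * n_rep
    for _ in range(max_restarts):
        remaining = np.full(n_faces, n_rep)
        last = np.full(n_faces, -(10**9))
        started = np.zeros(n_faces, dtype=bool)
        seq = np.empty(n_pos, dtype=int)
        ok = True
        for pos in range(n_pos):
            due = np.flatnonzero(started & (remaining > 0)
                                 & (pos - last >= design.max_gap))
            if len(due) > 1:
                ok = False
                break
            if len(due) == 1:
                choice = due[0]
            else:
                eligible = np.flatnonzero(
                    (remaining > 0) & (pos - last >= design.min_gap)
                )
                if len(eligible) == 0:
                    ok = False
                    break
                # bias toward faces with many presentations left to avoid
                # painting the tail of the run into a corner
                w = remaining[eligible].astype(float)
                choice = rng.choice(eligible, p=w / w.sum())
            seq[pos] = choice
            remaining[choice] -= 1
            last[choice] = pos
            started[choice] = True
        if ok:
            return seq
    raise ScheduleInfeasibleError(
        f"could not satisfy same-face gap constraints [{design.min_gap}, "
        f"{design.max_gap}] for {n_faces} faces x {n_rep} presentations "
        f"after {max_restarts} restarts"
    )


def generate_association_schedule(design: TaskDesign, seed: int) -> pd.DataFrame:
    """Generate a per-trial schedule for the association-learning task.

    Returns one row per trial with run index (1-based), ``face_id``
    (globally unique across runs), presentation number (1..4), epoch onsets
    and durations, and the jittered ITI preceding and following the trial.
    Each run has its own clock starting at 0; run 1 trial 1 begins after an
    initial ITI.  The ITI *following* a trial is recorded as the trial's
    ``iti`` epoch (the putative rehearsal window).
    """
    rng = np.random.default_rng(seed)
    dur = design.event_durations
    rows = []
    for run in range(1, design.n_runs + 1):
        seq = _order_one_run(design, rng)
        itis = rng.uniform(*design.iti_range, size=len(seq) + 1)
        pres_counter = np.zeros(design.faces_per_run, dtype=int)
        t = itis[0]
        for i, face in enumerate(seq):
            pres_counter[face] += 1
            recall_on = t
            conf_on = recall_on + dur["recall"]
            fb_on = conf_on + dur["confidence"] + design.feedback_delay
            enc_on = fb_on + dur["feedback"]
            iti_on = enc_on + dur["encoding"]
            iti_dur = itis[i + 1]
            rows.append(
                dict(
                    run=run,
                    trial=i + 1,
                    face_id=f"r{run}f{face + 1}",
                    presentation=int(pres_counter[face]),
                    recall_onset=recall_on,
                    recall_duration=dur["recall"],
                    confidence_onset=conf_on,
                    confidence_duration=dur["confidence"],
                    feedback_onset=fb_on,
                    feedback_duration=dur["feedback"],
                    encoding_onset=enc_on,
                    encoding_duration=dur["encoding"],
                    iti_onset=iti_on,
                    iti_duration=iti_dur,
                )
            )
            t = iti_on + iti_dur
    return pd.DataFrame(rows)


def generate_localizer_schedule(design: TaskDesign, seed: int) -> pd.DataFrame:
    """Generate a per-trial schedule for the 1-back localizer task.

    Each run presents 2 new faces and 2 new houses four times each
    (16 trials, category-balanced 8/8).  A fixed number of trials per run
    (``round(repetition_rate * 16)``, default 2) are direct repetitions of
    the immediately preceding stimulus/gabor pair; triples never occur and
    the first trial of a run is never a repetition.
    """
    rng = np.random.default_rng(seed)
    n_stim_per_cat = 2
    n_pres = 4
    n_per_run = 2 * n_stim_per_cat * n_pres  # 16
    n_rep = int(round(design.repetition_rate * n_per_run))
    rows = []
    for run in range(1, design.n_runs + 1):
        stimuli = [f"r{run}face{i + 1}" for i in range(n_stim_per_cat)] + [
            f"r{run}house{i + 1}" for i in range(n_stim_per_cat)
        ]
        pool = np.repeat(np.arange(4), n_pres)
        for _ in range(20000):
            seq = rng.permutation(pool)
            adj = seq[1:] == seq[:-1]
            if adj.sum() != n_rep:
                continue
            # no triples: a repetition's predecessor must itself be fresh
            if np.any(adj[1:] & adj[:-1]):
                continue
            break
        else:
            raise ScheduleInfeasibleError(
                f"could not place {n_rep} direct repetitions in {n_per_run} trials"
            )
        is_rep = np.concatenate([[False], adj])
        orientations = rng.integers(0, 8, size=n_per_run)
        for i in range(1, n_per_run):
            if is_rep[i]:
                orientations[i] = orientations[i - 1]
            elif orientations[i] == orientations[i - 1] and seq[i] == seq[i - 1]:
                orientations[i] = (orientations[i] + 1) % 8
        itis = rng.uniform(*design.iti_range, size=n_per_run + 1)
        stim_dur = design.event_durations["encoding"]
        t = itis[0]
        for i in range(n_per_run):
            rows.append(
                dict(
                    run=run,
                    trial=i + 1,
                    stimulus_id=stimuli[seq[i]],
                    category="face" if seq[i] < n_stim_per_cat else "house",
                    gabor_orientation=int(orientations[i]),
                    is_repetition=bool(is_rep[i]),
                    stimulus_onset=t,
                    stimulus_duration=stim_dur,
                    iti_onset=t + stim_dur,
                    iti_duration=itis[i + 1],
                )
            )
            t += stim_dur + itis[i + 1]
    return pd.DataFrame(rows)


def events_long(schedule: pd.DataFrame, epochs: tuple[str, ...],
                trial_type: str | pd.Series | None = None) -> pd.DataFrame:
    """Convert a wide per-trial schedule to a BIDS-style long event table.

    One row per (trial, epoch) with columns ``onset``, ``duration``,
    ``trial_type`` plus the schedule's metadata columns.  ``trial_type``
    defaults to the epoch name; pass a Series (indexed like ``schedule``)
    or a column name to refine labels per trial (e.g. condition codes).
    """
    frames = []
    meta_cols = [c for c in schedule.columns
                 if not c.endswith("_onset") and not c.endswith("_duration")]
    for epoch in epochs:
        part = schedule[meta_cols].copy()
        part["onset"] = schedule[f"{epoch}_onset"].to_numpy()
        part["duration"] = schedule[f"{epoch}_duration"].to_numpy()
        part["epoch"] = epoch
        if trial_type is None:
            part["trial_type"] = epoch
        elif isinstance(trial_type, str):
            part["trial_type"] = epoch + "_" + schedule[trial_type].astype(str)
        else:
            part["trial_type"] = epoch + "_" + trial_type.astype(str)
        frames.append(part)
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["run", "onset"], kind="stable").reset_index(drop=True)
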