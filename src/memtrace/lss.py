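"""Least-squares-separate (LSS) single-trial deconvolution.

Each target trial gets its own GLM: one HRF-convolved regressor for the
target event, one nuisance regressor per included epoch aggregating every
other event of that epoch, plus confounds, cosine drift and an intercept.
The target coefficient map is the trial's beta map; stacking them yields
the betaseries for multivoxel analysis.

Epoch inclusion follows a stepwise rule: the recall deconvolution models
only recall events, the encoding deconvolution recall and encoding events,
and the inter-trial-interval deconvolution all three — each later epoch is
estimated while controlling for everything that precedes it in the trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .glm import hrf_regressor, make_drift_basis
from .group import smooth_volume
from .simulate.bold import VolumeSeries

__all__ = ["LssSpec", "BetaSeries", "lss_deconvolve", "extract_roi",
           "STEPWISE_EPOCHS"]

STEPWISE_EPOCHS: dict[str, tuple[str, ...]] = {
    "recall": ("recall",),
    "encoding": ("recall", "encoding"),
    "iti": ("recall", "encoding", "iti"),
    "stimulus": ("stimulus",),
}


@dataclass
class LssSpec:
    """Configuration of one LSS deconvolution pass.

    ``epoch`` names the target epoch; ``included_epochs`` defaults to the
    stepwise set for that epoch and must contain it.  ``trial_filter`` is
    an optional row predicate on the schedule (e.g. keep only correct-
    rejection localizer trials).
    """

    epoch: str
    included_epochs: tuple[str, ...] | None = None
    smoothing_fwhm: float = 6.0
    trial_filter: Callable[[pd.Series], bool] | None = None

    def __post_init__(self) -> None:
        if self.epoch not in STEPWISE_EPOCHS:
            raise ValueError(f"unknown epoch {self.epoch!r}")
        if self.included_epochs is None:
            self.included_epochs = STEPWISE_EPOCHS[self.epoch]
        required = STEPWISE_EPOCHS[self.epoch]
        if tuple(self.included_epochs) != required:
            raise ValueError(
                f"epoch {self.epoch!r} requires included_epochs {required}, "
                f"got {tuple(self.included_epochs)}")


@dataclass
class BetaSeries:
    """Trial x voxel matrix of single-trial betas with trial metadata."""

    matrix: np.ndarray          # (n_trials, n_voxels)
    trial_meta: pd.DataFrame
    mask: np.ndarray            # boolean volume the columns were taken from

    def __post_init__(self) -> None:
        if len(self.trial_meta) != self.matrix.shape[0]:
            raise ValueError("trial metadata and matrix rows differ")
        if np.isnan(self.matrix).any():
            raise ValueError("betaseries contains missing values")


def _epoch_events(schedule: pd.DataFrame, epoch: str) -> tuple[np.ndarray, np.ndarray]:
    return (schedule[f"{epoch}_onset"].to_numpy(float),
            schedule[f"{epoch}_duration"].to_numpy(float))


def lss_deconvolve(volumes: VolumeSeries, events: pd.DataFrame,
                   confounds: pd.DataFrame | None, spec: LssSpec,
                   ) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-trial LSS beta maps for one run.

    Returns a 4D array (x, y, z, n_kept_trials) plus the matching trial
    metadata (with a ``skipped`` reason column removed — skipped trials are
    simply absent).  GLMs are fit per run; the events table must belong to
    the same single run as ``volumes``.
    """
    if events["run"].nunique() != 1:
        raise ValueError("lss_deconvolve expects a single-run event table")
    n_frames = volumes.n_frames
    frame_times = np.arange(n_frames) * volumes.tr
    onset_col = f"{spec.epoch}_onset"
    if onset_col not in events.columns:
        raise ValueError(f"events lack the target epoch column {onset_col!r}")

    # per-(trial, epoch) unit regressors, and their per-epoch sums
    per_epoch_reg: dict[str, np.ndarray] = {}
    for ep in spec.included_epochs:
        on, du = _epoch_events(events, ep)
        regs = np.stack([
            hrf_regressor([o], [d], [1.0], frame_times) for o, d in zip(on, du)
        ])
        per_epoch_reg[ep] = regs
    epoch_sum = {ep: r.sum(axis=0) for ep, r in per_epoch_reg.items()}

    nuisance_cols = []
    if confounds is not None and len(confounds.columns):
        if len(confounds) != n_frames:
            raise ValueError("confound rows must match scan frames")
        nuisance_cols.append(confounds.to_numpy(float))
    drift = make_drift_basis(frame_times).to_numpy()
    if drift.shape[1]:
        nuisance_cols.append(drift)
    nuisance_cols.append(np.ones((n_frames, 1)))
    nuisance = np.hstack(nuisance_cols)

    data = volumes.data.reshape(-1, n_frames).T  # frames x voxels
    keep_idx: list[int] = []
    betas: list[np.ndarray] = []
    rows = list(events.reset_index(drop=True).iterrows())
    for i, row in rows:
        if spec.trial_filter is not None and not spec.trial_filter(row):
            continue
        target = per_epoch_reg[spec.epoch][i]
        cols = [target[:, None]]
        for ep in spec.included_epochs:
            other = epoch_sum[ep] - (per_epoch_reg[ep][i] if ep == spec.epoch else 0.0)
            if np.ptp(other) > 0:
                cols.append(other[:, None])
        X = np.hstack(cols + [nuisance])
        coef, _, _, _ = np.linalg.lstsq(X, data, rcond=None)
        betas.append(coef[0])
        keep_idx.append(i)

    meta = events.reset_index(drop=True).loc[keep_idx].reset_index(drop=True)
    meta = meta.copy()
    meta["epoch"] = spec.epoch
    stack = np.stack(betas, axis=-1) if betas else np.empty((data.shape[1], 0))
    return stack.reshape(*volumes.shape, len(keep_idx)), meta


def extract_roi(beta_maps: np.ndarray, trial_meta: pd.DataFrame,
                mask: np.ndarray, fwhm: float = 6.0,
                voxel_size: float = 2.2) -> BetaSeries:
    """Smooth each beta map, then extract masked voxels into a BetaSeries."""
    mask = np.asarray(mask, bool)
    if mask.shape != beta_maps.shape[:3]:
        raise ValueError("mask geometry does not match beta maps")
    if not mask.any():
        raise ValueError("ROI mask is empty")
    smoothed = np.stack(
        [smooth_volume(beta_maps[..., i], fwhm, voxel_size)
         for i in range(beta_maps.shape[-1])], axis=-1)
    matrix = smoothed[mask].T  # trials x voxels
    return BetaSeries(matrix=np.ascontiguousarray(matrix),
                      trial_meta=trial_meta.reset_index(drop=True), mask=mask)
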