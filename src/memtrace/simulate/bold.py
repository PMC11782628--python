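"""Forward BOLD simulation with embedded multivoxel patterns.

Voxel time series are built as a sum of HRF-convolved event responses,
low-frequency drift, nuisance-confound loadings and AR(1) Gaussian noise.
A designated contiguous ROI (standing in for the face-selective
mid-fusiform region) carries distinct multivoxel patterns for faces and
houses; in the association task the face-pattern amplitude is modulated by
encoding demand and subsequent recall success, providing the recoverable
ground truth for every downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.signal import lfilter

from ..glm import hrf_regressor, make_drift_basis

__all__ = [
    "VolumeSeries",
    "PatternSpec",
    "NoiseSpec",
    "GroundTruth",
    "simulate_bold",
    "default_grid_shape",
    "DEFAULT_VOXEL_SIZE",
]

DEFAULT_VOXEL_SIZE = 2.2  # mm, isotropic — matches the 2.2 mm acquisition grid
# Neural gain of the face pattern per association-task epoch.  Calibrated
# noise-free so that the *measured* single-trial amplitude gradient under
# the stepwise deconvolution declines recall > encoding > ITI (the stepwise
# rule leaves later-epoch signal unmodeled in earlier steps, which shifts
# part of it, with negative sign, into the earlier target estimates; the
# raw gains are chosen jointly with that estimation geometry).
DEFAULT_EPOCH_GAINS = {"recall": 1.2, "encoding": 0.7, "iti": 0.15, "stimulus": 1.0}


def default_grid_shape() -> tuple[int, int, int]:
    """Desk-scale simulation grid (keeps voxel size, shrinks the head)."""
    return (12, 12, 10)


@dataclass
class VolumeSeries:
    """A 4D volume series with affine and repetition time."""

    data: np.ndarray               # (x, y, z, t)
    affine: np.ndarray
    tr: float

    @property
    def n_frames(self) -> int:
        return self.data.shape[-1]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(np.asarray(self.data, np.float64), self.affine)
        img.header.set_zooms((*img.header.get_zooms()[:3], self.tr))
        return img

    @classmethod
    def from_nifti(cls, img_or_path, tr: float | None = None) -> "VolumeSeries":
        img = nib.load(str(img_or_path)) if not isinstance(img_or_path, nib.Nifti1Image) else img_or_path
        if tr is None:
            tr = float(img.header.get_zooms()[3])
        return cls(data=np.asarray(img.get_fdata()), affine=img.affine, tr=tr)


def default_affine(voxel_size: float = DEFAULT_VOXEL_SIZE) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size
    return aff


@dataclass
class PatternSpec:
    """Ground-truth multivoxel patterns and their behavioral modulation.

    ``roi_mask`` is a boolean volume marking the face-selective ROI;
    ``face_pattern`` / ``house_pattern`` are per-ROI-voxel response vectors.
    The amplitude of the face pattern on an association-task event is
    ``base_amplitude + demand_effect*demand + success_effect*success``,
    scaled by the epoch's gain.  The default epoch gains decline from
    recall (face alone on screen) through encoding (face plus gabor) to the
    inter-trial interval (rehearsal only), producing the declining
    face-evidence gradient across epochs the decoding analysis should find.
    """

    roi_mask: np.ndarray
    face_pattern: np.ndarray
    house_pattern: np.ndarray
    base_amplitude: float = 1.0
    demand_effect: float = 0.0
    success_effect: float = 0.0
    epoch_gains: dict = field(default_factory=lambda: dict(DEFAULT_EPOCH_GAINS))

    def __post_init__(self) -> None:
        k = int(self.roi_mask.sum())
        if len(self.face_pattern) != k or len(self.house_pattern) != k:
            raise ValueError("pattern vectors must match ROI voxel count")
        cos = float(
            self.face_pattern @ self.house_pattern
            / (np.linalg.norm(self.face_pattern) * np.linalg.norm(self.house_pattern))
        )
        if cos > 1.0 - 1e-12:
            raise ValueError("face and house patterns must be non-collinear")

    @classmethod
    def default(cls, grid_shape: tuple[int, int, int] | None = None,
                seed: int = 0, **kwargs) -> "PatternSpec":
        """FFA-like ROI: an 18-voxel block whose face response exceeds the
        house response on average (so face-preferring voxels exist for
        ANOVA-based feature selection)."""
        if grid_shape is None:
            grid_shape = default_grid_shape()
        rng = np.random.default_rng(seed)
        mask = np.zeros(grid_shape, dtype=bool)
        mask[2:5, 2:5, 3:5] = True  # 3 x 3 x 2 = 18 voxels
        k = int(mask.sum())
        face = 1.0 + 0.4 * rng.standard_normal(k)
        house = 0.5 + 0.4 * rng.standard_normal(k)
        return cls(roi_mask=mask, face_pattern=face, house_pattern=house, **kwargs)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise model: AR(1) Gaussian + drift + confound loadings."""

    sigma: float = 0.35            # stationary noise SD, BOLD units
    ar_coefficient: float = 0.3    # lag-1 autocorrelation, in [0, 1)
    n_drift: int = 3               # cosine drift terms with random weights
    n_confounds: int = 6           # motion/physiology-like nuisance columns
    confound_loading: float = 0.3
    drift_amplitude: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise ValueError("ar_coefficient must be in [0, 1)")


@dataclass
class GroundTruth:
    """What was injected: per-event amplitudes and the nuisance structure."""

    amplitudes: pd.DataFrame       # one row per (trial, epoch) signal event
    confounds: pd.DataFrame        # frame x confound nuisance signals
    roi_mask: np.ndarray
    face_pattern: np.ndarray
    house_pattern: np.ndarray

    def to_dict(self) -> dict:
        return {
            "amplitudes": self.amplitudes.to_dict(orient="list"),
            "confound_columns": list(self.confounds.columns),
            "n_roi_voxels": int(self.roi_mask.sum()),
            "face_pattern": self.face_pattern.tolist(),
            "house_pattern": self.house_pattern.tolist(),
        }


def _confound_signals(n_frames: int, n_confounds: int,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Standardized nuisance signals: slow random walks (motion-like) and
    sinusoids with jittered frequency (cardiac/respiratory-like)."""
    cols = {}
    for j in range(n_confounds):
        if j % 2 == 0:
            s = np.cumsum(rng.standard_normal(n_frames))
        else:
            f = rng.uniform(0.05, 0.2)  # cycles per frame
            s = np.sin(2 * np.pi * f * np.arange(n_frames) + rng.uniform(0, 2 * np.pi))
        s = s - s.mean()
        sd = s.std()
        cols[f"confound_{j}"] = s / sd if sd > 0 else s
    return pd.DataFrame(cols)


def _signal_events(schedule: pd.DataFrame, pattern: PatternSpec) -> pd.DataFrame:
    """Table of pattern-carrying events with ground-truth amplitudes."""
    rows = []
    if "category" in schedule.columns:  # localizer
        for _, tr_row in schedule.iterrows():
            rows.append(dict(
                run=tr_row["run"], trial=tr_row["trial"], epoch="stimulus",
                onset=tr_row["stimulus_onset"], duration=tr_row["stimulus_duration"],
                pattern=tr_row["category"],
                amplitude=pattern.base_amplitude * pattern.epoch_gains.get("stimulus", 1.0),
            ))
        return pd.DataFrame(rows)
    # association task: face information at recall, encoding and (weakly) ITI
    if "demand" in schedule.columns:
        demand = schedule["demand"].fillna(0).to_numpy(float)
        success = schedule["success"].fillna(0).to_numpy(float)
        included = schedule["included"].to_numpy(bool)
    else:
        demand = success = np.zeros(len(schedule))
        included = np.zeros(len(schedule), dtype=bool)
    for i, (_, tr_row) in enumerate(schedule.iterrows()):
        amp = pattern.base_amplitude
        if included[i]:
            amp = amp + pattern.demand_effect * demand[i] + pattern.success_effect * success[i]
        for epoch in ("recall", "encoding", "iti"):
            gain = pattern.epoch_gains.get(epoch, 0.0)
            if gain == 0.0:
                continue
            rows.append(dict(
                run=tr_row["run"], trial=tr_row["trial"], epoch=epoch,
                onset=tr_row[f"{epoch}_onset"], duration=tr_row[f"{epoch}_duration"],
                pattern="face", amplitude=amp * gain,
            ))
    return pd.DataFrame(rows)


def simulate_bold(schedule: pd.DataFrame, pattern: PatternSpec, noise: NoiseSpec,
                  design, n_frames: int | None = None,
                  grid_shape: tuple[int, int, int] | None = None,
                  voxel_size: float = DEFAULT_VOXEL_SIZE,
                  ) -> tuple[VolumeSeries, GroundTruth]:
    """Simulate one run of BOLD data for a scheduled task.

    ``schedule`` must contain exactly one run.  Association-task schedules
    should carry behavioral outcomes (and, if demand/success modulation is
    wanted, the factor codes from :func:`memtrace.linking.code_factors`);
    localizer schedules carry category labels.  Returns the simulated
    4D series plus a :class:`GroundTruth` record of everything injected.
    """
    if schedule["run"].nunique() != 1:
        raise ValueError("simulate_bold expects a single-run schedule")
    if grid_shape is None:
        grid_shape = default_grid_shape()
    tr = design.tr
    end_cols = [c for c in schedule.columns if c.endswith("_onset")]
    last_end = max(
        float((schedule[c] + schedule[c.replace("_onset", "_duration")]).max())
        for c in end_cols
    )
    needed = int(np.ceil((last_end + 16.0) / tr))  # let the HRF return to baseline
    if n_frames is None:
        n_frames = needed
    elif last_end > n_frames * tr:
        raise ValueError(
            f"schedule runs to {last_end:.1f}s but scan covers only "
            f"{n_frames * tr:.1f}s")
    frame_times = np.arange(n_frames) * tr
    rng = np.random.default_rng(noise.seed)

    n_vox = int(np.prod(grid_shape))
    flat = np.zeros((n_vox, n_frames))
    roi_idx = np.flatnonzero(pattern.roi_mask.ravel())
    patterns = {"face": pattern.face_pattern, "house": pattern.house_pattern}

    events = _signal_events(schedule, pattern)
    for _, ev in events.iterrows():
        reg = hrf_regressor([ev["onset"]], [ev["duration"]], [1.0], frame_times)
        flat[roi_idx] += (ev["amplitude"] * patterns[ev["pattern"]])[:, None] * reg[None, :]

    confounds = _confound_signals(n_frames, noise.n_confounds, rng)
    if noise.n_confounds:
        loadings = rng.normal(0.0, noise.confound_loading, size=(n_vox, noise.n_confounds))
        flat += loadings @ confounds.to_numpy().T
    if noise.n_drift:
        basis = make_drift_basis(frame_times).to_numpy()[:, : noise.n_drift]
        if basis.shape[1]:
            coeff = rng.normal(0.0, noise.drift_amplitude, size=(n_vox, basis.shape[1]))
            flat += coeff @ basis.T
    if noise.sigma > 0:
        innov_sd = noise.sigma * np.sqrt(1.0 - noise.ar_coefficient ** 2)
        innov = rng.normal(0.0, innov_sd, size=(n_vox, n_frames))
        flat += lfilter([1.0], [1.0, -noise.ar_coefficient], innov, axis=1)

    data = (100.0 + flat).reshape(*grid_shape, n_frames)
    series = VolumeSeries(data=data, affine=default_affine(voxel_size), tr=tr)
    truth = GroundTruth(
        amplitudes=events, confounds=confounds, roi_mask=pattern.roi_mask,
        face_pattern=pattern.face_pattern, house_pattern=pattern.house_pattern,
    )
    return series, truth
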