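"""First-level voxelwise GLM: design construction, OLS fitting, contrasts.

Event regressors are boxcars convolved with the canonical Glover
double-gamma HRF (via nilearn's regressor machinery), to which confound
columns, a cosine drift basis (128 s high-pass) and an intercept are
appended.  Estimation is plain OLS per voxel; t statistics are mapped to
z scores through matched two-sided tail probabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from nilearn.glm.first_level import compute_regressor
from scipy import stats

__all__ = [
    "hrf_regressor",
    "make_drift_basis",
    "label_association_events",
    "label_localizer_events",
    "build_design",
    "fit_glm",
    "contrast",
    "collinearity_diagnostics",
    "t_to_z",
    "GlmFit",
    "ContrastResult",
    "SingularDesignError",
]

HRF_OVERSAMPLING = 50
DEFAULT_HIGH_PASS = 1.0 / 128.0  # Hz


class SingularDesignError(ValueError):
    """Raised when the design matrix is rank deficient."""


def hrf_regressor(onsets, durations, amplitudes, frame_times) -> np.ndarray:
    """HRF-convolved regressor for a set of events, sampled at frame times.

    Thin wrapper over nilearn's Glover-model regressor so that the forward
    simulator and every GLM in the package share one bit-identical
    convolution path (the construction is exactly linear in amplitudes,
    which makes noise-free forward/inverse consistency exact).
    """
    onsets = np.atleast_1d(np.asarray(onsets, float))
    durations = np.atleast_1d(np.asarray(durations, float))
    amplitudes = np.atleast_1d(np.asarray(amplitudes, float))
    reg, _ = compute_regressor(
        (onsets, durations, amplitudes), "glover",
        np.asarray(frame_times, float), con_id="ev",
        oversampling=HRF_OVERSAMPLING,
    )
    return reg[:, 0]


def make_drift_basis(frame_times, high_pass: float = DEFAULT_HIGH_PASS) -> pd.DataFrame:
    """Cosine (DCT-II) drift basis up to the high-pass cutoff frequency.

    Returns ``floor(2 * duration * high_pass)`` unit-norm cosine columns
    (``drift_1`` is the slowest), the standard discrete cosine set used for
    high-pass filtering within the GLM.
    """
    ft = np.asarray(frame_times, float)
    n = len(ft)
    duration = ft[-1] - ft[0] + (ft[-1] - ft[0]) / max(n - 1, 1)
    order = int(np.floor(2 * duration * high_pass))
    t = np.arange(n)
    cols = {}
    for k in range(1, order + 1):
        basis = np.cos(np.pi * (2 * t + 1) * k / (2 * n))
        cols[f"drift_{k}"] = basis * np.sqrt(2.0 / n)
    return pd.DataFrame(cols, index=ft)


# ---------------------------------------------------------------------------
# condition labeling for the two univariate model variants

def label_association_events(schedule: pd.DataFrame, model_variant: str) -> pd.DataFrame:
    """Long event table with condition labels for one association-task run.

    ``recall_confidence_feedback`` models recall (split by accuracy x
    confidence), confidence selection (low/high) and feedback valence
    (positive/negative).  ``recall_confidence_encoding`` replaces the
    feedback regressors — which overlap the encoding display in time —
    with encoding regressors split by the (current, next) recall outcome
    transition; final presentations, which have no next outcome, form their
    own ``encoding_Last`` condition.
    """
    from .linking import transition_labels  # local import avoids a cycle

    sched = schedule
    acc = np.where(sched["accuracy"] == 1, "Correct", "Error")
    conf = np.where(sched["confidence"] == "high", "ConfidenceHigh", "ConfidenceLow")
    recall_lab = pd.Series([f"{a}_{c}" for a, c in zip(acc, conf)], index=sched.index)
    conf_lab = sched["confidence"].astype(str)
    parts = []

    def epoch_rows(epoch: str, labels: pd.Series) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "onset": sched[f"{epoch}_onset"].to_numpy(),
                "duration": sched[f"{epoch}_duration"].to_numpy(),
                "trial_type": epoch + "_" + labels.astype(str),
                "epoch": epoch,
                "run": sched["run"].to_numpy(),
                "trial": sched["trial"].to_numpy(),
            }
        )
        return df

    parts.append(epoch_rows("recall", recall_lab))
    parts.append(epoch_rows("confidence", conf_lab))
    if model_variant == "recall_confidence_feedback":
        fb_lab = pd.Series(np.where(sched["accuracy"] == 1, "positive", "negative"),
                           index=sched.index)
        parts.append(epoch_rows("feedback", fb_lab))
    elif model_variant == "recall_confidence_encoding":
        trans = transition_labels(sched)
        parts.append(epoch_rows("encoding", trans.fillna("Last")))
    else:
        raise ValueError(f"unknown model_variant {model_variant!r}")
    out = pd.concat(parts, ignore_index=True)
    return out.sort_values("onset", kind="stable").reset_index(drop=True)


def label_localizer_events(schedule: pd.DataFrame) -> pd.DataFrame:
    """Long event table for one localizer run: category x SDT trial type."""
    from .behavior import sdt_trial_types

    sdt = sdt_trial_types(schedule)
    return pd.DataFrame(
        {
            "onset": schedule["stimulus_onset"].to_numpy(),
            "duration": schedule["stimulus_duration"].to_numpy(),
            "trial_type": schedule["category"].astype(str) + "_" + sdt,
            "epoch": "stimulus",
            "run": schedule["run"].to_numpy(),
            "trial": schedule["trial"].to_numpy(),
        }
    )


def build_design(events: pd.DataFrame, confounds: pd.DataFrame | None,
                 tr: float, n_frames: int,
                 high_pass: float = DEFAULT_HIGH_PASS) -> pd.DataFrame:
    """Assemble the frame-times x regressors design matrix.

    ``events`` is a long table with ``onset``, ``duration`` and
    ``trial_type``; one HRF-convolved regressor is built per unique
    trial_type (sorted for deterministic column order).  Conditions whose
    convolved regressor has zero variance are dropped with a warning.
    Confound columns, the cosine drift set and an intercept are appended.
    """
    frame_times = np.arange(n_frames) * tr
    cols: dict[str, np.ndarray] = {}
    for cond in sorted(events["trial_type"].unique()):
        sel = events[events["trial_type"] == cond]
        reg = hrf_regressor(sel["onset"], sel["duration"],
                            np.ones(len(sel)), frame_times)
        if np.ptp(reg) == 0.0:
            warnings.warn(f"condition {cond!r} yields a constant regressor; dropped")
            continue
        cols[cond] = reg
    design = pd.DataFrame(cols, index=frame_times)
    if confounds is not None and len(confounds.columns):
        conf = confounds.reset_index(drop=True)
        if len(conf) != n_frames:
            raise ValueError(
                f"confounds have {len(conf)} rows, expected {n_frames} frames")
        for c in conf.columns:
            design[str(c)] = conf[c].to_numpy()
    drift = make_drift_basis(frame_times, high_pass)
    for c in drift.columns:
        design[c] = drift[c].to_numpy()
    design["intercept"] = 1.0
    design.attrs["event_columns"] = list(cols)
    design.attrs["tr"] = tr
    return design


# ---------------------------------------------------------------------------
# fitting and contrasts

@dataclass
class GlmFit:
    """Per-voxel OLS fit of one design against a 4D volume series."""

    design: pd.DataFrame
    beta: np.ndarray          # (n_regressors, n_voxels)
    sigma2: np.ndarray        # (n_voxels,) residual variance
    df: int
    xtx_inv: np.ndarray
    shape: tuple[int, int, int]

    def beta_map(self, column: str) -> np.ndarray:
        idx = list(self.design.columns).index(column)
        return self.beta[idx].reshape(self.shape)


@dataclass
class ContrastResult:
    """Effect/statistic volumes for one linear contrast of GLM betas."""

    effect: np.ndarray
    t: np.ndarray
    z: np.ndarray
    df: float
    r_squared: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Columns involved in exact linear dependences (via QR pivoting)."""
    r = np.linalg.qr(X, mode="r")
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    return [names[i] for i in range(len(names)) if i < len(diag) and diag[i] < tol]


def fit_glm(volumes, design: pd.DataFrame) -> GlmFit:
    """OLS fit of ``design`` to every voxel of a :class:`VolumeSeries`.

    Raises :class:`SingularDesignError` when the design is rank deficient,
    naming the offending columns.
    """
    data = volumes.data if hasattr(volumes, "data") else np.asarray(volumes)
    X = design.to_numpy(float)
    n_frames = X.shape[0]
    if data.shape[-1] != n_frames:
        raise ValueError(
            f"volume series has {data.shape[-1]} frames, design has {n_frames}")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _collinear_columns(X, list(design.columns))
        raise SingularDesignError(
            f"design is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns: {bad or 'undetermined'}")
    shape = data.shape[:3]
    Y = data.reshape(-1, n_frames).T  # frames x voxels
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    df = n_frames - rank
    sigma2 = (resid ** 2).sum(axis=0) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    return GlmFit(design=design, beta=beta, sigma2=sigma2, df=df,
                  xtx_inv=xtx_inv, shape=shape)


def t_to_z(t: np.ndarray, df: float) -> np.ndarray:
    """Map t values to z scores preserving two-sided tail probability."""
    t = np.asarray(t, float)
    p_half = stats.t.sf(np.abs(t), df)          # one tail, in [0, 0.5]
    p_half = np.clip(p_half, 1e-300, None)       # keep z finite (~ |z| <= 37)
    return np.sign(t) * stats.norm.isf(p_half)


def contrast(fit: GlmFit, weights: dict[str, float],
             alpha: float = 0.05) -> ContrastResult:
    """Linear contrast of GLM betas with t, z, R^2 and CI95 volumes.

    ``weights`` maps design column names to contrast weights; unnamed
    columns get weight 0.  R^2 is the partial effect size t^2/(t^2+df).
    """
    names = list(fit.design.columns)
    missing = [k for k in weights if k not in names]
    if missing:
        raise KeyError(f"contrast references missing design columns: {missing}")
    c = np.zeros(len(names))
    for k, v in weights.items():
        c[names.index(k)] = v
    effect = c @ fit.beta
    var_scale = float(c @ fit.xtx_inv @ c)
    se = np.sqrt(fit.sigma2 * var_scale)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, effect / se, 0.0)
    z = t_to_z(t, fit.df)
    r2 = t ** 2 / (t ** 2 + fit.df)
    tcrit = stats.t.isf(alpha / 2, fit.df)
    shape = fit.shape
    return ContrastResult(
        effect=effect.reshape(shape), t=t.reshape(shape), z=z.reshape(shape),
        df=fit.df, r_squared=r2.reshape(shape),
        ci_low=(effect - tcrit * se).reshape(shape),
        ci_high=(effect + tcrit * se).reshape(shape),
    )


def collinearity_diagnostics(design: pd.DataFrame,
                             event_columns: list[str] | None = None) -> pd.DataFrame:
    """VIF and pairwise Pearson r diagnostics for convolved event regressors.

    VIF_j = 1/(1 - R^2_j) from regressing column j on the other event
    columns (plus an intercept).  Flags: none (VIF <= 5), moderate
    (5 < VIF < 10), high (VIF >= 10); ``r_flag`` marks any pairwise
    |r| >= 0.90.  Perfectly collinear columns report infinite VIF.
    """
    if event_columns is None:
        event_columns = design.attrs.get("event_columns")
    if not event_columns or len(event_columns) < 2:
        raise ValueError("need at least two event regressors for diagnostics")
    X = design[event_columns].to_numpy(float)
    Xc = X - X.mean(axis=0)
    norm = np.linalg.norm(Xc, axis=0)
    norm[norm == 0] = 1.0
    corr = (Xc / norm).T @ (Xc / norm)
    rows = []
    for j, name in enumerate(event_columns):
        others = np.delete(Xc, j, axis=1)
        y = Xc[:, j]
        ss_tot = float(y @ y)
        if ss_tot == 0:
            vif = np.inf
        else:
            coef, _, _, _ = np.linalg.lstsq(others, y, rcond=None)
            resid = y - others @ coef
            r2 = 1.0 - float(resid @ resid) / ss_tot
            vif = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        if vif >= 10:
            flag = "high"
        elif vif > 5:
            flag = "moderate"
        else:
            flag = "none"
        max_r = float(np.max(np.abs(np.delete(corr[j], j)))) if len(event_columns) > 1 else 0.0
        rows.append(dict(regressor=name, vif=vif, flag=flag,
                         max_abs_r=max_r, r_flag=max_r >= 0.90))
    return pd.DataFrame(rows)
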