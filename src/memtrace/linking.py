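"""Trial-level linkage of decoded stimulus evidence to behavior.

Each association-task trial (except a face's last presentation) is coded by
the transition between its recall outcome and the outcome of the *next*
presentation of the same face: ErrorError, ErrorCorrect, CorrectCorrect or
CorrectError.  Encoding demand is 1 when the current recall failed
(ErrorError, ErrorCorrect) and 0 for CorrectCorrect; subsequent recall
success is 1 when the next recall succeeds (ErrorCorrect, CorrectCorrect)
and 0 for ErrorError.  CorrectError trials are excluded.  A linear mixed
model with participant random intercepts then regresses single-trial face
evidence on the two factors, so the fixed-effect coefficients read as
probability-scale increments in face-processing evidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TRANSITIONS",
    "transition_labels",
    "code_factors",
    "MixedModelResult",
    "fit_mixed_model",
    "wholebrain_evidence_regression",
]

TRANSITIONS = ("ErrorError", "ErrorCorrect", "CorrectCorrect", "CorrectError")


def transition_labels(schedule: pd.DataFrame) -> pd.Series:
    """(current, next) recall-outcome transition per trial; NaN for trials
    whose face is never presented again."""
    out = pd.Series(np.nan, index=schedule.index, dtype=object)
    for _, grp in schedule.groupby(["run", "face_id"], sort=False):
        grp = grp.sort_values("presentation")
        acc = grp["accuracy"].to_numpy(int)
        labels = [
            ("Correct" if acc[i] else "Error") + ("Correct" if acc[i + 1] else "Error")
            for i in range(len(acc) - 1)
        ]
        out.loc[grp.index[:-1]] = labels
    return out


def code_factors(trials: pd.DataFrame) -> pd.DataFrame:
    """Append ``transition``, ``demand``, ``success`` and ``included`` codes.

    ``included`` is True only for ErrorError / ErrorCorrect /
    CorrectCorrect trials; CorrectError trials and trials without a
    transition (a face's final presentation) are excluded.
    """
    out = trials.copy()
    trans = transition_labels(out)
    out["transition"] = trans
    demand = trans.map({"ErrorError": 1, "ErrorCorrect": 1, "CorrectCorrect": 0,
                        "CorrectError": np.nan})
    success = trans.map({"ErrorError": 0, "ErrorCorrect": 1, "CorrectCorrect": 1,
                         "CorrectError": np.nan})
    out["demand"] = demand
    out["success"] = success
    out["included"] = trans.notna() & (trans != "CorrectError")
    return out


@dataclass
class MixedModelResult:
    beta_demand: float
    beta_success: float
    z_demand: float
    z_success: float
    p_demand: float
    p_success: float
    ci_demand: tuple[float, float]
    ci_success: tuple[float, float]
    intercept: float
    n_trials: int
    n_participants: int
    method: str                      # 'mixed' or 'cluster-robust-ols'
    control: dict | None = None      # error-trials-only success coefficient


def _wald(params, bse, names) -> dict:
    res = {}
    for name in names:
        b = float(params[name])
        se = float(bse[name])
        z = b / se if se > 0 else np.inf * np.sign(b)
        res[name] = dict(
            beta=b, z=z, p=float(2 * stats.norm.sf(abs(z))),
            ci=(b - 1.959963984540054 * se, b + 1.959963984540054 * se),
        )
    return res


def _fit_lmm(df: pd.DataFrame, formula: str):
    """REML random-intercept fit; falls back to participant-clustered OLS
    when the random-effects fit is singular or fails to converge."""
    import statsmodels.formula.api as smf

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm(formula, df, groups=df["participant_id"])
            fit = model.fit(reml=True)
            if np.isfinite(fit.bse_fe).all() and fit.converged:
                return fit, "mixed"
        except (np.linalg.LinAlgError, ValueError):
            pass
        ols = smf.ols(formula, df).fit(
            cov_type="cluster", cov_kwds={"groups": df["participant_id"]})
        warnings.warn("singular mixed-effects fit; downgraded to "
                      "participant-clustered robust OLS")
        return ols, "cluster-robust-ols"


def fit_mixed_model(evidence: pd.DataFrame, epoch: str | None = None,
                    run_control: bool = True) -> MixedModelResult:
    """Mixed model of face evidence on encoding demand and recall success.

    ``evidence`` must hold one row per trial with ``face_probability``,
    ``demand``, ``success``, ``included`` and ``participant_id`` (join the
    evidence table with :func:`code_factors` output first); rows are
    restricted to included trials and, if given, the requested epoch.
    Also fits the control variant restricted to error trials (ErrorError /
    ErrorCorrect, success as sole fixed effect), which checks that the
    success effect is not carried by CorrectCorrect trials alone.
    """
    df = evidence
    if epoch is not None:
        df = df[df["epoch"] == epoch]
    df = df[df["included"]].copy()
    if df["participant_id"].nunique() < 2:
        raise ValueError("mixed model needs at least 2 participants")
    for col in ("demand", "success"):
        if df[col].nunique() < 2:
            raise ValueError(f"factor {col!r} has a single level in the data")
    fit, method = _fit_lmm(df, "face_probability ~ demand + success")
    w = _wald(fit.params, fit.bse, ["Intercept", "demand", "success"])

    control = None
    if run_control:
        err = df[df["transition"].isin(["ErrorError", "ErrorCorrect"])]
        if err["success"].nunique() == 2 and err["participant_id"].nunique() >= 2:
            cfit, cmethod = _fit_lmm(err, "face_probability ~ success")
            cw = _wald(cfit.params, cfit.bse, ["success"])
            control = dict(method=cmethod, n_trials=len(err), **cw["success"])

    return MixedModelResult(
        beta_demand=w["demand"]["beta"], beta_success=w["success"]["beta"],
        z_demand=w["demand"]["z"], z_success=w["success"]["z"],
        p_demand=w["demand"]["p"], p_success=w["success"]["p"],
        ci_demand=w["demand"]["ci"], ci_success=w["success"]["ci"],
        intercept=w["Intercept"]["beta"],
        n_trials=len(df), n_participants=int(df["participant_id"].nunique()),
        method=method, control=control,
    )


def wholebrain_evidence_regression(beta_maps_per_participant: list[np.ndarray],
                                   evidence_per_participant: list[np.ndarray],
                                   center: bool = True) -> list[np.ndarray]:
    """Per-participant slope maps of voxel betaseries on decoded evidence.

    ``beta_maps_per_participant[i]`` is a 4D array (x, y, z, trials) and
    ``evidence_per_participant[i]`` the matching per-trial face
    probabilities.  The evidence regressor is centered within participant
    (so the slope is insensitive to a participant's overall evidence
    level).  Returns one 3D slope map per participant, ready for
    :func:`memtrace.group.second_level`; participants with constant
    evidence are dropped with a warning.
    """
    maps = []
    for i, (betas, ev) in enumerate(zip(beta_maps_per_participant,
                                        evidence_per_participant)):
        ev = np.asarray(ev, float)
        if betas.shape[-1] != len(ev):
            raise ValueError(f"participant {i}: {betas.shape[-1]} maps vs "
                             f"{len(ev)} evidence rows")
        x = ev - ev.mean() if center else ev.copy()
        ssx = float(x @ x)
        if ssx == 0.0:
            warnings.warn(f"participant {i} has constant evidence; dropped")
            continue
        flat = betas.reshape(-1, len(ev))
        slope = (flat - flat.mean(axis=1, keepdims=True)) @ x / ssx
        maps.append(slope.reshape(betas.shape[:3]))
    return maps
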