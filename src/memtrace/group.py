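"""Second-level inference on contrast maps.

Participant contrast maps are Gaussian-smoothed, tested voxelwise with a
one-sample t against zero, thresholded with Benjamini-Hochberg FDR plus a
cluster-extent rule, and combined across contrasts by a minimum-statistic
conjunction whose significance is calibrated with a participant-level
sign-flip permutation null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .glm import t_to_z

__all__ = [
    "GroupResult",
    "ThresholdedMap",
    "ConjunctionResult",
    "smooth_volume",
    "second_level",
    "threshold_map",
    "conjunction",
    "network_overlap",
]

_FWHM_TO_SIGMA = np.sqrt(8.0 * np.log(2.0))
_T_CAP = 1e6   # identical maps give sd = 0; cap rather than propagate inf

_CONNECTIVITY = {"face": 1, "edge": 2, "corner": 3}


@dataclass
class GroupResult:
    mean: np.ndarray
    t: np.ndarray
    z: np.ndarray
    df: int
    r_squared: np.ndarray
    n_participants: int


@dataclass
class ThresholdedMap:
    z_map: np.ndarray
    significant: np.ndarray     # boolean volume
    q: float
    min_extent: int
    connectivity: str = "face"


@dataclass
class ConjunctionResult:
    conjunction_mask: np.ndarray
    min_stat_map: np.ndarray
    p_map: np.ndarray
    n_permutations: int
    p_threshold: float


def smooth_volume(data: np.ndarray, fwhm: float, voxel_size: float) -> np.ndarray:
    """Gaussian smoothing of a 3D volume; ``fwhm=0`` is the identity."""
    if fwhm == 0:
        return np.asarray(data, float).copy()
    sigma = fwhm / (_FWHM_TO_SIGMA * voxel_size)
    return ndimage.gaussian_filter(np.asarray(data, float), sigma)


def _one_sample_t(stack: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Vectorized one-sample t against 0 over the first axis."""
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t = np.where(np.isfinite(t), t, np.sign(mean) * _T_CAP)
    t = np.where(mean == 0, 0.0, t)
    return mean, np.clip(t, -_T_CAP, _T_CAP), n - 1


def second_level(contrast_maps: list[np.ndarray], fwhm: float = 8.0,
                 voxel_size: float = 2.2) -> GroupResult:
    """Smooth each participant's contrast map, then one-sample t per voxel."""
    if len(contrast_maps) < 3:
        raise ValueError("second-level inference needs at least 3 participants")
    shapes = {m.shape for m in contrast_maps}
    if len(shapes) != 1:
        raise ValueError(f"participant maps differ in geometry: {shapes}")
    stack = np.stack([smooth_volume(m, fwhm, voxel_size) for m in contrast_maps])
    mean, t, df = _one_sample_t(stack)
    z = t_to_z(t, df)
    return GroupResult(mean=mean, t=t, z=z, df=df,
                       r_squared=t ** 2 / (t ** 2 + df),
                       n_participants=len(contrast_maps))


def _remove_small_clusters(sig: np.ndarray, min_extent: int,
                           connectivity: str) -> np.ndarray:
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY[connectivity])
    labels, n = ndimage.label(sig, structure=structure)
    if n == 0:
        return sig
    sizes = np.bincount(labels.ravel())
    keep = np.flatnonzero(sizes >= min_extent)
    keep = keep[keep > 0]
    return np.isin(labels, keep)


def threshold_map(group: GroupResult, q: float = 0.05, min_extent: int = 5,
                  mask: np.ndarray | None = None,
                  connectivity: str = "face") -> ThresholdedMap:
    """Benjamini-Hochberg FDR over in-mask voxels + cluster-extent pruning.

    Two-sided p values come from the group z map; clusters smaller than
    ``min_extent`` voxels under the stated connectivity are removed (5
    voxels at 2.2 mm isotropic corresponds to 53.24 mm^3).
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    if mask is None:
        mask = np.ones(group.z.shape, dtype=bool)
    if not mask.any():
        raise ValueError("analysis mask is empty")
    z_in = group.z[mask]
    p = 2.0 * stats.norm.sf(np.abs(z_in))
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    sig = np.zeros(group.z.shape, dtype=bool)
    sig[mask] = reject
    sig = _remove_small_clusters(sig, min_extent, connectivity)
    return ThresholdedMap(z_map=group.z, significant=sig, q=q,
                          min_extent=min_extent, connectivity=connectivity)


def conjunction(thresholded: list[ThresholdedMap],
                participant_maps: list[list[np.ndarray]],
                n_perm: int = 10000, seed: int = 0,
                p_threshold: float = 0.05, fwhm: float = 8.0,
                voxel_size: float = 2.2) -> ConjunctionResult:
    """Minimum-statistic conjunction with a sign-flip permutation null.

    ``participant_maps[c][i]`` is participant i's (unsmoothed) map for
    contrast c.  The observed statistic per voxel is the minimum across
    contrasts of the one-sample t (computed on maps smoothed exactly as in
    :func:`second_level`).  The null flips each participant's sign, with
    the *same* flips applied to every contrast (valid under a symmetric
    null, and preserving the between-contrast dependence).  A voxel joins
    the conjunction when it is significant in every thresholded input map
    and its min-statistic permutation p is below ``p_threshold``.
    """
    if len(thresholded) < 2 or len(participant_maps) != len(thresholded):
        raise ValueError("conjunction needs >= 2 contrasts with matching maps")
    if n_perm < 100:
        raise ValueError("n_perm < 100 gives an unstable permutation null")
    shape = thresholded[0].significant.shape
    rng = np.random.default_rng(seed)
    n_subj = len(participant_maps[0])
    stacks = []
    for maps in participant_maps:
        if len(maps) != n_subj:
            raise ValueError("contrasts differ in participant count")
        stacks.append(np.stack(
            [smooth_volume(m, fwhm, voxel_size).ravel() for m in maps]))

    # Sign flips leave per-voxel sums of squares unchanged, so permuted t
    # values need only the flipped means.
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
    obs_min = None
    null_min = None
    for stack in stacks:
        _, t_obs, _ = _one_sample_t(stack)
        sumsq = (stack ** 2).sum(axis=0)
        mean_p = signs @ stack / n_subj                      # (n_perm, n_vox)
        var_p = (sumsq[None, :] - n_subj * mean_p ** 2) / (n_subj - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_p = mean_p / np.sqrt(var_p / n_subj)
        t_p = np.where(np.isfinite(t_p), t_p, np.sign(mean_p) * _T_CAP)
        obs_min = t_obs if obs_min is None else np.minimum(obs_min, t_obs)
        null_min = t_p if null_min is None else np.minimum(null_min, t_p)
    p_map = (1.0 + (null_min >= obs_min[None, :]).sum(axis=0)) / (n_perm + 1.0)
    inter = np.logical_and.reduce([tm.significant for tm in thresholded])
    conj = inter & (p_map.reshape(shape) < p_threshold)
    return ConjunctionResult(
        conjunction_mask=conj, min_stat_map=obs_min.reshape(shape),
        p_map=p_map.reshape(shape), n_permutations=n_perm,
        p_threshold=p_threshold,
    )


def network_overlap(thresholded: ThresholdedMap, parcellation: np.ndarray,
                    labels: dict[int, str] | None = None) -> dict[str, float]:
    """Fraction of significant voxels falling in each parcellation network.

    ``parcellation`` is an integer-labeled volume (0 = outside all
    networks); voxels outside every network count as ``unassigned``.
    Fractions sum to 1 when the significant set is non-empty.
    """
    if parcellation.shape != thresholded.significant.shape:
        raise ValueError("parcellation geometry does not match the map")
    sig = thresholded.significant
    n_sig = int(sig.sum())
    ids = sorted(int(v) for v in np.unique(parcellation) if v != 0)
    if labels is None:
        labels = {i: f"network_{i}" for i in ids}
    if n_sig == 0:
        warnings.warn("empty significant set; overlap proportions are all zero")
        out = {labels[i]: 0.0 for i in ids}
        out["unassigned"] = 0.0
        return out
    in_lab = parcellation[sig]
    counts = np.bincount(in_lab.astype(int), minlength=max(ids, default=0) + 1)
    out = {labels[i]: counts[i] / n_sig for i in ids}
    out["unassigned"] = counts[0] / n_sig if len(counts) else 0.0
    return out
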