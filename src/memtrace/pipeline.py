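"""Pipeline orchestration: simulate -> behavior -> GLM -> LSS -> MVPA -> link.

Two layers: in-memory per-participant helpers (used by the staged runner
and by analysis scripts), and a file-based staged pipeline driven by a
single serializable :class:`RunConfig`, with per-stage seeds derived
deterministically from one master seed and a manifest of checksummed
artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as behavior_analysis
from . import glm, group, io, linking, lss, mvpa
from .simulate import (DEFAULT_VOXEL_SIZE, BehaviorParams, NoiseSpec,
                       PatternSpec, TaskDesign, VolumeSeries,
                       generate_association_schedule,
                       generate_localizer_schedule, simulate_behavior,
                       simulate_bold, simulate_localizer_behavior)
from .simulate.bold import default_affine

logger = logging.getLogger("memtrace")

__all__ = [
    "RunConfig", "derive_seed", "simulate_participant", "decode_participant",
    "run_pipeline", "toy_parcellation",
]

MEMORY_EPOCHS = ("recall", "encoding", "iti")


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: blake2s(master_seed:stage) mod 2^31."""
    digest = hashlib.blake2s(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class RunConfig:
    """Full configuration of one simulated study."""

    design: TaskDesign = field(default_factory=TaskDesign)
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    pattern_seed: int = 0
    demand_effect: float = 0.0       # BOLD-amplitude increment per demand
    success_effect: float = 0.0      # BOLD-amplitude increment per success
    n_participants: int = 4
    master_seed: int = 0
    smoothing_fwhm: float = 6.0      # betaseries smoothing
    group_fwhm: float = 8.0          # second-level smoothing
    fdr_q: float = 0.05
    min_extent: int = 5
    n_permutations: int = 500
    mvpa: mvpa.MvpaConfig = field(default_factory=mvpa.MvpaConfig)

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return enc(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        design = dict(data.pop("design", {}))
        if "iti_range" in design:
            design["iti_range"] = tuple(design["iti_range"])
        kwargs = dict(
            design=TaskDesign(**design),
            behavior=BehaviorParams(**data.pop("behavior", {})),
            noise=NoiseSpec(**data.pop("noise", {})),
            mvpa=mvpa.MvpaConfig(**data.pop("mvpa", {})),
        )
        kwargs.update(data)
        return cls(**kwargs)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def pattern(self) -> PatternSpec:
        return PatternSpec.default(
            seed=self.pattern_seed,
            demand_effect=self.demand_effect,
            success_effect=self.success_effect,
        )


# ---------------------------------------------------------------------------
# in-memory per-participant helpers

def simulate_participant(config: RunConfig, participant: int) -> dict:
    """Simulate one participant's schedules, behavior and BOLD runs."""
    seed = derive_seed(config.master_seed, f"participant-{participant}")
    rng = np.random.default_rng(seed)
    sched_seed, beh_seed, loc_seed, bold_seed = rng.integers(0, 2**31, 4)
    design = config.design
    pattern = config.pattern()

    assoc = generate_association_schedule(design, int(sched_seed))
    assoc = simulate_behavior(
        assoc, dataclasses.replace(config.behavior, seed=int(beh_seed)))
    assoc = linking.code_factors(assoc)
    loc = generate_localizer_schedule(design, int(loc_seed))
    loc = simulate_localizer_behavior(loc, seed=int(loc_seed))

    assoc_runs, loc_runs = {}, {}
    for task, sched, store in (("assoc", assoc, assoc_runs),
                               ("loc", loc, loc_runs)):
        for run in sorted(sched["run"].unique()):
            noise = dataclasses.replace(
                config.noise,
                seed=derive_seed(int(bold_seed), f"{task}-run-{run}"))
            store[int(run)] = simulate_bold(
                sched[sched["run"] == run], pattern, noise, design)
    return dict(participant=participant, association=assoc, localizer=loc,
                assoc_runs=assoc_runs, loc_runs=loc_runs, pattern=pattern)


def _betaseries_over_runs(runs: dict, schedule: pd.DataFrame, spec: lss.LssSpec,
                          mask: np.ndarray, fwhm: float) -> lss.BetaSeries:
    mats, metas = [], []
    for run, (vol, truth) in sorted(runs.items()):
        sub = schedule[schedule["run"] == run]
        maps, meta = lss.lss_deconvolve(vol, sub, truth.confounds, spec)
        bs = lss.extract_roi(maps, meta, mask, fwhm=fwhm)
        mats.append(bs.matrix)
        metas.append(bs.trial_meta)
    return lss.BetaSeries(np.vstack(mats), pd.concat(metas, ignore_index=True),
                          mask)


def decode_participant(sim: dict, config: RunConfig,
                       epochs: tuple[str, ...] = MEMORY_EPOCHS) -> dict:
    """Localizer-trained decoding of one simulated participant.

    Runs the localizer LSS (correct-rejection trials), leave-one-run-out
    cross-validation, the full-model fit, and cross-classification of the
    requested association-task epochs.  Returns the betaseries, the CV
    summary, the fitted model and the combined evidence table.
    """
    mask = sim["pattern"].roi_mask
    cr_filter = lambda r: (not r["is_repetition"]) and (not r["pressed"])  # noqa: E731
    loc_spec = lss.LssSpec(epoch="stimulus", smoothing_fwhm=config.smoothing_fwhm,
                           trial_filter=cr_filter)
    loc_series = _betaseries_over_runs(sim["loc_runs"], sim["localizer"],
                                       loc_spec, mask, config.smoothing_fwhm)
    cv = mvpa.cross_validate(loc_series, config.mvpa)
    model = mvpa.fit_full_model(loc_series, config.mvpa)
    evidence = []
    for epoch in epochs:
        spec = lss.LssSpec(epoch=epoch, smoothing_fwhm=config.smoothing_fwhm)
        series = _betaseries_over_runs(sim["assoc_runs"], sim["association"],
                                       spec, mask, config.smoothing_fwhm)
        evidence.append(mvpa.predict_evidence(model, series, epoch,
                                              participant_id=sim["participant"]))
    return dict(localizer_series=loc_series, cv=cv, model=model,
                evidence=pd.concat(evidence, ignore_index=True))


def toy_parcellation(grid_shape: tuple[int, int, int], seed: int = 0,
                     n_networks: int = 7) -> np.ndarray:
    """Toy integer-labeled parcellation: contiguous slabs for 7 networks
    plus an unlabeled margin, standing in for a cortical network atlas."""
    rng = np.random.default_rng(seed)
    parc = np.zeros(grid_shape, dtype=int)
    x = np.arange(grid_shape[0])
    edges = np.linspace(0, grid_shape[0], n_networks + 1).astype(int)
    for i in range(n_networks):
        parc[edges[i]:edges[i + 1], :, :] = i + 1
    parc[:, :, 0] = 0            # unassigned margin
    parc[:, 0, :] = 0
    if seed:
        parc = np.roll(parc, rng.integers(0, grid_shape[0]), axis=0)
    return parc


# ---------------------------------------------------------------------------
# file-based staged pipeline

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _record(manifest: dict, stage: str, path: Path, root: Path) -> None:
    manifest["artifacts"].append(
        dict(stage=stage, path=str(path.relative_to(root)),
             sha256=_sha256(path)))


def run_pipeline(config: RunConfig, output_root) -> dict:
    """Execute every stage and write a checksummed run manifest.

    Stages communicate through files under ``output_root`` only.  A stage
    failure halts the pipeline with the stage name; the partial manifest is
    still written.  Re-running with an identical config reproduces every
    checksum.
    """
    root = Path(output_root)
    root.mkdir(parents=True, exist_ok=True)
    manifest: dict = dict(config=config.to_dict(), stages=[], artifacts=[],
                          seeds={}, version=__import__("memtrace").__version__)
    stage = "init"
    try:
        if config.n_participants < 2:
            raise ValueError(
                "group stages need >= 2 participants (>= 3 for second-level "
                "maps); set n_participants accordingly")

        stage = "simulate"
        sims = []
        for p in range(1, config.n_participants + 1):
            sim = simulate_participant(config, p)
            sims.append(sim)
            pdir = root / f"sub-{p:02d}"
            io.write_events_tsv(sim["association"], pdir / "association_events.tsv")
            io.write_events_tsv(sim["localizer"], pdir / "localizer_events.tsv")
            for task, runs in (("assoc", sim["assoc_runs"]),
                               ("loc", sim["loc_runs"])):
                for run, (vol, truth) in runs.items():
                    io.write_volume(vol, pdir / f"{task}_run-{run}_bold.nii")
                    io.write_confounds_tsv(
                        truth.confounds, pdir / f"{task}_run-{run}_confounds.tsv")
                    io.write_json(truth.to_dict(),
                                  pdir / f"{task}_run-{run}_truth.json")
            manifest["seeds"][f"participant-{p}"] = derive_seed(
                config.master_seed, f"participant-{p}")
            for f in sorted(pdir.glob("*")):
                _record(manifest, stage, f, root)
        manifest["stages"].append(stage)

        stage = "behavior"
        rows = []
        for sim in sims:
            assoc = io.read_events_tsv(
                root / f"sub-{sim['participant']:02d}" / "association_events.tsv")
            mm = behavior_analysis.meta_memory(assoc)
            rows.append(dict(
                participant_id=sim["participant"],
                accuracy_pct=100.0 * assoc["accuracy"].mean(),
                d_prime=mm.d_prime, d_bias=mm.d_bias,
            ))
        path = io.write_events_tsv(pd.DataFrame(rows),
                                   root / "behavior_summary.tsv")
        _record(manifest, stage, path, root)
        manifest["stages"].append(stage)

        stage = "glm"
        contrast_maps: dict[str, list[np.ndarray]] = {
            "failed_recall": [], "negative_feedback": []}
        for sim in sims:
            pdir = root / f"sub-{sim['participant']:02d}"
            assoc = io.read_events_tsv(pdir / "association_events.tsv")
            effects = {k: [] for k in contrast_maps}
            for run in sorted(assoc["run"].unique()):
                sub = assoc[assoc["run"] == run]
                vol = VolumeSeries.from_nifti(
                    pdir / f"assoc_run-{run}_bold.nii", tr=config.design.tr)
                conf = io.read_confounds_tsv(pdir / f"assoc_run-{run}_confounds.tsv")
                events = glm.label_association_events(
                    sub, "recall_confidence_feedback")
                X = glm.build_design(events, conf, config.design.tr, vol.n_frames)
                fit = glm.fit_glm(vol, X)
                for name, weights in (
                    ("failed_recall", {"recall_Error_ConfidenceLow": 1,
                                       "recall_Correct_ConfidenceHigh": -1}),
                    ("negative_feedback", {"feedback_negative": 1,
                                           "feedback_positive": -1}),
                ):
                    usable = {k: v for k, v in weights.items() if k in X.columns}
                    if len(usable) == len(weights):
                        effects[name].append(glm.contrast(fit, usable).effect)
            for name, maps in effects.items():
                if maps:
                    avg = np.mean(maps, axis=0)
                    contrast_maps[name].append(avg)
                    path = io.write_volume(avg, pdir / f"contrast_{name}.nii",
                                           affine=default_affine())
                    _record(manifest, stage, path, root)
        manifest["stages"].append(stage)

        stage = "group"
        if config.n_participants < 3:
            raise ValueError("second-level inference needs >= 3 participants")
        voxel = DEFAULT_VOXEL_SIZE
        thresholded, per_contrast = [], []
        group_summary = {}
        for name, maps in contrast_maps.items():
            g = group.second_level(maps, fwhm=config.group_fwhm, voxel_size=voxel)
            tm = group.threshold_map(g, q=config.fdr_q,
                                     min_extent=config.min_extent)
            thresholded.append(tm)
            per_contrast.append(maps)
            path = io.write_volume(g.z, root / f"group_{name}_z.nii")
            _record(manifest, stage, path, root)
            group_summary[name] = dict(max_z=float(g.z.max()),
                                       n_significant=int(tm.significant.sum()))
        conj = group.conjunction(
            thresholded, per_contrast, n_perm=config.n_permutations,
            seed=derive_seed(config.master_seed, "conjunction"),
            fwhm=config.group_fwhm, voxel_size=voxel)
        parc = toy_parcellation(thresholded[0].significant.shape)
        overlap = group.network_overlap(
            dataclasses.replace(thresholded[0],
                                significant=conj.conjunction_mask), parc)
        path = io.write_json(dict(contrasts=group_summary,
                                  conjunction_voxels=int(conj.conjunction_mask.sum()),
                                  network_overlap=overlap),
                             root / "group_summary.json")
        _record(manifest, stage, path, root)
        manifest["stages"].append(stage)

        stage = "mvpa"
        evidence_frames = []
        cv_rows = []
        for sim in sims:
            decoded = decode_participant(sim, config)
            cv_rows.append(dict(participant_id=sim["participant"],
                                balanced_accuracy=decoded["cv"]["mean_balanced_accuracy"]))
            evidence_frames.append(decoded["evidence"])
        evidence = pd.concat(evidence_frames, ignore_index=True)
        path = io.write_events_tsv(evidence, root / "evidence.tsv")
        _record(manifest, stage, path, root)
        path = io.write_events_tsv(pd.DataFrame(cv_rows), root / "decoding_cv.tsv")
        _record(manifest, stage, path, root)
        manifest["stages"].append(stage)

        stage = "link"
        evidence = io.read_events_tsv(root / "evidence.tsv")
        link_summary = {}
        for epoch in MEMORY_EPOCHS:
            try:
                res = linking.fit_mixed_model(evidence, epoch=epoch)
            except ValueError as exc:
                link_summary[epoch] = dict(error=str(exc))
                continue
            link_summary[epoch] = dict(
                beta_demand=res.beta_demand, beta_success=res.beta_success,
                z_demand=res.z_demand, z_success=res.z_success,
                p_demand=res.p_demand, p_success=res.p_success,
                n_trials=res.n_trials, method=res.method)
        path = io.write_json(link_summary, root / "mixed_model.json")
        _record(manifest, stage, path, root)
        manifest["stages"].append(stage)
        manifest["mixed_model"] = link_summary

    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        io.write_json(manifest, root / "manifest.json")
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    io.write_json(manifest, root / "manifest.json")
    logger.info("pipeline complete: %d artifacts", len(manifest["artifacts"]))
    return manifest
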