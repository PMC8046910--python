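"""Synthetic BOLD data with the statistical structure the analysis assumes.

The generator emulates a resting run (180 volumes, TR 2 s, first 10
discarded) in which a ~213-voxel compact ROI — a stand-in for the primary
visual area — hosts sparse transient high-amplitude events confined to
partially overlapping voxel subsets, on top of spatially smooth 1/f-plus-
white background noise, linear drift, and a motion-correlated component.
A matching task run (18 trial blocks of 24 s, 385 volumes, first 5
discarded) carries HRF-convolved boxcar responses with known per-condition
effect maps. Cohorts come with age/sex covariates (8 of each sex at n=16,
ages near 21 +/- 1.4 years).

Everything is a deterministic function of the config and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .base import BoldRun, MaskVolume
from .hrf import canonical_hrf, event_regressor
from .preprocess import MOTION_COLUMNS

# retained-volume indices (1-based) aligned to the 5-TR sampling stride,
# seven of them to sit near the reported group-mean CTP count of ~6.9
DEFAULT_EVENT_TIMES = (16, 41, 66, 86, 106, 131, 156)


@dataclass
class SyntheticSceneConfig:
    """Parameters of the synthetic scene; identical config + seed gives
    bit-identical output.

    ``event_amplitude`` is expressed in units of the baseline noise SD;
    ``event_extent_frac`` is the fraction of ROI voxels recruited per event
    (default 0.095, i.e. ~20 of 213 voxels); ``event_overlap_frac`` is the
    expected voxel-set overlap between consecutive events.
    """

    grid_shape: tuple = (24, 28, 24)
    voxel_size_mm: tuple = (3.0, 3.0, 3.0)
    tr_s: float = 2.0
    n_volumes_rest: int = 180
    n_discard_rest: int = 10
    n_volumes_task: int = 385
    n_discard_task: int = 5
    n_trials_task: int = 18
    trial_duration_s: float = 24.0
    trial_spacing_s: float = 40.0
    task_start_s: float = 12.0
    roi_n_voxels: int = 213
    event_times: tuple = DEFAULT_EVENT_TIMES
    event_amplitude: float = 4.0
    event_extent_frac: float = 0.095
    event_overlap_frac: float = 0.5
    noise_sd: float = 1.0
    noise_pink_frac: float = 0.3
    noise_smooth_fwhm_mm: float = 6.0
    drift_slope: float = 0.01
    motion_step_mm: float = 0.02
    motion_step_deg: float = 0.02
    motion_coupling: float = 0.1
    n_parcels: int = 90
    seed: int = 0

    def validate(self) -> None:
        if any(g < 6 for g in self.grid_shape) or len(self.grid_shape) != 3:
            raise ValueError("grid_shape must be 3 axes of at least 6 voxels")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.event_amplitude < 0:
            raise ValueError("event_amplitude must be non-negative")
        if not 0 < self.event_extent_frac <= 1:
            raise ValueError("event_extent_frac must lie in (0, 1]")
        if not 0 <= self.event_overlap_frac <= 1:
            raise ValueError("event_overlap_frac must lie in [0, 1]")
        n_retained = self.n_volumes_rest - self.n_discard_rest
        if n_retained < 1:
            raise ValueError("no retained volumes")
        for e in self.event_times:
            if not 1 <= e <= n_retained:
                raise ValueError(f"event time {e} outside retained range "
                                 f"1..{n_retained}")
        if self.noise_smooth_fwhm_mm < 0:
            raise ValueError("noise_smooth_fwhm_mm must be non-negative")

    @property
    def n_retained_rest(self) -> int:
        return self.n_volumes_rest - self.n_discard_rest

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag((*self.voxel_size_mm, 1.0))
        aff[:3, 3] = -np.asarray(self.grid_shape) * np.asarray(self.voxel_size_mm) / 2
        return aff


@dataclass
class SyntheticDataset:
    """One synthetic subject: BOLD run, masks, motion, covariates, truth."""

    bold: BoldRun
    roi_mask: MaskVolume
    brain_mask: MaskVolume
    motion_table: pd.DataFrame
    covariates: dict = field(default_factory=dict)
    ground_truth: dict = field(default_factory=dict)
    wm_mask: MaskVolume = None
    csf_mask: MaskVolume = None
    parcellation: np.ndarray = None
    events: pd.DataFrame = None
    config: SyntheticSceneConfig = None
    task: "SyntheticDataset" = None  # matching task run, set by generate_cohort

    def ground_truth_json(self) -> str:
        gt = {str(k): sorted(int(v) for v in vals)
              for k, vals in self.ground_truth.get("event_voxels", {}).items()}
        return json.dumps({"event_times": [int(e) for e in
                                           self.ground_truth.get("event_times", [])],
                           "event_voxels": gt})


def _ball_mask(shape, center, n_target: int, within: np.ndarray | None = None
               ) -> np.ndarray:
    """Compact blob of exactly n_target voxels nearest to ``center``."""
    idx = np.indices(shape).reshape(3, -1).T
    if within is not None:
        idx = idx[within.ravel() != 0]
    d = ((idx - np.asarray(center)) ** 2).sum(axis=1)
    if n_target > len(idx):
        raise ValueError(f"grid too small: need {n_target} voxels, "
                         f"have {len(idx)}")
    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0], d))
    chosen = idx[order[:n_target]]
    out = np.zeros(shape, dtype=bool)
    out[tuple(chosen.T)] = True
    return out


def make_anatomy(config: SyntheticSceneConfig) -> dict:
    """Deterministic masks: ellipsoidal brain, compact posterior ROI,
    WM and CSF compartments, and a ~90-parcel block labelling."""
    shape = np.asarray(config.grid_shape)
    ctr = (shape - 1) / 2.0
    ax = np.indices(config.grid_shape)
    semi = shape * 0.46
    brain = (((ax[0] - ctr[0]) / semi[0]) ** 2 + ((ax[1] - ctr[1]) / semi[1]) ** 2
             + ((ax[2] - ctr[2]) / semi[2]) ** 2) <= 1.0
    if brain.sum() < config.roi_n_voxels + 200:
        raise ValueError("grid too small to host the ROI inside the brain mask")
    # ROI sits posterior (low y), like an occipital region
    roi_center = (ctr[0], ctr[1] - semi[1] * 0.55, ctr[2])
    roi = _ball_mask(config.grid_shape, roi_center, config.roi_n_voxels,
                     within=brain)
    wm = _ball_mask(config.grid_shape,
                    (ctr[0] - semi[0] * 0.4, ctr[1] + semi[1] * 0.3, ctr[2]),
                    80, within=brain & ~roi)
    csf = _ball_mask(config.grid_shape,
                     (ctr[0] + semi[0] * 0.4, ctr[1] + semi[1] * 0.3, ctr[2]),
                     80, within=brain & ~roi & ~wm)
    # parcellation: coarse boxes over the bounding grid, labelled within brain
    n_boxes = np.array([5, 6, 3])
    box = np.ceil(shape / n_boxes).astype(int)
    labels = np.zeros(config.grid_shape, dtype=int)
    xi, yi, zi = ax[0] // box[0], ax[1] // box[1], ax[2] // box[2]
    labels_all = 1 + xi * (n_boxes[1] * n_boxes[2]) + yi * n_boxes[2] + zi
    labels[brain] = labels_all[brain]
    aff = config.affine
    return {"brain": MaskVolume(brain, aff), "roi": MaskVolume(roi, aff),
            "wm": MaskVolume(wm, aff), "csf": MaskVolume(csf, aff),
            "parcellation": labels}


def _pink_white_noise(rng: np.random.Generator, n_vox: int, n_t: int,
                      pink_frac: float) -> np.ndarray:
    white = rng.standard_normal((n_vox, n_t))
    if pink_frac <= 0:
        return white
    spec = np.fft.rfft(rng.standard_normal((n_vox, n_t)), axis=1)
    freqs = np.fft.rfftfreq(n_t)
    freqs[0] = freqs[1]
    spec /= np.sqrt(freqs)
    pink = np.fft.irfft(spec, n=n_t, axis=1)
    pink /= pink.std(axis=1, keepdims=True) + 1e-12
    return (1 - pink_frac) * white + pink_frac * pink


def _motion_table(rng: np.random.Generator, n_t: int,
                  config: SyntheticSceneConfig) -> pd.DataFrame:
    steps = rng.standard_normal((n_t, 6))
    steps[:, :3] *= config.motion_step_mm
    steps[:, 3:] *= config.motion_step_deg
    params = np.cumsum(steps, axis=0)
    params -= params[0]
    return pd.DataFrame(params, columns=MOTION_COLUMNS)


def _background(rng: np.random.Generator, config: SyntheticSceneConfig,
                brain: np.ndarray, n_t: int,
                motion: pd.DataFrame) -> np.ndarray:
    """Smoothed 1/f+white noise + linear drift + motion-correlated component,
    rescaled so the in-brain marginal SD equals noise_sd."""
    shape = config.grid_shape
    n_vox = int(np.prod(shape))
    noise = _pink_white_noise(rng, n_vox, n_t, config.noise_pink_frac)
    noise = noise.reshape(*shape, n_t)
    if config.noise_smooth_fwhm_mm > 0:
        sigma_vox = (config.noise_smooth_fwhm_mm
                     / (2 * np.sqrt(2 * np.log(2)))
                     / np.asarray(config.voxel_size_mm))
        noise = ndimage.gaussian_filter(noise, sigma=(*sigma_vox, 0.0))
    sd = noise[brain].std()
    noise *= config.noise_sd / max(sd, 1e-12)
    t = np.arange(n_t) - (n_t - 1) / 2.0
    drift_pattern = 0.5 + rng.random(shape)
    data = noise + config.drift_slope * drift_pattern[..., None] * t
    if config.motion_coupling > 0:
        coupling = rng.standard_normal((*shape, 6)) * config.motion_coupling
        coupling = ndimage.gaussian_filter(coupling, sigma=(2, 2, 2, 0))
        data += np.einsum("xyzk,tk->xyzt", coupling,
                          motion.to_numpy()) * config.noise_sd
    data[~brain] = 0.0
    return data


def _event_voxel_sets(roi: MaskVolume, config: SyntheticSceneConfig) -> dict:
    """Contiguous, partially overlapping recruited voxel sets per event.

    Events model a recurring coactivation pattern: every event recruits a
    shared core of round(overlap_frac * k) voxels plus an event-specific
    contiguous slice of the remaining ROI, where k = round(extent_frac *
    n_roi). Any two events therefore share ~overlap_frac of their voxels.
    ROI voxels are kept in a spatially coherent raster order so each
    recruited set is a compact region.
    """
    coords = roi.coords()
    order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0]))
    coords = coords[order]
    n_roi = len(coords)
    shape = roi.data.shape
    strides = np.array([shape[1] * shape[2], shape[2], 1])
    flat = coords @ strides
    k = max(1, int(round(config.event_extent_frac * n_roi)))
    n_core = int(round(k * config.event_overlap_frac))
    core = flat[:n_core]
    pool = flat[n_core:]
    span = k - n_core
    sets = {}
    start = 0
    for e in config.event_times:
        if span == 0:
            sets[int(e)] = core.copy()
            continue
        if start + span > len(pool):
            start = 0
        sets[int(e)] = np.concatenate([core, pool[start:start + span]])
        start += span
    return sets


def generate_resting_run(config: SyntheticSceneConfig) -> SyntheticDataset:
    """Resting run with planted transient ROI events.

    Each planted event adds a canonical-HRF-shaped transient, peaking at the
    event volume with amplitude event_amplitude * noise_sd, to its recruited
    voxel set. Events are recorded in ``ground_truth`` even when the
    amplitude is zero.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    anat = make_anatomy(config)
    brain = anat["brain"].data
    n_t = config.n_volumes_rest
    motion = _motion_table(rng, n_t, config)
    data = _background(rng, config, brain, n_t, motion)
    event_sets = _event_voxel_sets(anat["roi"], config)
    if config.event_amplitude > 0:
        h = canonical_hrf(config.tr_s)
        peak = int(np.argmax(h))
        flat = data.reshape(-1, n_t)
        for e, voxels in event_sets.items():
            vol = config.n_discard_rest + e - 1  # 0-based volume of the event
            t0 = vol - peak
            for i, hv in enumerate(h):
                t = t0 + i
                if 0 <= t < n_t:
                    flat[voxels, t] += config.event_amplitude * config.noise_sd * hv
    run = BoldRun(data=data, tr_s=config.tr_s, affine=config.affine,
                  provenance="rest")
    gt = {"event_times": list(config.event_times),
          "event_voxels": {int(e): v for e, v in event_sets.items()}}
    return SyntheticDataset(bold=run, roi_mask=anat["roi"],
                            brain_mask=anat["brain"], motion_table=motion,
                            ground_truth=gt, wm_mask=anat["wm"],
                            csf_mask=anat["csf"],
                            parcellation=anat["parcellation"], config=config)


def default_task_events(config: SyntheticSceneConfig) -> pd.DataFrame:
    """18 non-overlapping 24 s blocks, conditions alternating creative/control."""
    onsets = config.task_start_s + config.trial_spacing_s * np.arange(
        config.n_trials_task)
    conditions = ["creative" if i % 2 == 0 else "control"
                  for i in range(config.n_trials_task)]
    return pd.DataFrame({"onset_s": onsets,
                         "duration_s": config.trial_duration_s,
                         "condition": conditions})


def default_beta_truth(config: SyntheticSceneConfig,
                       rng: np.random.Generator) -> dict:
    """Smooth random per-condition effect maps (unit scale, in-brain)."""
    anat = make_anatomy(config)
    maps = {}
    for cond in ("creative", "control"):
        m = ndimage.gaussian_filter(rng.standard_normal(config.grid_shape), 2.0)
        m /= np.abs(m[anat["brain"].data]).mean() + 1e-12
        m[~anat["brain"].data] = 0.0
        maps[cond] = m
    return maps


def generate_task_run(config: SyntheticSceneConfig,
                      beta_truth: dict | None = None,
                      events: pd.DataFrame | None = None) -> SyntheticDataset:
    """Task run: HRF-convolved boxcar responses with known effect maps.

    Each voxel's time course is the sum over trials of
    beta_truth[condition][voxel] * (boxcar * HRF) plus drift and noise.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 7)))
    if events is None:
        events = default_task_events(config)
    ends = events["onset_s"].to_numpy() + events["duration_s"].to_numpy()
    order = np.argsort(events["onset_s"].to_numpy())
    if np.any(events["onset_s"].to_numpy()[order][1:] < ends[order][:-1]):
        raise ValueError("overlapping trials are not supported")
    duration = config.n_volumes_task * config.tr_s
    if ends.max() > duration:
        raise ValueError("trials do not fit within the task run")
    if beta_truth is None:
        beta_truth = default_beta_truth(config, rng)
    anat = make_anatomy(config)
    brain = anat["brain"].data
    n_t = config.n_volumes_task
    motion = _motion_table(rng, n_t, config)
    data = _background(rng, config, brain, n_t, motion)
    frame_times = np.arange(n_t) * config.tr_s
    for i in range(len(events)):
        reg = event_regressor(frame_times, events.loc[i, "onset_s"],
                              events.loc[i, "duration_s"], tr_s=config.tr_s)
        bmap = np.asarray(beta_truth[events.loc[i, "condition"]], dtype=float)
        if bmap.ndim == 0:
            bmap = np.full(config.grid_shape, float(bmap))
            bmap[~brain] = 0.0
        data += bmap[..., None] * reg
    run = BoldRun(data=data, tr_s=config.tr_s, affine=config.affine,
                  provenance="task")
    gt = {"beta_truth": beta_truth}
    return SyntheticDataset(bold=run, roi_mask=anat["roi"],
                            brain_mask=anat["brain"], motion_table=motion,
                            ground_truth=gt, wm_mask=anat["wm"],
                            csf_mask=anat["csf"],
                            parcellation=anat["parcellation"], events=events,
                            config=config)


def cohort_covariates(n_subjects: int, seed: int) -> pd.DataFrame:
    """Ages near 21 +/- 1.4 years; sexes balanced (F/M alternating shuffle)."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 99)))
    ages = np.round(rng.normal(21.0, 1.4, size=n_subjects), 1)
    sexes = np.array(["F", "M"] * ((n_subjects + 1) // 2))[:n_subjects]
    rng.shuffle(sexes)
    return pd.DataFrame({"subject_id": [f"sub-{i + 1:02d}" for i in range(n_subjects)],
                         "age": ages, "sex": sexes})


def generate_cohort(n_subjects: int,
                    config_template: SyntheticSceneConfig | None = None,
                    seed: int = 0, include_task: bool = True
                    ) -> tuple[list[SyntheticDataset], pd.DataFrame]:
    """Deterministic cohort: per-subject seeds spawned from the master seed.

    Returns (rest datasets with ``task`` attribute attached when requested,
    covariate table). Adding a subject never perturbs earlier subjects'
    streams.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    template = config_template or SyntheticSceneConfig()
    covs = cohort_covariates(n_subjects, seed)
    datasets = []
    for i in range(n_subjects):
        sub_seed = int(np.random.SeedSequence((seed, i)).generate_state(1)[0]
                       % (2 ** 31))
        cfg = replace(template, seed=sub_seed)
        ds = generate_resting_run(cfg)
        ds.covariates = {"subject_id": covs.loc[i, "subject_id"],
                         "age": float(covs.loc[i, "age"]),
                         "sex": covs.loc[i, "sex"]}
        if include_task:
            ds.task = generate_task_run(cfg)
        datasets.append(ds)
    return datasets, covs
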