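"""Cube-similarity network construction for rest and task data.

Nodes are non-overlapping 3x3x3-voxel cubes tiling the brain mask; an edge
between two cubes is the Pearson correlation of their 27-voxel value
patterns in a single volume (a resting volume at one time point, or a task
beta image). Only positive correlations are kept. Per-condition networks
are element-wise averages over the constituent single-volume networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .base import BoldRun, MaskVolume
from .hrf import event_regressor
from .preprocess import dct_drift_basis

logger = logging.getLogger(__name__)


@dataclass
class CubeParcellation:
    """Tiling of the brain mask by axis-aligned cubes.

    ``voxel_ids`` holds, per cube, the flat (C-order) indices of its voxels
    in fixed raster order; ``labels`` is the dominant parcel label of each
    cube (0 when no parcellation volume is supplied).
    """

    cube_edge: int
    anchors: np.ndarray          # (n_cubes, 3) minimum-corner voxel coordinates
    voxel_ids: np.ndarray        # (n_cubes, cube_edge**3) flat indices
    labels: np.ndarray           # (n_cubes,) parcel label per cube
    grid_shape: tuple

    @property
    def n_cubes(self) -> int:
        return len(self.anchors)


def build_cube_parcellation(mask: MaskVolume, cube_edge: int = 3,
                            parcellation: np.ndarray | None = None) -> CubeParcellation:
    """Tile the mask bounding box with cubes fully inside the mask.

    The tiling is anchored at the minimum corner of the mask bounding box;
    a block becomes a node iff every one of its voxels is in-mask, so all
    pattern vectors have the full cube_edge**3 length.
    """
    if cube_edge < 1:
        raise ValueError("cube_edge must be >= 1")
    coords = mask.coords()
    lo = coords.min(axis=0)
    hi = coords.max(axis=0) + 1
    shape = mask.data.shape
    anchors, ids, labels = [], [], []
    strides = np.array([shape[1] * shape[2], shape[2], 1])
    for x in range(lo[0], hi[0] - cube_edge + 1, cube_edge):
        for y in range(lo[1], hi[1] - cube_edge + 1, cube_edge):
            for z in range(lo[2], hi[2] - cube_edge + 1, cube_edge):
                block = mask.data[x:x + cube_edge, y:y + cube_edge, z:z + cube_edge]
                if block.all():
                    anchors.append((x, y, z))
                    gx, gy, gz = np.meshgrid(range(x, x + cube_edge),
                                             range(y, y + cube_edge),
                                             range(z, z + cube_edge),
                                             indexing="ij")
                    vox = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
                    ids.append(vox @ strides)
                    if parcellation is not None:
                        vals = np.asarray(parcellation)[tuple(vox.T)]
                        vals = vals[vals > 0]
                        labels.append(int(np.bincount(vals.astype(int)).argmax())
                                      if vals.size else 0)
                    else:
                        labels.append(0)
    if not anchors:
        raise ValueError("no complete cube fits inside the mask")
    return CubeParcellation(cube_edge=cube_edge,
                            anchors=np.array(anchors, dtype=int),
                            voxel_ids=np.array(ids, dtype=int),
                            labels=np.array(labels, dtype=int),
                            grid_shape=shape)


@dataclass
class SimilarityNetwork:
    """Symmetric matrix of retained (positive) cube-pattern correlations.

    ``weights`` is the full n_cubes x n_cubes matrix with zero diagonal;
    non-positive similarities are stored as 0 (absent). Rows/columns of
    excluded (zero-variance) cubes are all zero.
    """

    weights: np.ndarray
    excluded_nodes: np.ndarray
    condition: str = ""
    source: object = None

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def active_nodes(self) -> np.ndarray:
        mask = np.ones(self.n_nodes, dtype=bool)
        mask[self.excluded_nodes] = False
        return np.flatnonzero(mask)

    def edge_list(self) -> pd.DataFrame:
        i, j = np.nonzero(np.triu(self.weights, k=1))
        return pd.DataFrame({"node_i": i, "node_j": j,
                             "weight": self.weights[i, j]})


def cube_similarity_network(volume: np.ndarray, parc: CubeParcellation,
                            condition: str = "", source=None) -> SimilarityNetwork:
    """Network of positive pairwise Pearson correlations between cube patterns."""
    vol = np.asarray(volume, dtype=float)
    if vol.shape != parc.grid_shape:
        raise ValueError("volume does not match the parcellation grid")
    patterns = vol.ravel()[parc.voxel_ids]  # (n_cubes, 27)
    sd = patterns.std(axis=1)
    excluded = np.flatnonzero(sd == 0)
    active = np.flatnonzero(sd > 0)
    if active.size == 0:
        raise ValueError("all cubes have zero-variance patterns")
    if excluded.size:
        logger.info("cube_similarity_network: excluded %d zero-variance cube(s)",
                    excluded.size)
    n = parc.n_cubes
    weights = np.zeros((n, n))
    r = np.corrcoef(patterns[active])
    r = np.atleast_2d(r)
    np.fill_diagonal(r, 0.0)
    r[r <= 0] = 0.0
    weights[np.ix_(active, active)] = r
    return SimilarityNetwork(weights=weights, excluded_nodes=excluded,
                             condition=condition, source=source)


def average_condition_network(networks: list[SimilarityNetwork],
                              condition: str) -> SimilarityNetwork:
    """Element-wise mean network; absent edges average as 0.

    A node excluded in any constituent network is excluded from the mean
    network (union-of-exclusions rule).
    """
    if not networks:
        raise ValueError("need at least one network to average")
    n = networks[0].n_nodes
    if any(net.n_nodes != n for net in networks):
        raise ValueError("networks have differing node counts")
    excluded = np.unique(np.concatenate([net.excluded_nodes for net in networks]
                                        + [np.array([], dtype=int)]))
    mean_w = np.mean([net.weights for net in networks], axis=0)
    mean_w[excluded, :] = 0.0
    mean_w[:, excluded] = 0.0
    return SimilarityNetwork(weights=mean_w, excluded_nodes=excluded.astype(int),
                             condition=condition,
                             source=[net.source for net in networks])


@dataclass
class BetaImageSet:
    """Per-trial beta volumes and per-condition mean beta volumes."""

    trial_betas: np.ndarray           # (n_trials, x, y, z)
    conditions: list                  # per-trial condition label
    condition_means: dict             # condition -> 3D mean beta volume
    design: pd.DataFrame = field(default=None, repr=False)


def glm_beta_series(run: BoldRun, events: pd.DataFrame,
                    drift_cutoff_s: float = 128.0,
                    oversampling: int = 16) -> BetaImageSet:
    """Beta-series GLM: one HRF-convolved boxcar regressor per trial.

    ``events`` needs columns onset_s, duration_s, condition, with onsets
    referring to the start of the original (pre-discard) run. The design is
    [trial regressors | discrete-cosine drift | intercept]; betas are
    ordinary least squares, and condition means average the trials of each
    condition.
    """
    for col in ("onset_s", "duration_s", "condition"):
        if col not in events.columns:
            raise ValueError(f"events table lacks column {col}")
    ev = events.sort_values("onset_s").reset_index(drop=True)
    ends = ev["onset_s"].to_numpy() + ev["duration_s"].to_numpy()
    if np.any(ev["onset_s"].to_numpy()[1:] < ends[:-1]):
        raise ValueError("overlapping trials are not supported")
    n_trials = len(ev)
    frame_times = (run.n_discarded + np.arange(run.n_volumes)) * run.tr_s
    X_trials = np.column_stack([
        event_regressor(frame_times, ev.loc[i, "onset_s"], ev.loc[i, "duration_s"],
                        oversampling=oversampling, tr_s=run.tr_s)
        for i in range(n_trials)])
    drift = dct_drift_basis(run.n_volumes, run.tr_s, drift_cutoff_s)
    X = np.hstack([X_trials, drift, np.ones((run.n_volumes, 1))])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient GLM design (check trial spacing/drift basis)")
    y = run.data.reshape(-1, run.n_volumes).T
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    trial_betas = beta[:n_trials].reshape(n_trials, *run.shape3d)
    conditions = list(ev["condition"])
    cond_means = {c: trial_betas[[i for i, ci in enumerate(conditions) if ci == c]]
                  .mean(axis=0) for c in dict.fromkeys(conditions)}
    return BetaImageSet(trial_betas=trial_betas, conditions=conditions,
                        condition_means=cond_means, design=ev)


def task_condition_network(betas: BetaImageSet, parc: CubeParcellation,
                           creative_label: str = "creative",
                           control_label: str = "control"
                           ) -> tuple[SimilarityNetwork, SimilarityNetwork]:
    """Cube-similarity networks of the creative and control mean beta maps.

    Exclusion bookkeeping is mirrored: a cube with a zero-variance pattern
    in either condition's beta map is excluded from both networks.
    """
    nets = {}
    for label in (creative_label, control_label):
        if label not in betas.condition_means:
            raise ValueError(f"no condition '{label}' in beta set")
        nets[label] = cube_similarity_network(betas.condition_means[label], parc,
                                              condition=label, source="beta")
    excl = np.unique(np.concatenate([nets[creative_label].excluded_nodes,
                                     nets[control_label].excluded_nodes]))
    for net in nets.values():
        net.weights[excl, :] = 0.0
        net.weights[:, excl] = 0.0
        net.excluded_nodes = excl.astype(int)
    return nets[creative_label], nets[control_label]
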