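"""Critical time point analysis (CTPA).

Sampled resting volumes are ranked by how many ROI voxels exceed Z = 2.
A point becomes a critical time point (CTP) when its suprathreshold count
exceeds 2.5% of the ROI (the Gaussian exceedance level is ~2.28%, so counts
above 2.5% are unlikely under noise alone) and, beyond the top two ranks,
when more than 30% of its suprathreshold voxels recur in the suprathreshold
sets of higher-ranked CTPs. Everything else is a remaining time point (RTP).
Downstream, volumes at CTPs and RTPs are contrasted voxelwise and combined
across subjects into an FDR- and cluster-extent-thresholded group map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .base import BoldRun, MaskVolume

logger = logging.getLogger(__name__)


class SubjectExcludedError(ValueError):
    """Raised when a subject cannot enter the group analysis."""


def select_sampled_timepoints(n_retained: int, stride: int = 5) -> np.ndarray:
    """1-based retained-volume indices sampled every ``stride`` TRs.

    With 170 retained volumes and stride 5 this yields the 34 points
    1, 6, 11, ..., 166.
    """
    if n_retained < 1 or stride < 1:
        raise ValueError("n_retained and stride must be >= 1")
    return np.arange(1, n_retained + 1, stride)


@dataclass
class ZScoreSeries:
    """Standardised ROI voxel values at the sampled time points.

    ``z`` has one row per retained ROI voxel and one column per sampled
    point. ``voxel_ids`` are flat indices into the 3D grid (C order) so that
    suprathreshold sets can be mapped back to space.
    """

    z: np.ndarray
    sampled_indices: np.ndarray  # 1-based retained-volume indices
    roi_n_voxels: int
    voxel_ids: np.ndarray
    n_excluded_voxels: int = 0


def zscore_roi(run: BoldRun, roi: MaskVolume, sampled_indices: np.ndarray,
               mode: str = "temporal") -> ZScoreSeries:
    """Standardise ROI voxel time courses and sample them.

    mode="temporal" (default): each voxel's full retained time course is
    standardised to mean 0, SD 1 (ddof=1) and then read off at the sampled
    indices — the Z > 2 exceedance rate of a Gaussian voxel is then 1-Phi(2).
    mode="spatial": each sampled volume is standardised across ROI voxels.
    Zero-variance voxels are excluded with a logged count.
    """
    sampled_indices = np.asarray(sampled_indices, dtype=int)
    if sampled_indices.min() < 1 or sampled_indices.max() > run.n_volumes:
        raise ValueError("sampled indices out of range for this run")
    if roi.data.shape != run.shape3d:
        raise ValueError("ROI mask does not match the run grid")
    flat_ids = np.flatnonzero(roi.data.ravel())
    ts = run.data.reshape(-1, run.n_volumes)[flat_ids]  # (V, T)
    sd = ts.std(axis=1, ddof=1) if ts.shape[1] > 1 else np.zeros(len(flat_ids))
    keep = sd > 0
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("zscore_roi: excluded %d zero-variance ROI voxel(s)", n_excluded)
    ts, flat_ids, sd = ts[keep], flat_ids[keep], sd[keep]
    if ts.shape[0] == 0:
        raise ValueError("all ROI voxels have zero variance")
    cols = sampled_indices - 1
    if mode == "temporal":
        z_full = (ts - ts.mean(axis=1, keepdims=True)) / sd[:, None]
        z = z_full[:, cols]
    elif mode == "spatial":
        sub = ts[:, cols]
        z = (sub - sub.mean(axis=0, keepdims=True)) / sub.std(axis=0, ddof=1,
                                                              keepdims=True)
    else:
        raise ValueError("mode must be 'temporal' or 'spatial'")
    return ZScoreSeries(z=z, sampled_indices=sampled_indices,
                        roi_n_voxels=int(keep.sum()), voxel_ids=flat_ids,
                        n_excluded_voxels=n_excluded)


@dataclass
class TimePointClassification:
    """CTP/RTP partition of the sampled points with per-point voxel sets."""

    ctp_indices: np.ndarray
    rtp_indices: np.ndarray
    sampled_indices: np.ndarray
    counts: np.ndarray                    # per sampled point, |{Z > z_threshold}|
    supra_sets: list = field(repr=False)  # per sampled point, frozenset of voxel rows
    roi_n_voxels: int = 0
    frac_threshold: float = 0.025
    overlap_threshold: float = 0.30
    z_threshold: float = 2.0
    top2_failed: bool = False

    @property
    def n_ctp(self) -> int:
        return len(self.ctp_indices)


def classify_timepoints(z: ZScoreSeries, frac_threshold: float = 0.025,
                        overlap_threshold: float = 0.30,
                        z_threshold: float = 2.0) -> TimePointClassification:
    """Partition the sampled points into CTPs and RTPs.

    Points are ranked by suprathreshold count (descending; ties broken by
    earlier acquisition time). If the top two counts both exceed
    ``frac_threshold * roi_n_voxels`` they are accepted as CTPs; each later
    point in rank order is accepted iff its count exceeds the same bound and
    strictly more than ``overlap_threshold`` of its suprathreshold voxels lie
    in the union of the suprathreshold sets of already-accepted CTPs. All
    inequalities are strict. If the top-two condition fails, the subject has
    zero CTPs (flagged via ``top2_failed``).
    """
    if z.roi_n_voxels <= 0:
        raise ValueError("empty ROI")
    supra = z.z > z_threshold
    counts = supra.sum(axis=0)
    sets = [frozenset(np.flatnonzero(supra[:, j])) for j in range(supra.shape[1])]
    n_pts = len(z.sampled_indices)
    count_bound = frac_threshold * z.roi_n_voxels
    order = sorted(range(n_pts), key=lambda j: (-counts[j], z.sampled_indices[j]))

    accepted: list[int] = []
    top2_failed = False
    if n_pts >= 2 and counts[order[0]] > count_bound and counts[order[1]] > count_bound:
        accepted = [order[0], order[1]]
        union = set(sets[order[0]] | sets[order[1]])
        for j in order[2:]:
            if counts[j] <= count_bound:
                continue
            s = sets[j]
            if len(s) and len(s & union) / len(s) > overlap_threshold:
                accepted.append(j)
                union |= s
    else:
        top2_failed = True

    accepted_set = set(accepted)
    ctp = np.array(sorted(z.sampled_indices[j] for j in accepted), dtype=int)
    rtp = np.array(sorted(z.sampled_indices[j] for j in range(n_pts)
                          if j not in accepted_set), dtype=int)
    return TimePointClassification(
        ctp_indices=ctp, rtp_indices=rtp, sampled_indices=z.sampled_indices,
        counts=counts, supra_sets=sets, roi_n_voxels=z.roi_n_voxels,
        frac_threshold=frac_threshold, overlap_threshold=overlap_threshold,
        z_threshold=z_threshold, top2_failed=top2_failed)


@dataclass
class ContrastResult:
    """Per-subject CTP-vs-RTP voxelwise contrast (Welch t and mean difference)."""

    t_map: np.ndarray
    mean_diff_map: np.ndarray
    n_ctp: int
    n_rtp: int


def subject_contrast_map(run: BoldRun, cls: TimePointClassification) -> ContrastResult:
    """Whole-brain Welch two-sample t map of volumes at CTPs vs at RTPs."""
    if cls.n_ctp < 2 or len(cls.rtp_indices) < 2:
        raise SubjectExcludedError(
            f"need >= 2 CTPs and >= 2 RTPs, got {cls.n_ctp}/{len(cls.rtp_indices)}")
    a = run.data[..., cls.ctp_indices - 1]
    b = run.data[..., cls.rtp_indices - 1]
    m_a, m_b = a.mean(axis=3), b.mean(axis=3)
    v_a = a.var(axis=3, ddof=1) / a.shape[3]
    v_b = b.var(axis=3, ddof=1) / b.shape[3]
    denom = np.sqrt(v_a + v_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (m_a - m_b) / denom, 0.0)
    return ContrastResult(t_map=t, mean_diff_map=m_a - m_b,
                          n_ctp=a.shape[3], n_rtp=b.shape[3])


@dataclass
class GroupMap:
    """Group one-sample t map with FDR + cluster-extent thresholding."""

    stat_volume: np.ndarray
    q_threshold: float
    cluster_min_voxels: int
    surviving_clusters: list  # (voxel coordinate array, peak coordinate, peak t)
    cluster_label_map: np.ndarray
    n_subjects: int


def group_ctp_map(contrasts: list[np.ndarray], brain_mask: MaskVolume | None = None,
                  q: float = 0.05, cluster_min: int = 50,
                  connectivity: int = 26) -> GroupMap:
    """One-sample two-tailed t across subjects with BH-FDR and extent rule.

    Voxels surviving Benjamini-Hochberg FDR at ``q`` are grouped into
    connected components (26- or 6-neighbour); components with strictly more
    than ``cluster_min`` voxels survive.
    """
    if len(contrasts) < 2:
        raise ValueError("group map needs at least 2 subjects")
    stack = np.stack([np.asarray(c, dtype=float) for c in contrasts], axis=-1)
    mask = brain_mask.data if brain_mask is not None else np.ones(stack.shape[:3], bool)
    vals = stack[mask]  # (V, n_subj)
    n = vals.shape[1]
    m = vals.mean(axis=1)
    se = vals.std(axis=1, ddof=1) / np.sqrt(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, m / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p[se == 0] = 1.0
    sig = multipletests(p, alpha=q, method="fdr_bh")[0] if p.size else \
        np.zeros_like(p, dtype=bool)
    t_vol = np.zeros(stack.shape[:3])
    t_vol[mask] = t
    sig_vol = np.zeros(stack.shape[:3], dtype=bool)
    sig_vol[mask] = sig
    if connectivity == 26:
        structure = np.ones((3, 3, 3), dtype=bool)
    elif connectivity == 6:
        structure = ndimage.generate_binary_structure(3, 1)
    else:
        raise ValueError("connectivity must be 6 or 26")
    labels, n_comp = ndimage.label(sig_vol, structure=structure)
    clusters = []
    label_map = np.zeros_like(labels)
    next_id = 0
    for comp in range(1, n_comp + 1):
        coords = np.argwhere(labels == comp)
        if len(coords) > cluster_min:
            next_id += 1
            label_map[labels == comp] = next_id
            comp_t = t_vol[tuple(coords.T)]
            peak = coords[np.argmax(np.abs(comp_t))]
            clusters.append((coords, tuple(int(x) for x in peak),
                             float(comp_t[np.argmax(np.abs(comp_t))])))
    return GroupMap(stat_volume=t_vol, q_threshold=q, cluster_min_voxels=cluster_min,
                    surviving_clusters=clusters, cluster_label_map=label_map,
                    n_subjects=n)
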