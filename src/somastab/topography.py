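"""Univariate topography on the ordered segment strip.

Condition activity is projected onto the K segments of the strip (mean beta
over the voxels of each segment), summarized by its center of gravity

    COG = sum_k k * beta_k / sum_k beta_k,

and tracked over sessions as COG shifts (post-session COG minus the average
of the pre-session COGs; positive = medial). The module also provides
ROI-mean activity (e.g. lip activity inside the hand sub-strip), fractional
max thresholding of statistic maps, and winner-takes-all labeling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core import (
    DegenerateProfileError,
    RunPattern,
    SegmentError,
    SegmentMap,
    mean_betas,
)

logger = logging.getLogger("somastab.topography")


@dataclass
class ActivityProfile:
    """Per-segment mean activity for one condition/session."""

    values: np.ndarray  # (K,)
    condition: str = ""
    session: str = ""
    participant: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("profile values must be a 1-D per-segment vector")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("profile values must be finite")

    @property
    def n_segments(self) -> int:
        return len(self.values)


@dataclass
class CogShift:
    """Signed COG displacement of a post session against the pre baseline."""

    value: float  # segment units, positive = medial
    post_session: str
    pre_sessions: list[str]


def project_to_segments(
    run_or_session_betas: RunPattern | Sequence[RunPattern] | np.ndarray,
    condition: str,
    segmap: SegmentMap,
) -> ActivityProfile:
    """Mean activity per segment for one condition.

    Accepts a single run, a list of runs (averaged voxelwise first), or a
    plain per-voxel vector already extracted for the condition.
    """
    session = ""
    participant = ""
    if isinstance(run_or_session_betas, RunPattern):
        vec = run_or_session_betas.beta_for(condition)
        session = run_or_session_betas.session
        participant = run_or_session_betas.participant
    elif isinstance(run_or_session_betas, np.ndarray):
        vec = np.asarray(run_or_session_betas, dtype=float)
    else:
        runs = list(run_or_session_betas)
        betas = mean_betas(runs)
        vec = betas[:, runs[0].conditions.index(condition)]
        session = runs[0].session
        participant = runs[0].participant
    if vec.shape[0] != segmap.n_voxels:
        raise SegmentError("beta vector does not cover the segment map's voxels")

    k = segmap.n_segments
    counts = np.bincount(segmap.segments, minlength=k + 1)[1:]
    empty = np.nonzero(counts == 0)[0]
    if empty.size:
        raise SegmentError(f"segment {int(empty[0]) + 1} has no voxels")
    sums = np.bincount(segmap.segments, weights=vec, minlength=k + 1)[1:]
    return ActivityProfile(values=sums / counts, condition=condition,
                           session=session, participant=participant)


def compute_cog(profile: ActivityProfile | np.ndarray) -> float:
    """Activity-weighted mean segment index of a profile.

    Computed on the raw per-segment means (negative values retained). When
    the summed activity is numerically indistinguishable from zero the COG
    is undefined and a DegenerateProfileError is raised instead of returning
    an arbitrary number.
    """
    values = profile.values if isinstance(profile, ActivityProfile) else np.asarray(
        profile, dtype=float
    )
    k = len(values)
    total = values.sum()
    eps = 1e-9 * k * (np.abs(values).max() if k else 0.0)
    if np.abs(total) <= eps:
        raise DegenerateProfileError(
            "summed profile activity is too close to zero for a COG"
        )
    weights = np.arange(1, k + 1, dtype=float)
    return float((weights * values).sum() / total)


def cog_shift(
    pre_profiles: Sequence[ActivityProfile | np.ndarray],
    post_profile: ActivityProfile | np.ndarray,
) -> CogShift:
    """COG(post) minus the average of the pre-session COGs.

    The average is taken over the pre-session COGs themselves, not over a
    pooled profile; the two differ for asymmetric profiles.
    """
    if not len(pre_profiles):
        raise ValueError("at least one pre-session profile is required")
    pre_cogs = [compute_cog(p) for p in pre_profiles]
    post_cog = compute_cog(post_profile)
    post_label = (
        post_profile.session if isinstance(post_profile, ActivityProfile) else ""
    )
    pre_labels = [
        p.session if isinstance(p, ActivityProfile) else "" for p in pre_profiles
    ]
    return CogShift(
        value=post_cog - float(np.mean(pre_cogs)),
        post_session=post_label,
        pre_sessions=pre_labels,
    )


def roi_mean_activity(
    session_runs: Sequence[RunPattern],
    condition: str,
    roi_voxels: np.ndarray,
) -> float:
    """Session estimate of mean (non-thresholded) ROI activity.

    The ROI mean is taken per run first, then averaged across the session's
    runs. ``roi_voxels`` is a boolean mask or an index array over voxels.
    """
    roi = np.asarray(roi_voxels)
    if roi.dtype == bool:
        if not roi.any():
            raise ValueError("ROI mask selects no voxels")
    elif roi.size == 0:
        raise ValueError("ROI voxel list is empty")
    if not session_runs:
        raise ValueError("no runs supplied")
    per_run = [float(r.beta_for(condition)[roi].mean()) for r in session_runs]
    return float(np.mean(per_run))


def threshold_map(statistic_map: np.ndarray, fraction: float = 0.33) -> np.ndarray:
    """Binary mask of values at or above ``fraction`` of the map maximum."""
    values = np.asarray(statistic_map, dtype=float)
    peak = values.max()
    if peak <= 0:
        warnings.warn(
            "statistic map has no positive maximum; returning an empty mask",
            stacklevel=2,
        )
        return np.zeros_like(values, dtype=bool)
    return values >= fraction * peak


def winner_takes_all(
    condition_maps: Mapping[str, np.ndarray],
    included_conditions: Sequence[str],
) -> tuple[np.ndarray, list[dict]]:
    """Per-voxel argmax labeling over the included conditions.

    Returns the label array and a tie report; exact ties are resolved toward
    the condition listed first (lowest condition index) and logged.
    """
    included = list(included_conditions)
    if len(included) < 2:
        raise ValueError("winner-takes-all needs at least two conditions")
    maps = [np.asarray(condition_maps[c], dtype=float) for c in included]
    n = maps[0].shape
    if any(m.shape != n for m in maps):
        raise ValueError("condition maps are not aligned on the same voxels")
    stack = np.stack(maps, axis=0)  # (C, V)
    winner_idx = stack.argmax(axis=0)  # ties -> first (lowest) index
    peak = stack.max(axis=0)
    tie_mask = (stack == peak).sum(axis=0) > 1
    ties = []
    for v in np.nonzero(tie_mask)[0]:
        tied = [included[i] for i in range(len(included)) if stack[i, v] == peak[v]]
        ties.append({"voxel": int(v), "tied": tied, "assigned": tied[0]})
    if ties:
        logger.info("winner_takes_all: %d tie(s) resolved to lowest index", len(ties))
    labels = np.array([included[i] for i in winner_idx])
    return labels, ties


# --- optional volumetric ingestion --------------------------------------------


def load_volumetric(beta_path: str, atlas_path: str):
    """Flatten a NIfTI beta map plus an integer segment atlas to tabular form.

    Voxels with a positive atlas label become the strip's voxels (ordered by
    segment, then scan order); returns (beta_vector, SegmentMap).
    """
    import nibabel as nib  # optional dependency

    beta_img = np.asarray(nib.load(beta_path).get_fdata())
    atlas = np.asarray(nib.load(atlas_path).get_fdata()).astype(int)
    if beta_img.shape != atlas.shape:
        raise ValueError("beta map and segment atlas have different shapes")
    mask = atlas > 0
    segments = atlas[mask]
    order = np.argsort(segments, kind="stable")
    segmap = SegmentMap(
        voxel_ids=np.arange(mask.sum()),
        segments=segments[order],
        n_segments=int(segments.max()),
    )
    return beta_img[mask][order], segmap
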