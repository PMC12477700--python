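"""Shared containers, configuration defaults and cohort I/O.

The analysis operates on run-wise GLM estimates: for every participant,
session and run there is a voxels x conditions matrix of beta (contrast)
values together with the run's GLM residuals (timepoints x voxels), plus a
single assignment of voxels to the ordered segments of the S1 strip.
Everything downstream (topography, MVPA, single-case statistics) consumes
these three objects.

Axis convention: segment 1 is the most lateral end of the strip (toward the
lip representation), segment K the most medial (toward the foot
representation), so a positive shift in segment units means a medial shift.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("somastab")

# --- configuration constants -------------------------------------------------

#: number of segments in the ordered S1 strip
DEFAULT_K = 49

#: inclusive segment bounds of the hand sub-strip used as the hand ROI
HAND_STRIP = (20, 35)

#: decimal places used for all numeric text exports
EXPORT_DECIMALS = 6

#: fingers of the analyzed (affected / nondominant) hand, lateral -> medial
FINGERS = ["thumb", "index", "middle", "ring", "little"]

#: fingers of the other hand (weak ipsilateral representation on this strip)
OTHER_FINGERS = ["o_thumb", "o_index", "o_middle", "o_ring", "o_little"]

LIPS = "lips"
FEET = "feet"

#: the 12 movement conditions (rest is the implicit zero baseline)
DEFAULT_CONDITIONS = FINGERS + OTHER_FINGERS + [LIPS, FEET]

#: default session labels; "Pre*" labels form the pre-amputation baseline
DEFAULT_SESSIONS = ["Pre1", "Pre2", "Post3m", "Post6m"]


def pre_sessions(sessions: Sequence[str]) -> list[str]:
    return [s for s in sessions if s.startswith("Pre")]


def post_sessions(sessions: Sequence[str]) -> list[str]:
    return [s for s in sessions if not s.startswith("Pre")]


# --- errors ------------------------------------------------------------------


class ConfigurationError(ValueError):
    """Invalid model / noise / cohort configuration."""


class DegenerateProfileError(ValueError):
    """Raised when a profile's total activity is too close to zero for a COG."""


class SegmentError(ValueError):
    """Raised when a segment is empty or a segment map is inconsistent."""


# --- segment map -------------------------------------------------------------


@dataclass(frozen=True)
class SegmentMap:
    """Ordered assignment of voxels to segments 1..K along the S1 strip."""

    voxel_ids: np.ndarray  # (V,) int
    segments: np.ndarray  # (V,) int in 1..K
    n_segments: int = DEFAULT_K

    def __post_init__(self) -> None:
        vid = np.asarray(self.voxel_ids, dtype=int)
        seg = np.asarray(self.segments, dtype=int)
        object.__setattr__(self, "voxel_ids", vid)
        object.__setattr__(self, "segments", seg)
        if vid.shape != seg.shape or vid.ndim != 1:
            raise SegmentError("voxel_ids and segments must be 1-D and aligned")
        if len(np.unique(vid)) != len(vid):
            raise SegmentError("voxel ids must be unique")
        if self.n_segments < 2:
            raise SegmentError("a strip needs at least 2 segments")
        if seg.min() < 1 or seg.max() > self.n_segments:
            raise SegmentError(
                f"segment indices must lie in 1..{self.n_segments}"
            )

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_ids)

    def positions(self) -> np.ndarray:
        """Per-voxel position on the segment axis (the segment index)."""
        return self.segments.astype(float)

    def roi_mask(self, lo: int, hi: int) -> np.ndarray:
        """Boolean voxel mask for segments lo..hi inclusive."""
        return (self.segments >= lo) & (self.segments <= hi)

    def hand_roi_mask(self, strip: tuple[int, int] = HAND_STRIP) -> np.ndarray:
        return self.roi_mask(*strip)

    # -- I/O --
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"voxel_id": self.voxel_ids, "segment_index": self.segments}
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, n_segments: int | None = None) -> "SegmentMap":
        df = pd.read_csv(path, sep="\t")
        k = n_segments or int(df["segment_index"].max())
        return cls(
            voxel_ids=df["voxel_id"].to_numpy(),
            segments=df["segment_index"].to_numpy(),
            n_segments=k,
        )


# --- run pattern -------------------------------------------------------------


@dataclass
class RunPattern:
    """One run's voxels x conditions beta matrix plus its GLM residuals."""

    betas: np.ndarray  # (V, C)
    conditions: list[str]
    residuals: np.ndarray | None  # (T, V) or None when not generated/needed
    participant: str
    session: str
    run: int

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        if self.betas.ndim != 2 or self.betas.shape[1] != len(self.conditions):
            raise ConfigurationError(
                "betas must be voxels x conditions matching the condition list"
            )
        if self.residuals is not None:
            self.residuals = np.asarray(self.residuals, dtype=float)
            if self.residuals.shape[1] != self.betas.shape[0]:
                raise ConfigurationError(
                    "residuals must be timepoints x voxels, aligned with betas"
                )

    @property
    def n_voxels(self) -> int:
        return self.betas.shape[0]

    def beta_for(self, condition: str) -> np.ndarray:
        return self.betas[:, self.conditions.index(condition)]

    def pattern_matrix(self, conditions: Sequence[str]) -> np.ndarray:
        """Conditions x voxels matrix restricted to the given conditions."""
        idx = [self.conditions.index(c) for c in conditions]
        return self.betas[:, idx].T


def mean_betas(runs: Sequence[RunPattern]) -> np.ndarray:
    """Voxelwise average beta matrix over runs (all runs share conditions)."""
    if not runs:
        raise ValueError("no runs to average")
    ref = runs[0].conditions
    for r in runs[1:]:
        if r.conditions != ref:
            raise ConfigurationError("runs have mismatched condition lists")
    return np.mean([r.betas for r in runs], axis=0)


# --- cohort ------------------------------------------------------------------


@dataclass
class Cohort:
    """A collection of participants' run patterns plus shared metadata."""

    runs: dict[str, list[RunPattern]]  # participant -> runs
    segmap: SegmentMap
    groups: dict[str, str]  # participant -> "control" | "case"
    sessions: list[str]
    conditions: list[str]
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def participants(self) -> list[str]:
        return sorted(self.runs)

    @property
    def controls(self) -> list[str]:
        return [p for p in self.participants if self.groups.get(p) == "control"]

    @property
    def cases(self) -> list[str]:
        return [p for p in self.participants if self.groups.get(p) == "case"]

    def runs_for(self, participant: str, session: str | None = None) -> list[RunPattern]:
        rr = self.runs[participant]
        if session is not None:
            rr = [r for r in rr if r.session == session]
        return sorted(rr, key=lambda r: (self.sessions.index(r.session), r.run))

    # -- directory layout -----------------------------------------------------
    # sub-XX_ses-YY_run-ZZ_beta.tsv  : voxels x conditions, first column voxel_id
    # sub-XX_ses-YY_run-ZZ_resid.tsv : timepoints x voxels, header = voxel ids
    # segmap.tsv                     : voxel_id, segment_index
    # cohort.yaml                    : groups, sessions, conditions, seed

    def to_dir(self, path: str | Path, include_residuals: bool = True) -> Path:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        fmt = f"%.{EXPORT_DECIMALS}f"
        self.segmap.to_tsv(path / "segmap.tsv")
        for pid in self.participants:
            for rp in self.runs[pid]:
                stem = f"{pid}_ses-{rp.session}_run-{rp.run:02d}"
                beta = pd.DataFrame(rp.betas, columns=self.conditions)
                beta.insert(0, "voxel_id", self.segmap.voxel_ids)
                beta.to_csv(path / f"{stem}_beta.tsv", sep="\t", index=False,
                            float_format=fmt)
                if include_residuals and rp.residuals is not None:
                    resid = pd.DataFrame(
                        rp.residuals,
                        columns=[str(v) for v in self.segmap.voxel_ids],
                    )
                    resid.to_csv(path / f"{stem}_resid.tsv", sep="\t",
                                 index=False, float_format=fmt)
        manifest = {
            "groups": self.groups,
            "sessions": list(self.sessions),
            "conditions": list(self.conditions),
            "seed": self.seed,
            "n_segments": int(self.segmap.n_segments),
            "meta": self.meta,
        }
        with open(path / "cohort.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
        return path

    @classmethod
    def from_dir(cls, path: str | Path, load_residuals: bool = True) -> "Cohort":
        path = Path(path)
        with open(path / "cohort.yaml") as fh:
            manifest = yaml.safe_load(fh)
        segmap = SegmentMap.from_tsv(
            path / "segmap.tsv", n_segments=manifest["n_segments"]
        )
        conditions = list(manifest["conditions"])
        runs: dict[str, list[RunPattern]] = {p: [] for p in manifest["groups"]}
        for beta_path in sorted(path.glob("*_beta.tsv")):
            stem = beta_path.name[: -len("_beta.tsv")]
            pid, ses_part, run_part = stem.rsplit("_", 2)
            session = ses_part.removeprefix("ses-")
            run = int(run_part.removeprefix("run-"))
            beta = pd.read_csv(beta_path, sep="\t")
            betas = beta[conditions].to_numpy()
            resid = None
            resid_path = path / f"{stem}_resid.tsv"
            if load_residuals and resid_path.exists():
                resid = pd.read_csv(resid_path, sep="\t").to_numpy()
            runs.setdefault(pid, []).append(
                RunPattern(
                    betas=betas,
                    conditions=conditions,
                    residuals=resid,
                    participant=pid,
                    session=session,
                    run=run,
                )
            )
        return cls(
            runs=runs,
            segmap=segmap,
            groups=dict(manifest["groups"]),
            sessions=list(manifest["sessions"]),
            conditions=conditions,
            seed=manifest.get("seed"),
            meta=manifest.get("meta", {}),
        )
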