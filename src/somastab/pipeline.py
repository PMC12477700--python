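"""End-to-end orchestration of the longitudinal stability analysis.

Given a cohort (a directory of run-wise beta/residual tables plus a segment
map, or an in-memory object), the pipeline produces the study's result
tables: per-participant COG shifts for the hand, each finger and the lips;
lip activity change inside the hand sub-strip; cross-session split-half
correlations, pairwise decoding accuracies and crossnobis distances;
typicality scores; and a single-case (Crawford-Howell) comparison of every
case measure against the control cohort at the designated post session.
Change scores always use the average of the pre sessions as the baseline.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import casestats, mvpa, topography
from .core import (
    DEFAULT_K,
    FINGERS,
    HAND_STRIP,
    LIPS,
    Cohort,
    pre_sessions,
    post_sessions,
)

logger = logging.getLogger("somastab.pipeline")

ALL_ANALYSES = (
    "cog",
    "lip_activity",
    "correlation",
    "decoding",
    "crossnobis",
    "typicality",
)


@dataclass
class AnalysisConfig:
    """Everything needed to reproduce one full analysis run."""

    cohort: str | None = None  # cohort directory (None when passed in memory)
    hand_strip: tuple[int, int] = HAND_STRIP
    n_segments: int = DEFAULT_K
    pre_sessions: list[str] | None = None  # default: labels starting with "Pre"
    post_sessions: list[str] | None = None
    comparison_session: str | None = None  # default: last shared post session
    analyses: tuple[str, ...] = ALL_ANALYSES
    whiten: bool = True
    covariance_regularization: float | None = None
    average_train_runs: bool = False
    average_pre_profiles: bool = False  # COG of averaged pre profiles instead
    seed: int = 0
    out_dir: str | None = None
    log_level: str = "INFO"

    def validate(self, sessions: Sequence[str]) -> tuple[list[str], list[str]]:
        pre = self.pre_sessions or pre_sessions(sessions)
        post = self.post_sessions or post_sessions(sessions)
        if not pre or not post:
            raise ValueError("need non-empty pre and post session sets")
        if set(pre) & set(post):
            raise ValueError("pre and post session sets must be disjoint")
        return list(pre), list(post)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if isinstance(cfg.hand_strip, list):
            cfg.hand_strip = tuple(cfg.hand_strip)
        if isinstance(cfg.analyses, list):
            cfg.analyses = tuple(cfg.analyses)
        return cfg

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ResultBundle:
    """Tidy result tables plus a machine-readable run manifest."""

    tables: dict[str, pd.DataFrame]
    manifest: dict
    issues: list[dict] = field(default_factory=list)

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables.items():
            table.to_csv(out / f"{name}.tsv", sep="\t", index=False,
                         float_format="%.6f")
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True, default=str)
        return out


# --- per-participant measures ---------------------------------------------------


def _session_profile(cohort: Cohort, pid: str, session: str,
                     condition: str) -> topography.ActivityProfile:
    """Run-averaged segment profile; 'hand' averages the five finger betas."""
    runs = cohort.runs_for(pid, session)
    if condition == "hand":
        from .core import mean_betas

        betas = mean_betas(runs)
        idx = [cohort.conditions.index(f) for f in FINGERS]
        vec = betas[:, idx].mean(axis=1)
        prof = topography.project_to_segments(vec, condition, cohort.segmap)
        prof.session, prof.participant, prof.condition = session, pid, "hand"
        return prof
    return topography.project_to_segments(runs, condition, cohort.segmap)


def _cog_rows(cohort: Cohort, pid: str, pre: list[str], post: list[str],
              average_pre_profiles: bool) -> list[dict]:
    rows = []
    for condition in ["hand", *FINGERS, LIPS]:
        pre_profiles = [_session_profile(cohort, pid, s, condition) for s in pre]
        for session in post:
            post_profile = _session_profile(cohort, pid, session, condition)
            if average_pre_profiles:
                pooled = np.mean([p.values for p in pre_profiles], axis=0)
                shift_val = topography.compute_cog(post_profile) - topography.compute_cog(pooled)
                shift = topography.CogShift(shift_val, session, list(pre))
            else:
                shift = topography.cog_shift(pre_profiles, post_profile)
            rows.append(
                {
                    "participant": pid,
                    "group": cohort.groups[pid],
                    "condition": condition,
                    "post_session": session,
                    "cog_shift": shift.value,
                }
            )
    return rows


def _lip_rows(cohort: Cohort, pid: str, pre: list[str], post: list[str],
              roi_mask: np.ndarray) -> list[dict]:
    by_session = {
        s: topography.roi_mean_activity(cohort.runs_for(pid, s), LIPS, roi_mask)
        for s in pre + post
    }
    pre_avg = float(np.mean([by_session[s] for s in pre]))
    return [
        {
            "participant": pid,
            "group": cohort.groups[pid],
            "post_session": s,
            "lip_activity": by_session[s],
            "pre_average": pre_avg,
            "change": by_session[s] - pre_avg,
        }
        for s in post
    ]


def run_full_analysis(
    config: AnalysisConfig, cohort: Cohort | None = None
) -> ResultBundle:
    """Run the configured analyses over every participant of a cohort.

    Participants with missing sessions/runs are reported in the bundle's
    issue list and skipped; the analysis continues for complete participants.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), None))
    if cohort is None:
        if config.cohort is None:
            raise ValueError("no cohort directory or in-memory cohort given")
        cohort = Cohort.from_dir(config.cohort)
    pre, post = config.validate(cohort.sessions)
    comparison = config.comparison_session or post[-1]
    roi_mask = cohort.segmap.roi_mask(*config.hand_strip)
    issues: list[dict] = []

    def complete(pid: str) -> bool:
        for s in pre + post:
            if len(cohort.runs_for(pid, s)) < 2:
                issues.append(
                    {"participant": pid, "session": s,
                     "issue": "fewer than 2 runs; participant skipped"}
                )
                return False
        return True

    participants = [p for p in cohort.participants if complete(p)]
    tables: dict[str, pd.DataFrame] = {}
    ses_pairs = list(itertools.combinations(pre + post, 2))

    if "cog" in config.analyses:
        rows = [
            r
            for pid in participants
            for r in _cog_rows(cohort, pid, pre, post, config.average_pre_profiles)
        ]
        tables["cog_shifts"] = pd.DataFrame(rows)

    if "lip_activity" in config.analyses:
        rows = [
            r
            for pid in participants
            for r in _lip_rows(cohort, pid, pre, post, roi_mask)
        ]
        tables["lip_activity"] = pd.DataFrame(rows)

    if "correlation" in config.analyses:
        rows = []
        for pid in participants:
            for ses_a, ses_b in ses_pairs:
                for finger in FINGERS:
                    r = mvpa.intra_finger_correlation(
                        cohort, pid, finger, (ses_a, ses_b), roi_mask
                    )
                    rows.append(
                        {
                            "participant": pid,
                            "group": cohort.groups[pid],
                            "session_pair": f"{ses_a}-{ses_b}",
                            "finger": finger,
                            "pearson_r": r,
                        }
                    )
        tables["correlations"] = pd.DataFrame(rows)

    if "decoding" in config.analyses:
        rows = []
        for pid in participants:
            for ses_a, ses_b in ses_pairs:
                table = mvpa.pairwise_decoding(
                    cohort, pid, ses_a, ses_b, roi_mask=roi_mask,
                    whiten=config.whiten,
                    average_train_runs=config.average_train_runs,
                )
                for (fa, fb), acc in table.accuracies.items():
                    rows.append(
                        {
                            "participant": pid,
                            "group": cohort.groups[pid],
                            "session_pair": f"{ses_a}-{ses_b}",
                            "finger_pair": f"{fa}-{fb}",
                            "accuracy": acc,
                            "n_combinations": table.n_combinations,
                        }
                    )
        tables["decoding"] = pd.DataFrame(rows)

    distance_tables: dict[tuple[str, str, str], mvpa.DistanceTable] = {}
    if "crossnobis" in config.analyses or "typicality" in config.analyses:
        for pid in participants:
            for ses_a, ses_b in ses_pairs:
                distance_tables[(pid, ses_a, ses_b)] = mvpa.crossnobis_distances(
                    cohort, pid, (ses_a, ses_b), roi_mask=roi_mask,
                    regularization=config.covariance_regularization,
                )

    if "crossnobis" in config.analyses:
        rows = []
        for (pid, ses_a, ses_b), table in distance_tables.items():
            for (ca, cb), d2 in table.entries.items():
                rows.append(
                    {
                        "participant": pid,
                        "group": cohort.groups[pid],
                        "session_pair": f"{ses_a}-{ses_b}",
                        "condition_pair": f"{ca}-{cb}",
                        "d2": d2,
                        "n_folds": table.n_folds,
                    }
                )
        tables["distances"] = pd.DataFrame(rows)

    typicality_by_pid: dict[str, float] = {}
    if "typicality" in config.analyses:
        pairs = mvpa.finger_pairs()
        cross_pairs = [(a, b) for a in pre for b in post]
        vectors = {
            pid: np.mean(
                [distance_tables[(pid, a, b)].vector(pairs) for a, b in cross_pairs],
                axis=0,
            )
            for pid in participants
        }
        ctrl_ids = [p for p in participants if cohort.groups[p] == "control"]
        ctrl_matrix = np.vstack([vectors[p] for p in ctrl_ids])
        rows = []
        for pid in participants:
            exclude = ctrl_ids.index(pid) if pid in ctrl_ids else None
            rho = mvpa.typicality_score(vectors[pid], ctrl_matrix, exclude)
            typicality_by_pid[pid] = rho
            rows.append(
                {
                    "participant": pid,
                    "group": cohort.groups[pid],
                    "typicality_rho": rho,
                }
            )
        tables["typicality"] = pd.DataFrame(rows)

    tables["casestats"] = _case_statistics(
        cohort, tables, typicality_by_pid, comparison, pre
    )

    manifest = {
        "config": asdict(config),
        "config_digest": config.digest(),
        "seed": config.seed,
        "comparison_session": comparison,
        "pre_sessions": pre,
        "post_sessions": post,
        "participants": participants,
        "versions": _versions(),
    }
    bundle = ResultBundle(tables=tables, manifest=manifest, issues=issues)
    if config.out_dir:
        bundle.write(config.out_dir)
    return bundle


def _case_statistics(
    cohort: Cohort,
    tables: dict[str, pd.DataFrame],
    typicality_by_pid: dict[str, float],
    comparison: str,
    pre: list[str],
) -> pd.DataFrame:
    """Crawford-Howell comparison of every case measure against controls."""
    measures: list[tuple[str, dict[str, float]]] = []

    if "cog_shifts" in tables and len(tables["cog_shifts"]):
        df = tables["cog_shifts"]
        at = df[df.post_session == comparison]
        for condition, sub in at.groupby("condition"):
            values = dict(zip(sub.participant, sub.cog_shift))
            measures.append((f"cog_shift_{condition}", values))
    if "lip_activity" in tables and len(tables["lip_activity"]):
        df = tables["lip_activity"]
        at = df[df.post_session == comparison]
        measures.append(("lip_in_hand_change", dict(zip(at.participant, at.change))))
    if "decoding" in tables and len(tables["decoding"]):
        df = tables["decoding"]
        mask = df.session_pair.isin([f"{p}-{comparison}" for p in pre])
        agg = df[mask].groupby("participant").accuracy.mean()
        measures.append(("decoding_pre_to_post", agg.to_dict()))
    if "distances" in tables and len(tables["distances"]):
        df = tables["distances"]
        mask = df.session_pair.isin([f"{p}-{comparison}" for p in pre])
        agg = df[mask].groupby("participant").d2.mean()
        measures.append(("crossnobis_pre_to_post", agg.to_dict()))
    if typicality_by_pid:
        measures.append(("typicality", dict(typicality_by_pid)))

    controls = set(cohort.controls)
    rows = []
    for name, values in measures:
        ctrl_values = np.array([v for p, v in values.items() if p in controls])
        if len(ctrl_values) < 2:
            continue
        for pid in cohort.cases:
            if pid not in values:
                continue
            try:
                res = casestats.crawford_howell_test(values[pid], ctrl_values)
            except ValueError as exc:
                # e.g. all controls at ceiling -> zero variance, test undefined
                logger.warning("skipping %s for %s: %s", name, pid, exc)
                continue
            rows.append(
                {
                    "case": pid,
                    "measure": name,
                    "case_value": res.case_value,
                    "control_n": len(ctrl_values),
                    "t": res.t,
                    "df": res.df,
                    "p_uncorr": res.p_two_tailed,
                    "ci_lo": res.interval_95[0],
                    "ci_hi": res.interval_95[1],
                }
            )
    return pd.DataFrame(
        rows,
        columns=["case", "measure", "case_value", "control_n", "t", "df",
                 "p_uncorr", "ci_lo", "ci_hi"],
    )


def _versions() -> dict[str, str]:
    import scipy
    import sklearn

    from . import __version__

    return {
        "somastab": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
    }


# --- cohort validation -----------------------------------------------------------


@dataclass
class ValidationReport:
    issues: list[dict] = field(default_factory=list)

    def add(self, severity: str, message: str) -> None:
        self.issues.append({"severity": severity, "message": message})

    @property
    def fatal(self) -> list[dict]:
        return [i for i in self.issues if i["severity"] == "fatal"]

    @property
    def ok(self) -> bool:
        return not self.fatal


def validate_cohort(path: str | Path) -> ValidationReport:
    """Check a cohort directory's layout, shapes and label coverage.

    Returns a report of fixable (warning) versus fatal issues instead of
    raising; an empty issue list means the directory is pristine.
    """
    report = ValidationReport()
    path = Path(path)
    manifest_path = path / "cohort.yaml"
    if not manifest_path.exists():
        report.add("fatal", "cohort.yaml is missing")
        return report
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    for key in ("groups", "sessions", "conditions", "n_segments"):
        if key not in manifest:
            report.add("fatal", f"cohort.yaml lacks the {key!r} field")
    if report.fatal:
        return report

    segmap_path = path / "segmap.tsv"
    if not segmap_path.exists():
        report.add("fatal", "segmap.tsv is missing")
        return report
    segmap_df = pd.read_csv(segmap_path, sep="\t")
    known_voxels = set(segmap_df["voxel_id"])
    conditions = list(manifest["conditions"])

    beta_files = sorted(path.glob("*_beta.tsv"))
    if not beta_files:
        report.add("fatal", "no *_beta.tsv run files found")
    seen: dict[str, set[str]] = {}
    for beta_path in beta_files:
        df = pd.read_csv(beta_path, sep="\t", nrows=5)
        missing = [c for c in conditions if c not in df.columns]
        for c in missing:
            report.add(
                "fatal", f"{beta_path.name}: missing condition column {c!r}"
            )
        full = pd.read_csv(beta_path, sep="\t", usecols=["voxel_id"])
        uncovered = set(full["voxel_id"]) - known_voxels
        for v in sorted(uncovered):
            report.add(
                "fatal",
                f"{beta_path.name}: voxel {v} is missing from segmap.tsv",
            )
        stem = beta_path.name[: -len("_beta.tsv")]
        pid, ses_part, _ = stem.rsplit("_", 2)
        seen.setdefault(pid, set()).add(ses_part.removeprefix("ses-"))
        if not (path / f"{stem}_resid.tsv").exists():
            report.add("warning", f"{stem}: no residual file (MVPA unavailable)")

    for pid in manifest["groups"]:
        if pid not in seen:
            report.add("fatal", f"participant {pid}: no run files")
            continue
        for ses in manifest["sessions"]:
            if ses not in seen[pid]:
                report.add(
                    "warning", f"participant {pid}: session {ses} has no runs"
                )
    return report
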