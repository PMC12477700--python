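"""Multivoxel pattern analyses within the hand ROI.

All analyses work on run-wise condition patterns restricted to a voxel ROI
(by default the hand sub-strip). Patterns are spatially pre-whitened with
the inverse square root of a shrinkage estimate of the residual voxel
covariance, so that Euclidean geometry on the whitened patterns equals
Mahalanobis geometry under the estimated noise covariance.

Cross-session analyses share one fold scheme: each session's runs are split
into unordered two-run partitions, and every partition of one session is
paired with every partition of the other (6 x 6 = 36 folds for two four-run
sessions). On these folds the module computes split-half Pearson
correlations per finger, pairwise linear-SVM decoding (both train/test
directions, 72 cells per finger pair), cross-validated squared Mahalanobis
(crossnobis) distances, and the typicality of a participant's ten
finger-pair distances against the control average.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.svm import LinearSVC

from .core import (
    FINGERS,
    Cohort,
    ConfigurationError,
    RunPattern,
)

logger = logging.getLogger("somastab.mvpa")

#: classifier hyperparameters (fixed and logged for reproducibility)
SVM_PARAMS: dict = {"C": 1.0, "loss": "squared_hinge", "random_state": 0}


def finger_pairs(fingers: Sequence[str] = tuple(FINGERS)) -> list[tuple[str, str]]:
    """The ten unordered finger pairs of one hand."""
    return list(itertools.combinations(fingers, 2))


# --- noise normalization -------------------------------------------------------


def estimate_noise_covariance(
    residuals_by_run: Sequence[np.ndarray],
    regularization: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Shrinkage estimate of the voxel noise covariance and its inverse sqrt.

    Run-wise sample covariances (per-run demeaned residuals) are averaged
    across runs and shrunk toward their diagonal, ``(1 - lam) * S + lam *
    diag(S)``. When ``regularization`` is None the intensity is the analytic
    optimal-shrinkage estimate (Schafer-Strimmer, diagonal target) computed
    from the pooled demeaned residuals, clipped to [0.01, 1].

    Returns (Sigma_hat, Sigma_hat^(-1/2)); the inverse square root is taken
    by eigendecomposition of the symmetric positive-definite estimate.
    """
    if not residuals_by_run:
        raise ValueError("at least one residual matrix is required")
    centered = []
    for res in residuals_by_run:
        res = np.asarray(res, dtype=float)
        if not np.all(np.isfinite(res)):
            raise ValueError("residuals contain non-finite values")
        if res.shape[0] < 2:
            raise ValueError("residuals need at least 2 timepoints")
        centered.append(res - res.mean(axis=0, keepdims=True))
    covs = [x.T @ x / (x.shape[0] - 1) for x in centered]
    s = np.mean(covs, axis=0)

    if regularization is None:
        lam = _analytic_shrinkage(np.vstack(centered))
        lam = float(np.clip(lam, 0.01, 1.0))
    else:
        lam = float(regularization)
        if not 0.0 <= lam <= 1.0:
            raise ConfigurationError("regularization must lie in [0, 1]")
    sigma = (1.0 - lam) * s + lam * np.diag(np.diag(s))

    evals, evecs = np.linalg.eigh(sigma)
    if evals.min() <= 0:
        raise ConfigurationError(
            "covariance estimate is not positive-definite; increase shrinkage"
        )
    inv_sqrt = (evecs / np.sqrt(evals)) @ evecs.T
    logger.debug("noise covariance: V=%d, lambda=%.4f", sigma.shape[0], lam)
    return sigma, inv_sqrt


def _analytic_shrinkage(x: np.ndarray) -> float:
    """Optimal shrinkage intensity toward the diagonal target.

    lam* = sum_{i != j} Var_hat(s_ij) / sum_{i != j} s_ij^2 for the centered
    data matrix x (timepoints x voxels).
    """
    t = x.shape[0]
    s = x.T @ x / (t - 1)
    x2 = x**2
    # Var_hat(s_ij) = t / (t-1)^3 * sum_t (x_ti x_tj - mean)^2
    mean_w = x.T @ x / t
    sum_w2 = x2.T @ x2
    var_s = (t / (t - 1) ** 3) * (sum_w2 - t * mean_w**2)
    off = ~np.eye(s.shape[0], dtype=bool)
    denom = (s[off] ** 2).sum()
    if denom <= 0:
        return 1.0
    return float(var_s[off].sum() / denom)


@dataclass
class WhitenedPattern:
    """Conditions x voxels noise-normalized pattern for one run."""

    matrix: np.ndarray  # (C, V)
    conditions: list[str]
    source_run: tuple[str, int]  # (session, run)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("whitened pattern contains non-finite values")


def whiten_patterns(
    betas: np.ndarray, whitener: np.ndarray
) -> np.ndarray:
    """Apply the inverse-sqrt covariance: patterns (C x V) -> patterns @ W.

    Euclidean distance on the result equals Mahalanobis distance under the
    covariance the whitener was derived from.
    """
    betas = np.asarray(betas, dtype=float)
    whitener = np.asarray(whitener, dtype=float)
    if betas.shape[-1] != whitener.shape[0]:
        raise ValueError(
            f"voxel dimension mismatch: patterns have {betas.shape[-1]} voxels, "
            f"whitener is {whitener.shape[0]}x{whitener.shape[1]}"
        )
    return betas @ whitener


# --- fold scheme ---------------------------------------------------------------


@dataclass(frozen=True)
class FoldPair:
    """One cross-validation fold: a two-run partition per session."""

    partition_a: tuple[int, int]  # run ids within session 1
    partition_b: tuple[int, int]  # run ids within session 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "partition_a", tuple(sorted(self.partition_a)))
        object.__setattr__(self, "partition_b", tuple(sorted(self.partition_b)))


def enumerate_between_session_folds(
    runs_s1: Sequence[int], runs_s2: Sequence[int]
) -> list[FoldPair]:
    """All unordered two-run partitions of one session crossed with the other.

    Two four-run sessions give C(4,2) x C(4,2) = 36 folds; ordering is
    lexicographic in the run ids so the enumeration is deterministic.
    """
    if len(runs_s1) < 2 or len(runs_s2) < 2:
        raise ValueError("each session needs at least 2 runs to form partitions")
    parts1 = list(itertools.combinations(sorted(runs_s1), 2))
    parts2 = list(itertools.combinations(sorted(runs_s2), 2))
    return [FoldPair(a, b) for a in parts1 for b in parts2]


# --- pattern assembly ----------------------------------------------------------


def participant_whitener(
    cohort: Cohort,
    participant: str,
    roi_mask: np.ndarray,
    regularization: float | None = None,
) -> np.ndarray:
    """Whitener from all of a participant's run residuals inside the ROI."""
    residuals = []
    for run in cohort.runs_for(participant):
        if run.residuals is None:
            raise ValueError(
                f"{participant} {run.session} run {run.run}: no residuals; "
                "whitening requires residual matrices"
            )
        residuals.append(run.residuals[:, roi_mask])
    _, inv_sqrt = estimate_noise_covariance(residuals, regularization)
    return inv_sqrt


def run_patterns(
    cohort: Cohort,
    participant: str,
    session: str,
    conditions: Sequence[str],
    roi_mask: np.ndarray,
    whitener: np.ndarray | None = None,
) -> dict[int, np.ndarray]:
    """Per-run conditions x voxels matrices inside the ROI, optionally whitened."""
    out: dict[int, np.ndarray] = {}
    for run in cohort.runs_for(participant, session):
        mat = run.pattern_matrix(conditions)[:, roi_mask]
        if whitener is not None:
            mat = whiten_patterns(mat, whitener)
        out[run.run] = mat
    if not out:
        raise ValueError(f"{participant} has no runs for session {session!r}")
    return out


def _partition_mean(patterns: Mapping[int, np.ndarray],
                    partition: tuple[int, int]) -> np.ndarray:
    for r in partition:
        if r not in patterns:
            raise ValueError(f"run {r} missing from session patterns")
    return 0.5 * (patterns[partition[0]] + patterns[partition[1]])


# --- split-half Pearson correlations -------------------------------------------


def intra_finger_correlation(
    cohort: Cohort,
    participant: str,
    finger: str,
    session_pair: tuple[str, str],
    roi_mask: np.ndarray | None = None,
    whiten: bool = False,
) -> float:
    """Mean split-half Pearson correlation of one finger's pattern.

    For each of the cross-session folds, the two runs of each partition are
    averaged voxelwise and the two averaged patterns are correlated across
    voxels; the fold coefficients are averaged arithmetically. Zero-variance
    folds are skipped with a warning.
    """
    if roi_mask is None:
        roi_mask = cohort.segmap.hand_roi_mask()
    whitener = (
        participant_whitener(cohort, participant, roi_mask) if whiten else None
    )
    pats = {
        ses: run_patterns(cohort, participant, ses, [finger], roi_mask, whitener)
        for ses in session_pair
    }
    folds = enumerate_between_session_folds(
        list(pats[session_pair[0]]), list(pats[session_pair[1]])
    )
    rs = []
    for fold in folds:
        a = _partition_mean(pats[session_pair[0]], fold.partition_a)[0]
        b = _partition_mean(pats[session_pair[1]], fold.partition_b)[0]
        if a.std() == 0 or b.std() == 0:
            warnings.warn(
                f"zero-variance pattern in fold {fold}; skipping", stacklevel=2
            )
            continue
        rs.append(float(stats.pearsonr(a, b).statistic))
    if not rs:
        raise ValueError("all folds were skipped (zero-variance patterns)")
    return float(np.mean(rs))


def session_pairs(sessions: Sequence[str]) -> list[tuple[str, str]]:
    """All unique session comparisons (6 for a four-session design)."""
    return list(itertools.combinations(sessions, 2))


# --- pairwise decoding ----------------------------------------------------------


@dataclass
class DecodingTable:
    """Mean pairwise decoding accuracies for one session pair."""

    accuracies: dict[tuple[str, str], float]
    session_pair: tuple[str, str]
    n_combinations: int

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(list(self.accuracies.values())))


def _decode_pair(
    train_pats: Mapping[int, np.ndarray],
    test_pats: Mapping[int, np.ndarray],
    idx_y: int,
    idx_z: int,
    average_train_runs: bool = False,
) -> list[float]:
    """Accuracy cells for one train->test direction of one condition pair.

    The classifier is fit per training partition on the two runs' unaveraged
    patterns (2 samples per class; or the partition mean, 1 per class, when
    ``average_train_runs``) and evaluated on each test partition's four
    patterns; 6 x 6 = 36 cells for four-run sessions.
    """
    train_parts = list(itertools.combinations(sorted(train_pats), 2))
    test_parts = list(itertools.combinations(sorted(test_pats), 2))
    cells: list[float] = []
    y = np.array([0, 0, 1, 1])
    for tp in train_parts:
        if average_train_runs:
            mean = _partition_mean(train_pats, tp)
            x_train = np.vstack([mean[idx_y], mean[idx_z]])
            y_train = np.array([0, 1])
        else:
            x_train = np.vstack(
                [train_pats[r][idx_y] for r in tp]
                + [train_pats[r][idx_z] for r in tp]
            )
            y_train = y
        if np.allclose(x_train[y_train == 0], x_train[y_train == 1]):
            warnings.warn(
                "identical training patterns across classes; recording chance",
                stacklevel=2,
            )
            cells.extend([0.5] * len(test_parts))
            continue
        clf = LinearSVC(**SVM_PARAMS)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # liblinear convergence chatter
            clf.fit(x_train, y_train)
        for sp in test_parts:
            x_test = np.vstack(
                [test_pats[r][idx_y] for r in sp] + [test_pats[r][idx_z] for r in sp]
            )
            cells.append(float((clf.predict(x_test) == y).mean()))
    return cells


def pairwise_decoding(
    cohort: Cohort,
    participant: str,
    session_train: str,
    session_test: str,
    fingers: Sequence[str] = tuple(FINGERS),
    roi_mask: np.ndarray | None = None,
    whiten: bool = True,
    average_train_runs: bool = False,
    patterns: Mapping[str, Mapping[int, np.ndarray]] | None = None,
) -> DecodingTable:
    """Between-session pairwise finger decoding (both directions).

    For each finger pair a linear SVM is trained on every two-run partition
    of one session and tested on every two-run partition of the other, in
    both directions (72 accuracy cells per pair for four-run sessions);
    the table holds the per-pair mean accuracy. ``patterns`` can inject
    pre-computed (e.g. label-permuted) per-run pattern matrices keyed by
    session, bypassing extraction and whitening.
    """
    if roi_mask is None:
        roi_mask = cohort.segmap.hand_roi_mask()
    fingers = list(fingers)
    if patterns is None:
        whitener = (
            participant_whitener(cohort, participant, roi_mask) if whiten else None
        )
        patterns = {
            ses: run_patterns(cohort, participant, ses, fingers, roi_mask, whitener)
            for ses in (session_train, session_test)
        }
    pats_a = patterns[session_train]
    pats_b = patterns[session_test]

    accuracies: dict[tuple[str, str], float] = {}
    n_cells = 0
    for y_f, z_f in itertools.combinations(fingers, 2):
        iy, iz = fingers.index(y_f), fingers.index(z_f)
        cells = _decode_pair(pats_a, pats_b, iy, iz, average_train_runs)
        cells += _decode_pair(pats_b, pats_a, iy, iz, average_train_runs)
        accuracies[(y_f, z_f)] = float(np.mean(cells))
        n_cells = len(cells)
    return DecodingTable(
        accuracies=accuracies,
        session_pair=(session_train, session_test),
        n_combinations=n_cells,
    )


def permute_condition_labels(
    run: RunPattern, conditions: Sequence[str], rng: np.random.Generator
) -> RunPattern:
    """Return a copy of the run with the given condition columns permuted.

    Used to build label-permutation null cohorts: shuffling which finger each
    pattern is attributed to, independently within each run, destroys any
    consistent finger information while preserving the patterns themselves.
    """
    idx = [run.conditions.index(c) for c in conditions]
    perm = rng.permutation(len(idx))
    betas = run.betas.copy()
    betas[:, idx] = betas[:, [idx[p] for p in perm]]
    return RunPattern(
        betas=betas,
        conditions=list(run.conditions),
        residuals=run.residuals,
        participant=run.participant,
        session=run.session,
        run=run.run,
    )


def permutation_null_decoding(
    cohort: Cohort,
    participant: str,
    session_pair: tuple[str, str],
    n_permutations: int,
    rng: np.random.Generator,
    fingers: Sequence[str] = tuple(FINGERS),
    roi_mask: np.ndarray | None = None,
    whiten: bool = True,
) -> np.ndarray:
    """Mean pairwise decoding accuracy under label permutation, per permutation.

    Finger labels are permuted independently within each run before every
    decoder run, which destroys consistent finger information and calibrates
    the decoder's chance level (expected accuracy 0.5).
    """
    if roi_mask is None:
        roi_mask = cohort.segmap.hand_roi_mask()
    fingers = list(fingers)
    whitener = (
        participant_whitener(cohort, participant, roi_mask) if whiten else None
    )
    base = {
        ses: {
            run.run: run.pattern_matrix(fingers)[:, roi_mask]
            for run in cohort.runs_for(participant, ses)
        }
        for ses in session_pair
    }
    if whitener is not None:
        base = {
            ses: {r: whiten_patterns(m, whitener) for r, m in runs.items()}
            for ses, runs in base.items()
        }
    accuracies = np.empty(n_permutations)
    for i in range(n_permutations):
        permuted = {
            ses: {r: m[rng.permutation(len(fingers))] for r, m in runs.items()}
            for ses, runs in base.items()
        }
        table = pairwise_decoding(
            cohort, participant, session_pair[0], session_pair[1],
            fingers=fingers, roi_mask=roi_mask, patterns=permuted,
        )
        accuracies[i] = table.mean_accuracy
    return accuracies


# --- crossnobis distances --------------------------------------------------------


@dataclass
class DistanceTable:
    """Condition-pair crossnobis distances for one session pair."""

    entries: dict[tuple[str, str], float]  # mean d^2 over folds (signed)
    session_pair: tuple[str, str]
    n_folds: int

    def distance(self, a: str, b: str) -> float:
        if (a, b) in self.entries:
            return self.entries[(a, b)]
        return self.entries[(b, a)]

    def vector(self, pairs: Sequence[tuple[str, str]]) -> np.ndarray:
        return np.array([self.distance(*p) for p in pairs])

    @property
    def mean_distance(self) -> float:
        return float(np.mean(list(self.entries.values())))


def crossnobis_from_patterns(
    pats_a: Mapping[int, np.ndarray],
    pats_b: Mapping[int, np.ndarray],
    pair_indices: Sequence[tuple[int, int]],
) -> np.ndarray:
    """Mean crossnobis d^2 per condition pair, vectorized over all folds.

    d^2 = (x_y - x_z)_A . (x_y - x_z)_B for whitened partition-mean patterns;
    averaging over all partition-A x partition-B folds. The estimator is
    unbiased, so single-fold (and even mean) values may be negative.
    """
    parts_a = list(itertools.combinations(sorted(pats_a), 2))
    parts_b = list(itertools.combinations(sorted(pats_b), 2))
    means_a = np.stack([_partition_mean(pats_a, p) for p in parts_a])  # (Pa, C, V)
    means_b = np.stack([_partition_mean(pats_b, p) for p in parts_b])
    iy = np.array([p[0] for p in pair_indices])
    iz = np.array([p[1] for p in pair_indices])
    diff_a = means_a[:, iy, :] - means_a[:, iz, :]  # (Pa, P, V)
    diff_b = means_b[:, iy, :] - means_b[:, iz, :]  # (Pb, P, V)
    d2 = np.einsum("apv,bpv->abp", diff_a, diff_b)  # (Pa, Pb, P)
    return d2.reshape(-1, len(pair_indices)).mean(axis=0)


def crossnobis_distances(
    cohort: Cohort,
    participant: str,
    session_pair: tuple[str, str],
    conditions: Sequence[str] | None = None,
    pairs: Sequence[tuple[str, str]] | None = None,
    roi_mask: np.ndarray | None = None,
    regularization: float | None = None,
) -> DistanceTable:
    """Cross-session crossnobis distances for the given condition pairs.

    Patterns are whitened with the participant's residual-derived whitener,
    partitioned into two-run splits per session, and the fold-mean inner
    product of the partition pattern differences is returned per pair
    (symmetric in which session plays partition A).
    """
    if roi_mask is None:
        roi_mask = cohort.segmap.hand_roi_mask()
    if conditions is None:
        conditions = list(FINGERS)
    conditions = list(conditions)
    if pairs is None:
        pairs = list(itertools.combinations(conditions, 2))
    for a, b in pairs:
        if a not in conditions or b not in conditions:
            raise ValueError(f"pair ({a}, {b}) not covered by conditions")
    whitener = participant_whitener(cohort, participant, roi_mask, regularization)
    pats = {
        ses: run_patterns(cohort, participant, ses, conditions, roi_mask, whitener)
        for ses in session_pair
    }
    folds = enumerate_between_session_folds(
        list(pats[session_pair[0]]), list(pats[session_pair[1]])
    )
    pair_idx = [(conditions.index(a), conditions.index(b)) for a, b in pairs]
    d2 = crossnobis_from_patterns(
        pats[session_pair[0]], pats[session_pair[1]], pair_idx
    )
    return DistanceTable(
        entries={pair: float(v) for pair, v in zip(pairs, d2)},
        session_pair=tuple(session_pair),
        n_folds=len(folds),
    )


# --- typicality ------------------------------------------------------------------


def typicality_score(
    case_distances: np.ndarray,
    control_distance_vectors: np.ndarray,
    exclude_index: int | None = None,
) -> float:
    """Spearman rho between a distance vector and the control-average vector.

    ``control_distance_vectors`` is controls x pairs; when scoring a control
    participant, pass its row index as ``exclude_index`` so its own distances
    are left out of the reference mean.
    """
    case = np.asarray(case_distances, dtype=float)
    ctrl = np.asarray(control_distance_vectors, dtype=float)
    if ctrl.ndim != 2 or ctrl.shape[1] != case.shape[0]:
        raise ValueError("control vectors must be controls x pairs, aligned with case")
    if exclude_index is not None:
        ctrl = np.delete(ctrl, exclude_index, axis=0)
    reference = ctrl.mean(axis=0)
    if np.ptp(case) == 0 or np.ptp(reference) == 0:
        raise ValueError("constant distance vector: Spearman rho is undefined")
    return float(stats.spearmanr(case, reference).statistic)
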