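"""Synthetic cohort generator with known somatotopy and noise structure.

Every participant's run-wise beta matrix is built from a ground-truth
somatotopic model: each movement condition activates voxels through a
Gaussian tuning curve over the ordered segment axis (lips lateral of the
hand, feet medial, the five fingers ordered thumb -> little within the hand
strip). On top of the noiseless tuning surface the generator adds
multiplicative run- and session-level gain fluctuations and spatially
correlated voxel noise; each run also gets a matching residual matrix drawn
i.i.d. over timepoints from the same spatial covariance, which is what the
MVPA whitening stage estimates.

Case participants can receive injectable amputation effects from a chosen
onset session: a signed displacement of the lip tuning center (positive =
medial, toward the hand) and a scaling of the finger-specific pattern
component (1 = intact selectivity, 0 = all fingers collapse onto their mean
pattern). These are the ground truths against which the downstream COG,
decoding and crossnobis analyses are validated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .core import (
    DEFAULT_CONDITIONS,
    DEFAULT_K,
    DEFAULT_SESSIONS,
    FEET,
    FINGERS,
    HAND_STRIP,
    LIPS,
    OTHER_FINGERS,
    Cohort,
    ConfigurationError,
    RunPattern,
    SegmentMap,
)

logger = logging.getLogger("somastab.synthgen")


# --- ground-truth models -----------------------------------------------------


@dataclass
class SomatotopyModel:
    """Gaussian tuning of each condition over the segment axis."""

    segment_centers: dict[str, float]
    tuning_width: float  # sigma, in segment units
    amplitudes: dict[str, float]
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.tuning_width <= 0:
            raise ConfigurationError("tuning_width must be positive")
        if set(self.segment_centers) != set(self.amplitudes):
            raise ConfigurationError("centers and amplitudes must share conditions")
        self.validate_layout()

    def validate_layout(self) -> None:
        """Check the somatotopic ordering for the default condition labels.

        Finger centers must increase strictly thumb -> little (more medial),
        lips must lie lateral of every finger and feet medial of every finger.
        Custom condition sets that do not use the default labels are accepted
        as-is.
        """
        for hand in (FINGERS, OTHER_FINGERS):
            present = [c for c in hand if c in self.segment_centers]
            cc = [self.segment_centers[c] for c in present]
            if len(cc) > 1 and not np.all(np.diff(cc) > 0):
                raise ConfigurationError(
                    f"finger centers must increase strictly lateral->medial: {present}"
                )
        fingers = [
            self.segment_centers[c]
            for c in FINGERS + OTHER_FINGERS
            if c in self.segment_centers
        ]
        if fingers and LIPS in self.segment_centers:
            if self.segment_centers[LIPS] >= min(fingers):
                raise ConfigurationError("lip center must lie lateral of all fingers")
        if fingers and FEET in self.segment_centers:
            if self.segment_centers[FEET] <= max(fingers):
                raise ConfigurationError("foot center must lie medial of all fingers")

    @property
    def conditions(self) -> list[str]:
        return list(self.segment_centers)


def default_somatotopy() -> SomatotopyModel:
    """Canonical single-hemisphere layout over the 49-segment strip.

    The five contralateral fingers sit inside the hand sub-strip (segments
    20-35) with 2.5-segment spacing; the other hand's fingers share those
    centers with a weak (ipsilateral) amplitude; lips and feet flank the hand
    laterally and medially.
    """
    lo, hi = HAND_STRIP
    finger_centers = np.linspace(lo + 2.0, hi - 3.0, num=5)  # 22 .. 32
    centers: dict[str, float] = {}
    amps: dict[str, float] = {}
    for name, c in zip(FINGERS, finger_centers):
        centers[name] = float(c)
        amps[name] = 1.0
    for name, c in zip(OTHER_FINGERS, finger_centers):
        centers[name] = float(c)
        amps[name] = 0.2
    centers[LIPS], amps[LIPS] = 8.0, 1.2
    centers[FEET], amps[FEET] = 44.0, 1.0
    return SomatotopyModel(segment_centers=centers, tuning_width=2.0,
                           amplitudes=amps, baseline=0.0)


@dataclass
class NoiseModel:
    """Spatially correlated beta/residual noise plus gain fluctuations.

    The generating voxel covariance is an exponential-decay kernel over the
    voxel ordering along the strip: Sigma[i, j] = sd^2 * exp(-|i-j| / L).
    L = 0 degenerates to independent voxels. Residuals are drawn i.i.d. over
    timepoints from this covariance (the whitening stage only uses spatial
    covariance, so no temporal autocorrelation is generated). Run- and
    session-level variability enter as multiplicative gains (1 + N(0, sd))
    on the activation component, emulating scanner/arousal amplitude drift
    without displacing the topography.
    """

    voxel_noise_sd: float = 0.05
    spatial_corr_length: float = 2.0  # in voxel-index units
    n_residual_timepoints: int = 120
    run_effect_sd: float = 0.05
    session_effect_sd: float = 0.1

    def __post_init__(self) -> None:
        for name in ("voxel_noise_sd", "spatial_corr_length",
                     "n_residual_timepoints", "run_effect_sd",
                     "session_effect_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")

    def covariance(self, n_voxels: int) -> np.ndarray:
        """Generating spatial covariance Sigma_true for n ordered voxels."""
        idx = np.arange(n_voxels)
        dist = np.abs(idx[:, None] - idx[None, :]).astype(float)
        if self.spatial_corr_length > 0:
            corr = np.exp(-dist / self.spatial_corr_length)
        else:
            corr = np.eye(n_voxels)
        return self.voxel_noise_sd**2 * corr

    def cholesky(self, n_voxels: int) -> np.ndarray | None:
        """Lower Cholesky factor of Sigma_true; None for the zero-noise case."""
        if self.voxel_noise_sd == 0:
            return None
        key = (self.voxel_noise_sd, self.spatial_corr_length, n_voxels)
        cached = _CHOL_CACHE.get(key)
        if cached is not None:
            return cached
        sigma = self.covariance(n_voxels)
        try:
            chol = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise ConfigurationError(
                "implied voxel covariance is not positive-definite"
            ) from exc
        if len(_CHOL_CACHE) > 8:
            _CHOL_CACHE.clear()
        _CHOL_CACHE[key] = chol
        return chol


#: memo for the generating covariance factor (keyed by noise parameters)
_CHOL_CACHE: dict[tuple, np.ndarray] = {}


@dataclass
class CaseEffects:
    """Injectable post-amputation ground-truth effects."""

    onset_session: str
    lip_shift_segments: float = 0.0  # positive = medial (toward the hand)
    selectivity_scale: float = 1.0  # 1 = intact, 0 = fingers collapse

    def __post_init__(self) -> None:
        if not 0.0 <= self.selectivity_scale <= 1.0:
            raise ConfigurationError("selectivity_scale must lie in [0, 1]")


@dataclass
class CohortSpec:
    """Design of a synthetic cohort (the study conditions)."""

    n_controls: int = 16
    n_cases: int = 1
    sessions: Sequence[str] = tuple(DEFAULT_SESSIONS)
    runs_per_session: int = 4
    n_voxels: int = 10 * DEFAULT_K
    n_segments: int = DEFAULT_K
    conditions: Sequence[str] = tuple(DEFAULT_CONDITIONS)
    seed: int = 0
    center_jitter_sd: float = 1.0  # between-participant somatotopy jitter

    def __post_init__(self) -> None:
        if self.runs_per_session < 2:
            raise ConfigurationError("runs_per_session must be >= 2")
        if len(set(self.conditions)) != len(self.conditions):
            raise ConfigurationError("condition labels must be unique")
        if self.n_voxels < self.n_segments:
            raise ConfigurationError("need at least one voxel per segment")


def default_segment_map(n_voxels: int = 10 * DEFAULT_K,
                        n_segments: int = DEFAULT_K) -> SegmentMap:
    """Voxels spread as evenly as possible over segments 1..K, in order."""
    segments = 1 + (np.arange(n_voxels) * n_segments) // n_voxels
    return SegmentMap(
        voxel_ids=np.arange(n_voxels),
        segments=segments.astype(int),
        n_segments=n_segments,
    )


# --- pattern construction ----------------------------------------------------


def _gauss(pos: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((pos - center) / width) ** 2)


def activation_matrix(
    model: SomatotopyModel,
    segmap: SegmentMap,
    conditions: Sequence[str],
    effects: CaseEffects | None = None,
    effects_active: bool = False,
) -> np.ndarray:
    """Noiseless voxels x conditions activation (without the baseline offset).

    When the case effects are active, the lip tuning center is displaced by
    ``lip_shift_segments`` and each finger's activation is pulled toward the
    across-finger mean: finger_c -> mean + selectivity_scale * (finger_c - mean).
    """
    pos = segmap.positions()
    act = np.empty((segmap.n_voxels, len(conditions)))
    for j, cond in enumerate(conditions):
        center = model.segment_centers[cond]
        if effects_active and effects is not None and cond == LIPS:
            center = center + effects.lip_shift_segments
        act[:, j] = model.amplitudes[cond] * _gauss(pos, center, model.tuning_width)
    if effects_active and effects is not None and effects.selectivity_scale != 1.0:
        f_idx = [j for j, c in enumerate(conditions) if c in FINGERS]
        if f_idx:
            common = act[:, f_idx].mean(axis=1, keepdims=True)
            act[:, f_idx] = common + effects.selectivity_scale * (
                act[:, f_idx] - common
            )
    return act


def tuning_surface(model: SomatotopyModel, segmap: SegmentMap,
                   conditions: Sequence[str]) -> np.ndarray:
    """Noiseless beta surface: baseline + activation."""
    return model.baseline + activation_matrix(model, segmap, conditions)


def simulate_run_pattern(
    model: SomatotopyModel,
    noise: NoiseModel,
    segmap: SegmentMap,
    rng: np.random.Generator,
    conditions: Sequence[str] | None = None,
    participant: str = "sub-00",
    session: str = "Pre1",
    run: int = 1,
    session_gain: float = 1.0,
    effects: CaseEffects | None = None,
    effects_active: bool = False,
    include_residuals: bool = True,
) -> RunPattern:
    """One run's beta matrix plus residuals.

    betas = baseline + run_gain * session_gain * activation + correlated noise,
    with run_gain ~ 1 + N(0, run_effect_sd) and the noise drawn column-wise
    from Sigma_true. Residuals are n_residual_timepoints i.i.d. draws from
    Sigma_true (mean zero).
    """
    conditions = list(conditions or model.conditions)
    act = activation_matrix(model, segmap, conditions, effects, effects_active)
    run_gain = 1.0 + (rng.normal(0.0, noise.run_effect_sd)
                      if noise.run_effect_sd > 0 else 0.0)
    betas = model.baseline + run_gain * session_gain * act

    chol = noise.cholesky(segmap.n_voxels)
    if chol is not None:
        betas = betas + chol @ rng.standard_normal((segmap.n_voxels, len(conditions)))
    residuals = None
    if include_residuals:
        t = noise.n_residual_timepoints
        if chol is not None:
            residuals = rng.standard_normal((t, segmap.n_voxels)) @ chol.T
        else:
            residuals = np.zeros((t, segmap.n_voxels))
    return RunPattern(
        betas=betas,
        conditions=conditions,
        residuals=residuals,
        participant=participant,
        session=session,
        run=run,
    )


def simulate_participant(
    spec: CohortSpec,
    model: SomatotopyModel,
    noise: NoiseModel,
    effects: CaseEffects | None,
    seed: int | np.random.SeedSequence,
    segmap: SegmentMap | None = None,
    participant: str = "sub-00",
    include_residuals: bool = True,
) -> list[RunPattern]:
    """All of a participant's runs, session-ordered.

    Sessions share the participant's somatotopy up to gain fluctuations; for
    case participants, the injected effects switch on at ``onset_session``
    and persist for every later session.
    """
    if effects is not None and effects.onset_session not in spec.sessions:
        raise ConfigurationError(
            f"onset_session {effects.onset_session!r} not among {list(spec.sessions)}"
        )
    segmap = segmap or default_segment_map(spec.n_voxels, spec.n_segments)
    rng = np.random.default_rng(seed)
    onset_idx = (
        list(spec.sessions).index(effects.onset_session) if effects else None
    )
    runs: list[RunPattern] = []
    for s_idx, session in enumerate(spec.sessions):
        gain = 1.0 + (rng.normal(0.0, noise.session_effect_sd)
                      if noise.session_effect_sd > 0 else 0.0)
        active = onset_idx is not None and s_idx >= onset_idx
        for r in range(1, spec.runs_per_session + 1):
            runs.append(
                simulate_run_pattern(
                    model, noise, segmap, rng,
                    conditions=spec.conditions,
                    participant=participant,
                    session=session,
                    run=r,
                    session_gain=gain,
                    effects=effects,
                    effects_active=active,
                    include_residuals=include_residuals,
                )
            )
    return runs


def _jittered_model(model: SomatotopyModel, sd: float,
                    rng: np.random.Generator,
                    max_tries: int = 100) -> SomatotopyModel:
    """Per-participant Gaussian perturbation of tuning centers.

    Redraws until the somatotopic ordering invariants still hold, so the
    jitter creates between-subject COG variability without scrambling the
    map layout.
    """
    if sd == 0:
        return model
    conds = model.conditions
    for _ in range(max_tries):
        centers = {
            c: model.segment_centers[c] + rng.normal(0.0, sd) for c in conds
        }
        try:
            return replace(model, segment_centers=centers)
        except ConfigurationError:
            continue
    raise ConfigurationError(
        "could not draw a valid somatotopy jitter; lower center_jitter_sd"
    )


def simulate_cohort(
    spec: CohortSpec,
    model: SomatotopyModel | None = None,
    noise: NoiseModel | None = None,
    case_effects: CaseEffects | Mapping[str, CaseEffects] | None = None,
    include_residuals: bool = True,
) -> Cohort:
    """A full cohort: controls plus case participants, deterministic in seed.

    Every participant gets an independent Gaussian jitter of the tuning
    centers (between-subject variability); case participants additionally
    receive the injected effects from their onset session.
    """
    model = model or default_somatotopy()
    noise = noise or NoiseModel()
    segmap = default_segment_map(spec.n_voxels, spec.n_segments)
    ss = np.random.SeedSequence(spec.seed)
    n_total = spec.n_controls + spec.n_cases
    children = ss.spawn(n_total)

    ids = [f"sub-{i + 1:02d}" for i in range(spec.n_controls)] + [
        f"case-{i + 1:02d}" for i in range(spec.n_cases)
    ]
    groups = {pid: ("control" if pid.startswith("sub-") else "case") for pid in ids}

    if isinstance(case_effects, CaseEffects):
        case_effects = {pid: case_effects for pid in ids if groups[pid] == "case"}
    case_effects = case_effects or {}

    runs: dict[str, list[RunPattern]] = {}
    for pid, child in zip(ids, children):
        rng = np.random.default_rng(child)
        pmodel = _jittered_model(model, spec.center_jitter_sd, rng)
        effects = case_effects.get(pid) if groups[pid] == "case" else None
        runs[pid] = simulate_participant(
            spec, pmodel, noise, effects, child.spawn(1)[0],
            segmap=segmap, participant=pid,
            include_residuals=include_residuals,
        )
    return Cohort(
        runs=runs,
        segmap=segmap,
        groups=groups,
        sessions=list(spec.sessions),
        conditions=list(spec.conditions),
        seed=spec.seed,
        meta={"generator": "somastab.synthgen", "center_jitter_sd": spec.center_jitter_sd},
    )
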