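"""Synthetic tapping, perception, annotation and lesion cohorts.

Generates data with the statistical structure the analysis pipeline assumes,
so every stage can be exercised end to end without the study's raw data:

* stimulus sets of three isochronous metronome sequences (60 tones at IOIs of
  600, 450 and 750 ms) and six 30 s music clips with an 11 s guide metronome;
* tappers whose phases follow a von Mises law around a mean asynchrony, with
  optional misses, spurious taps, phase drift, or pure chance tapping;
* Beat Alignment Test responders parameterized directly by (d', c), inverting
  the signal-detection scoring model;
* multi-annotator beat annotations (true beats plus Gaussian timing jitter);
* 3D lesion cohorts of spherical lesions where damage to a planted critical
  region lowers the behavioral score.

Reproducibility: every simulated entity draws from its own RNG stream keyed by
(seed, participant id, trial index), so partial re-runs are bitwise stable.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .perception import ALIGNED, NOT_ALIGNED, BATPlan, BATSession
from .beat_extraction import BeatAnnotationSet
from .lesion_mapping import LesionCohort, roi_damage
from .tapping import TapTrial, local_ioi

__all__ = [
    "Stimulus",
    "StimulusSet",
    "TapperProfile",
    "LesionCohortSpec",
    "make_stimulus_set",
    "simulate_tapper",
    "simulate_bat_responder",
    "simulate_annotators",
    "simulate_lesion_cohort",
]

# study stimulus parameters
DEFAULT_IOIS_MS = (600.0, 450.0, 750.0)
N_TONES = 60
N_MUSIC = 6
MUSIC_DURATION_S = 30.0
GUIDE_END_S = 11.0
TEMPO_RANGE_BPM = (80.0, 140.0)

#: effectively deterministic phase above this concentration
_KAPPA_DETERMINISTIC = 1e7


@dataclass(frozen=True)
class Stimulus:
    id: str
    modality: str  # "isochronous" | "music"
    beat_times: np.ndarray
    guide_end: float
    duration: float
    n_repetitions: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "beat_times", np.asarray(self.beat_times, float))
        if np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat_times must be strictly increasing")


@dataclass
class StimulusSet:
    stimuli: list[Stimulus]

    def __iter__(self):
        return iter(self.stimuli)

    def __len__(self) -> int:
        return len(self.stimuli)

    def by_id(self, stim_id: str) -> Stimulus:
        for s in self.stimuli:
            if s.id == stim_id:
                return s
        raise KeyError(stim_id)


@dataclass
class TapperProfile:
    """Generative model of one tapper.

    mean_phase_deg: mean asynchrony (negative = anticipates the beat).
    concentration_kappa: von Mises concentration; larger = more consistent.
    miss_prob: probability a beat gets no tap.
    extra_tap_rate: spurious taps per second (Poisson).
    phase_drift_sd: degrees of random-walk drift added per beat.
    is_chance_tapper: draws phases uniformly, ignoring mean/kappa.
    """

    mean_phase_deg: float = 0.0
    concentration_kappa: float = 8.0
    miss_prob: float = 0.0
    extra_tap_rate: float = 0.0
    phase_drift_sd: float = 0.0
    is_chance_tapper: bool = False
    participant: str = "sim"

    def __post_init__(self) -> None:
        if self.concentration_kappa < 0:
            raise ValueError("kappa must be nonnegative")
        for p in (self.miss_prob,):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.extra_tap_rate < 0 or self.phase_drift_sd < 0:
            raise ValueError("rates must be nonnegative")
        if not -180.0 < self.mean_phase_deg <= 180.0:
            raise ValueError("mean phase must lie in (-180, 180]")


@dataclass
class LesionCohortSpec:
    """Configuration of a synthetic lesion cohort.

    Defaults emulate the study cohort: 33 patients with spherical lesions whose
    radii span volumes of roughly 2.1-435 cm3, a baseline behavioral score of
    63.7 (the control mean), and a planted critical region whose damage
    proportion lowers the score by ``effect_size`` per unit.
    """

    grid_shape: tuple = (32, 32, 32)
    voxel_size_mm: float = 5.0
    n_patients: int = 33
    lesion_radius_range_mm: tuple = (8.0, 47.0)
    critical_roi: np.ndarray | None = None
    effect_size: float = 40.0
    noise_sd: float = 10.0
    baseline: float = 63.7
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        lo, hi = self.lesion_radius_range_mm
        if not 0 < lo <= hi:
            raise ValueError("invalid lesion radius range")
        extent = min(self.grid_shape) * self.voxel_size_mm
        if 2 * lo > extent:
            raise ValueError(
                f"grid extent {extent} mm too small for minimum lesion radius {lo} mm"
            )
        if self.critical_roi is not None:
            roi = np.asarray(self.critical_roi)
            if roi.shape != tuple(self.grid_shape):
                raise ValueError("critical_roi must match grid_shape")


def _entity_rng(seed: int | None, participant: str, trial_index: int) -> np.random.Generator:
    """Independent RNG stream keyed by (seed, participant, trial)."""
    pid_key = zlib.crc32(participant.encode())
    return np.random.default_rng(
        np.random.SeedSequence(entropy=0 if seed is None else int(seed),
                               spawn_key=(pid_key, trial_index))
    )


def make_stimulus_set(
    iois_ms: Sequence[float] = DEFAULT_IOIS_MS,
    n_tones: int = N_TONES,
    music_tempi_bpm: Sequence[float] | None = None,
    n_music: int = N_MUSIC,
    music_duration_s: float = MUSIC_DURATION_S,
    guide_end_s: float = GUIDE_END_S,
    seed: int | None = None,
) -> StimulusSet:
    """Default stimulus inventory: 3 isochronous + 6 music stimuli.

    Isochronous grids have exactly ``n_tones`` beats at the configured IOI;
    music clips are surrogate isochronous-at-tempo grids truncated at the clip
    end (tempi drawn uniformly in 80-140 BPM when not supplied), with the
    guide metronome covering the first 11 s and two repetitions each.
    """
    if any(ioi <= 0 for ioi in iois_ms):
        raise ValueError("IOIs must be positive")
    if n_tones < 2:
        raise ValueError("need at least 2 tones")
    if guide_end_s >= music_duration_s:
        raise ValueError("guide must end before the clip does")
    stimuli: list[Stimulus] = []
    for ioi in iois_ms:
        ioi_s = ioi / 1000.0
        beats = np.arange(n_tones) * ioi_s
        stimuli.append(
            Stimulus(
                id=f"iso{int(round(ioi))}", modality="isochronous",
                beat_times=beats, guide_end=0.0,
                duration=float(beats[-1] + ioi_s), n_repetitions=1,
            )
        )
    if music_tempi_bpm is None:
        rng = np.random.default_rng(seed)
        music_tempi_bpm = rng.uniform(*TEMPO_RANGE_BPM, size=n_music)
    if len(music_tempi_bpm) != n_music:
        raise ValueError(f"need {n_music} music tempi")
    for i, bpm in enumerate(music_tempi_bpm, start=1):
        if bpm <= 0:
            raise ValueError("tempo must be positive")
        period = 60.0 / bpm
        beats = np.arange(0.0, music_duration_s, period)
        stimuli.append(
            Stimulus(
                id=f"music{i}", modality="music", beat_times=beats,
                guide_end=guide_end_s, duration=music_duration_s, n_repetitions=2,
            )
        )
    return StimulusSet(stimuli)


def _draw_phases(rng: np.random.Generator, profile: TapperProfile, n: int) -> np.ndarray:
    """Per-beat phases in degrees, including any random-walk drift."""
    if profile.is_chance_tapper:
        return rng.uniform(-180.0, 180.0, size=n)
    drift = (
        np.cumsum(rng.normal(0.0, profile.phase_drift_sd, size=n))
        if profile.phase_drift_sd > 0
        else np.zeros(n)
    )
    mu = np.deg2rad(profile.mean_phase_deg + drift)
    if profile.concentration_kappa >= _KAPPA_DETERMINISTIC or np.isinf(
        profile.concentration_kappa
    ):
        return np.rad2deg(mu)
    return np.rad2deg(rng.vonmises(mu, profile.concentration_kappa))


def simulate_tapper(
    profile: TapperProfile, stimuli: StimulusSet, seed: int | None = None
) -> list[TapTrial]:
    """Simulate one tapper over every stimulus repetition.

    Each realized tap sits at beat + (phase/360) * local IOI with phase drawn
    from a von Mises law (uniform for chance tappers); beats are skipped with
    ``miss_prob`` and spurious taps arrive as a Poisson process over the clip.
    """
    trials: list[TapTrial] = []
    trial_index = 0
    for stim in stimuli:
        ioi = local_ioi(stim.beat_times)
        for rep in range(1, stim.n_repetitions + 1):
            rng = _entity_rng(seed, profile.participant, trial_index)
            trial_index += 1
            phases = _draw_phases(rng, profile, stim.beat_times.size)
            taps = stim.beat_times + phases / 360.0 * ioi
            if profile.miss_prob > 0:
                taps = taps[rng.random(taps.size) >= profile.miss_prob]
            if profile.extra_tap_rate > 0:
                n_extra = rng.poisson(profile.extra_tap_rate * stim.duration)
                taps = np.concatenate([taps, rng.uniform(0, stim.duration, n_extra)])
            trials.append(
                TapTrial(
                    participant=profile.participant, stimulus=stim.id,
                    repetition=rep, tap_times=np.sort(taps),
                    beat_times=stim.beat_times, modality=stim.modality,
                    guide_end=stim.guide_end,
                )
            )
    return trials


def simulate_bat_responder(
    dprime: float,
    criterion: float,
    plan: BATPlan,
    seed: int | None = None,
    participant: str = "sim",
) -> BATSession:
    """BAT responder with a fixed sensitivity and bias.

    Responds "aligned" with probability Phi(d'/2 - c) on on-beat trials and
    Phi(-d'/2 - c) on off-beat (and filler) trials — the inverse of the
    equal-variance signal-detection scoring model.
    """
    rng = _entity_rng(seed, participant, 0)
    p_on = norm.cdf(dprime / 2.0 - criterion)
    p_off = norm.cdf(-dprime / 2.0 - criterion)
    responses: list[str] = []
    for trial in plan.trials:
        p = p_on if trial.condition == "on" else p_off
        responses.append(ALIGNED if rng.random() < p else NOT_ALIGNED)
    return BATSession(plan=plan, responses=responses)


def simulate_annotators(
    true_beats: Sequence[float],
    timing_sd_ms: float,
    n_annotators: int,
    seed: int | None = None,
    miss_prob: float = 0.0,
    clip_id: str = "clip",
) -> BeatAnnotationSet:
    """Annotator tap series = true beats + Gaussian timing jitter, with
    optional per-annotator missed beats."""
    if timing_sd_ms < 0:
        raise ValueError("timing sd must be nonnegative")
    beats = np.asarray(true_beats, float)
    series = []
    for a in range(n_annotators):
        rng = _entity_rng(seed, f"annotator{a}", 0)
        taps = beats + rng.normal(0.0, timing_sd_ms / 1000.0, size=beats.size)
        if miss_prob > 0:
            taps = taps[rng.random(taps.size) >= miss_prob]
        series.append(np.sort(np.clip(taps, 0.0, None)))
    return BeatAnnotationSet(clip_id=clip_id, annotator_series=series)


def default_critical_roi(
    grid_shape: tuple, voxel_size_mm: float, radius_mm: float = 15.0,
    center_frac: tuple = (0.35, 0.5, 0.55),
) -> np.ndarray:
    """Spherical 'critical region' planted off-center in the grid."""
    center = np.array(grid_shape) * np.array(center_frac)
    return _sphere_mask(grid_shape, center, radius_mm / voxel_size_mm)


def _sphere_mask(grid_shape: tuple, center_vox: np.ndarray, radius_vox: float) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in grid_shape)]
    dist2 = sum((g - c) ** 2 for g, c in zip(grids, center_vox))
    return dist2 <= radius_vox**2


def simulate_lesion_cohort(
    spec: LesionCohortSpec,
) -> tuple[LesionCohort, np.ndarray, np.ndarray]:
    """Spherical-lesion cohort with behavior coupled to critical-ROI damage.

    Behavioral score = baseline - effect_size * (proportion of the critical
    ROI lesioned) + Gaussian noise. Returns (cohort, scores, roi_damage
    proportions); total lesion volumes are available from the cohort.
    """
    roi = (
        np.asarray(spec.critical_roi, bool)
        if spec.critical_roi is not None
        else default_critical_roi(spec.grid_shape, spec.voxel_size_mm)
    )
    lo, hi = spec.lesion_radius_range_mm
    shape = tuple(spec.grid_shape)
    vs = spec.voxel_size_mm
    masks = np.zeros((spec.n_patients,) + shape, dtype=np.uint8)
    scores = np.zeros(spec.n_patients)
    damage = np.zeros(spec.n_patients)
    for i in range(spec.n_patients):
        rng = _entity_rng(spec.seed, f"patient{i}", 0)
        radius_vox = rng.uniform(lo, hi) / vs
        # centers concentrate in the middle of the grid, mimicking the shared
        # vascular territory of a stroke cohort (gives usable voxel coverage)
        center = rng.uniform(0.2 * np.array(shape, float), 0.8 * np.array(shape, float))
        mask = _sphere_mask(shape, center, radius_vox)
        if not mask.any():  # tiny lesion between grid points: place one voxel
            mask = np.zeros(shape, bool)
            mask[tuple(np.clip(center.astype(int), 0, np.array(shape) - 1))] = True
        masks[i] = mask
        damage[i] = roi_damage(mask, roi)
        scores[i] = (
            spec.baseline
            - spec.effect_size * damage[i]
            + rng.normal(0.0, spec.noise_sd)
        )
    # MNI-like affine: isotropic voxels, origin at the grid center
    affine = np.diag([vs, vs, vs, 1.0])
    affine[:3, 3] = -np.array(shape) / 2.0 * vs
    cohort = LesionCohort(masks=masks, affine=affine)
    return cohort, scores, damage
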