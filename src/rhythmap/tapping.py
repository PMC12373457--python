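"""Circular-statistics scoring of sensorimotor synchronization (tapping) trials.

Each tap is mapped to a phase angle relative to the stimulus beat grid
(0 deg = on the beat, negative = anticipation). A trial is summarized by the
mean resultant vector: length ``R`` in [0, 1] indexes synchronization
consistency, direction ``theta`` in (-180, 180] indexes accuracy, and
Rayleigh's test of circular uniformity asks whether tapping is above chance.
Per-participant performance is condensed into a composite score: the mean of
the rescaled vector lengths (0-180) and the sign-flipped absolute angles
across the nine stimuli (three isochronous metronomes, six music clips), so
that higher values always mean better tapping and the composite lives in
[-90, 90].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TapTrial",
    "CircularSummary",
    "CompositeScore",
    "trim_trial",
    "taps_to_phases",
    "circular_summary",
    "average_repetitions",
    "composite_score",
    "TappingScorer",
]

#: resultant lengths below this are treated as "no preferred direction"
THETA_UNDEFINED_TOL = 1e-12

#: angle component substituted when theta is undefined (chance tapper): worst case
UNDEFINED_ANGLE_COMPONENT = -180.0


@dataclass
class TapTrial:
    """Tap onsets and the beat grid for one trial of one participant."""

    participant: str
    stimulus: str
    repetition: int
    tap_times: np.ndarray
    beat_times: np.ndarray
    modality: str  # "isochronous" | "music"
    guide_end: float = 0.0
    trimmed: bool = False
    empty_after_trim: bool = False

    def __post_init__(self) -> None:
        self.tap_times = np.asarray(self.tap_times, dtype=float)
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        if self.modality not in ("isochronous", "music"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.beat_times.size >= 2 and not np.all(np.diff(self.beat_times) > 0):
            raise ValueError("beat_times must be strictly increasing")
        self.tap_times = np.sort(self.tap_times)


@dataclass
class CircularSummary:
    """Mean resultant vector of tap phases plus the Rayleigh uniformity p."""

    R: float
    theta_deg: float
    n_taps: int
    rayleigh_p: float
    theta_undefined: bool = False
    note: str = ""

    @property
    def missing(self) -> bool:
        return self.n_taps == 0


@dataclass
class CompositeScore:
    participant: str
    value: float
    length_components: dict = field(default_factory=dict)  # stimulus -> 180*R
    angle_components: dict = field(default_factory=dict)  # stimulus -> -|theta|


def trim_trial(trial: TapTrial) -> TapTrial:
    """Apply the pre-analysis trim: isochronous trials drop the first two taps,
    music trials keep only taps after the guide metronome ends."""
    if trial.modality == "isochronous":
        taps = trial.tap_times[2:]
    else:
        taps = trial.tap_times[trial.tap_times > trial.guide_end]
    return replace(
        trial,
        tap_times=taps,
        trimmed=True,
        empty_after_trim=taps.size == 0,
    )


def _wrap_deg(phase: np.ndarray) -> np.ndarray:
    """Wrap angles to (-180, 180]; exactly -180 maps to +180."""
    phase = np.asarray(phase, dtype=float)
    return phase - 360.0 * np.ceil((phase - 180.0) / 360.0)


def local_ioi(beat_times: np.ndarray) -> np.ndarray:
    """Inter-beat interval used to convert tap offsets to phase at each beat.

    Interval from each beat to its successor; the last beat reuses its
    predecessor's interval (music grids may have variable tempo).
    """
    beats = np.asarray(beat_times, dtype=float)
    if beats.size < 2:
        raise ValueError("need at least two beats to define an inter-beat interval")
    d = np.diff(beats)
    return np.append(d, d[-1])


def taps_to_phases(tap_times: np.ndarray, beat_times: np.ndarray) -> np.ndarray:
    """Map each tap to a phase in degrees relative to its nearest beat.

    phase = 360 * (tap - beat) / local IOI, wrapped to (-180, 180]. Exact
    midpoints between two beats are assigned to the earlier beat (phase +180).
    Taps before the first or after the last beat use the boundary interval;
    every tap contributes a phase.
    """
    taps = np.asarray(tap_times, dtype=float)
    beats = np.asarray(beat_times, dtype=float)
    if taps.size == 0:
        return np.empty(0, dtype=float)
    if beats.size < 2:
        raise ValueError("need at least one beat interval")
    ioi = local_ioi(beats)
    right = np.searchsorted(beats, taps)  # first beat index >= tap
    left = np.clip(right - 1, 0, beats.size - 1)
    right = np.clip(right, 0, beats.size - 1)
    d_left = np.abs(taps - beats[left])
    d_right = np.abs(beats[right] - taps)
    # ties (exact midpoint) go to the earlier beat -> phase +180 not -180
    idx = np.where(d_right < d_left, right, left)
    phase = 360.0 * (taps - beats[idx]) / ioi[idx]
    return _wrap_deg(phase)


def rayleigh_p(R: float, n: int) -> float:
    """Rayleigh test of circular uniformity, large-sample approximation.

    p = exp( sqrt(1 + 4n + 4(n^2 - S^2)) - (1 + 2n) ) with S = n*R, which is
    accurate even for small n.
    """
    if n < 2:
        return float("nan")
    S = n * R
    arg = 1.0 + 4.0 * n + 4.0 * (n * n - S * S)
    p = math.exp(math.sqrt(max(arg, 0.0)) - (1.0 + 2.0 * n))
    return min(max(p, 0.0), 1.0)


def circular_summary(phases_deg: Sequence[float]) -> CircularSummary:
    """Mean resultant vector (R, theta) and Rayleigh p of a set of phases.

    R is the modulus and theta the argument of the mean of the unit vectors at
    the phase angles. With no taps a missing summary (n_taps=0) is returned;
    theta is flagged undefined when R is numerically zero.
    """
    phases = np.asarray(phases_deg, dtype=float)
    n = phases.size
    if n == 0:
        return CircularSummary(
            R=float("nan"), theta_deg=float("nan"), n_taps=0,
            rayleigh_p=float("nan"), theta_undefined=True, note="no taps",
        )
    z = np.exp(1j * np.deg2rad(phases)).mean()
    R = float(abs(z))
    undefined = R < THETA_UNDEFINED_TOL
    theta = float("nan") if undefined else float(_wrap_deg(np.rad2deg(np.angle(z))))
    return CircularSummary(
        R=R, theta_deg=theta, n_taps=int(n),
        rayleigh_p=rayleigh_p(R, n), theta_undefined=undefined,
    )


def average_repetitions(
    s1: CircularSummary | None, s2: CircularSummary | None
) -> CircularSummary:
    """Average two repetitions of the same stimulus.

    R is averaged arithmetically; theta circularly (direction of the mean of
    the two unit vectors). If only one repetition is usable it is returned
    with a provenance note; the Rayleigh p of an average is not defined and is
    reported as NaN.
    """
    def usable(s: CircularSummary | None) -> bool:
        return s is not None and s.n_taps > 0

    if not usable(s1) and not usable(s2):
        return CircularSummary(
            R=float("nan"), theta_deg=float("nan"), n_taps=0,
            rayleigh_p=float("nan"), theta_undefined=True,
            note="both repetitions missing",
        )
    if not usable(s1) or not usable(s2):
        kept = s1 if usable(s1) else s2
        return replace(kept, note="single usable repetition")

    R = 0.5 * (s1.R + s2.R)
    units = [
        np.exp(1j * np.deg2rad(s.theta_deg))
        for s in (s1, s2)
        if not s.theta_undefined
    ]
    if units:
        mean_vec = np.mean(units)
        if abs(mean_vec) < THETA_UNDEFINED_TOL:
            theta, undefined = float("nan"), True
        else:
            theta = float(_wrap_deg(np.rad2deg(np.angle(mean_vec))))
            undefined = False
    else:
        theta, undefined = float("nan"), True
    return CircularSummary(
        R=R, theta_deg=theta, n_taps=s1.n_taps + s2.n_taps,
        rayleigh_p=float("nan"), theta_undefined=undefined,
        note="mean of 2 repetitions (scalar R, circular theta)",
    )


def composite_score(
    summaries: Mapping[str, CircularSummary], participant: str = ""
) -> CompositeScore:
    """Composite tapping score across the nine stimuli.

    Per stimulus the vector length is stretched to 0-180 (180*R) and the angle
    replaced by -|theta|; the score is the mean of the 18 resulting components
    (range [-90, 90], higher = better). A chance tapper's undefined angle is
    charged the worst case (-180) rather than dropped.
    """
    if len(summaries) != 9:
        raise ValueError(
            f"composite requires exactly 9 per-stimulus summaries, got {len(summaries)}"
        )
    lengths: dict[str, float] = {}
    angles: dict[str, float] = {}
    for stim, s in summaries.items():
        if s is None or s.missing:
            raise ValueError(f"stimulus {stim!r} has no usable summary")
        lengths[stim] = 180.0 * s.R
        angles[stim] = (
            UNDEFINED_ANGLE_COMPONENT if s.theta_undefined else -abs(s.theta_deg)
        )
    components = list(lengths.values()) + list(angles.values())
    return CompositeScore(
        participant=participant,
        value=float(np.mean(components)),
        length_components=lengths,
        angle_components=angles,
    )


class TappingScorer:
    """Estimator that turns tap trials into participant composite scores.

    Parameters
    ----------
    trim : bool
        Apply the pre-analysis trim (drop first two isochronous taps; keep
        only post-guide music taps). Default True.
    n_stimuli : int
        Number of unique stimuli expected per participant (default 9).

    Attributes (after :meth:`fit`)
    ------------------------------
    trial_summaries_ : pandas.DataFrame
        One row per trial: R, theta_deg, n_taps, rayleigh_p.
    stimulus_summaries_ : dict[(participant, stimulus) -> CircularSummary]
        Repetition-averaged summaries.
    composite_scores_ : pandas.DataFrame
        One row per participant with the composite value.
    """

    def __init__(self, trim: bool = True, n_stimuli: int = 9):
        self.trim = trim
        self.n_stimuli = n_stimuli

    def get_params(self, deep: bool = True) -> dict:
        return {"trim": self.trim, "n_stimuli": self.n_stimuli}

    def set_params(self, **params) -> "TappingScorer":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, trials: Iterable[TapTrial], y=None) -> "TappingScorer":
        trials = list(trials)
        if not trials:
            raise ValueError("no trials supplied")
        rows = []
        per_trial: dict[tuple, CircularSummary] = {}
        for tr in trials:
            t = trim_trial(tr) if self.trim else tr
            phases = taps_to_phases(t.tap_times, t.beat_times)
            s = circular_summary(phases)
            per_trial[(t.participant, t.stimulus, t.repetition)] = s
            rows.append(
                dict(
                    participant=t.participant, stimulus=t.stimulus,
                    repetition=t.repetition, R=s.R, theta_deg=s.theta_deg,
                    n_taps=s.n_taps, rayleigh_p=s.rayleigh_p,
                    theta_undefined=s.theta_undefined,
                )
            )
        self.trial_summaries_ = pd.DataFrame(rows)

        # collapse repetitions per (participant, stimulus)
        self.stimulus_summaries_ = {}
        for (pid, stim), grp in self.trial_summaries_.groupby(
            ["participant", "stimulus"], sort=True
        ):
            reps = sorted(grp["repetition"].tolist())
            summs = [per_trial[(pid, stim, r)] for r in reps]
            if len(summs) == 1:
                self.stimulus_summaries_[(pid, stim)] = summs[0]
            else:
                avg = summs[0]
                for s in summs[1:]:
                    avg = average_repetitions(avg, s)
                self.stimulus_summaries_[(pid, stim)] = avg

        comp_rows = []
        participants = sorted({k[0] for k in self.stimulus_summaries_})
        for pid in participants:
            summaries = {
                stim: s for (p, stim), s in self.stimulus_summaries_.items() if p == pid
            }
            if len(summaries) != self.n_stimuli:
                raise ValueError(
                    f"participant {pid!r}: expected {self.n_stimuli} stimuli, "
                    f"got {len(summaries)}"
                )
            cs = composite_score(summaries, participant=pid)
            comp_rows.append(dict(participant=pid, composite=cs.value))
        self.composite_scores_ = pd.DataFrame(comp_rows)
        return self

    def transform(self, trials: Iterable[TapTrial]) -> pd.DataFrame:
        """Fit on ``trials`` and return the participant composite table."""
        return self.fit(trials).composite_scores_
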