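"""Beat Alignment Test (BAT) trial plans and signal-detection scoring.

The BAT presents music clips with superimposed beeps that are either aligned
with the beat (on-beat) or phase-shifted off the beat; listeners judge the
alignment. Sessions contain 9 on-beat and 9 off-beat scored trials plus 3
unscored tempo-shifted fillers at fixed positions. Sensitivity is d-prime
(z(hit rate) - z(false-alarm rate)) with extreme rates of 1 and 0 corrected
to 0.99 and 0.01; response bias c and percent accuracy over the 18 scored
trials are also reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm

__all__ = [
    "BATTrial",
    "BATPlan",
    "BATSession",
    "SDTScores",
    "make_trial_plan",
    "validate_plan",
    "score_bat",
    "ALIGNED",
    "NOT_ALIGNED",
    "DEFAULT_FILLER_POSITIONS",
]

ALIGNED = "aligned"
NOT_ALIGNED = "not_aligned"

#: 1-indexed positions of the unscored fillers in the 21-trial sequence.
#: The original fixed positions are not published; these are the package default.
DEFAULT_FILLER_POSITIONS = (5, 12, 19)

N_ON = 9
N_OFF = 9
N_FILLER = 3


@dataclass(frozen=True)
class BATTrial:
    position: int  # 1-indexed position in the session
    clip_id: str
    condition: str  # "on" | "off" | "filler"


@dataclass
class BATPlan:
    trials: list[BATTrial]

    @property
    def scored_trials(self) -> list[BATTrial]:
        return [t for t in self.trials if t.condition in ("on", "off")]

    def counts(self) -> dict[str, int]:
        out = {"on": 0, "off": 0, "filler": 0}
        for t in self.trials:
            out[t.condition] += 1
        return out


@dataclass
class BATSession:
    plan: BATPlan
    responses: list[str | None]  # ALIGNED / NOT_ALIGNED / None per trial

    def __post_init__(self) -> None:
        if len(self.responses) != len(self.plan.trials):
            raise ValueError("one response per trial required")


@dataclass
class SDTScores:
    hit_rate: float
    fa_rate: float
    hit_rate_corrected: float
    fa_rate_corrected: float
    dprime: float
    criterion_c: float
    accuracy_pct: float
    n_missing: int = 0


def validate_plan(
    plan: BATPlan, filler_positions: Sequence[int] = DEFAULT_FILLER_POSITIONS
) -> list[str]:
    """Return a list of constraint violations (empty = valid plan).

    Checks: 9/9/3 condition counts, fillers at the fixed positions, no clip
    twice in a row, no condition three times in a row.
    """
    problems = []
    counts = plan.counts()
    if counts != {"on": N_ON, "off": N_OFF, "filler": N_FILLER}:
        problems.append(f"condition counts {counts} != 9 on / 9 off / 3 filler")
    positions = [t.position for t in plan.trials]
    if positions != list(range(1, len(plan.trials) + 1)):
        problems.append("positions must be 1..n in order")
    actual_filler = tuple(t.position for t in plan.trials if t.condition == "filler")
    if actual_filler != tuple(sorted(filler_positions)):
        problems.append(
            f"filler positions {actual_filler} != fixed {tuple(sorted(filler_positions))}"
        )
    for a, b in zip(plan.trials, plan.trials[1:]):
        if a.clip_id == b.clip_id:
            problems.append(f"clip {a.clip_id!r} twice in a row at position {b.position}")
    for a, b, c in zip(plan.trials, plan.trials[1:], plan.trials[2:]):
        if a.condition == b.condition == c.condition:
            problems.append(
                f"condition {a.condition!r} three times in a row ending at {c.position}"
            )
    return problems


def make_trial_plan(
    clips: Sequence[str] | None = None,
    seed: int | None = None,
    filler_positions: Sequence[int] = DEFAULT_FILLER_POSITIONS,
    filler_clips: Sequence[str] | None = None,
    max_tries: int = 10_000,
) -> BATPlan:
    """Randomized 21-trial BAT plan satisfying the adjacency constraints.

    Each of the 9 clips appears once on-beat and once off-beat; 3 tempo-shifted
    fillers sit at fixed positions shared by all participants. Orders are
    rejection-sampled until no clip repeats back-to-back and no condition runs
    three in a row.
    """
    if clips is None:
        clips = [f"bat{i:02d}" for i in range(1, N_ON + 1)]
    if len(clips) != N_ON:
        raise ValueError(f"need {N_ON} scored clips, got {len(clips)}")
    if filler_clips is None:
        filler_clips = [f"filler{i}" for i in range(1, N_FILLER + 1)]
    if len(filler_clips) != N_FILLER:
        raise ValueError(f"need {N_FILLER} filler clips, got {len(filler_clips)}")
    filler_positions = tuple(sorted(filler_positions))
    n_total = N_ON + N_OFF + N_FILLER
    if len(set(filler_positions)) != N_FILLER or not all(
        1 <= p <= n_total for p in filler_positions
    ):
        raise ValueError(f"filler positions must be {N_FILLER} distinct values in 1..{n_total}")

    scored = [(c, "on") for c in clips] + [(c, "off") for c in clips]
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        order = [scored[i] for i in rng.permutation(len(scored))]
        trials: list[BATTrial] = []
        it = iter(order)
        fill_it = iter(filler_clips)
        for pos in range(1, n_total + 1):
            if pos in filler_positions:
                trials.append(BATTrial(pos, next(fill_it), "filler"))
            else:
                clip, cond = next(it)
                trials.append(BATTrial(pos, clip, cond))
        plan = BATPlan(trials)
        if not validate_plan(plan, filler_positions):
            return plan
    raise ValueError(
        f"could not satisfy plan constraints in {max_tries} tries; "
        "check the clip inventory and filler positions"
    )


def _correct_extreme(rate: float) -> float:
    """Extreme-rate rule: a rate of exactly 1 becomes 0.99, exactly 0 becomes 0.01."""
    if rate >= 1.0:
        return 0.99
    if rate <= 0.0:
        return 0.01
    return rate


def score_bat(session: BATSession) -> SDTScores:
    """Score a BAT session with signal detection theory.

    Hits are on-beat trials answered "aligned"; false alarms are off-beat
    trials answered "aligned"; fillers are not scored. d' = z(H) - z(F) and
    c = -(z(H) + z(F))/2 on the corrected rates; accuracy is percent correct
    over the 18 scored trials.
    """
    on_resp, off_resp, missing = [], [], 0
    for trial, resp in zip(session.plan.trials, session.responses):
        if trial.condition == "filler":
            continue
        if resp is None:
            missing += 1
            continue
        if resp not in (ALIGNED, NOT_ALIGNED):
            raise ValueError(f"unknown response {resp!r} at position {trial.position}")
        (on_resp if trial.condition == "on" else off_resp).append(resp)
    n_scored = len(on_resp) + len(off_resp)
    if n_scored == 0:
        raise ValueError("no scored responses in session")

    hits = sum(r == ALIGNED for r in on_resp)
    fas = sum(r == ALIGNED for r in off_resp)
    hit_rate = hits / len(on_resp) if on_resp else float("nan")
    fa_rate = fas / len(off_resp) if off_resp else float("nan")
    h = _correct_extreme(hit_rate)
    f = _correct_extreme(fa_rate)
    zh, zf = norm.ppf(h), norm.ppf(f)
    correct = hits + sum(r == NOT_ALIGNED for r in off_resp)
    return SDTScores(
        hit_rate=hit_rate,
        fa_rate=fa_rate,
        hit_rate_corrected=h,
        fa_rate_corrected=f,
        dprime=float(zh - zf),
        criterion_c=float(-(zh + zf) / 2.0),
        accuracy_pct=100.0 * correct / (N_ON + N_OFF),
        n_missing=missing,
    )
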