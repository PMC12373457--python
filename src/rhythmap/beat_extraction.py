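"""Canonical beat locations from multi-annotator tap series.

Tap annotations from many listeners are pooled and turned into a probability
density over time with a Gaussian kernel (default width 20 ms); the density's
peaks are taken as the beat locations. This recovers a consensus beat grid
for a music clip from noisy human tapping without any audio analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "BeatAnnotationSet",
    "DensityCurve",
    "pooled_kde",
    "find_beat_peaks",
    "extract_beats",
    "read_annotations_csv",
    "read_annotations_mirex",
    "write_beats_csv",
]

DEFAULT_BANDWIDTH_MS = 20.0
DEFAULT_GRID_STEP_MS = 1.0
DEFAULT_MIN_SEPARATION_MS = 250.0  # half the period of a 240 BPM beat is ~125 ms
DEFAULT_MIN_PROMINENCE_FRAC = 0.1


@dataclass
class BeatAnnotationSet:
    clip_id: str
    annotator_series: list[np.ndarray]

    def __post_init__(self) -> None:
        if not self.annotator_series:
            raise ValueError("at least one annotator required")
        self.annotator_series = [
            np.sort(np.asarray(s, dtype=float)) for s in self.annotator_series
        ]

    @property
    def pooled(self) -> np.ndarray:
        return np.sort(np.concatenate(self.annotator_series))

    @property
    def n_annotators(self) -> int:
        return len(self.annotator_series)


@dataclass
class DensityCurve:
    grid: np.ndarray  # uniform time grid, seconds
    density: np.ndarray  # nonnegative, integrates to ~1
    bandwidth_ms: float

    @property
    def step(self) -> float:
        return float(self.grid[1] - self.grid[0])

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


def pooled_kde(
    annotations: BeatAnnotationSet,
    bandwidth_ms: float = DEFAULT_BANDWIDTH_MS,
    grid_step_ms: float = DEFAULT_GRID_STEP_MS,
    t_min: float | None = None,
    t_max: float | None = None,
) -> DensityCurve:
    """Gaussian kernel density over the pooled annotator taps.

    The grid spans the pooled taps padded by 5 kernel widths (or the supplied
    clip bounds) at a uniform step (default 1 ms); the step must be at most a
    quarter of the bandwidth so peaks are resolved.
    """
    taps = annotations.pooled
    if taps.size == 0:
        raise ValueError("no taps in any annotation series")
    if bandwidth_ms <= 0:
        raise ValueError("bandwidth must be positive")
    if grid_step_ms > bandwidth_ms / 4.0:
        raise ValueError("grid step must be <= bandwidth/4")
    bw = bandwidth_ms / 1000.0
    pad = 5.0 * bw
    lo = taps[0] - pad if t_min is None else t_min
    hi = taps[-1] + pad if t_max is None else t_max
    step = grid_step_ms / 1000.0
    grid = np.arange(lo, hi + step / 2.0, step)
    # evaluate the Gaussian mixture in chunks to bound memory
    density = np.zeros_like(grid)
    norm = 1.0 / (taps.size * bw * np.sqrt(2.0 * np.pi))
    chunk = 200_000 // max(taps.size, 1) + 1
    for i in range(0, grid.size, chunk):
        g = grid[i : i + chunk, None]
        density[i : i + chunk] = norm * np.exp(
            -0.5 * ((g - taps[None, :]) / bw) ** 2
        ).sum(axis=1)
    return DensityCurve(grid=grid, density=density, bandwidth_ms=bandwidth_ms)


def find_beat_peaks(
    density: DensityCurve,
    min_separation_ms: float = DEFAULT_MIN_SEPARATION_MS,
    min_prominence_frac: float = DEFAULT_MIN_PROMINENCE_FRAC,
) -> np.ndarray:
    """Beat times = density peaks above a prominence floor, min separation apart.

    Prominence floor is ``min_prominence_frac`` of the density maximum; peaks
    closer than ``min_separation_ms`` keep only the higher one. Plateau peaks
    resolve to the plateau midpoint. A flat density yields no peaks (warning).
    """
    d = density.density
    if np.ptp(d) == 0:
        warnings.warn("flat density: no peaks found", stacklevel=2)
        return np.empty(0)
    distance = max(1, int(round(min_separation_ms / 1000.0 / density.step)))
    peaks, props = find_peaks(
        d,
        distance=distance,
        prominence=min_prominence_frac * float(d.max()),
        plateau_size=(1, None),
    )
    # plateau midpoints for deterministic output on flat-topped peaks
    mids = (props["left_edges"] + props["right_edges"]) // 2
    return np.sort(density.grid[mids])


def extract_beats(
    annotations: BeatAnnotationSet,
    bandwidth_ms: float = DEFAULT_BANDWIDTH_MS,
    min_separation_ms: float = DEFAULT_MIN_SEPARATION_MS,
    min_prominence_frac: float = DEFAULT_MIN_PROMINENCE_FRAC,
    **kde_kwargs,
) -> np.ndarray:
    """Convenience wrapper: pooled KDE followed by peak picking."""
    curve = pooled_kde(annotations, bandwidth_ms=bandwidth_ms, **kde_kwargs)
    return find_beat_peaks(curve, min_separation_ms, min_prominence_frac)


def read_annotations_csv(path: str | Path, clip_id: str | None = None) -> BeatAnnotationSet:
    """Read annotations with one tap-time column per annotator (CSV/TSV).

    Columns may have unequal lengths; empty cells are ignored.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    series = [df[c].dropna().to_numpy(float) for c in df.columns]
    series = [s for s in series if s.size]
    return BeatAnnotationSet(clip_id=clip_id or path.stem, annotator_series=series)


def read_annotations_mirex(directory: str | Path, clip_id: str | None = None) -> BeatAnnotationSet:
    """Read a directory of per-annotator text files (one tap time per line)."""
    directory = Path(directory)
    files = sorted(directory.glob("*.txt"))
    if not files:
        raise FileNotFoundError(f"no annotator .txt files in {directory}")
    series = [np.loadtxt(f, ndmin=1) for f in files]
    return BeatAnnotationSet(clip_id=clip_id or directory.name, annotator_series=series)


def write_beats_csv(beats: np.ndarray, path: str | Path, clip_id: str = "") -> None:
    pd.DataFrame({"clip": clip_id, "beat_time_s": np.asarray(beats, float)}).to_csv(
        path, index=False
    )
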