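"""Readers and writers for the pipeline's file formats.

Tables are UTF-8 comma-separated CSV with a header row (times in seconds,
angles in degrees, volumes in mm3); provenance (config hash, seed) travels in
leading ``# key=value`` comment lines. Lesion volumes are NIfTI (.nii/.nii.gz)
with a shared affine across the cohort.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import nibabel as nib
import numpy as np
import pandas as pd

from .lesion_mapping import LesionCohort
from .synthetic import StimulusSet
from .tapping import TapTrial
from .perception import BATPlan, BATSession, BATTrial

__all__ = [
    "write_csv",
    "read_csv",
    "write_tap_table",
    "read_tap_table",
    "write_beat_grids",
    "read_beat_grids",
    "write_session",
    "read_session",
    "write_lesion_cohort",
    "read_lesion_cohort",
]


def write_csv(df: pd.DataFrame, path: str | Path, meta: Mapping | None = None) -> None:
    """Write a CSV with optional ``# key=value`` provenance header lines."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False)


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_tap_table(
    trials: Iterable[TapTrial], path: str | Path, meta: Mapping | None = None
) -> None:
    """Long-format tap-onset table: participant, stimulus, repetition, tap_time_s."""
    rows = [
        dict(participant=t.participant, stimulus=t.stimulus,
             repetition=t.repetition, tap_time_s=tap)
        for t in trials
        for tap in t.tap_times
    ]
    write_csv(
        pd.DataFrame(rows, columns=["participant", "stimulus", "repetition", "tap_time_s"]),
        path, meta,
    )


def write_beat_grids(
    stimuli: StimulusSet, path: str | Path, meta: Mapping | None = None
) -> None:
    """Beat-grid table: stimulus, modality, guide_end_s, beat_time_s."""
    rows = [
        dict(stimulus=s.id, modality=s.modality, guide_end_s=s.guide_end,
             n_repetitions=s.n_repetitions, beat_time_s=b)
        for s in stimuli
        for b in s.beat_times
    ]
    write_csv(pd.DataFrame(rows), path, meta)


def read_beat_grids(path: str | Path) -> dict[str, dict]:
    """Return {stimulus: {beat_times, modality, guide_end, n_repetitions}}."""
    df = read_csv(path)
    grids: dict[str, dict] = {}
    for stim, grp in df.groupby("stimulus", sort=False):
        grids[stim] = dict(
            beat_times=np.sort(grp["beat_time_s"].to_numpy(float)),
            modality=str(grp["modality"].iloc[0]),
            guide_end=float(grp["guide_end_s"].iloc[0]),
            n_repetitions=int(grp["n_repetitions"].iloc[0]),
        )
    return grids


def read_tap_table(taps_path: str | Path, beats_path: str | Path) -> list[TapTrial]:
    """Join a tap-onset table with its beat grids into TapTrial objects."""
    taps = read_csv(taps_path)
    grids = read_beat_grids(beats_path)
    trials = []
    for (pid, stim, rep), grp in taps.groupby(
        ["participant", "stimulus", "repetition"], sort=True
    ):
        if stim not in grids:
            raise KeyError(f"no beat grid for stimulus {stim!r}")
        g = grids[stim]
        trials.append(
            TapTrial(
                participant=str(pid), stimulus=str(stim), repetition=int(rep),
                tap_times=grp["tap_time_s"].to_numpy(float),
                beat_times=g["beat_times"], modality=g["modality"],
                guide_end=g["guide_end"],
            )
        )
    return trials


def write_session(
    session: BATSession, path: str | Path, meta: Mapping | None = None
) -> None:
    rows = [
        dict(position=t.position, clip=t.clip_id, condition=t.condition,
             response=r if r is not None else "")
        for t, r in zip(session.plan.trials, session.responses)
    ]
    write_csv(pd.DataFrame(rows), path, meta)


def read_session(path: str | Path) -> BATSession:
    df = read_csv(path).sort_values("position")
    trials = [
        BATTrial(int(r.position), str(r.clip), str(r.condition))
        for r in df.itertuples()
    ]
    responses = [
        None if (pd.isna(r.response) or r.response == "") else str(r.response)
        for r in df.itertuples()
    ]
    return BATSession(plan=BATPlan(trials), responses=responses)


def write_lesion_cohort(cohort: LesionCohort, directory: str | Path) -> list[Path]:
    """One NIfTI mask per patient, named by patient id."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for pid, mask in zip(cohort.patient_ids, cohort.masks):
        p = directory / f"{pid}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), cohort.affine), p)
        paths.append(p)
    return paths


def read_lesion_cohort(directory: str | Path, smoothed: bool = False) -> LesionCohort:
    """Load all NIfTI masks in a directory into a cohort.

    All files must share shape and affine; binary values are enforced unless
    the volumes are declared smoothing output via ``smoothed=True``.
    """
    directory = Path(directory)
    files = sorted(
        p for p in directory.iterdir() if p.name.endswith((".nii", ".nii.gz"))
    )
    if not files:
        raise FileNotFoundError(f"no NIfTI masks in {directory}")
    masks, ids = [], []
    shape, affine = None, None
    for f in files:
        img = nib.load(str(f))
        data = np.asarray(img.dataobj, dtype=float)
        if shape is None:
            shape, affine = data.shape, img.affine
        else:
            if data.shape != shape:
                raise ValueError(f"{f.name}: shape {data.shape} != {shape}")
            if not np.allclose(img.affine, affine, atol=1e-4):
                raise ValueError(f"{f.name}: affine differs from the cohort affine")
        if not smoothed and not np.isin(np.unique(data), [0, 1]).all():
            raise ValueError(
                f"{f.name}: non-binary voxel values (declare smoothed=True if intended)"
            )
        masks.append(data)
        ids.append(f.name.replace(".nii.gz", "").replace(".nii", ""))
    return LesionCohort(
        masks=np.stack(masks), affine=affine, patient_ids=ids, smoothed=smoothed
    )
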