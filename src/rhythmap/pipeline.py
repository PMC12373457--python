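"""End-to-end pipeline: simulate (or load) -> score tapping -> score BAT ->
classify against control norms -> lesion-symptom mapping -> report tables.

With no input files configured, a fully synthetic cohort is generated whose
patients' tapping consistency, perceptual sensitivity, and behavioral scores
all degrade with damage to a planted critical brain region, so the pipeline's
final VLSM stage has a ground truth to recover. Every output table carries
the config hash and seed in its header.
"""

from __future__ import annotations

import logging
import shutil
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import io as rio
from .config import PipelineConfig
from .lesion_mapping import VLSM, lesion_overlay
from .perception import make_trial_plan, score_bat
from .single_case import CrawfordHowellClassifier
from .synthetic import (
    LesionCohortSpec,
    TapperProfile,
    default_critical_roi,
    make_stimulus_set,
    simulate_bat_responder,
    simulate_lesion_cohort,
    simulate_tapper,
)
from .tapping import TappingScorer

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "PipelineError"]

# group-level generative settings (control tapping near the study's control
# distribution; patient ability degrades with critical-region damage)
CONTROL_KAPPA_RANGE = (4.0, 14.0)
CONTROL_PHASE_SD = 15.0
CONTROL_DPRIME = (3.0, 1.3)
PATIENT_DPRIME = (1.4, 1.3)
PATIENT_DPRIME_DAMAGE_DROP = 1.0


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _patient_profile(pid: str, damage: float, rng: np.random.Generator) -> TapperProfile:
    """Tapping ability degrades smoothly with critical-ROI damage."""
    kappa = max(0.2, 10.0 * (1.0 - damage) ** 2 + rng.normal(0, 1.0))
    phase = float(np.clip(-10.0 - 90.0 * damage + rng.normal(0, 10.0), -179.9, 180.0))
    return TapperProfile(
        mean_phase_deg=phase, concentration_kappa=kappa,
        miss_prob=min(0.6, 0.05 + 0.4 * damage), extra_tap_rate=0.05 * damage,
        participant=pid,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns a report bundle of output paths and
    key tables. Any stage failure aborts with a stage-named error and removes
    partial outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    meta = config.meta()
    logger.info("pipeline start: %s", meta)
    logger.info(
        "defaults in force: trim=%s fwhm=%s min_patients=%s voxel_p=%s "
        "cluster_alpha=%s connectivity=%s alpha=%s",
        config.trim, config.fwhm_mm, config.min_patients, config.voxel_p,
        config.cluster_alpha, config.connectivity, config.alpha,
    )

    def emit(df: pd.DataFrame, name: str) -> Path:
        p = out / name
        rio.write_csv(df, p, meta)
        written.append(p)
        return p

    try:
        bundle: dict = {"config_hash": meta["config_hash"], "seed": config.seed}
        stage = "simulate"
        rng = np.random.default_rng(config.seed)
        control_ids = [f"c{i:02d}" for i in range(1, config.n_controls + 1)]
        patient_ids = [f"a{i:02d}" for i in range(1, config.n_patients + 1)]

        roi = default_critical_roi(config.grid_shape, config.voxel_size_mm)
        spec = LesionCohortSpec(
            grid_shape=config.grid_shape, voxel_size_mm=config.voxel_size_mm,
            n_patients=config.n_patients,
            lesion_radius_range_mm=config.lesion_radius_range_mm,
            critical_roi=roi, seed=config.seed,
        )
        cohort, _, damage = simulate_lesion_cohort(spec)
        cohort.patient_ids = list(patient_ids)

        stimuli = make_stimulus_set(seed=config.seed)
        trials = []
        for pid in control_ids:
            prof = TapperProfile(
                mean_phase_deg=float(rng.normal(-15.0, CONTROL_PHASE_SD)),
                concentration_kappa=float(rng.uniform(*CONTROL_KAPPA_RANGE)),
                miss_prob=0.02, participant=pid,
            )
            trials.extend(simulate_tapper(prof, stimuli, seed=config.seed))
        for pid, dmg in zip(patient_ids, damage):
            trials.extend(
                simulate_tapper(_patient_profile(pid, dmg, rng), stimuli, seed=config.seed)
            )

        stage = "score-tapping"
        scorer = TappingScorer(trim=config.trim).fit(trials)
        composites = scorer.composite_scores_
        comp = composites.set_index("participant")["composite"]
        emit(scorer.trial_summaries_, "trial_summaries.csv")
        emit(composites, "composite_scores.csv")

        stage = "score-bat"
        bat_rows = []
        for i, pid in enumerate(control_ids + patient_ids):
            plan = make_trial_plan(seed=int(rng.integers(2**31)))
            if pid in control_ids:
                d = max(0.0, rng.normal(*CONTROL_DPRIME))
            else:
                dmg = damage[patient_ids.index(pid)]
                d = max(
                    0.0,
                    rng.normal(*PATIENT_DPRIME) - PATIENT_DPRIME_DAMAGE_DROP * dmg,
                )
            session = simulate_bat_responder(
                d, 0.0, plan, seed=config.seed, participant=pid
            )
            s = score_bat(session)
            bat_rows.append(
                dict(participant=pid, dprime=s.dprime, criterion_c=s.criterion_c,
                     hit_rate=s.hit_rate, fa_rate=s.fa_rate, accuracy_pct=s.accuracy_pct)
            )
        bat = pd.DataFrame(bat_rows).set_index("participant")
        emit(bat.reset_index(), "bat_scores.csv")

        stage = "classify"
        tables = {}
        for measure, series in (("tapping", comp), ("bat_dprime", bat["dprime"])):
            clf = CrawfordHowellClassifier(
                alpha=config.alpha, exclude_ids=config.excluded_controls
            )
            clf.fit(series.loc[control_ids].to_numpy(), ids=control_ids)
            table = clf.classification_table(
                series.loc[patient_ids].to_numpy(), ids=patient_ids
            )
            tables[measure] = table
            emit(table, f"classification_{measure}.csv")
        bundle["n_impaired_tapping"] = int(tables["tapping"]["impaired"].sum())
        bundle["n_impaired_bat"] = int(tables["bat_dprime"]["impaired"].sum())

        stage = "vlsm"
        impaired = tables["tapping"].set_index("case")["impaired"].loc[patient_ids]
        vlsm = VLSM(
            fwhm_mm=config.fwhm_mm, min_patients=config.min_patients,
            voxel_p=config.voxel_p, cluster_alpha=config.cluster_alpha,
            n_permutations=config.n_perm, connectivity=config.connectivity,
            behavior_direction="impairment", random_state=config.seed,
        ).fit(cohort, impaired.to_numpy(float))
        emit(vlsm.clusters_, "cluster_table.csv")
        for name, vol, dtype in (
            ("t_map.nii.gz", np.nan_to_num(vlsm.t_map_), np.float32),
            ("lesion_overlay.nii.gz", lesion_overlay(cohort), np.int16),
            ("critical_roi.nii.gz", roi, np.uint8),
        ):
            p = out / name
            nib.save(nib.Nifti1Image(np.asarray(vol, dtype=dtype), cohort.affine), p)
            written.append(p)

        stage = "report"
        bundle.update(
            composites=composites, bat_scores=bat.reset_index(),
            classification=tables, clusters=vlsm.clusters_,
            significant_clusters=vlsm.significant_clusters_,
            outputs=[str(p) for p in written],
        )
        report = pd.DataFrame(
            [
                dict(quantity="n_impaired_tapping", value=bundle["n_impaired_tapping"]),
                dict(quantity="n_impaired_bat", value=bundle["n_impaired_bat"]),
                dict(quantity="n_significant_clusters", value=len(vlsm.significant_clusters_)),
                dict(quantity="voxel_threshold_t", value=vlsm.voxel_threshold_t_),
            ]
        )
        emit(report, "report.csv")
        return bundle
    except Exception as exc:  # noqa: BLE001 - stage-named rethrow, outputs removed
        for p in written:
            p.unlink(missing_ok=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc
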