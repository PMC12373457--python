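"""Voxel-based lesion-symptom mapping (VLSM) with cluster permutation correction.

At every voxel lesioned in at least ``min_patients`` patients, behavior is
regressed on the (optionally Gaussian-smoothed) lesion value with total lesion
volume as a covariate. The lesion coefficient's t statistic is thresholded at
a one-tailed voxelwise p < 0.01; suprathreshold voxels are grouped into
connected clusters, and family-wise error is controlled by permuting the
behavior vector across patients (lesions and their volumes stay attached to
their patients), recording the maximum cluster extent per permutation, and
reporting each observed cluster's corrected p against that null distribution
(right-tailed, corrected p < 0.05).

The voxelwise GLM is computed by residualizing both the behavior and the
lesion values against the nuisance design (intercept + covariates), which is
algebraically identical to the full OLS t with df = n - p and lets each
permutation run as a single matrix-vector product.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

__all__ = [
    "LesionCohort",
    "Cluster",
    "VLSMResult",
    "fwhm_to_sigma",
    "smooth_mask",
    "coverage_mask",
    "lesion_overlay",
    "vlsm_tmap",
    "cluster_correct",
    "roi_damage",
    "VLSM",
]

GAUSSIAN_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ~2.3548


@dataclass
class LesionCohort:
    """Per-patient lesion masks on a shared grid.

    masks: (n_patients, nx, ny, nz); binary {0,1} unless declared smoothed.
    affine: 4x4 voxel-to-world matrix (MNI mm assumed).
    """

    masks: np.ndarray
    affine: np.ndarray
    patient_ids: list = field(default_factory=list)
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.masks.ndim != 4:
            raise ValueError("masks must be (n_patients, nx, ny, nz)")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not self.patient_ids:
            self.patient_ids = [f"p{i:03d}" for i in range(self.masks.shape[0])]
        if len(self.patient_ids) != self.masks.shape[0]:
            raise ValueError("patient_ids length != number of masks")
        if not self.smoothed:
            vals = np.unique(self.masks)
            if not np.isin(vals, [0, 1]).all():
                raise ValueError("binary cohort contains values other than {0, 1}")

    @property
    def n_patients(self) -> int:
        return self.masks.shape[0]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def binary_masks(self) -> np.ndarray:
        return self.masks > 0.5 if self.smoothed else self.masks.astype(bool)

    def total_volumes_mm3(self) -> np.ndarray:
        """Total lesion volume per patient: voxel count x voxel volume."""
        return (
            self.binary_masks().reshape(self.n_patients, -1).sum(axis=1)
            * self.voxel_volume_mm3
        )

    def smooth(self, fwhm_mm: float = 8.0) -> "LesionCohort":
        smoothed = np.stack(
            [smooth_mask(m, self.voxel_size_mm, fwhm_mm) for m in self.masks]
        )
        return LesionCohort(
            masks=smoothed, affine=self.affine,
            patient_ids=list(self.patient_ids), smoothed=True,
        )


@dataclass
class Cluster:
    label: int
    size_voxels: int
    size_mm3: float
    center_of_mass_mm: tuple
    peak_t: float
    corrected_p: float


@dataclass
class VLSMResult:
    t_map: np.ndarray
    coverage_mask: np.ndarray
    voxel_threshold_t: float
    clusters: list[Cluster]
    null_max_cluster_sizes: np.ndarray
    n_permutations: int
    seed: int | None
    connectivity: int

    def cluster_table(self) -> pd.DataFrame:
        rows = [
            dict(
                cluster=c.label, size_voxels=c.size_voxels, size_mm3=c.size_mm3,
                com_x_mm=c.center_of_mass_mm[0], com_y_mm=c.center_of_mass_mm[1],
                com_z_mm=c.center_of_mass_mm[2], peak_t=c.peak_t,
                corrected_p=c.corrected_p,
            )
            for c in self.clusters
        ]
        return pd.DataFrame(
            rows,
            columns=["cluster", "size_voxels", "size_mm3", "com_x_mm", "com_y_mm",
                     "com_z_mm", "peak_t", "corrected_p"],
        )


def fwhm_to_sigma(fwhm_mm: float) -> float:
    return fwhm_mm / GAUSSIAN_FWHM_FACTOR


def smooth_mask(
    mask: np.ndarray, voxel_size_mm: float | Sequence[float], fwhm_mm: float = 8.0
) -> np.ndarray:
    """Gaussian-smooth a binary lesion mask (zero-padded boundaries).

    sigma = FWHM / (2 sqrt(2 ln 2)) per axis, converted from mm to voxels;
    turns lesion status into a continuous variable in [0, 1].
    """
    mask = np.asarray(mask, dtype=float)
    vs = np.broadcast_to(np.atleast_1d(np.asarray(voxel_size_mm, float)), (mask.ndim,))
    if not np.allclose(vs, vs[0]):
        warnings.warn(
            f"anisotropic voxels {tuple(vs)}; smoothing with per-axis sigma",
            stacklevel=2,
        )
    sigma_vox = fwhm_to_sigma(fwhm_mm) / vs
    return ndimage.gaussian_filter(mask, sigma=sigma_vox, mode="constant", cval=0.0)


def coverage_mask(cohort: LesionCohort, min_patients: int = 5) -> np.ndarray:
    """Voxels lesioned in at least ``min_patients`` patients (binary masks)."""
    return cohort.binary_masks().sum(axis=0) >= min_patients


def lesion_overlay(cohort: LesionCohort) -> np.ndarray:
    """Per-voxel count of patients with a lesion there."""
    return cohort.binary_masks().sum(axis=0).astype(int)


def roi_damage(lesion_mask: np.ndarray, roi_mask: np.ndarray) -> float:
    """Proportion of the ROI's voxels that are lesioned."""
    lesion = np.asarray(lesion_mask).astype(bool)
    roi = np.asarray(roi_mask).astype(bool)
    if lesion.shape != roi.shape:
        raise ValueError("lesion and ROI grids differ")
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise ValueError("ROI mask is empty")
    return float((lesion & roi).sum() / n_roi)


def _connectivity_structure(connectivity: int) -> np.ndarray:
    try:
        rank = {6: 1, 18: 2, 26: 3}[connectivity]
    except KeyError:
        raise ValueError("connectivity must be 6, 18 or 26") from None
    return ndimage.generate_binary_structure(3, rank)


class _VoxelwiseGLM:
    """Residualized voxelwise regression shared by the observed fit and the
    permutations.

    Per-voxel design: [intercept, lesion value, covariates]; t is the lesion
    coefficient over its SE with df = n - n_columns, computed exactly via
    Frisch-Waugh residualization.
    """

    def __init__(self, lesion_values: np.ndarray, covariates: np.ndarray):
        n = lesion_values.shape[0]
        Z = np.column_stack([np.ones(n), covariates])
        self.df = n - Z.shape[1] - 1
        if self.df < 1:
            raise ValueError("not enough patients for the covariate design")
        self.Q, _ = np.linalg.qr(Z)
        Xr = lesion_values - self.Q @ (self.Q.T @ lesion_values)
        self.xnorm = np.linalg.norm(Xr, axis=0)
        # voxels whose lesion regressor is collinear with the nuisance design
        self.degenerate = self.xnorm < 1e-10 * max(float(self.xnorm.max(initial=0.0)), 1.0)
        if self.degenerate.any():
            logger.info(
                "%d voxels dropped: lesion regressor collinear with covariates",
                int(self.degenerate.sum()),
            )
        safe = np.where(self.degenerate, 1.0, self.xnorm)
        self._Xr_unit = Xr / safe

    def t_values(self, behavior: np.ndarray) -> np.ndarray:
        """Lesion-coefficient t per voxel for one behavior vector."""
        y = np.asarray(behavior, dtype=float)
        yr = y - self.Q @ (self.Q.T @ y)
        ynorm = np.linalg.norm(yr)
        if ynorm < 1e-12:
            raise ValueError("behavior is constant (or fully explained by covariates)")
        r = np.clip((self._Xr_unit.T @ yr) / ynorm, -1.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * np.sqrt(self.df / np.maximum(1.0 - r * r, 1e-300))
        t[self.degenerate] = np.nan
        return t


def _prepare(
    cohort: LesionCohort,
    behavior: Sequence[float],
    covariates: np.ndarray | None,
    min_patients: int,
    behavior_direction: str,
    coverage: np.ndarray | None,
    lesion_values: np.ndarray | None,
):
    behavior = np.asarray(behavior, dtype=float)
    if behavior.shape[0] != cohort.n_patients:
        raise ValueError("behavior length must equal the number of patients")
    if np.ptp(behavior) == 0:
        raise ValueError("behavior is constant")
    if behavior_direction not in ("impairment", "score"):
        raise ValueError("behavior_direction must be 'impairment' or 'score'")
    cov = coverage_mask(cohort, min_patients) if coverage is None else np.asarray(coverage, bool)
    if cov.shape != cohort.masks.shape[1:]:
        raise ValueError("coverage mask shape does not match the grid")
    if not cov.any():
        raise ValueError(f"no voxel is lesioned in >= {min_patients} patients")
    if covariates is None:
        covariates = cohort.total_volumes_mm3()[:, None]
    else:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        if covariates.shape[0] != cohort.n_patients:
            raise ValueError("covariates must have one row per patient")
    values = cohort.masks if lesion_values is None else np.asarray(lesion_values, float)
    X = values.reshape(cohort.n_patients, -1)[:, cov.ravel()].astype(float)
    sign = 1.0 if behavior_direction == "impairment" else -1.0
    return behavior, cov, covariates, X, sign


def vlsm_tmap(
    cohort: LesionCohort,
    behavior: Sequence[float],
    covariates: np.ndarray | None = None,
    min_patients: int = 5,
    voxel_p: float = 0.01,
    behavior_direction: str = "impairment",
    coverage: np.ndarray | None = None,
    lesion_values: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Voxelwise lesion-behavior t map and the one-tailed voxel threshold.

    OLS of behavior on [intercept, lesion value, total lesion volume] at every
    coverage voxel; returns (t_map, voxel_threshold_t) with NaN outside
    coverage. Positive t means damage associates with worse behavior: pass an
    impairment indicator (1 = impaired) with behavior_direction="impairment",
    or a higher-is-better score with behavior_direction="score".
    """
    behavior, cov, covariates, X, sign = _prepare(
        cohort, behavior, covariates, min_patients, behavior_direction,
        coverage, lesion_values,
    )
    glm = _VoxelwiseGLM(X, covariates)
    t_map = np.full(cohort.masks.shape[1:], np.nan)
    t_map[cov] = sign * glm.t_values(behavior)
    return t_map, float(stats.t.ppf(1.0 - voxel_p, glm.df))


def _label_and_sizes(supra: np.ndarray, structure: np.ndarray):
    labels, n = ndimage.label(supra, structure=structure)
    if n == 0:
        return labels, 0, np.empty(0, dtype=np.int64)
    sizes = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    return labels, n, sizes


def cluster_correct(
    t_map: np.ndarray,
    cohort: LesionCohort,
    behavior: Sequence[float],
    covariates: np.ndarray | None = None,
    n_perm: int = 10_000,
    voxel_p: float = 0.01,
    cluster_alpha: float = 0.05,
    connectivity: int = 26,
    min_patients: int = 5,
    behavior_direction: str = "impairment",
    seed: int | None = None,
    coverage: np.ndarray | None = None,
    lesion_values: np.ndarray | None = None,
) -> VLSMResult:
    """Cluster-extent permutation correction of a VLSM t map.

    Each permutation shuffles the behavior vector across patients (masks and
    the volume covariate stay attached to their patients), recomputes the
    voxelwise t map, and records the maximum suprathreshold cluster extent.
    Observed clusters get corrected p = (1 + #{null >= observed}) / (1 + n_perm)
    (right-tailed); sizes are reported in mm3 and centers of mass in world
    (MNI) coordinates via the cohort affine.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very low for a permutation null", stacklevel=2)
    behavior, cov, covariates, X, sign = _prepare(
        cohort, behavior, covariates, min_patients, behavior_direction,
        coverage, lesion_values,
    )
    glm = _VoxelwiseGLM(X, covariates)
    threshold = float(stats.t.ppf(1.0 - voxel_p, glm.df))
    structure = _connectivity_structure(connectivity)

    observed = np.asarray(t_map, dtype=float)
    if observed.shape != cohort.masks.shape[1:]:
        raise ValueError("t_map shape does not match the cohort grid")
    supra = np.zeros_like(observed, dtype=bool)
    with np.errstate(invalid="ignore"):
        supra[cov] = observed[cov] >= threshold
    labels, n_clusters, sizes = _label_and_sizes(supra, structure)

    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_perm, dtype=np.int64)
    perm_supra = np.zeros(observed.shape, dtype=bool)
    cov_idx = np.flatnonzero(cov.ravel())
    flat = perm_supra.ravel()
    for b in range(n_perm):
        perm_y = behavior[rng.permutation(behavior.shape[0])]
        t_perm = sign * glm.t_values(perm_y)
        flat[:] = False
        with np.errstate(invalid="ignore"):
            flat[cov_idx] = t_perm >= threshold
        _, n_p, sizes_p = _label_and_sizes(perm_supra, structure)
        null_max[b] = sizes_p.max() if n_p else 0

    clusters: list[Cluster] = []
    vox_vol = cohort.voxel_volume_mm3
    for lab in range(1, n_clusters + 1):
        in_cluster = labels == lab
        size_vox = int(sizes[lab - 1])
        corrected = float((1 + int((null_max >= size_vox).sum())) / (1 + n_perm))
        com_vox = ndimage.center_of_mass(in_cluster)
        com_mm = tuple((cohort.affine @ np.array([*com_vox, 1.0]))[:3])
        clusters.append(
            Cluster(
                label=lab, size_voxels=size_vox, size_mm3=size_vox * vox_vol,
                center_of_mass_mm=com_mm,
                peak_t=float(np.nanmax(observed[in_cluster])),
                corrected_p=corrected,
            )
        )
    clusters.sort(key=lambda c: (-c.size_voxels, c.label))
    return VLSMResult(
        t_map=observed, coverage_mask=cov, voxel_threshold_t=threshold,
        clusters=clusters, null_max_cluster_sizes=null_max,
        n_permutations=n_perm, seed=seed, connectivity=connectivity,
    )


class VLSM(BaseEstimator):
    """Voxel-based lesion-symptom mapping estimator.

    ``fit(cohort, behavior)`` smooths the lesion masks (8 mm FWHM by default),
    restricts the search to voxels lesioned in at least ``min_patients``
    patients (computed on the binary masks regardless of smoothing), fits the
    voxelwise GLM with total lesion volume as covariate, and corrects clusters
    by permutation.

    Parameters
    ----------
    fwhm_mm : float
        Gaussian smoothing FWHM in mm; 0 regresses on the binary masks.
    min_patients : int
        Coverage threshold (default 5).
    voxel_p : float
        One-tailed voxelwise threshold (default 0.01).
    cluster_alpha : float
        Corrected cluster significance level (default 0.05, right-tailed).
    n_permutations : int
        Behavior-shuffle permutations (default 10_000).
    connectivity : int
        Cluster connectivity, 6/18/26 (default 26).
    behavior_direction : str
        "impairment" (1 = impaired; default) or "score" (higher = better).
    random_state : int or None
        Permutation seed.

    Attributes
    ----------
    t_map_, coverage_mask_, voxel_threshold_t_, clusters_,
    significant_clusters_, result_
    """

    def __init__(
        self,
        fwhm_mm: float = 8.0,
        min_patients: int = 5,
        voxel_p: float = 0.01,
        cluster_alpha: float = 0.05,
        n_permutations: int = 10_000,
        connectivity: int = 26,
        behavior_direction: str = "impairment",
        random_state: int | None = None,
    ):
        self.fwhm_mm = fwhm_mm
        self.min_patients = min_patients
        self.voxel_p = voxel_p
        self.cluster_alpha = cluster_alpha
        self.n_permutations = n_permutations
        self.connectivity = connectivity
        self.behavior_direction = behavior_direction
        self.random_state = random_state

    def fit(self, cohort: LesionCohort, behavior: Sequence[float]) -> "VLSM":
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        cov = coverage_mask(cohort, min_patients=self.min_patients)
        volumes = cohort.total_volumes_mm3()[:, None]
        values = (
            cohort.smooth(self.fwhm_mm).masks if self.fwhm_mm > 0 else cohort.masks
        )
        t_map, threshold = vlsm_tmap(
            cohort, behavior, covariates=volumes, voxel_p=self.voxel_p,
            behavior_direction=self.behavior_direction,
            coverage=cov, lesion_values=values,
        )
        result = cluster_correct(
            t_map, cohort, behavior, covariates=volumes,
            n_perm=self.n_permutations, voxel_p=self.voxel_p,
            cluster_alpha=self.cluster_alpha, connectivity=self.connectivity,
            behavior_direction=self.behavior_direction, seed=self.random_state,
            coverage=cov, lesion_values=values,
        )
        self.result_ = result
        self.t_map_ = result.t_map
        self.coverage_mask_ = cov
        self.voxel_threshold_t_ = threshold
        self.clusters_ = result.cluster_table()
        self.significant_clusters_ = self.clusters_[
            self.clusters_["corrected_p"] < self.cluster_alpha
        ].reset_index(drop=True)
        return self
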