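import numpy as np
import pytest

from rhythmap.lesion_mapping import LesionCohort
from rhythmap.synthetic import (
    LesionCohortSpec,
    default_critical_roi,
    make_stimulus_set,
    simulate_lesion_cohort,
)


@pytest.fixture(scope="session")
def stimuli():
    """Default stimulus inventory (3 isochronous + 6 surrogate music clips)."""
    return make_stimulus_set(seed=42)


@pytest.fixture
def small_cohort():
    """Small random binary lesion cohort on a 12^3 grid (no planted effect)."""
    spec = LesionCohortSpec(
        grid_shape=(12, 12, 12), voxel_size_mm=8.0, n_patients=16,
        lesion_radius_range_mm=(12, 40), effect_size=0.0, noise_sd=5.0, seed=7,
    )
    cohort, scores, _ = simulate_lesion_cohort(spec)
    return cohort, scores


@pytest.fixture
def planted_cohort():
    """Cohort with a planted critical region strongly coupled to behavior."""
    shape = (20, 20, 20)
    roi = default_critical_roi(shape, 8.0, radius_mm=20, center_frac=(0.5, 0.5, 0.5))
    spec = LesionCohortSpec(
        grid_shape=shape, voxel_size_mm=8.0, n_patients=30,
        lesion_radius_range_mm=(20, 60), critical_roi=roi,
        effect_size=60.0, noise_sd=1.0, seed=11,
    )
    cohort, scores, damage = simulate_lesion_cohort(spec)
    return cohort, scores, damage, roi


def identical_mask_cohort(mask, n, voxel_size=2.0):
    masks = np.repeat(mask[None].astype(np.uint8), n, axis=0)
    affine = np.diag([voxel_size] * 3 + [1.0])
    return LesionCohort(masks=masks, affine=affine)
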