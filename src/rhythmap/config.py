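"""Pipeline configuration: validated parameters, YAML/JSON loading, hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    """Parameters of an end-to-end run (synthetic or from files).

    All analysis parameters are validated against their documented ranges
    before any stage executes.
    """

    seed: int = 0
    out_dir: str = "rhythmap_out"

    # optional input paths (synthetic generation is used when absent)
    tap_table: str | None = None
    beat_grids: str | None = None
    bat_sessions_dir: str | None = None
    lesion_dir: str | None = None

    # cohort sizes for synthetic generation
    n_controls: int = 29
    n_patients: int = 33

    # analysis parameters
    alpha: float = 0.02  # single-case cutoff, one-tailed
    n_perm: int = 10_000
    fwhm_mm: float = 8.0
    min_patients: int = 5
    voxel_p: float = 0.01
    cluster_alpha: float = 0.05
    connectivity: int = 26
    bandwidth_ms: float = 20.0
    trim: bool = True
    excluded_controls: tuple = ()

    # synthetic lesion grid (scaled-down by default so a laptop run finishes)
    grid_shape: tuple = (24, 24, 24)
    voxel_size_mm: float = 6.0
    lesion_radius_range_mm: tuple = (10.0, 45.0)

    def __post_init__(self) -> None:
        checks = [
            (self.n_perm >= 1, "n_perm must be >= 1"),
            (0 < self.alpha < 1, "alpha must be in (0, 1)"),
            (0 < self.voxel_p < 1, "voxel_p must be in (0, 1)"),
            (0 < self.cluster_alpha < 1, "cluster_alpha must be in (0, 1)"),
            (self.fwhm_mm >= 0, "fwhm_mm must be nonnegative"),
            (self.min_patients >= 1, "min_patients must be >= 1"),
            (self.bandwidth_ms > 0, "bandwidth_ms must be positive"),
            (self.connectivity in (6, 18, 26), "connectivity must be 6, 18 or 26"),
            (self.n_controls >= 3, "need at least 3 controls"),
            (self.n_patients >= 1, "need at least 1 patient"),
            (int(self.seed) >= 0, "seed must be a nonnegative integer"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid config: {msg}")
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        self.lesion_radius_range_mm = tuple(float(r) for r in self.lesion_radius_range_mm)
        self.excluded_controls = tuple(self.excluded_controls)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def meta(self) -> dict:
        return {"config_hash": self.hash(), "seed": self.seed}


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a YAML or JSON config file, applying keyword overrides."""
    data: dict = {}
    if path is not None:
        path = Path(path)
        text = path.read_text()
        data = (
            json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        ) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**data)
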