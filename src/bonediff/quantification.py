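"""Quantification of remodelling label volumes and overlay rendering.

Formed and resorbed volumes are expressed both in mm**3 and as a
percentage of the baseline bone volume, where "baseline bone" is a
BV/TV-matched segmentation of the baseline scan restricted to the LCV:
the bone volume fraction is set to the mean trabecular density divided by
1200 mg HA/cm**3 (taken to represent fully mineralised bone) and the
segmentation keeps exactly that fraction of highest-density voxels, so
the target is met up to integer rounding with no threshold iteration.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .change_detection import FilterParams
from .core import (
    LABEL_FORMATION,
    LABEL_RESORPTION,
    LABEL_UNCHANGED,
    BinaryMask,
    DensityVolume,
    RemodellingLabelVolume,
    require_same_grid,
)

__all__ = [
    "RemodellingResult",
    "FULL_MINERALISATION",
    "segment_bvtv",
    "quantify",
    "make_overlay",
    "export_overlay_slices",
]

#: density assumed to represent fully mineralised bone, mg HA/cm**3
FULL_MINERALISATION = 1200.0

#: fixed overlay palette (RGB): background, unchanged bone, formation, resorption
OVERLAY_PALETTE = np.array(
    [[0, 0, 0],        # black
     [128, 128, 128],  # grey
     [0, 255, 0],      # green
     [255, 0, 255]],   # magenta
    dtype=np.uint8,
)


@dataclass
class RemodellingResult:
    """Formation/resorption volumes for one registered scan pair.

    Percentages share a single denominator: the number of baseline-bone
    voxels inside the LCV.  ``net_pct`` is formation_pct - resorption_pct
    exactly (positive = net gain).
    """

    formation_volume_mm3: float
    resorption_volume_mm3: float
    formation_pct: float
    resorption_pct: float
    net_pct: float
    formation_voxels: int
    resorption_voxels: int
    baseline_bone_voxels: int
    lcv_fraction: float | None = None
    registration_correlation: float | None = None
    threshold: float | None = None
    min_cluster: int | None = None
    connectivity: int | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | os.PathLike) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "RemodellingResult":
        with open(path) as fh:
            return cls(**json.load(fh))


def segment_bvtv(
    density: DensityVolume,
    region: BinaryMask,
    full_mineralisation: float = FULL_MINERALISATION,
) -> tuple[BinaryMask, float]:
    """BV/TV-matched bone segmentation by rank selection.

    The target bone volume fraction is the mean density within ``region``
    divided by ``full_mineralisation``, clamped to [0, 1]; the returned
    mask contains the round(target * N) highest-density voxels of the
    region (N = region size), ties at the selection boundary broken by
    ascending linear voxel index for full determinism.  Returns the mask
    and the achieved BV/TV, always within 1/N of the target.
    """
    require_same_grid(density, region, what="density and region")
    region.require_nonempty("segmentation region")
    if not full_mineralisation > 0:
        raise ValueError("full_mineralisation must be > 0")
    values = density.data[region.data]
    n = values.size
    target = float(np.clip(values.mean() / full_mineralisation, 0.0, 1.0))
    k = int(round(target * n))
    mask = np.zeros(density.data.shape, dtype=bool)
    if target <= 0.0:
        warnings.warn("non-positive mean density: empty bone mask", stacklevel=2)
        return BinaryMask(mask, density.voxel_size, density.origin), 0.0
    if np.ptp(values) == 0 and 0 < target < 1:
        warnings.warn(
            "all densities equal in region; BV/TV selection falls back to "
            "the deterministic index-order tie-break",
            stacklevel=2,
        )
    flat_idx = np.flatnonzero(region.data.ravel())
    # stable sort on descending density => ties resolved by ascending index
    order = np.argsort(-values, kind="stable")
    chosen = flat_idx[order[:k]]
    mask.ravel()[chosen] = True
    achieved = k / n
    return BinaryMask(mask, density.voxel_size, density.origin), achieved


def quantify(
    labels: RemodellingLabelVolume,
    baseline_bone: BinaryMask,
    lcv: BinaryMask,
    voxel_size: float | None = None,
    params: FilterParams | None = None,
    lcv_fraction: float | None = None,
    registration_correlation: float | None = None,
) -> RemodellingResult:
    """Convert a label volume into formation/resorption metrics.

    Percentages are of the baseline bone volume within the LCV; volumes in
    mm**3 are voxel counts times voxel_size**3.
    """
    require_same_grid(labels, baseline_bone, lcv, what="quantification inputs")
    if voxel_size is None:
        voxel_size = labels.voxel_size
    denom = int((baseline_bone.data & lcv.data).sum())
    if denom == 0:
        raise ValueError("baseline bone and LCV do not intersect: empty "
                         "percentage denominator")
    counts = labels.counts()
    n_form = counts[LABEL_FORMATION]
    n_res = counts[LABEL_RESORPTION]
    vox_mm3 = float(voxel_size) ** 3
    formation_pct = 100.0 * n_form / denom
    resorption_pct = 100.0 * n_res / denom
    return RemodellingResult(
        formation_volume_mm3=n_form * vox_mm3,
        resorption_volume_mm3=n_res * vox_mm3,
        formation_pct=formation_pct,
        resorption_pct=resorption_pct,
        net_pct=formation_pct - resorption_pct,
        formation_voxels=n_form,
        resorption_voxels=n_res,
        baseline_bone_voxels=denom,
        lcv_fraction=lcv_fraction,
        registration_correlation=registration_correlation,
        threshold=params.threshold if params else None,
        min_cluster=params.min_cluster if params else None,
        connectivity=params.connectivity if params else None,
    )


def make_overlay(
    baseline_bone: BinaryMask, labels: RemodellingLabelVolume
) -> RemodellingLabelVolume:
    """Three-colour overlay: formation (green) and resorption (magenta)
    voxels drawn over the segmented baseline bone (grey), black elsewhere.

    Precedence: formation/resorption > unchanged bone > background; only
    voxels inside the LCV (label != 0) can be non-zero.
    """
    require_same_grid(baseline_bone, labels, what="overlay inputs")
    inside = labels.data != 0
    out = np.zeros(labels.data.shape, dtype=np.uint8)
    out[inside & baseline_bone.data] = LABEL_UNCHANGED
    out[labels.data == LABEL_FORMATION] = LABEL_FORMATION
    out[labels.data == LABEL_RESORPTION] = LABEL_RESORPTION
    return RemodellingLabelVolume(out, labels.voxel_size, labels.origin)


_AXES = {"axial": 0, "coronal": 1, "sagittal": 2}


def export_overlay_slices(
    overlay: RemodellingLabelVolume,
    axis: str = "axial",
    out_dir: str | os.PathLike = ".",
) -> list[Path]:
    """Write one PNG per slice with the fixed grey/green/magenta palette."""
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {sorted(_AXES)}, got {axis!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ax = _AXES[axis]
    paths = []
    for i in range(overlay.data.shape[ax]):
        sl = np.take(overlay.data, i, axis=ax)
        rgb = OVERLAY_PALETTE[sl]
        path = out_dir / f"{axis}_{i:04d}.png"
        iio.imwrite(path, rgb)
        paths.append(path)
    return paths
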