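"""Synthetic longitudinal bone phantom with ground-truth remodelling.

The phantom emulates the geometry and density regime of a distal-limb
HR-pQCT acquisition at 82 µm isotropic voxels: a cylindrical periosteal
region holding a trabecular-like network (a thresholded, smoothed Gaussian
random field hitting a target bone volume fraction) surrounded by a closed
cortical shell.  Bone sits at a nominal mineral density, background at a
soft-tissue-like density, with a one-voxel partial-volume ramp at every
interface so that registration and interpolation behave as they would on
real, band-limited scans rather than on artificially crisp binary edges.

Follow-up scans are derived from the baseline by inserting connected
formation (density gain) and resorption (density loss) events seeded on
the bone surface, each recorded voxel-by-voxel as ground truth, and then
"degrading" the result with a known rigid misalignment, white Gaussian
noise and, optionally, laterally shifted slice slabs that mimic motion
artefacts.  Everything is deterministic given the seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import (
    LABEL_FORMATION,
    LABEL_RESORPTION,
    BinaryMask,
    DensityVolume,
    RemodellingLabelVolume,
    RigidTransform3D,
    ScanMeta,
)
from .registration import resample

__all__ = [
    "PhantomSpec",
    "RemodellingEventSpec",
    "EventRecord",
    "GroundTruth",
    "Phantom",
    "NOISE_PRESETS",
    "generate_phantom",
    "apply_events",
    "degrade",
    "make_longitudinal_series",
]

#: named repeated-scan noise levels (standard deviation, mg HA/cm**3)
NOISE_PRESETS = {"hrpqct-like": 80.0, "noise-free": 0.0}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and density regime of the synthetic bone phantom."""

    shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size: float = 0.082
    bvtv: float = 0.15
    corr_length_mm: float = 0.25
    shell_thickness: int = 3
    bone_density: float = 900.0
    background_density: float = 50.0
    #: scanner-PSF-like blur (voxels); 0.8 ~ a 150 um FWHM point spread at
    #: 82 um voxels and yields the ~1-voxel partial-volume ramp of real scans
    psf_sigma_vox: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.bvtv < 1:
            raise ValueError(f"BV/TV must be in (0, 1), got {self.bvtv}")
        if self.shell_thickness < 0:
            raise ValueError("shell thickness must be >= 0")
        if min(self.shape) < 16:
            raise ValueError(f"phantom grid must be >= 16 per axis, got {self.shape}")
        if not (np.isfinite(self.bone_density) and np.isfinite(self.background_density)):
            raise ValueError("densities must be finite")


@dataclass(frozen=True)
class RemodellingEventSpec:
    """A batch of remodelling events to insert.

    kind
        "formation" (density gain growing outward from the bone surface)
        or "resorption" (density loss eating into bone).
    count
        Number of events of this batch.
    size_range
        Inclusive (min, max) voxels per event.
    magnitude
        Absolute density change per modified voxel, mg HA/cm**3.
    placement
        "bone-surface" (default) or "cortical-pore" (resorption confined
        to the cortical shell, emulating developing porosity).
    """

    kind: str
    count: int
    size_range: tuple[int, int] = (10, 30)
    magnitude: float = 500.0
    placement: str = "bone-surface"

    def __post_init__(self) -> None:
        if self.kind not in ("formation", "resorption"):
            raise ValueError(f"kind must be formation/resorption, got {self.kind!r}")
        if self.placement not in ("bone-surface", "cortical-pore"):
            raise ValueError(f"unknown placement {self.placement!r}")
        if self.size_range[0] < 1 or self.size_range[1] < self.size_range[0]:
            raise ValueError(f"bad size_range {self.size_range}")
        if not self.magnitude > 0:
            raise ValueError("magnitude must be > 0")
        if self.count < 1:
            raise ValueError("count must be >= 1")


@dataclass(frozen=True)
class EventRecord:
    kind: str
    voxels: int
    centroid: tuple[float, float, float]  # array-index coordinates


@dataclass
class GroundTruth:
    """Per-voxel and per-event bookkeeping of inserted remodelling."""

    labels: RemodellingLabelVolume
    events: list[EventRecord] = field(default_factory=list)

    @property
    def formation_voxels(self) -> int:
        return int((self.labels.data == LABEL_FORMATION).sum())

    @property
    def resorption_voxels(self) -> int:
        return int((self.labels.data == LABEL_RESORPTION).sum())

    def check_conservation(self) -> None:
        by_kind = {"formation": 0, "resorption": 0}
        for ev in self.events:
            by_kind[ev.kind] += ev.voxels
        assert by_kind["formation"] == self.formation_voxels
        assert by_kind["resorption"] == self.resorption_voxels


@dataclass
class Phantom:
    """A generated baseline scan with its masks."""

    density: DensityVolume
    periosteal: BinaryMask
    trabecular: BinaryMask
    bone: BinaryMask
    shell: BinaryMask
    spec: PhantomSpec


def _cylinder_masks(spec: PhantomSpec):
    nz, ny, nx = spec.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    r = np.hypot(yy - cy, xx - cx)
    radius = 0.46 * min(ny, nx)
    peri2d = r <= radius
    shell2d = peri2d & (r > radius - spec.shell_thickness) \
        if spec.shell_thickness > 0 else np.zeros_like(peri2d)
    trab2d = r <= radius - spec.shell_thickness - 1
    tile = lambda m: np.broadcast_to(m, (nz, ny, nx)).copy()
    return tile(peri2d), tile(shell2d), tile(trab2d)


def generate_phantom(spec: PhantomSpec = PhantomSpec()) -> Phantom:
    """Generate the baseline phantom; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    peri, shell, trab = _cylinder_masks(spec)
    if not trab.any():
        raise ValueError(
            "grid too small for the requested shell: no trabecular region left"
        )
    sigma = 0.5 * spec.corr_length_mm / spec.voxel_size
    fieldv = ndimage.gaussian_filter(rng.standard_normal(spec.shape), sigma)
    cut = np.quantile(fieldv[trab], 1.0 - spec.bvtv)
    bone = (trab & (fieldv > cut)) | shell
    if not bone.any():
        raise ValueError("requested BV/TV is unachievable on this grid")
    ramp = ndimage.gaussian_filter(bone.astype(np.float64), spec.psf_sigma_vox)
    density = spec.background_density + (
        spec.bone_density - spec.background_density
    ) * ramp
    v = spec.voxel_size
    return Phantom(
        density=DensityVolume(density, v, meta=ScanMeta(timepoint="baseline")),
        periosteal=BinaryMask(peri, v),
        trabecular=BinaryMask(trab, v),
        bone=BinaryMask(bone, v),
        shell=BinaryMask(shell, v),
        spec=spec,
    )


_N6 = ndimage.generate_binary_structure(3, 1)
_N26 = ndimage.generate_binary_structure(3, 3)


def _mark_with_buffer(occupied: np.ndarray, event: np.ndarray) -> None:
    """Mark event voxels plus a 1-voxel buffer, working on the bounding box."""
    idx = np.argwhere(event)
    lo = np.maximum(idx.min(axis=0) - 2, 0)
    hi = np.minimum(idx.max(axis=0) + 3, event.shape)
    box = tuple(slice(a, b) for a, b in zip(lo, hi))
    occupied[box] |= ndimage.binary_dilation(event[box], _N26)


def _grow_blob(seed_idx, allowed: np.ndarray, target: int,
               rng: np.random.Generator) -> np.ndarray | None:
    """Grow a 6-connected blob of ``target`` voxels inside ``allowed``."""
    shape = allowed.shape
    blob = np.zeros(shape, dtype=bool)
    blob[tuple(seed_idx)] = True
    size = 1
    offsets = [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]

    # iterative growth: keep a candidate pool of allowed neighbours
    def neighbours(p):
        for di, dj, dk in offsets:
            q = (p[0] + di, p[1] + dj, p[2] + dk)
            if 0 <= q[0] < shape[0] and 0 <= q[1] < shape[1] and 0 <= q[2] < shape[2]:
                yield q
    pool = [q for q in neighbours(tuple(seed_idx)) if allowed[q] and not blob[q]]
    while size < target:
        if not pool:
            return None
        pick = int(rng.integers(len(pool)))
        p = pool.pop(pick)
        if blob[p]:
            continue
        blob[p] = True
        size += 1
        for q in neighbours(p):
            if allowed[q] and not blob[q]:
                pool.append(q)
    return blob


def apply_events(
    phantom: Phantom,
    events: list[RemodellingEventSpec],
    seed: int = 0,
    forbidden: np.ndarray | None = None,
) -> tuple[DensityVolume, GroundTruth]:
    """Insert remodelling events into a copy of the baseline.

    Formation events add ``magnitude`` to connected background blobs
    seeded on the bone surface and growing outward; resorption events
    subtract it from blobs growing into the bone (cortical-pore placement
    stays within the shell).  Events never overlap or touch (1-voxel
    separation buffer so that detected clusters stay attributable to one
    event) and avoid any ``forbidden`` voxels (e.g. events of earlier
    intervals in a longitudinal series).  The returned ground truth
    records every modified voxel.
    """
    rng = np.random.default_rng(seed)
    spec = phantom.spec
    bone = phantom.bone.data
    peri = phantom.periosteal.data
    shell = phantom.shell.data

    followup = phantom.density.data.copy()
    gt = np.zeros(spec.shape, dtype=np.uint8)
    occupied = (np.asarray(forbidden, dtype=bool).copy()
                if forbidden is not None else np.zeros(spec.shape, dtype=bool))
    records: list[EventRecord] = []

    surface_out = peri & ~bone & ndimage.binary_dilation(bone, _N6)   # formation seeds
    surface_in = bone & ndimage.binary_dilation(~bone & peri, _N6)    # resorption seeds

    for batch in events:
        for _ in range(batch.count):
            if batch.kind == "formation":
                seeds = surface_out
                allowed = peri & ~bone
                delta, label = batch.magnitude, LABEL_FORMATION
            else:
                delta, label = -batch.magnitude, LABEL_RESORPTION
                if batch.placement == "cortical-pore":
                    seeds = shell
                    allowed = shell
                else:
                    seeds = surface_in
                    allowed = bone
            target = int(rng.integers(batch.size_range[0],
                                      batch.size_range[1] + 1))
            blob = None
            for _attempt in range(60):
                open_seeds = np.argwhere(seeds & ~occupied)
                if open_seeds.size == 0:
                    break
                seed_idx = open_seeds[int(rng.integers(len(open_seeds)))]
                blob = _grow_blob(seed_idx, allowed & ~occupied, target, rng)
                if blob is not None:
                    break
            if blob is None:
                raise ValueError(
                    f"could not place a {batch.kind} event of {target} voxels "
                    "without overlap; request fewer or smaller events"
                )
            followup[blob] += delta
            gt[blob] = label
            _mark_with_buffer(occupied, blob)
            centroid = tuple(np.argwhere(blob).mean(axis=0))
            records.append(EventRecord(batch.kind, int(blob.sum()), centroid))

    truth = GroundTruth(
        labels=RemodellingLabelVolume(gt, spec.voxel_size),
        events=records,
    )
    meta = ScanMeta(timepoint="follow-up")
    return DensityVolume(followup, spec.voxel_size, meta=meta), truth


def degrade(
    volume: DensityVolume,
    noise_sd: float = NOISE_PRESETS["hrpqct-like"],
    transform: RigidTransform3D | None = None,
    motion_slices: int = 0,
    seed: int = 0,
) -> DensityVolume:
    """Apply scan degradation: rigid misalignment, noise, motion slabs.

    The volume is first resampled (linear) under ``transform`` — the map
    from the original to the degraded scanner frame, so registering the
    result back to the original recovers the inverse — then independent
    Gaussian noise of standard deviation ``noise_sd`` is added everywhere;
    finally ``motion_slices`` randomly chosen axial slices are shifted
    laterally by 1–2 voxels to mimic stack-shift motion artefacts.
    Deterministic given ``seed``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    out = volume
    if transform is not None and not transform.is_identity():
        out = resample(volume, transform, volume.grid, mode="linear")
    data = out.data.copy()
    if noise_sd > 0:
        data += rng.normal(0.0, noise_sd, size=data.shape)
    if motion_slices > 0:
        picks = rng.choice(data.shape[0], size=min(motion_slices, data.shape[0]),
                           replace=False)
        for z in picks:
            axis = int(rng.integers(2))         # in-plane axis
            shift = int(rng.integers(1, 3)) * (1 if rng.integers(2) else -1)
            data[z] = np.roll(data[z], shift, axis=axis)
    return DensityVolume(data, volume.voxel_size, volume.origin, volume.meta)


def _random_misalignment(rng: np.random.Generator, voxel_size: float,
                         max_shift_vox: float, max_rot_deg: float,
                         center) -> RigidTransform3D:
    t = rng.uniform(-max_shift_vox, max_shift_vox, 3) * voxel_size
    a = rng.uniform(-max_rot_deg, max_rot_deg, 3)
    return RigidTransform3D.from_euler(a, t, center)


def make_longitudinal_series(
    spec: PhantomSpec,
    schedule: list[list[RemodellingEventSpec]],
    timepoints: list[str],
    seed: int = 0,
    noise_sd: float = NOISE_PRESETS["hrpqct-like"],
    max_shift_vox: float = 2.0,
    max_rot_deg: float = 1.0,
) -> tuple[Phantom, list[tuple[str, DensityVolume]], list[GroundTruth]]:
    """Simulate a multi-year series by cumulative remodelling.

    ``schedule`` holds one event list per interval (len == len(timepoints));
    events accumulate, so the ground truth at each timepoint is relative to
    the baseline.  Each follow-up is independently degraded with its own
    misalignment and noise; the baseline is returned as generated.
    Event voxels are never reused across intervals, so cumulative labels
    stay well defined.
    """
    if len(schedule) != len(timepoints):
        raise ValueError("need one event list per timepoint")
    baseline = generate_phantom(spec)
    rng = np.random.default_rng(seed)

    current = Phantom(
        density=baseline.density.copy(),
        periosteal=baseline.periosteal,
        trabecular=baseline.trabecular,
        bone=baseline.bone.copy(),
        shell=baseline.shell,
        spec=spec,
    )
    cumulative = np.zeros(spec.shape, dtype=np.uint8)
    cum_events: list[EventRecord] = []
    series: list[tuple[str, DensityVolume]] = []
    truths: list[GroundTruth] = []

    for label, events in zip(timepoints, schedule):
        if events:
            sub_seed = int(rng.integers(2**31 - 1))
            followup, truth = apply_events(
                current, events, seed=sub_seed,
                forbidden=ndimage.binary_dilation(cumulative > 0, _N26))
            # forbid event reuse: previously modified voxels are kept out by
            # updating the evolving bone occupancy
            new = truth.labels.data
            overlap = (cumulative > 0) & (new > 0)
            if overlap.any():  # pragma: no cover - buffer makes this unlikely
                raise RuntimeError("longitudinal events overlapped")
            cumulative[new > 0] = new[new > 0]
            cum_events.extend(truth.events)
            bone_now = current.bone.data.copy()
            bone_now[new == LABEL_RESORPTION] = False
            bone_now[new == LABEL_FORMATION] = True
            current = Phantom(
                density=followup,
                periosteal=current.periosteal,
                trabecular=current.trabecular,
                bone=BinaryMask(bone_now, spec.voxel_size),
                shell=current.shell,
                spec=spec,
            )
        misalign = _random_misalignment(
            rng, spec.voxel_size, max_shift_vox, max_rot_deg,
            baseline.periosteal.centroid_physical(),
        )
        degraded = degrade(
            current.density, noise_sd=noise_sd, transform=misalign,
            seed=int(rng.integers(2**31 - 1)),
        )
        degraded.meta = ScanMeta(timepoint=label)
        series.append((label, degraded))
        truths.append(GroundTruth(
            labels=RemodellingLabelVolume(cumulative.copy(), spec.voxel_size),
            events=list(cum_events),
        ))
    return baseline, series, truths
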