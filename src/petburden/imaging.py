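"""Volumetric skeletal tumor-burden index from NaF PET/CT.

The quantity computed here is a 3D analogue of the bone scan index: focal
supra-threshold uptake in an SUV volume is segmented into connected
"hotspots", hotspots overlapping the segmented axial skeleton are kept
(and, in manual mode, restricted to those classified as metastatic), and
the index is

    index_percent = 100 * skeletal_fraction * sum(hotspot volumes) / V_bone

where ``skeletal_fraction`` (default 0.33) extrapolates the segmented bones
— roughly a third of total skeletal volume — to the whole skeleton.

Conventions used throughout:

* Volumes are 3D arrays with axis 0 = superior-inferior (slowest varying)
  and axes 1-2 in-plane.  Physical geometry is axis-aligned: each volume
  carries per-axis voxel spacing (mm) and the world coordinate of the
  center of voxel (0, 0, 0).
* Hotspot volumes are measured on the PET grid; a bone mask on a different
  grid is resampled PET-ward with nearest-neighbor interpolation.
* Connected components use 26-connectivity; thresholding is strict
  (``value > threshold``) by default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger("petburden")

# --------------------------------------------------------------------------
# module-wide defaults / constants
# --------------------------------------------------------------------------

#: fully automated detection threshold (SUV units)
DEFAULT_AUTO_THRESHOLD = 15.0
#: Gaussian pre-smoothing standard deviation applied before thresholding (mm)
DEFAULT_SIGMA_MM = 2.0
#: segmented axial bones comprise ~33% of total skeletal volume
DEFAULT_SKELETAL_FRACTION = 0.33
#: plausible per-patient manual thresholds (SUV units); outside -> warning
MANUAL_THRESHOLD_RANGE = (4.0, 12.0)
#: 3D 26-connectivity structuring element for component labeling
CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)
#: Gaussian kernel truncation, in standard deviations
GAUSSIAN_TRUNCATE = 4.0

LABEL_METASTASIS = "metastasis"
LABEL_BENIGN = "benign"
LABEL_UNCLASSIFIED = "unclassified"
VALID_LABELS = (LABEL_METASTASIS, LABEL_BENIGN)


class PetburdenError(ValueError):
    """Base class for invalid inputs or parameters."""


# --------------------------------------------------------------------------
# grids and volumes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Grid:
    """Axis-aligned sampling lattice: shape, voxel spacing and world origin.

    ``origin_mm`` is the world coordinate of the center of voxel (0, 0, 0);
    voxel centers sit at ``origin + index * spacing``.
    """

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) <= 0 for n in self.shape):
            raise PetburdenError(f"grid shape must be 3 positive ints, got {self.shape}")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise PetburdenError(f"voxel spacing must be positive, got {self.spacing_mm}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        return self.origin_mm[axis] + np.arange(self.shape[axis]) * self.spacing_mm[axis]

    def index_to_world(self, index: np.ndarray) -> np.ndarray:
        """Map (N, 3) voxel indices to (N, 3) world mm coordinates."""
        idx = np.atleast_2d(np.asarray(index, dtype=float))
        return np.asarray(self.origin_mm) + idx * np.asarray(self.spacing_mm)

    def same_as(self, other: "Grid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm, atol=tol)
            and np.allclose(self.origin_mm, other.origin_mm, atol=tol)
        )


@dataclass
class ImageVolume:
    """A 3D scalar lattice with physical voxel spacing and world origin."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise PetburdenError(f"expected a 3D volume, got ndim={self.values.ndim}")
        if not np.all(np.isfinite(self.values)):
            raise PetburdenError("volume contains non-finite values")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise PetburdenError(f"voxel spacing must be positive, got {self.spacing_mm}")

    @property
    def grid(self) -> Grid:
        return Grid(tuple(self.values.shape), self.spacing_mm, self.origin_mm)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass
class SUVMap(ImageVolume):
    """Body-weight-normalized standardized-uptake-value volume (dimensionless, >= 0)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(self.values < 0):
            raise PetburdenError("SUV values must be non-negative")


@dataclass
class BoneMask(ImageVolume):
    """Binary skeletal mask; 1 = bone."""

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = np.asarray(self.values)
        uniq = np.unique(vals)
        if not np.all(np.isin(uniq, (0, 1))):
            raise PetburdenError(f"bone mask must be binary, found values {uniq[:10]}")
        self.values = vals.astype(np.uint8)

    @property
    def bone_volume_mm3(self) -> float:
        return float(np.count_nonzero(self.values)) * self.voxel_volume_mm3


# --------------------------------------------------------------------------
# hotspots
# --------------------------------------------------------------------------

@dataclass
class Hotspot:
    """One connected supra-threshold PET component.

    ``voxels`` holds the (N, 3) integer indices of member voxels on the
    source PET grid; ``volume_mm3 = voxel_count * voxel_volume``.
    """

    hotspot_id: int
    voxel_count: int
    volume_mm3: float
    peak_suv: float
    centroid_mm: tuple[float, float, float]
    overlaps_bone: bool = False
    label: str = LABEL_UNCLASSIFIED
    voxels: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]


@dataclass
class HotspotSet:
    """Ordered collection of hotspots detected on one PET grid."""

    hotspots: list[Hotspot]
    source_grid: Grid
    threshold_suv: float
    sigma_mm: float = 0.0

    def __post_init__(self) -> None:
        ids = [h.hotspot_id for h in self.hotspots]
        if len(set(ids)) != len(ids):
            raise PetburdenError("hotspot ids must be unique")
        if ids != sorted(ids):
            raise PetburdenError("hotspots must be ordered by ascending id")

    def __len__(self) -> int:
        return len(self.hotspots)

    def __iter__(self) -> Iterator[Hotspot]:
        return iter(self.hotspots)

    @property
    def ids(self) -> list[int]:
        return [h.hotspot_id for h in self.hotspots]

    @property
    def total_volume_mm3(self) -> float:
        return float(sum(h.volume_mm3 for h in self.hotspots))

    def to_dataframe(self) -> pd.DataFrame:
        """Hotspot table in the interchange CSV schema."""
        rows = [
            {
                "hotspot_id": h.hotspot_id,
                "voxel_count": h.voxel_count,
                "volume_mm3": h.volume_mm3,
                "peak_suv": h.peak_suv,
                "centroid_x_mm": h.centroid_mm[0],
                "centroid_y_mm": h.centroid_mm[1],
                "centroid_z_mm": h.centroid_mm[2],
                "overlaps_bone": h.overlaps_bone,
                "label": h.label,
            }
            for h in self.hotspots
        ]
        columns = [
            "hotspot_id", "voxel_count", "volume_mm3", "peak_suv",
            "centroid_x_mm", "centroid_y_mm", "centroid_z_mm",
            "overlaps_bone", "label",
        ]
        return pd.DataFrame(rows, columns=columns)


@dataclass
class IndexResult:
    """Computed skeletal tumor-burden index (percent) with provenance."""

    mode: str
    threshold_suv: float
    sigma_mm: float
    n_hotspots_detected: int
    n_hotspots_included: int
    total_hotspot_volume_mm3: float
    bone_volume_mm3: float
    skeletal_fraction: float
    index_percent: float

    def __post_init__(self) -> None:
        if self.n_hotspots_included > self.n_hotspots_detected:
            raise PetburdenError("included hotspot count exceeds detected count")
        expected = 100.0 * self.skeletal_fraction * (
            self.total_hotspot_volume_mm3 / self.bone_volume_mm3
        )
        if not np.isclose(self.index_percent, expected, rtol=0, atol=1e-9):
            raise PetburdenError("index_percent inconsistent with its own fields")

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "threshold_suv": self.threshold_suv,
            "sigma_mm": self.sigma_mm,
            "n_hotspots_detected": self.n_hotspots_detected,
            "n_hotspots_included": self.n_hotspots_included,
            "total_hotspot_volume_mm3": self.total_hotspot_volume_mm3,
            "bone_volume_mm3": self.bone_volume_mm3,
            "skeletal_fraction": self.skeletal_fraction,
            "index_percent": self.index_percent,
        }


# --------------------------------------------------------------------------
# operations, in pipeline order
# --------------------------------------------------------------------------

def gaussian_smooth(suv: SUVMap, sigma_mm: float) -> SUVMap:
    """Gaussian smoothing with the standard deviation given in millimeters.

    The per-axis sigma in voxel units is ``sigma_mm / spacing_mm[axis]``, so
    anisotropic grids are smoothed isotropically in physical space.  The
    kernel is truncated at 4 sigma with reflecting boundaries.  ``sigma_mm
    = 0`` returns the input values unchanged.
    """
    if sigma_mm < 0:
        raise PetburdenError(f"sigma_mm must be >= 0, got {sigma_mm}")
    if sigma_mm == 0:
        return SUVMap(suv.values.copy(), suv.spacing_mm, suv.origin_mm)
    sigma_vox = [sigma_mm / s for s in suv.spacing_mm]
    smoothed = ndimage.gaussian_filter(
        suv.values, sigma=sigma_vox, mode="reflect", truncate=GAUSSIAN_TRUNCATE
    )
    return SUVMap(smoothed, suv.spacing_mm, suv.origin_mm)


def detect_hotspots(
    suv_smoothed: SUVMap, threshold_suv: float, *, inclusive: bool = False
) -> HotspotSet:
    """Label supra-threshold voxels into 26-connected hotspots.

    Components are numbered 1..n in order of their lexicographically
    smallest member voxel (axis0, axis1, axis2), so ids are reproducible
    across runs and usable as keys in manual-label files.  Thresholding is
    strict (``> threshold``) unless ``inclusive`` is set.
    """
    if threshold_suv <= 0:
        raise PetburdenError(f"threshold_suv must be > 0, got {threshold_suv}")
    vals = suv_smoothed.values
    mask = vals >= threshold_suv if inclusive else vals > threshold_suv
    labeled, n_comp = ndimage.label(mask, structure=CONNECTIVITY_26)
    grid = suv_smoothed.grid

    if n_comp == 0:
        return HotspotSet([], grid, float(threshold_suv))

    if n_comp == 1 and int(mask.sum()) == vals.size:
        warnings.warn(
            "entire volume is supra-threshold: one hotspot spans the volume",
            stacklevel=2,
        )

    # raster-order first occurrence == lexicographic minimum voxel of each component
    flat = labeled.ravel()
    nz = np.flatnonzero(flat)
    comp_labels, first_pos = np.unique(flat[nz], return_index=True)
    order = comp_labels[np.argsort(nz[first_pos])]

    voxvol = grid.voxel_volume_mm3
    spacing = np.asarray(grid.spacing_mm)
    origin = np.asarray(grid.origin_mm)
    slices = ndimage.find_objects(labeled)

    hotspots: list[Hotspot] = []
    for new_id, lab in enumerate(order, start=1):
        sl = slices[lab - 1]
        local = labeled[sl] == lab
        idx_local = np.argwhere(local)
        offset = np.array([s.start for s in sl])
        idx = idx_local + offset
        peak = float(vals[sl][local].max())
        centroid = tuple(origin + idx.mean(axis=0) * spacing)
        hotspots.append(
            Hotspot(
                hotspot_id=new_id,
                voxel_count=int(idx.shape[0]),
                volume_mm3=float(idx.shape[0]) * voxvol,
                peak_suv=peak,
                centroid_mm=centroid,
                voxels=idx.astype(np.int32),
            )
        )
    return HotspotSet(hotspots, grid, float(threshold_suv))


def resample_mask_to_grid(mask: BoneMask, target: Grid) -> BoneMask:
    """Nearest-neighbor resampling of a binary mask onto another grid.

    Each target voxel takes the value of the source voxel whose center is
    nearest to the target voxel's world position (per-axis rounding, ties
    broken toward the higher index).  Target voxels farther than half a
    source voxel beyond the source lattice are 0.
    """
    src_grid = mask.grid
    if isinstance(target, ImageVolume):
        target = target.grid

    nearest: list[np.ndarray] = []
    inside: list[np.ndarray] = []
    for axis in range(3):
        world = target.axis_coords(axis)
        frac = (world - src_grid.origin_mm[axis]) / src_grid.spacing_mm[axis]
        idx = np.floor(frac + 0.5).astype(np.int64)
        ok = (idx >= 0) & (idx < src_grid.shape[axis])
        nearest.append(np.clip(idx, 0, src_grid.shape[axis] - 1))
        inside.append(ok)

    out = mask.values[np.ix_(nearest[0], nearest[1], nearest[2])].astype(np.uint8)
    valid = (
        inside[0][:, None, None] & inside[1][None, :, None] & inside[2][None, None, :]
    )
    out[~valid] = 0
    if not valid.any():
        warnings.warn("target grid lies entirely outside the mask extent", stacklevel=2)
    return BoneMask(out, target.spacing_mm, target.origin_mm)


def filter_by_bone_overlap(
    hotspots: HotspotSet, bone_on_pet_grid: BoneMask, *, volume_mode: str = "full"
) -> HotspotSet:
    """Drop hotspots with no overlap with the skeletal mask.

    Hotspots with at least one voxel inside the mask are kept with
    ``overlaps_bone = True``.  Under the default ``volume_mode='full'`` the
    whole component volume is retained; under ``'intersection'`` only the
    in-bone voxels count toward the volume.  Ids are preserved.
    """
    if volume_mode not in ("full", "intersection"):
        raise PetburdenError(f"volume_mode must be 'full' or 'intersection', got {volume_mode!r}")
    if not hotspots.source_grid.same_as(bone_on_pet_grid.grid):
        raise PetburdenError("bone mask grid does not match the hotspot PET grid")

    voxvol = hotspots.source_grid.voxel_volume_mm3
    bone = bone_on_pet_grid.values
    kept: list[Hotspot] = []
    for h in hotspots:
        member = bone[h.voxels[:, 0], h.voxels[:, 1], h.voxels[:, 2]] > 0
        n_in = int(member.sum())
        if n_in == 0:
            continue
        if volume_mode == "intersection":
            vox = h.voxels[member]
            kept.append(
                replace(
                    h,
                    overlaps_bone=True,
                    voxels=vox,
                    voxel_count=n_in,
                    volume_mm3=n_in * voxvol,
                )
            )
        else:
            kept.append(replace(h, overlaps_bone=True))
    return HotspotSet(kept, hotspots.source_grid, hotspots.threshold_suv, hotspots.sigma_mm)


def apply_classification(
    hotspots: HotspotSet,
    labels: Mapping[int, str] | pd.DataFrame | Sequence[tuple[int, str]],
    *,
    require_complete: bool = False,
) -> HotspotSet:
    """Attach manual metastasis/benign labels to hotspots.

    ``labels`` maps hotspot id -> label ('metastasis' or 'benign').  Ids
    absent from the hotspot set, duplicate ids, and unknown label values are
    hard errors.  Unlabeled hotspots default to 'metastasis' with a warning
    (so a labels file need only list exclusions); ``require_complete=True``
    makes missing labels an error instead.
    """
    if isinstance(labels, pd.DataFrame):
        pairs = [(int(r.hotspot_id), str(r.label)) for r in labels.itertuples()]
    elif isinstance(labels, Mapping):
        pairs = [(int(k), str(v)) for k, v in labels.items()]
    else:
        pairs = [(int(k), str(v)) for k, v in labels]

    seen: dict[int, str] = {}
    for hid, lab in pairs:
        if hid in seen:
            raise PetburdenError(f"duplicate hotspot_id in labels: {hid}")
        if lab not in VALID_LABELS:
            raise PetburdenError(
                f"invalid label {lab!r} for hotspot {hid}; expected one of {VALID_LABELS}"
            )
        seen[hid] = lab

    known = set(hotspots.ids)
    unknown = sorted(set(seen) - known)
    if unknown:
        raise PetburdenError(f"labels reference unknown hotspot ids: {unknown}")

    missing = sorted(known - set(seen))
    if missing:
        if require_complete:
            raise PetburdenError(f"missing labels for hotspot ids: {missing}")
        warnings.warn(
            f"hotspots {missing} unlabeled; treating as metastasis", stacklevel=2
        )

    relabeled = [
        replace(h, label=seen.get(h.hotspot_id, LABEL_METASTASIS)) for h in hotspots
    ]
    return HotspotSet(
        relabeled, hotspots.source_grid, hotspots.threshold_suv, hotspots.sigma_mm
    )


def compute_index(
    included: HotspotSet,
    bone_volume_mm3: float,
    skeletal_fraction: float = DEFAULT_SKELETAL_FRACTION,
    *,
    mode: str = "auto",
    sigma_mm: float | None = None,
    n_hotspots_detected: int | None = None,
) -> IndexResult:
    """Tumor-burden index percent from an included hotspot set.

    ``index_percent = 100 * skeletal_fraction * sum(v_i) / bone_volume``.
    The ``included`` set must already be restricted to hotspots that count
    (bone-overlapping and, in manual mode, metastasis-labeled).
    """
    if bone_volume_mm3 <= 0:
        raise PetburdenError(f"bone volume must be > 0, got {bone_volume_mm3}")
    if not (0 < skeletal_fraction <= 1):
        raise PetburdenError(f"skeletal_fraction must be in (0, 1], got {skeletal_fraction}")
    total = included.total_volume_mm3
    index = 100.0 * skeletal_fraction * (total / bone_volume_mm3)
    return IndexResult(
        mode=mode,
        threshold_suv=included.threshold_suv,
        sigma_mm=included.sigma_mm if sigma_mm is None else sigma_mm,
        n_hotspots_detected=len(included) if n_hotspots_detected is None else n_hotspots_detected,
        n_hotspots_included=len(included),
        total_hotspot_volume_mm3=total,
        bone_volume_mm3=float(bone_volume_mm3),
        skeletal_fraction=float(skeletal_fraction),
        index_percent=index,
    )


def baseline_bone_mask_from_ct(
    ct: ImageVolume, hu_threshold: float = 200.0, min_component_mm3: float = 500.0
) -> BoneMask:
    """Rule-based bone mask from a CT volume in Hounsfield-like units.

    Thresholds at ``HU > hu_threshold`` and removes 26-connected components
    smaller than ``min_component_mm3``.  A deliberately simple baseline for
    use when no dedicated skeletal segmentation is available.
    """
    mask = ct.values > hu_threshold
    labeled, n_comp = ndimage.label(mask, structure=CONNECTIVITY_26)
    if n_comp:
        voxvol = ct.voxel_volume_mm3
        counts = np.bincount(labeled.ravel())
        small = np.flatnonzero(counts * voxvol < min_component_mm3)
        small = small[small > 0]
        if small.size:
            mask &= ~np.isin(labeled, small)
    return BoneMask(mask.astype(np.uint8), ct.spacing_mm, ct.origin_mm)


def run_pipeline(
    suv: SUVMap,
    bone: BoneMask,
    mode: str,
    threshold_suv: float | None = None,
    sigma_mm: float = DEFAULT_SIGMA_MM,
    labels: Mapping[int, str] | pd.DataFrame | None = None,
    skeletal_fraction: float = DEFAULT_SKELETAL_FRACTION,
    volume_mode: str = "full",
    *,
    inclusive_threshold: bool = False,
    require_complete_labels: bool = False,
) -> tuple[IndexResult, HotspotSet]:
    """Full index computation: smooth -> detect -> bone filter -> (classify) -> index.

    ``mode='auto'`` uses the fixed SUV-15 threshold (no manual selection:
    every bone-overlapping hotspot is included; passing labels is an error).
    ``mode='manual'`` requires an explicit per-patient threshold (a warning
    is emitted outside the plausible range) and includes only hotspots
    classified as metastasis.  The index denominator is the bone volume of
    the mask on its native grid; overlap is evaluated after resampling the
    mask onto the PET grid.
    """
    if mode not in ("auto", "manual"):
        raise PetburdenError(f"mode must be 'auto' or 'manual', got {mode!r}")
    if mode == "auto":
        if labels is not None:
            raise PetburdenError("auto mode performs no manual selection; labels not accepted")
        threshold = DEFAULT_AUTO_THRESHOLD if threshold_suv is None else float(threshold_suv)
    else:
        if threshold_suv is None:
            raise PetburdenError("manual mode requires an explicit threshold_suv")
        threshold = float(threshold_suv)
        lo, hi = MANUAL_THRESHOLD_RANGE
        if not (lo <= threshold <= hi):
            warnings.warn(
                f"manual threshold {threshold} outside plausible range [{lo}, {hi}]",
                stacklevel=2,
            )

    bone_volume = bone.bone_volume_mm3
    if bone_volume <= 0:
        raise PetburdenError("bone mask is empty; index undefined")

    smoothed = gaussian_smooth(suv, sigma_mm)
    detected = detect_hotspots(smoothed, threshold, inclusive=inclusive_threshold)
    detected = HotspotSet(detected.hotspots, detected.source_grid, threshold, sigma_mm)
    n_detected = len(detected)

    if bone.grid.same_as(suv.grid):
        bone_on_pet = bone
    else:
        bone_on_pet = resample_mask_to_grid(bone, suv.grid)
    surviving = filter_by_bone_overlap(detected, bone_on_pet, volume_mode=volume_mode)

    if mode == "manual":
        surviving = apply_classification(
            surviving, labels if labels is not None else {},
            require_complete=require_complete_labels,
        )
        included_hotspots = [h for h in surviving if h.label == LABEL_METASTASIS]
    else:
        included_hotspots = list(surviving)

    included = HotspotSet(included_hotspots, surviving.source_grid, threshold, sigma_mm)
    result = compute_index(
        included,
        bone_volume,
        skeletal_fraction,
        mode=mode,
        sigma_mm=sigma_mm,
        n_hotspots_detected=n_detected,
    )
    logger.info(
        "pipeline %s: %d detected, %d included, index %.4f%%",
        mode, n_detected, len(included), result.index_percent,
    )
    return result, surviving
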