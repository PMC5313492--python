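"""Synthetic co-registered SUV/bone-mask phantoms with analytic ground truth.

The phantom emulates the geometry the index pipeline consumes: a PET SUV
volume with soft-tissue background near 1, skeletal background uptake well
below the automated detection threshold, and spherical plateau lesions
placed inside or outside bone regions built from ellipsoids and tubes
(finite cylinders).  Lesions are hard plateaus — not Gaussian blobs — so
the supra-threshold voxel set is exactly the digitized sphere and the
expected index is known in closed form:

    expected_index_percent = 100 * 0.33 * sum(in-bone lesion volumes) / V_bone

Digitization uses voxel-center membership throughout, matching the
pipeline's conventions.  The PET and CT grids may differ (the default CT
grid is finer) to exercise mask resampling.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .imaging import (
    BoneMask,
    DEFAULT_AUTO_THRESHOLD,
    DEFAULT_SKELETAL_FRACTION,
    Grid,
    PetburdenError,
    SUVMap,
)


# --------------------------------------------------------------------------
# geometric primitives
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid bone primitive (mm)."""

    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes_mm):
            raise PetburdenError("ellipsoid semi-axes must be positive")

    @property
    def volume_mm3(self) -> float:
        a, b, c = self.semi_axes_mm
        return 4.0 / 3.0 * math.pi * a * b * c

    def contains(self, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        cx, cy, cz = self.center_mm
        ax, ay, az = self.semi_axes_mm
        return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


@dataclass(frozen=True)
class Tube:
    """Finite-cylinder bone primitive between two axis endpoints (mm)."""

    start_mm: tuple[float, float, float]
    end_mm: tuple[float, float, float]
    radius_mm: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise PetburdenError("tube radius must be positive")
        if np.allclose(self.start_mm, self.end_mm):
            raise PetburdenError("tube endpoints must be distinct")

    @property
    def length_mm(self) -> float:
        return float(np.linalg.norm(np.subtract(self.end_mm, self.start_mm)))

    @property
    def volume_mm3(self) -> float:
        return math.pi * self.radius_mm**2 * self.length_mm

    def contains(self, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        p0 = np.asarray(self.start_mm)
        u = np.subtract(self.end_mm, self.start_mm)
        length = self.length_mm
        u = u / length
        dx, dy, dz = x - p0[0], y - p0[1], z - p0[2]
        t = dx * u[0] + dy * u[1] + dz * u[2]
        d2 = dx**2 + dy**2 + dz**2
        perp2 = d2 - t**2
        return (t >= 0) & (t <= length) & (perp2 <= self.radius_mm**2)


@dataclass(frozen=True)
class SphereLesion:
    """Spherical plateau lesion: constant SUV inside the sphere."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    suv_plateau: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise PetburdenError("lesion radius must be positive")
        if self.suv_plateau < 0:
            raise PetburdenError("lesion plateau SUV must be non-negative")

    @property
    def volume_mm3(self) -> float:
        # same product order as Ellipsoid.volume_mm3 with equal semi-axes,
        # so a sphere lesion coinciding with a sphere bone matches bit-exactly
        r = self.radius_mm
        return 4.0 / 3.0 * math.pi * r * r * r

    def contains(self, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        cx, cy, cz = self.center_mm
        return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= self.radius_mm**2


BonePrimitive = Ellipsoid | Tube


# --------------------------------------------------------------------------
# phantom specification and truth
# --------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Declarative phantom description.

    ``shape`` is the PET lattice; the CT lattice covers the same physical
    extent at ``ct_spacing_mm``.  ``bone_background_suv`` defaults to 4 —
    realistic mild skeletal NaF uptake, safely below the automated
    threshold of 15.
    """

    shape: tuple[int, int, int]
    pet_spacing_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    ct_spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    bones: Sequence[BonePrimitive] = field(default_factory=list)
    lesions: Sequence[SphereLesion] = field(default_factory=list)
    background_suv: float = 1.0
    bone_background_suv: float = 4.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(n) <= 0 for n in self.shape):
            raise PetburdenError("phantom shape must be positive")
        if self.background_suv < 0 or self.bone_background_suv < 0 or self.noise_sd < 0:
            raise PetburdenError("background levels and noise sd must be non-negative")
        if self.bone_background_suv >= DEFAULT_AUTO_THRESHOLD:
            warnings.warn(
                f"bone background SUV {self.bone_background_suv} is not below the "
                f"automated threshold {DEFAULT_AUTO_THRESHOLD}; the whole skeleton "
                "will be detected as hotspot",
                stacklevel=2,
            )
        self.shape = tuple(int(n) for n in self.shape)

    @property
    def pet_grid(self) -> Grid:
        return Grid(self.shape, tuple(self.pet_spacing_mm))

    @property
    def ct_grid(self) -> Grid:
        extent = np.asarray(self.shape) * np.asarray(self.pet_spacing_mm)
        ct_shape = tuple(int(math.ceil(e / s)) for e, s in zip(extent, self.ct_spacing_mm))
        return Grid(ct_shape, tuple(self.ct_spacing_mm))

    # -- JSON round trip ----------------------------------------------------

    def to_json(self) -> str:
        def prim(p: BonePrimitive) -> dict:
            if isinstance(p, Ellipsoid):
                return {"type": "ellipsoid", "center_mm": list(p.center_mm),
                        "semi_axes_mm": list(p.semi_axes_mm)}
            return {"type": "tube", "start_mm": list(p.start_mm),
                    "end_mm": list(p.end_mm), "radius_mm": p.radius_mm}

        payload = {
            "shape": list(self.shape),
            "pet_spacing_mm": list(self.pet_spacing_mm),
            "ct_spacing_mm": list(self.ct_spacing_mm),
            "bones": [prim(b) for b in self.bones],
            "lesions": [
                {"center_mm": list(l.center_mm), "radius_mm": l.radius_mm,
                 "suv_plateau": l.suv_plateau}
                for l in self.lesions
            ],
            "background_suv": self.background_suv,
            "bone_background_suv": self.bone_background_suv,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        d = json.loads(text)
        bones: list[BonePrimitive] = []
        for b in d.get("bones", []):
            if b["type"] == "ellipsoid":
                bones.append(Ellipsoid(tuple(b["center_mm"]), tuple(b["semi_axes_mm"])))
            elif b["type"] == "tube":
                bones.append(Tube(tuple(b["start_mm"]), tuple(b["end_mm"]), b["radius_mm"]))
            else:
                raise PetburdenError(f"unknown bone primitive type {b['type']!r}")
        lesions = [
            SphereLesion(tuple(l["center_mm"]), l["radius_mm"], l["suv_plateau"])
            for l in d.get("lesions", [])
        ]
        return cls(
            shape=tuple(d["shape"]),
            pet_spacing_mm=tuple(d.get("pet_spacing_mm", (4.0, 4.0, 4.0))),
            ct_spacing_mm=tuple(d.get("ct_spacing_mm", (2.0, 2.0, 2.0))),
            bones=bones,
            lesions=lesions,
            background_suv=d.get("background_suv", 1.0),
            bone_background_suv=d.get("bone_background_suv", 4.0),
            noise_sd=d.get("noise_sd", 0.0),
            seed=d.get("seed", 0),
        )


@dataclass
class PhantomTruth:
    """Analytic and digitized ground truth, recomputable from the spec alone."""

    lesion_volumes_mm3: list[float]           # analytic (voxel-counted if clipped)
    lesion_volumes_digitized_mm3: list[float]  # PET-grid voxel-center counts
    lesion_in_bone: list[bool]                 # lesion center inside a bone primitive
    bone_volume_mm3: float                     # analytic sum of primitive volumes
    bone_volume_digitized_mm3: float           # CT-grid voxel-center count
    expected_index_percent: float              # from analytic volumes
    expected_index_percent_digitized: float    # from digitized volumes


def _axis_center_arrays(grid: Grid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Broadcastable voxel-center world coordinates (z, y, x axes 0-2)."""
    c0 = grid.axis_coords(0)[:, None, None]
    c1 = grid.axis_coords(1)[None, :, None]
    c2 = grid.axis_coords(2)[None, None, :]
    return c0, c1, c2


def _bone_membership(grid: Grid, bones: Sequence[BonePrimitive]) -> np.ndarray:
    x, y, z = _axis_center_arrays(grid)
    mask = np.zeros(grid.shape, dtype=bool)
    for b in bones:
        mask |= np.broadcast_to(b.contains(x, y, z), grid.shape)
    return mask


def _point_in_bones(point: Sequence[float], bones: Sequence[BonePrimitive]) -> bool:
    p = [np.asarray([v], dtype=float) for v in point]
    return any(bool(b.contains(*p)[0]) for b in bones)


def _lesion_clipped(lesion: SphereLesion, grid: Grid) -> bool:
    """True when the sphere extends beyond the span of voxel centers."""
    for axis in range(3):
        lo = grid.origin_mm[axis]
        hi = grid.origin_mm[axis] + (grid.shape[axis] - 1) * grid.spacing_mm[axis]
        c = lesion.center_mm[axis]
        if c - lesion.radius_mm < lo or c + lesion.radius_mm > hi:
            return True
    return False


def compute_truth(spec: PhantomSpec) -> PhantomTruth:
    """Ground-truth volumes and expected index for a phantom spec."""
    pet = spec.pet_grid
    ct = spec.ct_grid
    x, y, z = _axis_center_arrays(pet)
    pet_voxvol = pet.voxel_volume_mm3

    lesion_vols: list[float] = []
    lesion_vols_dig: list[float] = []
    in_bone: list[bool] = []
    for lesion in spec.lesions:
        inside = np.broadcast_to(lesion.contains(x, y, z), pet.shape)
        dig = float(np.count_nonzero(inside)) * pet_voxvol
        lesion_vols_dig.append(dig)
        if _lesion_clipped(lesion, pet):
            warnings.warn(
                f"lesion at {lesion.center_mm} extends outside the lattice; "
                "using voxel-counted volume as truth",
                stacklevel=2,
            )
            lesion_vols.append(dig)
        else:
            lesion_vols.append(lesion.volume_mm3)
        in_bone.append(_point_in_bones(lesion.center_mm, spec.bones))

    bone_vol = float(sum(b.volume_mm3 for b in spec.bones))
    bone_dig = float(np.count_nonzero(_bone_membership(ct, spec.bones))) * ct.voxel_volume_mm3

    def _index(vols: Sequence[float], bone: float) -> float:
        if bone <= 0:
            return 0.0
        total = sum(v for v, ok in zip(vols, in_bone) if ok)
        return 100.0 * DEFAULT_SKELETAL_FRACTION * (total / bone)

    return PhantomTruth(
        lesion_volumes_mm3=lesion_vols,
        lesion_volumes_digitized_mm3=lesion_vols_dig,
        lesion_in_bone=in_bone,
        bone_volume_mm3=bone_vol,
        bone_volume_digitized_mm3=bone_dig,
        expected_index_percent=_index(lesion_vols, bone_vol),
        expected_index_percent_digitized=_index(lesion_vols_dig, bone_dig),
    )


def generate_phantom(spec: PhantomSpec) -> tuple[SUVMap, BoneMask, PhantomTruth]:
    """Render a phantom: SUV map on the PET grid, bone mask on the CT grid.

    Voxel SUV = max(background, bone background if the center is in a bone,
    plateau if in a lesion), plus seeded Gaussian noise clipped at zero.
    Deterministic for a fixed spec and seed.
    """
    pet = spec.pet_grid
    suv = np.full(pet.shape, float(spec.background_suv))
    bone_on_pet = _bone_membership(pet, spec.bones)
    suv[bone_on_pet] = np.maximum(suv[bone_on_pet], spec.bone_background_suv)

    x, y, z = _axis_center_arrays(pet)
    for lesion in spec.lesions:
        inside = np.broadcast_to(lesion.contains(x, y, z), pet.shape)
        suv[inside] = np.maximum(suv[inside], lesion.suv_plateau)

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        suv = np.clip(suv + rng.normal(0.0, spec.noise_sd, size=suv.shape), 0.0, None)

    ct = spec.ct_grid
    mask = _bone_membership(ct, spec.bones).astype(np.uint8)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # truth warnings already raised if relevant
        truth = compute_truth(spec)
    return (
        SUVMap(suv, pet.spacing_mm, pet.origin_mm),
        BoneMask(mask, ct.spacing_mm, ct.origin_mm),
        truth,
    )


def truth_index(
    spec: PhantomSpec,
    skeletal_fraction: float = DEFAULT_SKELETAL_FRACTION,
    *,
    digitized: bool = False,
) -> float:
    """Expected index percent for a phantom, analytic or voxel-counted."""
    truth = compute_truth(spec)
    in_bone = truth.lesion_in_bone
    if digitized:
        vols, bone = truth.lesion_volumes_digitized_mm3, truth.bone_volume_digitized_mm3
    else:
        vols, bone = truth.lesion_volumes_mm3, truth.bone_volume_mm3
    if bone <= 0:
        if any(in_bone):
            raise PetburdenError("phantom has in-bone lesions but zero bone volume")
        return 0.0
    total = sum(v for v, ok in zip(vols, in_bone) if ok)
    return 100.0 * skeletal_fraction * (total / bone)
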