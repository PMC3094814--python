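"""Digital anthropomorphic striatal phantom.

Emulates the physical basal-ganglia phantom used for dopamine-transporter
SPECT quantification studies: an ellipsoidal head with four fillable
striatal chambers (left/right caudate and putamen) inside a large uniform
"brain" background chamber, surrounded by an attenuating scalp/skull shell
that carries no activity.  Both striatal chambers on one side are filled
with the same activity concentration; the two sides may differ.  The
quantitative endpoint is the specific uptake ratio

    SUR = (striatal concentration - background concentration) / background concentration

which is known exactly from the generating concentrations and serves as the
ground truth against which reconstructed values are judged.

Label legend (integer label volume): 0 = outside the head, 1 = brain
background chamber, 2 = left striatum, 3 = right striatum, 4 = scalp shell.

Axis convention used throughout the package: axis 0 = x (left-right),
axis 1 = y (posterior-anterior, +y anterior), axis 2 = z (the tomographic
rotation axis).  Voxels are isotropic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Sequence, Tuple

import numpy as np
from scipy import ndimage

__all__ = [
    "VoxelGrid",
    "Ellipsoid",
    "PhantomSpec",
    "PhantomVolume",
    "VoiSet",
    "GeometryError",
    "build_phantom",
    "build_phantom_series",
    "default_sur_schedule",
    "define_vois",
    "true_sur",
    "LABEL_OUTSIDE",
    "LABEL_BACKGROUND",
    "LABEL_LEFT",
    "LABEL_RIGHT",
    "LABEL_SCALP",
]

LABEL_OUTSIDE = 0
LABEL_BACKGROUND = 1
LABEL_LEFT = 2
LABEL_RIGHT = 3
LABEL_SCALP = 4

LABEL_LEGEND = {
    LABEL_OUTSIDE: "outside",
    LABEL_BACKGROUND: "brain background chamber",
    LABEL_LEFT: "left striatum (caudate + putamen)",
    LABEL_RIGHT: "right striatum (caudate + putamen)",
    LABEL_SCALP: "scalp/skull shell (no activity)",
}


class GeometryError(ValueError):
    """Raised when phantom geometry is inconsistent (overlap, containment)."""


@dataclass(frozen=True)
class VoxelGrid:
    """Isotropic voxel grid; axis 2 (z) is the tomographic rotation axis."""

    shape: Tuple[int, int, int] = (64, 64, 32)
    voxel_size_mm: float = 5.9

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 8 for s in self.shape):
            raise ValueError(f"grid shape must be 3 integers >= 8, got {self.shape}")
        if not self.voxel_size_mm > 0:
            raise ValueError("voxel_size_mm must be positive")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_size_mm**3 / 1000.0

    def axis_coords_mm(self, axis: int) -> np.ndarray:
        """Voxel-centre coordinates (mm) along *axis*, origin at grid centre."""
        n = self.shape[axis]
        return (np.arange(n) - (n - 1) / 2.0) * self.voxel_size_mm

    def coordinate_arrays_mm(self):
        return np.meshgrid(
            self.axis_coords_mm(0),
            self.axis_coords_mm(1),
            self.axis_coords_mm(2),
            indexing="ij",
        )


@dataclass(frozen=True)
class Ellipsoid:
    center_mm: Tuple[float, float, float]
    semiaxes_mm: Tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semiaxes_mm):
            raise ValueError("ellipsoid semi-axes must be positive")

    def contains(self, x, y, z):
        cx, cy, cz = self.center_mm
        ax, ay, az = self.semiaxes_mm
        return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0

    @property
    def volume_ml(self) -> float:
        ax, ay, az = self.semiaxes_mm
        return 4.0 / 3.0 * np.pi * ax * ay * az / 1000.0


def _default_chambers() -> Dict[str, Ellipsoid]:
    # Caudate ~4 mL, putamen ~6 mL, at plausible stereotactic positions;
    # mirror-symmetric across the midline (x = 0).
    return {
        "left_caudate": Ellipsoid((-15.0, 22.0, 4.0), (6.5, 14.0, 11.0)),
        "right_caudate": Ellipsoid((15.0, 22.0, 4.0), (6.5, 14.0, 11.0)),
        "left_putamen": Ellipsoid((-29.0, -6.0, 0.0), (8.0, 16.0, 11.0)),
        "right_putamen": Ellipsoid((29.0, -6.0, 0.0), (8.0, 16.0, 11.0)),
    }


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters for one phantom fill.

    Concentrations are in arbitrary activity-per-mL units (nominally the
    kBq/mL scale of the physical phantom; only ratios matter downstream).
    Attenuation coefficients are in 1/cm at 159 keV.
    """

    grid: VoxelGrid = field(default_factory=VoxelGrid)
    head_semiaxes_mm: Tuple[float, float, float] = (72.0, 90.0, 58.0)
    scalp_thickness_mm: float = 11.8
    chambers: Dict[str, Ellipsoid] = field(default_factory=_default_chambers)
    background_concentration: float = 5.0
    striatal_concentration_left: float = 15.0
    striatal_concentration_right: float = 25.0
    mu_background: float = 0.15
    mu_chambers: float = 0.15
    mu_scalp: float = 0.20
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.background_concentration, self.striatal_concentration_left,
               self.striatal_concentration_right) < 0:
            raise ValueError("concentrations must be non-negative")
        if min(self.mu_background, self.mu_chambers, self.mu_scalp) < 0:
            raise ValueError("attenuation coefficients must be non-negative")
        if self.scalp_thickness_mm < 0:
            raise ValueError("scalp_thickness_mm must be non-negative")
        required = {"left_caudate", "right_caudate", "left_putamen", "right_putamen"}
        if set(self.chambers) != required:
            raise ValueError(f"chambers must be exactly {sorted(required)}")


@dataclass(frozen=True)
class PhantomVolume:
    """Rendered phantom: activity, attenuation map, labels, true SURs."""

    activity: np.ndarray
    mu_map: np.ndarray
    labels: np.ndarray
    true_sur_left: float
    true_sur_right: float
    grid: VoxelGrid
    spec: PhantomSpec

    @property
    def striatal_mask_left(self) -> np.ndarray:
        return self.labels == LABEL_LEFT

    @property
    def striatal_mask_right(self) -> np.ndarray:
        return self.labels == LABEL_RIGHT


@dataclass(frozen=True)
class VoiSet:
    """Volumes of interest defined on exactly known phantom geometry."""

    left_striatum: np.ndarray
    right_striatum: np.ndarray
    background: np.ndarray
    source: str = "labels"

    def masks(self) -> Dict[str, np.ndarray]:
        return {
            "left_striatum": self.left_striatum,
            "right_striatum": self.right_striatum,
            "background": self.background,
        }


def true_sur(striatal_concentration: float, background_concentration: float) -> float:
    """Specific uptake ratio of the generating concentrations."""
    if background_concentration <= 0:
        raise ValueError("background concentration must be positive")
    return (striatal_concentration - background_concentration) / background_concentration


def build_phantom(spec: PhantomSpec) -> PhantomVolume:
    """Voxelize the phantom onto its grid.

    A voxel belongs to a structure iff its centre lies inside the structure's
    ellipsoid, which makes voxel counts an exact oracle for total activity.
    Deterministic given the spec.
    """
    grid = spec.grid
    x, y, z = grid.coordinate_arrays_mm()

    head = Ellipsoid((0.0, 0.0, 0.0), spec.head_semiaxes_mm)
    head_mask = head.contains(x, y, z)
    if spec.scalp_thickness_mm > 0:
        outer = Ellipsoid(
            (0.0, 0.0, 0.0),
            tuple(a + spec.scalp_thickness_mm for a in spec.head_semiaxes_mm),
        )
        scalp_mask = outer.contains(x, y, z) & ~head_mask
    else:
        scalp_mask = np.zeros_like(head_mask)

    labels = np.zeros(grid.shape, dtype=np.int16)
    labels[head_mask] = LABEL_BACKGROUND
    labels[scalp_mask] = LABEL_SCALP

    claimed = np.zeros(grid.shape, dtype=bool)
    for name, ell in spec.chambers.items():
        mask = ell.contains(x, y, z)
        if not mask.any():
            raise GeometryError(f"chamber {name} renders to zero voxels on this grid")
        if (mask & ~head_mask).any():
            raise GeometryError(f"chamber {name} extends outside the head ellipsoid")
        if (mask & claimed).any():
            raise GeometryError(f"chamber {name} overlaps another chamber")
        claimed |= mask
        labels[mask] = LABEL_LEFT if name.startswith("left") else LABEL_RIGHT

    vv = grid.voxel_volume_ml
    activity = np.zeros(grid.shape, dtype=np.float64)
    activity[labels == LABEL_BACKGROUND] = spec.background_concentration * vv
    activity[labels == LABEL_LEFT] = spec.striatal_concentration_left * vv
    activity[labels == LABEL_RIGHT] = spec.striatal_concentration_right * vv

    mu_map = np.zeros(grid.shape, dtype=np.float64)
    mu_map[labels == LABEL_BACKGROUND] = spec.mu_background
    mu_map[(labels == LABEL_LEFT) | (labels == LABEL_RIGHT)] = spec.mu_chambers
    mu_map[labels == LABEL_SCALP] = spec.mu_scalp

    return PhantomVolume(
        activity=activity,
        mu_map=mu_map,
        labels=labels,
        true_sur_left=true_sur(spec.striatal_concentration_left, spec.background_concentration),
        true_sur_right=true_sur(spec.striatal_concentration_right, spec.background_concentration),
        grid=grid,
        spec=spec,
    )


def default_sur_schedule(n_acquisitions: int = 7,
                         sur_min: float = 2.08,
                         sur_max: float = 14.70) -> list[tuple[float, float]]:
    """Left/right true-SUR pairs spanning the clinically relevant range.

    2*n distinct side SURs are spread evenly over [sur_min, sur_max]; each
    acquisition pairs a low value on one side with a high value on the other,
    alternating which side carries the higher uptake.
    """
    values = np.linspace(sur_min, sur_max, 2 * n_acquisitions)
    pairs = []
    for i in range(n_acquisitions):
        lo, hi = values[i], values[2 * n_acquisitions - 1 - i]
        pairs.append((lo, hi) if i % 2 == 0 else (hi, lo))
    return [(float(a), float(b)) for a, b in pairs]


def build_phantom_series(base: PhantomSpec,
                         sur_pairs: Sequence[Tuple[float, float]] | None = None,
                         ) -> list[PhantomVolume]:
    """One phantom per requested (left, right) true-SUR pair.

    Striatal concentrations are back-solved from the SUR definition:
    conc = background * (SUR + 1).  Background concentration is held fixed
    across the series, as in repeated refills of the physical phantom.
    """
    if sur_pairs is None:
        sur_pairs = default_sur_schedule()
    volumes = []
    for left_sur, right_sur in sur_pairs:
        if left_sur <= 0 or right_sur <= 0:
            raise ValueError(f"requested SUR must be positive, got ({left_sur}, {right_sur})")
        bg = base.background_concentration
        spec = replace(
            base,
            striatal_concentration_left=bg * (left_sur + 1.0),
            striatal_concentration_right=bg * (right_sur + 1.0),
        )
        volumes.append(build_phantom(spec))
    return volumes


def define_vois(reference: PhantomVolume,
                background_box_mm: tuple[tuple[float, float], ...] | None = None,
                min_voxels: int = 20) -> VoiSet:
    """VOIs from the exactly known phantom geometry.

    The physical study defines VOIs on a CT of the phantom with air-filled
    striatal chambers; here the label field *is* that exactly registered
    geometry.  Striatal masks are the chamber labels; the background VOI is
    an axis-aligned box placed posteriorly in the brain chamber, clipped to
    the background label.

    ``background_box_mm`` is ((x_lo, x_hi), (y_lo, y_hi), (z_lo, z_hi)) in mm
    about the grid centre; the default sits in the posterior third of the
    head at mid-axial level.
    """
    labels = reference.labels
    left = labels == LABEL_LEFT
    right = labels == LABEL_RIGHT

    if background_box_mm is None:
        background_box_mm = ((-27.0, 27.0), (-72.0, -38.0), (-17.0, 17.0))

    grid = reference.grid
    coords = [grid.axis_coords_mm(a) for a in range(3)]
    box = np.ones(grid.shape, dtype=bool)
    for axis, (lo, hi) in enumerate(background_box_mm):
        sel = (coords[axis] >= lo) & (coords[axis] <= hi)
        shape = [1, 1, 1]
        shape[axis] = -1
        box &= sel.reshape(shape)
    background = box & (labels == LABEL_BACKGROUND)
    if not background.any():
        raise GeometryError("background box is empty after clipping to the brain chamber")

    striatal_dilated = ndimage.binary_dilation(left | right, iterations=2)
    if (background & striatal_dilated).any():
        raise GeometryError("background box intersects the dilated striatal chambers")

    for name, mask in (("left_striatum", left), ("right_striatum", right),
                       ("background", background)):
        if mask.sum() < min_voxels:
            raise GeometryError(f"VOI {name} has fewer than {min_voxels} voxels")

    return VoiSet(left_striatum=left, right_striatum=right, background=background,
                  source="labels")
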