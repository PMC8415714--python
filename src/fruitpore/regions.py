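"""Mesocarp risk-zone partition and fruit-core analysis.

Cork spot develops preferentially in the outer mesocarp; the package
partitions the flesh between the core surface and the skin into three
shells by normalized depth u = d_core / (d_core + d_skin): the inner
low-risk area (LRA), the middle-risk area (MRA) and the outer high-risk
area (HRA).  The core itself is extracted by gray level (it images
brighter than the flesh in healthy fruit) and its shape is quantified by
volume, solidity (volume over convex-hull volume) and sphericity
(pi^(1/3) (6V)^(2/3) / A).  When the core has no gray-level contrast —
the disordered-fruit situation — core extraction fails as a reported
outcome and a fitted geometric fallback core keeps the partition usable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks
from scipy.spatial import ConvexHull
from skimage.measure import marching_cubes, mesh_surface_area

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)

CORE, LRA, MRA, HRA = 1, 2, 3, 4  # partition label codes (0 = background)


class CoreNotSeparableError(RuntimeError):
    """The core has no gray-level contrast against the flesh."""


@dataclass
class RegionPartition:
    """Disjoint core/LRA/MRA/HRA masks covering the fruit mask.

    ``labels`` uses codes 0 background, 1 core, 2 LRA, 3 MRA, 4 HRA.
    """

    labels: np.ndarray  # uint8
    boundary_fractions: tuple[float, float]
    voxel_size_um: float

    def mask(self, code: int) -> np.ndarray:
        return self.labels == code

    @property
    def core_mask(self) -> np.ndarray:
        return self.labels == CORE


@dataclass
class CoreShape:
    """Shape metrics of the extracted core."""

    volume_mm3: float
    solidity: float
    sphericity: float


def extract_core(vol, fruit_mask: np.ndarray) -> np.ndarray:
    """Extract the core as the bright central structure of the fruit.

    The gray-level histogram restricted to the central third of the
    fruit's bounding box is searched for a mode brighter than the
    dominant (flesh) mode; the threshold is the deepest valley between
    the two, and voxels above it form core candidates.  The candidate
    component containing (or nearest to) the fruit centroid is kept and
    closed morphologically (radius 2).

    Raises
    ------
    CoreNotSeparableError
        When the central histogram has no two modes (no gray-level
        contrast between core and flesh).
    """
    if not fruit_mask.any():
        raise ValueError("empty fruit mask")
    arr = vol.intensities
    idx = np.argwhere(fruit_mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    third_lo = lo + (hi - lo) // 3
    third_hi = lo + 2 * (hi - lo) // 3
    central = np.zeros_like(fruit_mask)
    central[third_lo[0]:third_hi[0], third_lo[1]:third_hi[1], third_lo[2]:third_hi[2]] = True
    central &= fruit_mask
    if not central.any():
        raise CoreNotSeparableError("central region of the fruit is empty")

    vals = arr[central]
    edges = np.arange(257, dtype=float) - 0.5 if vol.bit_depth == 8 else np.linspace(-0.5, 65535.5, 1025)
    counts, edges = np.histogram(vals, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    kernel = np.ones(9) / 9.0
    smooth = np.convolve(counts.astype(float), kernel, mode="same")

    # the flesh is the dominant gray mode; the core must form a distinct
    # mode brighter than it, else there is no gray-level contrast
    peaks, _ = find_peaks(smooth, prominence=0.02 * smooth.max())
    if len(peaks) == 0:
        peaks = np.array([int(np.argmax(smooth))])
    dominant = peaks[int(np.argmax(smooth[peaks]))]
    brighter = peaks[peaks > dominant]
    if len(brighter) == 0:
        raise CoreNotSeparableError(
            "core not separable by grayscale: no mode brighter than the flesh "
            "in the central region"
        )
    core_mode = brighter[int(np.argmax(smooth[brighter]))]
    between = smooth[dominant + 1 : core_mode]
    if len(between) == 0:
        raise CoreNotSeparableError("core and flesh modes are adjacent; no valley")
    threshold = float(centers[dominant + 1 + int(np.argmin(between))])

    bright = fruit_mask & central & (arr > threshold)
    if not bright.any():
        raise CoreNotSeparableError("no voxels above the core threshold")
    labels, n = ndimage.label(bright, structure=_STRUCT_26)
    centroid = idx.mean(axis=0)
    c = tuple(np.round(centroid).astype(int))
    chosen = labels[c]
    if chosen == 0:
        # nearest component to the fruit centroid
        comp_idx = np.argwhere(labels > 0)
        nearest = comp_idx[np.argmin(((comp_idx - centroid) ** 2).sum(axis=1))]
        chosen = labels[tuple(nearest)]
    core = labels == chosen
    core = ndimage.binary_closing(
        core, structure=ndimage.generate_binary_structure(3, 1), iterations=2
    )
    return core & fruit_mask


def fallback_core(fruit_mask: np.ndarray, scale: float = 0.25) -> np.ndarray:
    """Geometric fallback core: central ellipsoid fitted to the fruit mask.

    Used when gray-level core extraction fails (no contrast); the
    ellipsoid has the fruit's per-axis half-extents scaled by ``scale``
    and is centered on the fruit centroid.
    """
    idx = np.argwhere(fruit_mask)
    centroid = idx.mean(axis=0)
    half_extent = (idx.max(axis=0) - idx.min(axis=0) + 1) / 2.0
    semi = np.maximum(half_extent * scale, 1.0)
    zz, yy, xx = np.ogrid[: fruit_mask.shape[0], : fruit_mask.shape[1], : fruit_mask.shape[2]]
    ell = (
        ((zz - centroid[0]) / semi[0]) ** 2
        + ((yy - centroid[1]) / semi[1]) ** 2
        + ((xx - centroid[2]) / semi[2]) ** 2
    ) <= 1.0
    return ell & fruit_mask


def partition_mesocarp(
    fruit_mask: np.ndarray,
    core_mask: np.ndarray,
    voxel_size_um: float,
    fractions: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0),
) -> RegionPartition:
    """Split the mesocarp into LRA/MRA/HRA shells by normalized depth.

    For each mesocarp voxel, u = d_core / (d_core + d_skin) with d_core
    the distance to the core surface and d_skin the distance to the
    outside of the fruit; u < f1 is LRA, f1 <= u < f2 is MRA, the rest
    HRA.  For concentric spheres u is linear in radius, so the default
    fractions give equal-thickness shells.
    """
    f1, f2 = fractions
    if not (0.0 < f1 < f2 < 1.0):
        raise ValueError(f"fractions must satisfy 0 < f1 < f2 < 1, got {fractions}")
    if not core_mask.any():
        raise ValueError("empty core mask")
    if (core_mask & ~fruit_mask).any():
        raise ValueError("core must lie strictly inside the fruit mask")

    d_core = ndimage.distance_transform_edt(~core_mask)
    outside = ~np.pad(fruit_mask, 1, constant_values=False)
    d_skin = ndimage.distance_transform_edt(~outside)[1:-1, 1:-1, 1:-1]

    meso = fruit_mask & ~core_mask
    denom = d_core + d_skin
    denom[denom == 0] = 1.0
    u = d_core / denom

    labels = np.zeros(fruit_mask.shape, dtype=np.uint8)
    labels[core_mask] = CORE
    labels[meso & (u < f1)] = LRA
    labels[meso & (u >= f1) & (u < f2)] = MRA
    labels[meso & (u >= f2)] = HRA
    return RegionPartition(labels=labels, boundary_fractions=(f1, f2), voxel_size_um=voxel_size_um)


def core_shape_metrics(core_mask: np.ndarray, voxel_size_um: float) -> CoreShape:
    """Volume, solidity and sphericity of a core mask.

    Solidity is voxel volume over the convex hull volume of voxel
    centers, clamped at 1 (digitization can push the raw ratio
    marginally above 1 for convex bodies).  The surface area in the
    sphericity uses a marching-cubes mesh, which tracks the true area of
    smooth bodies closely enough that digitized balls stay at or below 1.
    """
    core_mask = np.asarray(core_mask, dtype=bool)
    if not core_mask.any():
        raise ValueError("empty core mask")
    n = int(core_mask.sum())
    volume_um3 = n * voxel_size_um**3

    pts = np.argwhere(core_mask).astype(float)
    if n >= 4 and not np.allclose(pts.min(axis=0), pts.max(axis=0)):
        try:
            hull = ConvexHull(pts)
            hull_vol_um3 = hull.volume * voxel_size_um**3
            solidity = min(volume_um3 / hull_vol_um3, 1.0) if hull_vol_um3 > 0 else 1.0
        except Exception:
            solidity = 1.0
    else:
        solidity = 1.0

    padded = np.pad(core_mask, 1, constant_values=False).astype(np.uint8)
    verts, faces, _, _ = marching_cubes(padded, level=0.5)
    area_um2 = mesh_surface_area(verts, faces) * voxel_size_um**2
    sphericity = np.pi ** (1.0 / 3.0) * (6.0 * volume_um3) ** (2.0 / 3.0) / area_um2
    return CoreShape(
        volume_mm3=volume_um3 * 1e-9, solidity=float(solidity), sphericity=float(sphericity)
    )
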