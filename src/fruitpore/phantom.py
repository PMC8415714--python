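"""Synthetic fruit phantoms with exact pore-phase ground truth.

A phantom is a fruit-shaped (ellipsoidal) or slab-shaped tissue matrix
containing a placed population of pore objects, rendered to a noisy
8-bit grayscale volume with a bimodal intensity histogram (dark pores,
bright tissue), optionally with a denser core.  Because the true phase
of every voxel and the parameters of every placed pore are known, each
pipeline stage (masking, thresholding, labeling, morphometry, skeleton
extraction) can be validated quantitatively without real scans.

Named presets encode the study conditions the package targets: whole
fruit at 79.4 um voxels with porosities of 3.52 % (healthy) and 9.37 %
(cork-spotted, U-shaped axial pore density), mesocarp risk zones at
1 % / 5 % / 20 %, and flesh pieces at 2 um voxels with monodisperse
22 um (healthy) or 87 um (cork-spotted) pores.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from fruitpore.segmentation import BACKGROUND, TISSUE, PORE
from fruitpore.volume_io import VoxelVolume


class GenerationError(RuntimeError):
    """Raised when a placement target cannot be reached (e.g. non-overlap exhaustion)."""


@dataclass
class CoreSpec:
    """Denser central core: an ellipsoid rendered brighter than the flesh."""

    semi_axes_um: tuple[float, float, float]
    center_offset_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    intensity_offset: float = 40.0


@dataclass
class PhantomSpec:
    """Parameters of a synthetic fruit volume.

    Exactly one of ``porosity_percent`` / ``count_density_per_mm3`` sets
    the placement target.  ``diameter_sigma_log = 0`` gives fixed-diameter
    pores; otherwise diameters are lognormal with the given median and
    log-standard-deviation.  ``fruit_semi_axes_um = None`` means the
    tissue fills the whole grid (a cut flesh piece rather than a whole
    fruit).  Intensities are on the 8-bit scale; pores must render darker
    than tissue.
    """

    grid_shape: tuple[int, int, int]
    voxel_size_um: float
    fruit_semi_axes_um: tuple[float, float, float] | None = None
    core: CoreSpec | None = None
    porosity_percent: float | None = None
    count_density_per_mm3: float | None = None
    diameter_um: float = 240.0
    diameter_sigma_log: float = 0.0
    axial_profile: str = "constant"  # constant | u_shaped | linear
    tissue_mean: float = 160.0
    pore_mean: float = 30.0
    air_mean: float = 10.0
    noise_sd: float = 8.0
    allow_overlap: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or min(self.grid_shape) < 1:
            raise ValueError(f"grid_shape must be three positive ints, got {self.grid_shape}")
        if not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be positive")
        if not self.pore_mean < self.tissue_mean:
            raise ValueError("pores must be darker than tissue (pore_mean < tissue_mean)")
        n_targets = (self.porosity_percent is not None) + (self.count_density_per_mm3 is not None)
        if n_targets != 1:
            raise ValueError("exactly one of porosity_percent / count_density_per_mm3 must be set")
        if self.porosity_percent is not None and not 0 <= self.porosity_percent < 50:
            raise ValueError(f"porosity_percent must lie in [0, 50), got {self.porosity_percent}")
        if self.diameter_um < self.voxel_size_um:
            raise ValueError("pore diameter must be at least one voxel")
        if self.axial_profile not in ("constant", "u_shaped", "linear"):
            raise ValueError(f"unknown axial_profile {self.axial_profile!r}")


@dataclass
class TruthSkeleton:
    """True centerlines of a tube phantom: segment polylines plus node sets."""

    segments: list[tuple[tuple[float, float, float], tuple[float, float, float], float]]
    junction_points: list[tuple[float, float, float]]
    endpoint_points: list[tuple[float, float, float]]
    n_components: int
    total_length_um: float


@dataclass
class GroundTruth:
    """Emitted truth of a phantom: phase labels, per-pore table, optional skeleton."""

    phase_map: np.ndarray  # uint8: 0 background, 1 tissue, 2 pore
    voxel_size_um: float
    pore_table: pd.DataFrame | None
    true_porosity_percent: float
    core_mask: np.ndarray | None = None
    skeleton: TruthSkeleton | None = None

    @property
    def fruit_mask(self) -> np.ndarray:
        return self.phase_map != BACKGROUND

    @property
    def pore_mask(self) -> np.ndarray:
        return self.phase_map == PORE


def _ellipsoid_mask(
    grid_shape: tuple[int, int, int],
    semi_axes_vox: tuple[float, float, float],
    center_vox: tuple[float, float, float],
) -> np.ndarray:
    # voxel-center-inside rule: voxel (i,j,k) belongs iff its center is inside
    zz, yy, xx = np.ogrid[: grid_shape[0], : grid_shape[1], : grid_shape[2]]
    az, ay, ax = semi_axes_vox
    cz, cy, cx = center_vox
    return ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _axial_weights(z: np.ndarray, nz: int, profile: str) -> np.ndarray:
    t = (z + 0.5) / nz  # normalized axial position in (0, 1)
    if profile == "constant":
        return np.ones_like(t, dtype=float)
    if profile == "u_shaped":
        # ends ~4x the middle: reproduces elevated porosity at calyx/stem ends
        return 1.0 + 3.0 * (2.0 * (t - 0.5)) ** 2
    if profile == "linear":
        return 0.5 + t
    raise ValueError(profile)


def _fruit_and_core(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray | None]:
    shape = tuple(spec.grid_shape)
    if spec.fruit_semi_axes_um is None:
        fruit = np.ones(shape, dtype=bool)
    else:
        semi_vox = tuple(a / spec.voxel_size_um for a in spec.fruit_semi_axes_um)
        center = tuple((n - 1) / 2.0 for n in shape)
        fruit = _ellipsoid_mask(shape, semi_vox, center)
        if not fruit.any():
            raise GenerationError("fruit ellipsoid contains no voxels on this grid")
    core = None
    if spec.core is not None:
        semi_vox = tuple(max(a / spec.voxel_size_um, 1.0) for a in spec.core.semi_axes_um)
        center = tuple(
            (n - 1) / 2.0 + off / spec.voxel_size_um
            for n, off in zip(shape, spec.core.center_offset_um)
        )
        core = _ellipsoid_mask(shape, semi_vox, center) & fruit
    return fruit, core


def _paint_sphere(
    phase: np.ndarray, center: np.ndarray, r_vox: float
) -> tuple[int, int, np.ndarray]:
    """Set voxels with centers inside the sphere to PORE.

    Returns (object voxel count, newly converted count, centroid in voxel
    coordinates).
    """
    lo = np.maximum(np.floor(center - r_vox).astype(int), 0)
    hi = np.minimum(np.ceil(center + r_vox).astype(int) + 1, phase.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    zz, yy, xx = np.ogrid[sl[0], sl[1], sl[2]]
    inside = (
        (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    ) <= r_vox**2
    sub = phase[sl]
    total = int(np.count_nonzero(inside))
    if total == 0:
        return 0, 0, center
    new = int(np.count_nonzero(inside & (sub != PORE)))
    sub[inside] = PORE
    idx = np.nonzero(inside)
    centroid = np.array(
        [idx[0].mean() + lo[0], idx[1].mean() + lo[1], idx[2].mean() + lo[2]]
    )
    return total, new, centroid


def _render(spec: PhantomSpec, phase: np.ndarray, core: np.ndarray | None,
            rng: np.random.Generator) -> np.ndarray:
    img = np.full(phase.shape, spec.air_mean, dtype=np.float64)
    img[phase == TISSUE] = spec.tissue_mean
    img[phase == PORE] = spec.pore_mean
    if core is not None and spec.core is not None:
        img[core & (phase == TISSUE)] = spec.tissue_mean + spec.core.intensity_offset
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=phase.shape)
    return np.floor(np.clip(img, 0, 255) + 0.5).astype(np.uint8)


def generate_phantom(spec: PhantomSpec) -> tuple[VoxelVolume, GroundTruth]:
    """Generate a fruit phantom and its ground truth.

    Pore centers are drawn from the fruit interior with the axial profile
    weighting; diameters from the configured distribution.  Placement
    stops once the target (pore-voxel fraction, or object count derived
    from the count density) is met to within half of one object's
    expected contribution.  Identical spec + seed give bit-identical
    output.

    Raises
    ------
    GenerationError
        If the target is not reached within 10x the expected number of
        placements (e.g. non-overlap exhaustion).
    """
    rng = np.random.default_rng(spec.seed)
    fruit, core = _fruit_and_core(spec)
    phase = np.where(fruit, TISSUE, BACKGROUND).astype(np.uint8)
    n_fruit = int(fruit.sum())

    # depth to the nearest non-fruit voxel (grid border counts as outside)
    padded = np.pad(fruit, 1, constant_values=False)
    depth = ndimage.distance_transform_edt(padded)[1:-1, 1:-1, 1:-1]

    eligible = fruit if core is None else (fruit & ~core)
    coords = np.argwhere(eligible)
    if len(coords) == 0:
        raise GenerationError("no eligible voxels for pore placement")
    weights = _axial_weights(coords[:, 0].astype(float), spec.grid_shape[0], spec.axial_profile)
    cdf = np.cumsum(weights)
    depth_at = depth[tuple(coords.T)]

    median_vox = spec.diameter_um / spec.voxel_size_um
    sigma = spec.diameter_sigma_log
    mean_obj_vox = (np.pi / 6.0) * median_vox**3 * np.exp(4.5 * sigma**2)

    if spec.porosity_percent is not None:
        target_vox = spec.porosity_percent / 100.0 * n_fruit
        n_target_objects = None
        expected_placements = max(1, int(np.ceil(target_vox / mean_obj_vox)))
    else:
        region_mm3 = n_fruit * (spec.voxel_size_um * 1e-3) ** 3
        n_target_objects = int(round(spec.count_density_per_mm3 * region_mm3))
        target_vox = None
        expected_placements = max(1, n_target_objects)

    max_attempts = max(10 * expected_placements, 100)
    placed_centers: list[np.ndarray] = []
    placed_radii: list[float] = []
    rows: list[dict] = []
    pore_vox = 0
    attempts = 0

    def done() -> bool:
        if target_vox is not None:
            return pore_vox >= target_vox - mean_obj_vox / 2.0
        return len(rows) >= n_target_objects

    while not done():
        attempts += 1
        if attempts > max_attempts:
            raise GenerationError(
                f"placement target not reached after {max_attempts} attempts "
                f"({len(rows)} objects, porosity {100 * pore_vox / n_fruit:.2f}%); "
                "constraint: "
                + ("non-overlap exhaustion" if not spec.allow_overlap else "fruit interior too small")
            )
        idx = int(np.searchsorted(cdf, rng.random() * cdf[-1]))
        d_vox = median_vox if sigma == 0 else median_vox * np.exp(sigma * rng.standard_normal())
        r_vox = max(d_vox / 2.0, 0.5)
        center = coords[idx] + rng.uniform(-0.5, 0.5, size=3)
        # margin of 2 voxels: one for the sub-voxel center jitter, one so the
        # object never touches the fruit surface (keeps pores hole-fillable)
        if depth_at[idx] < r_vox + 2.0:
            continue
        if not spec.allow_overlap and placed_centers:
            centers = np.asarray(placed_centers)
            radii = np.asarray(placed_radii)
            gap = np.sqrt(((centers - center) ** 2).sum(axis=1)) - (radii + r_vox)
            if gap.min() < 1.5:  # keep a >1-voxel moat so objects never 26-touch
                continue
        total, new, centroid = _paint_sphere(phase, center, r_vox)
        if total == 0:
            continue
        placed_centers.append(center)
        placed_radii.append(r_vox)
        vol_um3 = total * spec.voxel_size_um**3
        rows.append(
            {
                "id": len(rows) + 1,
                "voxel_count": total,
                "volume_um3": vol_um3,
                "d_eq_um": (6.0 * vol_um3 / np.pi) ** (1.0 / 3.0),
                "centroid_z_um": (centroid[0] + 0.5) * spec.voxel_size_um,
                "centroid_y_um": (centroid[1] + 0.5) * spec.voxel_size_um,
                "centroid_x_um": (centroid[2] + 0.5) * spec.voxel_size_um,
                "nominal_diameter_um": d_vox * spec.voxel_size_um,
            }
        )
        pore_vox += new

    img = _render(spec, phase, core, rng)
    table = pd.DataFrame(
        rows,
        columns=[
            "id",
            "voxel_count",
            "volume_um3",
            "d_eq_um",
            "centroid_z_um",
            "centroid_y_um",
            "centroid_x_um",
            "nominal_diameter_um",
        ],
    )
    truth = GroundTruth(
        phase_map=phase,
        voxel_size_um=spec.voxel_size_um,
        pore_table=table,
        true_porosity_percent=100.0 * pore_vox / n_fruit,
        core_mask=core,
    )
    vol = VoxelVolume(
        img, spec.voxel_size_um, provenance=f"synthetic phantom, seed {spec.seed}"
    )
    return vol, truth


# ---------------------------------------------------------------------------
# tube phantoms: capsule unions with known centerlines, for skeleton tests
# ---------------------------------------------------------------------------


def _paint_capsule(phase: np.ndarray, p0: np.ndarray, p1: np.ndarray, r: float) -> None:
    lo = np.maximum(np.floor(np.minimum(p0, p1) - r).astype(int), 0)
    hi = np.minimum(np.ceil(np.maximum(p0, p1) + r).astype(int) + 1, phase.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    zz, yy, xx = np.meshgrid(
        np.arange(sl[0].start, sl[0].stop),
        np.arange(sl[1].start, sl[1].stop),
        np.arange(sl[2].start, sl[2].stop),
        indexing="ij",
    )
    pts = np.stack([zz, yy, xx], axis=-1).astype(float)
    axis = p1 - p0
    length2 = float(axis @ axis)
    t = np.clip(((pts - p0) @ axis) / length2, 0.0, 1.0)
    nearest = p0 + t[..., None] * axis
    dist2 = ((pts - nearest) ** 2).sum(axis=-1)
    phase[sl][dist2 <= r**2] = PORE


def generate_tube_phantom(
    segments: list[tuple[tuple[float, float, float], tuple[float, float, float], float]],
    grid_shape: tuple[int, int, int],
    voxel_size_um: float = 1.0,
    intensity: PhantomSpec | None = None,
    seed: int = 0,
) -> tuple[VoxelVolume, GroundTruth]:
    """Generate a tube phantom: a union of capsules with a known skeleton.

    Each segment is ``(start, end, radius)`` in voxel coordinates (radius
    in voxels); the pore phase is the union of the capsules (cylinders
    with hemispherical caps).  The returned truth skeleton is the given
    polylines with junctions at points shared by >= 3 segment ends and
    endpoints at points used once.
    """
    segs = []
    for p0, p1, r in segments:
        p0 = np.asarray(p0, dtype=float)
        p1 = np.asarray(p1, dtype=float)
        if np.allclose(p0, p1):
            raise ValueError(f"zero-length segment at {tuple(p0)}")
        if r <= 0:
            raise ValueError("segment radius must be positive")
        segs.append((p0, p1, float(r)))

    phase = np.full(tuple(grid_shape), TISSUE, dtype=np.uint8)
    for p0, p1, r in segs:
        _paint_capsule(phase, p0, p1, r)

    # node bookkeeping on exact endpoint coordinates
    ends: dict[tuple, int] = {}
    for p0, p1, _ in segs:
        for p in (tuple(p0), tuple(p1)):
            ends[p] = ends.get(p, 0) + 1
    junctions = [p for p, k in ends.items() if k >= 3]
    endpoints = [p for p, k in ends.items() if k == 1]

    # connected components of the segment graph (shared endpoints merge)
    parent = list(range(len(segs)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    keys = [(tuple(p0), tuple(p1)) for p0, p1, _ in segs]
    for i in range(len(segs)):
        for j in range(i + 1, len(segs)):
            if set(keys[i]) & set(keys[j]):
                pi, pj = find(i), find(j)
                if pi != pj:
                    parent[pi] = pj
    n_components = len({find(i) for i in range(len(segs))})

    total_len = sum(float(np.linalg.norm(p1 - p0)) for p0, p1, _ in segs) * voxel_size_um
    skel = TruthSkeleton(
        segments=[(tuple(p0), tuple(p1), r * voxel_size_um) for p0, p1, r in segs],
        junction_points=junctions,
        endpoint_points=endpoints,
        n_components=n_components,
        total_length_um=total_len,
    )

    ispec = intensity or PhantomSpec(
        grid_shape=tuple(grid_shape), voxel_size_um=voxel_size_um, porosity_percent=0.0
    )
    rng = np.random.default_rng(seed)
    img = _render(ispec, phase, None, rng)
    truth = GroundTruth(
        phase_map=phase,
        voxel_size_um=voxel_size_um,
        pore_table=None,
        true_porosity_percent=100.0 * float((phase == PORE).mean()),
        skeleton=skel,
    )
    vol = VoxelVolume(img, voxel_size_um, provenance=f"synthetic tube phantom, seed {seed}")
    return vol, truth


# ---------------------------------------------------------------------------
# presets: the study conditions, fixed once
# ---------------------------------------------------------------------------

#: Named phantom presets.  Whole-fruit presets use 79.4 um voxels on a
#: 128^3 grid (a reduced-extent whole fruit); flesh presets use 2 um
#: voxels.  Targets are the porosities / pore diameters the conditions
#: represent: healthy vs cork-spotted whole fruit (3.52 / 9.37 %),
#: mesocarp risk zones (1 / 5 / 20 %), flesh pieces (22 / 87 um pores).
PRESETS: dict[str, dict] = {
    "healthy_whole": dict(
        grid_shape=(128, 128, 128),
        voxel_size_um=79.4,
        fruit_semi_axes_um=(60 * 79.4, 55 * 79.4, 55 * 79.4),
        porosity_percent=3.52,
        diameter_um=240.0,
        diameter_sigma_log=0.35,
        axial_profile="constant",
        allow_overlap=True,
    ),
    "corkspot_whole": dict(
        grid_shape=(128, 128, 128),
        voxel_size_um=79.4,
        fruit_semi_axes_um=(60 * 79.4, 55 * 79.4, 55 * 79.4),
        porosity_percent=9.37,
        diameter_um=260.0,
        diameter_sigma_log=0.35,
        axial_profile="u_shaped",
        allow_overlap=True,
    ),
    "healthy_mesocarp": dict(
        grid_shape=(96, 96, 96),
        voxel_size_um=79.4,
        fruit_semi_axes_um=None,
        porosity_percent=1.0,
        diameter_um=240.0,
        diameter_sigma_log=0.35,
        axial_profile="constant",
        allow_overlap=True,
    ),
    "mra_corkspot": dict(
        grid_shape=(96, 96, 96),
        voxel_size_um=79.4,
        fruit_semi_axes_um=None,
        porosity_percent=5.0,
        diameter_um=260.0,
        diameter_sigma_log=0.35,
        axial_profile="constant",
        allow_overlap=True,
    ),
    "hra_corkspot": dict(
        grid_shape=(96, 96, 96),
        voxel_size_um=79.4,
        fruit_semi_axes_um=None,
        porosity_percent=20.0,
        diameter_um=300.0,
        diameter_sigma_log=0.35,
        axial_profile="constant",
        allow_overlap=True,
    ),
    "healthy_flesh": dict(
        grid_shape=(192, 192, 192),
        voxel_size_um=2.0,
        fruit_semi_axes_um=None,
        porosity_percent=5.0,
        diameter_um=22.0,
        diameter_sigma_log=0.0,
        axial_profile="constant",
        allow_overlap=False,
    ),
    "corkspot_flesh": dict(
        grid_shape=(224, 224, 224),
        voxel_size_um=2.0,
        fruit_semi_axes_um=None,
        porosity_percent=8.0,
        diameter_um=87.0,
        diameter_sigma_log=0.0,
        axial_profile="constant",
        allow_overlap=False,
    ),
}


def preset_spec(name: str, seed: int = 0) -> PhantomSpec:
    """Build the PhantomSpec for a named preset with the given seed."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return PhantomSpec(seed=seed, **PRESETS[name])


def spec_to_yaml(spec: PhantomSpec, path: str | Path) -> None:
    d = dataclasses.asdict(spec)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def spec_from_yaml(path: str | Path) -> PhantomSpec:
    d = yaml.safe_load(Path(path).read_text())
    if d.get("core") is not None:
        d["core"] = CoreSpec(
            semi_axes_um=tuple(d["core"]["semi_axes_um"]),
            center_offset_um=tuple(d["core"].get("center_offset_um", (0, 0, 0))),
            intensity_offset=float(d["core"].get("intensity_offset", 40.0)),
        )
    d["grid_shape"] = tuple(d["grid_shape"])
    if d.get("fruit_semi_axes_um") is not None:
        d["fruit_semi_axes_um"] = tuple(d["fruit_semi_axes_um"])
    return PhantomSpec(**d)
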