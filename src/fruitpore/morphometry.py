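"""Per-pore labeling and morphometric statistics.

Pores are connected components of the pore phase; two pore voxels are
connected when they share a face, an edge, or a corner (26-connectivity;
6-connectivity available for sensitivity checks).  Each pore gets a
volume, an equivalent-sphere diameter d_eq = (6 V / pi)^(1/3), and a
centroid.  Sample-level statistics are the pore count per mm^3, the
unweighted (optionally volume-weighted) mean d_eq, a pore-size class
histogram, the porosity (pore volume fraction, percent), and the axial
porosity profile from the calyx end to the stem end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from fruitpore.segmentation import PhaseMap

_STRUCTS = {
    26: np.ones((3, 3, 3), dtype=bool),
    6: ndimage.generate_binary_structure(3, 1),
}


@dataclass
class PoreLabelMap:
    """Dense per-voxel pore ids (0 = not pore) under a stated connectivity."""

    labels: np.ndarray  # int32
    n_pores: int
    connectivity: int
    voxel_size_um: float


def label_pores(phase: PhaseMap, connectivity: int = 26) -> PoreLabelMap:
    """Label 26- (or 6-)connected components of the pore phase.

    Ids are 1..K, ordered by ascending first-voxel linear index (the
    raster order scipy's labeling produces), so output is deterministic.
    """
    if connectivity not in _STRUCTS:
        raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")
    labels, n = ndimage.label(phase.pore_mask, structure=_STRUCTS[connectivity])
    return PoreLabelMap(
        labels=labels.astype(np.int32),
        n_pores=int(n),
        connectivity=connectivity,
        voxel_size_um=phase.voxel_size_um,
    )


def build_pore_table(labels: PoreLabelMap) -> pd.DataFrame:
    """Per-pore table: id, voxel count, volume (um^3), d_eq (um), centroid (um).

    The centroid is the mean of voxel centers; voxel index i has its
    center at (i + 0.5) * voxel_size_um.
    """
    lab = labels.labels
    k = labels.n_pores
    if k == 0:
        return pd.DataFrame(
            columns=[
                "id", "voxel_count", "volume_um3", "d_eq_um",
                "centroid_z_um", "centroid_y_um", "centroid_x_um",
            ]
        )
    ids = np.arange(1, k + 1)
    counts = np.bincount(lab.ravel(), minlength=k + 1)[1:]
    centroids = np.asarray(ndimage.center_of_mass(lab > 0, lab, ids))
    vs = labels.voxel_size_um
    volume = counts * vs**3
    return pd.DataFrame(
        {
            "id": ids,
            "voxel_count": counts,
            "volume_um3": volume,
            "d_eq_um": (6.0 * volume / np.pi) ** (1.0 / 3.0),
            "centroid_z_um": (centroids[:, 0] + 0.5) * vs,
            "centroid_y_um": (centroids[:, 1] + 0.5) * vs,
            "centroid_x_um": (centroids[:, 2] + 0.5) * vs,
        }
    )


def porosity(phase: PhaseMap, region_mask: np.ndarray | None = None) -> float:
    """Porosity in percent: pore voxels over total voxels of the region.

    The region defaults to the whole fruit mask and must be non-empty.
    """
    region = phase.fruit_mask if region_mask is None else np.asarray(region_mask, bool)
    n = int(region.sum())
    if n == 0:
        raise ValueError("empty region")
    return 100.0 * int((phase.pore_mask & region).sum()) / n


@dataclass
class PorosityProfile:
    """Per-slice porosity along the calyx-to-stem axis.

    ``valid`` marks slices whose fruit-mask cross-section is non-empty;
    porosity entries of empty slices are NaN, never zero-filled.
    """

    slice_index: np.ndarray
    porosity_percent: np.ndarray
    valid: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "slice_index": self.slice_index,
                "porosity_percent": self.porosity_percent,
                "valid": self.valid,
            }
        )


def porosity_profile(phase: PhaseMap) -> PorosityProfile:
    """Per-slice porosity within each slice's fruit-mask cross-section."""
    fruit = phase.fruit_mask
    pore = phase.pore_mask
    area = fruit.sum(axis=(1, 2))
    if not area.any():
        raise ValueError("phase map has no non-empty slice")
    pores = pore.sum(axis=(1, 2))
    valid = area > 0
    prof = np.full(len(area), np.nan)
    prof[valid] = 100.0 * pores[valid] / area[valid]
    return PorosityProfile(
        slice_index=np.arange(len(area)), porosity_percent=prof, valid=valid
    )


def pore_size_histogram(
    table: pd.DataFrame, class_width_um: float = 100.0, max_um: float = 3000.0
) -> pd.DataFrame:
    """Pore counts per equivalent-diameter class.

    Classes are centered at class_width, 2*class_width, ..., max_um; each
    pore goes to the nearest class center (diameters at or beyond the top
    edge fall in the top class).  Returns a frame with columns
    ``class_center_um`` and ``count``; counts sum to the pore count.
    """
    n_classes = int(round(max_um / class_width_um))
    centers = class_width_um * np.arange(1, n_classes + 1)
    d = np.asarray(table["d_eq_um"], dtype=float)
    idx = np.clip(np.round(d / class_width_um).astype(int), 1, n_classes) - 1
    counts = np.bincount(idx, minlength=n_classes)
    return pd.DataFrame({"class_center_um": centers, "count": counts})


def pore_number_density(table: pd.DataFrame, region_volume_mm3: float) -> float:
    """Number of pores per mm^3 of the analyzed region."""
    if not region_volume_mm3 > 0:
        raise ValueError("region volume must be positive")
    return len(table) / region_volume_mm3


def mean_equivalent_diameter(table: pd.DataFrame, volume_weighted: bool = False) -> float:
    """Mean d_eq over pores; optionally weighted by pore volume."""
    if len(table) == 0:
        return float("nan")
    if volume_weighted:
        w = np.asarray(table["volume_um3"], dtype=float)
        return float(np.average(table["d_eq_um"], weights=w))
    return float(np.mean(table["d_eq_um"]))
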