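"""Fruit/air masking, grayscale histogram, valley threshold, phase labeling.

Pores attenuate X-rays weakly and appear dark; tissue appears bright.
Because surrounding air is as dark as the pores, segmentation proceeds
in two steps: first the fruit is isolated from air (Otsu threshold,
largest bright 26-connected component, 3D hole filling), then a global
gray-level threshold — placed in the deep valley between the pore and
tissue modes of the masked histogram — splits the fruit interior into
pore and tissue.  Thresholds may be fractional (e.g. 69.7 on an 8-bit
scale); the comparison ``intensity < T -> pore`` is strict, so such
values need no re-quantization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

BACKGROUND: int = 0
TISSUE: int = 1
PORE: int = 2

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


class NoObjectFoundError(RuntimeError):
    """Raised when the volume contains no dominant bright object."""


@dataclass
class GrayHistogram:
    """Gray-level frequency histogram over a masked voxel population."""

    bin_edges: np.ndarray
    counts: np.ndarray
    mask_voxel_count: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class SegmentationParams:
    """A global pore/tissue threshold and how it was obtained.

    ``source`` is "valley" when the deep-valley rule located it,
    "otsu_fallback" when the histogram had no two modes, "manual" when
    supplied by the user.
    """

    threshold: float
    smoothing_window: int = 9
    source: str = "valley"


@dataclass
class PhaseMap:
    """Per-voxel phase labels: 0 background (air), 1 tissue, 2 pore."""

    labels: np.ndarray  # uint8
    voxel_size_um: float
    source: str = ""

    @property
    def fruit_mask(self) -> np.ndarray:
        return self.labels != BACKGROUND

    @property
    def pore_mask(self) -> np.ndarray:
        return self.labels == PORE


def compute_fruit_mask(vol) -> np.ndarray:
    """Isolate the fruit from surrounding air.

    Otsu threshold on the full volume, keep the largest 26-connected
    bright component, then fill 3D holes (internal pores belong to the
    fruit).  Raises :class:`NoObjectFoundError` when the largest bright
    component covers less than 1 % of the volume.
    """
    arr = vol.intensities
    if arr.min() == arr.max():
        raise NoObjectFoundError("volume is constant; no object found")
    t = threshold_otsu(arr)
    bright = arr > t
    labels, n = ndimage.label(bright, structure=_STRUCT_26)
    if n == 0:
        raise NoObjectFoundError("no bright voxels above Otsu threshold")
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    biggest = int(sizes.argmax())
    if sizes[biggest] < 0.01 * arr.size:
        raise NoObjectFoundError(
            f"largest bright component covers {100 * sizes[biggest] / arr.size:.2f}% "
            "of the volume (< 1%); no object found"
        )
    return ndimage.binary_fill_holes(labels == biggest)


def compute_histogram(vol, mask: np.ndarray) -> GrayHistogram:
    """Histogram of gray-level frequencies over masked voxels (256 bins at
    8 bit, 1024 at 16 bit)."""
    if not mask.any():
        raise ValueError("empty mask")
    if vol.bit_depth == 8:
        edges = np.arange(257, dtype=float) - 0.5
    else:
        edges = np.linspace(-0.5, 65535.5, 1025)
    counts, edges = np.histogram(vol.intensities[mask], bins=edges)
    return GrayHistogram(bin_edges=edges, counts=counts, mask_voxel_count=int(mask.sum()))


def _local_maxima(y: np.ndarray) -> list[int]:
    """Indices of strict-plateau local maxima of a 1D sequence."""
    out = []
    n = len(y)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and y[j + 1] == y[i]:
            j += 1
        left_ok = i == 0 or y[i - 1] < y[i]
        right_ok = j == n - 1 or y[j + 1] < y[i]
        if left_ok and right_ok and y[i] > 0:
            out.append((i + j) // 2)
        i = j + 1
    return out


def find_valley_threshold(hist: GrayHistogram, smoothing_window: int = 9) -> SegmentationParams:
    """Locate the deep valley between the two dominant histogram modes.

    Counts are smoothed with a centered moving average; the two highest
    distinct local maxima are taken as the pore and tissue modes, and the
    threshold is the center of the lowest bin strictly between them
    (lowest-intensity such bin on ties).  A unimodal histogram falls back
    to Otsu on the binned data, flagged via ``source="otsu_fallback"``.
    """
    counts = np.asarray(hist.counts, dtype=float)
    if counts.sum() == 0:
        raise ValueError("empty histogram")
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise ValueError("smoothing_window must be an odd integer >= 1")
    kernel = np.ones(smoothing_window) / smoothing_window
    smooth = np.convolve(counts, kernel, mode="same")
    centers = hist.bin_centers

    peaks = _local_maxima(smooth)
    if len(peaks) >= 2:
        top_two = sorted(sorted(peaks, key=lambda i: -smooth[i])[:2])
        lo, hi = top_two
        if hi - lo >= 2:
            between = smooth[lo + 1 : hi]
            valley = lo + 1 + int(np.argmin(between))  # argmin takes lowest index on ties
            return SegmentationParams(
                threshold=float(centers[valley]),
                smoothing_window=smoothing_window,
                source="valley",
            )

    # unimodal (or adjacent peaks): Otsu on the histogram
    t = threshold_otsu(hist=(counts, centers))
    return SegmentationParams(
        threshold=float(t), smoothing_window=smoothing_window, source="otsu_fallback"
    )


def segment_phases(vol, params: SegmentationParams, fruit_mask: np.ndarray) -> PhaseMap:
    """Label each voxel background / tissue / pore.

    Inside the fruit mask, ``intensity < threshold`` is pore and the rest
    tissue; outside is background.  Strict comparison admits fractional
    thresholds on integer intensity scales.
    """
    labels = np.zeros(vol.intensities.shape, dtype=np.uint8)
    pore = fruit_mask & (vol.intensities < params.threshold)
    labels[fruit_mask] = TISSUE
    labels[pore] = PORE
    return PhaseMap(
        labels=labels,
        voxel_size_um=vol.voxel_size_um,
        source=f"threshold {params.threshold:g} ({params.source})",
    )
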