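"""Volumetric grayscale image I/O with physical voxel size.

Supported on-disk forms: multi-page TIFF, a directory of numbered
single-slice TIFFs, and MHD header + raw payload.  Volumes are held as
``VoxelVolume``: a 3D unsigned-integer array indexed ``[z, y, x]`` where
slice 0 is the calyx end of the fruit and the last slice the stem end
(the scan axis convention; the loader records it but cannot verify it).

Physical positions follow the voxel-center convention: the center of
voxel index ``i`` lies at ``(i + 0.5) * voxel_size_um`` along each axis.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

AXIS_CONVENTION = "slice 0 = calyx end, last slice = stem end"

_MHD_TYPES = {
    "MET_UCHAR": np.uint8,
    "MET_USHORT": np.uint16,
}
_MHD_TYPE_NAMES = {np.dtype(np.uint8): "MET_UCHAR", np.dtype(np.uint16): "MET_USHORT"}


class VolumeFormatError(ValueError):
    """Raised when on-disk data violates the volume format contract."""


class VoxelSizeError(ValueError):
    """Raised when no voxel size is available from metadata or override."""


@dataclass
class VoxelVolume:
    """A 3D grayscale grid with isotropic physical voxel size.

    Parameters
    ----------
    intensities
        3D array of ``uint8`` or ``uint16``, indexed ``[z, y, x]``.
    voxel_size_um
        Isotropic voxel edge length in micrometers; must be positive.
    axis_convention
        Free-text record of the slice-axis orientation; propagated
        unchanged through all downstream stages.
    provenance
        Source file and acquisition notes.
    """

    intensities: np.ndarray
    voxel_size_um: float
    axis_convention: str = AXIS_CONVENTION
    provenance: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 3 or min(arr.shape) < 1:
            raise VolumeFormatError(f"expected a 3D grid, got shape {arr.shape}")
        if arr.dtype not in (np.dtype(np.uint8), np.dtype(np.uint16)):
            raise VolumeFormatError(f"expected uint8/uint16 intensities, got {arr.dtype}")
        if not self.voxel_size_um > 0:
            raise VoxelSizeError(f"voxel_size_um must be positive, got {self.voxel_size_um}")
        self.intensities = arr

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def bit_depth(self) -> int:
        return 8 if self.intensities.dtype == np.uint8 else 16

    def with_intensities(self, arr: np.ndarray, note: str = "") -> "VoxelVolume":
        prov = self.provenance if not note else f"{self.provenance}; {note}".lstrip("; ")
        return replace(self, intensities=arr, provenance=prov)


def _read_tiff_stack_dir(path: Path) -> np.ndarray:
    files = [p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff")]
    if not files:
        raise VolumeFormatError(f"no TIFF slices found in {path}")

    def numeric_key(p: Path):
        nums = re.findall(r"\d+", p.stem)
        return (int(nums[-1]) if nums else 0, p.name)

    files.sort(key=numeric_key)
    slices = [tifffile.imread(f) for f in files]
    shapes = {s.shape for s in slices}
    if len(shapes) != 1:
        raise VolumeFormatError(f"inconsistent slice dimensions in {path}: {sorted(shapes)}")
    return np.stack(slices, axis=0)


def _read_mhd(path: Path) -> tuple[np.ndarray, float | None]:
    header: dict[str, str] = {}
    for line in path.read_text().splitlines():
        if "=" in line:
            key, _, value = line.partition("=")
            header[key.strip()] = value.strip()
    try:
        dims = [int(v) for v in header["DimSize"].split()]
        dtype = _MHD_TYPES[header["ElementType"]]
        datafile = header["ElementDataFile"]
    except KeyError as exc:
        raise VolumeFormatError(f"MHD header {path} missing field {exc}") from exc
    spacing = None
    if "ElementSpacing" in header:
        spacing = float(header["ElementSpacing"].split()[0])
    raw = (path.parent / datafile).read_bytes()
    # MHD DimSize is x y z (fastest-varying first); our arrays are [z, y, x].
    nx, ny, nz = dims
    arr = np.frombuffer(raw, dtype=dtype)
    if arr.size != nx * ny * nz:
        raise VolumeFormatError(
            f"raw payload for {path} has {arr.size} elements, header implies {nx * ny * nz}"
        )
    return arr.reshape(nz, ny, nx).copy(), spacing


def read_volume(
    path: str | Path,
    voxel_size_um: float | None = None,
    format_hint: str | None = None,
) -> VoxelVolume:
    """Read a volume from a multi-page TIFF, a slice directory, or an MHD header.

    Parameters
    ----------
    path
        File or directory to read.  Directories are treated as numbered
        TIFF slice stacks (ascending numeric sort of filenames).
    voxel_size_um
        Explicit voxel size override; required for TIFF input (TIFF
        carries no physical spacing we trust) and optional for MHD.
    format_hint
        One of ``"tiff"``, ``"tiff_dir"``, ``"mhd"``; inferred from the
        path when omitted.

    Raises
    ------
    FileNotFoundError, VolumeFormatError, VoxelSizeError
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format_hint is None:
        if path.is_dir():
            format_hint = "tiff_dir"
        elif path.suffix.lower() == ".mhd":
            format_hint = "mhd"
        else:
            format_hint = "tiff"

    spacing = None
    if format_hint == "tiff_dir":
        arr = _read_tiff_stack_dir(path)
    elif format_hint == "mhd":
        arr, spacing = _read_mhd(path)
    elif format_hint == "tiff":
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None, :, :]
    else:
        raise ValueError(f"unknown format_hint {format_hint!r}")

    size = voxel_size_um if voxel_size_um is not None else spacing
    if size is None:
        raise VoxelSizeError(
            f"{path}: no voxel size in metadata and no override given"
        )
    if arr.dtype not in (np.dtype(np.uint8), np.dtype(np.uint16)):
        raise VolumeFormatError(f"{path}: unsupported intensity dtype {arr.dtype}")
    return VoxelVolume(arr, float(size), provenance=f"read from {path}")


def write_volume(vol: VoxelVolume, path: str | Path, format: str | None = None) -> None:
    """Write a volume so that :func:`read_volume` round-trips it bit-identically.

    MHD stores the voxel size in ``ElementSpacing``; TIFF output gets a
    ``<name>.voxelsize.txt`` sidecar with the size in micrometers.
    """
    path = Path(path)
    if format is None:
        format = "mhd" if path.suffix.lower() == ".mhd" else "tiff"
    if format == "mhd":
        nz, ny, nx = vol.shape
        rawname = path.with_suffix(".raw").name
        header = "\n".join(
            [
                "ObjectType = Image",
                "NDims = 3",
                "BinaryData = True",
                "BinaryDataByteOrderMSB = False",
                f"DimSize = {nx} {ny} {nz}",
                f"ElementSpacing = {vol.voxel_size_um:g} {vol.voxel_size_um:g} {vol.voxel_size_um:g}",
                f"ElementType = {_MHD_TYPE_NAMES[vol.intensities.dtype]}",
                f"ElementDataFile = {rawname}",
            ]
        )
        path.write_text(header + "\n")
        if np.little_endian:
            payload = np.ascontiguousarray(vol.intensities)
        else:  # pragma: no cover - big-endian hosts
            payload = np.ascontiguousarray(vol.intensities.byteswap())
        (path.parent / rawname).write_bytes(payload.tobytes())
    elif format == "tiff":
        tifffile.imwrite(path, vol.intensities, photometric="minisblack")
        sidecar = path.parent / (path.stem + ".voxelsize.txt")
        sidecar.write_text(f"voxel_size_um = {vol.voxel_size_um:g}\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def convert_to_8bit(
    vol: VoxelVolume,
    window_min: float | None = None,
    window_max: float | None = None,
) -> VoxelVolume:
    """Rescale a volume to 8 bit through an intensity window.

    Each intensity ``v`` maps to ``round(255 * (clamp(v) - window_min) /
    (window_max - window_min))`` with half-away-from-zero rounding (so the
    window midpoint maps to 128, not numpy's banker's 127).  The default
    window is the observed min/max of the volume, which is parameter-free
    and preserves the histogram shape the valley detector relies on.
    """
    arr = vol.intensities
    lo = float(arr.min()) if window_min is None else float(window_min)
    hi = float(arr.max()) if window_max is None else float(window_max)
    if not lo < hi:
        raise ValueError(f"degenerate window [{lo}, {hi}]")
    scaled = 255.0 * (np.clip(arr.astype(np.float64), lo, hi) - lo) / (hi - lo)
    out = np.floor(scaled + 0.5).astype(np.uint8)  # half-away-from-zero (values >= 0)
    return vol.with_intensities(out, note=f"converted to 8-bit, window [{lo:g}, {hi:g}]")


def map_threshold_to_8bit(threshold: float, window_min: float, window_max: float) -> float:
    """Map a 16-bit-scale threshold through the same window as :func:`convert_to_8bit`."""
    if not window_min < window_max:
        raise ValueError(f"degenerate window [{window_min}, {window_max}]")
    return 255.0 * (threshold - window_min) / (window_max - window_min)
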