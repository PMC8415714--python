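"""Shared fixtures: small phantoms and segmented phases, generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

import fruitpore as fp
from fruitpore.phantom import PhantomSpec, CoreSpec, generate_phantom, preset_spec
from fruitpore.segmentation import PhaseMap, TISSUE, PORE


@pytest.fixture(scope="session")
def mesocarp_phantom():
    """Small slab phantom (96^3, 1 % porosity) with its ground truth."""
    return generate_phantom(preset_spec("healthy_mesocarp", seed=1))


@pytest.fixture(scope="session")
def mesocarp_segmented(mesocarp_phantom):
    vol, truth = mesocarp_phantom
    mask = fp.compute_fruit_mask(vol)
    params = fp.find_valley_threshold(fp.compute_histogram(vol, mask))
    phase = fp.segment_phases(vol, params, mask)
    return vol, truth, mask, params, phase


@pytest.fixture(scope="session")
def cored_phantom():
    """Ellipsoidal fruit with a denser (brighter) core, for core extraction."""
    spec = PhantomSpec(
        grid_shape=(96, 96, 96),
        voxel_size_um=79.4,
        fruit_semi_axes_um=(44 * 79.4, 40 * 79.4, 40 * 79.4),
        core=CoreSpec(semi_axes_um=(12 * 79.4, 10 * 79.4, 10 * 79.4), intensity_offset=40.0),
        porosity_percent=3.0,
        diameter_um=240.0,
        diameter_sigma_log=0.35,
        seed=3,
    )
    return generate_phantom(spec)


def phase_from_pore_mask(pore_mask: np.ndarray, voxel_size_um: float = 1.0,
                         fruit_mask: np.ndarray | None = None) -> PhaseMap:
    """Build a PhaseMap directly from a boolean pore mask (fruit = whole grid)."""
    labels = np.full(pore_mask.shape, TISSUE, dtype=np.uint8)
    if fruit_mask is not None:
        labels[~fruit_mask] = 0
    labels[pore_mask] = PORE
    return PhaseMap(labels=labels, voxel_size_um=voxel_size_um)
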