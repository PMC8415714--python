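"""Pore labeling, equivalent diameters, porosity, profiles, size classes."""

import numpy as np
import pytest

from fruitpore.morphometry import (
    build_pore_table,
    label_pores,
    mean_equivalent_diameter,
    pore_number_density,
    pore_size_histogram,
    porosity,
    porosity_profile,
)
from tests.conftest import phase_from_pore_mask


def bfs_label_count(field: np.ndarray, connectivity: int) -> int:
    """Independent brute-force BFS component counter."""
    if connectivity == 26:
        offsets = [
            (a, b, c)
            for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
            if (a, b, c) != (0, 0, 0)
        ]
    else:
        offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    seen = np.zeros_like(field, bool)
    count = 0
    for start in zip(*np.nonzero(field)):
        if seen[start]:
            continue
        count += 1
        stack = [start]
        seen[start] = True
        while stack:
            z, y, x = stack.pop()
            for dz, dy, dx in offsets:
                p = (z + dz, y + dy, x + dx)
                if all(0 <= p[i] < field.shape[i] for i in range(3)) and field[p] and not seen[p]:
                    seen[p] = True
                    stack.append(p)
    return count


class TestLabelPores:
    def test_no_pores_gives_zero_components(self):
        phase = phase_from_pore_mask(np.zeros((5, 5, 5), bool))
        assert label_pores(phase).n_pores == 0

    def test_corner_sharing_voxels(self):
        pore = np.zeros((4, 4, 4), bool)
        pore[0, 0, 0] = pore[1, 1, 1] = True  # share only a corner
        phase = phase_from_pore_mask(pore)
        assert label_pores(phase, connectivity=26).n_pores == 1
        assert label_pores(phase, connectivity=6).n_pores == 2

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_bfs_oracle(self, connectivity):
        rng = np.random.default_rng(7)
        field = rng.random((20, 20, 20)) < 0.2
        phase = phase_from_pore_mask(field)
        assert label_pores(phase, connectivity).n_pores == bfs_label_count(field, connectivity)

    def test_26_never_more_components_than_6(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            field = rng.random((15, 15, 15)) < 0.3
            phase = phase_from_pore_mask(field)
            assert label_pores(phase, 26).n_pores <= label_pores(phase, 6).n_pores


class TestPoreTable:
    def test_single_voxel_at_scanner_resolution(self):
        pore = np.zeros((3, 3, 3), bool)
        pore[1, 1, 1] = True
        table = build_pore_table(label_pores(phase_from_pore_mask(pore, 79.4)))
        v = 79.4**3
        assert table.loc[0, "volume_um3"] == pytest.approx(v)
        assert table.loc[0, "d_eq_um"] == pytest.approx((6 * v / np.pi) ** (1 / 3))
        # centroid at the voxel center
        assert table.loc[0, "centroid_z_um"] == pytest.approx(1.5 * 79.4)

    def test_equivalent_diameter_formula_inverse(self):
        # a pore of volume pi/6 um^3 has d_eq exactly 1 um
        vs = (np.pi / 6.0) ** (1.0 / 3.0)
        pore = np.zeros((3, 3, 3), bool)
        pore[1, 1, 1] = True
        table = build_pore_table(label_pores(phase_from_pore_mask(pore, vs)))
        assert table.loc[0, "d_eq_um"] == pytest.approx(1.0)

    def test_digitized_sphere_diameter_within_2_percent(self):
        # 100 um sphere at 2 um voxels: 25 voxels radius
        zz, yy, xx = np.ogrid[:60, :60, :60]
        pore = ((zz - 30) ** 2 + (yy - 30) ** 2 + (xx - 30) ** 2) <= 25**2
        table = build_pore_table(label_pores(phase_from_pore_mask(pore, 2.0)))
        assert len(table) == 1
        assert table.loc[0, "d_eq_um"] == pytest.approx(100.0, rel=0.02)

    def test_empty_table(self):
        table = build_pore_table(label_pores(phase_from_pore_mask(np.zeros((4, 4, 4), bool))))
        assert len(table) == 0


class TestPorosity:
    def test_all_tissue_zero(self):
        phase = phase_from_pore_mask(np.zeros((10, 10, 10), bool))
        assert porosity(phase) == 0.0

    def test_counted_toy_mask_exact(self):
        pore = np.zeros((10, 10, 10), bool)
        pore.ravel()[:35] = True
        phase = phase_from_pore_mask(pore)
        assert porosity(phase) == pytest.approx(3.5)

    def test_phantom_measured_vs_truth(self, mesocarp_segmented):
        _, truth, _, _, phase = mesocarp_segmented
        assert porosity(phase) == pytest.approx(truth.true_porosity_percent, abs=0.3)

    def test_empty_region_rejected(self):
        phase = phase_from_pore_mask(np.zeros((5, 5, 5), bool))
        with pytest.raises(ValueError):
            porosity(phase, np.zeros((5, 5, 5), bool))

    def test_invariant_under_axis_permutation(self):
        rng = np.random.default_rng(4)
        pore = rng.random((8, 10, 12)) < 0.2
        phase = phase_from_pore_mask(pore)
        p0 = porosity(phase)
        for axes in [(1, 0, 2), (2, 1, 0), (1, 2, 0)]:
            permuted = phase_from_pore_mask(np.transpose(pore, axes))
            assert porosity(permuted) == pytest.approx(p0)


class TestPorosityProfile:
    def test_single_slice_consistency(self):
        rng = np.random.default_rng(5)
        pore = rng.random((1, 20, 20)) < 0.1
        phase = phase_from_pore_mask(pore)
        prof = porosity_profile(phase)
        assert len(prof.slice_index) == 1
        assert prof.porosity_percent[0] == pytest.approx(porosity(phase))

    def test_slices_recompose_whole_volume(self, mesocarp_segmented):
        _, _, _, _, phase = mesocarp_segmented
        prof = porosity_profile(phase)
        fruit_per_slice = phase.fruit_mask.sum(axis=(1, 2))
        pore_total = np.nansum(prof.porosity_percent / 100.0 * fruit_per_slice)
        assert pore_total == pytest.approx(phase.pore_mask.sum(), rel=1e-9)

    def test_uniform_phantom_profile_flat(self, mesocarp_phantom):
        _, truth = mesocarp_phantom
        phase = phase_from_pore_mask(truth.pore_mask, truth.voxel_size_um)
        prof = porosity_profile(phase)
        p = truth.true_porosity_percent / 100.0
        n = truth.fruit_mask.sum(axis=(1, 2))
        # pores land as whole objects, so per-slice counts are compound-
        # Poisson: inflate the voxel-binomial variance by the mean object
        # size (a conservative cluster bound), then take a 3-sigma band
        m = truth.pore_table["voxel_count"].mean()
        se = 100.0 * 3.0 * np.sqrt(m * p * (1 - p) / n)
        within = np.abs(prof.porosity_percent - 100.0 * p) <= se
        assert within.all()

    def test_empty_slice_flagged_not_zeroed(self):
        pore = np.zeros((3, 5, 5), bool)
        fruit = np.zeros((3, 5, 5), bool)
        fruit[0] = fruit[2] = True
        pore[0, 0, 0] = True
        phase = phase_from_pore_mask(pore, fruit_mask=fruit)
        prof = porosity_profile(phase)
        assert not prof.valid[1]
        assert np.isnan(prof.porosity_percent[1])


class TestSizeHistogram:
    def test_single_pore_in_class_300(self):
        table = build_pore_table(label_pores(phase_from_pore_mask(
            np.pad(np.ones((1, 1, 1), bool), 1), 1.0)))
        table.loc[0, "d_eq_um"] = 300.0
        hist = pore_size_histogram(table)
        assert hist.set_index("class_center_um").loc[300.0, "count"] == 1

    def test_counts_conserved(self, mesocarp_segmented):
        _, _, _, _, phase = mesocarp_segmented
        table = build_pore_table(label_pores(phase))
        hist = pore_size_histogram(table)
        assert hist["count"].sum() == len(table)

    def test_87um_spheres_fall_in_class_100(self):
        # nearest class center to 87 um is 100 um
        zz, yy, xx = np.ogrid[:50, :50, :50]
        pore = ((zz - 25) ** 2 + (yy - 25) ** 2 + (xx - 25) ** 2) <= 21.75**2
        table = build_pore_table(label_pores(phase_from_pore_mask(pore, 2.0)))
        hist = pore_size_histogram(table)
        modal = hist.loc[hist["count"].idxmax(), "class_center_um"]
        assert modal == 100.0

    def test_oversized_pores_go_to_top_class(self):
        import pandas as pd
        table = pd.DataFrame({"d_eq_um": [5000.0], "volume_um3": [1.0], "voxel_count": [1]})
        hist = pore_size_histogram(table)
        assert hist.set_index("class_center_um").loc[3000.0, "count"] == 1


class TestNumberDensity:
    def test_direct_ratio(self):
        import pandas as pd
        table = pd.DataFrame({"id": range(10)})
        assert pore_number_density(table, 50.0) == pytest.approx(0.2)

    def test_zero_pores(self):
        import pandas as pd
        assert pore_number_density(pd.DataFrame(), 10.0) == 0.0

    def test_zero_volume_rejected(self):
        import pandas as pd
        with pytest.raises(ValueError):
            pore_number_density(pd.DataFrame(), 0.0)


def test_mean_diameter_weighted_flag():
    import pandas as pd
    table = pd.DataFrame({"d_eq_um": [10.0, 20.0], "volume_um3": [1.0, 7.0]})
    assert mean_equivalent_diameter(table) == pytest.approx(15.0)
    assert mean_equivalent_diameter(table, volume_weighted=True) == pytest.approx(18.75)
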