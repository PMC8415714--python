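"""Distance map, skeletonization, and pore-network graph extraction."""

import networkx as nx
import numpy as np
import pytest
from scipy import ndimage

from fruitpore.network import (
    NetworkStats,
    SkeletonGraph,
    analyze_pore_network,
    distance_map,
    extract_network,
    network_stats,
    skeletonize_pores,
)
from fruitpore.phantom import generate_tube_phantom
from fruitpore.segmentation import PhaseMap
from tests.conftest import phase_from_pore_mask


def ball_phase(radius=10, pad=10, voxel=1.0):
    n = 2 * (radius + pad)
    zz, yy, xx = np.ogrid[:n, :n, :n]
    c = n // 2
    pore = ((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2) <= radius**2
    return phase_from_pore_mask(pore, voxel)


class TestDistanceMap:
    def test_single_pore_voxel(self):
        pore = np.zeros((5, 5, 5), bool)
        pore[2, 2, 2] = True
        d = distance_map(phase_from_pore_mask(pore, 79.4))
        assert d.values_um[2, 2, 2] == pytest.approx(79.4)
        assert d.values_um[0, 0, 0] == 0.0

    def test_capsule_axis_distance_matches_radius(self):
        _, truth = generate_tube_phantom([((32, 32, 10), (32, 32, 54), 5.0)], (64, 64, 64))
        phase = PhaseMap(labels=truth.phase_map, voxel_size_um=1.0)
        d = distance_map(phase)
        assert 4.5 <= d.values_um.max() <= 5.5

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(13)
        pore = rng.random((15, 15, 15)) < 0.4
        d = distance_map(phase_from_pore_mask(pore, 1.0))
        non_pore = np.argwhere(~pore)
        for v in np.argwhere(pore)[::7]:
            brute = np.sqrt(((non_pore - v) ** 2).sum(axis=1)).min()
            assert d.values_um[tuple(v)] == pytest.approx(brute, abs=1e-9)


class TestSkeletonize:
    def test_thin_line_is_fixed_point(self):
        pore = np.zeros((5, 5, 34), bool)
        pore[2, 2, 2:32] = True
        skel = skeletonize_pores(pore)
        np.testing.assert_array_equal(skel, pore)

    def test_capsule_skeleton_is_single_curve_of_right_length(self):
        _, truth = generate_tube_phantom([((32, 32, 7), (32, 32, 57), 5.0)], (64, 64, 64))
        skel = skeletonize_pores(truth.phase_map == 2)
        _, n = ndimage.label(skel, structure=np.ones((3, 3, 3), bool))
        assert n == 1
        zs = np.argwhere(skel)[:, 2]
        assert abs((zs.max() - zs.min()) - 50) <= 3

    def test_disjoint_capsules_two_components(self):
        segs = [((10, 10, 10), (10, 10, 40), 3.0), ((40, 40, 10), (40, 40, 40), 3.0)]
        _, truth = generate_tube_phantom(segs, (54, 54, 54))
        skel = skeletonize_pores(truth.phase_map == 2)
        _, n = ndimage.label(skel, structure=np.ones((3, 3, 3), bool))
        assert n == 2

    def test_empty_input_empty_skeleton(self):
        assert not skeletonize_pores(np.zeros((6, 6, 6), bool)).any()

    def test_topology_preserved_on_random_fields(self):
        S = np.ones((3, 3, 3), bool)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            field = rng.random((14, 14, 14)) < 0.25
            n_pore = ndimage.label(field, structure=S)[1]
            n_skel = ndimage.label(skeletonize_pores(field), structure=S)[1]
            assert n_skel == n_pore


class TestExtractNetwork:
    def test_isolated_sphere_collapses_to_one_node(self):
        phase = ball_phase(radius=10)
        sg, stats = analyze_pore_network(phase)
        assert sg.n_nodes == 1
        assert sg.n_edges == 0
        assert list(dict(sg.graph.nodes(data="type")).values()) == ["isolated"]
        assert stats.avg_coordination == 0.0
        assert stats.max_coordination == 0

    def test_straight_capsule_two_endpoints_one_edge(self):
        _, truth = generate_tube_phantom([((32, 32, 7), (32, 32, 57), 5.0)], (64, 64, 64))
        phase = PhaseMap(labels=truth.phase_map, voxel_size_um=1.0)
        sg, _ = analyze_pore_network(phase)
        types = sorted(dict(sg.graph.nodes(data="type")).values())
        assert types == ["endpoint", "endpoint"]
        assert sg.n_edges == 1
        (_, _, d), = sg.graph.edges(data=True)
        assert d["throat_diameter_um"] == pytest.approx(10.0, rel=0.10)
        assert d["path_length_um"] == pytest.approx(50.0, abs=3.0)

    def test_y_tube_one_junction_three_endpoints(self):
        segs = [
            ((20, 32, 32), (40, 32, 32), 4.0),
            ((40, 32, 32), (55, 20, 32), 4.0),
            ((40, 32, 32), (55, 44, 32), 4.0),
        ]
        _, truth = generate_tube_phantom(segs, (64, 64, 64))
        phase = PhaseMap(labels=truth.phase_map, voxel_size_um=1.0)
        sg, stats = analyze_pore_network(phase)
        from collections import Counter
        c = Counter(dict(sg.graph.nodes(data="type")).values())
        assert c == {"endpoint": 3, "junction": 1}
        assert sg.n_edges == 3
        assert stats.max_coordination == 3
        # junction located near the true meeting point (40, 32, 32)
        (jid,) = [n for n, t in sg.graph.nodes(data="type") if t == "junction"]
        jcoord = np.array(sg.graph.nodes[jid]["coord_um"]) - 0.5
        assert np.linalg.norm(jcoord - np.array([40, 32, 32])) <= 2.0
        # equal radii r -> average pore length close to 2r
        assert stats.avg_pore_length_um == pytest.approx(8.0, rel=0.15)

    def test_total_path_length_tracks_truth_centerline(self):
        segs = [
            ((20, 32, 32), (40, 32, 32), 4.0),
            ((40, 32, 32), (55, 20, 32), 4.0),
            ((40, 32, 32), (55, 44, 32), 4.0),
        ]
        _, truth = generate_tube_phantom(segs, (64, 64, 64))
        phase = PhaseMap(labels=truth.phase_map, voxel_size_um=1.0)
        sg, _ = analyze_pore_network(phase)
        total = sum(d["path_length_um"] for _, _, d in sg.graph.edges(data=True))
        # thinning erodes branch tips by up to about one radius per free end
        assert total == pytest.approx(truth.skeleton.total_length_um, rel=0.15)

    def test_graph_components_match_skeleton_components(self, mesocarp_segmented):
        _, _, _, _, phase = mesocarp_segmented
        sg, _ = analyze_pore_network(phase)
        n_graph = nx.number_connected_components(sg.graph)
        n_skel = ndimage.label(sg.skeleton, structure=np.ones((3, 3, 3), bool))[1]
        assert n_graph == n_skel

    def test_degree_sum_twice_edges(self, mesocarp_segmented):
        _, _, _, _, phase = mesocarp_segmented
        sg, _ = analyze_pore_network(phase)
        assert sum(d for _, d in sg.graph.degree()) == 2 * sg.n_edges

    def test_stats_invariant_under_rotation(self):
        segs = [
            ((20, 32, 32), (40, 32, 32), 4.0),
            ((40, 32, 32), (55, 20, 32), 4.0),
            ((40, 32, 32), (55, 44, 32), 4.0),
        ]
        _, truth = generate_tube_phantom(segs, (64, 64, 64))
        pore = truth.phase_map == 2
        sg0, s0 = analyze_pore_network(phase_from_pore_mask(pore, 1.0))
        rotated = np.rot90(pore, k=1, axes=(0, 2)).copy()
        sg1, s1 = analyze_pore_network(phase_from_pore_mask(rotated, 1.0))
        assert s0.n_nodes == s1.n_nodes
        assert s0.n_edges == s1.n_edges
        assert s0.avg_throat_length_um == pytest.approx(s1.avg_throat_length_um, abs=1.0)
        assert s0.avg_throat_diameter_um == pytest.approx(s1.avg_throat_diameter_um, abs=1.0)

    def test_shape_mismatch_rejected(self):
        phase = ball_phase(radius=5, pad=5)
        dmap = distance_map(phase)
        with pytest.raises(ValueError):
            extract_network(np.zeros((4, 4, 4), bool), dmap)

    def test_throat_diameter_bounded_by_body_radii(self, mesocarp_segmented):
        _, _, _, _, phase = mesocarp_segmented
        sg, _ = analyze_pore_network(phase)
        for a, b, d in sg.graph.edges(data=True):
            limit = 2.0 * min(sg.graph.nodes[a]["body_radius_um"],
                              sg.graph.nodes[b]["body_radius_um"])
            assert d["throat_diameter_um"] <= limit + 1e-9


class TestNetworkStats:
    def test_hand_built_degrees(self):
        g = nx.MultiGraph()
        for i, r in enumerate([5.0, 3.0, 3.0, 3.0]):
            g.add_node(i, coord_um=(0, 0, 0), type="junction" if i == 0 else "endpoint",
                       body_radius_um=r, voxels=[])
        for i in (1, 2, 3):
            g.add_edge(0, i, path=[], path_length_um=10.0,
                       throat_diameter_um=4.0, throat_length_um=2.0)
        stats = network_stats(SkeletonGraph(g, np.zeros((1, 1, 1), bool), 1.0))
        assert stats.avg_coordination == pytest.approx(1.5)
        assert stats.max_coordination == 3
        assert stats.avg_pore_length_um == pytest.approx(2 * 3.5)
        assert stats.avg_throat_length_um == pytest.approx(2.0)

    def test_only_isolated_nodes_zero_coordination(self):
        # several disconnected voids: the healthy-fruit situation
        pore = np.zeros((40, 40, 40), bool)
        zz, yy, xx = np.ogrid[:40, :40, :40]
        for c in [(10, 10, 10), (10, 28, 28), (28, 10, 28), (28, 28, 10)]:
            pore |= ((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2) <= 25
        sg, stats = analyze_pore_network(phase_from_pore_mask(pore, 1.0))
        assert stats.avg_coordination == 0.0
        assert stats.max_coordination == 0
        assert stats.n_edges == 0

    def test_empty_graph_all_zero(self):
        stats = network_stats(SkeletonGraph(nx.MultiGraph(), np.zeros((1, 1, 1), bool), 1.0))
        assert stats == NetworkStats(0.0, 0.0, 0.0, 0.0, 0, 0, 0)
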