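"""Contact graphs and centrality measures against brute-force oracles."""

import networkx as nx
import numpy as np
import pytest

from cgmem.core_io import Frame, RoleMap, SimulationBox
from cgmem.graphs import (
    build_contact_graph,
    centrality_time_average,
    closeness_values,
    connected_components,
    degree_values,
)

ROLE_MAP = RoleMap.from_dict(
    {"cation_head": [["CAT", "RNG"]], "cation_tail": [["CAT", "CT1"]]}
)


def tail_frame(tail_positions, box=SimulationBox(10, 10, 10)):
    """One single-tail-bead cation per position."""
    n = len(tail_positions)
    return Frame(
        0.0, box, np.arange(1, n + 1),
        np.array(["CAT"] * n, dtype=object),
        np.array(["CT1"] * n, dtype=object),
        np.asarray(tail_positions, dtype=float),
    )


def bfs_closeness_oracle(graph):
    """Independent BFS implementation of Wasserman–Faust closeness."""
    nodes = list(graph.nodes)
    n = len(nodes)
    adj = {v: set(graph.neighbors(v)) for v in nodes}
    out = {}
    for v in nodes:
        dist = {v: 0}
        frontier = [v]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for w in adj[u]:
                    if w not in dist:
                        dist[w] = d
                        nxt.append(w)
            frontier = nxt
        r = len(dist)
        sd = sum(dist.values())
        out[v] = 0.0 if sd == 0 or n < 2 else ((r - 1) / (n - 1)) * ((r - 1) / sd)
    return out


class TestContactGraph:
    def test_edge_within_cutoff(self):
        g = build_contact_graph(
            tail_frame([[1, 1, 1], [1.5, 1, 1]]), ROLE_MAP, "cation", 0.7
        )
        assert g.number_of_edges() == 1

    def test_no_edge_beyond_cutoff(self):
        g = build_contact_graph(
            tail_frame([[1, 1, 1], [1.8, 1, 1]]), ROLE_MAP, "cation", 0.7
        )
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 2  # isolated nodes retained

    def test_periodic_contact_across_boundary(self):
        g = build_contact_graph(
            tail_frame([[0.2, 5, 5], [9.9, 5, 5]]), ROLE_MAP, "cation", 0.7
        )
        assert g.number_of_edges() == 1

    def test_any_tail_pair_counts(self):
        # two 2-tail molecules whose closest tail pair only is within cutoff
        frame = Frame(
            0.0, SimulationBox(10, 10, 10),
            np.array([1, 1, 2, 2]),
            np.array(["CAT"] * 4, dtype=object),
            np.array(["CT1"] * 4, dtype=object),
            np.array([[1, 1, 1], [5, 5, 5], [1.5, 1, 1], [8, 8, 8]], dtype=float),
        )
        g = build_contact_graph(frame, ROLE_MAP, "cation", 0.7)
        assert g.has_edge(1, 2)

    def test_translation_invariance_under_wrap(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 10, (40, 3))
        g1 = build_contact_graph(tail_frame(pts), ROLE_MAP, "cation", 0.7)
        shifted = np.mod(pts + np.array([3.7, -2.2, 8.9]), 10.0)
        g2 = build_contact_graph(tail_frame(shifted), ROLE_MAP, "cation", 0.7)
        assert set(g1.edges) == set(g2.edges)

    def test_largest_component_monotone_in_cutoff(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 10, (60, 3))
        fracs = [
            connected_components(
                build_contact_graph(tail_frame(pts), ROLE_MAP, "cation", c)
            )[2]
            for c in (0.4, 0.7, 1.0, 1.5, 2.5)
        ]
        assert all(a <= b + 1e-12 for a, b in zip(fracs, fracs[1:]))


class TestCentrality:
    def test_path_graph_closeness(self):
        g = nx.path_graph(3)
        clo, _ = closeness_values(g)
        assert clo[1] == pytest.approx(1.0)
        assert clo[0] == pytest.approx(2 / 3)
        assert clo[2] == pytest.approx(2 / 3)

    def test_complete_graph_closeness_one(self):
        clo, mean = closeness_values(nx.complete_graph(4))
        assert list(clo.values()) == pytest.approx([1.0] * 4)
        assert mean == pytest.approx(1.0)

    def test_single_edge_plus_isolated(self):
        g = nx.Graph()
        g.add_nodes_from(range(4))
        g.add_edge(0, 1)
        clo, _ = closeness_values(g)
        assert clo[0] == pytest.approx(1 / 3)
        assert clo[1] == pytest.approx(1 / 3)
        assert clo[2] == 0.0 and clo[3] == 0.0

    def test_degrees_complete_and_empty(self):
        deg, mean = degree_values(nx.complete_graph(4))
        assert list(deg.values()) == [3, 3, 3, 3] and mean == 3.0
        g = nx.Graph()
        g.add_nodes_from(range(5))
        deg, mean = degree_values(g)
        assert set(deg.values()) == {0} and mean == 0.0

    def test_handshake_lemma_on_random_graphs(self):
        rng = np.random.default_rng(2)
        for i in range(100):
            n = int(rng.integers(2, 51))
            g = nx.gnp_random_graph(n, rng.uniform(0.05, 0.6), seed=int(rng.integers(1e6)))
            deg, _ = degree_values(g)
            assert sum(deg.values()) == 2 * g.number_of_edges()

    def test_closeness_matches_bfs_oracle_on_random_graphs(self):
        rng = np.random.default_rng(3)
        for i in range(100):
            n = int(rng.integers(2, 51))
            p = rng.uniform(0.02, 0.5)
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(1e6)))
            clo, _ = closeness_values(g)
            oracle = bfs_closeness_oracle(g)
            for v in g.nodes:
                assert clo[v] == pytest.approx(oracle[v], abs=1e-12)
                assert 0.0 <= clo[v] <= 1.0

    def test_closeness_one_only_for_hub_of_connected_graph(self):
        g = nx.star_graph(5)  # hub adjacent to all others
        clo, _ = closeness_values(g)
        assert clo[0] == pytest.approx(1.0)
        assert all(clo[v] < 1.0 for v in range(1, 6))


class TestComponentsAndTimeAverage:
    def test_planted_droplet_single_component(self, droplet_system, role_map):
        g = build_contact_graph(droplet_system.frame, role_map, "cation", 0.7)
        comps, sizes, frac = connected_components(g)
        cluster = set(
            droplet_system.truth.query("species == 'cation' and cluster == 0")
            .molecule_id
        )
        assert frac == 1.0
        assert comps[0] == cluster

    def test_dispersed_all_singletons(self, flat_system, role_map):
        from cgmem.synthetic import IonPlacement, place_ions

        system = place_ions(flat_system, IonPlacement(20, "dispersed_external"), seed=8)
        g = build_contact_graph(system.frame, role_map, "cation", 0.7)
        _, sizes, frac = connected_components(g)
        assert np.all(sizes == 1)

    def test_two_planted_micelles_two_components(self, role_map):
        from cgmem.core_io import SimulationBox
        from cgmem.synthetic import (
            BilayerSpec, IonPlacement, generate_two_bilayer_system, place_ions,
        )

        box = SimulationBox(14.0, 14.0, 28.0)
        s1 = BilayerSpec(306, 0.64, 4.0, 0.0, (1, 0), 7.0)
        s2 = BilayerSpec(306, 0.64, 4.0, 0.0, (1, 0), 21.0)
        base = generate_two_bilayer_system(s1, s2, box, seed=20)
        one = place_ions(base, IonPlacement(20, "micelle", 1.5), seed=21)
        two = place_ions(one, IonPlacement(20, "micelle", 1.5), seed=99)
        g = build_contact_graph(two.frame, role_map, "cation", 0.7)
        _, sizes, _ = connected_components(g)
        assert sorted(sizes.tolist(), reverse=True)[:2] == [20, 20]

    def test_static_trajectory_time_average_equals_single_frame(
        self, droplet_system, role_map
    ):
        frames = [droplet_system.frame] * 5
        summary = centrality_time_average(
            frames, role_map, "cation", window=slice(0, 5)
        )
        g = build_contact_graph(droplet_system.frame, role_map, "cation", 0.7)
        _, mean_deg = degree_values(g)
        _, mean_clo = closeness_values(g)
        assert summary.mean_degree == pytest.approx(mean_deg)
        assert summary.mean_closeness == pytest.approx(mean_clo)
        assert summary.degrees.size == 5 * g.number_of_nodes()

    def test_droplet_plus_dispersed_bimodal_closeness(self, flat_system, role_map):
        from cgmem.synthetic import IonPlacement, place_ions

        system = place_ions(
            flat_system, IonPlacement(50, "core_droplet", 2.0), seed=30
        )
        system = place_ions(system, IonPlacement(10, "dispersed_external"), seed=31)
        summary = centrality_time_average(
            [system.frame], role_map, "cation", window=slice(0, 1)
        )
        counts, edges = summary.histogram("closeness", bins=20)
        assert counts.sum() == summary.closenesses.size
        # zero mode (dispersed) and a high mode (droplet)
        assert counts[0] >= 10
        assert counts[-1] + counts[-2] > 0
        assert counts[len(counts) // 2] == 0

    def test_empty_window_rejected(self, droplet_system, role_map):
        with pytest.raises(ValueError):
            centrality_time_average(
                [droplet_system.frame], role_map, "cation", window=slice(1, 1)
            )
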