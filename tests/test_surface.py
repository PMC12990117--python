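"""Leaflet grids, morphology metrics and compartment geometry."""

import numpy as np
import pytest
from scipy.integrate import quad

from cgmem.core_io import Frame, SimulationBox
from cgmem.surface import (
    BilayerSurfaces,
    LeafletAssignmentError,
    LeafletGrid,
    SurfaceGeometryError,
    assign_leaflets,
    bilayer_thickness,
    build_leaflet_grid,
    locate_compartment,
    per_lipid_metrics,
    surface_area,
)
from tests.conftest import make_undulated_system

BOX = SimulationBox(10.0, 10.0, 20.0)


def flat_grid(z, n=16, box=BOX, label=""):
    return LeafletGrid(np.full((n, n), float(z)), box, label)


def lattice_points(fn, box, n=50, z0=10.0):
    x = (np.arange(n) + 0.5) * box.Lx / n
    y = (np.arange(n) + 0.5) * box.Ly / n
    X, Y = np.meshgrid(x, y, indexing="ij")
    return np.column_stack([X.ravel(), Y.ravel(), z0 + fn(X, Y).ravel()])


class TestAssignLeaflets:
    def test_recovers_construction_groups_under_jitter(self, role_map):
        rng = np.random.default_rng(0)
        sys_ = make_undulated_system(seed=1, amplitude=0.0)
        frame = sys_.frame
        jittered = frame.positions.copy()
        ph = role_map.mask(frame, "phosphate")
        jittered[ph, 2] += rng.uniform(-0.1, 0.1, ph.sum())
        frame2 = Frame(
            frame.time, frame.box, frame.molecule_ids, frame.residue_names,
            frame.bead_names, jittered,
        )
        leaflets = assign_leaflets(frame2, role_map, external="wrap")
        lipid_truth = sys_.truth.query("species == 'lipid'")
        for label, beads in leaflets.items():
            mols = set(frame2.molecule_ids[beads])
            expected = set(lipid_truth[lipid_truth.label == label].molecule_id)
            assert mols == expected, label

    def test_jitter_up_to_quarter_separation_still_separable(self, role_map):
        # leaflet sheets 4 nm apart within a bilayer; jitter +-1 nm
        rng = np.random.default_rng(4)
        sys_ = make_undulated_system(seed=5, amplitude=0.0)
        frame = sys_.frame
        pos = frame.positions.copy()
        ph = role_map.mask(frame, "phosphate")
        pos[ph, 2] += rng.uniform(-1.0, 1.0, ph.sum())
        frame2 = Frame(frame.time, frame.box, frame.molecule_ids,
                       frame.residue_names, frame.bead_names, pos)
        leaflets = assign_leaflets(frame2, role_map, external="wrap")
        assert sum(len(v) for v in leaflets.values()) == int(ph.sum())

    def test_single_bilayer_rejected(self, role_map):
        rng = np.random.default_rng(2)
        n = 60
        pos = np.column_stack(
            [rng.uniform(0, 10, n), rng.uniform(0, 10, n),
             np.repeat([3.0, 7.0], n // 2) + rng.uniform(-0.05, 0.05, n)]
        )
        frame = Frame(
            0.0, BOX, np.arange(1, n + 1),
            np.array(["DPPC"] * n, dtype=object),
            np.array(["PO4"] * n, dtype=object), pos,
        )
        with pytest.raises(LeafletAssignmentError, match="gap"):
            assign_leaflets(frame, role_map)

    def test_too_few_phosphates_rejected(self, role_map):
        frame = Frame(
            0.0, BOX, np.arange(1, 5),
            np.array(["DPPC"] * 4, dtype=object),
            np.array(["PO4"] * 4, dtype=object),
            np.random.default_rng(0).uniform(0, 10, (4, 3)),
        )
        with pytest.raises(LeafletAssignmentError):
            assign_leaflets(frame, role_map)


class TestBuildGrid:
    def test_constant_field_exact(self):
        pts = lattice_points(lambda X, Y: 0.0 * X, BOX, n=10, z0=5.0)
        g = build_leaflet_grid(pts, BOX, 32, 32)
        assert np.allclose(g.heights, 5.0)

    def test_sinusoid_reproduced_within_tolerance(self):
        box = SimulationBox(20.0, 20.0, 20.0)
        pts = lattice_points(
            lambda X, Y: 2.0 * np.sin(2 * np.pi * X / box.Lx), box, n=50
        )
        g = build_leaflet_grid(pts, box, 64, 64)
        gx = np.arange(64) * box.Lx / 64
        exact = 10.0 + 2.0 * np.sin(2 * np.pi * gx / box.Lx)
        assert np.abs(g.heights - exact[:, None]).max() < 0.05

    def test_three_points_covered_via_images(self):
        pts = np.array([[1.0, 1.0, 5.0], [8.0, 2.0, 5.0], [4.0, 8.0, 5.0]])
        g = build_leaflet_grid(pts, BOX, 16, 16, margin=12.0)
        assert np.allclose(g.heights, 5.0)

    def test_collinear_points_rejected(self):
        pts = np.array([[1.0, 5.0, 3.0], [2.0, 5.0, 3.0], [3.0, 5.0, 3.0]])
        with pytest.raises(ValueError):
            build_leaflet_grid(pts, BOX, 8, 8, margin=0.5)

    def test_leaflet_straddling_z_boundary_stays_continuous(self):
        rng = np.random.default_rng(1)
        n = 100
        xy = rng.uniform(0, 10, (n, 2))
        z = np.mod(19.8 + rng.uniform(0, 0.4, n), 20.0)  # wraps through 0
        g = build_leaflet_grid(np.column_stack([xy, z]), BOX)
        assert np.ptp(g.heights) < 1.0  # no 20 nm jump


class TestMorphology:
    def test_flat_area_is_box_cross_section(self):
        assert surface_area(flat_grid(5.0)) == pytest.approx(100.0, abs=1e-9)

    def test_sinusoid_area_matches_quadrature(self):
        box = SimulationBox(20.0, 20.0, 20.0)
        A = 2.0
        gx = np.arange(64) * box.Lx / 64
        g = LeafletGrid(
            np.tile(A * np.sin(2 * np.pi * gx / box.Lx)[:, None], (1, 64)), box
        )
        oracle = box.Ly * quad(
            lambda t: np.sqrt(
                1 + (A * 2 * np.pi / box.Lx * np.cos(2 * np.pi * t / box.Lx)) ** 2
            ),
            0, box.Lx, limit=200,
        )[0]
        assert surface_area(g) == pytest.approx(oracle, rel=0.01)

    def test_area_never_below_cross_section_and_refinement_converges(self):
        box = SimulationBox(20.0, 20.0, 20.0)
        pts = lattice_points(
            lambda X, Y: 1.5 * np.sin(2 * np.pi * X / box.Lx)
            * np.cos(2 * np.pi * Y / box.Ly),
            box, n=60,
        )
        areas = [
            surface_area(build_leaflet_grid(pts, box, n, n)) for n in (32, 64, 128)
        ]
        assert all(a >= box.Lx * box.Ly for a in areas)
        assert abs(areas[2] - areas[1]) / areas[1] < 1e-3

    def test_thickness_flat(self):
        assert bilayer_thickness(flat_grid(7.0), flat_grid(3.0)) == pytest.approx(4.0)

    def test_thickness_parallel_undulation_unchanged(self):
        rng = np.random.default_rng(3)
        und = rng.uniform(-1, 1, (16, 16))
        a = LeafletGrid(3.0 + und, BOX)
        b = LeafletGrid(7.0 + und, BOX)
        assert bilayer_thickness(b, a) == pytest.approx(4.0)

    def test_thickness_across_periodic_boundary(self):
        assert bilayer_thickness(flat_grid(19.0), flat_grid(1.0)) == pytest.approx(2.0)

    def test_resolution_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bilayer_thickness(flat_grid(3.0, n=8), flat_grid(7.0, n=16))


class TestCompartments:
    def surfaces(self):
        return BilayerSurfaces(
            tuple(
                flat_grid(z, label=l)
                for z, l in zip(
                    (4.0, 6.0, 14.0, 16.0),
                    ("b1_external", "b1_internal", "b2_internal", "b2_external"),
                )
            ),
            BOX,
        )

    def test_flat_slab_volumes(self):
        vols = self.surfaces().compartment_volumes()
        assert vols == pytest.approx(
            {"bilayer1": 200.0, "internal": 800.0, "bilayer2": 200.0, "external": 800.0}
        )
        assert sum(vols.values()) == pytest.approx(BOX.volume)

    def test_undulated_parallel_bilayer_volume_unchanged(self):
        und = 1.2 * np.sin(2 * np.pi * np.arange(16) / 16)[:, None] * np.ones((1, 16))
        grids = tuple(
            LeafletGrid(z + und, BOX, l)
            for z, l in zip((4.0, 6.0, 14.0, 16.0),
                            ("b1_external", "b1_internal", "b2_internal", "b2_external"))
        )
        vols = BilayerSurfaces(grids, BOX).compartment_volumes()
        assert vols["bilayer1"] == pytest.approx(200.0)
        assert sum(vols.values()) == pytest.approx(BOX.volume)

    def test_crossing_surfaces_rejected(self):
        h = np.full((8, 8), 6.0)
        h2 = np.full((8, 8), 4.0)
        h2[3, 3] = 6.5  # crosses above the upper leaflet locally
        grids = (
            LeafletGrid(h2, BOX, "b1_external"),
            LeafletGrid(h, BOX, "b1_internal"),
            flat_grid(14.0, n=8, label="b2_internal"),
            flat_grid(16.0, n=8, label="b2_external"),
        )
        with pytest.raises(SurfaceGeometryError, match="column"):
            BilayerSurfaces(grids, BOX).compartment_volumes()

    def test_locate_flat_cuts(self):
        s = self.surfaces()
        assert locate_compartment((1.0, 1.0, 15.0), s) == "bilayer2"
        assert locate_compartment((1.0, 1.0, 10.0), s) == "internal"
        assert locate_compartment((1.0, 1.0, 2.0), s) == "external"
        assert locate_compartment((1.0, 1.0, 19.0), s) == "external"
        assert locate_compartment((1.0, 1.0, 5.0), s) == "bilayer1"

    def test_planted_molecules_located_in_truth_compartments(self, role_map):
        from cgmem.profiles import molecule_centroids
        from cgmem.synthetic import IonPlacement, place_ions

        sys_ = make_undulated_system(seed=9, amplitude=0.4)
        sys_ = place_ions(sys_, IonPlacement(12, "dispersed_external"), seed=10)
        surf = BilayerSurfaces.from_frame(sys_.frame, role_map, external="wrap")
        frame = sys_.frame
        # waters and ions against construction labels
        for species, role in (("water", "water"), ("anion", "anion")):
            truth = sys_.truth.query("species == @species").set_index("molecule_id")
            centroids = molecule_centroids(frame, role_map, role)
            mols = sorted(
                {
                    int(m)
                    for m, r in zip(frame.molecule_ids, frame.residue_names)
                    if (r == "W") == (species == "water") and r in ("W", "ANI")
                }
            )
            labels = surf.locate(centroids)
            agree = [
                lab == truth.loc[m, "label"] for m, lab in zip(mols, labels)
            ]
            assert np.mean(agree) == 1.0

    def test_volume_conservation_on_random_undulated_systems(self, role_map):
        for seed in range(10):
            sys_ = make_undulated_system(
                seed=seed, amplitude=0.2 + 0.05 * seed, periods=(1 + seed % 2, seed % 3)
            )
            surf = BilayerSurfaces.from_frame(sys_.frame, role_map, external="wrap")
            vols = surf.compartment_volumes()
            assert sum(vols.values()) == pytest.approx(
                sys_.box.volume, rel=1e-3
            )


class TestPerLipid:
    def test_division(self):
        grids = tuple(
            flat_grid(z, label=l)
            for z, l in zip((4.0, 6.0, 14.0, 16.0),
                            ("b1_external", "b1_internal", "b2_internal", "b2_external"))
        )
        s = BilayerSurfaces(grids, BOX)
        counts = {l: 100 for l in
                  ("b1_external", "b1_internal", "b2_internal", "b2_external")}
        m = per_lipid_metrics(s, counts)
        assert m["area_per_lipid_b1_external"] == pytest.approx(1.0)
        assert m["volume_per_lipid_bilayer1"] == pytest.approx(1.0)
        # symmetric flat system: equal per-lipid areas on both sides
        assert m["area_per_lipid_b1_external"] == m["area_per_lipid_b1_internal"]

    def test_zero_count_rejected(self):
        s = BilayerSurfaces(
            tuple(flat_grid(z, label=l) for z, l in
                  zip((4.0, 6.0, 14.0, 16.0),
                      ("b1_external", "b1_internal", "b2_internal", "b2_external"))),
            BOX,
        )
        with pytest.raises(ValueError):
            per_lipid_metrics(s, {})
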