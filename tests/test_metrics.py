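"""Percentile statistics, profiles, convergence selection, distances, volumes."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.spatial.distance import cdist

from tpvdeploy.geometry import constant_profile, make_rvot_tube
from tpvdeploy.metrics import (
    convergence_study,
    field_statistics,
    intramural_profile,
    mesh_distances,
    perimeter_derived_diameter,
    section_perimeter,
    stent_enclosed_volume,
    weighted_percentiles,
)


class TestWeightedPercentiles:
    def test_matches_stated_interpolation_rule(self):
        # 1..100 with unit weights: the inclusive linear rule gives 95.05
        v = np.arange(1.0, 101.0)
        got = weighted_percentiles(v, np.ones_like(v), 0.95)
        assert got == pytest.approx(95.05)
        # and agrees with numpy's default linear quantile for unit weights
        q = np.linspace(0, 1, 11)
        assert weighted_percentiles(v, np.ones_like(v), q) == pytest.approx(
            np.quantile(v, q))

    def test_single_value(self):
        assert weighted_percentiles([3.3], [2.0], [0.0, 0.5, 1.0]) == pytest.approx(
            [3.3, 3.3, 3.3])

    def test_weight_scale_invariance(self, rng):
        v = rng.random(50)
        w = rng.random(50) + 0.1
        q = [0.25, 0.5, 0.9, 0.95]
        assert weighted_percentiles(v, w, q) == pytest.approx(
            weighted_percentiles(v, 2.0 * w, q))

    def test_reorder_invariance(self, rng):
        v = rng.random(80)
        w = rng.random(80) + 0.1
        perm = rng.permutation(80)
        assert weighted_percentiles(v, w, 0.95) == pytest.approx(
            weighted_percentiles(v[perm], w[perm], 0.95))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            weighted_percentiles([], [], 0.5)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.lists(st.floats(-100, 100), min_size=2, max_size=30), st.floats(0, 1))
def test_weighted_percentile_within_range(values, q):
    got = weighted_percentiles(values, np.ones(len(values)), q)[0]
    assert min(values) - 1e-9 <= got <= max(values) + 1e-9


class TestIntramuralProfile:
    def test_unloaded_station_zero_profile(self, default_deployment):
        # first station lies outside the device: identity solution
        t, e1 = intramural_profile(default_deployment, 0)
        assert np.allclose(e1, 0.0, atol=1e-14)

    def test_endpoints_exact(self, default_deployment):
        j = int(np.argmin(default_deployment.geometry.R_inner))
        t, e1 = intramural_profile(default_deployment, j)
        assert t[0] == 0.0 and t[-1] == 1.0

    def test_strain_decreases_outward(self, default_deployment):
        j = int(np.argmin(default_deployment.geometry.R_inner))
        t, e1 = intramural_profile(default_deployment, j)
        assert np.all(np.diff(e1) < 0)


class TestConvergence:
    def test_loose_criterion_selects_two(self, config, baseline_materials):
        from tpvdeploy.study import run_convergence

        table, selected = run_convergence(config, criterion_pct=100.0)
        assert selected == 2
        assert len(table) == 6

    def test_refinement_change_shrinks(self, config):
        from tpvdeploy.study import run_convergence

        table, selected = run_convergence(config, criterion_pct=1.0)
        assert selected is not None
        ch = table.change_p99_pct.to_numpy()[1:]
        assert ch[-1] < ch[0]  # refinement 5->6 moves far less than 1->2

    def test_selection_monotone_in_criterion(self, config):
        from tpvdeploy.study import run_convergence

        _, tight = run_convergence(config, criterion_pct=0.5)
        _, loose = run_convergence(config, criterion_pct=5.0)
        if tight is not None and loose is not None:
            assert loose <= tight


class TestMeshDistances:
    def test_self_distance_zero(self):
        m = make_rvot_tube(constant_profile(8.0), 20.0, 1.5).surface_trimesh()
        h, mean, p95 = mesh_distances(m, m, n_surface_samples=200, seed=0)
        assert h == pytest.approx(0.0, abs=1e-12)
        assert mean == pytest.approx(0.0, abs=1e-12)

    def test_concentric_cylinders(self):
        a = make_rvot_tube(constant_profile(10.0), 30.0, 1.0).surface_trimesh()
        b = make_rvot_tube(constant_profile(11.0), 30.0, 1.0).surface_trimesh()
        h, mean, p95 = mesh_distances(a, b, n_surface_samples=1500, seed=1)
        assert h == pytest.approx(1.0, abs=0.05)
        assert mean == pytest.approx(1.0, abs=0.02)
        assert p95 == pytest.approx(1.0, abs=0.03)

    def test_symmetry(self):
        a = make_rvot_tube(constant_profile(9.0), 25.0, 1.5).surface_trimesh()
        b = make_rvot_tube(constant_profile(10.5), 25.0, 1.5).surface_trimesh()
        f = mesh_distances(a, b, n_surface_samples=400, seed=7)
        g = mesh_distances(b, a, n_surface_samples=400, seed=7)
        assert f == pytest.approx(g)

    def test_point_cloud_brute_force_oracle(self, rng):
        """On raw point sets the implementation is the exact max-min Hausdorff."""
        A = rng.random((60, 3))
        B = rng.random((80, 3))
        D = cdist(A, B)
        h_exact = max(D.min(axis=1).max(), D.min(axis=0).max())
        pooled = np.concatenate([D.min(axis=1), D.min(axis=0)])
        h, mean, p95 = mesh_distances(A, B)
        assert h == pytest.approx(h_exact, abs=1e-12)
        assert mean == pytest.approx(pooled.mean(), abs=1e-12)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            mesh_distances(np.zeros((0, 3)), np.zeros((3, 3)))


class TestPerimeterDiameter:
    def test_circle(self):
        th = np.linspace(0, 2 * math.pi, 400, endpoint=False)
        pts = np.column_stack([6.0 * np.cos(th), 6.0 * np.sin(th)])
        assert section_perimeter(pts) / math.pi == pytest.approx(12.0, rel=1e-4)

    def test_ellipse_vs_quadrature(self):
        a, b = 6.0, 4.0
        th = np.linspace(0, 2 * math.pi, 2000, endpoint=False)
        pts = np.column_stack([a * np.cos(th), b * np.sin(th)])
        per = section_perimeter(pts)
        ref, _ = quad(lambda t: math.hypot(a * math.sin(t), b * math.cos(t)),
                      0, 2 * math.pi, limit=200)
        assert per == pytest.approx(ref, rel=1e-5)
        # Ramanujan approximation agrees too
        h = ((a - b) / (a + b)) ** 2
        ram = math.pi * (a + b) * (1 + 3 * h / (10 + math.sqrt(4 - 3 * h)))
        assert per / math.pi == pytest.approx(ram / math.pi, rel=1e-4)

    def test_rotation_invariance(self, rng):
        th = np.linspace(0, 2 * math.pi, 500, endpoint=False)
        pts = np.column_stack([6.0 * np.cos(th), 4.0 * np.sin(th)])
        ang = rng.random() * math.pi
        R = np.array([[math.cos(ang), -math.sin(ang)], [math.sin(ang), math.cos(ang)]])
        assert section_perimeter(pts @ R.T) == pytest.approx(section_perimeter(pts))

    def test_narrowest_station_of_deployment(self, default_deployment):
        d = perimeter_derived_diameter(default_deployment)
        r = default_deployment.r_inner_deployed
        covered = default_deployment.stent.covers(default_deployment.z)
        assert d == pytest.approx(2.0 * r[covered].min(), rel=1e-9)


class TestEnclosedVolume:
    def test_uniform_cylinder_thirds(self, baseline_materials):
        from tpvdeploy.geometry import make_stent_profile
        from tpvdeploy.rings import deploy

        geom = make_rvot_tube(constant_profile(10.0), 45.0, 1.5, 4)
        stent = make_stent_profile(geom, free_radius=12.5, length=45.0)
        res = deploy(geom, stent, baseline_materials)
        vols = stent_enclosed_volume(res)
        r = res.r_inner_deployed[0]
        expected = math.pi * r**2 * stent.length / 3.0
        for key in ("distal", "middle", "proximal"):
            assert vols[key] == pytest.approx(expected, rel=1e-9)

    def test_thirds_sum_to_total(self, default_deployment):
        vols = stent_enclosed_volume(default_deployment)
        assert vols["distal"] + vols["middle"] + vols["proximal"] == pytest.approx(
            vols["total"], rel=1e-10)

    def test_against_mesh_divergence_volume(self, default_deployment):
        """Trapezoidal volume vs the divergence-theorem volume of the deployed
        triangulated surface, capped, over the whole device extent."""
        import trimesh

        res = default_deployment
        stent = res.stent
        mask = stent.covers(res.z)
        zs = res.z[mask]
        rs = res.r_inner_deployed[mask]
        th = np.linspace(0, 2 * math.pi, 128, endpoint=False)
        rings = [np.column_stack([r * np.cos(th), r * np.sin(th), np.full_like(th, z)])
                 for z, r in zip(zs, rs)]
        verts = np.vstack(rings + [[[0, 0, zs[0]]], [[0, 0, zs[-1]]]])
        n = len(th)
        faces = []
        for i in range(len(zs) - 1):
            for j in range(n):
                a, b = i * n + j, i * n + (j + 1) % n
                c, d = (i + 1) * n + j, (i + 1) * n + (j + 1) % n
                faces += [[a, b, d], [a, d, c]]
        bot, top = len(verts) - 2, len(verts) - 1
        for j in range(n):
            faces.append([bot, (j + 1) % n, j])
            faces.append([top, (len(zs) - 1) * n + j, (len(zs) - 1) * n + (j + 1) % n])
        mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
        assert mesh.is_watertight
        vols = stent_enclosed_volume(res)
        assert vols["total"] == pytest.approx(abs(mesh.volume), rel=5e-3)


class TestFieldStatistics:
    def test_reorder_invariance(self, default_deployment, rng):
        tb = default_deployment.field_table
        shuffled = tb.sample(frac=1.0, random_state=1)
        assert field_statistics(tb) == pytest.approx(field_statistics(shuffled))

    def test_scope_partition_consistency(self, default_deployment):
        """Scoping to a label covering every row equals the whole-field stats."""
        tb = default_deployment.field_table.copy()
        tb["material_id"] = "patch"
        assert field_statistics(tb, scope="patch") == pytest.approx(
            field_statistics(tb))

    def test_percentile_ordering(self, default_deployment):
        s = field_statistics(default_deployment.field_table)
        for f in ("stress", "strain"):
            assert s[f"{f}_p75"] <= s[f"{f}_p95"] <= s[f"{f}_p99"] <= s[f"{f}_max"]
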