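"""Source space, spherical-conductor forward, whitening, minimum-norm inverse."""

import numpy as np
import pytest
from scipy.sparse.csgraph import shortest_path

from megalpha.source_model import (
    DB_FLOOR,
    MU0_OVER_4PI,
    compute_whitener,
    folded_normals,
    minimum_norm_inverse,
    octahedral_source_space,
    sarvas_field,
    sarvas_forward,
    source_band_power,
)


@pytest.fixture(scope="module")
def space3():
    return folded_normals(octahedral_source_space(3), tilt=1.0)


@pytest.fixture(scope="module")
def fwd3(space3, layout102):
    return sarvas_forward(space3, layout102)


class TestSourceSpace:
    @pytest.mark.parametrize(
        "depth,n_vertices", [(0, 6), (1, 18), (2, 66), (5, 4098)]
    )
    def test_vertex_counts(self, depth, n_vertices):
        space = octahedral_source_space(depth)
        assert space.n_vertices == n_vertices == 2 + 4 ** (depth + 1)

    def test_octahedron_euler(self):
        space = octahedral_source_space(0)
        assert space.faces.shape[0] == 8
        assert space.n_edges == 12
        assert space.euler_characteristic() == 2

    @pytest.mark.parametrize("depth", [1, 3, 5])
    def test_closed_surface_euler(self, depth):
        assert octahedral_source_space(depth).euler_characteristic() == 2

    def test_vertices_on_sphere_normals_unit(self):
        space = octahedral_source_space(3, radius=0.07)
        np.testing.assert_allclose(
            np.linalg.norm(space.vertices, axis=1), 0.07, atol=1e-12
        )
        np.testing.assert_allclose(
            np.linalg.norm(space.normals, axis=1), 1.0, atol=1e-12
        )

    def test_depth_guard(self):
        with pytest.raises(ValueError):
            octahedral_source_space(8)
        with pytest.raises(ValueError):
            octahedral_source_space(-1)

    def test_folded_normals_not_radial(self, space3):
        radial = space3.vertices / np.linalg.norm(
            space3.vertices, axis=1, keepdims=True
        )
        cosines = np.einsum("ij,ij->i", space3.normals, radial)
        assert np.median(cosines) < 0.95  # genuinely tilted
        np.testing.assert_allclose(
            np.linalg.norm(space3.normals, axis=1), 1.0, atol=1e-12
        )

    def test_mesh_adjacency_symmetric(self, space3):
        adj = space3.adjacency()
        np.testing.assert_array_equal(adj, adj.T)
        assert not adj.diagonal().any()
        assert (adj.sum(1) >= 4).all()


class TestSarvasForward:
    def test_radial_dipoles_silent(self, layout102):
        # the canonical spherical-conductor property: radially oriented
        # dipoles produce no external field
        rng = np.random.default_rng(0)
        for _ in range(20):
            r0 = rng.normal(size=3)
            r0 = 0.06 * r0 / np.linalg.norm(r0)
            q_rad = r0 / np.linalg.norm(r0)
            tang = np.cross(q_rad, [0.0, 0.0, 1.0])
            tang /= np.linalg.norm(tang)
            b_rad = sarvas_field(r0, q_rad, layout102.positions)
            b_tan = sarvas_field(r0, tang, layout102.positions)
            assert np.abs(b_rad).max() < 1e-12 * np.abs(b_tan).max()

    def test_linearity_in_moment(self, layout102):
        r0 = np.array([0.02, 0.01, 0.05])
        q = np.array([0.0, 1.0, 0.0])
        b1 = sarvas_field(r0, q, layout102.positions)
        b2 = sarvas_field(r0, 2 * q, layout102.positions)
        np.testing.assert_allclose(b2, 2 * b1, rtol=1e-12)

    def test_radial_component_matches_primary_dipole_oracle(self, layout102):
        # outside a spherically symmetric conductor the volume currents are
        # magnetically silent in the radial direction, so the radial field
        # equals that of the primary current dipole alone (Biot-Savart)
        r0 = np.array([0.0, 0.03, 0.05])
        q = np.array([1.0, 0.0, 0.0])
        b = sarvas_field(r0, q, layout102.positions)
        r = layout102.positions
        rhat = r / np.linalg.norm(r, axis=1, keepdims=True)
        a = r - r0
        primary = (
            MU0_OVER_4PI
            * np.cross(q, a)
            / np.linalg.norm(a, axis=1, keepdims=True) ** 3
        )
        oracle = np.einsum("ij,ij->i", primary, rhat)
        measured = np.einsum("ij,ij->i", b, rhat)
        np.testing.assert_allclose(measured, oracle, rtol=1e-10)

    def test_closer_source_has_larger_field(self, layout102):
        q = np.array([1.0, 0.0, 0.0])
        maxima = []
        for radius in (0.02, 0.04, 0.06, 0.08):
            r0 = np.array([0.0, 0.0, radius])
            b = sarvas_field(r0, q, layout102.positions)
            maxima.append(np.abs(b).max())
        assert np.all(np.diff(maxima) > 0)

    def test_lead_field_shape_and_units(self, fwd3, space3, layout102):
        assert fwd3.lead_field.shape == (306, space3.n_vertices)
        assert np.isfinite(fwd3.lead_field).all()

    def test_sensor_inside_conductor_rejected(self, space3, layout102):
        import dataclasses

        bad = dataclasses.replace(layout102, positions=layout102.positions * 0.5)
        with pytest.raises(ValueError, match="outside"):
            sarvas_forward(space3, bad)

    def test_source_outside_conductor_rejected(self, layout102):
        space = octahedral_source_space(1, radius=0.095)
        with pytest.raises(ValueError, match="inside"):
            sarvas_forward(space, layout102)


class TestWhitener:
    def test_identity_covariance(self, rng):
        x = rng.standard_normal((20, 20_000))
        w = compute_whitener(x)
        wx = w @ x
        cov = np.cov(wx)
        assert np.linalg.norm(cov - np.eye(20)) / np.linalg.norm(np.eye(20)) < 0.05

    def test_equalises_scaled_channels(self, rng):
        x = rng.standard_normal((10, 10_000))
        x[5:] *= 10.0  # "gradiometers" in different units
        w = compute_whitener(x)
        var = (w @ x).var(axis=1)
        np.testing.assert_allclose(var, 1.0, rtol=0.1)

    def test_rank_deficient_needs_ridge(self, rng):
        x = rng.standard_normal((6, 1000))
        x[5] = x[4]  # duplicated channel
        with pytest.raises(ValueError, match="ridge"):
            compute_whitener(x)
        w = compute_whitener(x, ridge=0.1)
        assert np.isfinite(w).all()


class TestMinimumNormInverse:
    def test_kernel_matches_closed_form_oracle(self, rng):
        # independent dense-linear-algebra computation on a 10-sensor /
        # 20-source toy with identity source covariance
        lead = rng.standard_normal((10, 20))
        whitener = np.linalg.cholesky(
            np.linalg.inv(np.cov(rng.standard_normal((10, 500))))
        ).T
        from megalpha.source_model import ForwardOperator

        fwd = ForwardOperator(
            lead_field=lead, sphere_center=np.zeros(3), conductor_radius=0.09
        )
        lam2 = 0.3
        inv = minimum_norm_inverse(fwd, whitener, lam2, scale_source_cov=False)
        lw = whitener @ lead
        oracle = lw.T @ np.linalg.pinv(lw @ lw.T + lam2 * np.eye(10))
        assert np.abs(inv.kernel - oracle).max() < 1e-8

    def test_ridge_limit_shrinks_estimates(self, fwd3, layout102, rng):
        w = np.eye(layout102.n_channels)
        data = fwd3.lead_field[:, 7][:, None]
        norms = []
        for lam2 in (0.01, 0.1, 1.0, 10.0, 100.0):
            inv = minimum_norm_inverse(fwd3, w, lam2)
            norms.append(np.linalg.norm(inv.apply(data)))
        assert np.all(np.diff(norms) < 0)

    def test_noiseless_localisation_within_two_neighbours(self, fwd3, space3,
                                                          layout102):
        w = np.eye(layout102.n_channels)
        inv = minimum_norm_inverse(fwd3, w, lambda2=1.0 / 9.0)
        adj = space3.adjacency()
        dist = shortest_path(adj, unweighted=True)
        rng = np.random.default_rng(3)
        for true_vertex in rng.choice(space3.n_vertices, size=8, replace=False):
            data = fwd3.lead_field[:, true_vertex][:, None]
            est = np.abs(inv.apply(data)[:, 0])
            peak = int(np.argmax(est))
            assert dist[true_vertex, peak] <= 2

    def test_two_separated_sources_recovered(self, fwd3, space3, layout102):
        # two tangential-ish sources > 60 degrees apart, noiseless data
        v1 = int(np.argmax(space3.vertices[:, 2]))  # top
        v2 = int(np.argmax(space3.vertices[:, 1]))  # side, 90 degrees away
        t = np.linspace(0, 2 * np.pi, 600)
        data = (
            np.outer(fwd3.lead_field[:, v1], np.sin(7 * t))
            + np.outer(fwd3.lead_field[:, v2], np.cos(11 * t))
        )
        inv = minimum_norm_inverse(fwd3, np.eye(layout102.n_channels), 1.0 / 9.0)
        power = (inv.apply(data) ** 2).sum(axis=1)
        adj = space3.adjacency()
        dist = shortest_path(adj, unweighted=True)
        # the two strongest well-separated peaks sit within 2 neighbours of truth
        order = np.argsort(power)[::-1]
        peak1 = int(order[0])
        peak2 = next(int(i) for i in order if dist[peak1, i] > 4)
        found = {peak1, peak2}
        for true_vertex in (v1, v2):
            assert any(dist[true_vertex, p] <= 2 for p in found)

    def test_nonfinite_lead_field_rejected(self, layout102):
        from megalpha.source_model import ForwardOperator

        lead = np.full((306, 5), np.nan)
        fwd = ForwardOperator(lead_field=lead, sphere_center=np.zeros(3),
                              conductor_radius=0.09)
        with pytest.raises(ValueError, match="finite"):
            minimum_norm_inverse(fwd, np.eye(306), 0.1)


class TestSourceBandPower:
    def make_inverse(self, n_src=4, n_ch=6, seed=0):
        from megalpha.source_model import InverseOperator

        rng = np.random.default_rng(seed)
        kernel = rng.standard_normal((n_src, n_ch))
        return InverseOperator(kernel=kernel, whitener=np.eye(n_ch), lambda2=0.1)

    def test_zero_data_floored(self):
        inv = self.make_inverse()
        db = source_band_power(inv, np.zeros((6, 2048)), (8, 12), 1000.0)
        assert (db == DB_FLOOR).all()

    def test_scaling_adds_20_db(self, rng):
        inv = self.make_inverse()
        x = rng.standard_normal((6, 4096))
        db1 = source_band_power(inv, x, (8, 12), 1000.0)
        db2 = source_band_power(inv, 10 * x, (8, 12), 1000.0)
        np.testing.assert_allclose(db2 - db1, 20.0, atol=1e-9)

    def test_simulated_source_peaks_at_own_vertex(self, fwd3, space3, layout102):
        v = int(np.argmax(space3.vertices[:, 2]))
        fs = 500.0
        t = np.arange(int(8 * fs)) / fs
        data = np.outer(fwd3.lead_field[:, v], np.sin(2 * np.pi * 10.0 * t))
        inv = minimum_norm_inverse(fwd3, np.eye(layout102.n_channels), 1.0 / 9.0)
        db = source_band_power(inv, data, (8, 12), fs)
        adj = space3.adjacency()
        dist = shortest_path(adj, unweighted=True, indices=[v])[0]
        assert dist[int(np.argmax(db))] <= 2
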