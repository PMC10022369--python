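"""Voxel morphometrics, ellipse fitting and CSSI from contour scaffolds."""

import math

import numpy as np
import pytest

import fiberfield as ff
from fiberfield.morphometry import (
    Ellipse,
    NeuronScaffold,
    cssi,
    cssi_of_neuron,
    dv_length,
    exclude_cut_somas,
    fit_ellipse,
    neuron_record,
    read_scaffolds,
    soma_centroid,
    soma_volume,
    write_scaffolds,
)
from fiberfield.synthetic_tissue import TissueVolume, rasterize_somas

from conftest import make_ellipsoid_population


def square_contour(cx, cy, half):
    return np.array(
        [[cx - half, cy - half], [cx + half, cy - half],
         [cx + half, cy + half], [cx - half, cy + half]]
    )


def circle_contour(cx, cy, r, n=64):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([cx + r * np.cos(t), cy + r * np.sin(t)])


def sphere_scaffold(center, radius, voxel=(0.81, 0.81, 3.0)):
    pop = make_ellipsoid_population(center=center, radius=radius)
    vol = TissueVolume(shape="box", dimensions=(200.0, 200.0, 300.0), voxel_size=voxel)
    return rasterize_somas(pop, vol)[0]


class TestSomaVolume:
    def test_single_voxel(self):
        # a tiny square around one voxel center (0.405, 0.405)
        sc = NeuronScaffold(
            "n1", [(0, square_contour(0.405, 0.405, 0.2))], z_step=3.0,
            voxel_size=(0.81, 0.81),
        )
        assert soma_volume(sc) == pytest.approx(0.81 * 0.81 * 3.0)

    def test_sphere_matches_analytic(self):
        sc = sphere_scaffold((30.0, 30.0, 150.0), 8.85)
        true = 4 / 3 * math.pi * 8.85**3
        assert soma_volume(sc) == pytest.approx(true, rel=0.10)
        assert true == pytest.approx(2.9e3, rel=0.01)

    def test_refinement_shrinks_error_monotonically(self):
        true = 4 / 3 * math.pi * 8.85**3
        errors = []
        for voxel in [(0.81, 0.81, 3.0), (0.405, 0.405, 1.5), (0.202, 0.202, 0.5)]:
            sc = sphere_scaffold((30.0, 30.0, 150.0), 8.85, voxel=voxel)
            errors.append(abs(soma_volume(sc) - true) / true)
        assert errors[0] > errors[1] > errors[2]

    def test_empty_scaffold_rejected(self):
        with pytest.raises(ValueError):
            NeuronScaffold("n1", [], z_step=3.0)


class TestSomaCentroid:
    def test_sphere_centroid_symmetric(self):
        sc = sphere_scaffold((30.0, 30.0, 150.0), 8.85)
        c = soma_centroid(sc)
        assert np.allclose(c, [30.0, 30.0, 150.0], atol=0.5)

    def test_hemisphere_centroid(self):
        # hemisphere of radius r cut at its equator: centroid 3r/8 above the cut
        r = 10.0
        z_step, vox = 0.5, 0.1
        contours = []
        for k in range(0, int(r / z_step) + 1):
            z = k * z_step
            if z >= r:
                break
            rho = math.sqrt(r * r - z * z)
            contours.append((k, circle_contour(0.0, 0.0, rho, n=128)))
        sc = NeuronScaffold("hemi", contours, z_step=z_step, voxel_size=(vox, vox))
        c = soma_centroid(sc)
        assert c[2] == pytest.approx(3 * r / 8, abs=z_step)

    def test_translation_equivariance(self):
        # shift by whole voxel pitches so the interior lattice translates
        # rigidly with the contours
        sc = sphere_scaffold((30.0, 30.0, 150.0), 6.0)
        shift = np.array([5 * 0.81, -3 * 0.81])
        moved = NeuronScaffold(
            sc.neuron_id,
            [(z, poly + shift) for z, poly in sc.contours],
            z_step=sc.z_step,
            voxel_size=sc.voxel_size,
        )
        assert np.allclose(
            soma_centroid(moved) - soma_centroid(sc), [*shift, 0.0], atol=1e-9
        )


class TestFitEllipse:
    @pytest.mark.parametrize("theta_deg", [0.0, 30.0, 117.0])
    def test_recovers_axes_and_orientation(self, theta_deg):
        t = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        pts = np.column_stack([12 * np.cos(t), 6 * np.sin(t)])
        th = math.radians(theta_deg)
        rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        e = fit_ellipse(pts @ rot.T + np.array([4.0, -2.0]))
        assert e.a == pytest.approx(6.0, abs=1e-6)
        assert e.b == pytest.approx(12.0, abs=1e-6)
        assert math.sin(e.orientation - th) == pytest.approx(0.0, abs=1e-6)
        assert e.center == pytest.approx((4.0, -2.0), abs=1e-6)

    def test_circle_gives_zero_cssi(self):
        e = fit_ellipse(circle_contour(1.0, 2.0, 5.0))
        assert e.a == pytest.approx(e.b, rel=1e-9)
        assert cssi(e) == pytest.approx(0.0, abs=1e-9)

    def test_collinear_rejected(self):
        pts = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(ValueError):
            fit_ellipse(pts)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_ellipse(np.zeros((4, 2)))

    def test_agrees_with_skimage_on_noisy_data(self):
        # independent cross-check against skimage's ellipse model
        from skimage.measure import EllipseModel

        rng = np.random.default_rng(5)
        t = np.linspace(0, 2 * np.pi, 60, endpoint=False)
        pts = np.column_stack([9 * np.cos(t) + 1, 5 * np.sin(t) - 2])
        pts += rng.normal(0, 0.05, pts.shape)
        ours = fit_ellipse(pts)
        model = EllipseModel.from_estimate(pts)
        assert model
        ref_minor, ref_major = sorted(model.axis_lengths)
        assert ours.a == pytest.approx(ref_minor, rel=0.02)
        assert ours.b == pytest.approx(ref_major, rel=0.02)


class TestCssi:
    @pytest.mark.parametrize(
        "a,b,expected", [(5.0, 5.0, 0.0), (2.0, 6.0, 1.0), (3.0, 4.0, 2 / 7)]
    )
    def test_values(self, a, b, expected):
        assert cssi(Ellipse((0, 0), a, b)) == pytest.approx(expected)

    def test_scale_invariance(self):
        e1 = Ellipse((0, 0), 3.0, 7.0)
        e2 = Ellipse((0, 0), 30.0, 70.0)
        assert cssi(e1) == pytest.approx(cssi(e2))

    def test_of_neuron_uses_equatorial_plane(self):
        pop = make_ellipsoid_population(cssi=0.5, orientation=0.7)
        vol = TissueVolume(
            shape="box", dimensions=(200.0, 200.0, 300.0),
            voxel_size=(0.405, 0.405, 1.5),
        )
        sc = rasterize_somas(pop, vol)[0]
        assert cssi_of_neuron(sc) == pytest.approx(0.5, abs=1e-3)

    def test_tie_breaks_to_dorsal_plane(self):
        # two equal-area planes with different shapes: the dorsal (lower
        # z-index) one decides the CSSI
        stretched = np.column_stack(
            [12 * np.cos(np.linspace(0, 2 * np.pi, 64, endpoint=False)),
             3 * np.sin(np.linspace(0, 2 * np.pi, 64, endpoint=False))]
        )
        circ = circle_contour(0.0, 0.0, 6.0)  # same area pi*36
        sc = NeuronScaffold("tie", [(0, circ), (1, stretched)], z_step=3.0)
        assert cssi_of_neuron(sc) == pytest.approx(0.0, abs=1e-6)

    def test_vertex_order_invariance(self):
        pts = circle_contour(0.0, 0.0, 5.0)
        sc_fwd = NeuronScaffold("a", [(0, pts)], z_step=3.0)
        sc_rev = NeuronScaffold("a", [(0, pts[::-1])], z_step=3.0)
        sc_rot = NeuronScaffold("a", [(0, np.roll(pts, 13, axis=0))], z_step=3.0)
        v = soma_volume(sc_fwd)
        assert soma_volume(sc_rev) == pytest.approx(v)
        assert soma_volume(sc_rot) == pytest.approx(v)
        assert cssi_of_neuron(sc_rev) == pytest.approx(cssi_of_neuron(sc_fwd), abs=1e-9)


class TestCssiProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        a=st.floats(0.5, 20.0),
        ratio=st.floats(1.0, 5.0),
        scale=st.floats(0.1, 10.0),
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_bounded_and_scale_invariant(self, a, ratio, scale):
        e1 = Ellipse((0.0, 0.0), a, a * ratio)
        e2 = Ellipse((0.0, 0.0), a * scale, a * ratio * scale)
        assert 0.0 <= cssi(e1) < 2.0
        assert cssi(e1) == pytest.approx(cssi(e2), rel=1e-9)

    @given(
        a=st.floats(2.0, 8.0),
        ratio=st.floats(1.05, 4.0),
        theta=st.floats(0.0, math.pi),
    )
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_fit_recovers_random_ellipses(self, a, ratio, theta):
        t = np.linspace(0, 2 * np.pi, 36, endpoint=False)
        pts = np.column_stack([a * ratio * np.cos(t), a * np.sin(t)])
        rot = np.array(
            [[math.cos(theta), -math.sin(theta)],
             [math.sin(theta), math.cos(theta)]]
        )
        e = fit_ellipse(pts @ rot.T)
        assert e.a == pytest.approx(a, rel=1e-6)
        assert e.b == pytest.approx(a * ratio, rel=1e-6)


class TestDvLength:
    def test_plane_count_times_step(self):
        contours = [(k, circle_contour(0, 0, 3.0)) for k in range(5)]
        assert dv_length(NeuronScaffold("n", contours, z_step=3.0)) == 15.0
        contours = [(k, circle_contour(0, 0, 3.0)) for k in range(20)]
        assert dv_length(NeuronScaffold("n", contours, z_step=0.5)) == 10.0

    def test_sphere_extent(self):
        sc = sphere_scaffold((30.0, 30.0, 150.0), 8.85)
        n_planes = len(set(sc.z_indices))
        assert dv_length(sc) == n_planes * sc.z_step
        assert dv_length(sc) >= 2 * 8.85 - 2 * sc.z_step


class TestBoundaryCutExclusion:
    def _records(self, scaffolds, bounds):
        return [neuron_record(s, slice_z_range=bounds) for s in scaffolds]

    def test_top_cut_excluded_interior_retained(self):
        bounds = (0.0, 300.0)
        top = sphere_scaffold((30.0, 30.0, 0.0), 8.85)  # equator at the top
        interior = sphere_scaffold((60.0, 60.0, 150.0), 8.85)
        top.neuron_id = "top"
        interior.neuron_id = "interior"
        records = self._records([top, interior], bounds)
        assert records[0].boundary_cut and not records[1].boundary_cut
        kept = exclude_cut_somas(records, [top, interior], bounds)
        assert [r.neuron_id for r in kept] == [interior.neuron_id]

    def test_hemisphere_clipped_at_equator_excluded(self):
        bounds = (0.0, 300.0)
        sc = sphere_scaffold((30.0, 30.0, 299.0), 8.85)  # max area near bottom
        rec = neuron_record(sc, slice_z_range=bounds)
        assert rec.boundary_cut


class TestScaffoldIO:
    def test_round_trip(self, tmp_path):
        sc = sphere_scaffold((30.0, 30.0, 150.0), 6.0)
        path = tmp_path / "scaffolds.json"
        write_scaffolds(path, [sc], slice_bounds=(0.0, 300.0))
        loaded, bounds = read_scaffolds(path)
        assert bounds == (0.0, 300.0)
        assert loaded[0].neuron_id == sc.neuron_id
        assert soma_volume(loaded[0]) == pytest.approx(soma_volume(sc))
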