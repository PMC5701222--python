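"""Fork centerline construction and rasterization."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import cfmsim as cm
from cfmsim.geometry import _fork_mask


def _params(**kw):
    defaults = dict(beta=0.0, diameter_um=5.6)
    defaults.update(kw)
    return cm.CFMParams(**defaults)


class TestCenterline:
    @pytest.mark.parametrize(
        "beta,expected_over_a",
        [(0.0, 2.0), (45.0, 1.0 + 2.0 * np.sqrt(2.0)), (90.0, 3.0)],
    )
    def test_total_length_identities(self, beta, expected_over_a):
        """Trunk + branches measure 2a, a(1+2*sqrt(2)), 3a at 0/45/90 deg."""
        p = _params(beta=beta)
        fork = cm.build_fork(p)
        assert fork.total_length() / p.half_side_um == pytest.approx(
            expected_over_a, abs=1e-12
        )

    @given(
        beta=st.one_of(st.just(0.0), st.floats(0.5, 90.0)),
        phi=st.floats(0.0, 90.0),
        orientation=st.sampled_from([1, 2, 3]),
    )
    def test_total_length_closed_form(self, beta, phi, orientation):
        """Union length = a + 2a/max(cos b, sin b) for b > 0, 2a at b = 0,
        independent of rotation angle and orientation.  (Angles below the
        double-precision branch-separation scale behave as b = 0.)"""
        p = _params(beta=beta, phi=phi, orientation=orientation)
        a = p.half_side_um
        b = np.deg2rad(beta)
        if beta == 0.0:
            expected = 2.0 * a
        else:
            expected = a + 2.0 * a / max(np.cos(b), np.sin(b))
        assert cm.build_fork(p).total_length() == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("beta", [0.0, 15.0, 45.0, 60.0, 90.0])
    def test_branches_terminate_on_cube_face(self, beta):
        p = _params(beta=beta)
        fork = cm.build_fork(p)
        for seg in (fork.branch_a, fork.branch_b):
            tip = seg[1]
            on_face = np.isclose(tip, 0.0, atol=1e-9) | np.isclose(
                tip, p.cube_side_um, atol=1e-9
            )
            assert on_face.any()

    def test_branches_collinear_at_beta_zero(self):
        fork = cm.build_fork(_params(beta=0.0))
        np.testing.assert_allclose(fork.branch_a, fork.branch_b)
        trunk_dir = fork.trunk[1] - fork.trunk[0]
        branch_dir = fork.branch_a[1] - fork.branch_a[0]
        cross = np.cross(trunk_dir, branch_dir)
        assert np.linalg.norm(cross) == pytest.approx(0.0, abs=1e-9)

    def test_branches_share_trunk_distal_endpoint(self):
        fork = cm.build_fork(_params(beta=30.0, phi=20.0))
        np.testing.assert_allclose(fork.trunk[1], fork.branch_a[0])
        np.testing.assert_allclose(fork.trunk[1], fork.branch_b[0])

    def test_t_shape_branches_perpendicular_to_trunk(self):
        fork = cm.build_fork(_params(beta=90.0))
        trunk_dir = fork.trunk[1] - fork.trunk[0]
        for seg in (fork.branch_a, fork.branch_b):
            d = seg[1] - seg[0]
            assert float(trunk_dir @ d) == pytest.approx(0.0, abs=1e-9)

    def test_offset_outside_cube_rejected(self):
        with pytest.raises(ValueError, match="outside the cube"):
            cm.build_fork(_params(beta=0.0), center_offset=(0.0, 40.0, 0.0))

    @pytest.mark.parametrize(
        "kw",
        [
            dict(beta=-1.0),
            dict(beta=91.0),
            dict(beta=0.0, phi=100.0),
            dict(beta=0.0, orientation=4),
            dict(beta=0.0, diameter_um=0.0),
            dict(beta=0.0, diameter_um=40.0),
            dict(beta=0.0, n_segments=2),
            dict(beta=0.0, n_segments=11),
            dict(beta=0.0, grid_n=33),
        ],
    )
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ValueError):
            _params(**kw)


class TestRasterize:
    def test_empty_geometry(self):
        smap = cm.rasterize([], _params())
        assert smap.volume_fraction == 0.0
        assert not smap.values.any()

    def test_single_cylinder_volume_fraction(self, cyl86_map):
        """Voxel count against the analytic cylinder volume pi R^2 L / V."""
        analytic = np.pi * 4.3**2 * 64.0 / 64.0**3
        assert cyl86_map.volume_fraction == pytest.approx(analytic, rel=0.10)

    def test_interior_value_is_si_susceptibility(self):
        p = _params(chi_cgs=1e-7, grid_n=64)
        smap = cm.build_susceptibility_map(p)
        inside = smap.values[smap.inside_mask]
        assert inside.min() == inside.max() == pytest.approx(4.0 * np.pi * 1e-7)
        assert not smap.values[~smap.inside_mask].any()

    def test_f_converges_with_resolution(self):
        """Shrinking voxels drives f toward the analytic fraction.

        Binary voxel-center rasterization converges with oscillating error,
        so the check compares the finest grid against the coarsest rather
        than demanding pairwise monotonicity.
        """
        analytic = np.pi * 4.3**2 * 64.0 / 64.0**3
        errors = []
        for n in (32, 64, 128):
            p = _params(diameter_um=8.6, grid_n=n)
            f = cm.build_susceptibility_map(p).volume_fraction
            errors.append(abs(f - analytic) / analytic)
        assert errors[2] < errors[0]
        assert errors[2] < 0.03
        assert max(errors) < 0.15

    def test_union_idempotence(self):
        p = _params(beta=45.0, grid_n=64)
        fork = cm.build_fork(p)
        once = cm.rasterize([fork], p)
        twice = cm.rasterize([fork, fork], p)
        np.testing.assert_array_equal(once.inside_mask, twice.inside_mask)

    def test_phi_rotation_preserves_voxel_count(self):
        """Orientation-1 in-plane rotation: equal masks counts within 2%."""
        counts = []
        for phi in (0.0, 90.0):
            p = _params(beta=45.0, phi=phi, grid_n=64)
            counts.append(cm.build_susceptibility_map(p).inside_mask.sum())
        assert abs(counts[0] - counts[1]) / counts[1] < 0.02

    def test_zero_length_segment_rejected(self):
        p = _params()
        point = np.array([[32.0, 32.0, 32.0], [32.0, 32.0, 32.0]])
        broken = cm.ForkCenterline(
            trunk=point, branch_a=point, branch_b=point, radius_um=1.0
        )
        with pytest.raises(ValueError, match="zero-length"):
            cm.rasterize([broken], p)


class TestPlacement:
    def test_single_fork_centered(self):
        p = _params(beta=30.0)
        (fork,) = cm.place_forks(p)
        np.testing.assert_allclose(fork.trunk[1], [32.0, 32.0, 32.0])

    def test_nine_straight_cylinders_cross_section(self):
        """n = 9 at beta = 0: 3x3 lattice, f about nine times the single-fork f."""
        p1 = _params(beta=0.0, n_segments=1, grid_n=64)
        p9 = _params(beta=0.0, n_segments=9, grid_n=64)
        f1 = cm.build_susceptibility_map(p1).volume_fraction
        f9 = cm.build_susceptibility_map(p9).volume_fraction
        assert f9 == pytest.approx(9.0 * f1, rel=0.02)
        forks = cm.place_forks(p9)
        trunks = np.array([f.trunk[1] for f in forks])
        # 3 distinct y levels x 3 distinct z levels
        assert len(set(np.round(trunks[:, 1], 6))) == 3
        assert len(set(np.round(trunks[:, 2], 6))) == 3

    def test_volume_fraction_increases_with_segments(self):
        fs = []
        for n_seg in (1, 3, 5, 7, 9):
            p = _params(beta=45.0, n_segments=n_seg, grid_n=64)
            fs.append(cm.build_susceptibility_map(p).volume_fraction)
        assert all(b > a for a, b in zip(fs, fs[1:]))

    def test_tight_lattice_overlap_detected(self):
        """Deliberately small spacing: rasterized masks intersect."""
        p = _params(beta=90.0, diameter_um=8.6, n_segments=3, grid_n=64)
        with pytest.raises(cm.OverlapError):
            cm.place_forks(p, spacing_um=6.0)
        with pytest.raises(cm.OverlapError):
            cm.build_susceptibility_map(p, spacing_um=6.0)

    def test_default_lattice_overlap_free(self):
        p = _params(beta=90.0, diameter_um=5.6, n_segments=9, grid_n=64)
        forks = cm.place_forks(p)
        masks = [_fork_mask(f, p) for f in forks]
        total = sum(m.sum() for m in masks)
        union = np.zeros_like(masks[0])
        for m in masks:
            union |= m
        assert union.sum() == total


class TestVolumeFraction:
    def test_empty_and_full(self, empty_map):
        assert cm.volume_fraction(empty_map) == 0.0
        n = empty_map.values.shape[0]
        full = cm.SusceptibilityMap(
            values=np.ones((n, n, n)),
            inside_mask=np.ones((n, n, n), dtype=bool),
            voxel_size_um=2.0,
            volume_fraction=1.0,
        )
        assert cm.volume_fraction(full) == 1.0

    def test_matches_mask_count(self, cyl86_map):
        n3 = cyl86_map.inside_mask.size
        assert cm.volume_fraction(cyl86_map) == cyl86_map.inside_mask.sum() / n3
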