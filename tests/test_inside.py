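"""The point-in-surface counting engine."""

import numpy as np
import pytest

from hippomesh.inside import (
    SampleGrid,
    build_grid,
    count_inside,
    occupancy,
    occupancy_bruteforce,
    points_inside,
    points_inside_bruteforce,
)
from hippomesh.surfaces import NotWatertightError, TriSurface


def _winding_number(surface, pts):
    """Independent oracle: generalized winding number via signed solid angles."""
    v, f = surface.vertices, surface.faces
    out = np.zeros(len(pts))
    for i, p in enumerate(pts):
        a, b, c = v[f[:, 0]] - p, v[f[:, 1]] - p, v[f[:, 2]] - p
        la, lb, lc = (np.linalg.norm(x, axis=1) for x in (a, b, c))
        num = np.einsum("ij,ij->i", a, np.cross(b, c))
        den = (
            la * lb * lc
            + np.einsum("ij,ij->i", a, b) * lc
            + np.einsum("ij,ij->i", b, c) * la
            + np.einsum("ij,ij->i", a, c) * lb
        )
        out[i] = np.sum(2 * np.arctan2(num, den)) / (4 * np.pi)
    return out


class TestBuildGrid:
    def test_unit_cube_grid_arithmetic(self, unit_cube_surface):
        g = build_grid([unit_cube_surface], spacing=0.5, margin=1.0)
        assert all(d >= 7 for d in g.dims)
        assert all(o <= -1 for o in g.origin)
        assert g.encloses(unit_cube_surface)

    def test_grid_encloses_disjoint_surfaces(self, two_blob_surface, sphere_surface):
        g = build_grid([two_blob_surface, sphere_surface], spacing=1.0, margin=2.0)
        assert g.encloses(two_blob_surface) and g.encloses(sphere_surface)

    def test_deterministic(self, sphere_surface):
        assert build_grid([sphere_surface], 0.5, 2.0) == build_grid([sphere_surface], 0.5, 2.0)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            build_grid([], 0.5)

    def test_invalid_spacing_rejected(self):
        with pytest.raises(ValueError):
            SampleGrid(origin=(0, 0, 0), spacing=-1.0, dims=(2, 2, 2))


class TestOccupancy:
    def test_sphere_centre_inside_far_point_outside(self, sphere_surface):
        flags = points_inside(sphere_surface, np.array([[0.0, 0.0, 0.0], [40.0, 40.0, 40.0]]))
        assert flags.tolist() == [True, False]

    def test_sphere_count_volume_within_one_percent(self, sphere_surface):
        g = build_grid([sphere_surface], spacing=0.5, margin=2.0)
        occ = occupancy(sphere_surface, g)
        assert occ.volume() == pytest.approx(sphere_surface.signed_volume(), rel=0.01)

    def test_complement_counts_sum_to_grid_size(self, small_sphere_surface):
        g = build_grid([small_sphere_surface], spacing=0.5, margin=2.0)
        occ = occupancy(small_sphere_surface, g)
        assert count_inside(occ) + int((~occ.inside_flags).sum()) == g.n_points

    def test_halving_spacing_scales_count_roughly_eightfold(self, small_sphere_surface):
        c = {}
        for h in (1.0, 0.5):
            g = build_grid([small_sphere_surface], spacing=h, margin=2.0)
            c[h] = count_inside(occupancy(small_sphere_surface, g))
        assert c[0.5] / c[1.0] == pytest.approx(8.0, rel=0.05)

    def test_boundary_layer_of_grid_is_outside(self, small_sphere_surface):
        g = build_grid([small_sphere_surface], spacing=1.0, margin=2.0)
        f = occupancy(small_sphere_surface, g).inside_flags
        assert not (f[0].any() or f[-1].any() or f[:, 0].any() or f[:, -1].any()
                    or f[:, :, 0].any() or f[:, :, -1].any())

    def test_open_surface_rejected(self, unit_cube_surface):
        open_surf = TriSurface(unit_cube_surface.vertices, unit_cube_surface.faces[:-1], validate=False)
        g = SampleGrid(origin=(-2, -2, -2), spacing=0.5, dims=(11, 11, 11))
        with pytest.raises(NotWatertightError):
            occupancy(open_surf, g)

    def test_grid_must_enclose_surface(self, sphere_surface):
        g = SampleGrid(origin=(-2, -2, -2), spacing=0.5, dims=(5, 5, 5))
        with pytest.raises(ValueError, match="enclose"):
            occupancy(sphere_surface, g)


class TestOracleEquivalence:
    @pytest.mark.parametrize("fixture", [
        "sphere_surface", "small_sphere_surface", "bent_tube_surface",
        "ellipsoid_surface", "two_blob_surface",
    ])
    def test_accelerated_equals_bruteforce_on_random_points(self, fixture, request):
        surf = request.getfixturevalue(fixture)
        rng = np.random.default_rng(hash(fixture) % 2**31)
        lo, hi = surf.bounds()
        pts = rng.uniform(lo - 2, hi + 2, (120, 3))
        acc = points_inside(surf, pts)
        bru = points_inside_bruteforce(surf, pts)
        assert np.array_equal(acc, bru)
        assert 0 < acc.sum() < len(pts)  # both classes exercised

    def test_grid_occupancy_accelerated_equals_bruteforce(self, small_sphere_surface):
        # the grid deliberately hits many mesh vertices/edges exactly
        g = build_grid([small_sphere_surface], spacing=0.5, margin=2.0)
        acc = occupancy(small_sphere_surface, g)
        bru = occupancy_bruteforce(small_sphere_surface, g)
        assert np.array_equal(acc.inside_flags, bru.inside_flags)

    def test_agreement_with_winding_number_oracle(self, bent_tube_surface):
        rng = np.random.default_rng(42)
        lo, hi = bent_tube_surface.bounds()
        pts = rng.uniform(lo - 1, hi + 1, (200, 3))
        w = _winding_number(bent_tube_surface, pts)
        clear = np.abs(w - 0.5) > 0.05  # skip points on/near the surface
        mine = points_inside(bent_tube_surface, pts[clear])
        assert np.array_equal(mine, w[clear] > 0.5)


class TestTranslationEquivariance:
    def test_shifting_surface_and_grid_together_keeps_flags(self, small_sphere_surface):
        from hypothesis import given, settings, strategies as st

        @settings(max_examples=10, deadline=None, derandomize=True)
        @given(st.tuples(*[st.floats(-7, 7, allow_nan=False) for _ in range(3)]))
        def run(shift):
            shift = np.asarray(shift)
            g = build_grid([small_sphere_surface], spacing=1.0, margin=2.0)
            base = occupancy(small_sphere_surface, g).inside_flags
            moved = TriSurface(small_sphere_surface.vertices + shift, small_sphere_surface.faces)
            g2 = SampleGrid(origin=tuple(np.asarray(g.origin) + shift), spacing=g.spacing, dims=g.dims)
            assert np.array_equal(occupancy(moved, g2).inside_flags, base)

        run()


def test_convergence_toward_analytic_sphere_volume():
    """Grid-count error versus the analytic ball volume shrinks as the grid refines.

    The unbiased half-open count leaves only boundary quantization noise of
    RMS h^2 sqrt(S/12); each refinement must beat the coarsest error or sit
    below its own noise floor.
    """
    from hippomesh.phantom import ShapeSpec, rasterize
    from hippomesh.surfaces import extract_surface

    vol = rasterize(ShapeSpec(kind="sphere", radii=(8, 8, 8)), (41, 41, 41), 0.5)
    surf = extract_surface(vol, 1)
    analytic = 4 / 3 * np.pi * 8**3
    area = 4 * np.pi * 64.0
    errs = {}
    for h in (1.0, 0.5, 0.25):
        g = build_grid([surf], spacing=h, margin=1.5)
        errs[h] = abs(occupancy(surf, g).volume() - analytic)
    for h in (0.5, 0.25):
        assert errs[h] <= max(errs[1.0], h**2 * np.sqrt(area / 12.0)), errs
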