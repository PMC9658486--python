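"""Crown geometry and canopy-height-model reductions."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from shrubvol import (
    HeightGrid,
    canopy_area,
    cone_volume,
    cover_area,
    mean_height,
    soil_reference,
    surface_volume,
)
from shrubvol.errors import DomainError, GridStateError, SoilReferenceError


def cone_grid(radius, height, cell=0.02, pad=0.5, mask_outside=False):
    """Rasterised cone on a regular grid (z0 = 0), apex at the centre."""
    half = radius + pad
    n = int(round(2 * half / cell))
    c = (np.arange(n) + 0.5) * cell - half
    xx, yy = np.meshgrid(c, c)
    d = np.hypot(xx, yy)
    z = height * np.clip(1 - d / radius, 0, None)
    if mask_outside:
        z[d > radius] = np.nan
    return HeightGrid(plot_id="cone", origin=(0, 0), cell_size=cell, z=z, z0=0.0)


class TestFieldGeometry:
    @pytest.mark.parametrize(
        "c1, c2, expected",
        [
            (2.0, 2.0, math.pi),             # radius exactly 1
            (4.0, 1e-6, math.pi),            # degenerate ellipse, mean radius ~1
            (3.0, 1.0, math.pi),             # mean radius (1.5 + 0.5)/2 = 1
            (4.0, 2.0, math.pi * 1.5**2),
        ],
    )
    def test_canopy_area_is_circle_from_mean_radius(self, c1, c2, expected):
        assert canopy_area(c1, c2) == pytest.approx(expected, rel=1e-5)

    @pytest.mark.parametrize("c1, c2", [(0, 1), (-1, -2), (1, 2)])
    def test_canopy_area_rejects_bad_diameters(self, c1, c2):
        with pytest.raises(DomainError):
            canopy_area(c1, c2)

    def test_cone_volume_examples_and_linearity(self):
        assert cone_volume(3.0, 1.0) == pytest.approx(1.0)
        assert cone_volume(7.2, 4.9) == pytest.approx(11.76)
        assert cone_volume(2 * 7.2, 4.9) == pytest.approx(2 * cone_volume(7.2, 4.9))
        with pytest.raises(DomainError):
            cone_volume(0.0, 1.0)


class TestSoilReference:
    def test_mean_of_bare_cells(self):
        z = np.full((4, 4), 10.0)
        grid = HeightGrid("p", (0, 0), 1.0, z)
        mask = np.zeros_like(z, bool)
        mask[0, :2] = True
        assert soil_reference(grid, mask) == 10.0
        z2 = z.copy()
        z2[0, 0], z2[0, 1] = 9.9, 10.1
        grid2 = HeightGrid("p", (0, 0), 1.0, z2)
        assert soil_reference(grid2, mask) == pytest.approx(10.0)

    def test_noisy_flat_site_recovers_truth(self, rng):
        z = 5.0 + rng.normal(0, 0.05, (20, 20))
        grid = HeightGrid("p", (0, 0), 1.0, z)
        z0 = soil_reference(grid, np.ones_like(z, bool))
        assert abs(z0 - 5.0) < 0.01  # sd 0.05 / sqrt(400) ~ 0.0025

    def test_plane_method_handles_slope(self):
        rows = np.arange(10)[:, None] * np.ones((1, 10))
        z = 2.0 + 0.1 * rows
        grid = HeightGrid("p", (0, 0), 1.0, z)
        z0 = soil_reference(grid, np.ones_like(z, bool), method="plane")
        assert z0 == pytest.approx(2.0 + 0.1 * 4.5)

    def test_empty_mask_is_an_error(self):
        grid = HeightGrid("p", (0, 0), 1.0, np.ones((3, 3)))
        with pytest.raises(SoilReferenceError):
            soil_reference(grid, np.zeros((3, 3), bool))


class TestGridReductions:
    def test_flat_grid_zero_volume_and_cover(self):
        grid = HeightGrid("p", (0, 0), 1.0, np.full((5, 5), 3.0), z0=3.0)
        assert surface_volume(grid) == 0.0
        assert cover_area(grid) == 0.0

    def test_single_cell_volume(self):
        grid = HeightGrid("p", (0, 0), 1.0, np.array([[2.0]]), z0=0.0)
        assert surface_volume(grid) == pytest.approx(2.0)

    def test_full_cover(self):
        grid = HeightGrid("p", (0, 0), 1.0, np.ones((5, 5)), z0=0.0)
        assert cover_area(grid) == pytest.approx(25.0)

    def test_unset_soil_reference_is_an_error(self):
        grid = HeightGrid("p", (0, 0), 1.0, np.ones((2, 2)))
        with pytest.raises(GridStateError):
            surface_volume(grid)

    def test_mean_height_of_points_and_constants(self):
        assert mean_height(np.full(10, 3.0)) == pytest.approx(3.0)
        assert mean_height(np.array([0.0, 6.0])) == pytest.approx(3.0)
        with pytest.raises(DomainError):
            mean_height(np.array([]))

    def test_negative_heights_counted_in_mean_but_not_volume(self):
        grid = HeightGrid("p", (0, 0), 1.0, np.array([[1.0, -1.0]]), z0=0.0)
        assert mean_height(grid) == pytest.approx(0.0)
        assert surface_volume(grid) == pytest.approx(1.0)  # clamped at zero

    def test_nodata_cells_are_ignored(self):
        z = np.array([[1.0, np.nan], [1.0, 1.0]])
        grid = HeightGrid("p", (0, 0), 1.0, z, z0=0.0)
        assert surface_volume(grid) == pytest.approx(3.0)
        assert cover_area(grid) == pytest.approx(3.0)
        assert mean_height(grid) == pytest.approx(1.0)


class TestConeOracles:
    """Grid estimates must converge to the closed forms of a cone."""

    def test_surface_volume_matches_cone_formula(self):
        radius = math.sqrt(3.0 / math.pi)  # base area 3 m^2
        grid = cone_grid(radius, 1.0, cell=0.02)
        assert surface_volume(grid) == pytest.approx(1.0, rel=0.02)

    def test_cover_area_matches_shrunken_disc(self):
        radius, height = 1.5, 1.0
        grid = cone_grid(radius, height, cell=0.02)
        # height > 0.3 inside radius * (1 - 0.3/H)
        expected = math.pi * (radius * (1 - 0.3 / height)) ** 2
        assert cover_area(grid, 0.30) == pytest.approx(expected, rel=0.02)

    def test_mean_height_over_disc_is_a_third_of_apex(self):
        grid = cone_grid(1.2, 3.0, cell=0.02, mask_outside=True)
        assert mean_height(grid) == pytest.approx(1.0, rel=0.02)


@given(
    scale=st.floats(0.1, 10.0),
    seed=st.integers(0, 10_000),
)
def test_scale_equivariance_of_grid_reductions(scale, seed):
    """Multiplying all heights by c multiplies volume and mean height by c."""
    z = np.random.default_rng(seed).uniform(0, 2, (12, 12))
    g1 = HeightGrid("a", (0, 0), 0.5, z, z0=0.0)
    g2 = HeightGrid("b", (0, 0), 0.5, z * scale, z0=0.0)
    assert surface_volume(g2) == pytest.approx(scale * surface_volume(g1), rel=1e-9)
    assert mean_height(g2) == pytest.approx(scale * mean_height(g1), rel=1e-9)
    assert surface_volume(g2) >= 0.0
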