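"""Terrain derivations against analytic cases and brute-force oracles."""

import numpy as np
import pytest

from burnsel import terrain
from burnsel.terrain import FLAT_ASPECT

from conftest import make_cat, make_grid


# ---------------------------------------------------------------- oracles
def brute_slope_aspect(z, cs):
    """Independent central/one-sided difference slope and aspect."""
    rows, cols = z.shape
    slope = np.zeros_like(z)
    aspect = np.zeros_like(z)
    for i in range(rows):
        for j in range(cols):
            if 0 < i < rows - 1:
                ddr = (z[i + 1, j] - z[i - 1, j]) / (2 * cs)
            elif i == 0:
                ddr = (z[1, j] - z[0, j]) / cs
            else:
                ddr = (z[i, j] - z[i - 1, j]) / cs
            if 0 < j < cols - 1:
                ddc = (z[i, j + 1] - z[i, j - 1]) / (2 * cs)
            elif j == 0:
                ddc = (z[i, 1] - z[i, 0]) / cs
            else:
                ddc = (z[i, j] - z[i, j - 1]) / cs
            dzdx, dzdy = ddc, -ddr
            slope[i, j] = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
            if dzdx == 0 and dzdy == 0:
                aspect[i, j] = FLAT_ASPECT
            else:
                aspect[i, j] = np.degrees(np.arctan2(-dzdx, -dzdy)) % 360.0
    return slope, aspect


def hli_scalar(slope_deg, aspect_deg, lat_deg):
    s, lat = np.radians(slope_deg), np.radians(lat_deg)
    a = np.radians(abs(180.0 - abs(aspect_deg - 225.0)))
    return np.exp(
        -1.467
        + 1.582 * np.cos(lat) * np.cos(s)
        - 1.500 * np.cos(a) * np.sin(s) * np.cos(lat)
        - 0.262 * np.sin(lat) * np.sin(s)
        + 0.607 * np.sin(a) * np.sin(s)
    )


# ---------------------------------------------------------------- slope/aspect
def test_constant_dem_is_flat():
    slope, aspect = terrain.slope_aspect(make_grid(np.full((5, 5), 100.0)))
    assert (slope.values == 0).all()
    assert (aspect.values == FLAT_ASPECT).all()


def test_plane_rising_north():
    # 1 m of rise per 30 m cell toward the north (row 0)
    z = np.arange(6)[::-1, None] * np.ones((6, 6))
    slope, aspect = terrain.slope_aspect(make_grid(z * 1.0))
    expected = np.degrees(np.arctan(1.0 / 30.0))
    np.testing.assert_allclose(slope.values, expected, atol=1e-12)
    np.testing.assert_allclose(aspect.values, 180.0, atol=1e-12)


def test_slope_aspect_matches_brute_force(rng):
    from scipy.ndimage import gaussian_filter

    z = gaussian_filter(rng.normal(size=(15, 15)), 2.0) * 200.0
    slope, aspect = terrain.slope_aspect(make_grid(z))
    bs, ba = brute_slope_aspect(z, 30.0)
    np.testing.assert_allclose(slope.values, bs, atol=1e-9)
    np.testing.assert_allclose(aspect.values, ba, atol=1e-9)


def test_all_nodata_dem_rejected():
    with pytest.raises(ValueError):
        terrain.slope_aspect(make_grid(np.full((4, 4), -9999.0), nodata=-9999.0))


# ---------------------------------------------------------------- heat load
def test_heat_load_flat_cells_ignore_aspect():
    slope = make_grid(np.zeros((2, 2)))
    for a0, a1 in [(0.0, 225.0), (90.0, 315.0)]:
        h0 = terrain.heat_load_index(slope, make_grid(np.full((2, 2), a0)), 48.0)
        h1 = terrain.heat_load_index(slope, make_grid(np.full((2, 2), a1)), 48.0)
        np.testing.assert_allclose(h0.values, h1.values, rtol=1e-12)


def test_heat_load_folded_symmetry_about_southwest():
    slope = make_grid(np.full((3, 3), 20.0))
    h180 = terrain.heat_load_index(slope, make_grid(np.full((3, 3), 180.0)), 48.0)
    h270 = terrain.heat_load_index(slope, make_grid(np.full((3, 3), 270.0)), 48.0)
    np.testing.assert_allclose(h180.values, h270.values, rtol=1e-12)


def test_heat_load_matches_direct_evaluation():
    slope = make_grid(np.full((2, 2), 20.0))
    aspect = make_grid(np.full((2, 2), 225.0))
    out = terrain.heat_load_index(slope, aspect, 48.0)
    np.testing.assert_allclose(out.values, hli_scalar(20.0, 225.0, 48.0), atol=1e-9)


def test_heat_load_southwest_exceeds_northeast():
    slope = make_grid(np.full((2, 2), 25.0))
    sw = terrain.heat_load_index(slope, make_grid(np.full((2, 2), 225.0)), 48.0)
    ne = terrain.heat_load_index(slope, make_grid(np.full((2, 2), 45.0)), 48.0)
    assert (sw.values > ne.values).all()
    assert (sw.values >= 0).all() and np.isfinite(sw.values).all()


def test_heat_load_latitude_validated():
    slope = make_grid(np.zeros((2, 2)))
    aspect = make_grid(np.zeros((2, 2)))
    for lat in (-10.0, 0.0, 60.0, 75.0):
        with pytest.raises(ValueError):
            terrain.heat_load_index(slope, aspect, lat)


# ---------------------------------------------------------------- flow accumulation
def test_plane_accumulation_monotone_downslope():
    z = np.arange(6, -1, -1)[:, None] * np.ones((7, 7)) * 5.0  # falls southward
    acc = terrain.flow_accumulation(make_grid(z)).values
    assert (np.diff(acc, axis=0) >= 0).all()  # grows along every flow line
    assert (acc[0] == 900.0).all()  # ridge row: one 30 m cell of area


def test_central_pit_collects_everything():
    z = np.full((5, 5), 10.0)
    for k, ring in [(1, 8.0)]:
        z[k:-k, k:-k] = ring
    z[2, 2] = 0.0
    # make the surface strictly funnel-shaped so every cell drains inward
    yy, xx = np.indices((5, 5))
    z = np.hypot(yy - 2, xx - 2) * 3.0
    acc = terrain.flow_accumulation(make_grid(z)).values
    assert acc[2, 2] == 25 * 900.0


def test_headwater_cell_has_own_area_only():
    z = np.arange(4, -1, -1)[:, None] * np.ones((5, 5))
    acc = terrain.flow_accumulation(make_grid(z)).values
    assert (acc[0] == 900.0).all()


def test_flat_plateau_drains_to_outlet():
    z = np.full((6, 6), 5.0)
    z[5, 3] = 1.0  # single lower outlet below an otherwise flat plateau
    acc = terrain.flow_accumulation(make_grid(z)).values
    assert acc[5, 3] == 36 * 900.0


# ---------------------------------------------------------------- wetness index
def test_cti_zero_when_ratio_is_one():
    # a = acc / cell_width; choose acc so that a / tan(beta) == 1
    beta = 10.0
    acc_val = 30.0 * np.tan(np.radians(beta))
    cti = terrain.compound_topographic_index(
        make_grid(np.full((3, 3), acc_val)), make_grid(np.full((3, 3), beta))
    )
    np.testing.assert_allclose(cti.values, 0.0, atol=1e-12)


def test_cti_matches_scalar_evaluation():
    cti = terrain.compound_topographic_index(
        make_grid(np.full((2, 2), 30000.0)),  # a = 1000 m^2/m
        make_grid(np.full((2, 2), 5.0)),
    )
    np.testing.assert_allclose(
        cti.values, np.log(1000.0 / np.tan(np.radians(5.0))), atol=1e-12
    )


def test_cti_flat_slope_capped():
    cti = terrain.compound_topographic_index(
        make_grid(np.full((2, 2), 900.0)), make_grid(np.zeros((2, 2)))
    )
    expected = np.log((900.0 / 30.0) / np.tan(terrain.CTI_SLOPE_FLOOR_RAD))
    np.testing.assert_allclose(cti.values, expected, atol=1e-12)


def test_cti_monotonicity():
    slope = make_grid(np.full((2, 2), 8.0))
    lo = terrain.compound_topographic_index(make_grid(np.full((2, 2), 1000.0)), slope)
    hi = terrain.compound_topographic_index(make_grid(np.full((2, 2), 2000.0)), slope)
    assert (hi.values > lo.values).all()
    steep = terrain.compound_topographic_index(
        make_grid(np.full((2, 2), 1000.0)), make_grid(np.full((2, 2), 20.0))
    )
    assert (steep.values < lo.values).all()


# ---------------------------------------------------------------- distances
def test_distance_all_targets_zero():
    cat = make_cat(np.ones((4, 4)), {1: "draw"})
    assert (terrain.distance_to_class(cat, [1]).values == 0).all()


def test_distance_single_target_matches_brute_force(rng):
    vals = np.zeros((10, 10), dtype=int)
    vals[3, 7] = 1
    cat = make_cat(vals, {0: "other", 1: "draw"})
    d = terrain.distance_to_class(cat, [1]).values
    yy, xx = np.indices((10, 10))
    expected = 30.0 * np.hypot(yy - 3, xx - 7)
    np.testing.assert_allclose(d, expected, atol=1e-9)
    assert abs(d[2, 6] - 30.0 * np.sqrt(2)) < 1e-9


def test_distance_requires_targets():
    with pytest.raises(ValueError):
        terrain.distance_to_class(make_cat(np.zeros((3, 3)), {0: "other"}), [1])


def test_burn_edge_distance_simple_cases():
    vals = np.zeros((3, 3))
    vals[1, 1] = 1
    d = terrain.burn_edge_distance(make_grid(vals))
    assert d.values[1, 1] == 30.0  # single burned pixel: one cell to the ring
    assert d.values[0, 0] == d.nodata  # outside the burn
    vals2 = np.ones((3, 4))
    vals2[:, 3] = 0
    d2 = terrain.burn_edge_distance(make_grid(vals2))
    assert d2.values[1, 2] == 30.0  # adjacent to the unburned column


def test_burn_edge_distance_matches_brute_force(rng):
    burn = (rng.uniform(size=(12, 12)) < 0.7).astype(float)
    burn[0, 0] = 1.0
    grid = make_grid(burn)
    d = terrain.burn_edge_distance(grid).values
    # oracle: distance to nearest unburned cell, including a phantom ring
    # of unburned cells just off the map edge
    padded = np.pad(burn, 1, constant_values=0.0)
    edges = np.argwhere(padded == 0) - 1
    for (i, j) in np.argwhere(burn == 1):
        expected = 30.0 * np.min(np.hypot(edges[:, 0] - i, edges[:, 1] - j))
        assert abs(d[i, j] - expected) < 1e-9
    dgrid = terrain.burn_edge_distance(grid)
    assert (dgrid.values[burn == 0] == dgrid.nodata).all()


def test_burn_covering_grid_uses_boundary_as_edge():
    d = terrain.burn_edge_distance(make_grid(np.ones((5, 5))))
    assert d.values[0, 0] == 30.0
    assert d.values[2, 2] == 90.0


# ---------------------------------------------------------------- focal stats
def test_focal_mean_constant_invariant():
    g = make_grid(np.full((8, 8), 3.25))
    for w in (3, 27):
        np.testing.assert_allclose(terrain.focal_mean(g, w).values, 3.25, atol=1e-12)


def test_focal_mean_matches_brute_force(rng):
    vals = rng.normal(size=(6, 6))
    out = terrain.focal_mean(make_grid(vals), 3).values
    for i in range(6):
        for j in range(6):
            window = vals[max(i - 1, 0): i + 2, max(j - 1, 0): j + 2]
            assert abs(out[i, j] - window.mean()) < 1e-9


def test_focal_mean_shift_commutes(rng):
    vals = rng.normal(size=(9, 9))
    base = terrain.focal_mean(make_grid(vals), 3).values
    shifted = terrain.focal_mean(make_grid(vals + 5.5), 3).values
    np.testing.assert_allclose(shifted, base + 5.5, atol=1e-9)


def test_focal_mean_skips_nodata(rng):
    vals = rng.normal(size=(5, 5))
    vals[2, 2] = -9999.0
    out = terrain.focal_mean(make_grid(vals, nodata=-9999.0), 3).values
    window = np.delete(vals[0:3, 0:3].ravel(), 8)  # drop the nodata corner
    assert abs(out[1, 1] - window.mean()) < 1e-9


def test_focal_fraction_absent_code_is_zero():
    cat = make_cat(np.ones((5, 5)), {1: "a", 2: "b"})
    assert (terrain.focal_fraction(cat, 2, 3).values == 0).all()


def test_focal_fraction_matches_brute_force(rng):
    vals = rng.integers(1, 4, size=(6, 6))
    cat = make_cat(vals, {1: "a", 2: "b", 3: "c"})
    out = terrain.focal_fraction(cat, 2, 3).values
    for i in range(6):
        for j in range(6):
            window = vals[max(i - 1, 0): i + 2, max(j - 1, 0): j + 2]
            assert abs(out[i, j] - (window == 2).mean()) < 1e-9


def test_even_window_rejected():
    with pytest.raises(ValueError):
        terrain.focal_mean(make_grid(np.zeros((4, 4))), 4)


# ---------------------------------------------------------------- nibble
def test_nibble_surrounded_pixel():
    vals = np.ones((3, 3), dtype=int)
    vals[1, 1] = 9
    out = terrain.nibble_reassign(
        make_cat(vals, {1: "lodgepole_pine", 9: "disturbed"}), [9]
    )
    assert out.values[1, 1] == 1
    assert (out.values == 1).all()


def test_nibble_matches_brute_force():
    vals = np.zeros((10, 10), dtype=int)
    vals[:, :3] = 1
    vals[:, 7:] = 2
    vals[:, 3:7] = 9
    out = terrain.nibble_reassign(
        make_cat(vals, {1: "left", 2: "right", 9: "disturbed"}), [9]
    ).values
    sources = np.argwhere(vals != 9)
    for (i, j) in np.argwhere(vals == 9):
        d2 = (sources[:, 0] - i) ** 2 + (sources[:, 1] - j) ** 2
        best = d2 == d2.min()
        codes = vals[sources[best, 0], sources[best, 1]]
        assert out[i, j] == codes.min()


def test_nibble_tie_breaks_to_lower_code():
    vals = np.array([[2, 9, 1]])
    out = terrain.nibble_reassign(make_cat(vals, {1: "a", 2: "b", 9: "fill"}), [9])
    assert out.values[0, 1] == 1


def test_nibble_needs_a_source():
    with pytest.raises(ValueError):
        terrain.nibble_reassign(make_cat(np.full((3, 3), 9), {9: "fill"}), [9])


# ---------------------------------------------------------------- burn classes
def test_classify_burn_rule_table():
    loss = make_grid(
        np.array(
            [
                [0.0, 30.0, 50.0, 51.0],
                [0.0, 30.0, 50.0, 80.0],
                [0.0, 30.0, 50.5, 100.0],
                [10.0, 0.0, 0.0, 0.0],
            ]
        )
    )
    year = make_cat(
        np.array(
            [
                [2006, 2006, 2006, 2006],
                [1994, 1994, 1994, 1994],
                [2006, 0, 2006, 1994],
                [1950, 2006, 1994, 0],
            ]
        ),
        {0: "none", 1950: "y1950", 1994: "y1994", 2006: "y2006"},
    )
    out = terrain.classify_burn(loss, year, analysis_year=2010)
    expected = np.array(
        [
            [0, 2, 2, 1],   # new fire: low up to 50% loss, then high
            [0, 4, 4, 3],   # old fire
            [0, 0, 1, 3],   # the (50, 51] gap resolves to high severity
            [0, 0, 0, 0],   # out-of-band year or zero loss: unburned
        ]
    )
    np.testing.assert_array_equal(out.values, expected)
    assert out.legend[1] == "new_high" and out.legend[4] == "old_low"


def test_classify_burn_rejects_bad_loss():
    loss = make_grid(np.array([[150.0]]))
    year = make_cat(np.array([[2006]]), {2006: "y"})
    with pytest.raises(ValueError):
        terrain.classify_burn(loss, year, 2010)
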