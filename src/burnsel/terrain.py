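"""Deterministic covariate derivations on raster grids.

Terrain indices (slope/aspect, heat load, D8 flow accumulation, wetness),
Euclidean distance transforms (burn-edge distance, distance to draws),
moving-window focal statistics at the two analysis scales (3x3 and 27x27
cells), nearest-neighbor reassignment of masked land-cover cells, and
burn age/severity classification.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .grid import CategoricalRaster, RasterGrid

__all__ = [
    "slope_aspect",
    "heat_load_index",
    "flow_accumulation",
    "compound_topographic_index",
    "distance_to_class",
    "burn_edge_distance",
    "focal_mean",
    "focal_fraction",
    "nibble_reassign",
    "classify_burn",
    "draw_mask",
    "FLAT_ASPECT",
    "BURN_LEGEND",
]

#: Aspect sentinel for cells with zero slope (no defined downhill direction).
FLAT_ASPECT = -1.0

#: Canonical burn-class codes shared by the classifier and the landscape
#: generator.  0 is outside any burn perimeter; 5 marks unburned islands
#: (fire skips) inside a perimeter.
BURN_LEGEND = {
    0: "unburned",
    1: "new_high",
    2: "new_low",
    3: "old_high",
    4: "old_low",
    5: "skip",
}

# Slope floor used in the wetness index, in radians.
CTI_SLOPE_FLOOR_RAD = 0.001

# Heat-load equation metadata: folded-aspect broad-scale equation of
# McCune & Keon (2002), ln-scale output exponentiated to a direct index.
HEAT_LOAD_EQUATION = "mccune-keon-2002-eq2-folded-225"


def _require_valid_dem(dem: RasterGrid) -> np.ndarray:
    z = dem.values.astype(float)
    if dem.nodata is not None:
        z = np.where(dem.values == dem.nodata, np.nan, z)
    if not np.isfinite(z).any():
        raise ValueError("DEM contains no valid cells")
    return z


def slope_aspect(dem: RasterGrid) -> tuple[RasterGrid, RasterGrid]:
    """Slope (degrees) and downhill aspect (degrees clockwise from north).

    Gradients use central differences in the interior and one-sided
    differences on edges.  Flat cells receive :data:`FLAT_ASPECT`.
    """
    if dem.shape[0] < 3 or dem.shape[1] < 3:
        raise ValueError("DEM must be at least 3x3")
    z = _require_valid_dem(dem)
    cs = dem.cell_size
    ddrow, ddcol = np.gradient(z, cs)
    dzdx = ddcol            # +x is east
    dzdy = -ddrow           # +y is north (row index grows southward)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    flat = (dzdx == 0) & (dzdy == 0)
    aspect = np.degrees(np.arctan2(-dzdx, -dzdy)) % 360.0
    aspect = np.where(flat, FLAT_ASPECT, aspect)
    nodata = -9999.0
    bad = ~np.isfinite(slope)
    slope = np.where(bad, nodata, slope)
    aspect = np.where(bad, nodata, aspect)
    return (
        dem.like(slope, nodata=nodata),
        dem.like(aspect, nodata=nodata),
    )


def heat_load_index(
    slope_deg: RasterGrid, aspect_deg: RasterGrid, latitude_deg: float
) -> RasterGrid:
    """Folded-aspect heat load index.

    The aspect is folded about 225 degrees (southwest), A' = |180 - |aspect
    - 225||, so that SW slopes receive the maximum load and NE the minimum;
    the ln-scale regression surface is exponentiated to a direct index.
    At zero slope every aspect term vanishes, so flat cells are
    aspect-invariant by construction.
    """
    if not (0.0 < latitude_deg < 60.0):
        raise ValueError("latitude must be in (0, 60) degrees")
    if not slope_deg.same_geometry(aspect_deg):
        raise ValueError("slope and aspect rasters are not co-registered")
    s = np.radians(slope_deg.values.astype(float))
    folded = np.abs(180.0 - np.abs(aspect_deg.values.astype(float) - 225.0))
    a = np.radians(folded)
    lat = np.radians(latitude_deg)
    ln_hl = (
        -1.467
        + 1.582 * np.cos(lat) * np.cos(s)
        - 1.500 * np.cos(a) * np.sin(s) * np.cos(lat)
        - 0.262 * np.sin(lat) * np.sin(s)
        + 0.607 * np.sin(a) * np.sin(s)
    )
    hli = np.exp(ln_hl)
    valid = slope_deg.valid_mask & aspect_deg.valid_mask
    nodata = -9999.0
    return slope_deg.like(np.where(valid, hli, nodata), nodata=nodata)


# D8 neighbor offsets in clockwise order starting due north; ties in
# steepest descent go to the first offset in this order.
_D8 = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def _d8_downstream(z: np.ndarray, cell_size: float) -> np.ndarray:
    """Flat index of the downstream D8 neighbor per cell (-1 = pit/outlet).

    Flats drain iteratively toward the nearest cell that already has an
    outflow, preserving the clockwise-from-north tie order.
    """
    rows, cols = z.shape
    n = rows * cols
    down = np.full(n, -1, dtype=np.int64)
    best_drop = np.zeros((rows, cols))
    has_equal = np.zeros((rows, cols), dtype=bool)
    idx = np.arange(n).reshape(rows, cols)

    def shifted(arr, dr, dc, fill):
        out = np.full(arr.shape, fill, dtype=arr.dtype)
        rs = slice(max(dr, 0), rows + min(dr, 0))
        cs_ = slice(max(dc, 0), cols + min(dc, 0))
        rs_src = slice(max(-dr, 0), rows + min(-dr, 0))
        cs_src = slice(max(-dc, 0), cols + min(-dc, 0))
        out[rs_src, cs_src] = arr[rs, cs_]
        return out

    for dr, dc in _D8:
        dist = cell_size * np.hypot(dr, dc)
        zn = shifted(z, dr, dc, np.inf)
        drop = (z - zn) / dist
        take = drop > best_drop  # strict: first-in-order wins ties
        best_drop = np.where(take, drop, best_drop)
        down_idx = shifted(idx, dr, dc, -1)
        down.reshape(rows, cols)[take] = down_idx[take]
        has_equal |= zn == z

    # iterative flat resolution: unresolved cells adopt the first
    # clockwise equal-height neighbor that already drains somewhere
    unresolved = (down.reshape(rows, cols) == -1) & has_equal
    while unresolved.any():
        resolved_grid = (down.reshape(rows, cols) != -1)
        assigned_any = False
        newly = np.zeros_like(unresolved)
        for dr, dc in _D8:
            zn = shifted(z, dr, dc, np.inf)
            nb_ok = shifted(resolved_grid, dr, dc, False)
            cand = unresolved & ~newly & (zn == z) & nb_ok
            if cand.any():
                down_idx = shifted(idx, dr, dc, -1)
                down.reshape(rows, cols)[cand] = down_idx[cand]
                newly |= cand
                assigned_any = True
        unresolved &= ~newly
        if not assigned_any:
            break  # enclosed flat with no outlet: remaining cells are pits
    return down


def flow_accumulation(dem: RasterGrid) -> RasterGrid:
    """D8 upstream contributing area in square meters (own cell included)."""
    if dem.shape[0] < 3 or dem.shape[1] < 3:
        raise ValueError("DEM must be at least 3x3")
    z = _require_valid_dem(dem)
    if np.isnan(z).any():
        # route around nodata by treating it as impassably high ground
        z = np.where(np.isnan(z), np.inf, z)
    down = _d8_downstream(z, dem.cell_size)
    n = down.size
    acc = np.ones(n)
    indeg = np.bincount(down[down >= 0], minlength=n)
    from collections import deque

    queue = deque(np.flatnonzero(indeg == 0).tolist())
    while queue:
        c = queue.popleft()
        d = down[c]
        if d >= 0:
            acc[d] += acc[c]
            indeg[d] -= 1
            if indeg[d] == 0:
                queue.append(d)
    area = acc.reshape(dem.shape) * dem.cell_size**2
    return dem.like(area, nodata=None)


def compound_topographic_index(flow_acc: RasterGrid, slope_deg: RasterGrid) -> RasterGrid:
    """Topographic wetness index ln(a / tan(beta)).

    ``a`` is the specific contributing area (contributing area divided by
    cell width, m^2/m); slope is floored at
    :data:`CTI_SLOPE_FLOOR_RAD` radians to keep flat cells finite.
    """
    if not flow_acc.same_geometry(slope_deg):
        raise ValueError("flow accumulation and slope rasters are not co-registered")
    a = flow_acc.values.astype(float) / flow_acc.cell_size
    beta = np.maximum(np.radians(slope_deg.values.astype(float)), CTI_SLOPE_FLOOR_RAD)
    cti = np.log(a / np.tan(beta))
    return flow_acc.like(cti, nodata=None)


def distance_to_class(mask: CategoricalRaster, target_codes) -> RasterGrid:
    """Per-cell Euclidean distance (m, center-to-center) to the nearest
    cell whose code is in ``target_codes``; zero on target cells."""
    target_codes = np.atleast_1d(target_codes)
    target = np.isin(mask.values, target_codes) & mask.valid_mask
    if not target.any():
        raise ValueError(f"no cells with codes {target_codes.tolist()} present")
    dist = ndimage.distance_transform_edt(~target, sampling=mask.cell_size)
    return mask.like(dist.astype(float), nodata=None)


def _as_bool_mask(grid: RasterGrid) -> np.ndarray:
    return (grid.values != 0) & grid.valid_mask


def burn_edge_distance(
    burn: RasterGrid,
    skip: RasterGrid | None = None,
    skips_are_edge: bool = True,
) -> RasterGrid:
    """Distance from each burned cell to the nearest burn edge.

    The distance is defined on every nonzero cell of ``burn`` (nodata
    elsewhere).  The edge is any cell outside that domain or the map
    boundary; when ``skips_are_edge`` and a ``skip`` mask is given, skip
    cells also count as edge (so a skip cell itself sits at distance 0,
    being unburned ground).
    """
    domain = _as_bool_mask(burn)
    if not domain.any():
        raise ValueError("burn mask is empty")
    interior = domain.copy()
    if skip is not None and skips_are_edge:
        interior &= ~_as_bool_mask(skip)
    padded = np.pad(interior, 1, constant_values=False)
    dist = ndimage.distance_transform_edt(padded, sampling=burn.cell_size)[1:-1, 1:-1]
    nodata = -9999.0
    out = np.where(domain, dist, nodata)
    return burn.like(out, nodata=nodata)


def _focal_sums(arr: np.ndarray, window: int) -> np.ndarray:
    # uniform_filter with zero padding turns the mean into a windowed sum;
    # edge cells then divide by the in-bounds count (shrunken window).
    return ndimage.uniform_filter(arr, size=window, mode="constant", cval=0.0) * window**2


def _check_window(window: int) -> None:
    if window % 2 == 0 or window < 3:
        raise ValueError("focal window must be odd and >= 3")


def focal_mean(grid: RasterGrid, window_cells: int) -> RasterGrid:
    """Moving-window mean over a centered square window, nodata-aware.

    Edge cells average over the in-bounds part of the window only.
    """
    _check_window(window_cells)
    valid = grid.valid_mask
    vals = np.where(valid, grid.values.astype(float), 0.0)
    sums = _focal_sums(vals, window_cells)
    counts = _focal_sums(valid.astype(float), window_cells)
    nodata = -9999.0
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0.5, sums / np.maximum(counts, 1e-300), nodata)
    return grid.like(mean, nodata=nodata)


def focal_fraction(grid: CategoricalRaster, code: int, window_cells: int) -> RasterGrid:
    """Fraction of valid cells equal to ``code`` within the window."""
    _check_window(window_cells)
    valid = grid.valid_mask
    hits = ((grid.values == code) & valid).astype(float)
    sums = _focal_sums(hits, window_cells)
    counts = _focal_sums(valid.astype(float), window_cells)
    nodata = -9999.0
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(counts > 0.5, sums / np.maximum(counts, 1e-300), nodata)
    return grid.like(frac, nodata=nodata)


def nibble_reassign(landcover: CategoricalRaster, fill_codes) -> CategoricalRaster:
    """Assign each fill-code cell the class of its nearest non-fill cell.

    Exact Euclidean nearest; distance ties break to the lower class code,
    then row-major source order.  Non-fill cells are unchanged.
    """
    fill_codes = np.atleast_1d(fill_codes)
    values = landcover.values.copy()
    fill = np.isin(values, fill_codes) & landcover.valid_mask
    source = ~np.isin(values, fill_codes) & landcover.valid_mask
    if not source.any():
        raise ValueError("every cell is a fill code; nothing to nibble from")
    if not fill.any():
        return landcover.like_categorical(values)

    src_rc = np.argwhere(source)  # row-major order
    tree = cKDTree(src_rc)
    fill_rc = np.argwhere(fill)
    dist, _ = tree.query(fill_rc, k=1)
    new_vals = np.empty(len(fill_rc), dtype=values.dtype)
    # collect all sources at the exact minimum squared distance per cell
    balls = tree.query_ball_point(fill_rc, r=dist + 1e-9)
    for i, (rc, cand) in enumerate(zip(fill_rc, balls)):
        cand_rc = src_rc[cand]
        d2 = ((cand_rc - rc) ** 2).sum(axis=1)
        best = d2 == d2.min()
        cand_rc = cand_rc[best]
        codes = values[cand_rc[:, 0], cand_rc[:, 1]]
        order = np.lexsort((cand_rc[:, 1], cand_rc[:, 0], codes))
        new_vals[i] = codes[order[0]]
    values[fill] = new_vals
    return landcover.like_categorical(values)


def classify_burn(
    canopy_loss_pct: RasterGrid,
    burn_year_map: CategoricalRaster,
    analysis_year: int,
    new_years: tuple[int, int] = (1998, 2007),
    old_years: tuple[int, int] = (1985, 1997),
) -> CategoricalRaster:
    """Combine burn year and canopy-cover loss into four burn classes.

    Severity: loss in (0, 50] is low, loss > 50 is high (the published
    class bounds of 1-50% and >51% leave (50, 51] open; it is assigned to
    high so the partition is exhaustive).  Age comes from the burn-year
    bands; years outside both bands (and zero loss) are unburned.
    """
    if not canopy_loss_pct.same_geometry(burn_year_map):
        raise ValueError("canopy loss and burn year rasters are not co-registered")
    loss = canopy_loss_pct.values.astype(float)
    valid = canopy_loss_pct.valid_mask
    if ((loss < 0) | (loss > 100))[valid].any():
        raise ValueError("canopy loss must be within [0, 100] percent")
    year = burn_year_map.values
    new = (year >= new_years[0]) & (year <= new_years[1]) & (year <= analysis_year)
    old = (year >= old_years[0]) & (year <= old_years[1])
    high = loss > 50.0
    low = (loss > 0.0) & ~high
    codes = np.zeros(loss.shape, dtype=np.int16)
    codes[new & high] = 1
    codes[new & low] = 2
    codes[old & high] = 3
    codes[old & low] = 4
    legend = {k: v for k, v in BURN_LEGEND.items() if k != 5}
    return CategoricalRaster(
        codes,
        cell_size=canopy_loss_pct.cell_size,
        origin=canopy_loss_pct.origin,
        nodata=None,
        crs_label=canopy_loss_pct.crs_label,
        legend=legend,
    )


def draw_mask(flow_acc: RasterGrid, quantile: float = 0.95) -> CategoricalRaster:
    """Convergent-drainage ("draw") cells: flow accumulation at or above
    the given quantile of the study-area distribution."""
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    thresh = np.quantile(flow_acc.values[flow_acc.valid_mask], quantile)
    mask = (flow_acc.values >= thresh).astype(np.int16)
    return CategoricalRaster(
        mask,
        cell_size=flow_acc.cell_size,
        origin=flow_acc.origin,
        nodata=None,
        crs_label=flow_acc.crs_label,
        legend={0: "other", 1: "draw"},
    )
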