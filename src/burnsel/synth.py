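"""Synthetic fire-mosaic landscapes.

Generates the raster stack the habitat-selection analysis consumes:
a correlated-random-field DEM, a single simply connected burn perimeter
containing high-severity, low-severity, old-burn, and unburned-skip
patches in configured area fractions, elevation-structured land cover in
eight classes, canopy cover depressed by burn severity, and growing-season
precipitation increasing with elevation.

Patchiness comes from Gaussian random fields (white noise smoothed at a
configurable correlation length); class membership is assigned by
quantile thresholding of those fields, which pins achieved area fractions
to their targets up to cell-count discreteness.

Two presets mirror the composition of the studied burns: ``tripod``
(63% high severity / 8% low / 8% old burn / 21% skips, elevations
855-2,390 m) and ``whiteface`` (82% high / 10% low / 8% skips,
1,280-2,222 m).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import ndimage

from .grid import CategoricalRaster, LandscapeStack, RasterGrid
from . import terrain
from .terrain import BURN_LEGEND

__all__ = [
    "LandscapeConfig",
    "PRESETS",
    "LANDCOVER_LEGEND",
    "generate_field",
    "generate_dem",
    "generate_burn_mosaic",
    "generate_landcover",
    "generate_canopy_and_climate",
    "build_landscape",
]

LANDCOVER_LEGEND = {
    1: "lodgepole_pine",
    2: "spruce_fir",
    3: "dry_forest",
    4: "mixed_forest",
    5: "deciduous",
    6: "grassy_meadow",
    7: "shrubby_meadow",
    8: "barren",
}

# per-elevation-band class proportions (low, mid, high thirds of the DEM);
# spruce-fir concentrates in the top band, dry forest in the bottom band
_DEFAULT_BANDS = (
    {3: 0.35, 4: 0.20, 1: 0.10, 5: 0.10, 6: 0.15, 7: 0.05, 8: 0.05, 2: 0.00},
    {1: 0.35, 2: 0.15, 4: 0.15, 3: 0.10, 5: 0.05, 6: 0.10, 7: 0.05, 8: 0.05},
    {2: 0.45, 1: 0.20, 8: 0.15, 7: 0.10, 6: 0.05, 4: 0.05, 3: 0.00, 5: 0.00},
)

# fixed per-layer offsets from the master seed (layer-wise reproducibility)
_SEED_OFFSETS = {
    "dem": 11,
    "perimeter": 23,
    "burn": 37,
    "landcover": 41,
    "canopy": 53,
    "canopy_jitter": 59,
    "precip": 61,
}


@dataclass
class LandscapeConfig:
    """Parameters of one synthetic study area."""

    shape: tuple[int, int] = (300, 300)
    cell_size: float = 30.0
    #: correlation length (m) per generated field
    correlation_lengths: Mapping[str, float] = field(
        default_factory=lambda: {
            "dem": 3000.0,
            "perimeter": 2500.0,
            "burn": 900.0,
            "landcover": 500.0,
            "canopy": 300.0,
            "precip": 1200.0,
        }
    )
    #: target within-perimeter area fractions; any remainder becomes skip
    burn_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"new_high": 0.63, "new_low": 0.08, "old_burn": 0.08, "skip": 0.21}
    )
    #: fraction of the whole map enclosed by the burn perimeter
    burn_area_fraction: float = 0.40
    landcover_proportions: tuple = _DEFAULT_BANDS
    elevation_range: tuple[float, float] = (855.0, 2390.0)
    latitude_deg: float = 48.5
    draw_quantile: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        fr = self.burn_fractions
        if any(not 0.0 <= v <= 1.0 for v in fr.values()):
            raise ValueError("burn fractions must each lie in [0, 1]")
        if sum(fr.values()) > 1.0 + 1e-9:
            raise ValueError("burn fractions must sum to at most 1")
        min_len = min(self.correlation_lengths.values())
        if min_len <= self.cell_size:
            raise ValueError("correlation lengths must exceed the cell size")
        for band in self.landcover_proportions:
            if abs(sum(band.values()) - 1.0) > 1e-9:
                raise ValueError("land-cover proportions must sum to 1 per band")

    def sub_seed(self, layer: str) -> int:
        return (int(self.seed) + _SEED_OFFSETS[layer]) % (2**31 - 1)


PRESETS: dict[str, LandscapeConfig] = {
    "tripod": LandscapeConfig(
        burn_fractions={"new_high": 0.63, "new_low": 0.08, "old_burn": 0.08, "skip": 0.21},
        elevation_range=(855.0, 2390.0),
    ),
    "whiteface": LandscapeConfig(
        burn_fractions={"new_high": 0.82, "new_low": 0.10, "old_burn": 0.0, "skip": 0.08},
        elevation_range=(1280.0, 2222.0),
    ),
}


def preset(name: str, **overrides) -> LandscapeConfig:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; valid presets: {sorted(PRESETS)}")
    return replace(PRESETS[name], **overrides)


def generate_field(
    shape: tuple[int, int],
    correlation_length: float,
    seed: int,
    cell_size: float = 30.0,
    amplitude: float = 1.0,
) -> RasterGrid:
    """Stationary Gaussian random field, zero mean and unit variance
    (before ``amplitude`` scaling).

    White noise is smoothed with a wrap-around Gaussian kernel whose sigma
    equals the correlation length, then standardized.
    """
    if correlation_length <= cell_size:
        raise ValueError("correlation length must exceed the cell size")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(shape)
    sigma_cells = correlation_length / cell_size
    smooth = ndimage.gaussian_filter(noise, sigma=sigma_cells, mode="wrap")
    smooth -= smooth.mean()
    sd = smooth.std()
    if sd > 0:
        smooth /= sd
    return RasterGrid(amplitude * smooth, cell_size=cell_size)


def generate_dem(config: LandscapeConfig) -> RasterGrid:
    """Smooth elevation surface rescaled exactly onto the configured range."""
    f = generate_field(
        config.shape,
        config.correlation_lengths["dem"],
        config.sub_seed("dem"),
        config.cell_size,
    ).values
    # gentle regional tilt so bands are not purely blob-shaped
    rows = config.shape[0]
    tilt = np.linspace(0.6, -0.6, rows)[:, None] * np.ones(config.shape)
    z = f + tilt
    lo, hi = config.elevation_range
    z = (z - z.min()) / (z.max() - z.min()) * (hi - lo) + lo
    return RasterGrid(z, cell_size=config.cell_size)


def _quantile_bands(values: np.ndarray, fractions: list[float]) -> np.ndarray:
    """Assign band index 0..k-1 to values by empirical quantile thresholds.

    ``fractions`` must sum to 1; band i captures fraction[i] of the values,
    taken in ascending value order.
    """
    edges = np.cumsum(fractions)[:-1]
    thresholds = np.quantile(values, edges) if len(edges) else np.array([])
    return np.searchsorted(thresholds, values, side="right")


def generate_burn_mosaic(dem: RasterGrid, config: LandscapeConfig) -> CategoricalRaster:
    """Burn perimeter plus within-perimeter severity/age/skip patches.

    Codes follow :data:`burnsel.terrain.BURN_LEGEND`; the configured
    ``old_burn`` fraction is split evenly between old-high and old-low.
    Any fraction mass not explicitly allocated joins the skips (unburned).
    """
    fr = config.burn_fractions
    # perimeter: largest super-threshold blob of a long-range field
    per_field = generate_field(
        config.shape,
        config.correlation_lengths["perimeter"],
        config.sub_seed("perimeter"),
        config.cell_size,
    ).values
    thresh = np.quantile(per_field, 1.0 - config.burn_area_fraction)
    blob = per_field >= thresh
    labels, nlab = ndimage.label(blob)
    if nlab == 0:
        raise ValueError("burn perimeter generation produced no burned area")
    largest = np.argmax(ndimage.sum_labels(blob, labels, index=np.arange(1, nlab + 1))) + 1
    perim = labels == largest
    perim = ndimage.binary_closing(perim, structure=np.ones((3, 3)), iterations=2)
    perim = ndimage.binary_fill_holes(perim)

    cls_field = generate_field(
        config.shape,
        config.correlation_lengths["burn"],
        config.sub_seed("burn"),
        config.cell_size,
    ).values
    inside = cls_field[perim]
    skip_frac = fr.get("skip", 0.0) + max(0.0, 1.0 - sum(fr.values()))
    old = fr.get("old_burn", 0.0)
    # ascending-value bands: new_high, new_low, old_high, old_low, skip;
    # zero-fraction classes are dropped so they get exactly zero cells
    parts = [
        (1, fr.get("new_high", 0.0)),
        (2, fr.get("new_low", 0.0)),
        (3, old / 2.0),
        (4, old / 2.0),
        (5, skip_frac),
    ]
    parts = [(code, p) for code, p in parts if p > 0]
    band = _quantile_bands(inside, [p for _, p in parts])
    band_to_code = np.array([code for code, _ in parts], dtype=np.int16)
    codes = np.zeros(config.shape, dtype=np.int16)
    codes[perim] = band_to_code[band]
    return CategoricalRaster(
        codes,
        cell_size=config.cell_size,
        origin=dem.origin,
        legend=dict(BURN_LEGEND),
    )


def generate_landcover(dem: RasterGrid, config: LandscapeConfig) -> CategoricalRaster:
    """Eight-class land cover structured along the elevation gradient.

    The DEM is cut into equal-area elevation bands; within each band a
    correlated field is quantile-thresholded into the band's class
    proportions, giving patchy but fraction-exact composition.
    """
    nbands = len(config.landcover_proportions)
    band_idx = _quantile_bands(dem.values.ravel(), [1.0 / nbands] * nbands).reshape(dem.shape)
    cls_field = generate_field(
        config.shape,
        config.correlation_lengths["landcover"],
        config.sub_seed("landcover"),
        config.cell_size,
    ).values
    codes = np.zeros(config.shape, dtype=np.int16)
    for b, props in enumerate(config.landcover_proportions):
        sel = band_idx == b
        items = [(c, p) for c, p in sorted(props.items()) if p > 0]
        band_assign = _quantile_bands(cls_field[sel], [p for _, p in items])
        code_arr = np.array([c for c, _ in items], dtype=np.int16)
        codes[sel] = code_arr[band_assign]
    return CategoricalRaster(
        codes,
        cell_size=config.cell_size,
        origin=dem.origin,
        legend=dict(LANDCOVER_LEGEND),
    )


def generate_canopy_and_climate(
    dem: RasterGrid, burn: CategoricalRaster, config: LandscapeConfig
) -> tuple[RasterGrid, RasterGrid]:
    """Canopy cover (percent) and growing-season precipitation (mm).

    Canopy: a correlated base surface around 60% cover, knocked down by
    burn class -- new high-severity cells are drawn from a low-canopy
    distribution (a few percent residual cover), new low-severity cells
    lose a moderate share, old burns have partly regenerated, skips keep
    the unburned canopy.  Precipitation increases linearly with elevation
    plus correlated noise.
    """
    base_field = generate_field(
        config.shape,
        config.correlation_lengths["canopy"],
        config.sub_seed("canopy"),
        config.cell_size,
    ).values
    base = np.clip(60.0 + 15.0 * base_field, 5.0, 95.0)
    rng = np.random.default_rng(config.sub_seed("canopy_jitter"))
    low = np.clip(6.0 + 3.0 * np.abs(rng.standard_normal(config.shape)), 0.0, 20.0)
    canopy = base.copy()
    b = burn.values
    canopy[b == 1] = low[b == 1]          # new high severity: residual snags only
    canopy[b == 2] = base[b == 2] * 0.65  # new low severity
    canopy[b == 3] = base[b == 3] * 0.80  # old high severity, regenerating
    canopy[b == 4] = base[b == 4] * 0.90  # old low severity
    canopy = np.clip(canopy, 0.0, 100.0)

    precip_field = generate_field(
        config.shape,
        config.correlation_lengths["precip"],
        config.sub_seed("precip"),
        config.cell_size,
    ).values
    lo, hi = config.elevation_range
    precip = 180.0 + 0.15 * (dem.values - lo) + 12.0 * precip_field
    return (
        RasterGrid(canopy, cell_size=config.cell_size, origin=dem.origin),
        RasterGrid(precip, cell_size=config.cell_size, origin=dem.origin),
    )


#: continuous layers that get 3x3 (_s) and 27x27 (_l) focal means
_FOCAL_CONTINUOUS = ("canopy", "hli", "cti", "precip")
#: class fractions computed at both focal scales: (layer, code, name)
_FOCAL_FRACTIONS = (
    ("burn", 1, "frac_new_high"),
    ("burn", 2, "frac_new_low"),
    ("burn", 5, "frac_skip"),
    ("landcover", 2, "frac_spruce_fir"),
    ("landcover", 3, "frac_dry_forest"),
)


def build_landscape(config: LandscapeConfig, scales: bool = True) -> LandscapeStack:
    """Generate the full co-registered covariate stack for one study area.

    Includes the primary surfaces (dem, burn, landcover, canopy, precip),
    the derived terrain covariates (slope, aspect, heat load, wetness,
    distance to burn edge, distance to draw) and, when ``scales`` is true,
    the 3x3 and 27x27 focal-window variants used in the two-scale design.
    """
    dem = generate_dem(config)
    burn = generate_burn_mosaic(dem, config)
    landcover = generate_landcover(dem, config)
    canopy, precip = generate_canopy_and_climate(dem, burn, config)

    slope, aspect = terrain.slope_aspect(dem)
    hli = terrain.heat_load_index(slope, aspect, config.latitude_deg)
    facc = terrain.flow_accumulation(dem)
    cti = terrain.compound_topographic_index(facc, slope)
    draws = terrain.draw_mask(facc, config.draw_quantile)
    dist_draw = terrain.distance_to_class(draws, [1])
    perimeter = burn.like((burn.values != 0).astype(np.int16))
    skips = burn.like((burn.values == 5).astype(np.int16))
    dist_edge = terrain.burn_edge_distance(perimeter, skip=skips, skips_are_edge=True)

    stack = LandscapeStack()
    stack.add("dem", dem)
    stack.add("slope", slope)
    stack.add("aspect", aspect)
    stack.add("hli", hli)
    stack.add("cti", cti)
    stack.add("canopy", canopy)
    stack.add("precip", precip)
    stack.add("burn", burn)
    stack.add("landcover", landcover)
    stack.add("dist_burn_edge", dist_edge)
    stack.add("dist_draw", dist_draw)
    if scales:
        for name in _FOCAL_CONTINUOUS:
            stack.add(f"{name}_s", terrain.focal_mean(stack[name], 3))
            stack.add(f"{name}_l", terrain.focal_mean(stack[name], 27))
        for layer, code, out in _FOCAL_FRACTIONS:
            cat = stack[layer]
            stack.add(f"{out}_s", terrain.focal_fraction(cat, code, 3))
            stack.add(f"{out}_l", terrain.focal_fraction(cat, code, 27))
    return stack


def achieved_burn_fractions(burn: CategoricalRaster) -> dict[str, float]:
    """Within-perimeter area fractions actually realized by a mosaic."""
    inside = burn.values != 0
    n = inside.sum()
    if n == 0:
        raise ValueError("mosaic has no within-perimeter cells")
    out = {}
    for code, name in BURN_LEGEND.items():
        if code == 0:
            continue
        out[name] = float((burn.values == code).sum() / n)
    out["old_burn"] = out.pop("old_high") + out.pop("old_low")
    return out
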