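"""GPS telemetry simulation and the used/available sampling design.

The simulator moves an animal in discrete 4-hour ticks.  At each tick a
set of candidate endpoints is proposed (gamma step lengths, uniform
headings) and one is chosen with probability proportional to
``exp(sum_k beta_k * z_k(candidate))`` where ``z_k`` are standardized
covariate surfaces -- a step-selection process with known coefficients,
so downstream model recovery can be validated against ground truth.
Each chosen location is recorded only with the configured fix-success
probability, emulating collar fix failure.

The sampling design mirrors a used/available analysis: the study area is
the union of step-path buffers, used points are recorded fixes inside the
analysis mask, and an equal number of available points is drawn uniformly
from the mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely

from .grid import CategoricalRaster, LandscapeStack, RasterGrid

__all__ = [
    "MovementConfig",
    "TelemetryTrack",
    "simulate_track",
    "delineate_study_area",
    "extract_used_points",
    "sample_available",
    "build_table",
    "burn_use_percent",
    "burn_use_summary",
]

FIX_INTERVAL_HOURS = 4.0


@dataclass
class MovementConfig:
    """Ground-truth movement and selection parameters.

    ``betas`` maps stack layer names to selection coefficients applied to
    the standardized layer values; an empty mapping gives selection-free
    (correlated random walk) movement.
    """

    betas: Mapping[str, float] = field(default_factory=dict)
    step_mean: float = 766.0        # mean 4-hr displacement, meters
    step_shape: float = 2.0         # gamma shape; right-skewed steps
    n_candidates: int = 20
    fix_success: float = 0.72
    n_steps: int = 2190             # one year of 4-hr attempts
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.fix_success <= 1.0):
            raise ValueError("fix success must be in (0, 1]")
        if self.n_candidates < 2:
            raise ValueError("need at least 2 candidate endpoints per step")


@dataclass
class TelemetryTrack:
    """Time-ordered recorded fixes for one animal (gaps = failed fixes)."""

    animal_id: str
    times_h: np.ndarray  # hours since deployment, strictly increasing
    xy: np.ndarray       # shape (n, 2), projected meters

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if len(self.times_h) != len(self.xy):
            raise ValueError("times and coordinates differ in length")
        if len(self.times_h) > 1 and not (np.diff(self.times_h) > 0).all():
            raise ValueError("fix times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times_h)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal_id": self.animal_id,
                "time_h": self.times_h,
                "x": self.xy[:, 0],
                "y": self.xy[:, 1],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, animal_id: str | None = None) -> "TelemetryTrack":
        if animal_id is not None:
            df = df[df["animal_id"] == animal_id]
        else:
            ids = df["animal_id"].unique()
            if len(ids) != 1:
                raise ValueError("frame holds multiple animals; pass animal_id")
            animal_id = ids[0]
        df = df.sort_values("time_h")
        return cls(str(animal_id), df["time_h"].to_numpy(), df[["x", "y"]].to_numpy())


def _standardized_layers(stack: LandscapeStack, names) -> dict[str, np.ndarray]:
    out = {}
    for name in names:
        if name not in stack:
            raise KeyError(f"selection coefficient references missing layer {name!r}")
        grid = stack[name]
        vals = grid.values.astype(float)
        m = grid.valid_mask
        mu, sd = vals[m].mean(), vals[m].std()
        z = (vals - mu) / (sd if sd > 0 else 1.0)
        z[~m] = np.nan
        out[name] = z
    return out


def simulate_track(
    stack: LandscapeStack,
    config: MovementConfig,
    start_xy: tuple[float, float] | None = None,
    animal_id: str = "lynx-0",
    collect_candidates: bool = False,
) -> tuple[TelemetryTrack, dict]:
    """Simulate one collared animal on a landscape stack.

    Returns the recorded track plus a diagnostics dict with the realized
    fix rate and the mean step length over *all* 4-hr attempts (recorded
    or not), matching how collar data summarize movement.  With
    ``collect_candidates`` the info dict also carries every candidate
    endpoint (``candidates_xy``) and every chosen endpoint
    (``chosen_xy``) -- the step-conditional availability sample against
    which selection-free movement is an exact null.
    """
    rng = np.random.default_rng(config.seed)
    ref = next(iter(stack.layers.values()))
    z_layers = _standardized_layers(stack, config.betas.keys())
    rows, cols = ref.shape

    if start_xy is None:
        start_xy = (
            ref.origin[0] + cols * ref.cell_size / 2.0,
            ref.origin[1] - rows * ref.cell_size / 2.0,
        )
    r0, c0 = ref.cell_containing(*start_xy)
    if not ref.contains(*start_xy) or not ref.valid_mask[r0, c0]:
        raise ValueError("start location is off-map or nodata")

    scale = config.step_mean / config.step_shape
    pos = np.array(start_xy, dtype=float)
    rec_times, rec_xy = [], []
    step_lengths = []
    cand_log, chosen_log = [], []
    n_recorded = 0
    for step in range(config.n_steps):
        # draw candidates; off-map proposals keep their gamma length and
        # redraw the heading (so map edges do not truncate step lengths),
        # falling back to a fresh length only if no heading fits
        lengths = rng.gamma(config.step_shape, scale, size=config.n_candidates)
        cand = np.empty((config.n_candidates, 2))
        pending = np.arange(config.n_candidates)
        tries = 0
        while len(pending):
            headings = rng.uniform(0.0, 2.0 * np.pi, size=len(pending))
            prop = pos + np.column_stack(
                (lengths[pending] * np.sin(headings), lengths[pending] * np.cos(headings))
            )
            ok = ref.contains(prop[:, 0], prop[:, 1])
            if ok.any():
                r, c = ref.cell_containing(prop[ok, 0], prop[ok, 1])
                good = np.flatnonzero(ok)[ref.valid_mask[r, c]]
                cand[pending[good]] = prop[good]
                pending = np.delete(pending, good)
            tries += 1
            if tries % 60 == 0 and len(pending):
                lengths[pending] = rng.gamma(config.step_shape, scale, size=len(pending))
        if z_layers:
            r, c = ref.cell_containing(cand[:, 0], cand[:, 1])
            util = np.zeros(config.n_candidates)
            for name, beta in config.betas.items():
                util += beta * z_layers[name][r, c]
            util -= util.max()
            w = np.exp(util)
            p = w / w.sum()
        else:
            p = np.full(config.n_candidates, 1.0 / config.n_candidates)
        choice = rng.choice(config.n_candidates, p=p)
        new_pos = cand[choice]
        if collect_candidates:
            cand_log.append(cand.copy())
            chosen_log.append(new_pos.copy())
        step_lengths.append(float(np.hypot(*(new_pos - pos))))
        pos = new_pos
        if rng.uniform() < config.fix_success:
            n_recorded += 1
            rec_times.append((step + 1) * FIX_INTERVAL_HOURS)
            rec_xy.append(pos.copy())

    track = TelemetryTrack(
        animal_id,
        np.array(rec_times, dtype=float),
        np.array(rec_xy, dtype=float).reshape(-1, 2),
    )
    info = {
        "n_attempts": config.n_steps,
        "n_recorded": n_recorded,
        "fix_rate": n_recorded / config.n_steps,
        "mean_step_m": float(np.mean(step_lengths)),
    }
    if collect_candidates:
        info["candidates_xy"] = np.vstack(cand_log)
        info["chosen_xy"] = np.vstack(chosen_log)
    return track, info


def _segments(track: TelemetryTrack) -> np.ndarray:
    """(n-1, 2, 2) array of consecutive-fix segments."""
    return np.stack([track.xy[:-1], track.xy[1:]], axis=1)


def _point_segment_distance(px, py, a, b) -> np.ndarray:
    """Distance from points (px, py) to segment a-b (each 2-vectors)."""
    d = b - a
    len2 = float(d @ d)
    if len2 == 0.0:
        return np.hypot(px - a[0], py - a[1])
    t = np.clip(((px - a[0]) * d[0] + (py - a[1]) * d[1]) / len2, 0.0, 1.0)
    return np.hypot(px - (a[0] + t * d[0]), py - (a[1] + t * d[1]))


def delineate_study_area(
    track: TelemetryTrack,
    buffer_m: float = 766.0,
    clip_polygon=None,
    grid: RasterGrid | None = None,
):
    """Study area = union of buffers around consecutive-fix segments.

    Returns ``(polygon, mask_grid)``.  The polygon is a shapely buffer of
    the step path (outer edge of the buffered lines); the raster mask
    marks cells whose *center* lies within ``buffer_m`` of the path,
    computed from exact point-segment distances.  ``mask_grid`` is None
    when no reference grid is given.
    """
    if len(track) < 2:
        raise ValueError("study-area delineation needs at least 2 fixes")
    segs = _segments(track)
    path = shapely.linestrings(track.xy)
    polygon = shapely.buffer(path, buffer_m, quad_segs=32)
    if clip_polygon is not None:
        polygon = polygon.intersection(clip_polygon)

    mask_grid = None
    if grid is not None:
        cs = grid.cell_size
        x0, y0 = grid.origin
        rows, cols = grid.shape
        xc = x0 + (np.arange(cols) + 0.5) * cs
        yc = y0 - (np.arange(rows) + 0.5) * cs
        within = np.zeros(grid.shape, dtype=bool)
        for a, b in segs:
            lo_x, hi_x = min(a[0], b[0]) - buffer_m, max(a[0], b[0]) + buffer_m
            lo_y, hi_y = min(a[1], b[1]) - buffer_m, max(a[1], b[1]) + buffer_m
            c0 = max(int((lo_x - x0) / cs) - 1, 0)
            c1 = min(int((hi_x - x0) / cs) + 2, cols)
            r0 = max(int((y0 - hi_y) / cs) - 1, 0)
            r1 = min(int((y0 - lo_y) / cs) + 2, rows)
            if r0 >= r1 or c0 >= c1:
                continue
            d = _point_segment_distance(
                xc[None, c0:c1], yc[r0:r1, None], a, b
            )
            within[r0:r1, c0:c1] |= d <= buffer_m
        if clip_polygon is not None:
            xs, ys = grid.cell_centers()
            within &= shapely.contains_xy(clip_polygon, xs, ys)
        mask_grid = CategoricalRaster(
            within.astype(np.int16),
            cell_size=grid.cell_size,
            origin=grid.origin,
            legend={0: "outside", 1: "study_area"},
        )
    return polygon, mask_grid


def extract_used_points(track: TelemetryTrack, mask: RasterGrid) -> np.ndarray:
    """Recorded fixes falling on nonzero cells of the analysis mask."""
    on_map = mask.contains(track.xy[:, 0], track.xy[:, 1])
    xy = track.xy[on_map]
    r, c = mask.cell_containing(xy[:, 0], xy[:, 1])
    inside = (mask.values[r, c] != 0) & mask.valid_mask[r, c]
    return xy[inside]


def sample_available(mask: RasterGrid, n: int, seed: int) -> np.ndarray:
    """``n`` points uniform over the nonzero area of the mask.

    A cell is drawn uniformly (with replacement -- availability is a
    design distribution) and the point jittered uniformly within it.
    """
    if n < 1:
        raise ValueError("need n >= 1 available points")
    cells = np.argwhere((mask.values != 0) & mask.valid_mask)
    if len(cells) == 0:
        raise ValueError("availability mask is empty")
    rng = np.random.default_rng(seed)
    pick = cells[rng.integers(0, len(cells), size=n)]
    cs = mask.cell_size
    u = rng.uniform(0.0, 1.0, size=(n, 2))
    x = mask.origin[0] + (pick[:, 1] + u[:, 0]) * cs
    y = mask.origin[1] - (pick[:, 0] + u[:, 1]) * cs
    return np.column_stack((x, y))


def sample_used_points(
    stack: LandscapeStack,
    betas: Mapping[str, float],
    n: int,
    seed: int,
    mask: RasterGrid | None = None,
) -> np.ndarray:
    """Point-level habitat selection with known coefficients.

    Draws ``n`` points over the mask (or the full map) with cell
    probability proportional to ``exp(sum_k beta_k * z_k)``, where the
    ``z_k`` are the standardized covariate surfaces -- an inhomogeneous
    point process whose log-intensity is the stated selection function.
    Points are jittered uniformly within their cell.
    """
    if n < 1:
        raise ValueError("need n >= 1 used points")
    ref = next(iter(stack.layers.values()))
    domain = np.ones(ref.shape, dtype=bool) if mask is None else (
        (mask.values != 0) & mask.valid_mask
    )
    if not domain.any():
        raise ValueError("sampling mask is empty")
    z_layers = _standardized_layers(stack, betas.keys())
    util = np.zeros(ref.shape)
    for name, beta in betas.items():
        util += beta * z_layers[name]
    util = np.where(np.isnan(util), -np.inf, util)
    cells = np.argwhere(domain)
    w = np.exp(util[domain] - util[domain].max())
    total = w.sum()
    if not total > 0:
        raise ValueError("selection weights vanish on the sampling mask")
    rng = np.random.default_rng(seed)
    pick = cells[rng.choice(len(cells), size=n, p=w / total)]
    cs = ref.cell_size
    u = rng.uniform(0.0, 1.0, size=(n, 2))
    x = ref.origin[0] + (pick[:, 1] + u[:, 0]) * cs
    y = ref.origin[1] - (pick[:, 0] + u[:, 1]) * cs
    return np.column_stack((x, y))


def build_table(
    used_xy: np.ndarray,
    available_xy: np.ndarray,
    stack: LandscapeStack,
    covariates: Sequence[str] | None = None,
    balance_seed: int = 0,
) -> pd.DataFrame:
    """Assemble the used/available model table.

    Covariates are sampled at the cell containing each point.  Rows with
    any nodata covariate are dropped; the larger class is then
    down-sampled (seeded) so used and available counts stay equal.
    Columns: ``used`` (1/0), ``x``, ``y``, one column per covariate.

    By default every continuous stack layer except raw elevation and the
    circular aspect angle is a covariate (terrain enters through slope,
    heat load, and wetness instead).
    """
    if covariates is None:
        covariates = [n for n in stack.continuous_names() if n not in ("dem", "aspect")]
    ref = next(iter(stack.layers.values()))
    frames = []
    n_dropped_outside = 0
    for label, pts in ((1, np.asarray(used_xy)), (0, np.asarray(available_xy))):
        pts = pts.reshape(-1, 2)
        on_map = ref.contains(pts[:, 0], pts[:, 1])
        n_dropped_outside += int((~on_map).sum())
        pts = pts[on_map]
        data = {"used": np.full(len(pts), label), "x": pts[:, 0], "y": pts[:, 1]}
        keep = np.ones(len(pts), dtype=bool)
        for name in covariates:
            grid = stack[name]
            r, c = grid.cell_containing(pts[:, 0], pts[:, 1])
            vals = grid.values[r, c].astype(float)
            keep &= grid.valid_mask[r, c]
            data[name] = vals
        frames.append(pd.DataFrame(data)[keep])
    if n_dropped_outside:
        import warnings

        warnings.warn(f"dropped {n_dropped_outside} points outside the stack extent")
    used_df, avail_df = frames
    n = min(len(used_df), len(avail_df))
    rng = np.random.default_rng(balance_seed)
    if len(used_df) > n:
        used_df = used_df.iloc[np.sort(rng.choice(len(used_df), n, replace=False))]
    if len(avail_df) > n:
        avail_df = avail_df.iloc[np.sort(rng.choice(len(avail_df), n, replace=False))]
    return pd.concat([used_df, avail_df], ignore_index=True)


def _round_half_up(x: float, ndigits: int = 0) -> float:
    f = 10.0**ndigits
    return np.floor(x * f + 0.5) / f


def burn_use_percent(n_inside: int, n_total: int) -> dict:
    """Share of locations inside the burn, as printed summaries.

    ``pct`` is exact, ``pct_1dp`` rounds half-up to one decimal, and
    ``pct_whole`` to the nearest whole percent.
    """
    if n_total <= 0:
        raise ValueError("need at least one location")
    pct = 100.0 * n_inside / n_total
    return {
        "n_total": int(n_total),
        "n_inside": int(n_inside),
        "pct": pct,
        "pct_1dp": _round_half_up(pct, 1),
        "pct_whole": _round_half_up(pct, 0),
    }


def burn_use_summary(track: TelemetryTrack, burn: RasterGrid) -> dict:
    """How many recorded fixes fall inside the burned area."""
    if len(track) == 0:
        raise ValueError("track has no recorded fixes")
    on_map = burn.contains(track.xy[:, 0], track.xy[:, 1])
    inside = np.zeros(len(track), dtype=bool)
    if on_map.any():
        xy = track.xy[on_map]
        r, c = burn.cell_containing(xy[:, 0], xy[:, 1])
        inside[on_map] = (burn.values[r, c] != 0) & burn.valid_mask[r, c]
    return burn_use_percent(int(inside.sum()), len(track))
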