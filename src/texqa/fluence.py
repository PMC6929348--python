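"""Integrated fluence maps from MLC control-point sequences.

Each control point's aperture (per leaf pair, the interval between the two
leaf tips, clipped by the jaws) is rasterized onto a regular grid at 1 mm
default resolution with exact area-weighted partial-pixel coverage, scaled
by that control point's monitor-unit share, and the per-control-point maps
are superposed over all beams of the plan. The integrated map is then
normalized to integer gray levels 0..127 for texture analysis, so every
nonzero map has a maximum gray level of 127.

The fluence is idealized: no leaf transmission, tongue-and-groove or
rounded-tip modeling — pixel value is purely MU-weighted open time.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from texqa.plan_model import Beam, ControlPoint, LeafGeometry, Plan, validate_plan


class FluenceError(ValueError):
    pass


@dataclass(frozen=True)
class FluenceGrid:
    """Regular 2D pixel grid. ``(x_origin, y_origin)`` is the center of
    pixel (row 0, col 0); x increases with column, y with row."""

    spacing_mm: float
    x_origin: float
    y_origin: float
    nx: int
    ny: int

    def __post_init__(self) -> None:
        if self.spacing_mm <= 0:
            raise FluenceError("grid spacing must be > 0")
        if self.nx < 1 or self.ny < 1:
            raise FluenceError("grid dimensions must be >= 1")
        object.__setattr__(self, "spacing_mm", float(self.spacing_mm))
        object.__setattr__(self, "x_origin", float(self.x_origin))
        object.__setattr__(self, "y_origin", float(self.y_origin))
        object.__setattr__(self, "nx", int(self.nx))
        object.__setattr__(self, "ny", int(self.ny))

    @property
    def x_edges(self) -> np.ndarray:
        """Pixel-boundary coordinates along x (nx + 1 values)."""
        return self.x_origin - self.spacing_mm / 2 + self.spacing_mm * np.arange(self.nx + 1)

    @property
    def y_edges(self) -> np.ndarray:
        return self.y_origin - self.spacing_mm / 2 + self.spacing_mm * np.arange(self.ny + 1)


@dataclass(frozen=True)
class FluenceMap:
    grid: FluenceGrid
    values: np.ndarray  # shape (ny, nx), MU per pixel

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.grid.ny, self.grid.nx):
            raise FluenceError(f"values shape {v.shape} != grid ({self.grid.ny}, {self.grid.nx})")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise FluenceError("fluence values must be finite and >= 0")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class GrayLevelMap:
    grid: FluenceGrid
    levels: np.ndarray  # shape (ny, nx), ints in [0, n_levels-1]
    n_levels: int = 128

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels)
        if lv.min() < 0 or lv.max() >= self.n_levels:
            raise FluenceError("gray levels out of range")
        object.__setattr__(self, "levels", lv.astype(np.int64))


def _interval_coverage(edges: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fraction of each pixel interval [edges[i], edges[i+1]] covered by
    [lo, hi]."""
    width = np.diff(edges)
    overlap = np.minimum(edges[1:], hi) - np.maximum(edges[:-1], lo)
    return np.clip(overlap, 0.0, None) / width


def aperture_fluence(
    cp: ControlPoint,
    geometry: LeafGeometry,
    grid: FluenceGrid,
    mu_weight: float,
    *,
    partial_pixels: bool = True,
) -> FluenceMap:
    """Rasterize one control point's aperture, scaled by its MU share.

    Pixel value = ``mu_weight`` x area fraction of the pixel inside the
    open region (leaf-gap interval intersected with the jaw rectangle).
    With ``partial_pixels=False`` a faster center-in test is used instead.
    """
    if mu_weight < 0:
        raise FluenceError("mu_weight must be >= 0")
    values = np.zeros((grid.ny, grid.nx))
    if mu_weight == 0:
        return FluenceMap(grid, values)
    x1, x2, y1, y2 = cp.jaws
    x_edges, y_edges = grid.x_edges, grid.y_edges
    bounds = np.asarray(geometry.leaf_boundaries)

    # grid must cover the jaw-clipped aperture; otherwise fluence is lost
    open_mask = np.asarray(cp.bank_B) > np.asarray(cp.bank_A)
    if open_mask.any():
        lo_x = max(min(a for a, o in zip(cp.bank_A, open_mask) if o), x1)
        hi_x = min(max(b for b, o in zip(cp.bank_B, open_mask) if o), x2)
        rows = np.nonzero(open_mask)[0]
        lo_y = max(bounds[rows.min()], y1)
        hi_y = min(bounds[rows.max() + 1], y2)
        if lo_x < hi_x and lo_y < hi_y:
            if lo_x < x_edges[0] or hi_x > x_edges[-1] or lo_y < y_edges[0] or hi_y > y_edges[-1]:
                raise FluenceError(
                    f"grid [{x_edges[0]},{x_edges[-1]}]x[{y_edges[0]},{y_edges[-1]}] does not "
                    f"cover aperture extent [{lo_x},{hi_x}]x[{lo_y},{hi_y}]"
                )

    for i in range(geometry.n_pairs):
        a = max(cp.bank_A[i], x1)
        b = min(cp.bank_B[i], x2)
        yl = max(bounds[i], y1)
        yh = min(bounds[i + 1], y2)
        if b <= a or yh <= yl:
            continue
        if partial_pixels:
            fx = _interval_coverage(x_edges, a, b)
            fy = _interval_coverage(y_edges, yl, yh)
        else:
            xc = (x_edges[:-1] + x_edges[1:]) / 2
            yc = (y_edges[:-1] + y_edges[1:]) / 2
            fx = ((xc >= a) & (xc < b)).astype(float)
            fy = ((yc >= yl) & (yc < yh)).astype(float)
        values += mu_weight * np.outer(fy, fx)
    return FluenceMap(grid, values)


def meterset_shares(beam: Beam, mode: str = "trapezoid") -> np.ndarray:
    """Monitor units attributed to each control point of a beam.

    ``trapezoid`` splits each meterset interval evenly between its two
    bounding apertures (with the end weights duplicated as virtual
    endpoints), so the shares sum to the beam's total MU. ``left`` assigns
    each interval wholly to its starting control point (the final control
    point then carries zero MU).
    """
    w = np.array([c.cumulative_meterset_weight for c in beam.control_points])
    if mode == "trapezoid":
        padded = np.concatenate([[w[0]], w, [w[-1]]])
        shares = (padded[2:] - padded[:-2]) / 2.0
    elif mode == "left":
        shares = np.concatenate([np.diff(w), [0.0]])
    else:
        raise ValueError(f"unknown meterset share mode: {mode!r}")
    return beam.total_mu * shares


def auto_grid(plan: Plan, spacing_mm: float = 1.0, pad_mm: float = 5.0) -> FluenceGrid:
    """Grid covering the union of jaw-clipped apertures over all control
    points, padded by ``pad_mm``, with a pixel centered on the isocenter axis."""
    lo_x = lo_y = np.inf
    hi_x = hi_y = -np.inf
    for beam in plan.beams:
        bounds = np.asarray(beam.geometry.leaf_boundaries)
        for cp in beam.control_points:
            a = np.maximum(np.asarray(cp.bank_A), cp.jaws[0])
            b = np.minimum(np.asarray(cp.bank_B), cp.jaws[1])
            yl = np.maximum(bounds[:-1], cp.jaws[2])
            yh = np.minimum(bounds[1:], cp.jaws[3])
            open_ = (b > a) & (yh > yl)
            if open_.any():
                lo_x = min(lo_x, a[open_].min())
                hi_x = max(hi_x, b[open_].max())
                lo_y = min(lo_y, yl[open_].min())
                hi_y = max(hi_y, yh[open_].max())
    if not np.isfinite(lo_x):
        raise FluenceError("plan has no open aperture at any control point")
    lo_x -= pad_mm
    hi_x += pad_mm
    lo_y -= pad_mm
    hi_y += pad_mm
    # snap pixel centers to multiples of spacing so maps are grid-aligned
    x0 = np.floor(lo_x / spacing_mm) * spacing_mm + spacing_mm / 2
    y0 = np.floor(lo_y / spacing_mm) * spacing_mm + spacing_mm / 2
    nx = int(np.ceil((hi_x - (x0 - spacing_mm / 2)) / spacing_mm))
    ny = int(np.ceil((hi_y - (y0 - spacing_mm / 2)) / spacing_mm))
    return FluenceGrid(spacing_mm=spacing_mm, x_origin=x0, y_origin=y0, nx=nx, ny=ny)


def integrate_fluence(
    plan: Plan,
    grid: FluenceGrid | None = None,
    *,
    share_mode: str = "trapezoid",
    partial_pixels: bool = True,
) -> FluenceMap:
    """Superpose the MU-weighted apertures of every control point of every
    beam into one integrated fluence map for the plan."""
    violations = validate_plan(plan)
    if violations:
        raise FluenceError("invalid plan: " + "; ".join(violations[:3]))
    if grid is None:
        grid = auto_grid(plan)
    total = np.zeros((grid.ny, grid.nx))
    for beam in plan.beams:
        shares = meterset_shares(beam, mode=share_mode)
        for cp, mu in zip(beam.control_points, shares):
            total += aperture_fluence(
                cp, beam.geometry, grid, mu, partial_pixels=partial_pixels
            ).values
    return FluenceMap(grid, total)


def crop_to_nonzero(fmap: FluenceMap, margin_mm: float = 0.0) -> FluenceMap:
    """Crop to the bounding box of nonzero fluence plus ``margin_mm``.

    Background zeros dilute every co-occurrence feature, so the map extent
    fed to texture analysis is made explicit and reproducible.
    """
    nz = np.nonzero(fmap.values)
    if len(nz[0]) == 0:
        raise FluenceError("cannot crop an all-zero fluence map")
    m = int(round(margin_mm / fmap.grid.spacing_mm))
    r0 = max(nz[0].min() - m, 0)
    r1 = min(nz[0].max() + m + 1, fmap.grid.ny)
    c0 = max(nz[1].min() - m, 0)
    c1 = min(nz[1].max() + m + 1, fmap.grid.nx)
    g = fmap.grid
    new_grid = FluenceGrid(
        spacing_mm=g.spacing_mm,
        x_origin=g.x_origin + c0 * g.spacing_mm,
        y_origin=g.y_origin + r0 * g.spacing_mm,
        nx=c1 - c0,
        ny=r1 - r0,
    )
    return FluenceMap(new_grid, fmap.values[r0:r1, c0:c1])


def quantize(fmap: FluenceMap, n_levels: int = 128) -> GrayLevelMap:
    """Normalize a fluence map to integer gray levels 0..n_levels-1.

    level = round_half_up((n_levels - 1) * value / max). Half-up rounding
    (not banker's) keeps quantization platform-reproducible. The maximum
    pixel always maps to the top level; an all-zero map is an error.
    """
    vmax = fmap.values.max()
    if vmax <= 0:
        raise FluenceError("cannot quantize an all-zero fluence map")
    scaled = (n_levels - 1) * fmap.values / vmax
    levels = np.floor(scaled + 0.5).astype(np.int64)
    return GrayLevelMap(fmap.grid, levels, n_levels=n_levels)


# ---------------------------------------------------------------------------
# CSV + sidecar I/O (text formats keep fixtures diffable)


def _grid_sidecar(grid: FluenceGrid) -> dict:
    return {
        "spacing_mm": grid.spacing_mm,
        "x_origin": grid.x_origin,
        "y_origin": grid.y_origin,
        "nx": grid.nx,
        "ny": grid.ny,
    }


def write_map_csv(fmap: FluenceMap, path: str | Path) -> None:
    """Write values as a CSV matrix with a ``<path>.grid.json`` sidecar."""
    import json

    path = Path(path)
    np.savetxt(path, fmap.values, delimiter=",", fmt="%.9g")
    Path(str(path) + ".grid.json").write_text(json.dumps(_grid_sidecar(fmap.grid)))


def read_map_csv(path: str | Path) -> FluenceMap:
    import json

    path = Path(path)
    values = np.atleast_2d(np.loadtxt(path, delimiter=","))
    sidecar = Path(str(path) + ".grid.json")
    if sidecar.exists():
        g = json.loads(sidecar.read_text())
        grid = FluenceGrid(g["spacing_mm"], g["x_origin"], g["y_origin"], g["nx"], g["ny"])
    else:
        grid = FluenceGrid(1.0, 0.0, 0.0, values.shape[1], values.shape[0])
    return FluenceMap(grid, values)
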