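"""Shared fixtures: tiny hand-built plans and independent brute-force
oracles used to cross-check the vectorized implementations."""

from __future__ import annotations

import numpy as np
import pytest

from texqa.fluence import FluenceGrid, FluenceMap
from texqa.plan_model import Beam, ControlPoint, LeafGeometry, Plan, uniform_geometry


@pytest.fixture
def two_pair_geometry() -> LeafGeometry:
    return LeafGeometry((-10.0, 0.0, 10.0), name="2x10mm")


@pytest.fixture
def small_plan(two_pair_geometry) -> Plan:
    """One beam, two control points, a 10 mm square opening that sweeps."""
    cp0 = ControlPoint(0, 0.0, 180.0, bank_A=(-5.0, -5.0), bank_B=(5.0, 5.0))
    cp1 = ControlPoint(1, 1.0, 200.0, bank_A=(0.0, 0.0), bank_B=(10.0, 10.0))
    return Plan("small", (Beam((cp0, cp1), total_mu=100.0, geometry=two_pair_geometry),))


@pytest.fixture
def static_plan() -> Plan:
    """Static 20x20 mm aperture held over two control points."""
    geom = uniform_geometry(4, 5.0)
    cps = tuple(
        ControlPoint(k, float(k), 0.0, bank_A=(-10.0,) * 4, bank_B=(10.0,) * 4)
        for k in range(2)
    )
    return Plan("static", (Beam(cps, total_mu=50.0, geometry=geom),))


def brute_force_aperture(cp: ControlPoint, geometry, grid: FluenceGrid, mu: float,
                         sub_mm: float = 0.1) -> np.ndarray:
    """Independent rasterizer: subsample each pixel on a sub-millimetre
    lattice and count sample points inside the jaw-clipped open region."""
    bounds = np.asarray(geometry.leaf_boundaries)
    x1, x2, y1, y2 = cp.jaws
    n_sub = int(round(grid.spacing_mm / sub_mm))
    out = np.zeros((grid.ny, grid.nx))
    for r in range(grid.ny):
        for c in range(grid.nx):
            xc = grid.x_origin + c * grid.spacing_mm
            yc = grid.y_origin + r * grid.spacing_mm
            xs = xc - grid.spacing_mm / 2 + sub_mm * (np.arange(n_sub) + 0.5)
            ys = yc - grid.spacing_mm / 2 + sub_mm * (np.arange(n_sub) + 0.5)
            inside = 0
            for y in ys:
                i = np.searchsorted(bounds, y) - 1
                if i < 0 or i >= geometry.n_pairs or not (y1 <= y <= y2):
                    continue
                a = max(cp.bank_A[i], x1)
                b = min(cp.bank_B[i], x2)
                inside += int(np.sum((xs >= a) & (xs < b)))
            out[r, c] = mu * inside / n_sub**2
    return out


def brute_force_glcm(img: np.ndarray, n_levels: int, dc: int, dr: int,
                     symmetric: bool = True) -> np.ndarray:
    """Double-loop pair counter, the reference for the vectorized GLCM."""
    ny, nx = img.shape
    counts = np.zeros((n_levels, n_levels), dtype=np.int64)
    for r in range(ny):
        for c in range(nx):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < ny and 0 <= c2 < nx:
                counts[img[r, c], img[r2, c2]] += 1
                if symmetric:
                    counts[img[r2, c2], img[r, c]] += 1
    return counts


def brute_force_haralick(p: np.ndarray) -> dict:
    """Plain-summation feature evaluation over all matrix cells."""
    n = p.shape[0]
    asm = idm = contrast = entropy = cross = 0.0
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = sum(i * px[i] for i in range(n))
    mu_y = sum(j * py[j] for j in range(n))
    for i in range(n):
        for j in range(n):
            v = p[i, j]
            asm += v * v
            idm += v / (1 + (i - j) ** 2)
            contrast += (i - j) ** 2 * v
            cross += i * j * v
            if v > 0:
                entropy -= v * np.log10(v)
    var_x = sum((i - mu_x) ** 2 * px[i] for i in range(n))
    var_y = sum((j - mu_y) ** 2 * py[j] for j in range(n))
    sxsy = np.sqrt(var_x * var_y)
    corr = (cross - mu_x * mu_y) / sxsy if sxsy > 0 else float("nan")
    return {
        "ASM": asm,
        "IDM": idm,
        "contrast": contrast,
        "variance": var_x,
        "correlation": corr,
        "entropy": entropy,
    }


def brute_force_gamma(reference, measured, crit, cap_factor=3.0, step_factor=0.1):
    """Exhaustive gamma search: per evaluated point, scan every offset on
    the fine lattice with no early termination."""
    from scipy.interpolate import RegularGridInterpolator

    dmax = reference.dose.max()
    dd = crit.dose_percent / 100 * dmax
    dta = crit.dta_mm
    cutoff = crit.low_dose_cutoff_percent / 100 * dmax
    interp = RegularGridInterpolator(
        (reference.y, reference.x), reference.dose, bounds_error=False, fill_value=np.nan
    )
    step = dta * step_factor
    k = int(np.floor(cap_factor * dta / step))
    ax = step * np.arange(-k, k + 1)
    ox, oy = np.meshgrid(ax, ax)
    keep = ox**2 + oy**2 <= (cap_factor * dta) ** 2 + 1e-9
    ox, oy = ox[keep], oy[keep]
    dist2 = (ox**2 + oy**2) / dta**2
    gmap = np.full(measured.dose.shape, np.nan)
    for r in range(measured.dose.shape[0]):
        for c in range(measured.dose.shape[1]):
            dm = measured.dose[r, c]
            if dm < cutoff:
                continue
            x = measured.x[c]
            y = measured.y[r]
            refs = interp(np.column_stack([y + oy, x + ox]))
            g2 = dist2 + (refs - dm) ** 2 / dd**2
            gmap[r, c] = np.sqrt(np.nanmin(g2))
    return gmap


def make_dose_plane(values: np.ndarray, spacing: float = 1.0):
    from texqa.delivery_accuracy import DosePlane

    ny, nx = values.shape
    return DosePlane(FluenceGrid(spacing, 0.0, 0.0, nx, ny), values)


def make_gray_map(levels: np.ndarray, n_levels: int = 128):
    from texqa.fluence import GrayLevelMap

    ny, nx = levels.shape
    return GrayLevelMap(FluenceGrid(1.0, 0.0, 0.0, nx, ny), levels, n_levels=n_levels)
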