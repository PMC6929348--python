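"""Gray-level co-occurrence matrices and Haralick texture features.

The co-occurrence matrix for a displacement distance d and angle theta
counts pairs of gray levels at pixel offsets (in (col, row) order, with the
row index increasing downward):

    0 deg: ( d,  0)    45 deg: ( d, -d)    90 deg: ( 0, -d)    135 deg: (-d, -d)

Symmetric mode also counts each pair in the reversed order, so the four
angles cover all eight neighbor directions and the marginal distributions
p_x and p_y coincide. From the normalized matrix p, six features are
computed:

    ASM         = sum p(i,j)^2
    IDM         = sum p(i,j) / (1 + (i-j)^2)
    contrast    = sum (i-j)^2 p(i,j)
    variance    = sum_i (i - mu)^2 p_x(i),   mu = marginal mean
    correlation = (sum i*j*p(i,j) - mu_x mu_y) / (sigma_x sigma_y)
    entropy     = -sum p(i,j) log p(i,j)     (base-10 logarithm by default)

On a 1 mm fluence-map grid, d in {1, 5, 10} probes pixel separations of
1/5/10 mm horizontally and vertically and sqrt(2)/5*sqrt(2)/10*sqrt(2) mm
diagonally. Features at each d are averaged over the four angles, giving
an 18-value panel (6 features x 3 distances) per plan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from texqa.fluence import GrayLevelMap, crop_to_nonzero, integrate_fluence, quantize
from texqa.plan_model import Plan

FEATURE_NAMES = ("ASM", "IDM", "contrast", "variance", "correlation", "entropy")

# (dc, dr) pixel offsets in (col, row) order; row index increases downward
ANGLE_OFFSETS = {0: (1, 0), 45: (1, -1), 90: (0, -1), 135: (-1, -1)}


class TextureError(ValueError):
    pass


@dataclass(frozen=True)
class TextureConfig:
    distances: tuple[int, ...] = (1, 5, 10)
    angles: tuple[int, ...] = (0, 45, 90, 135)
    n_levels: int = 128
    symmetric: bool = True
    normalized: bool = True
    log_base: float = 10.0
    variance_mean: str = "marginal"  # or "joint" (identical in symmetric mode)

    def __post_init__(self) -> None:
        if any(d < 1 for d in self.distances):
            raise TextureError("distances must be >= 1")
        bad = set(self.angles) - set(ANGLE_OFFSETS)
        if bad:
            raise TextureError(f"unsupported angles: {sorted(bad)}")
        if self.variance_mean not in ("marginal", "joint"):
            raise TextureError("variance_mean must be 'marginal' or 'joint'")


@dataclass(frozen=True)
class GLCM:
    p: np.ndarray  # (n_levels, n_levels)
    d: int
    theta: int
    pair_count: int
    normalized: bool


@dataclass(frozen=True)
class TextureFeatureSet:
    ASM: float
    IDM: float
    contrast: float
    variance: float
    correlation: float
    entropy: float
    d: int
    # per-direction audit trail, populated by direction averaging
    per_direction: dict = field(default_factory=dict)
    n_defined_correlation: int = 0

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def glcm(img: GrayLevelMap, d: int, theta: int, cfg: TextureConfig | None = None) -> GLCM:
    """Co-occurrence matrix of ``img`` at displacement ``d`` pixels, angle
    ``theta`` degrees."""
    cfg = cfg or TextureConfig()
    if theta not in ANGLE_OFFSETS:
        raise TextureError(f"unsupported angle {theta}")
    if d < 1:
        raise TextureError("d must be >= 1")
    dc, dr = (off * d for off in ANGLE_OFFSETS[theta])
    lv = img.levels
    ny, nx = lv.shape
    r0, r1 = max(0, -dr), min(ny, ny - dr)
    c0, c1 = max(0, -dc), min(nx, nx - dc)
    if r1 <= r0 or c1 <= c0:
        raise TextureError(f"no pairs: image {lv.shape} smaller than offset ({dc},{dr})")
    src = lv[r0:r1, c0:c1].ravel()
    dst = lv[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
    n = img.n_levels
    counts = np.bincount(src * n + dst, minlength=n * n).reshape(n, n).astype(np.int64)
    if cfg.symmetric:
        counts = counts + counts.T
    pair_count = int(counts.sum())
    p = counts.astype(float)
    if cfg.normalized:
        p = p / pair_count
    return GLCM(p=p, d=d, theta=theta, pair_count=pair_count, normalized=cfg.normalized)


def haralick_features(g: GLCM, cfg: TextureConfig | None = None) -> TextureFeatureSet:
    """The six features from one normalized co-occurrence matrix.

    For a degenerate matrix concentrated on a single level, the gray-level
    standard deviation vanishes and correlation is undefined; it is
    returned as NaN (never silently zeroed).
    """
    cfg = cfg or TextureConfig()
    if not g.normalized:
        raise TextureError("features require a normalized GLCM")
    p = g.p
    n = p.shape[0]
    i = np.arange(n, dtype=float)
    diff2 = (i[:, None] - i[None, :]) ** 2

    asm = float(np.sum(p * p))
    idm = float(np.sum(p / (1.0 + diff2)))
    contrast = float(np.sum(diff2 * p))

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(np.dot(i, px))
    mu_y = float(np.dot(i, py))
    var_x = float(np.dot((i - mu_x) ** 2, px))
    var_y = float(np.dot((i - mu_y) ** 2, py))

    if cfg.variance_mean == "marginal":
        variance = var_x
    else:
        mu = (mu_x + mu_y) / 2.0
        variance = float(np.sum(((i[:, None] - mu) ** 2) * p))

    sxsy = math.sqrt(var_x) * math.sqrt(var_y)
    if sxsy > 0:
        correlation = (float(np.sum(np.outer(i, i) * p)) - mu_x * mu_y) / sxsy
    else:
        correlation = float("nan")

    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log(nz)) / math.log(cfg.log_base))

    return TextureFeatureSet(
        ASM=asm,
        IDM=idm,
        contrast=contrast,
        variance=variance,
        correlation=correlation,
        entropy=entropy,
        d=g.d,
        n_defined_correlation=0 if math.isnan(correlation) else 1,
    )


def direction_averaged_features(
    img: GrayLevelMap, d: int, cfg: TextureConfig | None = None
) -> TextureFeatureSet:
    """Arithmetic mean of each feature over the configured angles.

    An undefined (NaN) correlation in some direction is averaged over the
    defined directions only, with the defined-direction count recorded; if
    no direction defines it, the average is NaN.
    """
    cfg = cfg or TextureConfig()
    per_dir = {theta: haralick_features(glcm(img, d, theta, cfg), cfg) for theta in cfg.angles}
    means: dict[str, float] = {}
    for name in FEATURE_NAMES:
        vals = np.array([getattr(f, name) for f in per_dir.values()])
        if name == "correlation":
            defined = vals[~np.isnan(vals)]
            means[name] = float(defined.mean()) if defined.size else float("nan")
        else:
            means[name] = float(vals.mean())
    n_def = sum(f.n_defined_correlation for f in per_dir.values())
    return TextureFeatureSet(
        **means,
        d=d,
        per_direction={t: f.as_dict() for t, f in per_dir.items()},
        n_defined_correlation=n_def,
    )


def feature_panel(
    plan: Plan,
    cfg: TextureConfig | None = None,
    *,
    crop_margin_mm: float = 0.0,
    grid=None,
) -> dict[tuple[str, int], float]:
    """The plan's texture panel: 6 features x the configured distances.

    Integrates the plan's fluence, crops to the nonzero extent (plus
    ``crop_margin_mm`` of background), quantizes to gray levels and
    computes direction-averaged features at every distance. With the
    default three distances the panel has 18 values keyed ``(feature, d)``.
    """
    cfg = cfg or TextureConfig()
    fmap = integrate_fluence(plan, grid)
    fmap = crop_to_nonzero(fmap, margin_mm=crop_margin_mm)
    img = quantize(fmap, n_levels=cfg.n_levels)
    panel: dict[tuple[str, int], float] = {}
    for d in cfg.distances:
        feats = direction_averaged_features(img, d, cfg)
        for name in FEATURE_NAMES:
            panel[(name, d)] = getattr(feats, name)
    return panel
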