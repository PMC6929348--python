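"""Delivery-accuracy measures and the feature-accuracy correlation study.

Three ingredients of patient-specific QA:

* global 2D gamma analysis of absolute-dose planes (composite
  dose-difference / distance-to-agreement index, dose difference
  normalized to the reference plane's maximum, low-dose cutoff),
* mechanical delivery errors from machine-log records matched to plan
  control points (mean absolute MLC, gantry-angle and monitor-unit
  differences),
* Spearman rank correlations (with exact permutation p-values at small n)
  between a plan cohort's texture-feature panel and its accuracy measures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import RegularGridInterpolator

from texqa.fluence import FluenceGrid
from texqa.plan_model import DeliveryRecord, Plan


class GammaError(ValueError):
    pass


class CorrelationError(ValueError):
    pass


@dataclass(frozen=True)
class DosePlane:
    """Absolute dose (Gy) sampled on a regular 2D grid."""

    grid: FluenceGrid
    dose: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.dose, dtype=float)
        if d.shape != (self.grid.ny, self.grid.nx):
            raise GammaError(f"dose shape {d.shape} != grid ({self.grid.ny}, {self.grid.nx})")
        if not np.all(np.isfinite(d)) or np.any(d < 0):
            raise GammaError("dose must be finite and >= 0")
        object.__setattr__(self, "dose", d)

    @property
    def x(self) -> np.ndarray:
        g = self.grid
        return g.x_origin + g.spacing_mm * np.arange(g.nx)

    @property
    def y(self) -> np.ndarray:
        g = self.grid
        return g.y_origin + g.spacing_mm * np.arange(g.ny)


@dataclass(frozen=True)
class GammaCriteria:
    dose_percent: float  # dose-difference criterion, % of global reference max
    dta_mm: float  # distance-to-agreement criterion
    low_dose_cutoff_percent: float = 10.0
    normalization: str = "global"

    def __post_init__(self) -> None:
        if self.dose_percent <= 0 or self.dta_mm <= 0 or self.low_dose_cutoff_percent <= 0:
            raise GammaError("gamma criteria must be strictly positive")
        if self.normalization != "global":
            raise GammaError("only global normalization is supported")


@dataclass(frozen=True)
class GammaResult:
    gamma_map: np.ndarray  # NaN at excluded (below-cutoff) points
    passing_rate: float  # % of evaluated points with gamma <= 1
    n_evaluated: int
    n_capped: int = 0  # points whose minimum may lie beyond the search cap


@dataclass(frozen=True)
class MechanicalErrorSummary:
    mlc_error_mm: float
    gantry_error_deg: float
    mu_error: float

    def __post_init__(self) -> None:
        if self.mlc_error_mm < 0 or self.gantry_error_deg < 0 or self.mu_error < 0:
            raise ValueError("mechanical errors are mean absolute values, must be >= 0")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p < 0.05


# ---------------------------------------------------------------------------
# Gamma analysis


def gamma_analysis(
    reference: DosePlane,
    measured: DosePlane,
    crit: GammaCriteria,
    *,
    search_cap_factor: float = 3.0,
    search_step_factor: float = 0.1,
) -> GammaResult:
    """Global 2D gamma of ``measured`` against ``reference``.

    For each measured point with dose at or above the low-dose cutoff
    (relative to the reference plane's global maximum), gamma is the
    minimum over candidate reference positions within
    ``search_cap_factor x DTA`` (sampled every ``search_step_factor x DTA``
    with bilinear interpolation of the reference) of

        sqrt( |dr|^2 / DTA^2 + (D_ref(r+dr) - D_meas(r))^2 / (delta Dmax)^2 ).

    Candidate offsets are visited in rings of increasing radius, and a
    point stops searching once no farther ring can lower its gamma, which
    makes the exhaustive search cheap on mostly-agreeing planes.
    """
    dmax = reference.dose.max()
    if dmax <= 0:
        raise GammaError("reference plane has no dose")
    if (
        measured.x[0] > reference.x[-1]
        or measured.x[-1] < reference.x[0]
        or measured.y[0] > reference.y[-1]
        or measured.y[-1] < reference.y[0]
    ):
        raise GammaError("reference and measured planes do not overlap")

    dd = crit.dose_percent / 100.0 * dmax
    dta = crit.dta_mm
    cutoff = crit.low_dose_cutoff_percent / 100.0 * dmax

    interp = RegularGridInterpolator(
        (reference.y, reference.x),
        reference.dose,
        method="linear",
        bounds_error=False,
        fill_value=np.nan,
    )

    yy, xx = np.meshgrid(measured.y, measured.x, indexing="ij")
    eval_mask = measured.dose >= cutoff
    px = xx[eval_mask]
    py = yy[eval_mask]
    pd_meas = measured.dose[eval_mask]
    n_eval = int(eval_mask.sum())
    gamma_map = np.full(measured.dose.shape, np.nan)
    if n_eval == 0:
        return GammaResult(gamma_map, float("nan"), 0)

    # candidate offsets, grouped into rings of equal radius
    step = dta * search_step_factor
    cap = dta * search_cap_factor
    k = int(math.floor(cap / step))
    ax = step * np.arange(-k, k + 1)
    ox, oy = np.meshgrid(ax, ax)
    r2 = ox**2 + oy**2
    keep = r2 <= cap**2 + 1e-9
    ox, oy, r2 = ox[keep], oy[keep], r2[keep]
    order = np.argsort(r2, kind="stable")
    ox, oy, r2 = ox[order], oy[order], r2[order]
    ring_ids = np.unique(np.round(r2, 9), return_inverse=True)[1]

    g2 = np.full(n_eval, np.inf)
    active = np.ones(n_eval, dtype=bool)
    for ring in range(ring_ids.max() + 1):
        sel = ring_ids == ring
        ring_r2 = r2[sel][0]
        dist_term = ring_r2 / dta**2
        # a farther ring cannot improve a point already below its floor
        active &= g2 > dist_term
        if not active.any():
            break
        axc = px[active]
        ayc = py[active]
        best = g2[active]
        for dx, dy in zip(ox[sel], oy[sel]):
            ref_vals = interp(np.column_stack([ayc + dy, axc + dx]))
            dose_term = (ref_vals - pd_meas[active]) ** 2 / dd**2
            cand = dist_term + dose_term
            valid = ~np.isnan(cand)
            best[valid] = np.minimum(best[valid], cand[valid])
        g2[active] = best

    n_capped = int(np.sum(g2 > (cap / dta) ** 2))
    gamma = np.sqrt(g2)
    gamma_map[eval_mask] = gamma
    passing = float(100.0 * np.sum(gamma <= 1.0 + 1e-12) / n_eval)
    return GammaResult(gamma_map, passing, n_eval, n_capped)


# ---------------------------------------------------------------------------
# Machine-log mechanical errors


def _circular_diff_deg(a: float, b: float) -> float:
    """Minimal angular difference on the circle, in [0, 180]."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def mechanical_errors(
    plan: Plan,
    record: DeliveryRecord,
    *,
    moving_leaves_only: bool = False,
) -> MechanicalErrorSummary:
    """Mean absolute plan-vs-recorded differences over all control points.

    MLC error averages per-leaf absolute position differences over both
    banks; gantry differences are taken on the circle; MU differences
    compare cumulative delivered MU (planned cumulative MU is the
    cumulative meterset weight times the beam's total MU). Snapshots must
    be matched one-to-one to plan control points (see
    :func:`align_record_to_plan` for resampling denser logs).

    ``moving_leaves_only`` restricts the MLC average to leaf pairs whose
    planned position changes during the beam.
    """
    if len(plan.beams) != len(record.beams):
        raise ValueError(
            f"plan has {len(plan.beams)} beams but record has {len(record.beams)}"
        )
    mlc_diffs: list[np.ndarray] = []
    gantry_diffs: list[float] = []
    mu_diffs: list[float] = []
    for beam, log_beam in zip(plan.beams, record.beams):
        if beam.geometry.n_pairs != log_beam.geometry.n_pairs:
            raise ValueError(
                f"leaf count mismatch: plan {beam.geometry.n_pairs} vs "
                f"log {log_beam.geometry.n_pairs}"
            )
        if len(beam.control_points) != len(log_beam.snapshots):
            raise ValueError(
                f"snapshot count {len(log_beam.snapshots)} != control point "
                f"count {len(beam.control_points)}"
            )
        plan_a = np.array([c.bank_A for c in beam.control_points])
        plan_b = np.array([c.bank_B for c in beam.control_points])
        rec_a = np.array([s.bank_A for s in log_beam.snapshots])
        rec_b = np.array([s.bank_B for s in log_beam.snapshots])
        da = np.abs(plan_a - rec_a)
        db = np.abs(plan_b - rec_b)
        if moving_leaves_only:
            moving = (np.ptp(plan_a, axis=0) > 0) | (np.ptp(plan_b, axis=0) > 0)
            if moving.any():
                da, db = da[:, moving], db[:, moving]
            # if nothing moves, fall back to all leaves
        mlc_diffs.append(np.concatenate([da.ravel(), db.ravel()]))
        for cp, s in zip(beam.control_points, log_beam.snapshots):
            gantry_diffs.append(_circular_diff_deg(cp.gantry_angle, s.gantry_angle))
            planned_mu = cp.cumulative_meterset_weight * beam.total_mu
            mu_diffs.append(abs(planned_mu - s.cumulative_mu))
    return MechanicalErrorSummary(
        mlc_error_mm=float(np.concatenate(mlc_diffs).mean()),
        gantry_error_deg=float(np.mean(gantry_diffs)),
        mu_error=float(np.mean(mu_diffs)),
    )


def align_record_to_plan(plan: Plan, record: DeliveryRecord) -> DeliveryRecord:
    """Resample a denser log to the plan's control points, linearly in
    cumulative delivered MU."""
    from texqa.plan_model import LogBeam, Snapshot

    beams = []
    for beam, log_beam in zip(plan.beams, record.beams):
        mu_log = np.array([s.cumulative_mu for s in log_beam.snapshots])
        gantry = np.array([s.gantry_angle for s in log_beam.snapshots])
        banks_a = np.array([s.bank_A for s in log_beam.snapshots])
        banks_b = np.array([s.bank_B for s in log_beam.snapshots])
        snaps = []
        for idx, cp in enumerate(beam.control_points):
            target = cp.cumulative_meterset_weight * beam.total_mu
            snaps.append(
                Snapshot(
                    index=idx,
                    cumulative_mu=target,
                    gantry_angle=float(np.interp(target, mu_log, gantry)),
                    bank_A=tuple(
                        np.interp(target, mu_log, banks_a[:, i])
                        for i in range(banks_a.shape[1])
                    ),
                    bank_B=tuple(
                        np.interp(target, mu_log, banks_b[:, i])
                        for i in range(banks_b.shape[1])
                    ),
                )
            )
        beams.append(LogBeam(snapshots=tuple(snaps), geometry=log_beam.geometry))
    return DeliveryRecord(plan_id=record.plan_id, beams=tuple(beams))


def average_summaries(summaries: list[MechanicalErrorSummary]) -> MechanicalErrorSummary:
    """Component-wise mean, e.g. over the QA sessions of one plan."""
    if not summaries:
        raise ValueError("cannot average an empty list of summaries")
    return MechanicalErrorSummary(
        mlc_error_mm=float(np.mean([s.mlc_error_mm for s in summaries])),
        gantry_error_deg=float(np.mean([s.gantry_error_deg for s in summaries])),
        mu_error=float(np.mean([s.mu_error for s in summaries])),
    )


# ---------------------------------------------------------------------------
# Spearman correlation

_EXACT_N_MAX = 9


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with a two-sided p-value.

    Ranks use midranks for ties; r is the Pearson correlation of the rank
    vectors. For n <= 9 the p-value is exact, by enumerating all n!
    permutations of one rank vector; for larger n the usual
    t = r sqrt((n-2)/(1-r^2)) approximation with n-2 degrees of freedom
    is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n or n < 3:
        raise CorrelationError("need equal-length samples with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise CorrelationError("undefined correlation: constant input")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    r = float(np.corrcoef(rx, ry)[0, 1])
    if n <= _EXACT_N_MAX:
        p = _exact_permutation_p(rx, ry, r)
    else:
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * math.sqrt((n - 2) / (1.0 - r * r))
            p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return CorrelationResult(r=r, p=min(p, 1.0), n=n)


def _exact_permutation_p(rx: np.ndarray, ry: np.ndarray, r_obs: float) -> float:
    perms = np.array(list(permutations(ry)))
    rx_c = rx - rx.mean()
    denom_x = math.sqrt(float(np.dot(rx_c, rx_c)))
    p_c = perms - perms.mean(axis=1, keepdims=True)
    denom_y = np.sqrt(np.einsum("ij,ij->i", p_c, p_c))
    r_all = (p_c @ rx_c) / (denom_x * denom_y)
    return float(np.mean(np.abs(r_all) >= abs(r_obs) - 1e-12))


# ---------------------------------------------------------------------------
# Correlation panel


def correlation_panel(
    features: pd.DataFrame,
    measures: pd.DataFrame,
    *,
    alpha: float = 0.05,
    bh_correction: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlate every texture feature with every accuracy measure.

    ``features``: one row per plan, columns keyed ``(feature, d)``.
    ``measures``: one row per plan, one column per accuracy measure.
    Returns the long-format panel (feature, d, measure, r, p, n,
    significant) and per-(feature, d) counts of significant correlations.
    Cells that fail significance are flagged, never dropped. Significance
    is raw p < alpha by default; ``bh_correction`` applies
    Benjamini-Hochberg across the whole panel instead.
    """
    shared = features.index.intersection(measures.index)
    if len(shared) < 3:
        raise CorrelationError(f"only {len(shared)} shared plans; need >= 3")
    feats = features.loc[shared]
    meas = measures.loc[shared]
    rows = []
    for col in feats.columns:
        fname, d = col if isinstance(col, tuple) else (col, None)
        for mname in meas.columns:
            res = spearman(feats[col].to_numpy(), meas[mname].to_numpy())
            rows.append(
                {
                    "feature": fname,
                    "d": d,
                    "measure": mname,
                    "r": res.r,
                    "p": res.p,
                    "n": res.n,
                }
            )
    panel = pd.DataFrame(rows)
    if bh_correction:
        panel["significant"] = _benjamini_hochberg(panel["p"].to_numpy(), alpha)
    else:
        panel["significant"] = panel["p"] < alpha
    counts = (
        panel.groupby(["feature", "d"])["significant"]
        .sum()
        .rename("n_significant")
        .reset_index()
    )
    return panel, counts


def _benjamini_hochberg(p: np.ndarray, alpha: float) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    thresh = alpha * (np.arange(1, m + 1)) / m
    passed = p[order] <= thresh
    k = np.max(np.nonzero(passed)[0]) + 1 if passed.any() else 0
    out = np.zeros(m, dtype=bool)
    out[order[:k]] = True
    return out
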