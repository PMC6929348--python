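"""Synthetic arc plans, machine logs and dose planes.

No clinical plan data ship with the package, so the correlation study runs
end-to-end on generated inputs that emulate its ingredients:

* arc plans whose leaf tips trace a smooth base aperture (an ellipse) plus
  a smoothed random perturbation whose amplitude sets the modulation
  degree — more perturbation means smaller, more irregular beam openings
  and hence a less homogeneous fluence map;
* delivery logs equal to the plan plus Gaussian mechanical noise on leaf
  positions, gantry angle and cumulative monitor units, optionally with
  leaf-position noise growing with leaf travel speed (fast leaves are
  harder to position);
* planar dose pairs standing in for a calculation/measurement pair:
  a blurred, rescaled fluence map as the reference, and a shifted, noisy
  copy as the measurement.

Every generator is a pure function of its spec, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, shift as nd_shift, uniform_filter1d

from texqa.delivery_accuracy import (
    DosePlane,
    GammaCriteria,
    MechanicalErrorSummary,
    average_summaries,
    correlation_panel,
    gamma_analysis,
    mechanical_errors,
)
from texqa.fluence import FluenceGrid, FluenceMap, crop_to_nonzero, integrate_fluence
from texqa.plan_model import (
    Beam,
    ControlPoint,
    DeliveryRecord,
    LeafGeometry,
    LogBeam,
    Plan,
    Snapshot,
    uniform_geometry,
    validate_plan,
)
from texqa.texture import TextureConfig, feature_panel

MU_TO_GY = 0.01  # synthetic dose scale: 1 MU-pixel = 1 cGy

LEAF_TRAVEL_LIMIT_MM = 200.0


@dataclass(frozen=True)
class SynthPlanSpec:
    """Recipe for one synthetic arc plan.

    ``modulation_amplitude_mm`` (sigma_m) is the standard deviation of the
    leaf-tip perturbation around the base ellipse;
    ``modulation_correlation`` is the moving-average window (in control
    points / leaf pairs) that smooths the perturbation, mimicking the low
    spatial frequency of clinically deliverable MLC trajectories.
    """

    n_control_points: int = 72
    geometry: LeafGeometry = field(default_factory=lambda: uniform_geometry(20, 5.0))
    semi_axis_x_mm: float = 30.0
    semi_axis_y_mm: float = 40.0
    modulation_amplitude_mm: float = 0.0
    modulation_correlation: int = 5
    total_mu: float = 400.0
    sinusoidal_mu: bool = False
    seed: int = 0
    plan_id: str = "synth"

    def __post_init__(self) -> None:
        if self.modulation_amplitude_mm < 0:
            raise ValueError("modulation amplitude must be >= 0")
        if self.n_control_points < 2:
            raise ValueError("need >= 2 control points")


@dataclass(frozen=True)
class SynthLogSpec:
    sigma_mlc_mm: float = 0.1
    sigma_gantry_deg: float = 0.1
    sigma_mu: float = 0.05
    mlc_error_coupling: float = 0.0  # extra noise per mm of per-CP leaf travel
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sigma_mlc_mm, self.sigma_gantry_deg, self.sigma_mu) < 0:
            raise ValueError("noise scales must be >= 0")


def generate_plan(spec: SynthPlanSpec) -> Plan:
    """Build a single-beam arc plan from a spec; seed-deterministic."""
    rng = np.random.default_rng(spec.seed)
    geom = spec.geometry
    bounds = np.asarray(geom.leaf_boundaries)
    yc = (bounds[:-1] + bounds[1:]) / 2.0
    a, b = spec.semi_axis_x_mm, spec.semi_axis_y_mm
    if a <= 0 or b <= 0:
        raise ValueError("ellipse semi-axes must be > 0")
    if a > LEAF_TRAVEL_LIMIT_MM:
        raise ValueError(
            f"aperture half-width {a} mm exceeds leaf travel range "
            f"({LEAF_TRAVEL_LIMIT_MM} mm)"
        )
    inside = np.abs(yc) < b
    half_width = np.where(inside, a * np.sqrt(np.clip(1 - (yc / b) ** 2, 0, None)), 0.0)

    n_cp, n_pairs = spec.n_control_points, geom.n_pairs
    base_a = np.tile(-half_width, (n_cp, 1))
    base_b = np.tile(half_width, (n_cp, 1))

    if spec.modulation_amplitude_mm > 0:
        noise = rng.standard_normal((2, n_cp, n_pairs))
        w = max(int(spec.modulation_correlation), 1)
        if w > 1:
            noise = uniform_filter1d(noise, size=w, axis=1, mode="nearest")
            noise = uniform_filter1d(noise, size=w, axis=2, mode="nearest")
        sd = noise.std()
        if sd > 0:
            noise = noise / sd * spec.modulation_amplitude_mm
        pert_a, pert_b = noise
        # perturb only rows the base aperture opens; keep closed rows closed
        pert_a[:, ~inside] = 0.0
        pert_b[:, ~inside] = 0.0
        new_a = base_a + pert_a
        new_b = base_b + pert_b
        crossed = new_a > new_b
        mid = (new_a + new_b) / 2.0
        new_a = np.where(crossed, mid, new_a)
        new_b = np.where(crossed, mid, new_b)
        base_a, base_b = new_a, new_b
    base_a = np.clip(base_a, -LEAF_TRAVEL_LIMIT_MM, LEAF_TRAVEL_LIMIT_MM)
    base_b = np.clip(base_b, -LEAF_TRAVEL_LIMIT_MM, LEAF_TRAVEL_LIMIT_MM)

    if spec.sinusoidal_mu:
        rates = 1.0 + 0.5 * np.sin(np.linspace(0, 4 * np.pi, n_cp - 1))
        weights = np.concatenate([[0.0], np.cumsum(rates)])
        weights = weights / weights[-1]
    else:
        weights = np.linspace(0.0, 1.0, n_cp)
    gantry = np.linspace(181.0, 179.0 + 360.0, n_cp) % 360.0  # one full arc

    cps = tuple(
        ControlPoint(
            index=k,
            cumulative_meterset_weight=float(weights[k]),
            gantry_angle=float(gantry[k]),
            bank_A=tuple(base_a[k]),
            bank_B=tuple(base_b[k]),
        )
        for k in range(n_cp)
    )
    plan = Plan(
        plan_id=spec.plan_id,
        beams=(Beam(control_points=cps, total_mu=spec.total_mu, geometry=geom, name="arc1"),),
    )
    assert not validate_plan(plan)
    return plan


def simulate_log(plan: Plan, spec: SynthLogSpec) -> DeliveryRecord:
    """Plan plus Gaussian mechanical noise, as a plan-shaped log record.

    With ``mlc_error_coupling`` > 0 the leaf-position noise scale grows
    linearly with the leaf's travel since the previous control point, so
    heavily modulated plans accrue larger recorded MLC errors. Cumulative
    MU noise is kept nondecreasing by a running maximum.
    """
    rng = np.random.default_rng(spec.seed)
    beams = []
    for beam in plan.beams:
        plan_a = np.array([c.bank_A for c in beam.control_points])
        plan_b = np.array([c.bank_B for c in beam.control_points])
        n_cp, n_pairs = plan_a.shape
        scale_a = np.full((n_cp, n_pairs), spec.sigma_mlc_mm)
        scale_b = scale_a.copy()
        if spec.mlc_error_coupling > 0:
            travel_a = np.abs(np.diff(plan_a, axis=0, prepend=plan_a[:1]))
            travel_b = np.abs(np.diff(plan_b, axis=0, prepend=plan_b[:1]))
            scale_a = scale_a + spec.mlc_error_coupling * travel_a
            scale_b = scale_b + spec.mlc_error_coupling * travel_b
        rec_a = plan_a + rng.standard_normal((n_cp, n_pairs)) * scale_a
        rec_b = plan_b + rng.standard_normal((n_cp, n_pairs)) * scale_b
        weights = np.array([c.cumulative_meterset_weight for c in beam.control_points])
        planned_mu = weights * beam.total_mu
        rec_mu = planned_mu + rng.standard_normal(n_cp) * spec.sigma_mu
        rec_mu = np.maximum.accumulate(rec_mu)
        gantry = np.array([c.gantry_angle for c in beam.control_points])
        rec_gantry = (gantry + rng.standard_normal(n_cp) * spec.sigma_gantry_deg) % 360.0
        snaps = tuple(
            Snapshot(
                index=k,
                cumulative_mu=float(rec_mu[k]),
                gantry_angle=float(rec_gantry[k]),
                bank_A=tuple(rec_a[k]),
                bank_B=tuple(rec_b[k]),
            )
            for k in range(n_cp)
        )
        beams.append(LogBeam(snapshots=snaps, geometry=beam.geometry, name=beam.name))
    return DeliveryRecord(plan_id=plan.plan_id, beams=tuple(beams))


def simulate_dose_planes(
    fmap: FluenceMap,
    blur_sigma_mm: float = 3.0,
    noise_percent: float = 1.0,
    shift_mm: float = 0.0,
    seed: int = 0,
) -> tuple[DosePlane, DosePlane]:
    """A reference/measured dose-plane pair derived from a fluence map.

    Reference: Gaussian-blurred fluence rescaled to Gy (1 MU-pixel =
    1 cGy). Measured: the reference shifted along x by ``shift_mm``
    (bilinear) with multiplicative Gaussian noise of ``noise_percent``.
    """
    if blur_sigma_mm < 0:
        raise ValueError("blur_sigma_mm must be >= 0")
    if not np.any(fmap.values > 0):
        raise ValueError("fluence map has no signal")
    rng = np.random.default_rng(seed)
    spacing = fmap.grid.spacing_mm
    ref = gaussian_filter(fmap.values, sigma=blur_sigma_mm / spacing) * MU_TO_GY
    meas = ref
    if shift_mm:
        meas = nd_shift(meas, (0.0, shift_mm / spacing), order=1, mode="constant", cval=0.0)
    if noise_percent > 0:
        meas = meas * (1.0 + rng.standard_normal(meas.shape) * noise_percent / 100.0)
    meas = np.clip(meas, 0.0, None)
    return DosePlane(fmap.grid, ref), DosePlane(fmap.grid, meas)


def _downsample(fmap: FluenceMap, factor: int) -> FluenceMap:
    """Block-average a fluence map by an integer factor (for coarser dose
    planes)."""
    if factor <= 1:
        return fmap
    v = fmap.values
    ny = (v.shape[0] // factor) * factor
    nx = (v.shape[1] // factor) * factor
    v = v[:ny, :nx].reshape(ny // factor, factor, nx // factor, factor).mean(axis=(1, 3))
    g = fmap.grid
    new_grid = FluenceGrid(
        spacing_mm=g.spacing_mm * factor,
        x_origin=g.x_origin + (factor - 1) * g.spacing_mm / 2,
        y_origin=g.y_origin + (factor - 1) * g.spacing_mm / 2,
        nx=v.shape[1],
        ny=v.shape[0],
    )
    return FluenceMap(new_grid, v)


DEFAULT_GAMMA_CRITERIA = (
    ("gamma_2_2", GammaCriteria(2.0, 2.0)),
    ("gamma_2_1", GammaCriteria(2.0, 1.0)),
    ("gamma_1_2", GammaCriteria(1.0, 2.0)),
    ("gamma_1_1", GammaCriteria(1.0, 1.0)),
)


@dataclass(frozen=True)
class StudyResult:
    features: pd.DataFrame  # plans x (feature, d)
    measures: pd.DataFrame  # plans x accuracy measures
    panel: pd.DataFrame  # long-format correlations
    counts: pd.DataFrame  # significant-correlation counts per (feature, d)


def run_study(
    n_plans: int = 40,
    sigma_grid: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0, 8.0),
    log_spec_rule: str = "coupled",
    seed: int = 0,
    *,
    n_sessions: int = 2,
    texture_cfg: TextureConfig | None = None,
    gamma_criteria=DEFAULT_GAMMA_CRITERIA,
    dose_spacing_mm: float = 2.0,
) -> StudyResult:
    """End-to-end feature-vs-accuracy correlation study on synthetic plans.

    Generates ``n_plans`` plans cycling through the modulation amplitudes
    in ``sigma_grid``, simulates ``n_sessions`` delivery logs per plan
    (averaged, as when a plan is delivered once per QA dosimeter) and a
    reference/measured dose-plane pair, computes the 18 texture features,
    gamma passing rates and mechanical errors, and correlates them.

    ``log_spec_rule``:
      * ``"coupled"`` — log noise and measurement degradation grow with
        the plan's modulation amplitude, emulating the clinical situation
        where heavily modulated plans are delivered less accurately;
      * ``"independent"`` — identical noise for every plan (a null study:
        accuracy carries no information about modulation).
    """
    if n_plans < 10:
        raise ValueError("need n_plans >= 10 for a meaningful correlation study")
    if log_spec_rule not in ("coupled", "independent"):
        raise ValueError(f"unknown log_spec_rule: {log_spec_rule!r}")
    cfg = texture_cfg or TextureConfig()
    children = np.random.SeedSequence(seed).spawn(n_plans)

    feat_rows = {}
    meas_rows = {}
    for p in range(n_plans):
        sigma_m = float(sigma_grid[p % len(sigma_grid)])
        sub = children[p].spawn(4)
        s_plan, s_log1, s_log2, s_dose = (int(s.generate_state(1)[0] % (2**31)) for s in sub)
        plan_id = f"plan{p:03d}"
        plan = generate_plan(
            SynthPlanSpec(
                modulation_amplitude_mm=sigma_m,
                seed=s_plan,
                plan_id=plan_id,
            )
        )
        feat_rows[plan_id] = feature_panel(plan, cfg)

        if log_spec_rule == "coupled":
            log_spec = SynthLogSpec(
                sigma_mlc_mm=0.02 + 0.05 * sigma_m,
                sigma_gantry_deg=0.05 + 0.02 * sigma_m,
                sigma_mu=0.02 + 0.01 * sigma_m,
                mlc_error_coupling=0.02,
            )
            noise_percent = 0.5 + 0.4 * sigma_m
            shift_mm = 0.2 + 0.1 * sigma_m
        else:
            log_spec = SynthLogSpec(
                sigma_mlc_mm=0.1, sigma_gantry_deg=0.1, sigma_mu=0.05
            )
            noise_percent = 1.0
            shift_mm = 0.3
        summaries = []
        for s_log in (s_log1, s_log2)[:n_sessions]:
            record = simulate_log(plan, replace(log_spec, seed=s_log))
            summaries.append(mechanical_errors(plan, record))
        mech = average_summaries(summaries)

        measures = {
            "mlc_error_mm": mech.mlc_error_mm,
            "gantry_error_deg": mech.gantry_error_deg,
            "mu_error": mech.mu_error,
        }
        if gamma_criteria:
            fmap = crop_to_nonzero(integrate_fluence(plan), margin_mm=5.0)
            factor = max(int(round(dose_spacing_mm / fmap.grid.spacing_mm)), 1)
            fmap_dose = _downsample(fmap, factor)
            ref, meas = simulate_dose_planes(
                fmap_dose,
                blur_sigma_mm=3.0,
                noise_percent=noise_percent,
                shift_mm=shift_mm,
                seed=s_dose,
            )
            for name, crit in gamma_criteria:
                measures[name] = gamma_analysis(ref, meas, crit).passing_rate
        meas_rows[plan_id] = measures

    features = pd.DataFrame.from_dict(feat_rows, orient="index")
    features.columns = pd.MultiIndex.from_tuples(features.columns, names=["feature", "d"])
    features.index.name = "plan_id"
    measures_df = pd.DataFrame.from_dict(meas_rows, orient="index")
    measures_df.index.name = "plan_id"
    measures_df.columns.name = "measure"
    panel, counts = correlation_panel(features, measures_df)
    return StudyResult(features=features, measures=measures_df, panel=panel, counts=counts)
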