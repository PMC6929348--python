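"""Domain types for VMAT plans, MLC geometry and delivery logs.

A plan is an ordered sequence of beams, each an ordered sequence of control
points carrying per-leaf MLC bank positions (mm at isocenter, IEC 61217
beam-limiting-device coordinates), the gantry angle and the cumulative
meterset weight (fraction of the beam's monitor units delivered so far).
A delivery record has the same shape but holds values the linac control
system actually recorded during delivery.

Two on-disk representations are supported: DICOM-RT Plan files (via
pydicom) and a versioned JSON fixture format that round-trips every field.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

JSON_SCHEMA_VERSION = 1

# Jaw positions default to a wide-open rectangle so clipping is a no-op
# when a file carries no jaw information.
DEFAULT_JAWS = (-200.0, 200.0, -200.0, 200.0)


class PlanFormatError(ValueError):
    """Raised when an input file is not a readable plan/log."""


class PlanInvariantError(ValueError):
    """Raised when plan content violates a structural invariant."""


@dataclass(frozen=True)
class LeafGeometry:
    """MLC leaf-pair geometry: leaf-edge coordinates along the axis
    orthogonal to leaf travel, in mm at the isocenter plane."""

    leaf_boundaries: tuple[float, ...]
    name: str = "custom"

    def __post_init__(self) -> None:
        b = np.asarray(self.leaf_boundaries, dtype=float)
        if b.size < 2:
            raise PlanInvariantError("leaf geometry needs at least 2 boundaries")
        if not np.all(np.diff(b) > 0):
            raise PlanInvariantError("leaf boundaries must be strictly increasing")
        object.__setattr__(self, "leaf_boundaries", tuple(float(v) for v in b))

    @property
    def n_pairs(self) -> int:
        return len(self.leaf_boundaries) - 1

    @property
    def widths(self) -> np.ndarray:
        return np.diff(np.asarray(self.leaf_boundaries))


def hd120() -> LeafGeometry:
    """HD 120 MLC: 32 central 2.5 mm pairs flanked by 14 pairs of 5 mm each."""
    edges = [-110.0 + 5.0 * i for i in range(15)]          # -110 .. -40
    edges += [-40.0 + 2.5 * i for i in range(1, 32)]       # -37.5 .. 37.5
    edges += [40.0 + 5.0 * i for i in range(15)]           # 40 .. 110
    return LeafGeometry(tuple(edges), name="hd120")


def millennium120() -> LeafGeometry:
    """Millennium 120 MLC: 40 central 5 mm pairs flanked by 10 pairs of 10 mm."""
    edges = [-200.0 + 10.0 * i for i in range(11)]         # -200 .. -100
    edges += [-100.0 + 5.0 * i for i in range(1, 40)]      # -95 .. 95
    edges += [100.0 + 10.0 * i for i in range(11)]         # 100 .. 200
    return LeafGeometry(tuple(edges), name="millennium120")


def uniform_geometry(n_pairs: int, width_mm: float, name: str = "uniform") -> LeafGeometry:
    half = n_pairs * width_mm / 2.0
    edges = tuple(-half + width_mm * i for i in range(n_pairs + 1))
    return LeafGeometry(edges, name=name)


_NAMED_GEOMETRIES = {"hd120": hd120, "millennium120": millennium120}


@dataclass(frozen=True)
class ControlPoint:
    """One snapshot of the planned delivery sequence."""

    index: int
    cumulative_meterset_weight: float
    gantry_angle: float
    bank_A: tuple[float, ...]  # left bank leaf tips, mm
    bank_B: tuple[float, ...]  # right bank leaf tips, mm
    jaws: tuple[float, float, float, float] = DEFAULT_JAWS

    def __post_init__(self) -> None:
        object.__setattr__(self, "bank_A", tuple(float(v) for v in self.bank_A))
        object.__setattr__(self, "bank_B", tuple(float(v) for v in self.bank_B))
        object.__setattr__(self, "jaws", tuple(float(v) for v in self.jaws))


@dataclass(frozen=True)
class Beam:
    control_points: tuple[ControlPoint, ...]
    total_mu: float
    geometry: LeafGeometry
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "control_points", tuple(self.control_points))


@dataclass(frozen=True)
class Plan:
    plan_id: str
    beams: tuple[Beam, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "beams", tuple(self.beams))


@dataclass(frozen=True)
class Snapshot:
    """One recorded snapshot from a machine log, aligned to a control point."""

    index: int
    cumulative_mu: float
    gantry_angle: float
    bank_A: tuple[float, ...]
    bank_B: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "bank_A", tuple(float(v) for v in self.bank_A))
        object.__setattr__(self, "bank_B", tuple(float(v) for v in self.bank_B))


@dataclass(frozen=True)
class LogBeam:
    snapshots: tuple[Snapshot, ...]
    geometry: LeafGeometry
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "snapshots", tuple(self.snapshots))


@dataclass(frozen=True)
class DeliveryRecord:
    plan_id: str
    beams: tuple[LogBeam, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "beams", tuple(self.beams))


# ---------------------------------------------------------------------------
# Validation


def validate_plan(plan: Plan) -> list[str]:
    """Check every structural invariant; return human-readable violations.

    Returns an empty list iff the plan is well formed. Never raises.
    """
    out: list[str] = []
    if not plan.beams:
        out.append("plan has no beams")
    for bi, beam in enumerate(plan.beams):
        tag = f"beam {bi}"
        if beam.total_mu <= 0:
            out.append(f"{tag}: total_mu must be > 0, got {beam.total_mu}")
        cps = beam.control_points
        if len(cps) < 2:
            out.append(f"{tag}: needs >= 2 control points, got {len(cps)}")
        n_pairs = beam.geometry.n_pairs
        prev_w = None
        for ci, cp in enumerate(cps):
            ctag = f"{tag} control point {ci}"
            if len(cp.bank_A) != n_pairs or len(cp.bank_B) != n_pairs:
                out.append(
                    f"{ctag}: bank lengths ({len(cp.bank_A)}, {len(cp.bank_B)}) "
                    f"!= n_pairs ({n_pairs})"
                )
            else:
                for i, (a, b) in enumerate(zip(cp.bank_A, cp.bank_B)):
                    if a > b:
                        out.append(f"{ctag}: leaf pair {i} crossed (A={a} > B={b})")
            w = cp.cumulative_meterset_weight
            if not (0.0 <= w <= 1.0 + 1e-12):
                out.append(f"{ctag}: cumulative weight {w} outside [0, 1]")
            if prev_w is not None and w < prev_w - 1e-12:
                out.append(f"{ctag}: cumulative weight decreases ({prev_w} -> {w})")
            prev_w = w
        if cps:
            if abs(cps[0].cumulative_meterset_weight) > 1e-9:
                out.append(f"{tag}: first cumulative weight must be 0")
            if abs(cps[-1].cumulative_meterset_weight - 1.0) > 1e-9:
                out.append(f"{tag}: last cumulative weight must be 1")
    return out


def validate_delivery_record(record: DeliveryRecord) -> list[str]:
    out: list[str] = []
    for bi, beam in enumerate(record.beams):
        prev = -math.inf
        for si, s in enumerate(beam.snapshots):
            if len(s.bank_A) != beam.geometry.n_pairs or len(s.bank_B) != beam.geometry.n_pairs:
                out.append(f"beam {bi} snapshot {si}: bank length != n_pairs")
            if s.cumulative_mu < prev - 1e-9:
                out.append(f"beam {bi} snapshot {si}: cumulative MU decreases")
            prev = s.cumulative_mu
    return out


# ---------------------------------------------------------------------------
# DICOM-RT Plan reading


def read_dicom_rtplan(path: str | Path) -> Plan:
    """Read a DICOM-RT Plan into a :class:`Plan`.

    Treatment beams only (setup beams are skipped). Control points that
    omit MLC positions, gantry angle or jaws inherit the previous control
    point's values, per DICOM-RT semantics; the first control point must
    carry them.
    """
    import pydicom

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    ds = pydicom.dcmread(str(path), force=True)
    sop = getattr(ds, "SOPClassUID", None)
    modality = getattr(ds, "Modality", None)
    if modality not in (None, "RTPLAN") and modality != "RTPLAN":
        raise PlanFormatError(f"{path}: not an RT Plan (Modality={modality})")
    if "BeamSequence" not in ds:
        raise PlanFormatError(f"{path}: no BeamSequence")
    _ = sop  # SOP class not enforced beyond modality; files in the wild vary

    beams: list[Beam] = []
    for beam_ds in ds.BeamSequence:
        if str(getattr(beam_ds, "TreatmentDeliveryType", "TREATMENT")) != "TREATMENT":
            continue
        geometry = _dicom_leaf_geometry(beam_ds)
        if geometry is None:
            continue  # beam without an MLC (e.g. static open field)
        total_mu = _dicom_beam_mu(ds, beam_ds)
        cps = _dicom_control_points(beam_ds, geometry)
        beams.append(
            Beam(
                control_points=tuple(cps),
                total_mu=total_mu,
                geometry=geometry,
                name=str(getattr(beam_ds, "BeamName", "")),
            )
        )
    plan = Plan(plan_id=str(getattr(ds, "RTPlanLabel", path.stem)), beams=tuple(beams))
    violations = validate_plan(plan)
    if violations:
        raise PlanInvariantError(f"{path}: " + "; ".join(violations[:5]))
    return plan


def _dicom_leaf_geometry(beam_ds) -> LeafGeometry | None:
    for dev in getattr(beam_ds, "BeamLimitingDeviceSequence", []):
        if str(dev.RTBeamLimitingDeviceType).startswith("MLC"):
            bounds = tuple(float(v) for v in dev.LeafPositionBoundaries)
            return LeafGeometry(bounds, name="dicom")
    return None


def _dicom_beam_mu(ds, beam_ds) -> float:
    beam_number = getattr(beam_ds, "BeamNumber", None)
    for fg in getattr(ds, "FractionGroupSequence", []):
        for rb in getattr(fg, "ReferencedBeamSequence", []):
            if getattr(rb, "ReferencedBeamNumber", None) == beam_number:
                mu = getattr(rb, "BeamMeterset", None)
                if mu is not None:
                    return float(mu)
    raise PlanFormatError(f"beam {beam_number}: no BeamMeterset in FractionGroupSequence")


def _dicom_control_points(beam_ds, geometry: LeafGeometry) -> list[ControlPoint]:
    n = geometry.n_pairs
    cps: list[ControlPoint] = []
    gantry = None
    bank_a: tuple[float, ...] | None = None
    bank_b: tuple[float, ...] | None = None
    jaws = DEFAULT_JAWS
    for idx, cp_ds in enumerate(beam_ds.ControlPointSequence):
        if hasattr(cp_ds, "GantryAngle"):
            gantry = float(cp_ds.GantryAngle)
        new_jaws = list(jaws)
        for bld in getattr(cp_ds, "BeamLimitingDevicePositionSequence", []):
            kind = str(bld.RTBeamLimitingDeviceType)
            pos = [float(v) for v in bld.LeafJawPositions]
            if kind.startswith("MLC"):
                if len(pos) != 2 * n:
                    raise PlanFormatError(
                        f"control point {idx}: {len(pos)} MLC positions, expected {2 * n}"
                    )
                bank_a = tuple(pos[:n])
                bank_b = tuple(pos[n:])
            elif kind in ("X", "ASYMX"):
                new_jaws[0], new_jaws[1] = pos[0], pos[1]
            elif kind in ("Y", "ASYMY"):
                new_jaws[2], new_jaws[3] = pos[0], pos[1]
        jaws = tuple(new_jaws)  # type: ignore[assignment]
        if bank_a is None or bank_b is None:
            raise PlanFormatError(f"control point {idx}: first control point lacks MLC positions")
        if gantry is None:
            raise PlanFormatError(f"control point {idx}: first control point lacks gantry angle")
        cps.append(
            ControlPoint(
                index=idx,
                cumulative_meterset_weight=float(cp_ds.CumulativeMetersetWeight),
                gantry_angle=gantry,
                bank_A=bank_a,
                bank_B=bank_b,
                jaws=jaws,  # type: ignore[arg-type]
            )
        )
    # normalize cumulative weights to [0, 1] (DICOM allows a final weight
    # equal to FinalCumulativeMetersetWeight, not necessarily 1)
    final = float(getattr(beam_ds, "FinalCumulativeMetersetWeight", 0.0) or 0.0)
    if final <= 0 and cps:
        final = cps[-1].cumulative_meterset_weight
    if final > 0 and abs(final - 1.0) > 1e-9:
        cps = [
            ControlPoint(
                index=c.index,
                cumulative_meterset_weight=c.cumulative_meterset_weight / final,
                gantry_angle=c.gantry_angle,
                bank_A=c.bank_A,
                bank_B=c.bank_B,
                jaws=c.jaws,
            )
            for c in cps
        ]
    return cps


# ---------------------------------------------------------------------------
# JSON fixture format


def _geometry_to_json(g: LeafGeometry) -> dict:
    return {"name": g.name, "leaf_boundaries": list(g.leaf_boundaries)}


def _geometry_from_json(obj: dict, where: str) -> LeafGeometry:
    _require(obj, "leaf_boundaries", where)
    return LeafGeometry(tuple(obj["leaf_boundaries"]), name=obj.get("name", "custom"))


def _require(obj: dict, key: str, where: str):
    if key not in obj:
        raise PlanFormatError(f"schema error at {where}: missing '{key}'")
    return obj[key]


def write_plan_json(plan: Plan, path: str | Path) -> None:
    """Serialize a plan to the versioned JSON fixture format."""
    doc = {
        "schema_version": JSON_SCHEMA_VERSION,
        "kind": "plan",
        "plan_id": plan.plan_id,
        "beams": [
            {
                "name": b.name,
                "total_mu": b.total_mu,
                "geometry": _geometry_to_json(b.geometry),
                "control_points": [
                    {
                        "index": c.index,
                        "cumulative_meterset_weight": c.cumulative_meterset_weight,
                        "gantry_angle": c.gantry_angle,
                        "bank_A": list(c.bank_A),
                        "bank_B": list(c.bank_B),
                        "jaws": list(c.jaws),
                    }
                    for c in b.control_points
                ],
            }
            for b in plan.beams
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def read_plan_json(path: str | Path) -> Plan:
    """Read a plan from the JSON fixture format, validating invariants."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise PlanFormatError(f"{path}: not valid JSON ({e})") from e
    beams_json = _require(doc, "beams", "$")
    beams = []
    for bi, bj in enumerate(beams_json):
        where = f"$.beams[{bi}]"
        geometry = _geometry_from_json(_require(bj, "geometry", where), where + ".geometry")
        cps = []
        for ci, cj in enumerate(_require(bj, "control_points", where)):
            cwhere = f"{where}.control_points[{ci}]"
            a = _require(cj, "bank_A", cwhere)
            b = _require(cj, "bank_B", cwhere)
            for i, (ai, bi_) in enumerate(zip(a, b)):
                if ai > bi_:
                    raise PlanInvariantError(
                        f"{cwhere}: leaf pair {i} crossed (bank_A[{i}]={ai} > bank_B[{i}]={bi_})"
                    )
            cps.append(
                ControlPoint(
                    index=cj.get("index", ci),
                    cumulative_meterset_weight=_require(
                        cj, "cumulative_meterset_weight", cwhere
                    ),
                    gantry_angle=_require(cj, "gantry_angle", cwhere),
                    bank_A=tuple(a),
                    bank_B=tuple(b),
                    jaws=tuple(cj.get("jaws", DEFAULT_JAWS)),
                )
            )
        beams.append(
            Beam(
                control_points=tuple(cps),
                total_mu=_require(bj, "total_mu", where),
                geometry=geometry,
                name=bj.get("name", ""),
            )
        )
    plan = Plan(plan_id=_require(doc, "plan_id", "$"), beams=tuple(beams))
    violations = validate_plan(plan)
    if violations:
        raise PlanInvariantError(f"{path}: " + "; ".join(violations[:5]))
    return plan


def write_delivery_json(record: DeliveryRecord, path: str | Path) -> None:
    doc = {
        "schema_version": JSON_SCHEMA_VERSION,
        "kind": "delivery_record",
        "plan_id": record.plan_id,
        "beams": [
            {
                "name": b.name,
                "geometry": _geometry_to_json(b.geometry),
                "snapshots": [
                    {
                        "index": s.index,
                        "cumulative_mu": s.cumulative_mu,
                        "gantry_angle": s.gantry_angle,
                        "bank_A": list(s.bank_A),
                        "bank_B": list(s.bank_B),
                    }
                    for s in b.snapshots
                ],
            }
            for b in record.beams
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def read_delivery_json(path: str | Path) -> DeliveryRecord:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    doc = json.loads(path.read_text())
    beams = []
    for bi, bj in enumerate(_require(doc, "beams", "$")):
        where = f"$.beams[{bi}]"
        geometry = _geometry_from_json(_require(bj, "geometry", where), where + ".geometry")
        snaps = tuple(
            Snapshot(
                index=sj.get("index", si),
                cumulative_mu=_require(sj, "cumulative_mu", f"{where}.snapshots[{si}]"),
                gantry_angle=_require(sj, "gantry_angle", f"{where}.snapshots[{si}]"),
                bank_A=tuple(_require(sj, "bank_A", f"{where}.snapshots[{si}]")),
                bank_B=tuple(_require(sj, "bank_B", f"{where}.snapshots[{si}]")),
            )
            for si, sj in enumerate(_require(bj, "snapshots", where))
        )
        beams.append(LogBeam(snapshots=snaps, geometry=geometry, name=bj.get("name", "")))
    record = DeliveryRecord(plan_id=_require(doc, "plan_id", "$"), beams=tuple(beams))
    violations = validate_delivery_record(record)
    if violations:
        raise PlanInvariantError(f"{path}: " + "; ".join(violations[:5]))
    return record
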