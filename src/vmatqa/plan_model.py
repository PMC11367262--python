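"""Domain model for VMAT plans and the shared aperture-geometry kernel.

A VMAT arc is an ordered sequence of control points, each a snapshot of the
machine state: gantry angle, cumulative meterset weight (fraction of the
beam's monitor units delivered so far), the two multileaf-collimator (MLC)
bank positions, and the jaw window.  Every complexity metric in this package
is a function of the aperture geometry exposed at each control point, so the
geometry is computed once, vectorized over control points, and cached.

Coordinates follow IEC 61217 at the isocenter plane, in millimetres.  Bank A
holds the left leaf tips (smaller x), bank B the right ones; an open leaf
pair exposes the interval [A_i, B_i] inside the jaw-x window over the y-strip
between two consecutive leaf boundaries.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .errors import UnsupportedBeamError, ValidationError

#: Leaf pairs with a clipped gap at or below this value (mm) are treated as
#: closed; suppresses the dosimetrically irrelevant gap of "closed" leaf
#: pairs parked with a sub-millimetre opening.
DEFAULT_MIN_GAP = 0.5

_RTPLAN_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.5"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ControlPoint:
    """One sampled machine state along an arc."""

    index: int
    gantry_angle: float
    cumulative_meterset_weight: float
    bank_a_positions: np.ndarray
    bank_b_positions: np.ndarray
    jaw_x: tuple[float, float]
    jaw_y: tuple[float, float]
    dose_rate: float | None = None

    def __post_init__(self) -> None:
        self.bank_a_positions = np.asarray(self.bank_a_positions, dtype=float)
        self.bank_b_positions = np.asarray(self.bank_b_positions, dtype=float)

    def validate(self) -> None:
        a, b = self.bank_a_positions, self.bank_b_positions
        if a.shape != b.shape or a.ndim != 1:
            raise ValidationError(
                f"control point {self.index}: bank shapes differ ({a.shape} vs {b.shape})"
            )
        if np.any(b < a - 1e-9):
            raise ValidationError(
                f"control point {self.index}: bank B position below bank A"
            )
        if not 0.0 <= self.cumulative_meterset_weight <= 1.0 + 1e-9:
            raise ValidationError(
                f"control point {self.index}: meterset weight outside [0, 1]"
            )
        if self.jaw_x[1] <= self.jaw_x[0] or self.jaw_y[1] <= self.jaw_y[0]:
            raise ValidationError(f"control point {self.index}: degenerate jaw window")


@dataclass
class Arc:
    """A single VMAT beam: the unit on which metrics and flags are defined."""

    beam_id: str
    machine: str
    energy: str
    total_mu: float
    control_points: list[ControlPoint]
    leaf_boundaries: np.ndarray
    treatment_site: str = ""

    def __post_init__(self) -> None:
        self.leaf_boundaries = np.asarray(self.leaf_boundaries, dtype=float)

    @property
    def n_control_points(self) -> int:
        return len(self.control_points)

    @property
    def n_leaf_pairs(self) -> int:
        return len(self.leaf_boundaries) - 1

    def validate(self) -> None:
        if len(self.control_points) < 2:
            raise ValidationError(f"arc {self.beam_id}: fewer than 2 control points")
        if self.total_mu <= 0:
            raise ValidationError(f"arc {self.beam_id}: total MU must be positive")
        if np.any(np.diff(self.leaf_boundaries) <= 0):
            raise ValidationError(
                f"arc {self.beam_id}: leaf boundaries not strictly increasing"
            )
        n_pairs = self.n_leaf_pairs
        weights = []
        for cp in self.control_points:
            cp.validate()
            if len(cp.bank_a_positions) != n_pairs:
                raise ValidationError(
                    f"arc {self.beam_id}: control point {cp.index} has "
                    f"{len(cp.bank_a_positions)} leaf pairs, expected {n_pairs}"
                )
            weights.append(cp.cumulative_meterset_weight)
        w = np.asarray(weights)
        if np.any(np.diff(w) < -1e-9):
            raise ValidationError(f"arc {self.beam_id}: meterset weights decrease")
        if abs(w[0]) > 1e-6 or abs(w[-1] - 1.0) > 1e-6:
            raise ValidationError(
                f"arc {self.beam_id}: meterset weights must run from 0 to 1 "
                f"(got {w[0]:g}..{w[-1]:g})"
            )

    def meterset_weights(self) -> np.ndarray:
        return np.array([cp.cumulative_meterset_weight for cp in self.control_points])

    def gantry_angles(self) -> np.ndarray:
        return np.array([cp.gantry_angle for cp in self.control_points])


@dataclass
class Plan:
    """A treatment plan: one or more arcs sharing a treatment site."""

    plan_id: str
    arcs: list[Arc]
    treatment_site: str
    approval_timestamp: _dt.datetime = field(
        default_factory=lambda: _dt.datetime(2000, 1, 1)
    )

    def validate(self) -> None:
        if not self.arcs:
            raise ValidationError(f"plan {self.plan_id}: no arcs")
        for arc in self.arcs:
            arc.validate()
            if arc.treatment_site and arc.treatment_site != self.treatment_site:
                raise ValidationError(
                    f"plan {self.plan_id}: arc {arc.beam_id} site "
                    f"{arc.treatment_site!r} differs from plan site "
                    f"{self.treatment_site!r}"
                )


@dataclass
class ApertureGeometry:
    """Geometry of the open aperture at one control point, after jaw clipping."""

    open_gaps: list[tuple[int, float]]
    open_area: float
    perimeter: float
    side_edge_length: float
    cap_edge_length: float
    exposed_lo: np.ndarray
    exposed_hi: np.ndarray
    open_mask: np.ndarray
    strip_widths: np.ndarray


# ---------------------------------------------------------------------------
# Geometry kernel
# ---------------------------------------------------------------------------

def _geometry_arrays(
    bank_a: np.ndarray,
    bank_b: np.ndarray,
    jaw_x: np.ndarray,
    jaw_y: np.ndarray,
    boundaries: np.ndarray,
    min_gap: float,
) -> dict[str, np.ndarray]:
    """Vectorized aperture geometry for K control points at once.

    Parameters are (K, N) leaf arrays, (K, 2) jaw arrays and the N+1 leaf
    boundaries.  Returns per-control-point areas, perimeters and edge
    lengths plus the per-pair exposed intervals used by downstream metrics.

    The open region at a control point is a union of axis-aligned rectangles,
    one per open leaf pair, stacked along y.  Its boundary decomposes into
    vertical leaf-end faces (two per open pair, each the strip width), and
    horizontal faces along strip boundaries given by the symmetric difference
    of the exposed intervals of the two adjacent strips (a closed strip
    contributes an empty interval, so run ends produce full "cap" edges).
    """
    lo = np.maximum(bank_a, jaw_x[:, :1])            # (K, N) exposed interval
    hi = np.minimum(bank_b, jaw_x[:, 1:])
    gap = np.clip(hi - lo, 0.0, None)

    y_lo = np.maximum(boundaries[:-1][None, :], jaw_y[:, :1])
    y_hi = np.minimum(boundaries[1:][None, :], jaw_y[:, 1:])
    width = np.clip(y_hi - y_lo, 0.0, None)          # (K, N) strip widths

    open_mask = (gap > min_gap) & (width > 0)
    gap = np.where(open_mask, gap, 0.0)
    lo = np.where(open_mask, lo, 0.0)
    hi = np.where(open_mask, hi, 0.0)

    area = np.sum(gap * width, axis=1)

    # Horizontal edges between consecutive strips: |I_i symdiff I_{i+1}|.
    inter = np.clip(
        np.minimum(hi[:, :-1], hi[:, 1:]) - np.maximum(lo[:, :-1], lo[:, 1:]),
        0.0,
        None,
    )
    both_open = open_mask[:, :-1] & open_mask[:, 1:]
    symdiff = np.where(both_open, gap[:, :-1] + gap[:, 1:] - 2.0 * inter, 0.0)
    side_edge = np.sum(symdiff, axis=1)

    one_open = open_mask[:, :-1] ^ open_mask[:, 1:]
    inner_caps = np.where(one_open, gap[:, :-1] + gap[:, 1:], 0.0).sum(axis=1)
    outer_caps = np.where(open_mask[:, 0], gap[:, 0], 0.0) + np.where(
        open_mask[:, -1], gap[:, -1], 0.0
    )
    cap_edge = inner_caps + outer_caps

    perimeter = 2.0 * np.sum(width * open_mask, axis=1) + side_edge + cap_edge

    return {
        "lo": lo,
        "hi": hi,
        "gap": gap,
        "width": width,
        "open": open_mask,
        "area": area,
        "perimeter": perimeter,
        "side_edge": side_edge,
        "cap_edge": cap_edge,
    }


def arc_geometry(arc: Arc, min_gap: float = DEFAULT_MIN_GAP) -> dict[str, np.ndarray]:
    """Aperture geometry arrays for every control point of *arc*."""
    cps = arc.control_points
    bank_a = np.stack([cp.bank_a_positions for cp in cps])
    bank_b = np.stack([cp.bank_b_positions for cp in cps])
    jaw_x = np.array([cp.jaw_x for cp in cps], dtype=float)
    jaw_y = np.array([cp.jaw_y for cp in cps], dtype=float)
    return _geometry_arrays(bank_a, bank_b, jaw_x, jaw_y, arc.leaf_boundaries, min_gap)


def aperture_geometry(
    cp: ControlPoint,
    boundaries: Sequence[float] | np.ndarray,
    min_gap: float = DEFAULT_MIN_GAP,
) -> ApertureGeometry:
    """Clipped aperture geometry of a single control point."""
    boundaries = np.asarray(boundaries, dtype=float)
    g = _geometry_arrays(
        cp.bank_a_positions[None, :],
        cp.bank_b_positions[None, :],
        np.array([cp.jaw_x], dtype=float),
        np.array([cp.jaw_y], dtype=float),
        boundaries,
        min_gap,
    )
    open_idx = np.nonzero(g["open"][0])[0]
    return ApertureGeometry(
        open_gaps=[(int(i), float(g["gap"][0, i])) for i in open_idx],
        open_area=float(g["area"][0]),
        perimeter=float(g["perimeter"][0]),
        side_edge_length=float(g["side_edge"][0]),
        cap_edge_length=float(g["cap_edge"][0]),
        exposed_lo=g["lo"][0],
        exposed_hi=g["hi"][0],
        open_mask=g["open"][0],
        strip_widths=g["width"][0],
    )


def control_point_table(arc: Arc) -> pd.DataFrame:
    """Flat per-(control point, leaf pair) table, for debugging/CSV export."""
    rows = []
    for cp in arc.control_points:
        for i in range(arc.n_leaf_pairs):
            rows.append(
                {
                    "cp_index": cp.index,
                    "gantry_angle": cp.gantry_angle,
                    "cum_weight": cp.cumulative_meterset_weight,
                    "pair": i,
                    "bank_a": cp.bank_a_positions[i],
                    "bank_b": cp.bank_b_positions[i],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# DICOM RTPLAN IO
# ---------------------------------------------------------------------------

def write_rtplan(plan: Plan, path) -> None:
    """Write *plan* as a DICOM RT Plan readable by :func:`read_rtplan`.

    Refuses to write a plan violating the domain invariants.
    """
    plan.validate()

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = _RTPLAN_SOP_CLASS
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = _RTPLAN_SOP_CLASS
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTPLAN"
    ds.PatientName = "QA^Synthetic"
    ds.PatientID = plan.plan_id
    ds.RTPlanLabel = plan.plan_id
    ds.RTPlanDescription = plan.treatment_site
    ds.RTPlanDate = plan.approval_timestamp.strftime("%Y%m%d")
    ds.RTPlanTime = plan.approval_timestamp.strftime("%H%M%S")
    ds.RTPlanGeometry = "TREATMENT_DEVICE"

    frac = Dataset()
    frac.FractionGroupNumber = 1
    frac.NumberOfFractionsPlanned = 1
    frac.NumberOfBeams = len(plan.arcs)
    frac.ReferencedBeamSequence = []
    ds.FractionGroupSequence = [frac]

    ds.BeamSequence = []
    for beam_number, arc in enumerate(plan.arcs, start=1):
        ref = Dataset()
        ref.ReferencedBeamNumber = beam_number
        ref.BeamMeterset = arc.total_mu
        frac.ReferencedBeamSequence.append(ref)

        beam = Dataset()
        beam.BeamNumber = beam_number
        beam.BeamName = arc.beam_id
        beam.BeamType = "DYNAMIC"
        beam.RadiationType = "PHOTON"
        beam.TreatmentDeliveryType = "TREATMENT"
        beam.TreatmentMachineName = arc.machine
        beam.NumberOfControlPoints = arc.n_control_points
        beam.FinalCumulativeMetersetWeight = 1.0

        bld_x = Dataset()
        bld_x.RTBeamLimitingDeviceType = "ASYMX"
        bld_x.NumberOfLeafJawPairs = 1
        bld_y = Dataset()
        bld_y.RTBeamLimitingDeviceType = "ASYMY"
        bld_y.NumberOfLeafJawPairs = 1
        bld_mlc = Dataset()
        bld_mlc.RTBeamLimitingDeviceType = "MLCX"
        bld_mlc.NumberOfLeafJawPairs = arc.n_leaf_pairs
        bld_mlc.LeafPositionBoundaries = [float(b) for b in arc.leaf_boundaries]
        beam.BeamLimitingDeviceSequence = [bld_x, bld_y, bld_mlc]

        beam.ControlPointSequence = []
        for cp in arc.control_points:
            item = Dataset()
            item.ControlPointIndex = cp.index
            item.GantryAngle = cp.gantry_angle
            item.GantryRotationDirection = "CC"
            item.CumulativeMetersetWeight = cp.cumulative_meterset_weight
            if cp.index == 0:
                item.NominalBeamEnergy = _energy_mv(arc.energy)
            if cp.dose_rate is not None:
                item.DoseRateSet = cp.dose_rate
            pos_x = Dataset()
            pos_x.RTBeamLimitingDeviceType = "ASYMX"
            pos_x.LeafJawPositions = [float(cp.jaw_x[0]), float(cp.jaw_x[1])]
            pos_y = Dataset()
            pos_y.RTBeamLimitingDeviceType = "ASYMY"
            pos_y.LeafJawPositions = [float(cp.jaw_y[0]), float(cp.jaw_y[1])]
            pos_mlc = Dataset()
            pos_mlc.RTBeamLimitingDeviceType = "MLCX"
            pos_mlc.LeafJawPositions = [
                float(x) for x in cp.bank_a_positions
            ] + [float(x) for x in cp.bank_b_positions]
            item.BeamLimitingDevicePositionSequence = [pos_x, pos_y, pos_mlc]
            beam.ControlPointSequence.append(item)

        ds.BeamSequence.append(beam)

    ds.save_as(str(path), enforce_file_format=True)


def _energy_mv(energy: str) -> float:
    digits = "".join(c for c in str(energy) if c.isdigit() or c == ".")
    try:
        return float(digits)
    except ValueError:
        return 6.0


def read_rtplan(path) -> Plan:
    """Read a DICOM RT Plan into a :class:`Plan`.

    One :class:`Arc` is produced per non-setup beam.  Cumulative meterset
    weights are re-normalized to [0, 1]; jaw and MLC positions omitted at
    later control points (the DICOM "only what changed" convention) are
    carried forward from the previous control point.

    Raises :class:`UnsupportedBeamError` for beams without an MLC
    control-point sequence or that are not dynamic arcs, and
    :class:`ValidationError` for non-monotone meterset weights.
    """
    ds = pydicom.dcmread(str(path), force=True)
    if "BeamSequence" not in ds:
        raise UnsupportedBeamError(f"{path}: no BeamSequence")

    mu_by_beam: dict[int, float] = {}
    for frac in getattr(ds, "FractionGroupSequence", []):
        for ref in getattr(frac, "ReferencedBeamSequence", []):
            if "BeamMeterset" in ref:
                mu_by_beam[int(ref.ReferencedBeamNumber)] = float(ref.BeamMeterset)

    site = str(getattr(ds, "RTPlanDescription", "") or "")
    plan_id = str(getattr(ds, "RTPlanLabel", "") or getattr(ds, "PatientID", "plan"))
    try:
        stamp = _dt.datetime.strptime(
            str(getattr(ds, "RTPlanDate", "20000101"))
            + str(getattr(ds, "RTPlanTime", "000000"))[:6],
            "%Y%m%d%H%M%S",
        )
    except ValueError:
        stamp = _dt.datetime(2000, 1, 1)

    arcs = []
    for beam in ds.BeamSequence:
        if str(getattr(beam, "TreatmentDeliveryType", "TREATMENT")) == "SETUP":
            continue
        name = str(getattr(beam, "BeamName", getattr(beam, "BeamNumber", "?")))
        if "ControlPointSequence" not in beam:
            raise UnsupportedBeamError(f"beam {name}: no ControlPointSequence")
        if str(getattr(beam, "BeamType", "")) != "DYNAMIC":
            raise UnsupportedBeamError(
                f"beam {name}: only dynamic VMAT beams are supported "
                f"(BeamType={getattr(beam, 'BeamType', None)!r})"
            )

        boundaries = None
        for bld in getattr(beam, "BeamLimitingDeviceSequence", []):
            if str(bld.RTBeamLimitingDeviceType).startswith("MLC"):
                boundaries = np.asarray(bld.LeafPositionBoundaries, dtype=float)
        if boundaries is None:
            raise UnsupportedBeamError(f"beam {name}: no MLC leaf boundaries")
        n_pairs = len(boundaries) - 1

        energy = "6"
        jaw_x = jaw_y = None
        mlc = None
        cps: list[ControlPoint] = []
        gantry = 0.0
        dose_rate = None
        for k, item in enumerate(beam.ControlPointSequence):
            if "NominalBeamEnergy" in item:
                energy = f"{float(item.NominalBeamEnergy):g}"
            if "GantryAngle" in item:
                gantry = float(item.GantryAngle)
            if "DoseRateSet" in item:
                dose_rate = float(item.DoseRateSet)
            for pos in getattr(item, "BeamLimitingDevicePositionSequence", []):
                kind = str(pos.RTBeamLimitingDeviceType)
                vals = np.asarray(pos.LeafJawPositions, dtype=float)
                if kind in ("ASYMX", "X"):
                    jaw_x = (float(vals[0]), float(vals[1]))
                elif kind in ("ASYMY", "Y"):
                    jaw_y = (float(vals[0]), float(vals[1]))
                elif kind.startswith("MLC"):
                    mlc = vals
            if mlc is None:
                raise UnsupportedBeamError(
                    f"beam {name}: control point {k} has no MLC positions"
                )
            if jaw_x is None or jaw_y is None:
                raise UnsupportedBeamError(f"beam {name}: missing jaw positions")
            if len(mlc) != 2 * n_pairs:
                raise ValidationError(
                    f"beam {name}: MLC position count {len(mlc)} does not match "
                    f"{n_pairs} leaf pairs"
                )
            cps.append(
                ControlPoint(
                    index=k,
                    gantry_angle=gantry,
                    cumulative_meterset_weight=float(item.CumulativeMetersetWeight),
                    bank_a_positions=mlc[:n_pairs].copy(),
                    bank_b_positions=mlc[n_pairs:].copy(),
                    jaw_x=jaw_x,
                    jaw_y=jaw_y,
                    dose_rate=dose_rate,
                )
            )

        weights = np.array([cp.cumulative_meterset_weight for cp in cps])
        if np.any(np.diff(weights) < -1e-9):
            raise ValidationError(f"beam {name}: meterset weights are not monotone")
        final = float(getattr(beam, "FinalCumulativeMetersetWeight", weights[-1]))
        if final <= 0:
            raise ValidationError(f"beam {name}: final cumulative meterset <= 0")
        lo = weights[0]
        span = weights[-1] - lo
        if span <= 0:
            raise ValidationError(f"beam {name}: zero meterset span")
        for cp, w in zip(cps, (weights - lo) / span):
            cp.cumulative_meterset_weight = float(w)

        beam_number = int(getattr(beam, "BeamNumber", len(arcs) + 1))
        arcs.append(
            Arc(
                beam_id=name,
                machine=str(getattr(beam, "TreatmentMachineName", "")),
                energy=energy,
                total_mu=mu_by_beam.get(beam_number, 100.0),
                control_points=cps,
                leaf_boundaries=boundaries,
                treatment_site=site,
            )
        )

    plan = Plan(plan_id=plan_id, arcs=arcs, treatment_site=site, approval_timestamp=stamp)
    plan.validate()
    return plan
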